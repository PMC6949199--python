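"""Forward attenuation physics and phantom calibration.

The contrast agents attenuate X-rays in proportion to their local
concentration (Beer-Lambert law with Bragg additivity), so the reconstructed
attenuation of a voxel containing iodine (CA4+), gadolinium (gadoteridol)
and, in the bath, bismuth nanoparticles is

    alpha_E = b_E + mu_I,E * C_I + mu_Gd,E * C_Gd + mu_Bi,E * C_Bi

where ``mu_X,E`` is the mass-attenuation coefficient of element X at beam
energy E (per mg/mL, in reconstructed attenuation units) and ``b_E`` the
solvent background.  The two beam energies, 32 and 34 keV, straddle the
iodine k-edge (33.2 keV) and both lie below the gadolinium k-edge
(50.3 keV); this ordering makes the 2x2 decomposition well conditioned.

Coefficients are calibrated as least-squares slopes of mean attenuation
against concentration over single-agent dilution phantoms.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import DegenerateFitError, IllConditionedCalibrationError, PhysicsViolationWarning

IODINE_K_EDGE_KEV = 33.2
GADOLINIUM_K_EDGE_KEV = 50.3

#: Default conditioning floor for |det| of the coefficient matrix.
DEFAULT_CONDITIONING_FLOOR = 1e-6


@dataclass(frozen=True)
class BeamEnergy:
    """Monochromatic beam energy in keV."""

    value: float

    def __post_init__(self):
        if not self.value > 0:
            raise ValueError(f"beam energy must be positive, got {self.value}")


def validate_energy_pair(low: float, high: float) -> None:
    """Check that two energies bracket the iodine k-edge and avoid gadolinium's.

    Raises ``ValueError`` if the pair cannot separate iodine from gadolinium.
    """
    lo, hi = sorted((float(low), float(high)))
    BeamEnergy(lo), BeamEnergy(hi)
    if not (lo < IODINE_K_EDGE_KEV < hi):
        raise ValueError(
            f"energies ({lo}, {hi}) keV must straddle the iodine k-edge "
            f"({IODINE_K_EDGE_KEV} keV)"
        )
    if hi >= GADOLINIUM_K_EDGE_KEV:
        raise ValueError(
            f"both energies must lie below the gadolinium k-edge "
            f"({GADOLINIUM_K_EDGE_KEV} keV); got {hi}"
        )


@dataclass
class PhantomSeries:
    """Single-agent dilution series measured at one energy.

    Parameters
    ----------
    agent : str
        ``"CA4+"`` or ``"gadoteridol"`` (or ``"BiNP"`` for the bath agent).
    energy_kev : float
        Beam energy of the measurements.
    concentrations : array
        Elemental concentrations in mg/mL (>= 0).
    attenuations : array
        Mean reconstructed attenuation of each phantom.
    """

    agent: str
    energy_kev: float
    concentrations: np.ndarray
    attenuations: np.ndarray

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.attenuations = np.asarray(self.attenuations, dtype=float)
        if self.concentrations.shape != self.attenuations.shape:
            raise ValueError("concentration and attenuation arrays differ in length")
        if np.any(self.concentrations < 0):
            raise ValueError("phantom concentrations must be non-negative")


@dataclass
class CoefficientMatrix:
    """Calibrated mass-attenuation coefficients of the two solvable agents.

    Slopes are attenuation-units per mg/mL; intercepts are the solvent
    background at each energy.  The determinant

        D = mu_i_34 * mu_gd_32 - mu_i_32 * mu_gd_34

    must be non-zero for the decomposition to exist; with physically ordered
    coefficients (iodine jumps up across its k-edge, gadolinium decreases
    with energy below its k-edge) D is strictly positive.
    """

    mu_i_32: float
    mu_i_34: float
    mu_gd_32: float
    mu_gd_34: float
    b_32: float = 0.0
    b_34: float = 0.0

    @property
    def determinant(self) -> float:
        return self.mu_i_34 * self.mu_gd_32 - self.mu_i_32 * self.mu_gd_34

    def _idx(self, energy_kev: float) -> str:
        for tag, e in (("32", 32.0), ("34", 34.0)):
            if abs(float(energy_kev) - e) < 0.5:
                return tag
        raise KeyError(f"no calibrated coefficients at {energy_kev} keV")

    def mu_iodine(self, energy_kev: float) -> float:
        return getattr(self, f"mu_i_{self._idx(energy_kev)}")

    def mu_gadolinium(self, energy_kev: float) -> float:
        return getattr(self, f"mu_gd_{self._idx(energy_kev)}")

    def intercept(self, energy_kev: float) -> float:
        return getattr(self, f"b_{self._idx(energy_kev)}")

    def require_conditioning(self, floor: float = DEFAULT_CONDITIONING_FLOOR) -> None:
        if abs(self.determinant) < floor:
            raise IllConditionedCalibrationError(
                f"|det| = {abs(self.determinant):.3g} below conditioning floor {floor:.3g}"
            )

    def to_json(self, path=None, diagnostics: dict | None = None) -> str:
        doc = asdict(self)
        doc["determinant"] = self.determinant
        if diagnostics:
            doc["diagnostics"] = diagnostics
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "CoefficientMatrix":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(**{k: doc[k] for k in ("mu_i_32", "mu_i_34", "mu_gd_32", "mu_gd_34", "b_32", "b_34")})


def fit_mass_attenuation(series: PhantomSeries, fit_intercept: bool = True) -> tuple[float, float]:
    """Least-squares line ``alpha = slope * C + intercept`` over a dilution series.

    The slope is the agent's mass-attenuation coefficient at the series
    energy.  With ``fit_intercept=False`` the line is forced through the
    origin (the intercept returned is 0).

    Raises
    ------
    DegenerateFitError
        If the series holds fewer than two distinct concentrations.

    Warns
    -----
    PhysicsViolationWarning
        If the fitted slope is negative (attenuation must grow with
        concentration).
    """
    c = series.concentrations
    a = series.attenuations
    if np.unique(c).size < 2:
        raise DegenerateFitError(
            f"need >= 2 distinct concentrations to fit {series.agent} at "
            f"{series.energy_kev} keV, got {np.unique(c).size}"
        )
    if fit_intercept:
        X = np.column_stack([c, np.ones_like(c)])
        (slope, intercept), *_ = np.linalg.lstsq(X, a, rcond=None)
    else:
        slope = float(c @ a) / float(c @ c)
        intercept = 0.0
    if slope < 0:
        warnings.warn(
            f"negative mass-attenuation slope ({slope:.4g}) for {series.agent} "
            f"at {series.energy_kev} keV",
            PhysicsViolationWarning,
            stacklevel=2,
        )
    return float(slope), float(intercept)


def forward_attenuation(
    c_iodine,
    c_gadolinium,
    c_bismuth,
    coeffs: CoefficientMatrix,
    energy_kev: float,
    mu_bismuth: float = 0.0,
):
    """Forward model: attenuation of a voxel from its agent concentrations.

    ``alpha_E = b_E + mu_I,E C_I + mu_Gd,E C_Gd + mu_Bi,E C_Bi``.  The
    bismuth term is only active in bath voxels (the 194-nm nanoparticles
    cannot enter the ~6-nm cartilage pore space) and is never decomposed.
    Accepts scalars or broadcastable arrays.
    """
    c_i = np.asarray(c_iodine, dtype=float)
    c_gd = np.asarray(c_gadolinium, dtype=float)
    c_bi = np.asarray(c_bismuth, dtype=float)
    if np.any(c_i < 0) or np.any(c_gd < 0) or np.any(c_bi < 0):
        raise ValueError("concentrations must be non-negative")
    alpha = (
        coeffs.intercept(energy_kev)
        + coeffs.mu_iodine(energy_kev) * c_i
        + coeffs.mu_gadolinium(energy_kev) * c_gd
        + mu_bismuth * c_bi
    )
    return alpha if alpha.ndim else float(alpha)


def build_coefficient_matrix(
    fit_ca4: dict,
    fit_gd: dict,
    intercepts: dict | None = None,
    conditioning_floor: float = DEFAULT_CONDITIONING_FLOOR,
) -> CoefficientMatrix:
    """Assemble a :class:`CoefficientMatrix` from per-energy slope fits.

    Parameters
    ----------
    fit_ca4, fit_gd : dict
        Mapping energy (32, 34) -> slope for each agent.
    intercepts : dict, optional
        Mapping energy -> solvent background.

    Raises
    ------
    IllConditionedCalibrationError
        If ``|det|`` falls below ``conditioning_floor``.
    """
    intercepts = intercepts or {}
    m = CoefficientMatrix(
        mu_i_32=float(fit_ca4[32]),
        mu_i_34=float(fit_ca4[34]),
        mu_gd_32=float(fit_gd[32]),
        mu_gd_34=float(fit_gd[34]),
        b_32=float(intercepts.get(32, 0.0)),
        b_34=float(intercepts.get(34, 0.0)),
    )
    m.require_conditioning(conditioning_floor)
    return m


def calibrate_from_table(
    table: pd.DataFrame,
    fit_intercept: bool = True,
    conditioning_floor: float = DEFAULT_CONDITIONING_FLOOR,
) -> tuple[CoefficientMatrix, dict]:
    """Calibrate from a tidy phantom table.

    Expects columns ``agent`` ("CA4+" / "gadoteridol"), ``energy_keV``,
    ``concentration_mg_per_mL``, ``mean_attenuation`` (the CSV calibration
    interface).  Returns the coefficient matrix and per-fit diagnostics
    (slope, intercept, RMS residual, n).
    """
    slopes: dict[str, dict[int, float]] = {"CA4+": {}, "gadoteridol": {}}
    inter: dict[int, list[float]] = {32: [], 34: []}
    diagnostics: dict[str, dict] = {}
    for (agent, energy), grp in table.groupby(["agent", "energy_keV"]):
        if agent not in slopes:
            continue
        series = PhantomSeries(
            agent=agent,
            energy_kev=float(energy),
            concentrations=grp["concentration_mg_per_mL"].to_numpy(),
            attenuations=grp["mean_attenuation"].to_numpy(),
        )
        slope, intercept = fit_mass_attenuation(series, fit_intercept=fit_intercept)
        resid = series.attenuations - (slope * series.concentrations + intercept)
        key = int(round(float(energy)))
        slopes[agent][key] = slope
        inter[key].append(intercept)
        diagnostics[f"{agent}@{key}keV"] = {
            "slope": slope,
            "intercept": intercept,
            "rms_residual": float(np.sqrt(np.mean(resid**2))),
            "n": int(len(grp)),
        }
    for agent in ("CA4+", "gadoteridol"):
        missing = {32, 34} - set(slopes[agent])
        if missing:
            raise DegenerateFitError(f"missing phantom series for {agent} at {sorted(missing)} keV")
    intercepts = {e: float(np.mean(v)) if v else 0.0 for e, v in inter.items()}
    matrix = build_coefficient_matrix(
        slopes["CA4+"], slopes["gadoteridol"], intercepts, conditioning_floor
    )
    return matrix, diagnostics
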