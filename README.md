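# qdect

Quantitative dual-energy microCT (QDECT) analysis of dual- and
triple-contrast-enhanced articular cartilage.

## The problem

Cartilage degeneration after joint injury begins with loss of proteoglycans
(PGs) and the fixed charge density (FCD) they carry, a rise in water
content, and disruption of the collagen network. Contrast-enhanced CT can
probe these changes: a **cationic iodinated agent (CA4+)** is drawn into
cartilage in proportion to FCD, while a **neutral gadolinium agent
(gadoteridol)** distributes with water content and steric hindrance. Imaged
together at two monochromatic energies that straddle the iodine k-edge
(32 and 34 keV; iodine edge 33.2 keV, gadolinium edge 50.3 keV), the two
agents can be separated voxel by voxel. A third bath agent — ~194 nm
**bismuth nanoparticles (BiNPs)** too large for the ~6 nm cartilage pores —
keeps the immersion bath bright so the articulating surface can be
segmented at early, clinically relevant diffusion times.

`qdect` implements the full analysis for this experiment family:

1. **Calibration** — least-squares mass-attenuation slopes from
   single-agent dilution phantoms: `alpha_E = b_E + mu_I,E C_I + mu_Gd,E C_Gd`.
2. **Decomposition** — the per-point 2x2 inversion

   ```
   C_I  = (a_34 mu_Gd,32 - a_32 mu_Gd,34) / D        D = mu_I,34 mu_Gd,32
   C_Gd = (a_32 mu_I,34  - a_34 mu_I,32)  / D            - mu_I,32 mu_Gd,34
   ```

   exposed as a scikit-learn style estimator (`MaterialDecomposition`:
   `fit` on a phantom table, `transform` attenuation pairs to mg/mL).
3. **Segmentation & profiling** — per-column surface/bone interface
   detection, a cylindrical VOI, crack masking by thresholding, and
   depth-normalised profiles (0 = articulating surface, 1 = bone
   interface), with the two 34 keV scans averaged against ongoing
   diffusion and the native (non-contrast) profile subtracted.
4. **Partition analysis** — tissue concentration over *measured* (depleted)
   bath concentration in percent, the gadoteridol-normalised CA4+ profile,
   and zone means (superficial 0–10%, middle 10–40%, deep 40–100%).
5. **Statistics** — zonal Pearson correlations against Safranin-O optical
   density (a stoichiometric PG proxy), Williams' t for dependent
   correlations (does normalisation improve the PG correlation?), and
   paired exact Wilcoxon signed-rank tests between intact, PG-depleted and
   impact-injured samples.
6. **Synthetic cohort generator** — osteochondral plugs in a contrast bath
   with erfc-profile Fickian uptake shaped by FCD/water/steric-hindrance
   depth profiles, bath depletion by mass conservation, sequential
   34/32/34 keV acquisitions with the diffusion front advancing between
   scans, surface cracks carrying exactly 100% partition, reconstruction
   noise, and full per-voxel ground truth.

## Worked example

Calibrate on the standard phantom series and validate on the eight
two-agent mixture phantoms:

```python
import numpy as np
from qdect import MaterialDecomposition, validate_mixture_phantoms
from qdect.synthetic import (MIXTURE_PHANTOMS_MG_ML, TRUE_COEFFICIENTS,
                             generate_phantom_table)

rng = np.random.default_rng(1)
table = generate_phantom_table(noise_sigma=0.04, rng=rng)
decomposer = MaterialDecomposition().fit(table)
c = decomposer.coeffs_
print(f"mu_I  = ({c.mu_i_32:.3f}, {c.mu_i_34:.3f})  per mg/mL at (32, 34) keV")
print(f"mu_Gd = ({c.mu_gd_32:.3f}, {c.mu_gd_34:.3f})  det = {c.determinant:.4f}")

err_i, err_gd = validate_mixture_phantoms(
    MIXTURE_PHANTOMS_MG_ML, c, noise_sigma=0.04, rng=rng,
    true_coeffs=TRUE_COEFFICIENTS,
)
print(f"mixture recovery error: CA4+ {err_i:.2f}%, gadoteridol {err_gd:.2f}%")
```

```
mu_I  = (0.379, 0.849)  per mg/mL at (32, 34) keV
mu_Gd = (0.698, 0.625)  det = 0.3555
mixture recovery error: CA4+ 0.74%, gadoteridol 1.51%
```

The iodine slope jumps across its k-edge (0.379 → 0.849) while the
gadolinium slope falls slightly (0.698 → 0.625); the positive determinant
is what makes the decomposition well conditioned. Recovery errors of ~1%
are the measurement-noise floor of the 2x2 inversion at these
concentrations.

Analyse one synthetic sample end to end:

```python
from qdect import RunConfig, analyze_sample
from qdect.pipeline import calibrate_stage
from qdect.synthetic import generate_cohort

config = RunConfig(seed=0, n_patellae=1)
coeffs = calibrate_stage(config, np.random.default_rng(0)).coeffs_
spec = generate_cohort(n_patellae=1, seed=0)[1]   # P01_intact_triple
row, profile, seg = analyze_sample(spec, coeffs, config)
print(f"{spec.sample_id}: CA4+ partition  sup/mid/deep = "
      f"{row['ca4_superficial']:.1f} / {row['ca4_middle']:.1f} / {row['ca4_deep']:.1f} %")
```

```
P01_intact_triple: CA4+ partition  sup/mid/deep = 110.1 / 71.7 / 15.4 %
                   gadoteridol     sup/mid/deep = 69.3 / 39.3 / 8.6 %
```

After 2 h of diffusion the cationic agent exceeds 100% partition near the
surface (charge attraction) and has barely reached the deep zone; the
neutral agent stays below 100% everywhere. The full cohort pipeline —
9 patellae x {intact, PG-depleted, injured} x {dual, triple} — runs from
the shell:

```bash
qdect run-all --seed 0 --out results/run0
```

writing `calibration.json`, per-sample `profiles.csv`, `zonal_summary.csv`,
the statistical battery in `statistics.csv`, and a `manifest.json` with
content hashes.

## Layout

```
src/qdect/
  calibration.py     forward model + phantom fits (CoefficientMatrix)
  decomposition.py   2x2 inversion, MaterialDecomposition estimator
  synthetic.py       tissue models, uptake physics, volume/cohort generator
  segmentation.py    interfaces, VOI, crack masking, depth profiles
  partition.py       bath referencing, normalisation, zonal summaries
  stats.py           Pearson / Williams / exact Wilcoxon, study battery
  pipeline.py        RunConfig, orchestration, manifest
  io.py, cli.py      TIFF+sidecar I/O, command-line surface
```

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
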