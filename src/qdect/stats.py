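"""The study's statistical battery.

Pearson correlations between zonal contrast-agent partitions and the
proteoglycan proxy (Safranin-O optical density); Williams' t (the variant
of the dependent-correlation test recommended by Steiger for two
correlations sharing one variable) for whether gadoteridol normalisation
significantly improves the CA4+-PG correlation; and paired Wilcoxon
signed-rank tests for group differences.  Significance threshold is
p < 0.05 throughout; no multiple-testing adjustment is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05
#: largest number of non-zero differences for which the exact Wilcoxon
#: null distribution is enumerated
EXACT_WILCOXON_MAX_N = 12


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-based p value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in an input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class CorrelationTriplet:
    """Dependent correlations sharing variable 3 (optical density).

    ``r13``: raw CA4+ partition vs OD; ``r23``: normalised CA4+ vs OD;
    ``r12``: raw vs normalised CA4+; ``n``: sample count.
    """

    r13: float
    r23: float
    r12: float
    n: int

    def __post_init__(self):
        for r in (self.r13, self.r23, self.r12):
            if not -1.0 <= r <= 1.0:
                raise ValueError("correlations must lie in [-1, 1]")

    @property
    def det(self) -> float:
        """Determinant of the 3x3 correlation matrix (must be >= 0)."""
        return (
            1.0
            - self.r12**2
            - self.r13**2
            - self.r23**2
            + 2.0 * self.r12 * self.r13 * self.r23
        )


def dependent_correlation_test(trip: CorrelationTriplet, method: str = "williams"):
    """Test r13 = r23 for two correlations sharing a variable.

    ``method="williams"`` (default) uses Williams' t with n - 3 degrees of
    freedom; ``method="steiger-z"`` uses the Fisher-z statistic with the
    dependent-correlation covariance.  Returns ``(statistic, df, p)``
    (``df`` is NaN for the z variant).
    """
    n = trip.n
    if n <= 3:
        raise ValueError("need n > 3 for the dependent-correlation test")
    det = trip.det
    if det < -1e-12:
        raise ValueError("inconsistent correlation matrix (negative determinant)")
    det = max(det, 0.0)
    r13, r23, r12 = trip.r13, trip.r23, trip.r12
    if method == "williams":
        rbar = 0.5 * (r13 + r23)
        denom = 2.0 * ((n - 1) / (n - 3)) * det + rbar**2 * (1.0 - r12) ** 3
        t = (r13 - r23) * np.sqrt((n - 1) * (1.0 + r12) / denom)
        df = n - 3
        p = 2.0 * sps.t.sf(abs(t), df)
        return float(t), df, float(p)
    if method == "steiger-z":
        z13, z23 = np.arctanh(np.clip([r13, r23], -0.999999, 0.999999))
        rbar = 0.5 * (r13 + r23)
        cov = (r12 * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r12**2)) / (
            (1 - rbar**2) ** 2
        )
        z = np.sqrt(n - 3) * (z13 - z23) / np.sqrt(2.0 - 2.0 * cov)
        return float(z), float("nan"), float(2.0 * sps.norm.sf(abs(z)))
    raise ValueError(f"unknown method {method!r}")


def _signed_ranks(differences, zero_method):
    d = np.asarray(differences, float)
    if zero_method == "wilcox":
        d = d[d != 0]
    elif zero_method != "pratt":
        raise ValueError(f"unknown zero_method {zero_method!r}")
    if d.size == 0 or np.all(d == 0):
        raise ValueError("all differences are zero; the test is undefined")
    ranks = sps.rankdata(np.abs(d))
    if zero_method == "pratt":
        keep = d != 0
        d, ranks = d[keep], ranks[keep]
    return d, ranks


def wilcoxon_signed_rank(
    differences,
    zero_method: str = "wilcox",
    method: str = "auto",
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on matched differences.

    Returns ``(W, p)`` where ``W`` is the positive-rank sum.  For up to
    :data:`EXACT_WILCOXON_MAX_N` non-zero differences the two-sided p is
    exact — the null distribution of ``W`` is enumerated over all 2^n sign
    assignments (ties handled through average ranks), and
    ``p = min(1, 2 * min(P(W <= w), P(W >= w)))``.  Larger samples use the
    normal approximation with tie correction.  Zero differences are dropped
    (``zero_method="wilcox"``) or retained in ranking then dropped
    (``"pratt"``).
    """
    d, ranks = _signed_ranks(differences, zero_method)
    n = d.size
    w_pos = float(ranks[d > 0].sum())
    use_exact = method == "exact" or (method == "auto" and n <= EXACT_WILCOXON_MAX_N)
    if use_exact:
        if n > 20:
            raise ValueError("exact enumeration limited to n <= 20")
        # all 2^n sign patterns: bit b of pattern m selects rank b as positive
        patterns = np.arange(2**n, dtype=np.int64)
        bits = (patterns[:, None] >> np.arange(n)) & 1
        w_all = bits @ ranks
        eps = 1e-9
        p_lo = np.mean(w_all <= w_pos + eps)
        p_hi = np.mean(w_all >= w_pos - eps)
        p = min(1.0, 2.0 * min(p_lo, p_hi))
        return w_pos, float(p)
    mu = n * (n + 1) / 4.0
    tie_counts = np.unique(ranks, return_counts=True)[1]
    tie_term = np.sum(tie_counts**3 - tie_counts) / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    z = (w_pos - mu) / sigma
    return w_pos, float(2.0 * sps.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Study-level comparison battery

_QUANTITIES = ("ca4", "gd", "norm")
_ZONE_KEYS = ("superficial", "middle", "deep", "full")


def _paired_differences(df, group_a, group_b, column):
    a = df[df["group"] == group_a].set_index("patella")[column]
    b = df[df["group"] == group_b].set_index("patella")[column]
    common = a.index.intersection(b.index)
    missing = a.index.symmetric_difference(b.index)
    if len(missing):
        raise ValueError(f"unpaired patellae for {group_a} vs {group_b}: {sorted(missing)}")
    return (a.loc[common] - b.loc[common]).to_numpy()


def run_group_comparisons(summaries: pd.DataFrame) -> pd.DataFrame:
    """Full statistical battery over a zonal-summary table.

    For every mixture x zone x quantity: paired Wilcoxon tests of intact vs
    PG-depleted and intact vs injured (paired by patella); Pearson
    correlation of the quantity with the zone's optical density pooled over
    all samples of the mixture; and Williams' test of whether the
    normalised CA4+ correlates better with OD than the raw CA4+ partition.
    Full-thickness dual-vs-triple comparisons are paired by parent sample
    (patella x group).  Returns a tidy results table with a significance
    flag at p < 0.05.
    """
    rows = []
    mixtures = sorted(summaries["mixture"].unique())
    for mixture in mixtures:
        sub = summaries[summaries["mixture"] == mixture]
        for zone in _ZONE_KEYS:
            od_col = f"od_{zone}"
            for quantity in _QUANTITIES:
                col = f"{quantity}_{zone}"
                for other in ("pg_depleted", "injured"):
                    if not (sub["group"] == other).any():
                        continue
                    diffs = _paired_differences(sub, "intact", other, col)
                    if np.all(diffs == 0):
                        w, p = np.nan, 1.0
                    else:
                        w, p = wilcoxon_signed_rank(diffs)
                    rows.append(
                        dict(
                            mixture=mixture,
                            zone=zone,
                            quantity=quantity,
                            comparison=f"intact_vs_{other}",
                            statistic=w,
                            p=p,
                        )
                    )
                vals = sub[[col, od_col]].dropna()
                r, p = pearson(vals[col], vals[od_col])
                rows.append(
                    dict(
                        mixture=mixture,
                        zone=zone,
                        quantity=quantity,
                        comparison="pearson_vs_od",
                        statistic=r,
                        p=p,
                    )
                )
            trip_df = sub[[f"ca4_{zone}", f"norm_{zone}", od_col]].dropna()
            trip = CorrelationTriplet(
                r13=pearson(trip_df[f"ca4_{zone}"], trip_df[od_col])[0],
                r23=pearson(trip_df[f"norm_{zone}"], trip_df[od_col])[0],
                r12=pearson(trip_df[f"ca4_{zone}"], trip_df[f"norm_{zone}"])[0],
                n=len(trip_df),
            )
            t, _, p = dependent_correlation_test(trip)
            rows.append(
                dict(
                    mixture=mixture,
                    zone=zone,
                    quantity="norm",
                    comparison="steiger_norm_benefit",
                    statistic=t,
                    p=p,
                )
            )
    if len(mixtures) == 2:
        a, b = mixtures  # alphabetical: dual, triple
        wide_a = summaries[summaries["mixture"] == a].set_index(["patella", "group"])
        wide_b = summaries[summaries["mixture"] == b].set_index(["patella", "group"])
        common = wide_a.index.intersection(wide_b.index)
        for quantity in _QUANTITIES:
            col = f"{quantity}_full"
            diffs = (wide_a.loc[common, col] - wide_b.loc[common, col]).dropna().to_numpy()
            if np.all(diffs == 0):
                w, p = np.nan, 1.0
            else:
                w, p = wilcoxon_signed_rank(diffs)
            rows.append(
                dict(
                    mixture=f"{a}_vs_{b}",
                    zone="full",
                    quantity=quantity,
                    comparison="dual_vs_triple",
                    statistic=w,
                    p=p,
                )
            )
    out = pd.DataFrame(rows)
    out["significant"] = out["p"] < ALPHA
    return out
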