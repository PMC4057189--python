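"""Paired-agreement and group statistics.

Implements the statistical toolkit of a paired two-dose CT comparison:
Bland-Altman analysis (bias, limits of agreement, proportional-bias
regression), automatic paired t / Wilcoxon signed-rank selection via a
Shapiro-Wilk normality check on the differences, measure-by-measure
agreement tables, per-bin histogram comparisons, and one-way ANOVA with
a rank-transform fallback for the dose/noise summary.

Differences are oriented reference minus alternative throughout, and the
limits of agreement use the conventional 1.96 multiplier, so the bias is
exactly the midpoint of the limits.  No multiple-testing correction is
applied across histogram bins or table rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .qct import COMPARTMENT_NAMES, HistogramResult, QCTResult

__all__ = [
    "PairedSeries",
    "BlandAltmanResult",
    "PairedTestResult",
    "AnovaResult",
    "bland_altman",
    "paired_test",
    "compare_pairs",
    "compare_histograms",
    "group_anova",
    "MEASURE_LABELS",
]

LOA_MULTIPLIER = 1.96

#: Row labels of the agreement tables, in report order.
MEASURE_LABELS = {
    "total_volume_ml": "Lung volume (ml)",
    "total_mass_g": "Lung tissue mass (g)",
    "hyperinflated": "Hyperinflated tissue (%)",
    "normally_aerated": "Normally aerated tissue (%)",
    "poorly_aerated": "Poorly aerated tissue (%)",
    "nonaerated": "Nonaerated tissue (%)",
}


@dataclass
class PairedSeries:
    """Per-pair values of one measure at the reference and compared dose."""

    name: str
    unit: str
    values_ref: np.ndarray
    values_alt: np.ndarray

    def __post_init__(self) -> None:
        self.values_ref = np.asarray(self.values_ref, dtype=float)
        self.values_alt = np.asarray(self.values_alt, dtype=float)
        if self.values_ref.shape != self.values_alt.shape or self.values_ref.ndim != 1:
            raise ValueError("values_ref and values_alt must be 1-D arrays of equal length")
        if self.n < 2:
            raise ValueError(f"need at least 2 pairs, got {self.n}")

    @property
    def n(self) -> int:
        return len(self.values_ref)

    @property
    def differences(self) -> np.ndarray:
        return self.values_ref - self.values_alt


@dataclass
class PairedTestResult:
    p: float
    test_name: str  # "paired t-test" | "Wilcoxon signed-rank" | "degenerate"
    degenerate: bool = False


@dataclass
class BlandAltmanResult:
    """Bland-Altman agreement summary for one paired measure."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    prop_slope: float
    prop_r2: float
    prop_p: float
    pair_r2: float
    p_paired: float
    test_name: str
    n: int
    degenerate: bool = False


def _paired_test_diffs(diffs: np.ndarray, alpha_normality: float = 0.05) -> PairedTestResult:
    diffs = np.asarray(diffs, dtype=float)
    if np.all(diffs == 0):
        return PairedTestResult(p=1.0, test_name="degenerate", degenerate=True)
    if len(diffs) < 3:
        raise ValueError("need at least 3 pairs for the normality check")
    if np.std(diffs) == 0:
        normal = False  # constant nonzero shift; Shapiro undefined
    else:
        normal = stats.shapiro(diffs).pvalue >= alpha_normality
    if normal:
        res = stats.ttest_1samp(diffs, 0.0)
        return PairedTestResult(p=float(res.pvalue), test_name="paired t-test")
    res = stats.wilcoxon(diffs)
    return PairedTestResult(p=float(res.pvalue), test_name="Wilcoxon signed-rank")


def paired_test(s: PairedSeries, alpha_normality: float = 0.05) -> PairedTestResult:
    """Paired t-test when the differences pass Shapiro-Wilk normality at
    ``alpha_normality``, Wilcoxon signed-rank otherwise.  All-zero
    differences return p = 1 flagged degenerate."""
    return _paired_test_diffs(s.differences, alpha_normality)


def bland_altman(s: PairedSeries, alpha_normality: float = 0.05) -> BlandAltmanResult:
    """Bland-Altman analysis of a paired series.

    bias = mean(ref - alt); limits of agreement = bias +/- 1.96 x SD of
    the differences (n-1 denominator).  The proportional-bias regression
    fits difference on pair mean; ``pair_r2`` is the r^2 of alt on ref.
    Zero-variance differences collapse the limits onto the bias and flag
    the regression degenerate.
    """
    diffs = s.differences
    means = (s.values_ref + s.values_alt) / 2.0
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    loa_low, loa_high = bias - LOA_MULTIPLIER * sd, bias + LOA_MULTIPLIER * sd

    degenerate = sd == 0 or np.ptp(means) == 0
    if degenerate:
        prop_slope = prop_r2 = prop_p = float("nan")
    else:
        reg = stats.linregress(means, diffs)
        prop_slope, prop_r2, prop_p = float(reg.slope), float(reg.rvalue**2), float(reg.pvalue)

    if np.ptp(s.values_ref) == 0:
        pair_r2 = float("nan")
    else:
        pair_r2 = float(stats.linregress(s.values_ref, s.values_alt).rvalue ** 2)

    if s.n >= 3:
        test = _paired_test_diffs(diffs, alpha_normality)
        p_paired, test_name = test.p, test.test_name
    else:
        p_paired, test_name = float("nan"), "n/a"

    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=loa_low,
        loa_high=loa_high,
        prop_slope=prop_slope,
        prop_r2=prop_r2,
        prop_p=prop_p,
        pair_r2=pair_r2,
        p_paired=p_paired,
        test_name=test_name,
        n=s.n,
        degenerate=bool(np.all(diffs == 0)),
    )


def _extract_measure(result: QCTResult, key: str) -> float:
    if key in ("total_volume_ml", "total_mass_g"):
        return getattr(result, key)
    return result.compartment_fraction_pct[key]


def compare_pairs(pairs) -> pd.DataFrame:
    """Measure-by-measure agreement table for paired quantitative results.

    One row per measure (volume, mass, four compartment fractions) with
    columns mean/SD per arm, paired p, pair r^2, bias and limits of
    agreement -- the standard layout of a paired-dose comparison table.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("need at least 2 result pairs")
    schemas = {tuple(sorted(r.compartment_fraction_pct)) for pair in pairs for r in pair}
    if len(schemas) != 1:
        raise ValueError(f"mismatched result schemas across pairs: {schemas}")
    if set(COMPARTMENT_NAMES) - set(next(iter(schemas))):
        raise ValueError("results are missing the standard aeration compartments")

    rows = []
    for key, label in MEASURE_LABELS.items():
        ref = np.array([_extract_measure(r, key) for r, _ in pairs])
        alt = np.array([_extract_measure(a, key) for _, a in pairs])
        ba = bland_altman(PairedSeries(name=label, unit="", values_ref=ref, values_alt=alt))
        rows.append(
            {
                "measure": label,
                "mean_ref": ref.mean(),
                "sd_ref": ref.std(ddof=1),
                "mean_alt": alt.mean(),
                "sd_alt": alt.std(ddof=1),
                "p": ba.p_paired,
                "r2": ba.pair_r2,
                "bias": ba.bias,
                "loa_low": ba.loa_low,
                "loa_high": ba.loa_high,
            }
        )
    return pd.DataFrame(rows).set_index("measure")


def compare_histograms(pairs, alpha: float = 0.05) -> pd.DataFrame:
    """Per-bin paired comparison of mass-frequency histograms.

    Runs the automatic paired test on each 50-HU bin across pairs and
    flags bins with p < ``alpha``.  No multiple-testing correction.
    """
    pairs = [(r, a) for r, a in pairs]
    if len(pairs) < 3:
        raise ValueError("need at least 3 histogram pairs")
    edges = pairs[0][0].bin_edges
    for r, a in pairs:
        if not (np.array_equal(r.bin_edges, edges) and np.array_equal(a.bin_edges, edges)):
            raise ValueError("histogram bin edges differ between pairs")

    ref = np.vstack([r.mass_fraction_pct for r, _ in pairs])
    alt = np.vstack([a.mass_fraction_pct for _, a in pairs])
    rows = []
    for k in range(ref.shape[1]):
        test = _paired_test_diffs(ref[:, k] - alt[:, k])
        rows.append(
            {
                "bin_lo_hu": edges[k],
                "mean_ref": ref[:, k].mean(),
                "mean_alt": alt[:, k].mean(),
                "mean_diff": (ref[:, k] - alt[:, k]).mean(),
                "p": test.p,
                "test": test.test_name,
                "significant": bool(test.p < alpha) and not test.degenerate,
            }
        )
    return pd.DataFrame(rows).set_index("bin_lo_hu")


@dataclass
class AnovaResult:
    statistic: float
    p: float
    rank_transformed: bool


def group_anova(groups, alpha_normality: float = 0.05) -> AnovaResult:
    """One-way ANOVA across >= 2 groups, with a rank transform applied
    first when any group fails Shapiro-Wilk normality or Levene's equal
    variance test."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 values")

    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return AnovaResult(statistic=0.0, p=1.0, rank_transformed=False)
    if all(np.ptp(g) == 0 for g in groups):
        # distinct constants: zero within-group variance, unbounded F
        return AnovaResult(statistic=float("inf"), p=0.0, rank_transformed=False)

    def _normal(g):
        if np.ptp(g) == 0 or len(g) < 3:
            return False
        return stats.shapiro(g).pvalue >= alpha_normality

    needs_ranks = not all(_normal(g) for g in groups)
    if not needs_ranks:
        needs_ranks = stats.levene(*groups).pvalue < alpha_normality
    if needs_ranks:
        ranks = stats.rankdata(pooled)
        split = np.cumsum([len(g) for g in groups])[:-1]
        groups = np.split(ranks, split)
    res = stats.f_oneway(*groups)
    return AnovaResult(statistic=float(res.statistic), p=float(res.pvalue), rank_transformed=needs_ranks)
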