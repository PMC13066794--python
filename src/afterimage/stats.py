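"""Inferential layer: tests against orthogonality, group comparisons,
permutation p-values and Benjamini-Hochberg FDR control."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "FdrResult",
    "wilcoxon_vs_90",
    "mannwhitney_groups",
    "paired_t",
    "bh_fdr",
    "permutation_pvalue",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    sidedness: str  # "one" or "two"
    n: tuple[int, ...]
    method: str
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1 or np.isnan(self.p_value)):
            # exact tests can produce p == 0 only through underflow
            self.p_value = max(self.p_value, np.finfo(float).tiny)


@dataclass
class FdrResult:
    p_values: np.ndarray
    q: float
    significant: np.ndarray  # boolean mask
    adjusted: np.ndarray  # BH-adjusted p-values

    def __post_init__(self) -> None:
        self.p_values = np.asarray(self.p_values, float)
        self.significant = np.asarray(self.significant, bool)
        self.adjusted = np.asarray(self.adjusted, float)


def wilcoxon_vs_90(median_angles_deg, reference: float = 90.0) -> TestResult:
    """One-sided one-sample Wilcoxon signed-rank test that per-odor median
    angles exceed the 90-degree orthogonality expectation.

    Exact small-sample p-values are used below n = 25 (so eleven values all
    above 90 give p = 2**-11).  Zero differences are discarded (classic
    Wilcoxon convention).
    """
    x = np.asarray(median_angles_deg, float)
    d = x - reference
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all values equal the reference; test degenerate")
    method = "exact" if d.size < 25 else "auto"
    res = scipy.stats.wilcoxon(d, alternative="greater", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), "one",
                      (int(d.size),), "wilcoxon_signed_rank_vs_90")


def mannwhitney_groups(ref_on_angles, ref_off_angles) -> TestResult:
    """One-sided Mann-Whitney U test that OFF-vs-reference angles exceed
    ON-vs-reference angles (independent samples)."""
    on = np.asarray(ref_on_angles, float)
    off = np.asarray(ref_off_angles, float)
    if on.size == 0 or off.size == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([on, off])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (no_ties and max(on.size, off.size) <= 25) else "auto"
    res = scipy.stats.mannwhitneyu(off, on, alternative="greater",
                                   method=method)
    return TestResult(float(res.statistic), float(res.pvalue), "one",
                      (int(off.size), int(on.size)), "mann_whitney_u")


def paired_t(solitary_corrs, sequential_corrs,
             sidedness: str = "one") -> TestResult:
    """Paired t-test on solitary minus sequential correlation differences.

    One-sided (default) tests the contrast-enhancement direction: solitary
    correlations exceed sequential ones.
    """
    a = np.asarray(solitary_corrs, float)
    b = np.asarray(sequential_corrs, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length paired samples with n >= 2")
    d = a - b
    if np.allclose(d, d[0]):
        if d[0] == 0:
            raise ValueError("zero variance of differences; test degenerate")
        # constant non-zero difference: t unbounded, report minimal p
        stat = np.inf if d[0] > 0 else -np.inf
        p = np.finfo(float).tiny if (sidedness == "one" and d[0] > 0) else (
            np.finfo(float).tiny)
        return TestResult(stat, p, sidedness, (int(a.size),), "paired_t")
    alt = "greater" if sidedness == "one" else "two-sided"
    res = scipy.stats.ttest_rel(a, b, alternative=alt)
    return TestResult(float(res.statistic), float(res.pvalue), sidedness,
                      (int(a.size),), "paired_t")


def bh_fdr(p_values, q: float = 0.05) -> FdrResult:
    """Benjamini-Hochberg step-up procedure at level q."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return FdrResult(p, q, np.zeros(0, bool), p.copy())
    if np.any(~np.isfinite(p)) or p.min() <= 0 or p.max() > 1:
        raise ValueError("p-values must lie in (0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return FdrResult(p, q, reject, adjusted)


def permutation_pvalue(observed: float, null_values) -> float:
    """One-sided permutation p with the add-one convention:
    p = (1 + #{null >= observed}) / (1 + N).  Never returns 0."""
    null = np.asarray(null_values, float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    return float((1 + np.sum(null >= observed)) / (1 + null.size))
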