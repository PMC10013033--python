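"""Statistical primitives shared by all analysis stages.

Wilcoxon rank-sum (exact for small tie-free samples, normal approximation
with tie and continuity correction otherwise), the paired t-test, and
Benjamini–Hochberg FDR adjustment.  Every group contrast in the pipeline
funnels through these three functions so that the conventions (one-sided
directions, exactness switch, step-up adjustment) live in one place.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = ["TestResult", "rank_sum_test", "paired_t_test", "fdr_adjust"]

#: sample-size bound below which the exact rank-sum null is enumerated
EXACT_RANKSUM_MAX_N = 12


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample (or paired) hypothesis test."""

    statistic: float
    p_value: float
    alternative: str
    method: str


def _check_alternative(alternative: str) -> str:
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(
            f"alternative must be 'two-sided', 'greater' or 'less', got {alternative!r}"
        )
    return alternative


def rank_sum_test(x, y, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon rank-sum (Mann–Whitney) test of ``x`` against ``y``.

    The null distribution is enumerated exactly when the pooled sample is
    small (``n_x + n_y <= 12``) and tie-free; otherwise the normal
    approximation with tie correction and continuity correction is used.
    ``alternative='greater'`` tests whether values in ``x`` tend to exceed
    those in ``y``.

    Returns the rank-sum statistic ``W`` of ``x`` (Mann–Whitney ``U`` plus
    ``n_x (n_x + 1) / 2``).
    """
    alternative = _check_alternative(alternative)
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires two nonempty samples")

    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= EXACT_RANKSUM_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"

    if has_ties and np.unique(pooled).size == 1:
        # all observations identical: the statistic is degenerate
        warnings.warn("rank_sum_test: all observations tied; returning p = 1")
        w = x.size * (pooled.size + 1) / 2.0
        return TestResult(w, 1.0, alternative, "degenerate")

    res = _sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    w = float(res.statistic + x.size * (x.size + 1) / 2.0)
    p = float(min(max(res.pvalue, np.finfo(float).tiny), 1.0))
    return TestResult(w, p, alternative, f"wilcoxon-ranksum/{method}")


def paired_t_test(x, y, alternative: str = "two-sided") -> TestResult:
    """Paired-sample t-test on the differences ``x - y`` with ``n - 1`` df.

    Raises on unequal lengths, fewer than two pairs, or a zero-variance
    difference vector (the t statistic is undefined there).
    """
    alternative = _check_alternative(alternative)
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("paired_t_test requires equal-length samples")
    if x.size < 2:
        raise ValueError("paired_t_test requires at least two pairs")
    d = x - y
    if np.allclose(d, d[0]):
        raise ValueError("paired_t_test: zero-variance differences, t undefined")
    res = _sps.ttest_rel(x, y, alternative=alternative)
    p = float(min(max(res.pvalue, np.finfo(float).tiny), 1.0))
    return TestResult(float(res.statistic), p, alternative, "paired-t")


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1.

    Input p-values must lie in ``(0, 1]``.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("fdr_adjust: p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
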