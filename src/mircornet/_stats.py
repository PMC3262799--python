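"""Vectorized group-comparison statistics computed from per-group summaries.

The specificity classifier needs, per transcript, a one-way ANOVA over a
transcript-dependent subset of cell-type groups and a two-sample test between
two transcript-dependent groups.  Both are computed here directly from group
means, variances and counts so that thousands of transcripts are handled with
array operations; unit tests check agreement with ``scipy.stats.f_oneway`` and
``scipy.stats.ttest_ind``.

Degenerate inputs (zero within-group variance) yield p = 1 when the group
means are equal and p = 0 when they differ, matching the limiting behaviour.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["oneway_anova_from_stats", "two_sample_t_from_stats", "bh_adjust"]


def oneway_anova_from_stats(
    means: np.ndarray, variances: np.ndarray, counts: np.ndarray
) -> np.ndarray:
    """One-way ANOVA p-values from per-group summaries.

    Parameters
    ----------
    means, variances, counts
        Arrays of shape ``(..., g)``: per-group sample means, unbiased (ddof=1)
        variances and sample sizes.  The ANOVA is over the last axis.

    Returns
    -------
    p-values with shape ``(...)``.
    """
    means = np.asarray(means, dtype=float)
    variances = np.asarray(variances, dtype=float)
    counts = np.asarray(counts, dtype=float)
    g = means.shape[-1]
    if g < 2:
        return np.ones(means.shape[:-1])
    n_total = counts.sum(axis=-1)
    grand = (counts * means).sum(axis=-1) / n_total
    ss_between = (counts * (means - grand[..., None]) ** 2).sum(axis=-1)
    ss_within = ((counts - 1.0) * variances).sum(axis=-1)
    df_b = g - 1
    df_w = n_total - g
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
        p = stats.f.sf(f, df_b, df_w)
    # zero within-group variance: all values identical inside each group
    degen = ss_within <= 0
    if np.any(degen):
        equal_means = ss_between <= 1e-12 * np.maximum(1.0, grand**2)
        p = np.where(degen, np.where(equal_means, 1.0, 0.0), p)
    return p


def two_sample_t_from_stats(
    m1: np.ndarray,
    v1: np.ndarray,
    n1: np.ndarray,
    m2: np.ndarray,
    v2: np.ndarray,
    n2: np.ndarray,
    equal_var: bool = False,
) -> np.ndarray:
    """Two-sided two-sample t-test p-values from group summaries.

    ``equal_var=False`` gives the Welch test with Satterthwaite degrees of
    freedom; ``equal_var=True`` the pooled-variance Student test.
    """
    m1, v1, n1, m2, v2, n2 = (np.asarray(a, dtype=float) for a in (m1, v1, n1, m2, v2, n2))
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        if equal_var:
            df = n1 + n2 - 2
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
            se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        else:
            a, b = v1 / n1, v2 / n2
            se2 = a + b
            df = se2**2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
        t = diff / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degen = ~np.isfinite(p)
    if np.any(degen):
        p = np.where(degen, np.where(np.abs(diff) <= 1e-12, 1.0, 0.0), p)
    return p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out
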