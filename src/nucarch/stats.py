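"""Rank statistics used across the imaging comparisons.

Two-sided Mann–Whitney (Wilcoxon rank-sum) tests compare per-nucleus counts
and per-object volumes between conditions; Bonferroni–Holm adjustment
controls the family-wise error over the pairwise condition contrasts.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

_EXACT_MAX_N = 12


def mann_whitney_two_sided(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Uses the exact null distribution when ``n_a + n_b <= 12`` and the data
    are tie-free; otherwise the normal approximation with tie and continuity
    corrections.  Returns ``(U, p)`` with U the statistic of the first
    sample.  If every value in both samples is identical the test is
    degenerate and ``p = 1``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(a.size * b.size / 2.0), 1.0
    ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= _EXACT_MAX_N and not ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def holm_adjust(p_values) -> np.ndarray:
    """Bonferroni–Holm step-down adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]
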