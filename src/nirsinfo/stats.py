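"""Nonparametric tests and effect sizes for the criterion comparisons.

Wilcoxon statistics are reported on the normal-approximation z scale
(tie-corrected, no continuity correction) because that is the scale on
which the reference effect sizes r = |z| / sqrt(N) are defined.  For
Kruskal-Wallis the effect size is r = sqrt(H / N) with N the total number
of observations.  Bonferroni correction multiplies each p-value by the
number of comparisons in the family, capped at 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _st

__all__ = [
    "TestResult",
    "rank_sum",
    "signed_rank",
    "kruskal_wallis",
    "bonferroni",
]


@dataclass
class TestResult:
    test: str
    statistic: float  # |z| for Wilcoxon variants, H for Kruskal-Wallis
    group_sizes: list[int]
    p_raw: float
    p_adjusted: float | None = None
    effect_size_r: float | None = None
    extra: dict = field(default_factory=dict)

    def adjusted(self, factor: int) -> "TestResult":
        self.p_adjusted = bonferroni([self.p_raw], factor)[0]
        return self


def _tie_term(ranks: np.ndarray) -> float:
    _, counts = np.unique(ranks, return_counts=True)
    return float(np.sum(counts**3 - counts))


def rank_sum(a, b, continuity: bool = True) -> TestResult:
    """Two-sample Wilcoxon rank-sum, normal approximation with tie correction.

    statistic = |z|; effect_size_r = |z| / sqrt(n_a + n_b).  The 0.5
    continuity correction is applied by default (so 50-vs-50 complete
    separation gives z = 8.6138); disable it to recover the algebraic
    identity H = z^2 against the two-group Kruskal-Wallis.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = len(a), len(b)
    if min(na, nb) < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([a, b])
    ranks = _st.rankdata(pooled)
    n = na + nb
    ra = ranks[:na].sum()
    mu = na * (n + 1) / 2.0
    tie = _tie_term(ranks)
    var = na * nb / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var <= 0:
        raise ValueError("all pooled values identical; rank-sum z undefined")
    d = ra - mu
    if continuity:
        d = np.sign(d) * max(abs(d) - 0.5, 0.0)
    z = d / np.sqrt(var)
    p = 2 * _st.norm.sf(abs(z))
    return TestResult(
        test="rank_sum",
        statistic=abs(z),
        group_sizes=[na, nb],
        p_raw=float(p),
        effect_size_r=float(abs(z) / np.sqrt(n)),
        extra={"z_signed": float(z), "rank_sum_a": float(ra)},
    )


def signed_rank(diff) -> TestResult:
    """One-sample Wilcoxon signed-rank on paired differences.

    Zero differences are dropped (Wilcoxon's original prescription);
    statistic = |z| from the normal approximation with tie correction;
    effect_size_r = |z| / sqrt(N) with N = 2 x number of pairs, the
    observation count of the paired design.
    """
    diff = np.asarray(diff, dtype=float).ravel()
    n_pairs = len(diff)
    nz = diff[diff != 0]
    n = len(nz)
    if n < 1:
        raise ValueError("all paired differences are zero")
    if n < 6:
        warnings.warn(
            f"only {n} non-zero differences; normal approximation is crude",
            stacklevel=2,
        )
    ranks = _st.rankdata(np.abs(nz))
    t_plus = ranks[nz > 0].sum()
    mu = n * (n + 1) / 4.0
    tie = _tie_term(ranks)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie / 48.0
    if var <= 0:
        raise ValueError("signed-rank variance degenerate")
    z = (t_plus - mu) / np.sqrt(var)
    p = 2 * _st.norm.sf(abs(z))
    return TestResult(
        test="signed_rank",
        statistic=abs(z),
        group_sizes=[n_pairs],
        p_raw=float(p),
        effect_size_r=float(abs(z) / np.sqrt(2 * n_pairs)),
        extra={"z_signed": float(z), "n_nonzero": n, "t_plus": float(t_plus)},
    )


def kruskal_wallis(groups) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p (k - 1 df).

    effect_size_r = sqrt(H / N) with N the total observation count.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(groups):
        if len(g) < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
    h, p = _st.kruskal(*groups)
    n = sum(len(g) for g in groups)
    return TestResult(
        test="kruskal_wallis",
        statistic=float(h),
        group_sizes=[len(g) for g in groups],
        p_raw=float(p),
        effect_size_r=float(np.sqrt(h / n)),
        extra={"df": len(groups) - 1},
    )


def bonferroni(p_values, factor: int) -> np.ndarray:
    """Multiply each p by the family size, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if factor < 1:
        raise ValueError("Bonferroni factor must be >= 1")
    return np.minimum(1.0, p * factor)
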