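"""Cross-cutting comparison statistics.

Sex bias (SB) per gene is log2((exp_F + 1) / (exp_M + 1)), binned into five
categories from strongly male-biased (MS) to strongly female-biased (FS)
at bounds -1, -0.3, 0.3, 1; distributions of CR deviance explained are
compared across bins with Mann-Whitney U tests.  Proportions of regulatory
categories are compared across samples with two-proportion z-tests or
Fisher's exact tests; the sharing of CR calls between two scopes is tested
with a 2x2 chi-square (no continuity correction); tissue specificity is a
fraction of atlas-wide expression, and its association with CR strength is
a Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .cr_glm import bh_adjust  # noqa: F401  (re-exported convenience)

__all__ = [
    "SB_CATEGORIES",
    "sex_bias",
    "sb_category",
    "compare_deviance_by_sb",
    "proportion_test_z",
    "proportion_test_fisher",
    "OverlapTable",
    "overlap_chi2",
    "tissue_specificity",
    "spearman_assoc",
]

SB_CATEGORIES = ("MS", "MB", "UB", "FB", "FS")


def sex_bias(exp_f, exp_m):
    """SB = log2((exp_F + 1)/(exp_M + 1)); vectorized over arrays."""
    exp_f = np.asarray(exp_f, dtype=float)
    exp_m = np.asarray(exp_m, dtype=float)
    if (exp_f < 0).any() or (exp_m < 0).any():
        raise ValueError("expression must be nonnegative")
    out = np.log2((exp_f + 1.0) / (exp_m + 1.0))
    return float(out) if out.ndim == 0 else out


def sb_category(sb: float, bounds=(-1.0, -0.3, 0.3, 1.0)) -> str:
    """Five-way sex-bias bin; boundary values go to the less-biased side.

    With the default bounds: MS for sb < -1, MB for -1 <= sb < -0.3,
    UB for -0.3 <= sb <= 0.3, FB for 0.3 < sb <= 1, FS for sb > 1.
    """
    b1, b2, b3, b4 = bounds
    if not (b1 < b2 < b3 < b4):
        raise ValueError("bounds must be strictly increasing")
    if sb < b1:
        return "MS"
    if sb < b2:
        return "MB"
    if sb <= b3:
        return "UB"
    if sb <= b4:
        return "FB"
    return "FS"


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p: exact for small tie-free samples,
    otherwise normal approximation with tie correction (no continuity)."""
    pooled = np.concatenate([x, y])
    exact_ok = max(len(x), len(y)) <= 20 and len(np.unique(pooled)) == len(pooled)
    method = "exact" if exact_ok else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.pvalue)


def compare_deviance_by_sb(
    deviance: pd.Series, sb_cats: pd.Series
) -> pd.DataFrame:
    """Pairwise Mann-Whitney U p-values of a per-gene statistic across the
    five SB bins.  Pairs where either bin has fewer than two genes are NA."""
    idx = deviance.index.intersection(sb_cats.index)
    dev = deviance[idx]
    cats = sb_cats[idx]
    out = pd.DataFrame(np.nan, index=list(SB_CATEGORIES), columns=list(SB_CATEGORIES))
    for a, b in combinations(SB_CATEGORIES, 2):
        xa = dev[cats == a].dropna().to_numpy()
        xb = dev[cats == b].dropna().to_numpy()
        if len(xa) < 2 or len(xb) < 2:
            continue
        p = _mannwhitney(xa, xb)
        out.loc[a, b] = p
        out.loc[b, a] = p
    np.fill_diagonal(out.values, 1.0)
    return out


def proportion_test_z(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test, no continuity correction.

    Returns (z, two-sided p); a degenerate pooled proportion (0 or 1) gives
    (0, 1).
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise ValueError("n must be positive")
        if not 0 <= k <= n:
            raise ValueError("k must lie in [0, n]")
    pool = (k1 + k2) / (n1 + n2)
    if pool in (0.0, 1.0):
        return 0.0, 1.0
    se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    z = (k1 / n1 - k2 / n2) / se
    return float(z), float(2 * stats.norm.sf(abs(z)))


def proportion_test_fisher(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher's exact p on [[k1, n1-k1], [k2, n2-k2]]."""
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise ValueError("n must be positive")
        if not 0 <= k <= n:
            raise ValueError("k must lie in [0, n]")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=np.int64)
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


@dataclass
class OverlapTable:
    """Shared-CR contingency between two scopes."""

    scope_pair: tuple[str, str]
    n11: int  # CR in both
    n10: int
    n01: int
    n00: int
    chi2: float
    p: float
    direction: str  # over | under representation of shared CR
    reason: str | None = None


def overlap_chi2(
    calls_a: pd.Series,
    calls_b: pd.Series,
    scope_pair: tuple[str, str] = ("scope1", "scope2"),
    min_genes: int = 20,
) -> OverlapTable:
    """Chi-square test (no continuity correction) for shared CR calls.

    Inputs are per-gene CR booleans; gene sets are intersected first.
    Direction is "over" when the shared-CR cell exceeds its expectation
    under independence.  A zero margin yields p = NA with a reason.
    """
    common = calls_a.index.intersection(calls_b.index)
    if len(common) < min_genes:
        raise ValueError(f"fewer than {min_genes} genes shared between scopes")
    a = calls_a[common].astype(bool)
    b = calls_b[common].astype(bool)
    n11 = int((a & b).sum())
    n10 = int((a & ~b).sum())
    n01 = int((~a & b).sum())
    n00 = int((~a & ~b).sum())
    table = np.array([[n11, n10], [n01, n00]], dtype=float)
    n = table.sum()
    expected11 = (n11 + n10) * (n11 + n01) / n
    direction = "over" if n11 >= expected11 else "under"
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return OverlapTable(
            scope_pair, n11, n10, n01, n00, np.nan, np.nan, direction,
            reason="zero margin",
        )
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return OverlapTable(scope_pair, n11, n10, n01, n00, float(chi2), float(p), direction)


def tissue_specificity(expression, focal_index: int) -> float:
    """Fraction of a gene's atlas-wide expression found in the focal tissue."""
    v = np.asarray(expression, dtype=float)
    if (v < 0).any():
        raise ValueError("expression must be nonnegative")
    total = v.sum()
    if total == 0:
        return np.nan
    return float(v[focal_index] / total)


def spearman_assoc(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with its p-value.

    Returns (nan, nan) for constant input or fewer than 3 finite pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan, np.nan
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
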