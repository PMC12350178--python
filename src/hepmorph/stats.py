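"""Statistical utilities used on pipeline outputs: exact two-tailed
Mann–Whitney U, Gaussian kernel density curves, and composition percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats as sps

__all__ = ["MWResult", "mann_whitney", "kde_curve", "composition_percentages"]

EXACT_LIMIT = 20       # exact enumeration for n1 + n2 <= this, no ties
N_PERMUTATIONS = 10_000


@dataclass
class MWResult:
    U: float
    p: float
    n1: int
    n2: int
    method: str  # 'exact' | 'permutation' | 'normal'


def _exact_u_counts(n1: int, n2: int) -> np.ndarray:
    """Number of rank assignments giving each U_x value for sizes n1, n2.

    Classic null-distribution recurrence (tie-free):
    c(i, j, u) = c(i-1, j, u-j) + c(i, j-1, u), the Gaussian-binomial
    counting of partitions fitting in an i x j box.
    """
    max_u = n1 * n2
    c = np.zeros((n1 + 1, n2 + 1, max_u + 1))
    c[0, :, 0] = 1.0
    c[:, 0, 0] = 1.0
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            c[i, j, j:] = c[i - 1, j, : max_u + 1 - j]
            c[i, j, :j] = 0.0
            c[i, j] += c[i, j - 1]
    return c[n1, n2]


def mann_whitney(x, y, seed: int = 0) -> MWResult:
    """Two-tailed Mann–Whitney U test.

    U = min(U_x, U_y).  For n1 + n2 <= 20 without ties the p value is exact:
    2 x P(U <= u_obs) under full enumeration of rank assignments, capped at 1.
    Ties in the exact regime fall back to a seeded permutation distribution
    over the observed values; larger samples use the normal approximation
    with tie-corrected variance and continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    r1 = ranks[:n1].sum()
    u_x = r1 - n1 * (n1 + 1) / 2.0
    u_y = n1 * n2 - u_x
    u = min(u_x, u_y)
    has_ties = len(np.unique(combined)) < n1 + n2

    if n1 + n2 <= EXACT_LIMIT and not has_ties:
        counts = _exact_u_counts(n1, n2)
        total = comb(n1 + n2, n1)
        p_le = counts[: int(u) + 1].sum() / total
        p = min(1.0, 2.0 * p_le)
        return MWResult(U=u, p=p, n1=n1, n2=n2, method="exact")

    if n1 + n2 <= EXACT_LIMIT:
        rng = np.random.default_rng(seed)
        cnt = 0
        for _ in range(N_PERMUTATIONS):
            perm = rng.permutation(combined)
            pr = sps.rankdata(perm)[:n1].sum()
            pu_x = pr - n1 * (n1 + 1) / 2.0
            pu = min(pu_x, n1 * n2 - pu_x)
            if pu <= u:
                cnt += 1
        p = min(1.0, (cnt + 1) / (N_PERMUTATIONS + 1))
        return MWResult(U=u, p=p, n1=n1, n2=n2, method="permutation")

    # normal approximation with tie correction and continuity correction
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return MWResult(U=u, p=1.0, n1=n1, n2=n2, method="normal")
    z = (u - n1 * n2 / 2.0 + 0.5) / np.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.cdf(z))
    return MWResult(U=u, p=p, n1=n1, n2=n2, method="normal")


def kde_curve(values, grid: np.ndarray | None = None,
              bandwidth: float | str = "scott",
              n_grid: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density estimate on a stated grid.

    Scott's-rule bandwidth by default; constant input raises with a hint to
    pass an explicit bandwidth.  Returns (grid, density); the density
    integrates to ~1 over a grid extending 4 bandwidths past the data.
    """
    values = np.asarray(values, float)
    if len(values) < 2:
        raise ValueError("need at least 2 values for a density estimate")
    if np.ptp(values) == 0 and not isinstance(bandwidth, (int, float)):
        raise ValueError(
            "all values identical: automatic bandwidth is zero; "
            "pass an explicit numeric bandwidth"
        )
    if isinstance(bandwidth, (int, float)):
        h = float(bandwidth)
        if grid is None:
            grid = np.linspace(values.min() - 4 * h, values.max() + 4 * h, n_grid)
        grid = np.asarray(grid, float)
        # explicit kernel sum; robust to zero-variance data
        dens = np.exp(-0.5 * ((grid[:, None] - values[None, :]) / h) ** 2).sum(1)
        return grid, dens / (len(values) * h * np.sqrt(2 * np.pi))
    kde = sps.gaussian_kde(values, bw_method=bandwidth)
    h = kde.factor * values.std(ddof=1)
    if grid is None:
        grid = np.linspace(values.min() - 4 * h, values.max() + 4 * h, n_grid)
    return np.asarray(grid, float), kde(grid)


def composition_percentages(counts) -> np.ndarray:
    """Per-structure cell-type percentages from raw counts.

    ``counts`` is a 1D count vector or a 2D array (structures x types);
    each row is scaled to sum to 100.
    """
    c = np.atleast_2d(np.asarray(counts, float))
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    totals = c.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("a structure has zero total count")
    out = 100.0 * c / totals
    return out[0] if np.asarray(counts).ndim == 1 else out
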