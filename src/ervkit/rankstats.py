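"""Rank statistics used throughout the figures-level analyses.

Self-contained implementations of the Mann-Whitney U test (independent
samples), the Wilcoxon signed-rank test (paired samples) and the Pearson
correlation.  Small tie-free inputs are handled by exact enumeration of the
permutation / sign-flip null; larger or tied inputs fall back on the normal
approximation with midranks, tie correction and (optionally) a continuity
correction.  Two-sided p-values use the conventional doubling rule
``min(1, 2 * min(tail p))``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import norm, rankdata

TWO_SIDED = "two_sided"
GREATER = "greater"
LESS = "less"
_SIDES = (TWO_SIDED, GREATER, LESS)

#: Largest total sample size for which the exact null is enumerated.
EXACT_N_MAX = 12


@dataclass
class TestResult:
    statistic: float
    p_value: float
    side: str
    n_effective: int
    method: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def _check_side(side: str) -> None:
    if side not in _SIDES:
        raise ValueError(f"side must be one of {_SIDES}, got {side!r}")


def _two_sided(p_less: float, p_greater: float) -> float:
    return min(1.0, 2.0 * min(p_less, p_greater))


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _mwu_exact_tails(ranks: np.ndarray, n_x: int, u_obs: float) -> tuple[float, float]:
    """Tail probabilities of U_x by enumerating all C(n, n_x) label
    assignments of the observed ranks to group x."""
    n = len(ranks)
    offset = n_x * (n_x + 1) / 2.0
    total = 0
    le = 0
    ge = 0
    for idx in combinations(range(n), n_x):
        u = ranks[list(idx)].sum() - offset
        total += 1
        if u <= u_obs + 1e-9:
            le += 1
        if u >= u_obs - 1e-9:
            ge += 1
    return le / total, ge / total


def mann_whitney_u(
    x,
    y,
    side: str = TWO_SIDED,
    *,
    exact: bool | None = None,
    continuity: bool = True,
) -> TestResult:
    """Mann-Whitney U test for two independent samples.

    The statistic is ``U_x``, the number of (x, y) pairs with x ranked above
    y (ties counted half via midranks).  ``side='greater'`` tests whether x
    tends to exceed y.  With ``exact=None`` the exact permutation null is
    enumerated whenever ``n_x + n_y <= 12`` and there are no ties.
    """
    _check_side(side)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n_x, n_y = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks
    u_x = ranks[:n_x].sum() - n_x * (n_x + 1) / 2.0

    has_ties = len(np.unique(pooled)) < len(pooled)
    use_exact = exact if exact is not None else (n_x + n_y <= EXACT_N_MAX and not has_ties)

    if use_exact:
        p_less, p_greater = _mwu_exact_tails(ranks, n_x, u_x)
        method = "exact"
    else:
        n = n_x + n_y
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = (counts**3 - counts).sum() / (n * (n - 1)) if n > 1 else 0.0
        mu = n_x * n_y / 2.0
        var = n_x * n_y / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p_less = p_greater = 1.0
        else:
            sd = np.sqrt(var)
            cc = 0.5 if continuity else 0.0
            p_greater = float(norm.sf((u_x - mu - cc) / sd))
            p_less = float(norm.cdf((u_x - mu + cc) / sd))
        method = "normal"

    if side == GREATER:
        p = p_greater
    elif side == LESS:
        p = p_less
    else:
        p = _two_sided(p_less, p_greater)
    return TestResult(float(u_x), min(1.0, p), side, n_x + n_y, method)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _wsr_exact_tails(ranks: np.ndarray, w_obs: float) -> tuple[float, float]:
    """Tail probabilities of W+ by enumerating all 2^n sign patterns."""
    n = len(ranks)
    total = 1 << n
    le = 0
    ge = 0
    for mask in range(total):
        w = 0.0
        for i in range(n):
            if mask >> i & 1:
                w += ranks[i]
        if w <= w_obs + 1e-9:
            le += 1
        if w >= w_obs - 1e-9:
            ge += 1
    return le / total, ge / total


def wilcoxon_signed_rank(
    x,
    y=None,
    side: str = TWO_SIDED,
    *,
    exact: bool | None = None,
    continuity: bool = True,
) -> TestResult:
    """Wilcoxon signed-rank test on paired samples (or raw differences).

    Zero differences are dropped; ``n_effective`` reports the pairs that
    remain.  The statistic is ``W+``, the sum of midranks of the positive
    differences; ``side='greater'`` tests whether x tends to exceed y.  All
    differences zero is reported as ``p = 1.0`` with ``n_effective = 0``
    rather than an error.  The exact sign-flip null is enumerated whenever
    ``n_effective <= 12`` and the |differences| carry no tied ranks.
    """
    _check_side(side)
    x = np.asarray(x, dtype=float)
    if y is not None:
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("paired samples must have equal length")
        d = x - y
    else:
        d = x
    if d.size == 0:
        raise ValueError("at least one pair is required")
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult(0.0, 1.0, side, 0, "degenerate")

    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()

    has_ties = len(np.unique(np.abs(d))) < n
    use_exact = exact if exact is not None else (n <= EXACT_N_MAX and not has_ties)

    if use_exact:
        p_less, p_greater = _wsr_exact_tails(ranks, w_plus)
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        _, counts = np.unique(np.abs(d), return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (counts**3 - counts).sum() / 48.0
        if var <= 0:
            p_less = p_greater = 1.0
        else:
            sd = np.sqrt(var)
            cc = 0.5 if continuity else 0.0
            p_greater = float(norm.sf((w_plus - mu - cc) / sd))
            p_less = float(norm.cdf((w_plus - mu + cc) / sd))
        method = "normal"

    if side == GREATER:
        p = p_greater
    elif side == LESS:
        p = p_less
    else:
        p = _two_sided(p_less, p_greater)
    return TestResult(float(w_plus), min(1.0, p), side, n, method)


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

class ZeroVarianceError(ValueError):
    """Raised when a correlation is requested for a constant vector."""


def pearson_r(x, y) -> float:
    """Sample Pearson correlation; requires length >= 3 and nonzero variance
    in both vectors (a constant vector raises ``ZeroVarianceError`` instead
    of leaking NaN)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        raise ZeroVarianceError("correlation undefined for a constant vector")
    r = float((xc * yc).sum() / (sx * sy))
    return max(-1.0, min(1.0, r))
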