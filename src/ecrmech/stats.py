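"""Cohort-level statistics: Poisson-binomial aggregation and Mann–Whitney U.

Both are implemented from first principles because their exact conventions
(strict upper tail by convolution; tie-corrected U with exact enumeration
at small n) are part of the analysis contract; scipy serves as an
independent cross-check in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

__all__ = ["poisson_binomial_tail", "poisson_binomial_pmf", "mann_whitney_u", "MannWhitneyResult"]


def poisson_binomial_pmf(probs: list[float] | np.ndarray) -> np.ndarray:
    """Exact pmf of a sum of independent Bernoulli(p_i) by convolution DP."""
    probs = np.asarray(probs, dtype=float)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    pmf = np.array([1.0])
    for p in probs:
        nxt = np.zeros(len(pmf) + 1)
        nxt[: len(pmf)] += pmf * (1.0 - p)
        nxt[1:] += pmf * p
        pmf = nxt
    return pmf


def poisson_binomial_tail(probs: list[float] | np.ndarray, k: int) -> float:
    """P(X >= k) for the Poisson-binomial sum of the given probabilities."""
    pmf = poisson_binomial_pmf(probs)
    if k <= 0:
        return 1.0
    if k >= len(pmf):
        return 0.0
    return float(min(1.0, pmf[k:].sum()))


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    p_value: float
    alternative: str
    method: str  # "exact" or "normal"


def _u_statistic(x, y) -> float:
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def mann_whitney_u(x, y, alternative: str = "two-sided") -> MannWhitneyResult:
    """Mann–Whitney U test by pair counting.

    U counts pairs (x_i, y_j) with x_i > y_j, crediting 0.5 to ties.  The
    p-value is exact (full label enumeration) when n_x + n_y <= 20 and no
    ties are present, otherwise a normal approximation with tie correction
    and continuity correction is used.

    alternative: "two-sided", "greater" (x tends larger), or "less".
    """
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    if not x or not y:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    nx, ny = len(x), len(y)
    u = _u_statistic(x, y)

    pooled = x + y
    has_ties = len(set(pooled)) < len(pooled)
    if nx + ny <= 20 and not has_ties:
        n = nx + ny
        us = []
        idx = list(range(n))
        for comb in combinations(idx, nx):
            cset = set(comb)
            xs = [pooled[i] for i in comb]
            ys = [pooled[i] for i in idx if i not in cset]
            us.append(_u_statistic(xs, ys))
        us = np.array(us)
        total = len(us)
        p_greater = float(np.sum(us >= u)) / total
        p_less = float(np.sum(us <= u)) / total
        if alternative == "greater":
            p = p_greater
        elif alternative == "less":
            p = p_less
        else:
            p = min(1.0, 2.0 * min(p_greater, p_less))
        return MannWhitneyResult(u, p, alternative, "exact")

    # normal approximation with tie correction
    mu = nx * ny / 2.0
    n = nx + ny
    _, counts = np.unique(np.array(pooled), return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all observations identical
        return MannWhitneyResult(u, 1.0, alternative, "normal")
    sd = math.sqrt(var)
    if alternative == "greater":
        z = (u - mu - 0.5) / sd
        p = 1.0 - _phi(z)
    elif alternative == "less":
        z = (u - mu + 0.5) / sd
        p = _phi(z)
    else:
        z = (abs(u - mu) - 0.5) / sd
        p = 2.0 * (1.0 - _phi(z))
    return MannWhitneyResult(u, float(min(1.0, max(0.0, p))), alternative, "normal")


def _phi(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))
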