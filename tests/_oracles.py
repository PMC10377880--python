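"""Independent brute-force oracles used by the test suite.

These deliberately avoid the production code paths: counting builds explicit
cell-tuple sets, the rank statistics are enumerated directly, and closed
forms are evaluated from first principles.
"""

import itertools
import math

import numpy as np


def count_boxes_bruteforce(points: np.ndarray, r: int) -> int:
    """Distinct grid cells as a Python set of integer tuples."""
    cells = set()
    for p in np.atleast_2d(points):
        cells.add(tuple(min(int(c * r), r - 1) for c in p))
    return len(cells)


def mann_whitney_u_bruteforce(x, y) -> float:
    """U for sample x by direct pairwise comparison (0.5 credit for ties)."""
    u = 0.0
    for a in x:
        for b in y:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u


def exact_two_sided_p(x, y) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all group assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = mann_whitney_u_bruteforce(x, y)
    mid = len(x) * len(y) / 2.0
    dev_obs = abs(u_obs - mid)
    total = extreme = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(len(pooled)) if i not in comb]
        total += 1
        if abs(mann_whitney_u_bruteforce(xs, ys) - mid) >= dev_obs - 1e-12:
            extreme += 1
    return extreme / total


def spearman_no_ties(x, y) -> float:
    """1 - 6*sum(d^2)/(n(n^2-1)) from raw ranks (valid without ties)."""
    rx = np.argsort(np.argsort(x))
    ry = np.argsort(np.argsort(y))
    n = len(x)
    d2 = float(np.sum((rx - ry) ** 2))
    return 1.0 - 6.0 * d2 / (n * (n * n - 1))


def chi2_2x2(table) -> float:
    """Direct 2x2 chi-squared formula, no continuity correction."""
    (a, b), (c, d) = table
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def folded_normal_activation_fraction() -> float:
    """P(|X| > mu_|X| + sigma_|X|) for X ~ N(0,1)."""
    mu = math.sqrt(2.0 / math.pi)
    sigma = math.sqrt(1.0 - 2.0 / math.pi)
    t = mu + sigma
    return math.erfc(t / math.sqrt(2.0))  # = 2 * (1 - Phi(t))
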