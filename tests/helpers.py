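"""Independent oracles used to cross-check the package's algorithms.

Everything here is deliberately brute force: exhaustive enumeration of
change-point placements, full permutation nulls, and optimal assignment via
the Hungarian algorithm.  None of it shares code with the implementations it
checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.optimize import linear_sum_assignment


def exhaustive_changepoints(
    x: np.ndarray, penalty: float, min_size: int = 2, max_k: int = 5
) -> list[int]:
    """Best change-point set by scoring every admissible placement.

    Enumerates all placements of k = 0..max_k change points with segments of
    at least ``min_size`` samples and returns the placement minimizing
    (sum of segment squared residuals) + penalty * k.
    """
    x = np.asarray(x, dtype=float)
    T = x.size
    s1 = np.concatenate(([0.0], np.cumsum(x)))
    s2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def cost(a: int, b: int) -> float:
        tot = s1[b] - s1[a]
        return (s2[b] - s2[a]) - tot * tot / (b - a)

    best_cost = cost(0, T)
    best: tuple[int, ...] = ()
    valid_positions = range(min_size, T - min_size + 1)
    for k in range(1, max_k + 1):
        for combo in combinations(valid_positions, k):
            if any(b - a < min_size for a, b in zip(combo, combo[1:])):
                continue
            bounds = (0, *combo, T)
            c = sum(cost(a, b) for a, b in zip(bounds[:-1], bounds[1:]))
            c += penalty * k
            if c < best_cost - 1e-12:
                best_cost = c
                best = combo
    return list(best)


def permutation_mann_whitney(a, b) -> dict:
    """Exact two-sided Mann-Whitney p by full enumeration of assignments.

    U is computed from scratch by pairwise comparison (ties count half);
    the two-sided p is 2 * min(P(U <= u), P(U >= u)), capped at 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n, n_a = pooled.size, a.size

    def u_stat(idx_a):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx_a)] = True
        xa, xb = pooled[mask], pooled[~mask]
        gt = (xa[:, None] > xb[None, :]).sum()
        eq = (xa[:, None] == xb[None, :]).sum()
        return gt + 0.5 * eq

    u_obs = u_stat(range(n_a))
    le = ge = total = 0
    for idx in combinations(range(n), n_a):
        u = u_stat(idx)
        total += 1
        if u <= u_obs + 1e-9:
            le += 1
        if u >= u_obs - 1e-9:
            ge += 1
    return {"U": float(u_obs), "p": min(1.0, 2.0 * min(le, ge) / total)}


def optimal_match_count(points_a, points_b, radius: float) -> int:
    """Maximum one-to-one matches within ``radius`` (Hungarian oracle)."""
    pa = np.atleast_2d(points_a)
    pb = np.atleast_2d(points_b)
    if pa.shape[0] == 0 or pb.shape[0] == 0:
        return 0
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    cost = (d > radius).astype(float)  # 0 if matchable, 1 otherwise
    rows, cols = linear_sum_assignment(cost)
    return int((d[rows, cols] <= radius).sum())
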