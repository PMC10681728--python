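"""Penalized least-squares change-point detection for piecewise-constant signals.

The model: a signal ``x`` is a sequence of constant levels plus noise.  A
segmentation with change points ``0 < c_1 < ... < c_k < T`` is scored by

    sum over segments of the within-segment sum of squared residuals
    + penalty * k

and the segmentation minimizing this criterion is returned.  The optimum is
found exactly with the PELT algorithm (pruned exact linear time); pruning
relies only on the subadditivity of the squared-error cost, so the result is
identical to exhaustive enumeration over all admissible segmentations, which
is what the test suite checks it against.

A minimum segment length can be imposed; change points closer than that to
each other or to either end are not considered.
"""

from __future__ import annotations

import numpy as np

__all__ = ["pelt_mean_shift", "segment_means", "estimate_noise_sd"]


def estimate_noise_sd(x: np.ndarray) -> float:
    """Robust noise SD from first differences.

    For x_t = level_t + e_t with e ~ N(0, s^2) and sparse level changes,
    diff(x) ~ N(0, 2 s^2) except at the changes; the median absolute
    difference is insensitive to those, giving
    s = median|diff| / (sqrt(2) * z_0.75), z_0.75 = 0.674489...
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return 0.0
    mad = float(np.median(np.abs(np.diff(x))))
    return mad / (np.sqrt(2.0) * 0.6744897501960817)


def pelt_mean_shift(
    x: np.ndarray, penalty: float, min_size: int = 1
) -> list[int]:
    """Exact minimizer of penalized least squares for a mean-shift model.

    Parameters
    ----------
    x : array
        Signal values.
    penalty : float
        Cost added per change point (>= 0).
    min_size : int
        Minimum number of samples per segment.

    Returns
    -------
    list of int
        Change-point positions ``c`` meaning the level changes between
        samples ``c-1`` and ``c`` (0 < c < len(x)), in increasing order.
    """
    x = np.asarray(x, dtype=float)
    T = x.size
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if T < min_size:
        return []

    s1 = np.concatenate(([0.0], np.cumsum(x)))
    s2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def seg_cost(starts: np.ndarray, end: int) -> np.ndarray:
        n = end - starts
        tot = s1[end] - s1[starts]
        return (s2[end] - s2[starts]) - tot * tot / n

    f = np.full(T + 1, np.inf)
    f[0] = -penalty
    last = np.zeros(T + 1, dtype=int)
    # candidate segment starts, kept sorted; entries > t - min_size are
    # not yet admissible and are exempt from pruning
    cand = np.array([0], dtype=int)

    for t in range(min_size, T + 1):
        valid = cand[cand <= t - min_size]
        if valid.size == 0:
            continue
        vals = f[valid] + seg_cost(valid, t) + penalty
        i = int(np.argmin(vals))
        f[t] = vals[i]
        last[t] = valid[i]
        # PELT pruning: a start s with f[s]+cost(s,t) > f[t] can never be
        # optimal for any later end (squared-error cost is subadditive)
        keep = valid[f[valid] + seg_cost(valid, t) <= f[t]]
        pending = cand[cand > t - min_size]
        cand = np.concatenate((keep, pending, [t]))

    # backtrack
    cps: list[int] = []
    t = T
    while t > 0:
        s = last[t]
        if s > 0:
            cps.append(int(s))
        t = s
    cps.reverse()
    return cps


def segment_means(x: np.ndarray, change_points: list[int]) -> np.ndarray:
    """Per-segment means for a segmentation given by change-point positions."""
    x = np.asarray(x, dtype=float)
    bounds = [0, *change_points, x.size]
    return np.array(
        [x[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])], dtype=float
    )
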