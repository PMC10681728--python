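"""Two-channel point colocalization, occupancy, and intensity correlation.

Foci detected in the two imaging channels are matched one-to-one by greedy
nearest-neighbor pairing in increasing distance order, up to a capture
radius (default 1 pixel, roughly one diffraction-limited focus at curtain
scale).  The colocalization fraction is matched A foci over all A foci;
occupancy statistics aggregate at replicate (field) level, and the intensity
relationship between matched channels is summarized by Pearson's r.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

__all__ = [
    "ColocPair",
    "colocalize",
    "occupancy_percentage",
    "intensity_correlation",
]


@dataclass(frozen=True)
class ColocPair:
    """One channel-A focus and its channel-B partner, if matched."""

    index_a: int
    position_a: tuple
    intensity_a: Optional[float] = None
    index_b: Optional[int] = None
    position_b: Optional[tuple] = None
    intensity_b: Optional[float] = None
    matched: bool = False
    distance: Optional[float] = None


def colocalize(
    points_a: np.ndarray,
    points_b: np.ndarray,
    radius: float = 1.0,
    intensities_a: Optional[np.ndarray] = None,
    intensities_b: Optional[np.ndarray] = None,
) -> dict:
    """Greedy one-to-one nearest-neighbor matching within a capture radius.

    Candidate A-B pairs closer than ``radius`` are sorted by distance (ties
    broken by index for determinism) and accepted greedily, each focus used
    at most once.  Returns the pair list, the matched fraction of channel-A
    foci, and the counts (n matched / N total).
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    pa = np.atleast_2d(np.asarray(points_a, dtype=float))
    pb = np.atleast_2d(np.asarray(points_b, dtype=float))
    if pa.shape[0] == 0:
        raise ValueError("channel A is empty: colocalization fraction undefined")

    cands: list[tuple[float, int, int]] = []
    if pb.shape[0] > 0:
        tree = cKDTree(pb)
        for i, neighbors in enumerate(tree.query_ball_point(pa, r=radius)):
            for j in neighbors:
                d = float(np.linalg.norm(pa[i] - pb[j]))
                cands.append((d, i, j))
    cands.sort()

    matched_a: dict[int, tuple[int, float]] = {}
    used_b: set[int] = set()
    for d, i, j in cands:
        if i in matched_a or j in used_b:
            continue
        matched_a[i] = (j, d)
        used_b.add(j)

    pairs = []
    for i in range(pa.shape[0]):
        ia = float(intensities_a[i]) if intensities_a is not None else None
        if i in matched_a:
            j, d = matched_a[i]
            pairs.append(
                ColocPair(
                    index_a=i,
                    position_a=tuple(pa[i]),
                    intensity_a=ia,
                    index_b=j,
                    position_b=tuple(pb[j]),
                    intensity_b=float(intensities_b[j])
                    if intensities_b is not None
                    else None,
                    matched=True,
                    distance=d,
                )
            )
        else:
            pairs.append(
                ColocPair(index_a=i, position_a=tuple(pa[i]), intensity_a=ia)
            )
    n_matched = len(matched_a)
    n_total = pa.shape[0]
    return {
        "pairs": pairs,
        "fraction": n_matched / n_total,
        "n_matched": n_matched,
        "n_total": n_total,
    }


def occupancy_percentage(fields: Sequence) -> dict:
    """Mean +/- SD occupancy across replicate fields.

    ``fields`` holds :func:`colocalize` results (or bare fractions).  The
    mean and sample SD are taken over per-field percentages — replicate
    level, not pooled foci — mirroring error bars computed across
    independent experiments.
    """
    if len(fields) == 0:
        raise ValueError("need at least one field")
    pcts = np.array(
        [
            100.0 * (f["fraction"] if isinstance(f, dict) else float(f))
            for f in fields
        ]
    )
    return {
        "mean": float(pcts.mean()),
        "sd": float(pcts.std(ddof=1)) if pcts.size > 1 else float("nan"),
        "n_fields": int(pcts.size),
        "per_field": pcts,
    }


def intensity_correlation(pairs: Sequence[ColocPair]) -> dict:
    """Pearson correlation of matched-pair intensities.

    Requires >= 3 matched pairs with intensities in both channels and
    nonzero variance in each channel.
    """
    xs, ys = [], []
    for p in pairs:
        if p.matched and p.intensity_a is not None and p.intensity_b is not None:
            xs.append(p.intensity_a)
            ys.append(p.intensity_b)
    x = np.asarray(xs)
    y = np.asarray(ys)
    if x.size < 3:
        raise ValueError("need >= 3 matched pairs with intensities")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a channel: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": int(x.size)}
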