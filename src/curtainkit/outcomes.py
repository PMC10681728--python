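"""Genetic-assay arithmetic and the statistical comparisons used with it.

Covers the plate-count calculators: interhomolog gene-conversion frequency
(selective vs dilution-adjusted non-selective colony counts), red/white
sectored-colony outcome percentages (CO / NCO / BIR over sectored colonies),
MMS survival percentage (treated over untreated CFU), and the two
significance tests used on such data (Mann-Whitney rank test, Welch t-test).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ColonyCounts",
    "OutcomeTable",
    "conversion_frequency",
    "outcome_percentages",
    "survival_percentage",
    "mann_whitney",
    "two_sample_t",
]

#: categories counted among sectored colonies; "other" (chromosome loss,
#: marker-check failures) is accepted in input but excluded from the
#: CO/NCO/BIR denominator, which is sectored colonies only.
OUTCOME_CATEGORIES = ("CO", "NCO", "BIR")


@dataclass
class ColonyCounts:
    """Replicate plate counts for a frequency assay.

    ``selective`` and ``nonselective`` are per-replicate colony counts.
    The non-selective culture is plated after ``dilution_factor``-fold
    dilution; plated volumes (ul) allow adjustment when they differ.
    """

    selective: np.ndarray
    nonselective: np.ndarray
    dilution_factor: float = 1.0
    volume_selective_ul: float = 30.0
    volume_nonselective_ul: float = 30.0

    def __post_init__(self) -> None:
        self.selective = np.atleast_1d(np.asarray(self.selective, dtype=int))
        self.nonselective = np.atleast_1d(np.asarray(self.nonselective, dtype=int))
        if self.selective.shape != self.nonselective.shape:
            raise ValueError("selective/nonselective need one count per replicate")
        if (self.selective < 0).any() or (self.nonselective < 0).any():
            raise ValueError("counts must be non-negative integers")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if min(self.volume_selective_ul, self.volume_nonselective_ul) <= 0:
            raise ValueError("plated volumes must be positive")

    @property
    def n_replicates(self) -> int:
        return self.selective.size


@dataclass
class OutcomeTable:
    """Per-replicate category counts among sectored colonies."""

    counts: pd.DataFrame  # columns: replicate plus category counts

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.counts)
        for cat in OUTCOME_CATEGORIES:
            if cat not in df.columns:
                df[cat] = 0
        if (df[list(OUTCOME_CATEGORIES)] < 0).any().any():
            raise ValueError("counts must be non-negative")
        self.counts = df


def conversion_frequency(counts: ColonyCounts) -> dict:
    """Gene-conversion frequency per replicate, with mean and SD.

    frequency = selective / (nonselective * dilution * volume ratio),
    the "adjusted" count being the non-selective count scaled back to the
    same plated volume of undiluted culture as the selective plate:

        cells plated selectively  = c * V_sel
        cells per non-sel. colony = dilution / 1  (each colony = 1 cell)
        frequency = (sel / V_sel) / (nonsel * dilution / V_nonsel)
    """
    if (counts.nonselective == 0).any():
        raise ValueError("every replicate needs a non-zero non-selective count")
    volume_ratio = counts.volume_selective_ul / counts.volume_nonselective_ul
    freq = counts.selective / (
        counts.nonselective * counts.dilution_factor * volume_ratio
    )
    return {
        "frequencies": freq,
        "mean": float(freq.mean()),
        "sd": float(freq.std(ddof=1)) if freq.size > 1 else float("nan"),
        "n": int(freq.size),
        "formula": "selective/(nonselective*dilution*volume_sel/volume_nonsel)",
    }


def outcome_percentages(table: OutcomeTable) -> dict:
    """CO / NCO / BIR percentages of sectored colonies, per replicate.

    Each category count is divided by that replicate's total sectored
    colonies (CO+NCO+BIR; "other" outcomes are excluded from the
    denominator) and multiplied by 100; mean and SD are taken across
    replicates.  Per-replicate percentages sum to 100 by construction.
    """
    df = table.counts
    totals = df[list(OUTCOME_CATEGORIES)].sum(axis=1)
    if (totals == 0).any():
        raise ValueError("every replicate needs at least one sectored colony")
    out = {}
    per_rep = {}
    for cat in OUTCOME_CATEGORIES:
        pct = 100.0 * df[cat] / totals
        per_rep[cat] = pct.to_numpy(dtype=float)
        out[cat] = {
            "mean": float(pct.mean()),
            "sd": float(pct.std(ddof=1)) if len(pct) > 1 else float("nan"),
        }
    out["n_replicates"] = int(len(df))
    out["per_replicate"] = per_rep
    return out


def survival_percentage(
    treated_cfu,
    untreated_cfu,
    treated_dilution: float = 1.0,
    untreated_dilution: float = 1.0,
):
    """Survival after treatment: 100 * treated CFU / untreated CFU.

    Counts are adjusted for their plating dilutions before the ratio is
    taken.  Accepts scalars or per-replicate arrays (returned elementwise).
    """
    treated = np.asarray(treated_cfu, dtype=float) * treated_dilution
    untreated = np.asarray(untreated_cfu, dtype=float) * untreated_dilution
    if np.any(untreated <= 0):
        raise ValueError("untreated CFU must be > 0")
    out = 100.0 * treated / untreated
    return float(out) if out.ndim == 0 else out


def _rank_sum_u(pooled_ranks: np.ndarray, idx_a, n_a: int) -> float:
    return float(pooled_ranks[list(idx_a)].sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney(sample_a: Sequence[float], sample_b: Sequence[float]) -> dict:
    """Two-sided Mann-Whitney rank test.

    For combined n <= 12 the null distribution of U is enumerated exactly
    over all assignments of the pooled (midrank-tied) observations; the
    two-sided p is 2 * min(P(U <= u), P(U >= u)), capped at 1.  For larger
    samples the tie- and continuity-corrected normal approximation is used.

    Returns ``{"U": ..., "p": ..., "method": ...}`` with U counted for
    sample_a (pairs where a exceeds b, ties counted half).
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_obs = _rank_sum_u(ranks, range(n_a), n_a)

    if n <= 12:
        total = comb(n, n_a)
        le = ge = 0
        for idx in combinations(range(n), n_a):
            u = _rank_sum_u(ranks, idx, n_a)
            if u <= u_obs + 1e-9:
                le += 1
            if u >= u_obs - 1e-9:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
        method = "exact enumeration"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "normal approximation (tie/continuity corrected)"
    return {"U": u_obs, "p": float(p), "n_a": n_a, "n_b": n_b, "method": method}


def two_sample_t(sample_a: Sequence[float], sample_b: Sequence[float]) -> dict:
    """Welch two-sided t-test (unequal variances)."""
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        equal = a.mean() == b.mean()
        return {"t": 0.0 if equal else float("inf"), "p": 1.0 if equal else 0.0}
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {"t": float(t), "p": float(p)}
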