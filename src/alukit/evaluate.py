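"""Call-set comparison within coordinate windows and cohort statistics.

Two call sets intersect when calls lie within a closed +/- window on the
same chromosome; sensitivity, precision and false discovery rate follow
from the overlap counts, with percentages rounded half-up to one decimal
(raw fractions retained).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .breakpoint import BreakpointCall
from .classify import percent

__all__ = [
    "CallSet",
    "PerformanceRow",
    "intersect_within",
    "performance_metrics",
    "performance_from_counts",
    "cohort_stats",
]


@dataclass
class CallSet:
    name: str
    calls: List[Tuple[str, int]]  # (chrom, position)

    def __len__(self) -> int:
        return len(self.calls)


@dataclass
class PerformanceRow:
    predicted: int
    predicted_with_overlap: int
    truth: int
    truth_with_overlap: int
    sensitivity: float  # raw fraction
    precision: float
    fdr: float
    sensitivity_pct: float  # rounded to one decimal
    precision_pct: float
    fdr_pct: float
    precision_defined: bool = True


def intersect_within(
    a: CallSet, b: CallSet, window: int
) -> Tuple[int, int]:
    """Counts of A calls with a B call within +/-window, and vice versa.

    The window is closed: distance exactly equal to ``window`` counts.
    Each call is counted once regardless of how many partners it has.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    by_chrom_b: Dict[str, np.ndarray] = {}
    for chrom, pos in b.calls:
        by_chrom_b.setdefault(chrom, []).append(pos)
    by_chrom_b = {c: np.sort(np.array(p)) for c, p in by_chrom_b.items()}
    by_chrom_a: Dict[str, np.ndarray] = {}
    for chrom, pos in a.calls:
        by_chrom_a.setdefault(chrom, []).append(pos)
    by_chrom_a = {c: np.sort(np.array(p)) for c, p in by_chrom_a.items()}

    def count_hits(query: Dict[str, np.ndarray], target: Dict[str, np.ndarray]):
        hits = 0
        for chrom, positions in query.items():
            t = target.get(chrom)
            if t is None or len(t) == 0:
                continue
            lo = np.searchsorted(t, positions - window, side="left")
            hi = np.searchsorted(t, positions + window, side="right")
            hits += int((hi > lo).sum())
        return hits

    return count_hits(by_chrom_a, by_chrom_b), count_hits(by_chrom_b, by_chrom_a)


def performance_from_counts(
    predicted: int,
    predicted_with_overlap: int,
    truth: int,
    truth_with_overlap: int,
) -> PerformanceRow:
    """Sensitivity / precision / FDR from overlap counts.

    ``sensitivity = truth_with_overlap / truth``;
    ``precision = predicted_with_overlap / predicted``; ``fdr = 1 -
    precision``.  An empty predicted set leaves precision undefined
    (reported as 0 with ``precision_defined=False``).
    """
    if truth <= 0:
        raise ValueError("truth count must be positive")
    sens = truth_with_overlap / truth
    if predicted > 0:
        prec = predicted_with_overlap / predicted
        defined = True
    else:
        prec = 0.0
        defined = False
    fdr = 1 - prec
    return PerformanceRow(
        predicted=predicted,
        predicted_with_overlap=predicted_with_overlap,
        truth=truth,
        truth_with_overlap=truth_with_overlap,
        sensitivity=sens,
        precision=prec,
        fdr=fdr,
        sensitivity_pct=percent(truth_with_overlap, truth),
        precision_pct=percent(predicted_with_overlap, predicted)
        if defined
        else 0.0,
        fdr_pct=percent(predicted - predicted_with_overlap, predicted)
        if defined
        else 0.0,
        precision_defined=defined,
    )


def performance_metrics(
    predicted: CallSet, truth: CallSet, window: int = 100
) -> PerformanceRow:
    """Window-intersection performance of a predicted set vs a truth set."""
    pred_hits, truth_hits = intersect_within(predicted, truth, window)
    return performance_from_counts(
        len(predicted), pred_hits, len(truth), truth_hits
    )


def cohort_stats(calls: Sequence[BreakpointCall]) -> Dict[str, object]:
    """Insertion-length and TSD summaries over a set of breakpoint calls."""
    if not calls:
        raise ValueError("at least one call is required")
    ins_lengths = np.array([len(c.insert_seq) for c in calls])
    tsd_lengths = np.array([len(c.tsd) for c in calls])
    return {
        "n": len(calls),
        "insert_len_min": int(ins_lengths.min()),
        "insert_len_median": float(np.median(ins_lengths)),
        "insert_len_max": int(ins_lengths.max()),
        "tsd_len_min": int(tsd_lengths.min()),
        "tsd_len_median": float(np.median(tsd_lengths)),
        "tsd_len_max": int(tsd_lengths.max()),
        "n_genotypable": sum(1 for c in calls if c.genotypable),
        "n_overlap": sum(1 for c in calls if c.overlap_len > 0),
        "n_deletion": sum(1 for c in calls if c.target_deletion > 0),
        "n_blunt": sum(
            1 for c in calls if c.overlap_len == 0 and c.target_deletion == 0
        ),
    }
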