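"""Subfamily assignment, 5' truncation measurement and microhomology.

Elements are aligned to a joint profile of the consensus library built by
progressive multiple alignment (pairwise-identity guide order,
profile-profile merges with the affine-gap global aligner).  Divergence to
each subfamily is the proportion of differing aligned columns with the
poly-A tail excluded; exact ties are left unclassified.  Truncation extent
is the first consensus position covered by the element, binned as
full-length (start 1-5), short (7-45) or long (55-171) truncation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .alignment import GlobalAlignParams, global_align
from .genome_io import Genome, reverse_complement

__all__ = [
    "ConsensusLibrary",
    "SubfamilyCall",
    "TruncationCall",
    "MicrohomologyCall",
    "build_profile",
    "assign_subfamily",
    "measure_truncation",
    "truncation_bin",
    "detect_microhomology",
    "summarize_cohort",
    "trim_polyA",
    "percent",
]

TIE_EPS = 1e-12
FULL_LENGTH_MAX = 5
SHORT_TRUNC_RANGE = (7, 45)
LONG_TRUNC_RANGE = (55, 171)


def percent(count: float, total: float, decimals: int = 1) -> float:
    """Percentage with round-half-up at ``decimals`` (table convention)."""
    if total == 0:
        return 0.0
    from decimal import ROUND_HALF_UP, Decimal

    raw = Decimal(count) / Decimal(total) * 100
    quant = Decimal(1).scaleb(-decimals)
    return float(raw.quantize(quant, rounding=ROUND_HALF_UP))


def trim_polyA(seq: str, min_len: int = 5, min_frac: float = 0.80) -> str:
    """Remove the 3'-terminal A-rich run (>= min_len, >= 80% A).

    The run is grown from the 3' end, tolerating isolated non-A bases but
    stopping at two consecutive non-A positions, and always begins on an A.
    """
    cut = None
    non_a = 0
    for i in range(len(seq) - 1, -1, -1):
        if seq[i] == "A":
            non_a = 0
            cut = i
        else:
            non_a += 1
            if non_a >= 2:
                break
    if cut is None:
        return seq
    tail = seq[cut:]
    if len(tail) >= min_len and tail.count("A") / len(tail) >= min_frac:
        return seq[:cut]
    return seq


@dataclass
class ConsensusLibrary:
    """Subfamily consensus sequences plus their joint profile alignment."""

    sequences: Dict[str, str]
    profile: Dict[str, str]  # name -> gapped row, equal lengths

    @property
    def width(self) -> int:
        return len(next(iter(self.profile.values())))

    def degapped(self, name: str) -> str:
        return self.profile[name].replace("-", "")


@dataclass
class SubfamilyCall:
    element_id: str
    subfamily: str  # best subfamily or "unclassified"
    divergence: float
    runner_up_divergence: float
    tie: bool


@dataclass
class TruncationCall:
    consensus_start: int  # 1-based first aligned consensus position
    bin: str  # full_length / short_trunc / long_trunc / other
    consensus_end: int  # 1-based last aligned consensus position


@dataclass
class MicrohomologyCall:
    shared_bases: int
    nic_hexamer: str
    canonical: bool  # 5' T4/A2 pattern


# ---------------------------------------------------------------------------
# profile construction
# ---------------------------------------------------------------------------

_PROFILE_PARAMS = GlobalAlignParams(match=5, mismatch=-4, gap_open=16,
                                    gap_extend=4)


def _pairwise_identity(a: str, b: str) -> float:
    aln = global_align(a, b, _PROFILE_PARAMS)
    matches = sum(1 for q, r in aln.columns() if q == r and q != "-")
    return matches / max(len(a), len(b))


def _column_scores(rows_a: List[str], rows_b: List[str]) -> np.ndarray:
    """Mean pairwise match/mismatch score between profile columns."""
    code = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        code[ord(b)] = i
    A = np.stack(
        [code[np.frombuffer(r.encode(), dtype=np.uint8)] for r in rows_a]
    )
    B = np.stack(
        [code[np.frombuffer(r.encode(), dtype=np.uint8)] for r in rows_b]
    )
    # per-column base counts (gap and N excluded from scoring mass)
    ca = np.stack([(A == i).sum(axis=0) for i in range(4)])  # 4 x wa
    cb = np.stack([(B == i).sum(axis=0) for i in range(4)])
    na = ca.sum(axis=0)
    nb = cb.sum(axis=0)
    matches = ca.T @ cb  # wa x wb: count of equal-base pairs
    totals = np.outer(na, nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(totals > 0, matches / np.maximum(totals, 1), 0.0)
    return frac * _PROFILE_PARAMS.match + (1 - frac) * _PROFILE_PARAMS.mismatch


def _align_profiles(
    rows_a: Dict[str, str], rows_b: Dict[str, str]
) -> Dict[str, str]:
    """Profile-profile global alignment via column score matrix."""
    a_rows = list(rows_a.values())
    b_rows = list(rows_b.values())
    S = _column_scores(a_rows, b_rows)
    n, m = S.shape
    open_, ext = _PROFILE_PARAMS.gap_open, _PROFILE_PARAMS.gap_extend
    NEG = -(10**9)
    M = np.full((n + 1, m + 1), NEG, dtype=np.float64)
    IX = np.full((n + 1, m + 1), NEG, dtype=np.float64)
    IY = np.full((n + 1, m + 1), NEG, dtype=np.float64)
    M[0, 0] = 0
    IX[0, 1:] = -open_ - ext * np.arange(m)
    IY[1:, 0] = -open_ - ext * np.arange(n)
    for i in range(1, n + 1):
        prev = np.maximum(np.maximum(M[i - 1], IX[i - 1]), IY[i - 1])
        M[i, 1:] = prev[:-1] + S[i - 1]
        IY[i] = np.maximum(np.maximum(M[i - 1], IX[i - 1]) - open_,
                           IY[i - 1] - ext)
        A = np.maximum(M[i], IY[i])
        js = np.arange(m)
        run = np.maximum.accumulate(A[:-1] + ext * js)
        IX[i, 1:] = run - open_ - ext * js
    i, j = n, m
    state = int(np.argmax((M[n, m], IY[n, m], IX[n, m])))
    ops: List[str] = []
    while i > 0 or j > 0:
        if state == 0:
            ops.append("M")
            state = int(
                np.argmax((M[i - 1, j - 1], IY[i - 1, j - 1], IX[i - 1, j - 1]))
            )
            i -= 1
            j -= 1
        elif state == 1:
            ops.append("A")  # consume column of A only
            came_open = max(M[i - 1, j], IX[i - 1, j]) - open_
            if came_open >= IY[i - 1, j] - ext:
                state = 0 if M[i - 1, j] >= IX[i - 1, j] else 2
            i -= 1
        else:
            ops.append("B")
            came_open = max(M[i, j - 1], IY[i, j - 1]) - open_
            if came_open >= IX[i, j - 1] - ext:
                state = 0 if M[i, j - 1] >= IY[i, j - 1] else 1
            j -= 1
    ops.reverse()
    out: Dict[str, str] = {}
    for name, row in rows_a.items():
        buf = []
        k = 0
        for op in ops:
            if op in ("M", "A"):
                buf.append(row[k])
                k += 1
            else:
                buf.append("-")
        out[name] = "".join(buf)
    for name, row in rows_b.items():
        buf = []
        k = 0
        for op in ops:
            if op in ("M", "B"):
                buf.append(row[k])
                k += 1
            else:
                buf.append("-")
        out[name] = "".join(buf)
    return out


def build_profile(consensus_sequences: Dict[str, str]) -> ConsensusLibrary:
    """Progressive multiple alignment of the consensus library.

    The merge order follows a greedy highest-identity guide (closest pair
    first), with profile-profile merges scored by mean pairwise column
    score.  De-gapping any profile row reproduces its input sequence.
    """
    if len(consensus_sequences) < 2:
        raise ValueError("at least two consensus sequences are required")
    names = sorted(consensus_sequences)
    ident: Dict[Tuple[str, str], float] = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ident[(a, b)] = _pairwise_identity(
                consensus_sequences[a], consensus_sequences[b]
            )
    clusters: List[Dict[str, str]] = [
        {name: consensus_sequences[name]} for name in names
    ]

    def cluster_identity(ca, cb) -> float:
        vals = []
        for a in ca:
            for b in cb:
                key = (a, b) if (a, b) in ident else (b, a)
                vals.append(ident[key])
        return float(np.mean(vals))

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                v = cluster_identity(clusters[i], clusters[j])
                if best is None or v > best[0]:
                    best = (v, i, j)
        _, i, j = best
        merged = _align_profiles(clusters[i], clusters[j])
        clusters = [
            c for k, c in enumerate(clusters) if k not in (i, j)
        ] + [merged]
    profile = clusters[0]
    return ConsensusLibrary(dict(consensus_sequences), profile)


# ---------------------------------------------------------------------------
# assignment / truncation / microhomology
# ---------------------------------------------------------------------------


def _align_element_to_profile(
    element: str, library: ConsensusLibrary
) -> Dict[str, str]:
    """Add the element as one more row against the joint profile."""
    rows = dict(library.profile)
    merged = _align_profiles(rows, {"__element__": element})
    return merged


def assign_subfamily(
    element: str,
    library: ConsensusLibrary,
    element_id: str = "",
    strand_check: bool = True,
) -> SubfamilyCall:
    """Closest subfamily by proportion of differences, poly-A excluded.

    Ties within ``1e-12`` of the minimum (equivalently, equal mismatch
    counts over the shared alignment) yield ``unclassified``.  The element
    strand is resolved against the library before scoring, so calls are
    strand-invariant.
    """
    if not element:
        raise ValueError("element must be non-empty")
    trimmed = trim_polyA(element.upper())
    if not trimmed:
        trimmed = element.upper()
    if strand_check:
        fwd = max(
            _pairwise_identity(trimmed, s) for s in library.sequences.values()
        )
        rc = reverse_complement(trimmed)
        rev = max(
            _pairwise_identity(rc, s) for s in library.sequences.values()
        )
        if rev > fwd:
            trimmed = rc
    merged = _align_element_to_profile(trimmed, library)
    elem_row = merged["__element__"]
    divergences: Dict[str, float] = {}
    for name in library.sequences:
        row = merged[name]
        aligned = mismatched = 0
        for e, c in zip(elem_row, row):
            if e != "-" and c != "-":
                aligned += 1
                if e != c:
                    mismatched += 1
        divergences[name] = mismatched / aligned if aligned else 1.0
    ranked = sorted(divergences.items(), key=lambda kv: (kv[1], kv[0]))
    best_name, best_div = ranked[0]
    runner = ranked[1][1] if len(ranked) > 1 else 1.0
    tie = abs(runner - best_div) <= TIE_EPS
    return SubfamilyCall(
        element_id=element_id,
        subfamily="unclassified" if tie else best_name,
        divergence=best_div,
        runner_up_divergence=runner,
        tie=tie,
    )


def truncation_bin(consensus_start: int) -> str:
    if 1 <= consensus_start <= FULL_LENGTH_MAX:
        return "full_length"
    if SHORT_TRUNC_RANGE[0] <= consensus_start <= SHORT_TRUNC_RANGE[1]:
        return "short_trunc"
    if LONG_TRUNC_RANGE[0] <= consensus_start <= LONG_TRUNC_RANGE[1]:
        return "long_trunc"
    return "other"


def measure_truncation(
    element: str, subfamily_consensus: str
) -> TruncationCall:
    """First/last consensus positions covered by the (poly-A trimmed) element."""
    trimmed = trim_polyA(element.upper())
    if not trimmed:
        trimmed = element.upper()
    aln = global_align(
        trimmed, subfamily_consensus, _PROFILE_PARAMS, end_gaps_free=True
    )
    q2r = aln.query_to_ref()
    if not q2r:
        return TruncationCall(0, "other", 0)
    start = min(q2r.values()) + 1
    end = max(q2r.values()) + 1
    return TruncationCall(start, truncation_bin(start), end)


def detect_microhomology(
    element_consensus: str,
    truncation_start: int,
    genome: Genome,
    chrom: str,
    insertion_point: int,
    strand: str = "+",
) -> MicrohomologyCall:
    """Shared bases between the target 5' of the break and the consensus.

    Walking 5' from the junction, counts contiguous positions where the
    genomic base equals the consensus base immediately 5' of the element's
    first aligned position.  Also reports the 6-bp nic-site window and
    whether it matches the canonical TTTT/AA pattern.
    """
    seq = genome[chrom]
    p = insertion_point
    if strand == "+":
        target_walk = seq[max(0, p - truncation_start + 1) : p][::-1]
    else:
        target_walk = seq[p : p + truncation_start - 1]
        target_walk = reverse_complement(target_walk)[::-1]
    cons_walk = element_consensus[: truncation_start - 1][::-1]
    shared = 0
    for tb, cb in zip(target_walk, cons_walk):
        if tb == cb:
            shared += 1
        else:
            break
    if strand == "+":
        hexamer = seq[max(0, p - 4) : p + 2]
    else:
        hexamer = reverse_complement(seq[max(0, p - 2) : p + 4])
    canonical = hexamer == "TTTTAA"
    return MicrohomologyCall(shared, hexamer, canonical)


# ---------------------------------------------------------------------------
# cohort summaries
# ---------------------------------------------------------------------------


def summarize_cohort(
    subfamily_calls: Sequence[SubfamilyCall],
    truncation_calls: Optional[Dict[str, TruncationCall]] = None,
    microhomology_calls: Optional[Dict[str, MicrohomologyCall]] = None,
) -> Dict[str, pd.DataFrame]:
    """Per-subfamily counts and percentage tables.

    ``%Total`` uses all elements as denominator, ``%Assigned`` only the
    elements carrying a subfamily label.  Truncation bins and the
    microhomology distribution (0 / 1 / >=2 shared bases) are reported when
    the corresponding calls are supplied.
    """
    if not subfamily_calls:
        raise ValueError("at least one call is required")
    total = len(subfamily_calls)
    counts: Dict[str, int] = {}
    for call in subfamily_calls:
        counts[call.subfamily] = counts.get(call.subfamily, 0) + 1
    assigned = total - counts.get("unclassified", 0)
    rows = []
    order = sorted(counts, key=lambda s: (s == "unclassified", -counts[s], s))
    for name in order:
        n = counts[name]
        rows.append(
            {
                "subfamily": name,
                "count": n,
                "pct_total": percent(n, total),
                "pct_assigned": (
                    percent(n, assigned) if name != "unclassified" else np.nan
                ),
            }
        )
    tables = {"subfamilies": pd.DataFrame(rows)}

    if truncation_calls:
        by_fam: Dict[str, Dict[str, int]] = {}
        fam_of = {c.element_id: c.subfamily for c in subfamily_calls}
        for eid, tc in truncation_calls.items():
            fam = fam_of.get(eid, "unclassified")
            by_fam.setdefault(fam, {})
            by_fam[fam][tc.bin] = by_fam[fam].get(tc.bin, 0) + 1
        rows = []
        for fam in sorted(by_fam):
            fam_total = sum(by_fam[fam].values())
            for b in ("full_length", "short_trunc", "long_trunc", "other"):
                n = by_fam[fam].get(b, 0)
                if n:
                    rows.append(
                        {
                            "subfamily": fam,
                            "bin": b,
                            "count": n,
                            "pct_total": percent(n, fam_total, 2),
                        }
                    )
        tables["truncation"] = pd.DataFrame(rows)

    if microhomology_calls:
        dist = {"0": 0, "1": 0, ">=2": 0}
        for mc in microhomology_calls.values():
            if mc.shared_bases == 0:
                dist["0"] += 1
            elif mc.shared_bases == 1:
                dist["1"] += 1
            else:
                dist[">=2"] += 1
        n = sum(dist.values())
        tables["microhomology"] = pd.DataFrame(
            [
                {
                    "shared_bases": k,
                    "count": v,
                    "pct": percent(v, n) if n else 0.0,
                }
                for k, v in dist.items()
            ]
        )
    return tables
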