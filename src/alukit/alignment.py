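"""Pairwise alignment primitives shared across the pipeline.

The global aligner is a Gotoh affine-gap dynamic program with a fully
deterministic traceback (diagonal preferred over up over left).  Gap costs
follow the "open + extend*(len-1)" convention: the first gapped column of a
run costs ``gap_open``, each subsequent column ``gap_extend``.

Local (Smith-Waterman style) matching against consensus libraries is
delegated to :class:`Bio.Align.PairwiseAligner`, which is C-backed; only
score, matched-base and identity summaries are consumed from it, so its
traceback tie conventions do not leak into any contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
from Bio import Align

__all__ = [
    "GlobalAlignParams",
    "PairwiseAlignment",
    "global_align",
    "LocalHit",
    "best_local_hit",
    "best_library_hit",
]

NEG_INF = -(10**9)


@dataclass(frozen=True)
class GlobalAlignParams:
    match: int = 5
    mismatch: int = -4
    gap_open: int = 16  # cost of the first gapped column (positive)
    gap_extend: int = 4  # cost of each additional gapped column (positive)


@dataclass
class PairwiseAlignment:
    """A gapped global alignment of ``query`` against ``reference``.

    ``gapped_query`` and ``gapped_reference`` have equal length and no
    column is a gap in both rows.
    """

    gapped_query: str
    gapped_reference: str
    score: int

    def __post_init__(self) -> None:
        assert len(self.gapped_query) == len(self.gapped_reference)

    def columns(self):
        return zip(self.gapped_query, self.gapped_reference)

    def query_to_ref(self) -> Dict[int, int]:
        """Map of query index -> reference index for non-gap column pairs."""
        out = {}
        qi = ri = 0
        for q, r in self.columns():
            if q != "-" and r != "-":
                out[qi] = ri
            if q != "-":
                qi += 1
            if r != "-":
                ri += 1
        return out


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def global_align(
    query: str,
    reference: str,
    params: GlobalAlignParams = GlobalAlignParams(),
    end_gaps_free: bool = False,
) -> PairwiseAlignment:
    """Optimal global alignment under affine-gap scoring.

    'N' mismatches everything, including another 'N'.  Traceback is
    deterministic: diagonal over up (gap in reference) over left (gap in
    query), with the match state preferred when states tie.

    With ``end_gaps_free`` the alignment is semi-global: leading and
    trailing gaps in either sequence are unpenalized.  This is the mode
    used when placing a short assembled flank inside a longer reference
    window.
    """
    if not query or not reference:
        raise ValueError("sequences must be non-empty")
    n, m = len(query), len(reference)
    q = _encode(query)
    r = _encode(reference)
    nmask_q = q == ord("N")
    nmask_r = r == ord("N")

    open_, ext = params.gap_open, params.gap_extend
    # state matrices: M ends in a substitution column, IY ends in a gap in
    # the reference (query base consumed), IX ends in a gap in the query.
    M = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)
    IX = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)
    IY = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)
    M[0, 0] = 0
    if m >= 1:
        IX[0, 1:] = (
            0 if end_gaps_free else -open_ - ext * np.arange(m)
        )
    if n >= 1:
        IY[1:, 0] = (
            0 if end_gaps_free else -open_ - ext * np.arange(n)
        )

    for i in range(1, n + 1):
        match_row = np.where(
            (q[i - 1] == r) & ~nmask_r & ~nmask_q[i - 1],
            params.match,
            params.mismatch,
        )
        prev_best = np.maximum(np.maximum(M[i - 1], IX[i - 1]), IY[i - 1])
        M[i, 1:] = prev_best[:-1] + match_row
        IY[i] = np.maximum(
            np.maximum(M[i - 1], IX[i - 1]) - open_, IY[i - 1] - ext
        )
        # IX within-row recurrence solved with a running-max transform:
        #   IX[i,j] = max_{k<j} (A[k] + ext*k) - open - ext*(j-1), A = max(M, IY)
        A = np.maximum(M[i], IY[i])
        js = np.arange(m)
        run = np.maximum.accumulate(A[:-1] + ext * js)
        IX[i, 1:] = run - open_ - ext * js

    # traceback; preference M (diagonal) > IY (up) > IX (left) at ties
    i, j = n, m
    end_scores = (M[n, m], IY[n, m], IX[n, m])
    score = int(max(end_scores))
    state = int(np.argmax(end_scores))  # 0=M, 1=IY, 2=IX
    tail_q = ""
    tail_r = ""
    if end_gaps_free:
        # trailing gaps are free: end anywhere on the last row or column
        for jj in range(m + 1):
            cands = (M[n, jj], IY[n, jj], IX[n, jj])
            v = int(max(cands))
            if v > score:
                score, state, i, j = v, int(np.argmax(cands)), n, jj
        for ii in range(n + 1):
            cands = (M[ii, m], IY[ii, m], IX[ii, m])
            v = int(max(cands))
            if v > score:
                score, state, i, j = v, int(np.argmax(cands)), ii, m
        tail_q = query[i:] + "-" * (m - j)
        tail_r = "-" * (n - i) + reference[j:]
    gq: list = []
    gr: list = []
    while i > 0 or j > 0:
        if state == 0:  # substitution column
            gq.append(query[i - 1])
            gr.append(reference[j - 1])
            cands = (M[i - 1, j - 1], IY[i - 1, j - 1], IX[i - 1, j - 1])
            state = int(np.argmax(cands))
            i -= 1
            j -= 1
        elif state == 1:  # gap in reference; consumed query base
            gq.append(query[i - 1])
            gr.append("-")
            came_open = max(M[i - 1, j], IX[i - 1, j]) - open_
            came_ext = IY[i - 1, j] - ext
            if came_open >= came_ext:
                state = 0 if M[i - 1, j] >= IX[i - 1, j] else 2
            i -= 1
        else:  # gap in query; consumed reference base
            gq.append("-")
            gr.append(reference[j - 1])
            came_open = max(M[i, j - 1], IY[i, j - 1]) - open_
            came_ext = IX[i, j - 1] - ext
            if came_open >= came_ext:
                state = 0 if M[i, j - 1] >= IY[i, j - 1] else 1
            j -= 1
    return PairwiseAlignment(
        "".join(reversed(gq)) + tail_q,
        "".join(reversed(gr)) + tail_r,
        score,
    )


@dataclass
class LocalHit:
    """Summary of the best local alignment of a query vs a target."""

    target: str
    score: float
    matched_bp: int  # aligned column pairs with equal bases
    aligned_bp: int  # aligned column pairs (both non-gap)
    identity: float
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    strand: str = "+"


def _local_aligner(match: float = 1.0, mismatch: float = -1.0,
                   gap_open: float = -2.0, gap_extend: float = -1.0):
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


_DEFAULT_LOCAL = _local_aligner()


def best_local_hit(
    query: str,
    target: str,
    target_name: str = "",
    both_strands: bool = True,
    aligner=None,
) -> Optional[LocalHit]:
    """Best local alignment of ``query`` against ``target`` (both strands)."""
    from .genome_io import reverse_complement

    if not query or not target:
        return None
    aligner = aligner or _DEFAULT_LOCAL
    best: Optional[LocalHit] = None
    strands = ("+", "-") if both_strands else ("+",)
    for strand in strands:
        qseq = query if strand == "+" else reverse_complement(query)
        try:
            aln = aligner.align(qseq, target)
        except (OverflowError, MemoryError):  # pragma: no cover
            continue
        if len(aln) == 0:
            continue
        top = aln[0]
        matched = aligned = 0
        for (qs, qe), (ts, te) in zip(*top.aligned):
            aligned += qe - qs
            a, b = qseq[qs:qe], target[ts:te]
            matched += sum(1 for x, y in zip(a, b) if x == y and x != "N")
        if aligned == 0:
            continue
        qblocks, tblocks = top.aligned
        hit = LocalHit(
            target=target_name,
            score=float(top.score),
            matched_bp=matched,
            aligned_bp=aligned,
            identity=matched / aligned,
            query_start=int(qblocks[0][0]),
            query_end=int(qblocks[-1][1]),
            target_start=int(tblocks[0][0]),
            target_end=int(tblocks[-1][1]),
            strand=strand,
        )
        if strand == "-":
            # report query coordinates on the original (input) strand
            qlen = len(query)
            hit.query_start, hit.query_end = (
                qlen - hit.query_end,
                qlen - hit.query_start,
            )
        if best is None or hit.score > best.score:
            best = hit
    return best


def best_library_hit(
    query: str, library: Dict[str, str], both_strands: bool = True
) -> Optional[LocalHit]:
    """Best local hit of ``query`` over every sequence in ``library``."""
    best: Optional[LocalHit] = None
    for name, seq in library.items():
        hit = best_local_hit(query, seq, name, both_strands=both_strands)
        if hit and (best is None or hit.score > best.score):
            best = hit
    return best
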