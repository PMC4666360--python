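"""Breakpoint resolution by three-way alignment scoring.

The assembled flanks on either side of the element are globally aligned to
the reference segment spanning the candidate site.  The two pairwise
alignments are merged on shared reference coordinates into a column-labeled
three-way alignment ('*' = all three match, '1' = left flank matches the
reference, '2' = right flank matches, 'N' = mismatch).  Cumulative score
tracks (+1 own-side match, -1 mismatch, -3 other-side match) are scanned
from each end; their maxima define the breakpoints, from which the overlap
region (candidate TSD span) or target-site deletion follows.  Candidate
TSDs are refined to the maximal exactly-matching segment within the
overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .alignment import (
    GlobalAlignParams,
    PairwiseAlignment,
    best_local_hit,
    best_library_hit,
    global_align,
)
from .genome_io import Genome, reverse_complement

__all__ = [
    "ThreeWayAlignment",
    "ScoreTrack",
    "BreakpointCall",
    "merge_threeway",
    "trim_to_flanks",
    "score_breakpoints",
    "refine_tsd",
    "call_site",
    "render_threeway",
    "global_align",
    "GlobalAlignParams",
]

FLANK_SPAN = 600
GENOTYPABLE_FLANK = 100
SCORE_OWN = 1
SCORE_MISMATCH = -1
SCORE_OTHER = -3


@dataclass
class ThreeWayAlignment:
    """Column-wise merge of left-flank and right-flank reference alignments.

    Per column: reference base (or '-'), left base (or '-'), right base
    (or '-'), label in {'*', '1', '2', 'N'}, and the 0-based reference
    coordinate (-1 for reference-gap columns).
    """

    ref: str
    left: str
    right: str
    labels: str
    ref_coords: List[int]

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class ScoreTrack:
    """Cumulative per-column score for one breakpoint side."""

    scores: List[int]
    direction: str  # 'left_to_right' or 'right_to_left'
    argmax_column: int


@dataclass
class BreakpointCall:
    chrom: str = ""
    left_bp: int = -1  # reference coordinate of the last left-matching base
    right_bp: int = -1  # reference coordinate of the first right-matching base
    overlap_len: int = 0
    tsd: str = ""
    target_deletion: int = 0
    element_start: int = 0  # scaffold coordinates (genome-forward)
    element_end: int = 0
    element_strand: str = "+"
    scaffold_seq: str = ""
    insert_seq: str = ""
    both_flanks_ok: bool = True
    gap_within_100bp: bool = False
    genotypable: bool = False
    flank5_len: int = 0
    flank3_len: int = 0

    @property
    def insertion_point(self) -> int:
        """Reference coordinate where the inserted sequence begins."""
        return self.left_bp + 1


def _label(ref: str, left: str, right: str) -> str:
    if ref != "-" and ref == left == right:
        return "*"
    if ref != "-" and ref == left:
        return "1"
    if ref != "-" and ref == right:
        return "2"
    return "N"


def merge_threeway(
    left_aln: PairwiseAlignment, right_aln: PairwiseAlignment
) -> ThreeWayAlignment:
    """Reference-coordinate-synchronized merge of two pairwise alignments.

    Wherever one alignment gaps the reference, a corresponding gap column
    is inserted in the other; every reference base appears exactly once.
    """
    ref_l = left_aln.gapped_reference.replace("-", "")
    ref_r = right_aln.gapped_reference.replace("-", "")
    if ref_l != ref_r:
        raise ValueError("alignments do not share the same reference")

    li = ri = 0
    lq, lr = left_aln.gapped_query, left_aln.gapped_reference
    rq, rr = right_aln.gapped_query, right_aln.gapped_reference
    ref_out: List[str] = []
    left_out: List[str] = []
    right_out: List[str] = []
    coords: List[int] = []
    ref_pos = 0
    while li < len(lr) or ri < len(rr):
        l_gap = li < len(lr) and lr[li] == "-"
        r_gap = ri < len(rr) and rr[ri] == "-"
        if l_gap:
            ref_out.append("-")
            left_out.append(lq[li])
            right_out.append("-")
            coords.append(-1)
            li += 1
        elif r_gap:
            ref_out.append("-")
            left_out.append("-")
            right_out.append(rq[ri])
            coords.append(-1)
            ri += 1
        else:
            if li >= len(lr) or ri >= len(rr):
                raise ValueError("alignments do not cover the same reference")
            ref_out.append(lr[li])
            left_out.append(lq[li])
            right_out.append(rq[ri])
            coords.append(ref_pos)
            ref_pos += 1
            li += 1
            ri += 1
    labels = "".join(
        _label(r, l, x) for r, l, x in zip(ref_out, left_out, right_out)
    )
    return ThreeWayAlignment(
        "".join(ref_out), "".join(left_out), "".join(right_out), labels, coords
    )


def trim_to_flanks(threeway: ThreeWayAlignment) -> ThreeWayAlignment:
    """Drop leading/trailing columns where neither flank has a base.

    A reference window longer than the assembled flanks produces runs of
    all-gap 'N' columns at both ends; these carry no breakpoint signal but
    would otherwise dominate the cumulative score tracks.
    """
    covered = [
        i
        for i in range(len(threeway))
        if threeway.left[i] != "-" or threeway.right[i] != "-"
    ]
    if not covered:
        return threeway
    lo, hi = covered[0], covered[-1] + 1
    return ThreeWayAlignment(
        threeway.ref[lo:hi],
        threeway.left[lo:hi],
        threeway.right[lo:hi],
        threeway.labels[lo:hi],
        threeway.ref_coords[lo:hi],
    )


def _coord_at_or_before(threeway: ThreeWayAlignment, col: int) -> int:
    for c in range(col, -1, -1):
        if threeway.ref_coords[c] >= 0:
            return threeway.ref_coords[c]
    return -1


def _coord_at_or_after(threeway: ThreeWayAlignment, col: int) -> int:
    for c in range(col, len(threeway)):
        if threeway.ref_coords[c] >= 0:
            return threeway.ref_coords[c]
    return -1


def score_breakpoints(
    threeway: ThreeWayAlignment,
) -> Tuple[ScoreTrack, ScoreTrack, BreakpointCall]:
    """Cumulative-score breakpoint determination.

    The left track scans left-to-right (+1 for '1'/'*', -1 for 'N', -3 for
    '2'); the right track scans right-to-left with the side roles swapped.
    The left breakpoint is the reference coordinate at the left track's
    maximum (rightmost on ties); the right breakpoint at the right track's
    maximum (leftmost on ties).  A non-negative breakpoint gap is a region
    of overlap (candidate TSD span); a positive gap the other way is a
    target site deletion.
    """
    if len(threeway) == 0:
        raise ValueError("empty three-way alignment")
    inc_left = {"1": SCORE_OWN, "*": SCORE_OWN, "N": SCORE_MISMATCH,
                "2": SCORE_OTHER}
    inc_right = {"2": SCORE_OWN, "*": SCORE_OWN, "N": SCORE_MISMATCH,
                 "1": SCORE_OTHER}
    n = len(threeway)
    left_scores: List[int] = []
    total = 0
    for lab in threeway.labels:
        total += inc_left[lab]
        left_scores.append(total)
    best = max(left_scores)
    left_col = max(i for i, s in enumerate(left_scores) if s == best)

    right_scores = [0] * n
    total = 0
    for i in range(n - 1, -1, -1):
        total += inc_right[threeway.labels[i]]
        right_scores[i] = total
    best = max(right_scores)
    right_col = min(i for i, s in enumerate(right_scores) if s == best)

    left_bp = _coord_at_or_before(threeway, left_col)
    right_bp = _coord_at_or_after(threeway, right_col)

    call = BreakpointCall(left_bp=left_bp, right_bp=right_bp)
    if left_bp >= right_bp:
        call.overlap_len = left_bp - right_bp + 1
        call.target_deletion = 0
    else:
        call.overlap_len = 0
        call.target_deletion = right_bp - left_bp - 1
    left_track = ScoreTrack(left_scores, "left_to_right", left_col)
    right_track = ScoreTrack(right_scores, "right_to_left", right_col)
    return left_track, right_track, call


def refine_tsd(
    call: BreakpointCall,
    threeway: ThreeWayAlignment,
    element_side: str = "left",
) -> BreakpointCall:
    """Refine the candidate TSD to an exactly matching segment.

    Within the overlap region, runs of columns where both flanks equal the
    reference are candidate TSDs; the maximal run wins, growing toward the
    element 3' end (``element_side`` names the flank adjacent to the
    element 3' end, which breaks ties between equal runs).
    """
    call.tsd = ""
    if call.overlap_len <= 0:
        return call
    cols = [
        c
        for c in range(len(threeway))
        if call.right_bp <= threeway.ref_coords[c] <= call.left_bp
    ]
    runs: List[List[int]] = []
    cur: List[int] = []
    for c in cols:
        if threeway.labels[c] == "*":
            cur.append(c)
        else:
            if cur:
                runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    if not runs:
        return call
    if element_side == "left":
        # element 3' end abuts the overlap from the left: prefer early runs
        best = max(runs, key=lambda r: (len(r), -r[0]))
    else:
        best = max(runs, key=lambda r: (len(r), r[0]))
    call.tsd = "".join(threeway.ref[c] for c in best)
    return call


def render_threeway(threeway: ThreeWayAlignment, width: int = 60) -> str:
    """Human-reviewable text rendering using the '1'/'2'/'*'/'N' notation."""
    out = []
    for i in range(0, len(threeway), width):
        sl = slice(i, i + width)
        out.append(f"ref    {threeway.ref[sl]}")
        out.append(f"left   {threeway.left[sl]}")
        out.append(f"right  {threeway.right[sl]}")
        out.append(f"label  {threeway.labels[sl]}")
        out.append("")
    return "\n".join(out)


def _non_gap_run(seq: str, idx: int, direction: int) -> int:
    n = 0
    while 0 <= idx < len(seq) and seq[idx] != "N":
        n += 1
        idx += direction
    return n


def _flank_alignment_ok(aln: PairwiseAlignment, min_matches: int = 20) -> bool:
    matches = sum(1 for q, r in aln.columns() if q == r and q != "-")
    return matches >= min_matches


def call_site(
    scaffold_seq: str,
    genome: Genome,
    chrom: str,
    pos: int,
    alu_library: Dict[str, str],
    flank_span: int = FLANK_SPAN,
    align_params: GlobalAlignParams = GlobalAlignParams(),
    junction_pad: int = 0,
) -> Optional[BreakpointCall]:
    """Resolve breakpoints for one assembled site.

    The scaffold is oriented against the reference by best flank mapping,
    the element located with the consensus library, flanks extracted
    (poly-A assigned to the element) and aligned to the +/- ``flank_span``
    reference window; a single automatic retry widens the flanks by 50 bp
    when the first pass leaves a flank unaligned.
    """
    win_start = max(0, pos - flank_span)
    win_end = min(genome.length(chrom), pos + flank_span)
    window = genome[chrom][win_start:win_end]

    orient = best_local_hit(scaffold_seq, window)
    if orient is None:
        return None
    seq = scaffold_seq if orient.strand == "+" else reverse_complement(
        scaffold_seq
    )
    hit = best_library_hit(seq, alu_library)
    if hit is None:
        return None
    # flanks are cut at the raw element-match bounds: the poly-A run stays
    # inside the aligned flank, where the cumulative score tracks resolve
    # the element/target boundary instead of a greedy A-run rule.
    # `junction_pad` optionally reaches into the element so junction bases
    # absorbed into the library match stay available to the score tracks.
    elt_lo, elt_hi = hit.query_start, hit.query_end
    lf_end = min(elt_lo + junction_pad, len(seq))
    rf_start = max(elt_hi - junction_pad, 0)

    def attempt(extra: int) -> Optional[BreakpointCall]:
        f5 = min(_non_gap_run(seq, elt_lo - 1, -1), flank_span + extra)
        f3 = min(_non_gap_run(seq, elt_hi, 1), flank_span + extra)
        if f5 == 0 or f3 == 0:
            return None
        left_flank = seq[elt_lo - f5 : lf_end]
        right_flank = seq[rf_start : elt_hi + f3]
        left_aln = global_align(
            left_flank, window, align_params, end_gaps_free=True
        )
        right_aln = global_align(
            right_flank, window, align_params, end_gaps_free=True
        )
        threeway = trim_to_flanks(merge_threeway(left_aln, right_aln))
        _, _, call = score_breakpoints(threeway)
        refine_tsd(call, threeway, element_side="left")
        call.chrom = chrom
        call.left_bp += win_start
        call.right_bp += win_start
        call.element_strand = hit.strand
        call.scaffold_seq = seq
        call.both_flanks_ok = _flank_alignment_ok(
            left_aln
        ) and _flank_alignment_ok(right_aln)
        # insertion sequence between the two junctions, genome-forward
        q2r_left = {
            q: r + win_start for q, r in left_aln.query_to_ref().items()
        }
        q2r_right = {
            q: r + win_start for q, r in right_aln.query_to_ref().items()
        }
        lo_off = elt_lo - f5
        sc_l = max(
            (lo_off + q for q, r in q2r_left.items() if r <= call.left_bp),
            default=lo_off - 1,
        )
        sc_r = min(
            (rf_start + q for q, r in q2r_right.items() if r >= call.right_bp),
            default=elt_hi + f3,
        )
        call.element_start = sc_l + 1
        call.element_end = sc_r
        call.insert_seq = seq[sc_l + 1 : sc_r]
        call.flank5_len = _non_gap_run(seq, sc_l, -1)
        call.flank3_len = _non_gap_run(seq, sc_r, 1)
        return call

    call = attempt(0)
    if call is None or not call.both_flanks_ok:
        retry = attempt(50)
        if retry is not None and (call is None or retry.both_flanks_ok):
            call = retry
    if call is None:
        return None
    call.gap_within_100bp = (
        "N" in seq[max(0, call.element_start - 100) : call.element_start]
        or "N" in seq[call.element_end : call.element_end + 100]
    )
    call.genotypable = (
        call.both_flanks_ok
        and not call.gap_within_100bp
        and call.flank5_len >= GENOTYPABLE_FLANK
        and call.flank3_len >= GENOTYPABLE_FLANK
    )
    return call
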