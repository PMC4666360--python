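"""Candidate insertion discovery from discordant pairs and soft clips.

A single streaming pass over a coordinate-sorted SAM/BAM collects
(1) non-concordant read pairs (candidate anchored pairs), (2) qualifying
soft-clipped reads and (3) a per-chromosome read-depth track.  Anchored
pairs are then validated against the Alu consensus library or reference
repeat catalog, clustered into candidate sites, and filtered by the locus
rules (minimum supporting pairs, read-depth cap, distance from annotated
reference Alus).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .alignment import best_library_hit
from .genome_io import RepeatCatalog, reverse_complement

__all__ = [
    "AnchoredPair",
    "SoftClip",
    "CandidateSite",
    "ScanResult",
    "scan_alignments",
    "find_discordant_pairs",
    "cluster_candidates",
    "filter_near_reference",
    "discover",
]

DEFAULT_ANCHOR_MAPQ = 20
DEFAULT_CLIP_MIN_LEN = 20
DEFAULT_CLIP_MIN_QUAL = 20.0
DEFAULT_MIN_READS = 2
DEFAULT_MAX_DEPTH = 1000
MATE_MATCH_MIN_BP = 30
MATE_MATCH_MIN_IDENTITY = 0.90


@dataclass
class AnchoredPair:
    """A discordant pair: unique anchor plus an Alu-matching floating mate."""

    qname: str
    chrom: str
    anchor_start: int
    anchor_end: int
    anchor_strand: str  # '+': insertion expected downstream of anchor_end
    anchor_mapq: int
    mate_seq: str
    evidence: str  # 'alu_library' or 'ref_alu'
    mate_target: str = ""
    mate_matched_bp: int = 0
    mate_identity: float = 0.0


@dataclass
class SoftClip:
    """A qualifying soft-clipped read end marking a putative junction."""

    qname: str
    chrom: str
    pos: int  # reference coordinate of the clip boundary
    side: str  # 'left' flank junction (clip at read 3' end) or 'right'
    clip_len: int
    clip_mean_qual: float
    clip_seq: str = ""


@dataclass
class CandidateSite:
    """A clustered putative insertion locus with its supporting evidence."""

    chrom: str
    pos: int
    fwd_count: int = 0
    rev_count: int = 0
    fwd_end: int = -1  # rightmost forward-anchor end
    rev_start: int = -1  # leftmost reverse-anchor start
    clip_left: int = 0
    clip_right: int = 0
    support_level: int = 0
    depth: int = 0
    read_names: List[str] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return self.fwd_count + self.rev_count

    @property
    def soft_clip_support(self) -> int:
        return self.clip_left + self.clip_right


@dataclass
class ScanResult:
    candidate_groups: Dict[str, list]
    soft_clips: List[SoftClip]
    depth: Dict[str, np.ndarray]


def _clip_info(rec) -> List[Tuple[str, int, int, float, str]]:
    """(side, ref_pos, clip_len, mean_qual, clip_seq) per soft-clipped end."""
    out = []
    cig = rec.cigartuples
    if not cig or rec.is_unmapped:
        return out
    quals = rec.query_qualities
    seq = rec.query_sequence or ""
    if cig[0][0] == 4:  # leading clip -> junction at alignment start
        n = cig[0][1]
        mq = float(np.mean(quals[:n])) if quals is not None else 0.0
        out.append(("right", rec.reference_start, n, mq, seq[:n]))
    if cig[-1][0] == 4:  # trailing clip -> junction at alignment end
        n = cig[-1][1]
        mq = float(np.mean(quals[-n:])) if quals is not None else 0.0
        out.append(("left", rec.reference_end, n, mq, seq[-n:]))
    return out


def scan_alignments(
    path: str,
    anchor_mapq_min: int = DEFAULT_ANCHOR_MAPQ,
    clip_min_len: int = DEFAULT_CLIP_MIN_LEN,
    clip_min_qual: float = DEFAULT_CLIP_MIN_QUAL,
    chrom_lengths: Optional[Dict[str, int]] = None,
) -> ScanResult:
    """Stream a coordinate-sorted SAM/BAM once, collecting raw evidence.

    Raises ``ValueError`` instructing a coordinate sort when positions go
    backwards within a chromosome.
    """
    groups: Dict[str, list] = defaultdict(list)
    clips: List[SoftClip] = []
    depth: Dict[str, np.ndarray] = {}
    last: Dict[str, int] = {}
    with pysam.AlignmentFile(path, check_sq=False) as af:
        lengths = chrom_lengths or dict(zip(af.references, af.lengths))
        for name, ln in lengths.items():
            depth[name] = np.zeros(ln + 1, dtype=np.int32)
        for rec in af:
            if rec.is_secondary or rec.is_supplementary:
                continue
            if not rec.is_unmapped:
                chrom = rec.reference_name
                if rec.reference_start < last.get(chrom, -1):
                    raise ValueError(
                        "input is not coordinate-sorted; run a coordinate "
                        "sort (e.g. samtools sort) first"
                    )
                last[chrom] = rec.reference_start
                d = depth.get(chrom)
                if d is not None:
                    s = rec.reference_start
                    e = min(rec.reference_end or s + 1, len(d))
                    d[s:e] += 1
                if rec.mapping_quality >= anchor_mapq_min:
                    for side, pos, n, mq, cseq in _clip_info(rec):
                        if n >= clip_min_len and mq >= clip_min_qual:
                            clips.append(
                                SoftClip(
                                    rec.query_name, chrom, pos, side, n, mq,
                                    cseq,
                                )
                            )
            if not rec.is_proper_pair:
                seq = rec.query_sequence
                if rec.is_reverse and seq and not rec.is_unmapped:
                    pass  # stored reference-forward; keep as is
                groups[rec.query_name].append(
                    (
                        rec.is_unmapped,
                        rec.reference_name if not rec.is_unmapped else None,
                        rec.reference_start if not rec.is_unmapped else -1,
                        (rec.reference_end or -1)
                        if not rec.is_unmapped
                        else -1,
                        rec.is_reverse,
                        rec.mapping_quality,
                        seq or "",
                    )
                )
    return ScanResult(dict(groups), clips, depth)


_SCREEN_K = 12


def _library_kmer_index(alu_library: Dict[str, str]) -> Dict[str, set]:
    from .genome_io import reverse_complement

    index: Dict[str, set] = {}
    for name, seq in alu_library.items():
        for s in (seq, reverse_complement(seq)):
            for i in range(0, len(s) - _SCREEN_K + 1):
                index.setdefault(s[i : i + _SCREEN_K], set()).add(name)
    return index


def _mate_evidence(
    mate,
    alu_library: Dict[str, str],
    reference_catalog: Optional[RepeatCatalog],
    library_index: Optional[Dict[str, set]] = None,
) -> Optional[Tuple[str, str, int, float]]:
    unmapped, chrom, start, end, is_rev, mapq, seq = mate
    if (
        reference_catalog is not None
        and not unmapped
        and any(
            iv.chrom == chrom and iv.start < end and start < iv.end
            for iv in reference_catalog
        )
    ):
        return ("ref_alu", "", 0, 0.0)
    if not seq:
        return None
    targets = alu_library
    if library_index is not None:
        # k-mer prescreen: only align against consensuses sharing a k-mer
        votes: Dict[str, int] = {}
        for i in range(0, len(seq) - _SCREEN_K + 1, 4):
            for name in library_index.get(seq[i : i + _SCREEN_K], ()):
                votes[name] = votes.get(name, 0) + 1
        if not votes:
            return None
        best_name = max(votes.items(), key=lambda kv: (kv[1], kv[0]))[0]
        targets = {best_name: alu_library[best_name]}
    hit = best_library_hit(seq, targets)
    if (
        hit is not None
        and hit.matched_bp >= MATE_MATCH_MIN_BP
        and hit.identity >= MATE_MATCH_MIN_IDENTITY
    ):
        return ("alu_library", hit.target, hit.matched_bp, hit.identity)
    return None


def find_discordant_pairs(
    scan: ScanResult,
    alu_library: Dict[str, str],
    reference_catalog: Optional[RepeatCatalog] = None,
    anchor_mapq_min: int = DEFAULT_ANCHOR_MAPQ,
) -> List[AnchoredPair]:
    """Anchored pairs: one uniquely mapped read, mate with Alu evidence."""
    if not alu_library:
        raise ValueError("alu_library must be non-empty")
    library_index = _library_kmer_index(alu_library)
    out: List[AnchoredPair] = []
    for qname, recs in scan.candidate_groups.items():
        if len(recs) != 2:
            continue
        picks = []
        for anchor, mate in ((recs[0], recs[1]), (recs[1], recs[0])):
            unmapped, chrom, start, end, is_rev, mapq, seq = anchor
            if unmapped or mapq < anchor_mapq_min:
                continue
            m_unmapped, m_chrom, m_start, m_end, m_rev, m_mapq, m_seq = mate
            # exactly-one-anchor rule: a well-mapped mate far from any
            # repeat is not floating evidence
            ev = _mate_evidence(
                mate, alu_library, reference_catalog, library_index
            )
            if ev is None:
                continue
            picks.append(
                AnchoredPair(
                    qname=qname,
                    chrom=chrom,
                    anchor_start=start,
                    anchor_end=end,
                    anchor_strand="-" if is_rev else "+",
                    anchor_mapq=mapq,
                    mate_seq=m_seq,
                    evidence=ev[0],
                    mate_target=ev[1],
                    mate_matched_bp=ev[2],
                    mate_identity=ev[3],
                )
            )
        if len(picks) == 1:
            out.append(picks[0])
    return out


def cluster_candidates(
    pairs: Sequence[AnchoredPair],
    soft_clips: Sequence[SoftClip],
    fragment_mean: float,
    fragment_sd: float,
    min_reads: int = DEFAULT_MIN_READS,
    max_depth: int = DEFAULT_MAX_DEPTH,
    depth: Optional[Dict[str, np.ndarray]] = None,
    emit_min_level: int = 6,
) -> List[CandidateSite]:
    """Cluster anchored pairs into candidate sites and assign support levels.

    Forward anchors upstream and reverse anchors downstream of a putative
    junction are merged when their implied insertion windows overlap.  The
    predicted position is the dominant soft-clip boundary when available,
    otherwise the midpoint between the rightmost forward-anchor end and the
    leftmost reverse-anchor start (ties toward the smaller coordinate).

    Support levels: 8 = both anchor clusters plus a junction-crossing clip
    on each side; 7 = both clusters plus a clip on one side; 6 = both
    clusters without clip support; lower levels denote one-sided evidence
    and are suppressed below ``emit_min_level``.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    window = int(fragment_mean + 3 * fragment_sd)
    events = []  # (chrom, win_start, win_end, pair)
    for p in pairs:
        if p.anchor_strand == "+":
            events.append((p.chrom, p.anchor_end, p.anchor_end + window, p))
        else:
            events.append(
                (p.chrom, max(0, p.anchor_start - window), p.anchor_start, p)
            )
    events.sort(key=lambda e: (e[0], e[1], e[2]))

    clusters: List[List[tuple]] = []
    cur: List[tuple] = []
    cur_end = -1
    cur_chrom = None
    for ev in events:
        chrom, ws, we, _ = ev
        if cur and chrom == cur_chrom and ws <= cur_end:
            cur.append(ev)
            cur_end = max(cur_end, we)
        else:
            if cur:
                clusters.append(cur)
            cur = [ev]
            cur_chrom = chrom
            cur_end = we
    if cur:
        clusters.append(cur)

    sites: List[CandidateSite] = []
    for cluster in clusters:
        chrom = cluster[0][0]
        fwd = [p for _, _, _, p in cluster if p.anchor_strand == "+"]
        rev = [p for _, _, _, p in cluster if p.anchor_strand == "-"]
        if len(fwd) + len(rev) < min_reads:
            continue
        fwd_end = max((p.anchor_end for p in fwd), default=-1)
        rev_start = min((p.anchor_start for p in rev), default=-1)
        span_lo = min(ws for _, ws, _, _ in cluster)
        span_hi = max(we for _, _, we, _ in cluster)
        in_span = [
            c
            for c in soft_clips
            if c.chrom == chrom and span_lo - 50 <= c.pos <= span_hi + 50
        ]
        clip_left = [c for c in in_span if c.side == "left"]
        clip_right = [c for c in in_span if c.side == "right"]
        if in_span:
            positions = sorted(c.pos for c in in_span)
            counts: Dict[int, int] = {}
            for pos in positions:
                counts[pos] = counts.get(pos, 0) + 1
            best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
            pos = best[0]
        elif fwd and rev:
            pos = (fwd_end + rev_start) // 2
        elif fwd:
            pos = fwd_end
        else:
            pos = rev_start
        if fwd and rev:
            if clip_left and clip_right:
                level = 8
            elif clip_left or clip_right:
                level = 7
            else:
                level = 6
        else:
            level = 4 if in_span else 3
        local_depth = 0
        if depth is not None and chrom in depth:
            d = depth[chrom]
            lo, hi = max(0, pos - 100), min(len(d), pos + 100)
            if hi > lo:
                local_depth = int(d[lo:hi].max())
        if local_depth > max_depth:
            continue
        if level < emit_min_level:
            continue
        names = sorted(
            {p.qname for p in fwd + rev} | {c.qname for c in in_span}
        )
        sites.append(
            CandidateSite(
                chrom=chrom,
                pos=pos,
                fwd_count=len(fwd),
                rev_count=len(rev),
                fwd_end=fwd_end,
                rev_start=rev_start,
                clip_left=len(clip_left),
                clip_right=len(clip_right),
                support_level=level,
                depth=local_depth,
                read_names=names,
            )
        )
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return sites


def filter_near_reference(
    sites: Sequence[CandidateSite],
    mask: RepeatCatalog,
    pad: int = 0,
) -> List[CandidateSite]:
    """Drop sites whose position falls within ``pad`` of a mask interval.

    ``mask`` is normally the already-padded output of
    :func:`alukit.genome_io.exclusion_mask`; ``pad`` adds further slack.
    Idempotent.
    """
    from .genome_io import in_mask

    return [s for s in sites if not in_mask(mask, s.chrom, s.pos, pad=pad)]


def discover(
    sam_paths: Sequence[str],
    alu_library: Dict[str, str],
    reference_catalog: Optional[RepeatCatalog],
    mask: Optional[RepeatCatalog],
    fragment_mean: float,
    fragment_sd: float,
    anchor_mapq_min: int = DEFAULT_ANCHOR_MAPQ,
    min_reads: int = DEFAULT_MIN_READS,
    max_depth: int = DEFAULT_MAX_DEPTH,
) -> Tuple[List[CandidateSite], List[SoftClip]]:
    """Multi-sample discovery: per-sample scans pooled before clustering."""
    all_pairs: List[AnchoredPair] = []
    all_clips: List[SoftClip] = []
    pooled_depth: Dict[str, np.ndarray] = {}
    for path in sam_paths:
        scan = scan_alignments(path, anchor_mapq_min=anchor_mapq_min)
        all_pairs.extend(
            find_discordant_pairs(
                scan, alu_library, reference_catalog, anchor_mapq_min
            )
        )
        all_clips.extend(scan.soft_clips)
        for chrom, d in scan.depth.items():
            if chrom in pooled_depth:
                pooled_depth[chrom] += d
            else:
                pooled_depth[chrom] = d.copy()
    sites = cluster_candidates(
        all_pairs,
        all_clips,
        fragment_mean,
        fragment_sd,
        min_reads=min_reads,
        max_depth=max_depth,
        depth=pooled_depth,
    )
    if mask is not None:
        sites = filter_near_reference(sites, mask)
    return sites, all_clips
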