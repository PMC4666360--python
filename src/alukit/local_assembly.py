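"""Per-site read collection and greedy overlap-layout-consensus assembly.

The assembler computes ungapped dovetail/containment overlaps between
units (reads, later contigs), seeded by shared k-mers, and iteratively
merges the highest-scoring overlap (score = matched bp; ties resolved
toward the longer resulting contig, then lexicographic read id).  The
consensus is a per-column quality-weighted majority.  Substitution-only
overlaps match the error model of the read simulator; indel sequencing
errors are out of scope.

Contigs linked by read pairs without sequence overlap are scaffolded with
300-N spacers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .alignment import best_library_hit
from .discovery import CandidateSite
from .genome_io import reverse_complement

__all__ = [
    "ReadRecord",
    "SiteReadSet",
    "Contig",
    "Scaffold",
    "AssemblyFilterResult",
    "AssemblyParams",
    "collect_reads",
    "collect_reads_batch",
    "assemble",
    "scaffold_contigs",
    "filter_assembly",
]

log = logging.getLogger(__name__)

SPACER = "N" * 300
DEFAULT_WINDOW = 200
CLIP_MIN_LEN = 20
CLIP_MIN_QUAL = 20.0
ALU_MATCH_MIN_BP = 30
ALU_MATCH_MIN_IDENTITY = 0.90
FLANK_MIN_BP = 30


@dataclass
class ReadRecord:
    read_id: str  # qname + "/1" or "/2"
    seq: str
    qual: str


@dataclass
class SiteReadSet:
    site_id: str
    reads: List[ReadRecord]
    pairs: List[Tuple[str, str]]  # (read_id_1, read_id_2)

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class AssemblyParams:
    min_overlap: int = 16
    min_identity: float = 0.90
    min_reads_per_contig: int = 2
    kmer: int = 14


@dataclass
class Contig:
    seq: str
    members: List[Tuple[str, int, str]]  # (read_id, offset, strand)
    depth: np.ndarray

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Scaffold:
    contigs: List[Contig]
    seq: str
    link_pairs: List[int] = field(default_factory=list)  # pairs per join

    def member_ids(self) -> List[str]:
        return [m[0] for c in self.contigs for m in c.members]


@dataclass
class AssemblyFilterResult:
    scaffold: Scaffold
    passed: bool
    alu_target: str = ""
    matched_bp: int = 0
    identity: float = 0.0
    match_start: int = 0  # scaffold coordinates of the Alu match
    match_end: int = 0
    match_strand: str = "+"
    flank5: int = 0
    flank3: int = 0
    gap_within_100bp: bool = False


# ---------------------------------------------------------------------------
# read collection
# ---------------------------------------------------------------------------


def _qualifying_clip(rec) -> bool:
    cig = rec.cigartuples
    if not cig:
        return False
    quals = rec.query_qualities
    for idx, (op, n) in ((0, cig[0]), (-1, cig[-1])):
        if op == 4 and n >= CLIP_MIN_LEN:
            if quals is None:
                continue
            sl = quals[:n] if idx == 0 else quals[-n:]
            if float(np.mean(sl)) >= CLIP_MIN_QUAL:
                return True
    return False


def collect_reads_batch(
    sites: Sequence[CandidateSite],
    sam_path: str,
    window: int = DEFAULT_WINDOW,
) -> Dict[str, SiteReadSet]:
    """Collect supporting read pairs per site in two streaming passes.

    The read set is the union of (a) the discovery manifest pairs and
    (b) pairs with a qualifying soft-clipped read inside the ``window``-bp
    region around the predicted breakpoint; both mates of each selected
    pair are included.
    """
    half = window // 2
    wanted: Dict[str, set] = {s.chrom + ":" + str(s.pos): set(s.read_names)
                              for s in sites}
    site_by_key = {s.chrom + ":" + str(s.pos): s for s in sites}
    with pysam.AlignmentFile(sam_path, check_sq=False) as af:
        for rec in af:
            if rec.is_secondary or rec.is_supplementary or rec.is_unmapped:
                continue
            if not _qualifying_clip(rec):
                continue
            for key, site in site_by_key.items():
                if (
                    rec.reference_name == site.chrom
                    and rec.reference_start < site.pos + half
                    and (rec.reference_end or 0) > site.pos - half
                ):
                    wanted[key].add(rec.query_name)
    all_names = set().union(*wanted.values()) if wanted else set()
    mates: Dict[str, Dict[int, ReadRecord]] = {}
    with pysam.AlignmentFile(sam_path, check_sq=False) as af:
        for rec in af:
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.query_name not in all_names:
                continue
            mate_no = 1 if rec.is_read1 else 2
            seq = rec.query_sequence or ""
            qual = (
                pysam.qualities_to_qualitystring(rec.query_qualities)
                if rec.query_qualities is not None
                else "I" * len(seq)
            )
            mates.setdefault(rec.query_name, {})[mate_no] = ReadRecord(
                f"{rec.query_name}/{mate_no}", seq, qual
            )
    out: Dict[str, SiteReadSet] = {}
    for key, names in wanted.items():
        reads: List[ReadRecord] = []
        pairs: List[Tuple[str, str]] = []
        for name in sorted(names):
            recs = mates.get(name, {})
            got = [recs[i] for i in (1, 2) if i in recs and recs[i].seq]
            reads.extend(got)
            if len(got) == 2:
                pairs.append((got[0].read_id, got[1].read_id))
        out[key] = SiteReadSet(key, reads, pairs)
    return out


def collect_reads(
    site: CandidateSite, sam_path: str, window: int = DEFAULT_WINDOW
) -> SiteReadSet:
    return collect_reads_batch([site], sam_path, window)[
        site.chrom + ":" + str(site.pos)
    ]


# ---------------------------------------------------------------------------
# greedy OLC assembly
# ---------------------------------------------------------------------------

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class _Unit:
    """A read or partial contig during greedy assembly."""

    __slots__ = (
        "uid", "seq", "codes", "rc_seq", "rc_codes", "kmap", "rc_kmap",
        "members", "reads",
    )

    def __init__(self, uid: int, seq: str, members, reads, k: int):
        self.uid = uid
        self.seq = seq
        self.codes = _encode(seq)
        self.rc_seq = reverse_complement(seq)
        self.rc_codes = _encode(self.rc_seq)
        self.kmap = _kmer_map(seq, k)
        self.rc_kmap = _kmer_map(self.rc_seq, k)
        self.members = members  # [(read_id, offset, strand)]
        self.reads = reads  # shared dict read_id -> (seq, qual)


def _kmer_map(seq: str, k: int) -> Dict[str, int]:
    out: Dict[str, int] = {}
    for i in range(0, len(seq) - k + 1):
        km = seq[i : i + k]
        if "N" not in km and km not in out:
            out[km] = i
    return out


def _overlap_at(
    a: np.ndarray, b: np.ndarray, d: int, min_overlap: int, min_identity: float
) -> Optional[Tuple[int, int]]:
    """Matched/overlap lengths for B placed at offset d relative to A."""
    lo = max(0, d)
    hi = min(len(a), d + len(b))
    ov = hi - lo
    if ov < min_overlap:
        return None
    sa = a[lo:hi]
    sb = b[lo - d : hi - d]
    matches = int(np.count_nonzero((sa == sb) & (sa < 4)))
    if matches < min_identity * ov:
        return None
    return matches, ov


def _consensus(
    members: List[Tuple[str, int, str]], reads: Dict[str, Tuple[str, str]]
) -> Tuple[str, np.ndarray]:
    """Quality-weighted per-column majority over the member layout."""
    length = max(off + len(reads[rid][0]) for rid, off, _ in members)
    sumq = np.zeros((length, 4), dtype=np.int64)
    maxq = np.zeros((length, 4), dtype=np.int64)
    depth = np.zeros(length, dtype=np.int32)
    for rid, off, strand in members:
        seq, qual = reads[rid]
        if strand == "-":
            seq = reverse_complement(seq)
            qual = qual[::-1]
        codes = _encode(seq)
        quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8) - 33
        valid = codes < 4
        idx = np.arange(len(codes)) + off
        np.add.at(sumq, (idx[valid], codes[valid]), quals[valid])
        np.maximum.at(maxq, (idx[valid], codes[valid]), quals[valid])
        depth[off : off + len(codes)] += 1
    key = sumq * 64 + maxq  # primary: summed quality; tie: best single read
    best = np.argmax(key, axis=1)  # argmax is first-hit -> alphabetical ties
    covered = key.max(axis=1) > 0
    bases = np.array(list("ACGT"))[best]
    bases[~covered] = "N"
    return "".join(bases), depth


def assemble(
    reads: Sequence[ReadRecord],
    params: AssemblyParams = AssemblyParams(),
) -> List[Contig]:
    """Greedy overlap-layout-consensus assembly of a site read set.

    Both orientations are considered; the highest-scoring overlap is merged
    first.  Reads left as singletons are discarded when
    ``min_reads_per_contig`` > 1.
    """
    if not reads:
        raise ValueError("reads must be non-empty")
    k = params.kmer
    read_data: Dict[str, Tuple[str, str]] = {}
    units: Dict[int, _Unit] = {}
    uid = 0
    for rec in reads:
        if not rec.seq or rec.read_id in read_data:
            continue
        read_data[rec.read_id] = (rec.seq, rec.qual or "I" * len(rec.seq))
        units[uid] = _Unit(
            uid, rec.seq, [(rec.read_id, 0, "+")], read_data, k
        )
        uid += 1

    # inverted index of forward k-mers (lazily pruned on merge)
    index: Dict[str, set] = {}

    def index_unit(u: _Unit) -> None:
        for km in u.kmap:
            index.setdefault(km, set()).add(u.uid)

    def candidate_partners(u: _Unit) -> set:
        found: set = set()
        for km in u.kmap:
            found |= index.get(km, set())
        for km in u.rc_kmap:
            found |= index.get(km, set())
        found.discard(u.uid)
        return {x for x in found if x in units}

    for u in units.values():
        index_unit(u)

    def best_pair_overlap(ua: _Unit, ub: _Unit):
        """(matched, ov, strand, offset) of best overlap of ub onto ua."""
        best = None
        for strand in ("+", "-"):
            bkmap = ub.kmap if strand == "+" else ub.rc_kmap
            bcodes = ub.codes if strand == "+" else ub.rc_codes
            small, big, small_is_b = (
                (bkmap, ua.kmap, True)
                if len(bkmap) <= len(ua.kmap)
                else (ua.kmap, bkmap, False)
            )
            offsets = set()
            for km, i in small.items():
                j = big.get(km)
                if j is None:
                    continue
                offsets.add(j - i if small_is_b else i - j)
            for d in offsets:
                res = _overlap_at(
                    ua.codes, bcodes, d, params.min_overlap,
                    params.min_identity,
                )
                if res is None:
                    continue
                matched, ov = res
                cand = (matched, ov, strand, d)
                if best is None or cand[0] > best[0]:
                    best = cand
        return best

    def merge(ua: _Unit, ub: _Unit, strand: str, d: int) -> _Unit:
        nonlocal uid
        members = list(ua.members)
        blen = len(ub.seq)
        for rid, off, st in ub.members:
            if strand == "-":
                rlen = len(read_data[rid][0])
                off = blen - (off + rlen)
                st = "-" if st == "+" else "+"
            members.append((rid, off + d, st))
        shift = -min(off for _, off, _ in members)
        if shift > 0:
            members = [(rid, off + shift, st) for rid, off, st in members]
        seq, _ = _consensus(members, read_data)
        unit = _Unit(uid, seq, members, read_data, k)
        uid += 1
        return unit

    # initial candidate overlaps via shared k-mers
    pending: Dict[Tuple[int, int], tuple] = {}
    first_read: Dict[int, str] = {
        u.uid: u.members[0][0] for u in units.values()
    }
    seen_pairs = set()
    for a in sorted(units):
        ua = units[a]
        for b in candidate_partners(ua):
            key = (min(a, b), max(a, b))
            if key in seen_pairs:
                continue
            seen_pairs.add(key)
            res = best_pair_overlap(units[key[0]], units[key[1]])
            if res:
                pending[key] = res

    while pending:
        # matched bp desc, then longer resulting contig, then lexicographic
        def sort_key(item):
            (a, b), (matched, ov, strand, d) = item
            result_len = max(len(units[a].seq), d + len(units[b].seq)) - min(
                0, d
            )
            return (-matched, -result_len, min(first_read[a], first_read[b]),
                    a, b)

        (a, b), (matched, ov, strand, d) = min(pending.items(), key=sort_key)
        new = merge(units[a], units[b], strand, d)
        del units[a], units[b]
        pending = {
            key: val
            for key, val in pending.items()
            if a not in key and b not in key
        }
        units[new.uid] = new
        index_unit(new)
        first_read[new.uid] = new.members[0][0]
        for other in candidate_partners(new):
            res = best_pair_overlap(units[other], new)
            if res:
                pending[(other, new.uid)] = res

    contigs = []
    for unit in units.values():
        if len(unit.members) < params.min_reads_per_contig:
            continue
        seq, depth = _consensus(unit.members, read_data)
        contigs.append(Contig(seq, sorted(unit.members), depth))
    contigs.sort(key=lambda c: (-len(c.seq), c.members[0][0]))
    return contigs


# ---------------------------------------------------------------------------
# scaffolding and filtering
# ---------------------------------------------------------------------------


def scaffold_contigs(
    contigs: Sequence[Contig], pairs: Sequence[Tuple[str, str]]
) -> List[Scaffold]:
    """Join pair-linked contigs with 300-N spacers.

    Contigs sharing opposite mates of at least one pair, with a consistent
    relative orientation across all shared links, are joined; contradictory
    link orientations leave the contigs separate (warning logged).
    Unlinked contigs become single-contig scaffolds.
    """
    where: Dict[str, Tuple[int, str]] = {}
    for ci, contig in enumerate(contigs):
        for rid, _, strand in contig.members:
            where[rid] = (ci, strand)
    links: Dict[Tuple[int, int], List[str]] = {}
    for r1, r2 in pairs:
        if r1 not in where or r2 not in where:
            continue
        (c1, s1), (c2, s2) = where[r1], where[r2]
        if c1 == c2:
            continue
        a, b = min(c1, c2), max(c1, c2)
        # FR mates read opposite template strands: joined forward-forward
        # when the member strands differ
        rel = "+" if s1 != s2 else "-"
        links.setdefault((a, b), []).append(rel)

    consistent: Dict[Tuple[int, int], Tuple[str, int]] = {}
    for key, rels in links.items():
        if len(set(rels)) > 1:
            log.warning(
                "contradictory link orientations between contigs %s; "
                "leaving unjoined",
                key,
            )
            continue
        consistent[key] = (rels[0], len(rels))

    # connected components over consistent links
    parent = list(range(len(contigs)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in consistent:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: Dict[int, List[int]] = {}
    for ci in range(len(contigs)):
        groups.setdefault(find(ci), []).append(ci)

    scaffolds = []
    for group in groups.values():
        group.sort(key=lambda ci: -len(contigs[ci].seq))
        ordered = [contigs[ci] for ci in group]
        orientations = ["+"] * len(group)
        for gi in range(1, len(group)):
            key = (min(group[0], group[gi]), max(group[0], group[gi]))
            rel = consistent.get(key, ("+", 0))[0]
            orientations[gi] = rel
        parts = []
        link_counts = []
        for gi, contig in enumerate(ordered):
            seq = contig.seq
            if orientations[gi] == "-":
                seq = reverse_complement(seq)
            parts.append(seq)
            if gi > 0:
                key = (min(group[0], group[gi]), max(group[0], group[gi]))
                link_counts.append(consistent.get(key, ("+", 0))[1])
        scaffolds.append(
            Scaffold(ordered, SPACER.join(parts), link_counts)
        )
    scaffolds.sort(key=lambda s: -len(s.seq))
    return scaffolds


def filter_assembly(
    scaffold: Scaffold, alu_library: Dict[str, str]
) -> AssemblyFilterResult:
    """Apply the element-content and flanking-sequence filters.

    Pass requires a >=30 bp Alu-library match at >=90% identity and >=30 bp
    of contiguous non-gap flanking sequence on at least one side of the
    match.
    """
    if not alu_library:
        raise ValueError("alu_library must be non-empty")
    hit = best_library_hit(scaffold.seq, alu_library)
    if hit is None:
        return AssemblyFilterResult(scaffold, passed=False)
    seq = scaffold.seq
    start, end = hit.query_start, hit.query_end

    def non_gap_run(idx: int, direction: int) -> int:
        n = 0
        while 0 <= idx < len(seq) and seq[idx] != "N":
            n += 1
            idx += direction
        return n

    flank5 = non_gap_run(start - 1, -1)
    flank3 = non_gap_run(end, 1)
    gap_near = "N" in seq[max(0, start - 100) : start] or "N" in seq[
        end : end + 100
    ]
    passed = (
        hit.matched_bp >= ALU_MATCH_MIN_BP
        and hit.identity >= ALU_MATCH_MIN_IDENTITY
        and max(flank5, flank3) >= FLANK_MIN_BP
    )
    return AssemblyFilterResult(
        scaffold,
        passed=passed,
        alu_target=hit.target,
        matched_bp=hit.matched_bp,
        identity=hit.identity,
        match_start=start,
        match_end=end,
        match_strand=hit.strand,
        flank5=flank5,
        flank3=flank3,
        gap_within_100bp=gap_near,
    )
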