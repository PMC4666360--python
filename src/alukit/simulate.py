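"""Synthetic inputs for the pipeline.

Provides the L1-EN nic-site position probability matrix and rejection
sampler, implantation of Alu-like insertions with retrotransposition
hallmarks (target site duplications, poly-A tails, 5' truncation, target
site deletions), and a paired-end read simulator whose alignments against
the unmodified reference are projected from the known truth (reads crossing
an insertion junction receive soft clips; reads internal to an insertion
are emitted as unmapped mates).

Coordinate conventions
----------------------
An insertion *position* ``p`` is the 0-based reference coordinate at which
the new sequence is introduced: ``hap = ref[:p] + insert + ref[p-tsd:p] +
ref[p+del:]``.  The 5-bp nic-site window scored by the PPM is, on the plus
strand, ``ref[p-4:p+1]`` (four bases 5' of the nick plus one 3' base, so
the canonical motif reads TTTT/A); on the minus strand it is the reverse
complement of ``ref[p-1:p+4]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genome_io import Genome, GenomicInterval, RepeatCatalog, reverse_complement

__all__ = [
    "PositionProbabilityMatrix",
    "build_ppm",
    "site_probability",
    "sample_insertion_sites",
    "ImplantSpec",
    "Haplotype",
    "implant_insertions",
    "SimulatedSample",
    "simulate_sample",
    "ReadPairSet",
    "simulate_paired_reads",
    "default_nic_sites",
    "default_consensus_library",
    "random_genome",
    "sample_implant_cohort",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

NIC_WINDOW = 5
DEFAULT_ATTEMPT_CAP = 10**7


# ---------------------------------------------------------------------------
# Position probability matrix and rejection sampling
# ---------------------------------------------------------------------------


@dataclass
class PositionProbabilityMatrix:
    """Per-column base probabilities of the nic-site motif.

    ``probs`` has shape (width, 4) with columns ordered A, C, G, T.  Every
    row sums to 1 within 1e-9.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must have shape (width, 4)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PPM columns must each sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def prob(self, column: int, base: str) -> float:
        return float(self.probs[column, _BASE_INDEX[base]])

    def max_window_probability(self) -> float:
        return float(np.prod(self.probs.max(axis=1)))


def build_ppm(
    nic_sites: Sequence[str], pseudocount: float = 1.0
) -> PositionProbabilityMatrix:
    """Column-wise base probabilities with a per-base pseudocount.

    ``probs[j][b] = (count of b at column j + pseudocount) / (n + 4*pseudocount)``
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if not nic_sites:
        if pseudocount == 0:
            raise ValueError("empty input requires pseudocount > 0")
        raise ValueError("at least one nic-site sequence is required")
    width = len(nic_sites[0])
    counts = np.zeros((width, 4), dtype=float)
    for site in nic_sites:
        if len(site) != width:
            raise ValueError("nic-site sequences must all have equal length")
        for j, b in enumerate(site.upper()):
            if b not in _BASE_INDEX:
                raise ValueError(f"invalid base {b!r} in nic-site sequence")
            counts[j, _BASE_INDEX[b]] += 1
    n = len(nic_sites)
    denom = n + 4 * pseudocount
    if denom == 0:
        raise ValueError("empty input with pseudocount 0")
    return PositionProbabilityMatrix((counts + pseudocount) / denom)


def site_probability(
    ppm: PositionProbabilityMatrix, window: str, strand: str = "+"
) -> float:
    """Product of per-column probabilities; 0 if the window contains N."""
    if len(window) != ppm.width:
        raise ValueError(
            f"window length {len(window)} != PPM width {ppm.width}"
        )
    if strand == "-":
        window = reverse_complement(window)
    p = 1.0
    for j, b in enumerate(window.upper()):
        if b not in _BASE_INDEX:
            return 0.0
        p *= ppm.probs[j, _BASE_INDEX[b]]
    return p


def _encode_genome(genome: Genome) -> Dict[str, np.ndarray]:
    """uint8 codes: A=0 C=1 G=2 T=3, N=4."""
    table = np.full(256, 4, dtype=np.uint8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
    return {
        name: table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        for name, seq in genome.items()
    }


def nic_window(genome: Genome, chrom: str, pos: int, strand: str) -> str:
    """The 5-bp nic-site window at an insertion position."""
    seq = genome[chrom]
    if strand == "+":
        return seq[pos - 4 : pos + 1]
    return reverse_complement(seq[pos - 1 : pos + 4])


def sample_insertion_sites(
    genome: Genome,
    ppm: PositionProbabilityMatrix,
    n: int,
    mask: Optional[RepeatCatalog] = None,
    seed: int = 0,
    attempt_cap: int = DEFAULT_ATTEMPT_CAP,
) -> List[Tuple[str, int, str]]:
    """Rejection-sample ``n`` insertion sites matching the PPM.

    Each draw picks a uniform genomic position and strand, scores the 5-bp
    nic window with the PPM, draws a uniform deviate ``p`` and accepts the
    site iff ``p < P``.  Positions inside ``mask`` intervals are rejected
    before scoring.  Raises ``RuntimeError`` after ``attempt_cap`` attempts
    per requested site.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    codes = _encode_genome(genome)
    names = genome.names()
    lengths = np.array([genome.length(c) for c in names], dtype=np.int64)
    # valid nick positions keep the window in bounds on both strands
    valid = lengths - 8
    if (valid <= 0).all():
        raise ValueError("genome too short for nic-site sampling")
    cum = np.cumsum(np.maximum(valid, 0))
    total = int(cum[-1])

    masked: Dict[str, np.ndarray] = {}
    if mask is not None:
        for name in names:
            flags = np.zeros(genome.length(name), dtype=bool)
            for iv in mask:
                if iv.chrom == name:
                    flags[iv.start : iv.end] = True
            masked[name] = flags

    # probability lookup padded with a zero column so N (code 4) scores 0
    probs_ext = np.zeros((ppm.width, 5))
    probs_ext[:, :4] = ppm.probs
    comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

    out: List[Tuple[str, int, str]] = []
    attempts = 0
    cap = attempt_cap * n
    batch = max(4096, min(1 << 18, n * 64))
    while len(out) < n:
        if attempts >= cap:
            raise RuntimeError(
                f"rejection sampling exceeded {cap} attempts "
                f"({len(out)}/{n} sites accepted)"
            )
        draws = rng.integers(0, total, size=batch)
        strands = rng.integers(0, 2, size=batch)
        unif = rng.random(size=batch)
        attempts += batch
        chrom_idx = np.searchsorted(cum, draws, side="right")
        offset = draws - np.concatenate(([0], cum[:-1]))[chrom_idx]
        positions = offset + 4
        prob = np.zeros(batch)
        keep = np.ones(batch, dtype=bool)
        for ci, name in enumerate(names):
            sel = chrom_idx == ci
            if not sel.any():
                continue
            pos = positions[sel]
            if mask is not None:
                keep[np.flatnonzero(sel)[masked[name][pos]]] = False
            arr = codes[name]
            plus = sel & (strands == 0)
            minus = sel & (strands == 1)
            if plus.any():
                win = arr[positions[plus, None] + np.arange(-4, 1)]
                prob[plus] = np.prod(
                    probs_ext[np.arange(5), win], axis=1
                )
            if minus.any():
                win = comp[
                    arr[positions[minus, None] + np.arange(-1, 4)]
                ][:, ::-1]
                prob[minus] = np.prod(
                    probs_ext[np.arange(5), win], axis=1
                )
        accepted = np.flatnonzero(keep & (unif < prob))
        for idx in accepted:
            out.append(
                (
                    names[chrom_idx[idx]],
                    int(positions[idx]),
                    "+" if strands[idx] == 0 else "-",
                )
            )
            if len(out) == n:
                break
    return out


# ---------------------------------------------------------------------------
# Implants
# ---------------------------------------------------------------------------


@dataclass
class ImplantSpec:
    """One non-reference insertion to implant into a reference genome."""

    chrom: str
    pos: int  # zero-width insertion point, reference coordinate
    element_source: str
    strand: str = "+"
    truncation_offset: int = 0  # bases removed from the element 5' end
    tsd_length: int = 0  # 0 = blunt join
    target_deletion: int = 0  # mutually exclusive with tsd_length > 0
    polyA_length: int = 20
    subst_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.tsd_length < 0 or self.target_deletion < 0:
            raise ValueError("tsd_length and target_deletion must be >= 0")
        if self.tsd_length > 0 and self.target_deletion > 0:
            raise ValueError(
                "tsd_length and target_deletion are mutually exclusive"
            )
        if self.polyA_length < 0:
            raise ValueError("polyA_length must be >= 0")


# segment kinds in a haplotype->reference map
_REF = "ref"
_INS = "ins"


@dataclass
class Haplotype:
    """A donor haplotype plus its segment map back to the reference.

    ``segmap[chrom]`` is a list of ``(hap_start, hap_end, kind, ref_start)``
    tuples; ``kind`` is ``"ref"`` for reference-derived segments (including
    TSD copies, whose ``ref_start`` jumps backwards) and ``"ins"`` for
    inserted element sequence (``ref_start`` is the insertion point).
    """

    genome: Genome
    segmap: Dict[str, List[Tuple[int, int, str, int]]]

    @classmethod
    def from_reference(cls, genome: Genome) -> "Haplotype":
        segmap = {
            name: [(0, genome.length(name), _REF, 0)] for name in genome
        }
        return cls(genome, segmap)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        base = chr(arr[i])
        choices = [b for b in BASES if b != base]
        arr[i] = ord(choices[rng.integers(0, 3)])
    return arr.tobytes().decode("ascii")


def inserted_sequence(
    spec: ImplantSpec,
    library: Dict[str, str],
    rng: Optional[np.random.Generator] = None,
) -> str:
    """The sequence introduced at the insertion point (strand applied)."""
    element = library[spec.element_source]
    if spec.truncation_offset >= len(element):
        raise ValueError("truncation_offset must be < element length")
    body = element[spec.truncation_offset :]
    if spec.subst_rate > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        body = _mutate(body, spec.subst_rate, rng)
    insert = body + "A" * spec.polyA_length
    if spec.strand == "-":
        insert = reverse_complement(insert)
    return insert


def implant_insertions(
    genome: Genome,
    specs: Sequence[ImplantSpec],
    consensus_library: Dict[str, str],
    rng: Optional[np.random.Generator] = None,
    min_separation: int = 100,
) -> Tuple[Haplotype, List[dict]]:
    """Apply implants to a reference genome, returning the haplotype + truth.

    At each site the inserted sequence is ``element[truncation:] + polyA``
    (reverse complemented on '-'), with the ``tsd_length`` bases immediately
    5' of the site duplicated after it, or ``target_deletion`` reference
    bases removed.  Truth-table coordinates refer both to the unmodified
    reference and to the resulting haplotype.
    """
    by_chrom: Dict[str, List[ImplantSpec]] = {}
    for spec in specs:
        if spec.element_source not in consensus_library:
            raise KeyError(f"unknown element source {spec.element_source!r}")
        if spec.chrom not in genome:
            raise KeyError(f"unknown chromosome {spec.chrom!r}")
        by_chrom.setdefault(spec.chrom, []).append(spec)

    hap_seqs: Dict[str, str] = {}
    segmap: Dict[str, List[Tuple[int, int, str, int]]] = {}
    truth: List[dict] = []

    for name, seq in genome.items():
        chrom_specs = sorted(by_chrom.get(name, []), key=lambda s: s.pos)
        for a, b in zip(chrom_specs, chrom_specs[1:]):
            if b.pos - a.pos < max(
                min_separation, a.tsd_length + a.target_deletion + 1
            ):
                raise ValueError(
                    f"overlapping implant specs at {name}:{a.pos} and {b.pos}"
                )
        parts: List[str] = []
        segs: List[Tuple[int, int, str, int]] = []
        cursor = 0  # reference coordinate
        hap_len = 0

        def emit(piece: str, kind: str, ref_start: int) -> None:
            nonlocal hap_len
            if piece:
                parts.append(piece)
                segs.append((hap_len, hap_len + len(piece), kind, ref_start))
                hap_len += len(piece)

        for spec in chrom_specs:
            if not (0 < spec.pos <= len(seq)):
                raise ValueError(f"implant position {spec.pos} out of range")
            if spec.tsd_length > spec.pos:
                raise ValueError("tsd_length extends past chromosome start")
            emit(seq[cursor : spec.pos], _REF, cursor)
            insert = inserted_sequence(spec, consensus_library, rng)
            ins_start = hap_len
            emit(insert, _INS, spec.pos)
            tsd_seq = seq[spec.pos - spec.tsd_length : spec.pos]
            emit(tsd_seq, _REF, spec.pos - spec.tsd_length)
            truth.append(
                {
                    "chrom": name,
                    "pos": spec.pos,
                    "strand": spec.strand,
                    "subfamily": spec.element_source,
                    "tsd_len": spec.tsd_length,
                    "tsd_seq": tsd_seq,
                    "target_del": spec.target_deletion,
                    "trunc_offset": spec.truncation_offset,
                    "polyA_len": spec.polyA_length,
                    "insert_len": len(insert),
                    "alt_start": ins_start,
                    "alt_end": ins_start + len(insert) + spec.tsd_length,
                }
            )
            cursor = spec.pos + spec.target_deletion
        emit(seq[cursor:], _REF, cursor)
        hap_seqs[name] = "".join(parts)
        segmap[name] = segs

    return Haplotype(Genome(hap_seqs), segmap), truth


@dataclass
class SimulatedSample:
    """Truth scaffold: a sample's haplotypes and per-implant dosages."""

    sample_id: str
    ploidy: int
    haplotypes: List[Haplotype]
    dosages: List[int]  # per implant spec, 0..ploidy
    truth: List[dict]


def simulate_sample(
    genome: Genome,
    specs: Sequence[ImplantSpec],
    dosages: Sequence[int],
    consensus_library: Dict[str, str],
    sample_id: str = "S1",
    ploidy: int = 2,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedSample:
    if len(dosages) != len(specs):
        raise ValueError("one dosage per implant spec required")
    if any(d < 0 or d > ploidy for d in dosages):
        raise ValueError("dosage must be in [0, ploidy]")
    haplotypes = []
    truth_all: List[dict] = []
    for h in range(ploidy):
        carried = [s for s, d in zip(specs, dosages) if d > h]
        hap, truth = implant_insertions(genome, carried, consensus_library, rng)
        haplotypes.append(hap)
        if h == 0:
            truth_all = truth
    # record dosage in the truth table (keyed by position order of specs)
    by_key = {(t["chrom"], t["pos"]): t for t in truth_all}
    for spec, d in zip(specs, dosages):
        rec = by_key.get((spec.chrom, spec.pos))
        if rec is not None:
            rec["dosage"] = d
    return SimulatedSample(sample_id, ploidy, haplotypes, list(dosages), truth_all)


# ---------------------------------------------------------------------------
# Paired-end read simulation
# ---------------------------------------------------------------------------


@dataclass
class SimRead:
    """One mate, with its truth-projected alignment vs the reference."""

    seq: str  # reference-forward orientation
    qual: str
    mapped: bool
    chrom: str
    pos: int  # leftmost aligned reference position (if mapped)
    cigar: str
    reverse: bool  # sequenced from the bottom strand


@dataclass
class SimPair:
    name: str
    r1: SimRead
    r2: SimRead


@dataclass
class ReadPairSet:
    """Simulated read pairs with FASTQ and SAM writers."""

    pairs: List[SimPair]
    read_len: int
    frag_mean: float
    frag_sd: float
    error_rate: float
    seed: int

    def write_fastq(self, path1, path2) -> None:
        with open(path1, "w") as f1, open(path2, "w") as f2:
            for pair in self.pairs:
                for fh, read, mate_no in (
                    (f1, pair.r1, 1),
                    (f2, pair.r2, 2),
                ):
                    seq, qual = read.seq, read.qual
                    if read.reverse:
                        seq = reverse_complement(seq)
                        qual = qual[::-1]
                    fh.write(f"@{pair.name}/{mate_no}\n{seq}\n+\n{qual}\n")

    def write_sam(self, path, reference: Genome) -> None:
        import pysam

        names = reference.names()
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": name, "LN": reference.length(name)} for name in names
            ],
        }
        refid = {name: i for i, name in enumerate(names)}

        records = []
        for pair in self.pairs:
            for read, mate, first in (
                (pair.r1, pair.r2, True),
                (pair.r2, pair.r1, False),
            ):
                flag = 0x1 | (0x40 if first else 0x80)
                if read.reverse:
                    flag |= 0x10
                if mate.reverse:
                    flag |= 0x20
                if not read.mapped:
                    flag |= 0x4
                if not mate.mapped:
                    flag |= 0x8
                tid = mpos = -1
                pos = -1
                if read.mapped:
                    tid, pos = refid[read.chrom], read.pos
                elif mate.mapped:
                    tid, pos = refid[mate.chrom], mate.pos
                if mate.mapped:
                    mtid, mpos = refid[mate.chrom], mate.pos
                elif read.mapped:
                    mtid, mpos = refid[read.chrom], read.pos
                else:
                    mtid = -1
                proper = (
                    read.mapped
                    and mate.mapped
                    and read.chrom == mate.chrom
                    and read.reverse != mate.reverse
                    and "S" not in read.cigar
                    and "S" not in mate.cigar
                )
                if proper:
                    flag |= 0x2
                records.append((tid, pos, flag, read, mtid, mpos, pair.name))

        records.sort(
            key=lambda rec: (
                rec[0] if rec[0] >= 0 else 10**9,
                rec[1] if rec[1] >= 0 else 10**9,
                rec[6],
            )
        )
        with pysam.AlignmentFile(path, "w", header=header) as out:
            for tid, pos, flag, read, mtid, mpos, name in records:
                a = pysam.AlignedSegment(out.header)
                a.query_name = name
                a.flag = flag
                a.reference_id = tid
                a.reference_start = pos if pos >= 0 else -1
                a.mapping_quality = 60 if read.mapped else 0
                a.cigarstring = read.cigar if read.mapped else None
                a.next_reference_id = mtid
                a.next_reference_start = mpos if mpos >= 0 else -1
                seq, qual = read.seq, read.qual
                if read.reverse and not read.mapped:
                    # unmapped mates are stored as sequenced
                    seq = reverse_complement(seq)
                    qual = qual[::-1]
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array(qual)
                out.write(a)


def _project_read(
    segs: List[Tuple[int, int, str, int]],
    start: int,
    end: int,
    min_anchor: int = 20,
    max_del: int = 100,
) -> Tuple[bool, int, str]:
    """Project a haplotype interval onto the reference.

    Returns ``(mapped, ref_pos, cigar)``.  The longest run of
    reference-compatible pieces anchors the read; flanking bases are soft
    clipped.  Adjacent reference pieces separated by a small forward jump
    are joined with a D op.
    """
    pieces = []
    for hs, he, kind, rs in segs:
        if he <= start or hs >= end:
            continue
        s, e = max(hs, start), min(he, end)
        pieces.append((kind, s, e, rs + (s - hs) if kind == _REF else rs))
    # split into candidate anchored runs of compatible ref pieces
    runs: List[List[tuple]] = []
    cur: List[tuple] = []
    for piece in pieces:
        kind = piece[0]
        if kind != _REF:
            if cur:
                runs.append(cur)
                cur = []
            continue
        if cur:
            pk, ps, pe, prs = cur[-1]
            jump = piece[3] - (prs + (pe - ps))
            if 0 <= jump <= max_del:
                cur.append(piece)
            else:
                runs.append(cur)
                cur = [piece]
        else:
            cur = [piece]
    if cur:
        runs.append(cur)
    if not runs:
        return False, -1, ""
    best = max(runs, key=lambda run: sum(e - s for _, s, e, _ in run))
    anchored = sum(e - s for _, s, e, _ in best)
    if anchored < min_anchor:
        return False, -1, ""
    ref_pos = best[0][3]
    lead = best[0][1] - start
    tail = end - best[-1][2]
    cig = []
    if lead:
        cig.append(f"{lead}S")
    prev_ref_end = None
    for _, s, e, rs in best:
        if prev_ref_end is not None and rs > prev_ref_end:
            cig.append(f"{rs - prev_ref_end}D")
        cig.append(f"{e - s}M")
        prev_ref_end = rs + (e - s)
    if tail:
        cig.append(f"{tail}S")
    # merge adjacent M ops
    merged: List[str] = []
    for op in cig:
        if merged and op.endswith("M") and merged[-1].endswith("M"):
            merged[-1] = f"{int(merged[-1][:-1]) + int(op[:-1])}M"
        else:
            merged.append(op)
    return True, ref_pos, "".join(merged)


def _apply_errors(
    seq: str, rate: float, rng: np.random.Generator
) -> str:
    if rate <= 0:
        return seq
    return _mutate(seq, rate, rng)


def simulate_paired_reads(
    haplotypes: Sequence[Haplotype],
    coverage: float,
    read_len: int = 100,
    frag_mean: float = 300.0,
    frag_sd: float = 30.0,
    error_rate: float = 0.0,
    seed: int = 0,
    base_quality: int = 38,
) -> ReadPairSet:
    """Simulate FR paired-end reads from one or more haplotypes.

    The expected pair count per haplotype is ``coverage * length /
    (ploidy * 2 * read_len)`` and is Poisson-realized; sequencing errors
    are i.i.d. substitutions.  Deterministic under ``seed``.
    """
    if frag_mean <= read_len:
        raise ValueError("frag_mean must exceed read_len")
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    rng = np.random.default_rng(seed)
    qual = chr(33 + base_quality) * read_len
    pairs: List[SimPair] = []
    n_haps = len(haplotypes)
    counter = 0
    for hap_idx, hap in enumerate(haplotypes):
        for chrom in hap.genome:
            seq = hap.genome[chrom]
            L = len(seq)
            if L < frag_mean:
                continue
            expect = coverage * L / (2 * read_len) / n_haps
            n_pairs = int(rng.poisson(expect))
            frags = rng.normal(frag_mean, frag_sd, size=n_pairs)
            frags = np.clip(np.rint(frags), read_len, L).astype(int)
            starts = (rng.random(n_pairs) * (L - frags + 1)).astype(int)
            segs = hap.segmap[chrom]
            for fs, fl in zip(starts, frags):
                fs = int(fs)
                fe = fs + int(fl)
                s1 = _apply_errors(seq[fs : fs + read_len], error_rate, rng)
                s2 = _apply_errors(seq[fe - read_len : fe], error_rate, rng)
                m1, p1, c1 = _project_read(segs, fs, fs + read_len)
                m2, p2, c2 = _project_read(segs, fe - read_len, fe)
                name = f"sim{counter:08d}"
                counter += 1
                pairs.append(
                    SimPair(
                        name,
                        SimRead(s1, qual, m1, chrom, p1, c1, reverse=False),
                        SimRead(s2, qual, m2, chrom, p2, c2, reverse=True),
                    )
                )
    return ReadPairSet(pairs, read_len, frag_mean, frag_sd, error_rate, seed)


# ---------------------------------------------------------------------------
# Synthetic defaults: nic sites, consensus library, genomes, cohorts
# ---------------------------------------------------------------------------


def default_nic_sites(n: int = 99, seed: int = 99) -> List[str]:
    """A synthetic stand-in for the published nic-site list.

    Sites are drawn from a sharply peaked distribution around the canonical
    TTTT/A motif; this does not claim to reproduce any published matrix.
    """
    target = np.array(
        [
            [0.05, 0.05, 0.05, 0.85],  # T
            [0.05, 0.05, 0.05, 0.85],  # T
            [0.08, 0.04, 0.04, 0.84],  # T
            [0.10, 0.05, 0.05, 0.80],  # T
            [0.75, 0.08, 0.09, 0.08],  # A
        ]
    )
    rng = np.random.default_rng(seed)
    sites = []
    for _ in range(n):
        idx = [rng.choice(4, p=row) for row in target]
        sites.append("".join(BASES[i] for i in idx))
    return sites


_SUBFAMILY_EDITS = {
    # name -> (list of (position, base) substitutions, insertion (pos, seq))
    "AluY": ([], None),
    "AluYa5": ([(10, "T"), (55, "C"), (120, "A"), (180, "G"), (230, "T")], None),
    "AluYa8": (
        [(10, "T"), (55, "C"), (120, "A"), (180, "G"), (230, "T"),
         (35, "G"), (90, "A"), (205, "C")],
        None,
    ),
    "AluYb8": ([(20, "A"), (70, "G"), (140, "C"), (210, "A")], (246, "CAGTCCG")),
    "AluYb9": (
        [(20, "A"), (70, "G"), (140, "C"), (210, "A"), (100, "T")],
        (246, "CAGTCCG"),
    ),
    "AluYc1": ([(15, "G"), (160, "T")], None),
}


def default_consensus_library(length: int = 281, seed: int = 17) -> Dict[str, str]:
    """Deterministic synthetic Alu-like subfamily consensus library.

    A shared ancestral core with subfamily-diagnostic substitutions (and a
    7-bp insertion for the Yb lineage), mirroring the structure -- not the
    sequence -- of real consensus sets.
    """
    rng = np.random.default_rng(seed)
    core = list(
        "".join(BASES[i] for i in rng.integers(0, 4, size=length))
    )
    library: Dict[str, str] = {}
    for name, (subs, insertion) in _SUBFAMILY_EDITS.items():
        seq = core.copy()
        for pos, base in subs:
            cur = seq[pos]
            seq[pos] = base if base != cur else ("A" if cur != "A" else "C")
        s = "".join(seq)
        if insertion:
            pos, ins = insertion
            s = s[:pos] + ins + s[pos:]
        library[name] = s
    return library


def random_genome(
    sizes: Dict[str, int],
    seed: int = 0,
    n_reference_alus: int = 0,
    consensus_library: Optional[Dict[str, str]] = None,
    alu_spacing: int = 20000,
) -> Tuple[Genome, RepeatCatalog]:
    """Uniform-random genome with optional annotated "reference Alu" copies.

    Reference copies are written into the sequence at regularly jittered,
    well-separated locations and reported in the returned catalog.
    """
    rng = np.random.default_rng(seed)
    seqs: Dict[str, List[str]] = {}
    for name, L in sizes.items():
        seqs[name] = list(
            "".join(BASES[i] for i in rng.integers(0, 4, size=L))
        )
    catalog = RepeatCatalog()
    if n_reference_alus:
        if consensus_library is None:
            consensus_library = default_consensus_library()
        fams = sorted(consensus_library)
        total = sum(sizes.values())
        placed = 0
        for name, L in sizes.items():
            share = max(1, round(n_reference_alus * L / total))
            for k in range(share):
                if placed >= n_reference_alus:
                    break
                anchor = int((k + 0.5) * L / share)
                jitter = int(rng.integers(-alu_spacing // 4, alu_spacing // 4))
                start = max(0, min(L - 400, anchor + jitter))
                fam = fams[int(rng.integers(0, len(fams)))]
                body = consensus_library[fam]
                strand = "+" if rng.integers(0, 2) == 0 else "-"
                ins = body if strand == "+" else reverse_complement(body)
                seqs[name][start : start + len(ins)] = list(ins)
                catalog.intervals.append(
                    GenomicInterval(name, start, start + len(ins), strand, fam)
                )
                placed += 1
    genome = Genome({name: "".join(chars) for name, chars in seqs.items()})
    return genome, catalog


def sample_truncation_offset(
    rng: np.random.Generator,
    weights: Tuple[float, float, float] = (0.85, 0.10, 0.05),
    element_length: int = 281,
) -> int:
    """Three-component truncation mixture over consensus start offsets.

    Components correspond to full-length (start 1-5), short truncation
    (7-45) and long truncation (55-171), expressed here as 0-based bases
    removed from the element 5' end.
    """
    u = rng.random()
    if u < weights[0]:
        start = int(rng.integers(1, 6))
    elif u < weights[0] + weights[1]:
        start = int(rng.integers(7, 46))
    else:
        start = int(rng.integers(55, 172))
    return min(start - 1, element_length - 30)


def sample_implant_cohort(
    genome: Genome,
    ppm: PositionProbabilityMatrix,
    n: int,
    consensus_library: Dict[str, str],
    mask: Optional[RepeatCatalog] = None,
    seed: int = 0,
    min_separation: int = 2000,
    mask_clearance: int = 1000,
    tsd_range: Tuple[int, int] = (5, 25),
    blunt_fraction: float = 0.05,
    deletion_fraction: float = 0.10,
    polyA_range: Tuple[int, int] = (10, 30),
    truncation_weights: Tuple[float, float, float] = (0.85, 0.10, 0.05),
    subfamilies: Optional[Sequence[str]] = None,
) -> List[ImplantSpec]:
    """Draw a cohort of non-overlapping implant specs at PPM-sampled sites.

    Sites are rejection-sampled with the nic-site PPM, kept
    ``mask_clearance`` away from mask intervals and ``min_separation``
    apart from each other.  TSD lengths are uniform over ``tsd_range``
    (with small blunt / target-deletion fractions) and truncation offsets
    follow the three-component mixture.

    Junctions are kept representationally unambiguous: parameter draws
    where the insert's first (or last) base equals the adjacent reference
    base are redrawn, since such events admit multiple equally valid
    TSD/truncation descriptions and no caller can recover the generating
    one.  Single-base target deletions are avoided for the same reason.
    """
    rng = np.random.default_rng(seed)
    fams = list(subfamilies or sorted(consensus_library))
    chosen: List[Tuple[str, int, str]] = []
    specs_by_site: Dict[Tuple[str, int], ImplantSpec] = {}
    edge = 1500
    attempts = 0
    while len(chosen) < n:
        attempts += 1
        if attempts > 200:
            raise RuntimeError("could not place implant cohort")
        need = (n - len(chosen)) * 3 + 8
        cands = sample_insertion_sites(
            genome, ppm, need, mask=None, seed=seed + attempts
        )
        for chrom, pos, strand in cands:
            if pos < edge or pos > genome.length(chrom) - edge:
                continue
            if mask is not None:
                from .genome_io import in_mask

                if in_mask(mask, chrom, pos, pad=mask_clearance):
                    continue
            if any(
                c == chrom and abs(pos - p) < min_separation
                for c, p, _ in chosen
            ):
                continue
            spec = _draw_unambiguous_spec(
                genome, chrom, pos, strand, consensus_library, fams, rng,
                tsd_range, blunt_fraction, deletion_fraction, polyA_range,
                truncation_weights,
            )
            if spec is None:
                continue  # no unambiguous parameterization at this site
            chosen.append((chrom, pos, strand))
            specs_by_site[(chrom, pos)] = spec
            if len(chosen) == n:
                break
    return [specs_by_site[key] for key in sorted(specs_by_site)]


def _draw_unambiguous_spec(
    genome: Genome,
    chrom: str,
    pos: int,
    strand: str,
    consensus_library: Dict[str, str],
    fams: Sequence[str],
    rng: np.random.Generator,
    tsd_range: Tuple[int, int],
    blunt_fraction: float,
    deletion_fraction: float,
    polyA_range: Tuple[int, int],
    truncation_weights: Tuple[float, float, float],
) -> Optional[ImplantSpec]:
    """Parameter draw satisfying the unambiguous-junction conditions."""
    ref = genome[chrom]
    if strand == "-" and ref[pos] == "T":
        return None  # minus-strand inserts begin with poly-T: C1 unsatisfiable
    if True:
        for _try in range(50):
            fam = fams[int(rng.integers(0, len(fams)))]
            u = rng.random()
            tsd = del_len = 0
            if u < blunt_fraction:
                pass
            elif u < blunt_fraction + deletion_fraction:
                del_len = int(rng.integers(3, 7))
            else:
                tsd = int(rng.integers(tsd_range[0], tsd_range[1] + 1))
            spec = ImplantSpec(
                chrom=chrom,
                pos=pos,
                element_source=fam,
                strand=strand,
                truncation_offset=sample_truncation_offset(
                    rng, truncation_weights, len(consensus_library[fam])
                ),
                tsd_length=tsd,
                target_deletion=del_len,
                polyA_length=int(
                    rng.integers(polyA_range[0], polyA_range[1] + 1)
                ),
            )
            insert = inserted_sequence(spec, consensus_library)
            # unambiguous-junction checks (see docstring): the insert must
            # not continue the reference across either junction, and the
            # consensus base 5' of a truncation point must differ from the
            # adjacent target base (else the element/target boundary is
            # ambiguous to any consensus-guided caller)
            if insert[0] == ref[pos]:
                continue
            if insert[-1] == ref[pos + del_len - tsd - 1]:
                continue
            if del_len and any(
                ref[pos + k] == insert[-1] for k in range(del_len)
            ):
                continue
            trunc = spec.truncation_offset
            if trunc > 0:
                cons = consensus_library[fam]
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                if strand == "+":
                    flank_walk = ref[max(0, pos - trunc) : pos][::-1]
                    cons_walk = cons[:trunc][::-1]
                else:
                    start = pos + del_len - tsd
                    flank_walk = ref[start : start + trunc]
                    cons_walk = "".join(
                        comp[b] for b in cons[:trunc][::-1]
                    )
                score = best = 0
                for fb, cb in zip(flank_walk[:8], cons_walk[:8]):
                    score += 5 if fb == cb else -4
                    best = max(best, score)
                if best > 0:
                    # a consensus-guided local match would absorb flank
                    # bases into the element: junction is ambiguous
                    continue
            return spec
    return None


def write_truth_table(truth: List[dict], path) -> None:
    cols = [
        "chrom", "pos", "strand", "subfamily", "tsd_len", "target_del",
        "trunc_offset", "polyA_len", "insert_len", "dosage",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for rec in truth:
            fh.write(
                "\t".join(str(rec.get(c, "")) for c in cols) + "\n"
            )
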