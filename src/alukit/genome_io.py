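"""Genome, interval and repeat-annotation I/O.

All internal coordinates are 0-based half-open.  Conversions happen only at
format boundaries: RepeatMasker ``.out`` files are 1-based inclusive, BED is
already half-open.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

__all__ = [
    "FormatError",
    "GenomicInterval",
    "Genome",
    "RepeatCatalog",
    "read_fasta",
    "write_fasta",
    "read_repeat_annotations",
    "write_bed",
    "exclusion_mask",
    "extract_sequence",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open, stranded, labelled genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


class Genome:
    """Ordered map of sequence name to uppercase nucleotide string."""

    def __init__(self, sequences: Optional[Dict[str, str]] = None) -> None:
        self._seqs: Dict[str, str] = {}
        if sequences:
            for name, seq in sequences.items():
                self.add(name, seq)

    def add(self, name: str, seq: str) -> None:
        if name in self._seqs:
            raise ValueError(f"duplicate sequence name {name!r}")
        if not seq:
            raise ValueError(f"empty sequence for {name!r}")
        seq = seq.upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FormatError(
                f"non-IUPAC characters {sorted(bad)} in sequence {name!r}"
            )
        self._seqs[name] = seq

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __iter__(self):
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def names(self) -> List[str]:
        return list(self._seqs)

    def items(self):
        return self._seqs.items()

    def length(self, name: str) -> int:
        return len(self._seqs[name])

    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def __eq__(self, other) -> bool:
        return isinstance(other, Genome) and self._seqs == other._seqs


@dataclass
class RepeatCatalog:
    """A list of labelled repeat intervals, optionally validated vs a genome."""

    intervals: List[GenomicInterval] = field(default_factory=list)

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def validate(self, genome: Genome) -> None:
        for iv in self.intervals:
            if iv.chrom not in genome:
                raise ValueError(f"interval chrom {iv.chrom!r} not in genome")
            if iv.end > genome.length(iv.chrom):
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                    f"chromosome length {genome.length(iv.chrom)}"
                )

    def matching(self, family_prefix: str) -> "RepeatCatalog":
        """Case-insensitive prefix match on the interval label."""
        pref = family_prefix.lower()
        return RepeatCatalog(
            [iv for iv in self.intervals if iv.label.lower().startswith(pref)]
        )


def read_fasta(path) -> Genome:
    """Load a (possibly multi-record) FASTA file into a :class:`Genome`.

    Records are case-normalized to uppercase; record order is preserved.
    Malformed headers or non-IUPAC characters raise :class:`FormatError`
    naming the offending line.
    """
    genome = Genome()
    name = None
    chunks: List[str] = []
    opened = open(path) if not isinstance(path, io.TextIOBase) else path
    try:
        for lineno, raw in enumerate(opened, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    genome.add(name, "".join(chunks))
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"line {lineno}: empty FASTA header")
                name = header.split()[0]
                chunks = []
            else:
                if name is None:
                    raise FormatError(
                        f"line {lineno}: sequence data before first header"
                    )
                bad = set(line.upper()) - _VALID_BASES
                if bad:
                    raise FormatError(
                        f"line {lineno}: non-IUPAC characters {sorted(bad)}"
                    )
                chunks.append(line)
        if name is not None:
            genome.add(name, "".join(chunks))
    finally:
        if opened is not path:
            opened.close()
    return genome


def write_fasta(genome, path, width: int = 60) -> None:
    """Write sequences wrapped at ``width`` columns.

    Accepts a :class:`Genome` or any mapping of name to sequence.
    """
    items = genome.items() if hasattr(genome, "items") else genome
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _parse_bed_line(line: str, lineno: int) -> GenomicInterval:
    fields = line.split("\t")
    if len(fields) < 3:
        raise FormatError(f"line {lineno}: BED line has <3 fields")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise FormatError(f"line {lineno}: non-integer BED coordinate") from exc
    label = fields[3] if len(fields) > 3 else ""
    strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "+"
    return GenomicInterval(chrom, start, end, strand, label)


def _parse_repeatmasker_line(line: str, lineno: int) -> Optional[GenomicInterval]:
    fields = line.split()
    if not fields:
        return None
    # data rows start with the Smith-Waterman score (an integer)
    if not fields[0].isdigit():
        return None
    if len(fields) < 11:
        raise FormatError(f"line {lineno}: truncated RepeatMasker row")
    chrom = fields[4]
    begin, end = int(fields[5]), int(fields[6])
    strand = "-" if fields[8] == "C" else "+"
    label = fields[9]
    # 1-based inclusive -> 0-based half-open
    return GenomicInterval(chrom, begin - 1, end, strand, label)


def read_repeat_annotations(
    path, dialect: str = "bed", genome: Optional[Genome] = None
) -> RepeatCatalog:
    """Read repeat annotations in ``bed`` or ``repeatmasker_out`` dialect.

    RepeatMasker coordinates (1-based inclusive) are converted to the
    internal 0-based half-open convention; strand ``C`` maps to ``-``.
    When ``genome`` is supplied, intervals are validated against it.
    """
    if dialect not in ("bed", "repeatmasker_out"):
        raise ValueError(f"unknown dialect {dialect!r}")
    catalog = RepeatCatalog()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if dialect == "bed":
                if line.startswith(("track", "browser", "#")):
                    continue
                catalog.intervals.append(_parse_bed_line(line, lineno))
            else:
                iv = _parse_repeatmasker_line(line, lineno)
                if iv is not None:
                    catalog.intervals.append(iv)
    if genome is not None:
        catalog.validate(genome)
    return catalog


def write_bed(catalog: RepeatCatalog, path) -> None:
    with open(path, "w") as fh:
        for iv in catalog:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\t0\t{iv.strand}\n"
            )


def exclusion_mask(
    catalog: RepeatCatalog,
    family_filter: str,
    pad: int,
    genome: Optional[Genome] = None,
) -> RepeatCatalog:
    """Padded, merged mask of intervals whose label matches ``family_filter``.

    Each matching interval is expanded by ``pad`` on both sides, clipped to
    the chromosome bounds when a genome is supplied, and overlapping or
    adjacent intervals are merged.  Output intervals are sorted and pairwise
    disjoint.
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    padded = []
    for iv in catalog.matching(family_filter):
        start = max(0, iv.start - pad)
        end = iv.end + pad
        if genome is not None and iv.chrom in genome:
            end = min(end, genome.length(iv.chrom))
        padded.append((iv.chrom, start, end))
    padded.sort()
    merged: List[GenomicInterval] = []
    for chrom, start, end in padded:
        if merged and merged[-1].chrom == chrom and start <= merged[-1].end:
            prev = merged[-1]
            if end > prev.end:
                merged[-1] = replace(prev, end=end)
        else:
            merged.append(GenomicInterval(chrom, start, end, "+", family_filter))
    return RepeatCatalog(merged)


def in_mask(mask: RepeatCatalog, chrom: str, pos: int, pad: int = 0) -> bool:
    """True when ``pos`` falls within ``pad`` of any mask interval."""
    for iv in mask:
        if iv.chrom == chrom and iv.start - pad <= pos < iv.end + pad:
            return True
    return False


def extract_sequence(genome: Genome, interval: GenomicInterval) -> str:
    """Extract the interval sequence; reverse complement on the '-' strand."""
    if interval.chrom not in genome:
        raise KeyError(f"unknown chromosome {interval.chrom!r}")
    if interval.end > genome.length(interval.chrom):
        raise ValueError(
            f"interval {interval.chrom}:{interval.start}-{interval.end} "
            "out of bounds"
        )
    seq = genome[interval.chrom][interval.start : interval.end]
    if interval.strand == "-":
        seq = reverse_complement(seq)
    return seq
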