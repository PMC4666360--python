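"""Remapping-based genotyping of assembled insertion sites.

For each genotypable site a reference allele (600 bp of flank either side
of the TSD span) and an insertion allele (the same flanks around the
assembled insert, with the TSD duplicated or target bases deleted) are
reconstructed.  Read pairs originally mapped to the reference-allele
region with MAPQ >= 20 are realigned to both alleles; each pair's
assignment quality is treated as an error probability
(``e = 10^(-q/10)``), giving genotype likelihoods over alt-allele dosage.
Population allele frequencies are estimated by ploidy-aware EM under
Hardy-Weinberg equilibrium and combined with the likelihoods into
posterior genotype calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam
from Bio import Align

from .breakpoint import BreakpointCall
from .genome_io import Genome, reverse_complement

__all__ = [
    "AllelePair",
    "PairMapping",
    "GenotypeLikelihoods",
    "AlleleFrequencyEstimate",
    "GenotypeCall",
    "build_alleles",
    "extract_and_remap",
    "compute_gl",
    "em_allele_frequency",
    "call_genotypes",
    "concordance",
    "hwe_priors",
]

DEFAULT_FLANK = 600
DEFAULT_MAPQ_MIN = 20
MAX_Q = 60


@dataclass
class AllelePair:
    site_id: str
    ref_allele: str
    alt_allele: str
    ref_start: int  # genome coordinate of the first ref-allele base
    ref_end: int
    chrom: str = ""


@dataclass
class PairMapping:
    pair_id: str
    best: str  # 'ref', 'alt' or 'tie'
    quality: int  # Phred-scaled confidence; tie <=> 0


@dataclass
class GenotypeLikelihoods:
    site_id: str
    sample_id: str
    ploidy: int
    log_likelihoods: List[float]  # index = alt dosage 0..ploidy
    n_informative: int = 0

    def normalized(self) -> np.ndarray:
        arr = np.array(self.log_likelihoods, dtype=float)
        arr -= arr.max()
        p = np.exp(arr)
        return p / p.sum()


@dataclass
class AlleleFrequencyEstimate:
    site_id: str
    frequency: float
    iterations: int
    converged: bool
    loglik_trace: List[float] = field(default_factory=list)


@dataclass
class GenotypeCall:
    site_id: str
    sample_id: str
    dosage: int
    posteriors: List[float]
    frequency: float


def build_alleles(
    site_call: BreakpointCall,
    genome: Genome,
    flank: int = DEFAULT_FLANK,
    site_id: Optional[str] = None,
) -> AllelePair:
    """Reconstruct reference and insertion alleles around the TSD span.

    The insertion allele honours the breakpoint call: with an overlap the
    TSD bases appear on both sides of the insert; with a target-site
    deletion the deleted reference bases are absent.  Flanks extending past
    the chromosome are truncated.
    """
    chrom = site_call.chrom
    seq = genome[chrom]
    p = site_call.insertion_point
    tsd = len(site_call.tsd) if site_call.overlap_len > 0 else 0
    deletion = site_call.target_deletion
    tsd_start = p - tsd
    span_end = p + deletion
    lo = max(0, tsd_start - flank)
    hi = min(len(seq), span_end + flank)
    ref_allele = seq[lo:hi]
    alt_allele = (
        seq[lo:p] + site_call.insert_seq + seq[tsd_start : tsd_start + tsd]
        + seq[span_end:hi]
    )
    return AllelePair(
        site_id=site_id or f"{chrom}:{p}",
        ref_allele=ref_allele,
        alt_allele=alt_allele,
        ref_start=lo,
        ref_end=hi,
        chrom=chrom,
    )


def _score_aligner():
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _score_aligner()


def _mate_score(seq: str, allele: str) -> float:
    # exact-substring shortcut: the maximum local score under the +1/-1
    # scheme is the full read length, so an exact hit needs no DP
    if seq in allele:
        return float(len(seq))
    rc = reverse_complement(seq)
    if rc in allele:
        return float(len(seq))
    best = 0.0
    for s in (seq, rc):
        try:
            score = _ALIGNER.score(s, allele)
        except (OverflowError, MemoryError):  # pragma: no cover
            continue
        best = max(best, float(score))
    return best


def remap_pair(
    seq1: str, seq2: str, allele_pair: AllelePair, pair_id: str = ""
) -> PairMapping:
    """Score a read pair against both alleles.

    The pair score per allele is the sum of each mate's best local
    alignment score (either orientation); the assignment quality is a
    Phred-like ``q = min(60, 2 * score_gap)``.  Equal scores give a tie
    with q = 0.
    """
    ref_score = _mate_score(seq1, allele_pair.ref_allele) + _mate_score(
        seq2, allele_pair.ref_allele
    )
    alt_score = _mate_score(seq1, allele_pair.alt_allele) + _mate_score(
        seq2, allele_pair.alt_allele
    )
    gap = alt_score - ref_score
    if gap == 0:
        return PairMapping(pair_id, "tie", 0)
    q = int(min(MAX_Q, round(2 * abs(gap))))
    if q == 0:
        return PairMapping(pair_id, "tie", 0)
    return PairMapping(pair_id, "alt" if gap > 0 else "ref", q)


def extract_and_remap_batch(
    sam_path: str,
    allele_pairs: Sequence[AllelePair],
    mapq_min: int = DEFAULT_MAPQ_MIN,
) -> Dict[str, List[PairMapping]]:
    """Remap qualifying pairs for many sites in one streaming pass.

    Pairs qualify for a site when at least one read's original mapping
    falls within its reference-allele coordinates with MAPQ >=
    ``mapq_min``.
    """
    import bisect

    qualifying: Dict[str, set] = {ap.site_id: set() for ap in allele_pairs}
    by_chrom: Dict[str, List[Tuple[int, int, str]]] = {}
    for ap in allele_pairs:
        by_chrom.setdefault(ap.chrom, []).append(
            (ap.ref_start, ap.ref_end, ap.site_id)
        )
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    starts = {c: [iv[0] for iv in ivs] for c, ivs in by_chrom.items()}
    all_names: set = set()
    with pysam.AlignmentFile(sam_path, check_sq=False) as af:
        for rec in af:
            if rec.is_secondary or rec.is_supplementary or rec.is_unmapped:
                continue
            if rec.mapping_quality < mapq_min:
                continue
            ivs = by_chrom.get(rec.reference_name)
            if not ivs:
                continue
            start = rec.reference_start
            end = rec.reference_end or start + 1
            idx = bisect.bisect_right(starts[rec.reference_name], end) - 1
            # allele windows of neighbouring sites may abut: check a couple
            for k in (idx, idx - 1):
                if 0 <= k < len(ivs):
                    lo, hi, site_id = ivs[k]
                    if start < hi and end > lo:
                        qualifying[site_id].add(rec.query_name)
                        all_names.add(rec.query_name)
    seqs: Dict[str, Dict[int, str]] = {}
    with pysam.AlignmentFile(sam_path, check_sq=False) as af:
        for rec in af:
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.query_name in all_names and rec.query_sequence:
                seqs.setdefault(rec.query_name, {})[
                    1 if rec.is_read1 else 2
                ] = rec.query_sequence
    out: Dict[str, List[PairMapping]] = {}
    for ap in allele_pairs:
        mappings = []
        for name in sorted(qualifying[ap.site_id]):
            mates = seqs.get(name, {})
            if len(mates) != 2:
                continue
            mappings.append(remap_pair(mates[1], mates[2], ap, name))
        out[ap.site_id] = mappings
    return out


def extract_and_remap(
    sam_path: str,
    allele_pair: AllelePair,
    sample_id: str = "",
    mapq_min: int = DEFAULT_MAPQ_MIN,
) -> List[PairMapping]:
    """Single-site convenience wrapper around the batch extraction."""
    return extract_and_remap_batch(sam_path, [allele_pair], mapq_min)[
        allele_pair.site_id
    ]


def compute_gl(
    mappings: Sequence[PairMapping],
    ploidy: int,
    site_id: str = "",
    sample_id: str = "",
) -> GenotypeLikelihoods:
    """Genotype likelihoods over alt dosage from per-pair assignments.

    Per pair ``e = 10^(-q/10)``; ``P(pair|best allele) = 1 - e`` and
    ``P(pair|other) = e``; dosage mixes the two allele likelihoods in
    proportion ``d/ploidy``.  Tie pairs contribute equally to every dosage
    and are dropped.
    """
    if ploidy not in (1, 2):
        raise ValueError("ploidy must be 1 or 2")
    logL = [0.0] * (ploidy + 1)
    n_used = 0
    for pm in mappings:
        if pm.best == "tie" or pm.quality <= 0:
            continue
        n_used += 1
        e = 10 ** (-pm.quality / 10)
        p_alt = 1 - e if pm.best == "alt" else e
        p_ref = 1 - e if pm.best == "ref" else e
        for d in range(ploidy + 1):
            w = d / ploidy
            logL[d] += math.log(w * p_alt + (1 - w) * p_ref)
    return GenotypeLikelihoods(site_id, sample_id, ploidy, logL, n_used)


def hwe_priors(f: float, ploidy: int) -> np.ndarray:
    if ploidy == 1:
        return np.array([1 - f, f])
    return np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])


def _marginal_loglik(gls: Sequence[GenotypeLikelihoods], f: float) -> float:
    total = 0.0
    for gl in gls:
        pri = hwe_priors(f, gl.ploidy)
        arr = np.array(gl.log_likelihoods)
        mx = arr.max()
        total += mx + math.log(float((np.exp(arr - mx) * pri).sum()))
    return total


def em_allele_frequency(
    gls: Sequence[GenotypeLikelihoods],
    tol: float = 1e-6,
    max_iter: int = 100,
    site_id: str = "",
) -> AlleleFrequencyEstimate:
    """Ploidy-aware EM for the population alt-allele frequency under HWE.

    Starts at f = 0.5; E-step computes per-sample dosage posteriors with
    HWE priors, M-step sets f to the posterior-expected allele count over
    total ploidy.  The marginal log-likelihood trace is non-decreasing.
    """
    if not gls:
        raise ValueError("at least one sample is required")
    f = 0.5
    trace: List[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        trace.append(_marginal_loglik(gls, f))
        num = 0.0
        denom = 0
        for gl in gls:
            pri = hwe_priors(f, gl.ploidy)
            arr = np.array(gl.log_likelihoods)
            arr = arr - arr.max()
            post = np.exp(arr) * pri
            s = post.sum()
            if s > 0:
                post /= s
            else:
                post = np.full(gl.ploidy + 1, 1 / (gl.ploidy + 1))
            num += float((post * np.arange(gl.ploidy + 1)).sum())
            denom += gl.ploidy
        new_f = num / denom if denom else 0.5
        if abs(new_f - f) < tol:
            f = new_f
            converged = True
            break
        f = new_f
    trace.append(_marginal_loglik(gls, f))
    return AlleleFrequencyEstimate(site_id, f, iterations, converged, trace)


def call_genotypes(
    gls: Sequence[GenotypeLikelihoods], f: float
) -> List[GenotypeCall]:
    """Posterior genotype calls with HWE priors at frequency ``f``.

    Deterministic ties resolve to the lower dosage.
    """
    if not 0 <= f <= 1:
        raise ValueError("f must be in [0, 1]")
    calls = []
    for gl in gls:
        pri = hwe_priors(f, gl.ploidy)
        arr = np.array(gl.log_likelihoods)
        arr = arr - arr.max()
        post = np.exp(arr) * pri
        s = post.sum()
        post = post / s if s > 0 else np.full_like(post, 1 / len(post))
        best = int(np.argmax(post))  # first max -> lower dosage on ties
        calls.append(
            GenotypeCall(gl.site_id, gl.sample_id, best, post.tolist(), f)
        )
    return calls


def concordance(
    calls: Dict[Tuple[str, str], int], truth: Dict[Tuple[str, str], int]
) -> float:
    """Fraction of matching genotypes over shared (site, sample) keys."""
    shared = set(calls) & set(truth)
    if not shared:
        raise ValueError("call and truth sets share no keys")
    matching = sum(1 for k in shared if calls[k] == truth[k])
    return matching / len(shared)
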