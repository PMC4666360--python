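"""Stage orchestration: simulate -> discover -> assemble -> breakpoint ->
classify -> genotype -> evaluate, with file-based artifacts between stages.

Every artifact carries a provenance header (version, config hash, seed);
reruns with unchanged inputs and seed produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

from . import __version__
from .breakpoint import BreakpointCall, call_site
from .classify import assign_subfamily, build_profile, measure_truncation
from .discovery import CandidateSite, discover
from .evaluate import CallSet, cohort_stats, performance_metrics
from .genome_io import (
    Genome,
    RepeatCatalog,
    exclusion_mask,
    write_bed,
    write_fasta,
)
from .genotype import (
    build_alleles,
    call_genotypes,
    compute_gl,
    em_allele_frequency,
    extract_and_remap_batch,
)
from .local_assembly import (
    assemble,
    collect_reads_batch,
    filter_assembly,
    scaffold_contigs,
)
from .simulate import (
    build_ppm,
    default_consensus_library,
    default_nic_sites,
    implant_insertions,
    random_genome,
    sample_implant_cohort,
    simulate_paired_reads,
    write_truth_table,
)

log = logging.getLogger(__name__)

# stage parameter defaults; every numeric threshold follows the published
# pipeline settings
DEFAULTS: Dict[str, object] = {
    "collect_window": 200,  # read-collection window around the breakpoint
    "exclusion_pad": 500,  # distance to annotated reference Alus
    "min_reads": 2,  # minimum supporting read pairs per call
    "max_depth": 1000,  # local read-depth cap
    "clip_min_len": 20,  # soft-clip length floor
    "clip_min_qual": 20.0,  # soft-clip mean quality floor
    "alu_match_min_bp": 30,  # assembly filter: Alu match length
    "alu_match_min_identity": 0.90,  # assembly filter: match identity
    "flank_min_bp": 30,  # assembly filter: non-gap flank
    "genotypable_flank": 100,  # non-gap flank for genotypable calls
    "allele_flank": 600,  # allele reconstruction flank
    "mapq_min": 20,  # genotyping read-extraction MAPQ
    "anchor_mapq_min": 20,  # discovery anchor MAPQ
    "spacer_len": 300,  # scaffold N-spacer length
    "intersect_window": 100,  # call-set comparison window
    "support_levels": (6, 7, 8),  # emitted support levels
}


def config_hash(config: Dict[str, object]) -> str:
    blob = json.dumps(
        {k: v for k, v in sorted(config.items())}, default=str
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(seed: int, config: Dict[str, object]) -> str:
    return (
        f"#alukit {__version__} seed={seed} config={config_hash(config)}\n"
    )


@dataclass
class SimulationArtifacts:
    genome: Genome
    catalog: RepeatCatalog
    mask: RepeatCatalog
    library: Dict[str, str]
    truth: List[dict]
    sam_path: str
    genome_path: str


@dataclass
class SiteResult:
    site: CandidateSite
    call: Optional[BreakpointCall]
    passed_filter: bool
    subfamily: str = ""
    divergence: float = float("nan")
    truncation_start: int = 0
    truncation_bin: str = ""
    genotype: Optional[int] = None
    allele_frequency: float = float("nan")


def simulate_stage(
    outdir: str,
    seed: int,
    genome_size: int = 2_000_000,
    n_implants: int = 50,
    n_reference_alus: int = 40,
    coverage: float = 30.0,
    read_len: int = 100,
    frag_mean: float = 300.0,
    frag_sd: float = 30.0,
    error_rate: float = 0.0,
    write_fastq: bool = False,
    **cohort_kwargs,
) -> SimulationArtifacts:
    """Generate the full synthetic input set for one homozygous sample."""
    os.makedirs(outdir, exist_ok=True)
    library = default_consensus_library()
    genome, catalog = random_genome(
        {"chr1": genome_size},
        seed=seed,
        n_reference_alus=n_reference_alus,
        consensus_library=library,
    )
    mask = exclusion_mask(
        catalog, "Alu", int(DEFAULTS["exclusion_pad"]), genome
    )
    ppm = build_ppm(default_nic_sites(), pseudocount=1)
    specs = sample_implant_cohort(
        genome, ppm, n_implants, library, mask=mask, seed=seed + 1,
        **cohort_kwargs,
    )
    hap, truth = implant_insertions(genome, specs, library)
    reads = simulate_paired_reads(
        [hap],
        coverage=coverage,
        read_len=read_len,
        frag_mean=frag_mean,
        frag_sd=frag_sd,
        error_rate=error_rate,
        seed=seed + 2,
    )
    genome_path = os.path.join(outdir, "genome.fa")
    sam_path = os.path.join(outdir, "reads.sam")
    write_fasta(genome, genome_path)
    write_fasta(library, os.path.join(outdir, "alu_library.fa"))
    write_bed(catalog, os.path.join(outdir, "reference_alus.bed"))
    write_truth_table(truth, os.path.join(outdir, "truth.tsv"))
    reads.write_sam(sam_path, genome)
    if write_fastq:
        reads.write_fastq(
            os.path.join(outdir, "reads_1.fastq"),
            os.path.join(outdir, "reads_2.fastq"),
        )
    return SimulationArtifacts(
        genome, catalog, mask, library, truth, sam_path, genome_path
    )


def run_end_to_end(
    outdir: str,
    seed: int = 1,
    genome_size: int = 2_000_000,
    n_implants: int = 50,
    coverage: float = 30.0,
    frag_mean: float = 300.0,
    frag_sd: float = 30.0,
    samples: int = 1,
    **sim_kwargs,
) -> Dict[str, object]:
    """Full pipeline on a fresh synthetic cohort; returns all stage outputs."""
    sim = simulate_stage(
        outdir,
        seed,
        genome_size=genome_size,
        n_implants=n_implants,
        coverage=coverage,
        frag_mean=frag_mean,
        frag_sd=frag_sd,
        **sim_kwargs,
    )
    sites, _ = discover(
        [sim.sam_path],
        sim.library,
        sim.catalog,
        sim.mask,
        fragment_mean=frag_mean,
        fragment_sd=frag_sd,
        anchor_mapq_min=int(DEFAULTS["anchor_mapq_min"]),
        min_reads=int(DEFAULTS["min_reads"]),
        max_depth=int(DEFAULTS["max_depth"]),
    )
    log.info("discovery: %d candidate sites", len(sites))
    readsets = collect_reads_batch(
        sites, sim.sam_path, window=int(DEFAULTS["collect_window"])
    )
    profile = build_profile(sim.library)
    results: List[SiteResult] = []
    gls = []
    for site in sites:
        key = f"{site.chrom}:{site.pos}"
        readset = readsets[key]
        if not readset.reads:
            results.append(SiteResult(site, None, False))
            continue
        contigs = assemble(readset.reads)
        if not contigs:
            results.append(SiteResult(site, None, False))
            continue
        scaffolds = scaffold_contigs(contigs, readset.pairs)
        filt = filter_assembly(scaffolds[0], sim.library)
        if not filt.passed:
            results.append(SiteResult(site, None, False))
            continue
        call = call_site(
            filt.scaffold.seq, sim.genome, site.chrom, site.pos, sim.library
        )
        if call is None:
            results.append(SiteResult(site, None, True))
            continue
        res = SiteResult(site, call, True)
        sub = assign_subfamily(call.insert_seq, profile, key)
        res.subfamily = sub.subfamily
        res.divergence = sub.divergence
        if sub.subfamily != "unclassified":
            trunc = measure_truncation(
                call.insert_seq
                if call.element_strand == "+"
                else _revcomp(call.insert_seq),
                sim.library[sub.subfamily],
            )
            res.truncation_start = trunc.consensus_start
            res.truncation_bin = trunc.bin
        results.append(res)

    # genotyping: one batched extraction pass over the alignments
    genotypable = [
        r for r in results if r.call is not None and r.call.genotypable
    ]
    alleles = [
        build_alleles(
            r.call,
            sim.genome,
            flank=int(DEFAULTS["allele_flank"]),
            site_id=f"{r.site.chrom}:{r.site.pos}",
        )
        for r in genotypable
    ]
    mapping_sets = extract_and_remap_batch(
        sim.sam_path, alleles, mapq_min=int(DEFAULTS["mapq_min"])
    )
    for r, ap in zip(genotypable, alleles):
        gl = compute_gl(
            mapping_sets[ap.site_id], ploidy=2, site_id=ap.site_id,
            sample_id="S1",
        )
        gls.append(gl)
        est = em_allele_frequency([gl], site_id=ap.site_id)
        gcall = call_genotypes([gl], est.frequency)[0]
        r.genotype = gcall.dosage
        r.allele_frequency = est.frequency

    called = [r for r in results if r.call is not None]
    predicted = CallSet(
        "called", [(r.call.chrom, r.call.insertion_point) for r in called]
    )
    truth_set = CallSet(
        "truth", [(t["chrom"], t["pos"]) for t in sim.truth]
    )
    metrics = (
        performance_metrics(
            predicted, truth_set, window=int(DEFAULTS["intersect_window"])
        )
        if called
        else None
    )
    stats = cohort_stats([r.call for r in called]) if called else None
    _write_site_table(outdir, seed, results)
    return {
        "simulation": sim,
        "sites": sites,
        "results": results,
        "metrics": metrics,
        "cohort_stats": stats,
        "genotype_likelihoods": gls,
    }


def _revcomp(seq: str) -> str:
    from .genome_io import reverse_complement

    return reverse_complement(seq)


def _write_site_table(
    outdir: str, seed: int, results: Sequence[SiteResult]
) -> None:
    path = os.path.join(outdir, "calls.tsv")
    cols = [
        "chrom", "pos", "support_level", "n_pairs", "insertion_point",
        "tsd", "overlap_len", "target_del", "strand", "subfamily",
        "divergence", "trunc_start", "trunc_bin", "genotypable", "genotype",
    ]
    with open(path, "w") as fh:
        fh.write(provenance_header(seed, DEFAULTS))
        fh.write("\t".join(cols) + "\n")
        for r in results:
            c = r.call
            row = [
                r.site.chrom, r.site.pos, r.site.support_level,
                r.site.n_pairs,
                c.insertion_point if c else "",
                c.tsd if c else "",
                c.overlap_len if c else "",
                c.target_deletion if c else "",
                c.element_strand if c else "",
                r.subfamily,
                f"{r.divergence:.4f}" if r.divergence == r.divergence else "",
                r.truncation_start or "",
                r.truncation_bin,
                int(c.genotypable) if c else "",
                r.genotype if r.genotype is not None else "",
            ]
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_vcf(
    path: str,
    results: Sequence[SiteResult],
    genome: Genome,
    sample_id: str = "S1",
    seed: int = 0,
) -> None:
    """Minimal VCF 4.2 with symbolic ALT records for called insertions."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=alukit{__version__}\n")
        for name in genome:
            fh.write(f"##contig=<ID={name},length={genome.length(name)}>\n")
        fh.write(
            '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description='
            '"Insertion length">\n'
            '##INFO=<ID=TSD,Number=1,Type=String,Description='
            '"Target site duplication">\n'
            '##INFO=<ID=SUBFAMILY,Number=1,Type=String,Description='
            '"Assigned subfamily">\n'
            '##INFO=<ID=AF,Number=1,Type=Float,Description='
            '"EM allele frequency">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description='
            '"Informative pairs">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample_id}\n"
        )
        for r in results:
            if r.call is None:
                continue
            c = r.call
            pos1 = c.insertion_point  # 0-based insertion point -> 1-based ref base before it
            ref_base = genome[c.chrom][max(0, pos1 - 1)]
            info = (
                f"SVLEN={len(c.insert_seq)};TSD={c.tsd or '.'};"
                f"SUBFAMILY={r.subfamily or '.'}"
            )
            if r.allele_frequency == r.allele_frequency:
                info += f";AF={r.allele_frequency:.4f}"
            gt = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}[r.genotype]
            fh.write(
                f"{c.chrom}\t{pos1}\t.\t{ref_base}\t<INS:ME:ALU>\t.\tPASS\t"
                f"{info}\tGT\t{gt}\n"
            )
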