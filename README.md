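# alukit

Discovery, local assembly, breakpoint resolution, subfamily classification
and genotyping of non-reference Alu insertions from paired-end short-read
data — plus a synthetic-data generator that makes every stage testable at
desk scale.

The pipeline follows the classic anchored-read-pair strategy: discordant
pairs whose floating mate matches an Alu consensus are clustered into
candidate loci, supporting reads are assembled with a greedy
overlap-layout-consensus assembler, breakpoints and candidate target site
duplications (TSDs) are resolved by a three-way alignment scoring scheme
(+1 own-side match / −1 mismatch / −3 other-side match cumulative tracks),
elements are assigned to subfamilies by divergence against a consensus
profile alignment, and genotypes are called by remapping read pairs to
reconstructed reference/insertion alleles with MAPQ-as-error-probability
likelihoods and ploidy-aware EM allele-frequency estimation under
Hardy–Weinberg equilibrium.

The simulator provides the complementary truth machinery: random genomes
with annotated "reference Alu" intervals, an L1-endonuclease nic-site
position probability matrix with rejection sampling of insertion sites,
implanted insertions carrying TSDs, poly-A tails, 5′ truncations and
target-site deletions, and paired-end reads with truth-projected SAM
alignments (junction reads soft-clipped, element-internal mates unmapped).

## Command line

```sh
# synthetic inputs: genome.fa, reference_alus.bed, alu_library.fa,
# reads.sam (+ FASTQ), truth.tsv
alukit simulate --out sim/ --seed 1 --genome-size 2000000 \
    --n-implants 50 --coverage 30 --fastq

# candidate discovery from a coordinate-sorted SAM/BAM
alukit discover --bam sim/reads.sam --alu-lib sim/alu_library.fa \
    --mask sim/reference_alus.bed --min-reads 2 --max-depth 1000 \
    --pad 500 --out sites.tsv

# composite pipeline (simulate -> discover -> assemble -> breakpoint ->
# classify -> genotype -> evaluate); writes calls.tsv, calls.vcf,
# summary.json
alukit run --out run/ --seed 1
alukit run --out run/ --config pipeline.yaml   # YAML overrides

# window-intersection benchmarking of two call sets
alukit evaluate --pred calls.tsv --truth truth.tsv --window 100
```

Stage defaults (collection window 200 bp, 500 bp reference-Alu exclusion,
min 2 supporting pairs, depth cap 1000, ≥20 bp / Q20 soft clips, ≥30 bp /
90% identity Alu match, ≥30 bp assembled flank, 100 bp genotypable-flank
rule, 600 bp allele flanks, MAPQ ≥ 20, 300-N scaffold spacers, 100 bp
intersection window) live in `alukit.pipeline.DEFAULTS` and are audited by
the test suite.

## Layout

```
src/alukit/
  genome_io.py       FASTA / BED / RepeatMasker I/O, intervals, masks
  alignment.py       affine-gap global aligner + local consensus matching
  simulate.py        PPM + rejection sampler, implants, read simulation
  discovery.py       discordant-pair discovery, clustering, locus filters
  local_assembly.py  read collection, greedy OLC assembly, scaffolding
  breakpoint.py      three-way alignment scoring, TSD refinement
  classify.py        profile alignment, subfamily/truncation/microhomology
  genotype.py        allele reconstruction, GLs, EM, posterior calls
  evaluate.py        window intersection, performance metrics
  pipeline.py        stage orchestration and artifacts
  cli.py             click entry points
```
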