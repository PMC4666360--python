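import numpy as np
import pytest
from scipy import stats

from alukit.genome_io import Genome, GenomicInterval, RepeatCatalog, reverse_complement
from alukit.simulate import (
    Haplotype,
    ImplantSpec,
    build_ppm,
    default_consensus_library,
    default_nic_sites,
    implant_insertions,
    nic_window,
    random_genome,
    sample_implant_cohort,
    sample_insertion_sites,
    simulate_paired_reads,
    site_probability,
)


class TestBuildPPM:
    def test_uniform(self):
        ppm = build_ppm(["A", "C", "G", "T"], pseudocount=0)
        assert ppm.width == 1
        assert np.allclose(ppm.probs, 0.25)

    def test_pseudocount_hand_count(self):
        ppm = build_ppm(["A", "A"], pseudocount=1)
        assert ppm.prob(0, "A") == pytest.approx(3 / 6)
        for b in "CGT":
            assert ppm.prob(0, b) == pytest.approx(1 / 6)

    def test_99_sites_min_prob(self):
        sites = ["TTTTA"] * 99  # C unobserved everywhere
        ppm = build_ppm(sites, pseudocount=1)
        assert ppm.width == 5
        assert np.allclose(ppm.probs.sum(axis=1), 1.0)
        assert ppm.prob(0, "C") == pytest.approx(1 / 103)

    def test_ragged_input_rejected(self):
        with pytest.raises(ValueError):
            build_ppm(["AA", "A"], 1)

    def test_empty_with_zero_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            build_ppm([], 0)

    def test_monotonicity(self):
        base = ["ACGTA"] * 10
        p0 = build_ppm(base, 1).prob(2, "G")
        p1 = build_ppm(base + ["ACGTA"], 1).prob(2, "G")
        assert p1 > p0


class TestSiteProbability:
    def test_uniform_window(self):
        ppm = build_ppm(["A", "C", "G", "T"], 0)
        ppm5 = build_ppm(["ACGTA", "CGTAC", "GTACG", "TACGT"], 1)
        uniform = build_ppm(
            ["AAAAA", "CCCCC", "GGGGG", "TTTTT"], 0
        )
        assert site_probability(uniform, "ACGTA") == pytest.approx(0.25**5)

    def test_window_with_n_is_zero(self):
        uniform = build_ppm(["AAAAA", "CCCCC", "GGGGG", "TTTTT"], 0)
        assert site_probability(uniform, "ACGNA") == 0.0

    def test_hand_product(self):
        ppm = build_ppm(["AA", "AC"], 0)
        assert site_probability(ppm, "AC", "+") == pytest.approx(1.0 * 0.5)

    def test_minus_strand_reverse_complements(self):
        ppm = build_ppm(["AA", "AC"], 0)
        # '-' scores the reverse complement: revcomp("GT") == "AC"
        assert site_probability(ppm, "GT", "-") == pytest.approx(0.5)

    def test_length_mismatch(self):
        ppm = build_ppm(["AA"], 1)
        with pytest.raises(ValueError):
            site_probability(ppm, "AAA")


class TestSampler:
    def test_count_and_strand_ratio(self):
        genome, _ = random_genome({"chr1": 50_000}, seed=0)
        uniform = build_ppm(["AAAAA", "CCCCC", "GGGGG", "TTTTT"], 0)
        sites = sample_insertion_sites(genome, uniform, 100, seed=3)
        assert len(sites) == 100
        n_plus = sum(1 for _, _, s in sites if s == "+")
        # binomial 99% CI around 0.5 for n=100
        assert 37 <= n_plus <= 63

    def test_mask_covering_genome_hits_attempt_cap(self):
        genome, _ = random_genome({"chr1": 5_000}, seed=0)
        mask = RepeatCatalog([GenomicInterval("chr1", 0, 5_000)])
        ppm = build_ppm(default_nic_sites(), 1)
        with pytest.raises(RuntimeError):
            sample_insertion_sites(
                genome, ppm, 3, mask=mask, seed=1, attempt_cap=1000
            )

    def test_unique_deterministic_motif(self):
        # probability 1 on a unique 5-mer: all sites land on it
        rng = np.random.default_rng(5)
        seq = "".join("CG"[i] for i in rng.integers(0, 2, 3000))
        seq = seq[:1500] + "AATTA" + seq[1500:]
        genome = Genome({"chr1": seq})
        ppm = build_ppm(["AATTA"], 0)
        sites = sample_insertion_sites(genome, ppm, 20, seed=2)
        positions = {(c, p) for c, p, _ in sites}
        for chrom, pos, strand in sites:
            win = nic_window(genome, chrom, pos, strand)
            assert win == "AATTA"
        assert len(positions) <= 2  # one placement per strand

    def test_mask_never_sampled(self):
        genome, _ = random_genome({"chr1": 30_000}, seed=1)
        mask = RepeatCatalog(
            [GenomicInterval("chr1", 8_000, 12_000),
             GenomicInterval("chr1", 20_000, 21_000)]
        )
        uniform = build_ppm(["AAAAA", "CCCCC", "GGGGG", "TTTTT"], 0)
        sites = sample_insertion_sites(
            genome, uniform, 10_000, mask=mask, seed=9
        )
        for _, pos, _ in sites:
            assert not (8_000 <= pos < 12_000)
            assert not (20_000 <= pos < 21_000)

    def test_reproducible_under_seed(self):
        genome, _ = random_genome({"chr1": 20_000}, seed=1)
        ppm = build_ppm(default_nic_sites(), 1)
        a = sample_insertion_sites(genome, ppm, 50, seed=4)
        b = sample_insertion_sites(genome, ppm, 50, seed=4)
        assert a == b


class TestImplants:
    def test_hand_construction_with_tsd(self):
        g = Genome({"chr1": "AAAACCCCGGGG"})
        spec = ImplantSpec(
            "chr1", 8, "X", tsd_length=4, polyA_length=0
        )
        hap, truth = implant_insertions(
            g, [spec], {"X": "TTTT"}, min_separation=1
        )
        assert hap.genome["chr1"] == "AAAACCCC" + "TTTT" + "CCCC" + "GGGG"
        assert truth[0]["tsd_seq"] == "CCCC"

    def test_blunt_insertion_length(self):
        g = Genome({"chr1": "A" * 100})
        spec = ImplantSpec("chr1", 50, "X", polyA_length=0)
        hap, _ = implant_insertions(g, [spec], {"X": "CGCG"})
        assert hap.genome.length("chr1") == 104

    def test_target_deletion_arithmetic(self):
        g = Genome({"chr1": "ACGT" * 25})
        spec = ImplantSpec(
            "chr1", 40, "X", target_deletion=3, polyA_length=0
        )
        hap, _ = implant_insertions(g, [spec], {"X": "GGGG"})
        assert hap.genome.length("chr1") == 100 - 3 + 4

    def test_minus_strand_reverse_complement(self):
        g = Genome({"chr1": "ACGT" * 25})
        spec = ImplantSpec(
            "chr1", 40, "X", strand="-", polyA_length=2
        )
        hap, truth = implant_insertions(g, [spec], {"X": "AACC"})
        inserted = hap.genome["chr1"][40 : 40 + 6]
        assert inserted == reverse_complement("AACC" + "AA")

    def test_tsd_round_trip_identity(self, library, ppm):
        genome, _ = random_genome({"chr1": 80_000}, seed=2)
        specs = sample_implant_cohort(
            genome, ppm, 5, library, seed=3, blunt_fraction=0,
            deletion_fraction=0,
        )
        hap, truth = implant_insertions(genome, specs, library)
        for t in truth:
            dup = genome[t["chrom"]][t["pos"] - t["tsd_len"] : t["pos"]]
            assert dup == t["tsd_seq"]
            hap_dup = hap.genome[t["chrom"]][
                t["alt_end"] - t["tsd_len"] : t["alt_end"]
            ]
            assert hap_dup == dup

    def test_overlapping_specs_rejected(self):
        g = Genome({"chr1": "A" * 1000})
        specs = [
            ImplantSpec("chr1", 100, "X"),
            ImplantSpec("chr1", 120, "X"),
        ]
        with pytest.raises(ValueError):
            implant_insertions(g, specs, {"X": "CCCC"})

    def test_truncation_exceeds_element_rejected(self):
        g = Genome({"chr1": "A" * 1000})
        spec = ImplantSpec("chr1", 100, "X", truncation_offset=10)
        with pytest.raises(ValueError):
            implant_insertions(g, [spec], {"X": "CCCC"})


class TestReadSimulation:
    def test_expected_pair_count(self):
        genome, _ = random_genome({"chr1": 10_000}, seed=3)
        hap = Haplotype.from_reference(genome)
        reads = simulate_paired_reads(
            [hap], coverage=30, read_len=100, frag_mean=300, seed=1
        )
        expect = 30 * 10_000 / (2 * 100)
        sd = np.sqrt(expect)
        assert abs(len(reads.pairs) - expect) <= 5 * sd

    def test_error_free_reads_are_substrings(self):
        genome, _ = random_genome({"chr1": 8_000}, seed=4)
        hap = Haplotype.from_reference(genome)
        reads = simulate_paired_reads([hap], coverage=5, seed=2)
        for pair in reads.pairs:
            assert pair.r1.seq in genome["chr1"]
            assert pair.r2.seq in genome["chr1"]

    def test_fastq_byte_identical_under_seed(self, tmp_path):
        genome, _ = random_genome({"chr1": 8_000}, seed=4)
        hap = Haplotype.from_reference(genome)
        for tag in ("a", "b"):
            reads = simulate_paired_reads([hap], coverage=5, seed=2)
            reads.write_fastq(
                tmp_path / f"{tag}_1.fq", tmp_path / f"{tag}_2.fq"
            )
        assert (tmp_path / "a_1.fq").read_bytes() == (
            tmp_path / "b_1.fq"
        ).read_bytes()
        assert (tmp_path / "a_2.fq").read_bytes() == (
            tmp_path / "b_2.fq"
        ).read_bytes()

    def test_error_rate_introduces_mismatches(self):
        genome, _ = random_genome({"chr1": 8_000}, seed=4)
        hap = Haplotype.from_reference(genome)
        reads = simulate_paired_reads(
            [hap], coverage=5, seed=2, error_rate=0.05
        )
        mismatched = sum(
            1
            for p in reads.pairs
            if p.r1.seq not in genome["chr1"]
        )
        assert mismatched > len(reads.pairs) / 2

    def test_junction_reads_soft_clipped(self, small_dataset):
        reads = small_dataset["reads"]
        clipped = [
            r
            for p in reads.pairs
            for r in (p.r1, p.r2)
            if r.mapped and "S" in r.cigar
        ]
        unmapped = [
            r for p in reads.pairs for r in (p.r1, p.r2) if not r.mapped
        ]
        assert clipped and unmapped


class TestAcceptanceFrequencies:
    def test_chi_square_goodness_of_fit(self):
        """Empirical acceptance frequencies track the PPM-implied law."""
        genome, _ = random_genome({"chr1": 60_000}, seed=6)
        ppm = build_ppm(default_nic_sites(), 1)
        n = 10_000
        sites = sample_insertion_sites(genome, ppm, n, seed=8)
        observed = {}
        for chrom, pos, strand in sites:
            w = nic_window(genome, chrom, pos, strand)
            observed[w] = observed.get(w, 0) + 1
        # expected proportions: genome-wide sum of P per 5-mer; a '+'
        # draw at p scores seq[p-4:p+1], a '-' draw its reverse complement
        seq = genome["chr1"]
        counts = {}
        for i in range(0, len(seq) - 4):
            pos = i + 4
            if not (4 <= pos <= len(seq) - 5):
                continue
            w = seq[i : i + 5]
            counts[w] = counts.get(w, 0) + 1
        expected_mass = {}
        for w, c in counts.items():
            expected_mass[w] = expected_mass.get(w, 0.0) + c * site_probability(ppm, w)
            rc = reverse_complement(w)
            expected_mass[rc] = expected_mass.get(rc, 0.0) + c * site_probability(ppm, rc)
        total = sum(expected_mass.values())
        obs, exp = [], []
        rare_obs = rare_exp = 0.0
        for w, mass in expected_mass.items():
            e = n * mass / total
            o = observed.get(w, 0)
            if e >= 5:
                obs.append(o)
                exp.append(e)
            else:
                rare_obs += o
                rare_exp += e
        if rare_exp > 0:
            obs.append(rare_obs)
            exp.append(rare_exp)
        obs = np.array(obs, dtype=float)
        exp = np.array(exp, dtype=float)
        exp *= obs.sum() / exp.sum()
        chi2 = ((obs - exp) ** 2 / exp).sum()
        pval = stats.chi2.sf(chi2, df=len(obs) - 1)
        assert pval > 0.01
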