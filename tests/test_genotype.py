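import math

import numpy as np
import pytest

from alukit.breakpoint import BreakpointCall
from alukit.genome_io import Genome
from alukit.genotype import (
    GenotypeLikelihoods,
    PairMapping,
    build_alleles,
    call_genotypes,
    compute_gl,
    concordance,
    em_allele_frequency,
    extract_and_remap_batch,
    hwe_priors,
    remap_pair,
)
from alukit.genotype import _marginal_loglik


def _template(n, seed=0):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _call(chrom="chr1", p=2_000, tsd="", deletion=0, insert="X" * 0):
    return BreakpointCall(
        chrom=chrom,
        left_bp=p - 1,
        right_bp=p - len(tsd) if tsd else p + deletion,
        overlap_len=len(tsd),
        tsd=tsd,
        target_deletion=deletion,
        insert_seq=insert,
        genotypable=True,
    )


@pytest.fixture(scope="module")
def genome():
    return Genome({"chr1": _template(5_000, seed=1)})


class TestBuildAlleles:

    def test_blunt_lengths(self, genome):
        insert = _template(300, seed=2)
        ap = build_alleles(_call(insert=insert), genome)
        assert len(ap.alt_allele) == len(ap.ref_allele) + 300

    def test_tsd_appears_twice(self, genome):
        p = 2_000
        tsd = genome["chr1"][p - 14 : p]
        insert = _template(300, seed=3)
        ap = build_alleles(_call(p=p, tsd=tsd, insert=insert), genome)
        assert len(ap.alt_allele) == len(ap.ref_allele) + 300 + 14
        assert ap.alt_allele.count(tsd + insert[:20]) == 1
        core = ap.alt_allele[
            len(ap.alt_allele) // 2 - 400 : len(ap.alt_allele) // 2 + 400
        ]
        assert ap.alt_allele.count(tsd) >= 2

    def test_target_deletion_lengths(self, genome):
        insert = _template(300, seed=4)
        ap = build_alleles(_call(deletion=3, insert=insert), genome)
        assert len(ap.alt_allele) == len(ap.ref_allele) - 3 + 300

    def test_flanks_shared_with_genome(self, genome):
        insert = _template(300, seed=5)
        ap = build_alleles(_call(insert=insert), genome)
        assert ap.ref_allele[:600] == ap.alt_allele[:600]
        assert ap.ref_allele[-600:] == ap.alt_allele[-600:]
        assert genome["chr1"][ap.ref_start : ap.ref_end] == ap.ref_allele

    def test_chromosome_edge_truncated(self, genome):
        insert = _template(100, seed=6)
        ap = build_alleles(_call(p=100, insert=insert), genome)
        assert ap.ref_start == 0


class TestRemapPair:
    def test_junction_pair_prefers_alt(self):
        ref = _template(1_000, seed=7)
        insert = _template(320, seed=8)
        alt = ref[:500] + insert + ref[500:]
        from alukit.genotype import AllelePair

        ap = AllelePair("s", ref, alt, 0, 1_000, "chr1")
        r1 = alt[450:550]  # spans the alt junction
        r2 = alt[700:800]
        pm = remap_pair(r1, r2, ap)
        assert pm.best == "alt" and pm.quality > 0

    def test_flank_pair_is_tie(self):
        ref = _template(1_000, seed=9)
        alt = ref[:500] + _template(320, seed=10) + ref[500:]
        from alukit.genotype import AllelePair

        ap = AllelePair("s", ref, alt, 0, 1_000, "chr1")
        pm = remap_pair(ref[100:200], ref[250:350], ap)
        assert pm.best == "tie" and pm.quality == 0

    def test_reference_junction_pair_prefers_ref(self):
        ref = _template(1_000, seed=11)
        alt = ref[:500] + _template(320, seed=12) + ref[500:]
        from alukit.genotype import AllelePair

        ap = AllelePair("s", ref, alt, 0, 1_000, "chr1")
        pm = remap_pair(ref[450:550], ref[600:700], ap)
        assert pm.best == "ref" and pm.quality > 0


class TestComputeGL:
    def test_single_alt_pair_closed_form(self):
        gl = compute_gl([PairMapping("p", "alt", 30)], 2)
        L = np.exp(gl.log_likelihoods)
        assert L[0] == pytest.approx(0.001)
        assert L[1] == pytest.approx(0.5)
        assert L[2] == pytest.approx(0.999)

    def test_no_informative_pairs_flat(self):
        gl = compute_gl([PairMapping("p", "tie", 0)], 2)
        assert gl.log_likelihoods == [0.0, 0.0, 0.0]
        assert gl.n_informative == 0

    def test_balanced_pairs_argmax_het(self):
        ms = [PairMapping(f"r{i}", "ref", 30) for i in range(5)] + [
            PairMapping(f"a{i}", "alt", 30) for i in range(5)
        ]
        gl = compute_gl(ms, 2)
        assert int(np.argmax(gl.log_likelihoods)) == 1

    def test_permutation_invariance(self):
        ms = [
            PairMapping("a", "alt", 25),
            PairMapping("b", "ref", 40),
            PairMapping("c", "alt", 12),
        ]
        gl1 = compute_gl(ms, 2)
        gl2 = compute_gl(ms[::-1], 2)
        assert gl1.log_likelihoods == pytest.approx(gl2.log_likelihoods)

    def test_doubling_doubles_log(self):
        ms = [PairMapping("a", "alt", 25), PairMapping("b", "ref", 40)]
        gl1 = compute_gl(ms, 2)
        gl2 = compute_gl(ms + ms, 2)
        assert gl2.log_likelihoods == pytest.approx(
            [2 * x for x in gl1.log_likelihoods]
        )

    def test_invalid_ploidy(self):
        with pytest.raises(ValueError):
            compute_gl([], 3)


class TestEM:
    def test_symmetric_certain_samples(self):
        g0 = GenotypeLikelihoods("s", "a", 2, [0.0, -60.0, -120.0])
        g2 = GenotypeLikelihoods("s", "b", 2, [-120.0, -60.0, 0.0])
        est = em_allele_frequency([g0, g2])
        assert est.frequency == pytest.approx(0.5, abs=1e-4)

    def test_all_homozygous_alt_boundary(self):
        g2 = GenotypeLikelihoods("s", "b", 2, [-120.0, -60.0, 0.0])
        est = em_allele_frequency([g2] * 4)
        assert est.frequency > 0.99

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(1)
        grid = np.arange(0, 1.0001, 0.001)
        for _ in range(20):
            gls = [
                GenotypeLikelihoods(
                    "s", f"x{i}", 2, list(-rng.random(3) * 8)
                )
                for i in range(8)
            ]
            est = em_allele_frequency(gls)
            vals = [_marginal_loglik(gls, f) for f in grid]
            fstar = grid[int(np.argmax(vals))]
            assert abs(est.frequency - fstar) <= 0.002

    def test_trace_non_decreasing(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            gls = [
                GenotypeLikelihoods(
                    "s", f"x{i}", 2, list(-rng.random(3) * 10)
                )
                for i in range(6)
            ]
            est = em_allele_frequency(gls)
            for a, b in zip(est.loglik_trace, est.loglik_trace[1:]):
                assert b >= a - 1e-9

    def test_parameter_recovery(self):
        """30 diploid samples, 10 informative q=30 pairs each."""
        rng = np.random.default_rng(3)
        for true_f in (0.1, 0.3, 0.5):
            gls = []
            truth = {}
            for i in range(30):
                d = int(rng.binomial(2, true_f))
                truth[("site", f"s{i}")] = d
                mappings = []
                for k in range(10):
                    alt_read = rng.random() < d / 2
                    mappings.append(
                        PairMapping(
                            f"p{k}", "alt" if alt_read else "ref", 30
                        )
                    )
                gls.append(
                    compute_gl(mappings, 2, site_id="site", sample_id=f"s{i}")
                )
            est = em_allele_frequency(gls)
            se = math.sqrt(true_f * (1 - true_f) / (2 * 30))
            assert abs(est.frequency - true_f) <= 3 * se
            calls = call_genotypes(gls, est.frequency)
            called = {(c.site_id, c.sample_id): c.dosage for c in calls}
            assert concordance(called, truth) >= 0.95

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            em_allele_frequency([])


class TestCallGenotypes:
    def test_prior_dominates_flat_likelihood(self):
        flat = GenotypeLikelihoods("s", "a", 2, [0.0, 0.0, 0.0])
        call = call_genotypes([flat], 0.1)[0]
        assert call.dosage == 0
        assert call.posteriors == pytest.approx([0.81, 0.18, 0.01])

    def test_het_prior_edges_out_near_tied_likelihood(self):
        # L = (0.001, 0.5, 0.999), f = 0.5: HWE priors (0.25, 0.5, 0.25)
        # give 0.5*0.5 = 0.25 > 0.999*0.25 = 0.24975, so d=1 wins
        gl = GenotypeLikelihoods(
            "s", "a", 2,
            [math.log(0.001), math.log(0.5), math.log(0.999)],
        )
        call = call_genotypes([gl], 0.5)[0]
        assert call.dosage == 1
        assert call.posteriors[1] > call.posteriors[2]

    def test_strong_likelihood_wins(self):
        gl = GenotypeLikelihoods(
            "s", "a", 2,
            [math.log(0.001), math.log(0.1), math.log(0.999)],
        )
        assert call_genotypes([gl], 0.5)[0].dosage == 2

    def test_posteriors_normalized(self):
        gl = GenotypeLikelihoods("s", "a", 2, [-1.0, -2.0, -3.0])
        call = call_genotypes([gl], 0.3)[0]
        assert sum(call.posteriors) == pytest.approx(1.0, abs=1e-9)

    def test_haploid_no_het(self):
        """Ploidy-1 samples only ever receive dosage 0 or 1."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            gl = GenotypeLikelihoods(
                "s", "a", 1, list(-rng.random(2) * 10)
            )
            call = call_genotypes([gl], rng.random())[0]
            assert call.dosage in (0, 1)
            assert len(call.posteriors) == 2

    def test_invalid_frequency(self):
        gl = GenotypeLikelihoods("s", "a", 2, [0.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            call_genotypes([gl], 1.5)


class TestConcordance:
    def test_109_of_110(self):
        truth = {(str(i), "x"): 1 for i in range(110)}
        calls = dict(truth)
        calls[("0", "x")] = 0
        assert concordance(calls, truth) == pytest.approx(109 / 110)

    def test_identical_sets(self):
        truth = {("a", "s"): 2, ("b", "s"): 0}
        assert concordance(truth, dict(truth)) == 1.0

    def test_disjoint_keys_rejected(self):
        with pytest.raises(ValueError):
            concordance({("a", "s"): 1}, {("b", "s"): 1})


class TestHwePriors:
    def test_diploid(self):
        assert hwe_priors(0.2, 2) == pytest.approx([0.64, 0.32, 0.04])

    def test_haploid(self):
        assert hwe_priors(0.2, 1) == pytest.approx([0.8, 0.2])


class TestEndToEndGenotyping:
    def test_homozygous_site_from_reads(self, small_dataset, library):
        """Reads from a homozygous implant genotype as dosage 2."""
        from alukit.breakpoint import call_site
        from alukit.discovery import discover
        from alukit.local_assembly import (
            assemble,
            collect_reads_batch,
            scaffold_contigs,
        )

        sites, _ = discover(
            [small_dataset["sam"]], library, small_dataset["catalog"],
            small_dataset["mask"], 300, 30,
        )
        genome = small_dataset["genome"]
        site = sites[0]
        readsets = collect_reads_batch([site], small_dataset["sam"])
        contigs = assemble(readsets[f"{site.chrom}:{site.pos}"].reads)
        sc = scaffold_contigs(
            contigs, readsets[f"{site.chrom}:{site.pos}"].pairs
        )[0]
        call = call_site(sc.seq, genome, site.chrom, site.pos, library)
        assert call is not None and call.genotypable
        ap = build_alleles(call, genome, site_id="s0")
        mappings = extract_and_remap_batch(small_dataset["sam"], [ap])["s0"]
        gl = compute_gl(mappings, 2, "s0", "S1")
        assert gl.n_informative > 0
        est = em_allele_frequency([gl])
        gcall = call_genotypes([gl], est.frequency)[0]
        assert gcall.dosage == 2
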