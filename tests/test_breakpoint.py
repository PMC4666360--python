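import numpy as np
import pytest

from alukit.alignment import PairwiseAlignment, global_align
from alukit.breakpoint import (
    BreakpointCall,
    call_site,
    merge_threeway,
    refine_tsd,
    render_threeway,
    score_breakpoints,
    trim_to_flanks,
)
from alukit.genome_io import Genome, reverse_complement
from alukit.simulate import ImplantSpec, implant_insertions, inserted_sequence


def _template(n, seed=0):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestMergeThreeway:
    def test_identical_all_star(self):
        ref = _template(30, seed=1)
        la = global_align(ref, ref)
        ra = global_align(ref, ref)
        tw = merge_threeway(la, ra)
        assert tw.labels == "*" * 30

    def test_disjoint_halves(self):
        ref = _template(40, seed=2)
        la = global_align(ref[:20], ref, end_gaps_free=True)
        ra = global_align(ref[20:], ref, end_gaps_free=True)
        tw = merge_threeway(la, ra)
        assert tw.labels == "1" * 20 + "2" * 20

    def test_tsd_fixture_central_stars(self):
        ref = _template(40, seed=3)
        left = ref[:25]  # ends 5 bp into the right flank's start
        right = ref[20:]  # 5 bp overlap: columns 20-24 match both
        la = global_align(left, ref, end_gaps_free=True)
        ra = global_align(right, ref, end_gaps_free=True)
        tw = merge_threeway(la, ra)
        assert tw.labels == "1" * 20 + "*" * 5 + "2" * 15

    def test_different_references_rejected(self):
        a = PairwiseAlignment("AC", "AC", 0)
        b = PairwiseAlignment("AG", "AG", 0)
        with pytest.raises(ValueError):
            merge_threeway(a, b)

    def test_every_reference_base_once(self):
        ref = _template(50, seed=4)
        left = ref[:20] + "GG" + ref[20:30]  # insertion in left flank
        la = global_align(left, ref, end_gaps_free=True)
        ra = global_align(ref[25:], ref, end_gaps_free=True)
        tw = merge_threeway(la, ra)
        assert tw.ref.replace("-", "") == ref
        assert sorted(c for c in tw.ref_coords if c >= 0) == list(range(50))

    def test_label_conservation(self):
        ref = _template(60, seed=5)
        la = global_align(ref[:35], ref, end_gaps_free=True)
        ra = global_align(ref[30:], ref, end_gaps_free=True)
        tw = merge_threeway(la, ra)
        assert all(lab in "*12N" for lab in tw.labels)
        assert len(tw.labels) == len(tw.ref) == len(tw.left) == len(tw.right)


def oracle_breakpoints(labels):
    """Exhaustive per-column argmax over the cumulative scores."""
    inc_l = {"1": 1, "*": 1, "N": -1, "2": -3}
    inc_r = {"2": 1, "*": 1, "N": -1, "1": -3}
    cum = 0
    ls = []
    for lab in labels:
        cum += inc_l[lab]
        ls.append(cum)
    best = max(ls)
    left_col = max(i for i, v in enumerate(ls) if v == best)
    rs = [0] * len(labels)
    cum = 0
    for i in range(len(labels) - 1, -1, -1):
        cum += inc_r[labels[i]]
        rs[i] = cum
    best = max(rs)
    right_col = min(i for i, v in enumerate(rs) if v == best)
    return left_col, right_col


def _threeway_from_labels(labels):
    """Construct a gapless three-way alignment realizing a label string."""
    ref = []
    left = []
    right = []
    for lab in labels:
        if lab == "*":
            ref.append("A"); left.append("A"); right.append("A")
        elif lab == "1":
            ref.append("C"); left.append("C"); right.append("G")
        elif lab == "2":
            ref.append("G"); left.append("T"); right.append("G")
        else:
            ref.append("T"); left.append("A"); right.append("C")
    from alukit.breakpoint import ThreeWayAlignment

    return ThreeWayAlignment(
        "".join(ref), "".join(left), "".join(right),
        labels, list(range(len(labels))),
    )


class TestScoreBreakpoints:
    def test_blunt_fixture(self):
        tw = _threeway_from_labels("1" * 10 + "2" * 10)
        _, _, call = score_breakpoints(tw)
        assert call.left_bp == 9 and call.right_bp == 10
        assert call.overlap_len == 0 and call.target_deletion == 0

    def test_14bp_tsd_fixture(self):
        tw = _threeway_from_labels("1" * 20 + "*" * 14 + "2" * 20)
        _, _, call = score_breakpoints(tw)
        assert call.overlap_len == 14
        assert call.left_bp == 33 and call.right_bp == 20

    def test_deletion_fixture(self):
        tw = _threeway_from_labels("1" * 10 + "NNN" + "2" * 10)
        _, _, call = score_breakpoints(tw)
        assert call.target_deletion == 3 and call.overlap_len == 0

    def test_agrees_with_exhaustive_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(5, 80))
            labels = "".join(
                rng.choice(list("*12N"), p=[0.2, 0.3, 0.3, 0.2])
                for _ in range(n)
            )
            tw = _threeway_from_labels(labels)
            lt, rt, call = score_breakpoints(tw)
            left_col, right_col = oracle_breakpoints(labels)
            assert lt.argmax_column == left_col, labels
            assert rt.argmax_column == right_col, labels

    def test_empty_rejected(self):
        from alukit.breakpoint import ThreeWayAlignment

        with pytest.raises(ValueError):
            score_breakpoints(ThreeWayAlignment("", "", "", "", []))


class TestRefineTsd:
    def test_identical_overlap_full_tsd(self):
        tw = _threeway_from_labels("1" * 5 + "*" * 14 + "2" * 5)
        _, _, call = score_breakpoints(tw)
        refine_tsd(call, tw)
        assert len(call.tsd) == 14

    def test_mismatch_inside_overlap_shortens_tsd(self):
        # overlap of 46 columns whose longest exact run is 20
        labels = (
            "1" * 5
            + "*" * 10 + "N" + "*" * 20 + "N" + "*" * 14
            + "2" * 5
        )
        tw = _threeway_from_labels(labels)
        _, _, call = score_breakpoints(tw)
        assert call.overlap_len == 46
        refine_tsd(call, tw)
        assert len(call.tsd) == 20
        assert call.overlap_len == 46  # overlap retained

    def test_zero_overlap_empty_tsd(self):
        tw = _threeway_from_labels("1" * 8 + "2" * 8)
        _, _, call = score_breakpoints(tw)
        refine_tsd(call, tw)
        assert call.tsd == ""


def _build_scaffold(genome, spec, library, flank=250):
    """Truth scaffold: the haplotype segment surrounding one implant."""
    hap, truth = implant_insertions(genome, [spec], library)
    t = truth[0]
    return (
        hap.genome[t["chrom"]][t["alt_start"] - flank : t["alt_end"] + flank],
        t,
    )


def _unambiguous_pos(genome, library, spec_kwargs, start=2_500):
    """First position whose junction bases admit a unique description."""
    ref = genome["chr1"]
    for pos in range(start, 4_000):
        spec = ImplantSpec("chr1", pos, **spec_kwargs)
        ins = inserted_sequence(spec, library)
        tsd = spec.tsd_length
        dl = spec.target_deletion
        if ins[0] == ref[pos]:
            continue
        if ins[-1] == ref[pos + dl - tsd - 1]:
            continue
        if dl and any(ref[pos + k] == ins[-1] for k in range(dl)):
            continue
        return spec
    raise AssertionError("no unambiguous position found")


@pytest.fixture(scope="module")
def genome():
    return Genome({"chr1": _template(6_000, seed=77)})


class TestCallSite:

    def _call(self, genome, spec, library):
        scaffold, t = _build_scaffold(genome, spec, library)
        call = call_site(scaffold, genome, "chr1", spec.pos, library)
        assert call is not None
        return call, t

    def test_tsd14_recovered(self, genome, library):
        spec = _unambiguous_pos(
            genome, library,
            dict(element_source="AluYa5", tsd_length=14, polyA_length=20),
        )
        call, t = self._call(genome, spec, library)
        assert call.insertion_point == spec.pos
        assert call.tsd == t["tsd_seq"]
        assert len(call.tsd) == 14
        assert call.genotypable

    def test_target_deletion_3_recovered(self, genome, library):
        spec = _unambiguous_pos(
            genome, library,
            dict(element_source="AluYb8", target_deletion=3, polyA_length=18),
        )
        call, t = self._call(genome, spec, library)
        assert call.target_deletion == 3
        assert call.overlap_len == 0

    def test_minus_strand_recovered(self, genome, library):
        spec = _unambiguous_pos(
            genome, library,
            dict(element_source="AluY", strand="-", tsd_length=10,
                 polyA_length=22),
        )
        call, t = self._call(genome, spec, library)
        assert call.element_strand == "-"
        assert call.tsd == t["tsd_seq"]

    def test_gap_near_element_not_genotypable(self, genome, library):
        spec = _unambiguous_pos(
            genome, library,
            dict(element_source="AluYa5", tsd_length=14, polyA_length=20),
        )
        scaffold, _ = _build_scaffold(genome, spec, library)
        # place a spacer 50 bp downstream of the element
        idx = scaffold.find(genome["chr1"][spec.pos : spec.pos + 50]) + 50
        gapped = scaffold[:idx] + "N" * 300 + scaffold[idx + 300 :]
        call = call_site(gapped, genome, "chr1", spec.pos, library)
        assert call is not None
        assert call.gap_within_100bp
        assert not call.genotypable

    def test_strand_symmetry(self, genome, library):
        """Reverse-complementing the scaffold leaves the call invariant."""
        spec = _unambiguous_pos(
            genome, library,
            dict(element_source="AluYa5", tsd_length=14, polyA_length=20),
        )
        scaffold, t = _build_scaffold(genome, spec, library)
        fwd = call_site(scaffold, genome, "chr1", spec.pos, library)
        rev = call_site(
            reverse_complement(scaffold), genome, "chr1", spec.pos, library
        )
        assert fwd.left_bp == rev.left_bp
        assert fwd.right_bp == rev.right_bp
        assert fwd.tsd == rev.tsd
        assert fwd.insert_seq == rev.insert_seq


def test_render_threeway_notation():
    tw = _threeway_from_labels("1*2N")
    text = render_threeway(tw)
    assert "1*2N" in text
    assert "ref" in text
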