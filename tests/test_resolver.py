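"""Tandem building, unit resolution, de-overlapping, targets and names."""

import itertools
import math

import pytest

from tiger.model import GeneClass, GeneFeature
from tiger.pipeline import run_pipeline
from tiger.resolve import (
    IgeCall, assign_target, build_tandems, deoverlap, name_ige, resolve,
    resolve_tandem,
)


def _ige(left, right, dr=40, support=1, fp=math.nan, seed_id="", source="tiger"):
    return IgeCall(replicon_id="r", left=left, right=right, dr_len=dr,
                   support=support, fp=fp, seed_id=seed_id, source=source)


def _int(start, end, fid="int"):
    return GeneFeature(id=fid, replicon_id="r", start=start, end=end,
                       strand="+", klass=GeneClass.Y_INT)


class TestBuildTandems:
    def test_chain_of_terminus_sharing_forms_one_tandem(self):
        # A: [1000, 9039]; B: [9000, 15039]; composite: [1000, 15039]
        a = _ige(1_000, 9_039)
        b = _ige(9_000, 15_039)
        comp = _ige(1_000, 15_039)
        tandems = build_tandems([a, b, comp])
        assert len(tandems) == 1
        assert tandems[0].termini == [1_000, 9_000, 15_000]

    def test_disjoint_calls_form_singletons(self):
        tandems = build_tandems([_ige(1_000, 9_039), _ige(20_000, 28_039)])
        assert len(tandems) == 2
        assert all(len(t.calls) == 1 for t in tandems)


class TestResolveTandem:
    def test_two_unit_tandem_cut_at_shared_terminus(self):
        a = _ige(1_000, 9_039, support=2)
        b = _ige(9_000, 15_039, support=2)
        comp = _ige(1_000, 15_039, support=1)
        ints = [_int(2_000, 3_000, "iA"), _int(10_000, 11_000, "iB")]
        (t,) = build_tandems([a, b, comp])
        units = resolve_tandem(t, ints)
        assert [(u.left, u.right) for u in units] == [(1_000, 9_039), (9_000, 15_039)]
        assert not any(u.inferred for u in units)

    def test_middle_segment_without_integrase_merges_into_neighbor(self):
        """A candidate internal cut that would strand an integrase-free
        unit is not taken."""
        a = _ige(1_000, 9_039, support=3)
        b = _ige(9_000, 15_039, support=3)
        comp = _ige(1_000, 15_039, support=1)
        ints = [_int(2_000, 3_000, "iA")]  # only the left unit has an int
        (t,) = build_tandems([a, b, comp])
        units = resolve_tandem(t, ints)
        assert [(u.left, u.right) for u in units] == [(1_000, 15_039)]

    def test_unsupported_interior_unit_is_inferred(self):
        """Termini imply a middle unit that no direct call covers."""
        a = _ige(1_000, 9_039, support=2)
        c = _ige(15_000, 22_039, support=2)
        bridge_ab = _ige(1_000, 15_039, support=1)   # connects A to middle
        bridge_bc = _ige(9_000, 22_039, support=1)   # connects middle to C
        ints = [_int(2_000, 3_000, "iA"), _int(10_000, 11_000, "iB"),
                _int(16_000, 17_000, "iC")]
        (t,) = build_tandems([a, c, bridge_ab, bridge_bc])
        units = resolve_tandem(t, ints)
        assert [(u.left, u.right) for u in units] == [
            (1_000, 9_039), (9_000, 15_039), (15_000, 22_039)]
        assert [u.inferred for u in units] == [False, True, False]


class TestDeoverlap:
    def test_lower_support_rejected(self):
        out = deoverlap([_ige(1_000, 9_000, support=6),
                         _ige(5_000, 13_000, support=2)])
        assert [(c.left, c.right) for c in out] == [(1_000, 9_000)]

    def test_support_tie_broken_by_fp_score(self):
        keep = _ige(1_000, 9_000, support=3, fp=0.2)
        drop = _ige(5_000, 13_000, support=3, fp=0.9)
        out = deoverlap([drop, keep])
        assert out == [keep]

    def test_fixpoint_on_chains_matches_brute_force(self):
        """On every overlap chain of <= 4 calls the result is a maximal
        overlap-free set consistent with the rejection order."""
        calls = [_ige(1_000, 9_000, support=5), _ige(8_000, 16_000, support=3),
                 _ige(15_000, 23_000, support=4), _ige(22_000, 30_000, support=1)]
        out = deoverlap(calls)
        # overlap-free
        for a, b in itertools.combinations(out, 2):
            assert not a.overlaps(b) or a.shares_terminus(b)
        # brute force: no rejected call could be added back
        for c in calls:
            if c not in out:
                assert any(c.overlaps(k) and not c.shares_terminus(k) for k in out)

    def test_tandem_neighbours_sharing_dr_not_rejected(self):
        a = _ige(1_000, 9_039, support=1)     # dr 40, block_right 9000
        b = _ige(9_000, 15_039, support=5)
        assert sorted(deoverlap([a, b]), key=lambda c: c.left) == [a, b]


class TestResolveModes:
    def test_nested_inner_call_dropped(self):
        outer = _ige(1_000, 30_000, support=2, seed_id="sO")
        inner = _ige(10_000, 15_000, support=9, seed_id="sI")
        ints = [_int(2_000, 3_000), _int(11_000, 12_000)]
        out = resolve([],
                      islander_calls=[outer, inner], mode="islander",
                      int_features=ints)
        assert [(c.left, c.right) for c in out] == [(1_000, 30_000)]

    def test_islander_pseudo_support(self):
        c = _ige(1_000, 9_000, support=0)
        out = resolve([], islander_calls=[c], mode="islander",
                      int_features=[_int(2_000, 3_000)])
        assert out[0].support == 1

    def test_combined_marks_doubly_confirmed(self, simple_fixture):
        fx = simple_fixture
        t = fx.truth[0]
        isl = [_ige(t.left, t.right, dr=t.dr_len, support=0)]
        for c in isl:
            c.replicon_id = fx.replicon.id
        calls, _ = run_pipeline(fx.genome, fx.refs, islander_calls=isl,
                                mode="combined")
        assert len(calls) == 1
        assert calls[0].source == "both"
        assert "doubly_confirmed" in calls[0].flags

    def test_combined_yield_covers_single_modes(self, simple_fixture):
        fx = simple_fixture
        t = fx.truth[0]
        isl = [_ige(t.left, t.right, dr=t.dr_len, support=0)]
        for c in isl:
            c.replicon_id = fx.replicon.id
        tiger_only, _ = run_pipeline(fx.genome, fx.refs, mode="tiger")
        isl_only = resolve([], islander_calls=[_ige(t.left, t.right, dr=t.dr_len)],
                           mode="islander",
                           int_features=[f for f in fx.genome.features
                                         if f.klass is GeneClass.Y_INT])
        combined, _ = run_pipeline(fx.genome, fx.refs, islander_calls=isl,
                                   mode="combined")
        spans = {(c.left, c.right) for c in combined}
        assert {(c.left, c.right) for c in tiger_only} <= spans
        assert {(c.left, c.right) for c in isl_only} <= spans

    def test_idempotence_of_resolution(self):
        a = _ige(1_000, 9_039, support=2)
        b = _ige(9_000, 15_039, support=2)
        ints = [_int(2_000, 3_000), _int(10_000, 11_000)]
        once = resolve([], islander_calls=[a, b], mode="islander",
                       int_features=ints)
        twice = resolve([], islander_calls=list(once), mode="islander",
                        int_features=ints)
        assert [(c.left, c.right) for c in once] == \
               [(c.left, c.right) for c in twice]


def _feat(klass, start, end, name=""):
    return GeneFeature(id=f"f{start}", replicon_id="r", start=start, end=end,
                       strand="+", klass=klass, name=name)


class TestTargets:
    def test_dr_inside_trna(self):
        call = _ige(1_000, 9_039, dr=40)
        ann = [_feat(GeneClass.TRNA, 960, 1_050, name="Arg")]
        assert assign_target(call, ann) == "tRNA-Arg"

    def test_dr_overlapping_single_cds_and_intergenic(self):
        call = _ige(1_000, 9_039, dr=40)
        ann = [_feat(GeneClass.CDS, 900, 1_010)]
        assert assign_target(call, ann) == "CDS"

    def test_dr_overlapping_two_genes_is_multi_gene(self):
        call = _ige(1_000, 9_039, dr=40)
        ann = [_feat(GeneClass.CDS, 900, 1_010), _feat(GeneClass.CDS, 1_015, 1_200)]
        assert assign_target(call, ann) == "multi-gene"

    def test_no_overlap_is_intergenic(self):
        call = _ige(1_000, 9_039, dr=40)
        assert assign_target(call, []) == "intergenic"

    def test_attr_side_checked_when_attl_intergenic(self):
        call = _ige(1_000, 9_039, dr=40)
        ann = [_feat(GeneClass.TMRNA, 9_000, 9_100)]
        assert assign_target(call, ann) == "tmRNA"


class TestNames:
    @pytest.mark.parametrize(
        "size,target,genome,expected",
        [
            (59_951, "tRNA-Arg", "Xor4", "Xor4.60.R"),
            (2_499, "intergenic", "Syn1", "Syn1.2.ig"),
            (120_000, "tRNA-Phe", "Sen346", "Sen346.120.F"),
            (10_400, "tmRNA", "Eco1", "Eco1.10.tmRNA"),
        ],
    )
    def test_formula(self, size, target, genome, expected):
        call = _ige(1_001, 1_000 + size)
        call.target = target
        assert name_ige(call, genome) == expected
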