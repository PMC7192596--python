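"""Ping-pong mapping: flank queries, junction placement, merging,
side deduplication, support counting and the transposed-IS artifact."""

import itertools

import pytest

from tiger.fixtures import (
    FixtureSpec, IgeSpec, RefSpec, generate_fixture, transposed_is_fixture,
)
from tiger.mapper import (
    MapperConfig, RawCall, dedupe_sides, map_genome, map_seed,
    merge_variant_calls, take_flank_queries,
)
from tiger.model import (
    GeneClass, GeneFeature, Replicon, SeedGene, SeedMode, Topology,
)


def _seed(mid, rep_id="r"):
    g = GeneFeature(id="int", replicon_id=rep_id, start=mid - 50, end=mid + 50,
                    strand="+", klass=GeneClass.Y_INT)
    return SeedGene(gene=g)


class TestFlankQueries:
    def test_linear_arithmetic(self):
        rep = Replicon(id="r", seq="A" * 100_000, topology=Topology.linear)
        (q1L, sL), (q1R, sR) = take_flank_queries(_seed(20_000), rep)
        assert sL == 5_000 and len(q1L) == 15_000   # covers 5000..19999
        assert sR == 20_001 and len(q1R) == 15_000  # covers 20001..35000

    def test_circular_wrap(self):
        rep = Replicon(id="r", seq="ACGTN" * 20_000, topology=Topology.circular)
        (q1L, sL), _ = take_flank_queries(_seed(1_000), rep)
        assert sL == 1_000 - 15_000
        # 15 kb ending at 999 wraps back to replicon position 86 000
        assert len(q1L) == 15_000
        assert rep.normalize(sL) == 86_000
        assert q1L == rep.fetch(86_000, 100_000) + rep.fetch(1, 999)

    def test_linear_truncation(self):
        rep = Replicon(id="r", seq="A" * 10_000, topology=Topology.linear)
        (q1L, sL), _ = take_flank_queries(_seed(1_000), rep)
        assert len(q1L) == 999 and sL == 1

    def test_short_replicon_rejected(self):
        rep = Replicon(id="r", seq="A" * 1_500, topology=Topology.linear)
        with pytest.raises(ValueError):
            take_flank_queries(_seed(700), rep)


def _call(left, right, support, refs=None, side="q1L", dr=40):
    return RawCall(
        replicon_id="r", left=left, right=right, dr_len=dr, seed=None,
        side=side, support=support,
        supporting_refs=list(refs or [f"ref{left}_{right}_{i}" for i in range(support)]),
        evidence=[],
    )


class TestMergeVariants:
    def test_close_termini_merge_to_best_supported(self):
        a = _call(1_000, 9_000, 4)
        b = _call(1_003, 9_002, 2)
        out = merge_variant_calls([a, b], window=20)
        assert len(out) == 1
        m = out[0]
        assert (m.left, m.right) == (1_000, 9_000)  # 4-support coordinates
        assert m.support == 6                        # summed support

    def test_distant_termini_stay_separate(self):
        out = merge_variant_calls([_call(1_000, 9_000, 1), _call(1_100, 9_100, 1)],
                                  window=20)
        assert len(out) == 2

    def test_chain_merge_equals_transitive_closure(self):
        """Three-way chains merge exactly as brute-force pairwise closure."""
        calls = [_call(1_000, 9_000, 1), _call(1_015, 9_010, 2),
                 _call(1_028, 9_022, 5), _call(2_000, 9_500, 1)]
        out = merge_variant_calls(calls, window=20)
        # oracle: transitive closure over the pairwise near-equality relation
        n = len(calls)
        adj = {i: {i} for i in range(n)}
        for i, j in itertools.combinations(range(n), 2):
            if (abs(calls[i].left - calls[j].left) <= 20
                    and abs(calls[i].right - calls[j].right) <= 20):
                adj[i] |= {j}
                adj[j] |= {i}
        changed = True
        while changed:
            changed = False
            for i in range(n):
                new = set().union(*(adj[k] for k in adj[i]))
                if new != adj[i]:
                    adj[i] = new
                    changed = True
        n_groups = len({frozenset(v) for v in adj.values()})
        assert len(out) == n_groups == 2
        big = max(out, key=lambda c: c.support)
        assert big.support == 8
        assert (big.left, big.right) == (1_028, 9_022)  # best-supported member


class TestDedupeSides:
    def test_identical_sides_collapse_without_doubling(self):
        a = _call(1_000, 9_000, 3, refs=["r1", "r2", "r3"], side="q1L")
        b = _call(1_000, 9_000, 3, refs=["r1", "r2", "r3"], side="q1R")
        a.evidence = [None] * 3
        b.evidence = [None] * 3
        out = dedupe_sides([a, b])
        assert len(out) == 1 and out[0].support == 3

    def test_distinct_coordinates_kept(self):
        a = _call(1_000, 9_000, 1, side="q1L")
        b = _call(1_000, 9_100, 1, side="q1R")
        a.evidence = [None]
        b.evidence = [None]
        assert len(dedupe_sides([a, b])) == 2


class TestMapSeed:
    def test_exact_recovery_with_support(self, simple_fixture):
        """One planted element, 3 clean references: one call at exactly the
        planted termini with support 3; the element-carrying reference
        contributes nothing."""
        fx = simple_fixture
        calls = map_genome(fx.genome, fx.refs)
        assert len(calls) == 1
        t = fx.truth[0]
        c = calls[0]
        assert (c.left, c.right, c.dr_len) == (t.left, t.right, t.dr_len)
        assert c.support == 3
        assert "carrier1" not in c.supporting_refs

    def test_short_element_seen_from_both_sides_once(self):
        """A 6-kb element (< flank length) is found via q1L and q1R and
        deduplicated to a single call."""
        spec = FixtureSpec(
            seed=13, replicon_len=60_000,
            iges=[IgeSpec("A", 30_000, interior_len=6_000, dr_len=30,
                          int_offset=2_500)],
            n_clean_refs=2,
        )
        fx = generate_fixture(spec)
        calls = map_genome(fx.genome, fx.refs)
        assert len(calls) == 1
        t = fx.truth[0]
        assert (calls[0].left, calls[0].right) == (t.left, t.right)
        assert calls[0].support == 2

    def test_all_refs_carrying_element_yield_no_call(self):
        spec = FixtureSpec(
            seed=5, replicon_len=60_000,
            iges=[IgeSpec("A", 30_000, interior_len=8_000, dr_len=45)],
            n_same_ige_refs=3,
        )
        fx = generate_fixture(spec)
        assert map_genome(fx.genome, fx.refs) == []

    def test_tandem_per_unit_support_below_isolated(
        self, tandem_fixture, isolated_fixture
    ):
        """Tandem units, each seen in only one flank-combination reference,
        have lower support than the same element isolated."""
        calls_t = map_genome(tandem_fixture.genome, tandem_fixture.refs)
        unit_spans = {(t.left, t.right) for t in tandem_fixture.truth}
        unit_calls = [c for c in calls_t if (c.left, c.right) in unit_spans]
        assert unit_calls and all(c.support == 1 for c in unit_calls)
        calls_i = map_genome(isolated_fixture.genome, isolated_fixture.refs)
        assert calls_i[0].support == 3

    def test_oversize_element_not_called(self):
        """An element beyond the configured maximum size yields no call."""
        spec = FixtureSpec(
            seed=9, replicon_len=40_000,
            iges=[IgeSpec("A", 20_000, interior_len=8_000, dr_len=30)],
            n_clean_refs=1,
        )
        fx = generate_fixture(spec)
        cfg = MapperConfig(max_size=5_000)
        assert map_genome(fx.genome, fx.refs, config=cfg) == []

    def test_is_mode_symmetry(self):
        """The same engine with IS-mode parameters (reachback 30, limits
        5–15 kb) recovers a planted IS exactly from its DDE seed."""
        spec = FixtureSpec(
            seed=21, replicon_len=60_000,
            iges=[IgeSpec("I", 30_000, interior_len=6_000, dr_len=8,
                          int_klass=GeneClass.DDE)],
            n_clean_refs=2,
        )
        fx = generate_fixture(spec)
        calls = map_genome(fx.genome, fx.refs, mode=SeedMode.IS)
        assert len(calls) == 1
        t = fx.truth[0]
        assert (calls[0].left, calls[0].right, calls[0].dr_len) == \
            (t.left, t.right, t.dr_len)


class TestIsArtifact:
    def test_regression_pair(self):
        """The transposed-IS fixture yields a spurious call with the filter
        off and none with it on."""
        fx, is_db = transposed_is_fixture(0)
        off = map_genome(fx.genome, fx.refs, is_filter=False)
        assert len(off) >= 1  # the artifact call
        on = map_genome(fx.genome, fx.refs, is_filter=True, is_db=is_db)
        assert on == []

    def test_database_only_check(self):
        """Without DDE annotation the IS database alone rejects the call."""
        fx, is_db = transposed_is_fixture(0)
        fx.genome.features = [
            f for f in fx.genome.features if f.klass is not GeneClass.DDE
        ]
        on = map_genome(fx.genome, fx.refs, is_filter=True, is_db=is_db)
        assert on == []
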