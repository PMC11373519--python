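"""Ancestral material, resolution, the simplification ladder."""

import itertools

import pytest

from gargkit import (
    IntervalSet,
    SimplifyOptions,
    ancestral_material,
    ancestry_segments,
    coalescence_intervals,
    coalescence_span,
    earg_to_garg,
    resolve,
    simplify,
    tree_at,
    validate,
)
from gargkit.earg import RECOMBINATION
from helpers import ancestral_nodes_at, mrca_table, region_midpoints, truncated_forest

MID = IntervalSet([(2, 7)])


class TestAncestralMaterial:
    def test_parental_generation_carriers_in_mid_region(self, fig1):
        """In [2,7) exactly F, G, H of the parents E-H carry ancestral
        material; E is blank there because A and C coalesced in F."""
        am = ancestral_material(fig1)
        carriers = [u for u in "EFGH" if am[u].intersect(MID)]
        assert carriers == ["F", "G", "H"]
        assert not am["E"].intersect(MID)
        assert am["E"] == IntervalSet([(0, 2), (7, 10)])

    def test_samples_carry_whole_genome(self, fig1):
        am = ancestral_material(fig1)
        for s in fig1.samples:
            assert am[s] == IntervalSet([(0, 10)])

    def test_segment_counts_record_local_coalescence(self, fig1):
        segs = {s.interval: s.sample_count for s in ancestry_segments(fig1)["F"]}
        from gargkit import Interval

        assert segs[Interval(2, 7)] == 2  # A and C have merged here
        assert segs[Interval(0, 2)] == 1

    def test_agrees_with_climb_oracle_on_simulations(self, wf_graphs):
        for g in wf_graphs[:5]:
            am = ancestral_material(g)
            samples = sorted(g.samples)
            for x in region_midpoints(g):
                expected = ancestral_nodes_at(g, samples, x)
                got = {u for u, ivs in am.items() if x in ivs}
                assert got == expected

    def test_unknown_sample_rejected(self, fig1):
        with pytest.raises(ValueError, match="not in graph"):
            ancestral_material(fig1, samples=["Z"])


class TestResolve:
    def test_wiuf_hein_example(self, fig3):
        """Resolution drops the recombination edge falling in nonancestral
        material (breakpoint 5) and the grand MRCA Q."""
        g = earg_to_garg(fig3)
        r = resolve(g)
        removed = {(e.child, e.parent) for e in g.edges} - {
            (e.child, e.parent) for e in r.edges
        }
        assert ("G", "J") in removed
        kinds = {n.id: n for n in fig3.nodes}
        removed_recomb = [
            (c, p) for c, p in removed if kinds[c].kind == RECOMBINATION
        ]
        assert removed_recomb == [("G", "J")]
        assert kinds["G"].breakpoint == 5.0
        ids = {n.id for n in r.nodes}
        assert "Q" not in ids
        assert {"G", "J", "K", "P"} <= ids  # retained, merely pruned around

    def test_full_coalescence_sites(self, fig3):
        g = earg_to_garg(fig3)
        coal = coalescence_intervals(g)
        assert coal["K"] == IntervalSet([(0, 2)])
        assert coal["P"] == IntervalSet([(2, 7)])
        assert coal["Q"] == IntervalSet()

    def test_idempotent(self, fig3, wf_graphs):
        graphs = [earg_to_garg(fig3), *wf_graphs[:3]]
        for g in graphs:
            r1 = resolve(g)
            assert resolve(r1).canonical() == r1.canonical()

    def test_preserves_sample_restricted_forests(self, wf_graphs):
        for g in wf_graphs[:5]:
            samples = sorted(g.samples)
            r = resolve(g)
            for x in region_midpoints(g):
                oracle = truncated_forest(g, samples, x)
                got = tree_at(r, x).restrict_to_ancestry(samples)
                assert got.parent_of == oracle

    def test_nonancestral_pedigree_members_removed(self, fig1):
        r = resolve(fig1)
        ids = {n.id for n in r.nodes}
        assert ids == set("ABCDEFGHIJLN")  # K, M, O, P carried nothing


class TestCoalescenceSpan:
    def test_mid_region_coalescence_in_F(self, fig1):
        span = coalescence_span(fig1)
        assert span["F"] == pytest.approx(0.5)  # [2,7) of a length-10 genome
        assert span["N"] == pytest.approx(1.0)

    def test_leaves_have_zero_span(self, fig1):
        span = coalescence_span(fig1)
        assert all(span[s] == 0.0 for s in fig1.samples)

    def test_zero_span_nodes_removed_at_unary_level(self, fig5a):
        span = coalescence_span(fig5a)
        res = simplify(
            fig5a, opts=SimplifyOptions.from_level("prune-unary")
        )
        for u, frac in span.items():
            if u in fig5a.samples:
                continue
            if frac == 0.0:
                assert u not in res.node_map
            elif frac > 0.0:
                assert u in res.node_map


LEVELS = SimplifyOptions.LEVELS


class TestSimplify:
    def test_binary_tree_is_fixed_point(self, single_tree_garg):
        g = single_tree_garg
        for level in LEVELS:
            res = simplify(g, opts=SimplifyOptions.from_level(level))
            assert len(res.graph.nodes) == len(g.nodes)
            assert len(res.graph.edges) == len(g.edges)
            # topology is identical modulo the dense renumbering
            nm = res.node_map
            got = {(nm[e.child], nm[e.parent]) for e in g.edges}
            assert got == {(e.child, e.parent) for e in res.graph.edges}

    def test_monotone_along_ladder(self, fig5a, wf_graphs):
        for g in [fig5a, *wf_graphs[:5]]:
            prev_nodes = len(g.nodes) + 1
            prev_span = sum(e.inherits.span for e in g.edges) + 1
            for level in LEVELS:
                res = simplify(g, opts=SimplifyOptions.from_level(level))
                n = len(res.graph.nodes)
                span = sum(e.inherits.span for e in res.graph.edges)
                assert n <= prev_nodes
                assert span <= prev_span + 1e-9
                prev_nodes, prev_span = n, span

    def test_idempotent_at_each_level(self, fig5a):
        for level in LEVELS:
            opts = SimplifyOptions.from_level(level)
            once = simplify(fig5a, opts=opts)
            twice = simplify(once.graph, opts=SimplifyOptions.from_level(level))
            assert once.graph.canonical() == twice.graph.canonical()

    def test_results_validate(self, fig5a, wf_graphs):
        for g in [fig5a, *wf_graphs[:3]]:
            for level in LEVELS:
                res = simplify(g, opts=SimplifyOptions.from_level(level))
                assert validate(res.graph).ok

    def test_node_map_total_and_injective_on_samples(self, fig5a):
        for level in LEVELS:
            res = simplify(fig5a, opts=SimplifyOptions.from_level(level))
            mapped = [res.node_map[s] for s in fig5a.samples]
            assert len(set(mapped)) == len(fig5a.samples)

    @pytest.mark.parametrize("level", LEVELS)
    def test_pairwise_mrca_invariant(self, wf_graphs, level):
        """Every pairwise sample MRCA (node identity and hence time) at
        every region is unchanged by simplification."""
        for g in wf_graphs[:5]:
            samples = sorted(g.samples)
            mids = region_midpoints(g)
            base = mrca_table(g, samples, mids)
            res = simplify(g, samples, SimplifyOptions.from_level(level))
            nm = res.node_map
            inverse = {v: k for k, v in nm.items()}
            got = mrca_table(res.graph, [nm[s] for s in samples], mids)
            for x in mids:
                for a, b in itertools.combinations(samples, 2):
                    new = got[(x, nm[a], nm[b])]
                    assert base[(x, a, b)] == (
                        inverse[new] if new is not None else None
                    )

    def test_fully_simplified_nodes_coalescent_where_present(self, fig5a):
        """After full simplification every non-sample node appears in a
        local tree only where it has >= 2 children."""
        res = simplify(fig5a, opts=SimplifyOptions.from_level("full"))
        g = res.graph
        for x in region_midpoints(g):
            f = tree_at(g, x)
            children = f.children_of()
            for u in f.covered_nodes:
                if u in g.samples:
                    continue
                local = children.get(u, [])
                assert len(local) != 1, (u, x)
                # no dangling non-sample leaves either
                assert not (len(local) == 0 and u in f.parent_of), (u, x)


class TestConservation:
    def test_sample_lineage_count_non_increasing_pastwards(self, wf_graphs):
        """At any position the number of distinct ancestors per generation
        never grows as we move pastwards."""
        for g in wf_graphs[:3]:
            samples = sorted(g.samples)
            gens = sorted({n.time for n in g.nodes})
            for x in (0.5, 5.0, 9.5):
                from helpers import climb_path

                paths = [climb_path(g, s, x) for s in samples]
                times = {n.id: n.time for n in g.nodes}
                prev = None
                for t in gens:
                    at_t = {p[i] for p in paths for i in range(len(p))
                            if times[p[i]] == t}
                    count = len(at_t)
                    if prev is not None and count:
                        assert count <= prev
                    if count:
                        prev = count
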