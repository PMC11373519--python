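"""The Wright-Fisher and coalescent-with-recombination generators."""

import numpy as np
import pytest

from gargkit import (
    CwRParams,
    IntervalSet,
    WFParams,
    distinct_tree_count,
    earg_to_garg,
    resolve,
    sim_earg,
    sim_wf,
    validate,
    validate_earg,
)
from gargkit.earg import RECOMBINATION
from gargkit.simulate import meiosis_mosaic
from gargkit.tableio import write_garg


class TestWrightFisher:
    def test_no_recombination_gives_single_full_edges(self):
        g = sim_wf(WFParams(4, 3, 10.0, crossover_rate=0.0, seed=1))
        by_child = g.edges_by_child()
        for child, edges in by_child.items():
            assert len(edges) == 1
            assert edges[0].inherits == IntervalSet([(0, 10)])

    def test_fixed_seed_reproduces_bit_identical_tables(self, tmp_path):
        for run in ("a", "b"):
            g = sim_wf(WFParams(5, 4, 10.0, crossover_rate=1.0,
                                gene_conversion_rate=0.3, seed=11))
            write_garg(g, tmp_path / f"{run}.nodes.tsv", tmp_path / f"{run}.edges.tsv")
        assert (tmp_path / "a.nodes.tsv").read_bytes() == (tmp_path / "b.nodes.tsv").read_bytes()
        assert (tmp_path / "a.edges.tsv").read_bytes() == (tmp_path / "b.edges.tsv").read_bytes()

    def test_inbound_edges_partition_genome(self, wf_graphs):
        g = sim_wf(WFParams(4, 3, 10.0, crossover_rate=2.0,
                            gene_conversion_rate=0.5, seed=2))
        for graph in [g, *wf_graphs[:3]]:
            founders = {n.id for n in graph.nodes
                        if not any(e.child == n.id for e in graph.edges)}
            for child, edges in graph.edges_by_child().items():
                union = IntervalSet()
                total = 0.0
                for e in edges:
                    union = union.union(e.inherits)
                    total += e.inherits.span
                assert union == IntervalSet([(0, graph.sequence_length)])
                assert total == pytest.approx(graph.sequence_length)  # no overlap

    def test_gene_conversion_yields_multi_interval_edges(self):
        g = sim_wf(WFParams(6, 4, 10.0, crossover_rate=0.0,
                            gene_conversion_rate=2.0, gc_tract_length=2.0, seed=3))
        assert any(len(e.inherits) >= 2 for e in g.edges)

    def test_simulated_graphs_validate(self, wf_graphs):
        for g in wf_graphs:
            assert validate(g).ok

    def test_crossover_count_matches_poisson_moment(self):
        """Mean observable crossovers per meiosis within 3 SE of the rate."""
        rng = np.random.default_rng(0)
        n, rate, L = 2000, 1.0, 10.0
        total = 0
        for _ in range(n):
            runs = meiosis_mosaic(rng, L, rate)
            total += len(runs) - 1
        mean = total / n
        assert abs(mean - rate) <= 3 * np.sqrt(rate / n)

    def test_more_recombination_means_more_local_trees(self):
        """Mean distinct-tree count of resolved graphs is non-decreasing in
        the crossover rate."""
        means = []
        for rate in (0.1, 1.0, 3.0):
            counts = []
            for seed in range(30):
                g = sim_wf(WFParams(4, 4, 10.0, crossover_rate=rate, seed=seed))
                counts.append(distinct_tree_count(resolve(g)))
            means.append(sum(counts) / len(counts))
        assert means[0] <= means[1] <= means[2]

    @pytest.mark.parametrize(
        "kwargs", [dict(population_size=0), dict(generations=0),
                   dict(crossover_rate=-1.0), dict(sequence_length=0.0)]
    )
    def test_invalid_params_rejected(self, kwargs):
        base = dict(population_size=4, generations=3, sequence_length=10.0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            WFParams(**base)


class TestCoalescentWithRecombination:
    def test_no_recombination_gives_binary_tree(self):
        e = sim_earg(CwRParams(sample_size=5, sequence_length=3.0,
                               recombination_rate=0.0, seed=4))
        assert validate_earg(e).ok
        assert not any(n.kind == RECOMBINATION for n in e.nodes)
        # a binary coalescent tree: n - 1 common ancestor events
        assert len(e.nodes) == 2 * 5 - 1

    def test_simulated_eargs_validate_and_convert(self, earg_sims):
        for e in earg_sims:
            assert validate_earg(e).ok
            g = earg_to_garg(e)
            assert validate(g).ok
            resolve(g)  # must not raise

    def test_recombination_node_count_conserved_by_conversion(self, earg_sims):
        for e in earg_sims:
            g = earg_to_garg(e)
            n_rec = sum(1 for n in e.nodes if n.kind == RECOMBINATION)
            n_split = sum(
                1 for child, edges in g.edges_by_child().items()
                if any(ed.inherits.right < g.sequence_length
                       or ed.inherits.left > 0 for ed in edges)
            )
            assert n_rec == n_split

    def test_breakpoints_fall_in_nonancestral_material_sometimes(self):
        """Some runs drop edges on resolution: the breakpoint missed the
        lineage's ancestral material."""
        drops = 0
        for seed in range(60):
            e = sim_earg(CwRParams(sample_size=3, sequence_length=7.0,
                                   recombination_rate=0.4, seed=seed))
            g = earg_to_garg(e)
            drops += len(resolve(g).edges) < len(g.edges)
        assert drops > 0

    def test_fixed_seed_deterministic(self):
        a = sim_earg(CwRParams(3, 7.0, recombination_rate=0.5, seed=13))
        b = sim_earg(CwRParams(3, 7.0, recombination_rate=0.5, seed=13))
        assert a.nodes == b.nodes and a.edges == b.edges

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CwRParams(sample_size=1, sequence_length=5.0)
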