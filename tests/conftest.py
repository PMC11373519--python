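import pytest

from gargkit import CwRParams, GraphARG, WFParams, sim_earg, sim_wf
from gargkit.fixtures import fig1_garg, fig2_earg, fig3_earg, fig5a_wf_garg


@pytest.fixture(scope="session")
def fig1():
    return fig1_garg()


@pytest.fixture(scope="session")
def fig2():
    return fig2_earg()


@pytest.fixture(scope="session")
def fig3():
    return fig3_earg()


@pytest.fixture(scope="session")
def fig5a():
    return fig5a_wf_garg()


@pytest.fixture(scope="session")
def wf_graphs():
    """A batch of small Wright-Fisher graphs across seeds."""
    params = [
        WFParams(population_size=4, generations=5, sequence_length=10.0,
                 crossover_rate=1.0, seed=seed)
        for seed in range(10)
    ]
    return [sim_wf(p) for p in params]


@pytest.fixture(scope="session")
def earg_sims():
    """A batch of small coalescent-with-recombination event ARGs."""
    return [
        sim_earg(CwRParams(sample_size=3, sequence_length=7.0,
                           recombination_rate=0.4, seed=seed))
        for seed in range(30)
    ]


@pytest.fixture
def single_tree_garg():
    """A gARG that is one binary tree over the whole genome."""
    from gargkit import GenomeNode, InheritanceEdge, IntervalSet

    L = 10.0
    nodes = [GenomeNode(i, time=float(t), is_sample=t == 0)
             for i, t in [("A", 0), ("B", 0), ("C", 0), ("D", 0),
                          ("E", 1), ("F", 1), ("G", 2)]]
    full = IntervalSet([(0, L)])
    edges = [InheritanceEdge(c, p, full)
             for c, p in [("A", "E"), ("B", "E"), ("C", "F"), ("D", "F"),
                          ("E", "G"), ("F", "G")]]
    return GraphARG(L, nodes, edges, samples="ABCD")
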