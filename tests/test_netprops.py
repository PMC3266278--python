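"""Split-graph descriptors vs brute-force recomputation."""

import numpy as np
import pytest

from grnrob.fixtures import make_toy_network
from grnrob.netprops import (
    MIXED,
    NO_EDGES,
    PURE_ACT,
    PURE_REP,
    count_autoregulation,
    interaction_similarity,
    pair_entropy,
    regulation_entropy,
    regulator_class,
    split_graph,
)
from grnrob.topology import (
    SIGN_ACT,
    SIGN_REP,
    NetworkTopology,
    TopologyParams,
    sample_topology,
)

from tests import oracles


def test_split_graph_branches():
    """A dimer A-B regulating g splits into A->g and B->g with the same sign."""
    d = (0, 1)
    topo = NetworkTopology(
        3, frozenset({d}),
        frozenset({(d, 2, SIGN_REP), (d, 0, SIGN_ACT), (d, 1, SIGN_ACT)}),
    )
    g = split_graph(topo)
    assert g.number_of_edges() == 6
    assert g.has_edge(0, 2) and g.has_edge(1, 2)
    assert all(d_["sign"] == SIGN_REP for d_ in g[0][2].values())


def test_pair_entropy_cases():
    # single path -> 0 bits; opposite-sign paths -> 1 bit
    topo, _, expected = make_toy_network("mixed_paths")
    g = split_graph(topo)
    src, dst, bits = expected["pair_entropy_bits"]
    assert pair_entropy(g, src, dst) == pytest.approx(bits)
    assert pair_entropy(g, 0, 1) == 0.0  # only the direct activating path
    # two repressing edges in series -> even parity -> positive, entropy 0
    chain = NetworkTopology(
        3, frozenset(),
        frozenset({(0, 1, SIGN_REP), (1, 2, SIGN_REP), (2, 0, SIGN_ACT)}),
    )
    signs = oracles.simple_path_signs(chain, 0, 2)
    assert signs == [1]
    assert pair_entropy(split_graph(chain), 0, 2) == 0.0


def test_autoregulation_counting():
    d = (0, 1)
    topo = NetworkTopology(
        2, frozenset({d}),
        frozenset({(d, 0, SIGN_ACT), (d, 1, SIGN_ACT)}),
    )
    assert count_autoregulation(topo) == (2, 0)  # both subunits self-regulated
    mono = NetworkTopology(2, frozenset(), frozenset({(0, 0, SIGN_REP), (0, 1, SIGN_ACT)}))
    assert count_autoregulation(mono) == (0, 1)
    clean = NetworkTopology(2, frozenset(), frozenset({(0, 1, SIGN_ACT), (1, 0, SIGN_ACT)}))
    assert count_autoregulation(clean) == (0, 0)


def test_homodimer_autoregulation_counts_twice():
    d = (0, 0)
    topo = NetworkTopology(
        2, frozenset({d}),
        frozenset({(d, 0, SIGN_ACT), (d, 1, SIGN_ACT)}),
    )
    assert count_autoregulation(topo) == (2, 0)


@pytest.mark.parametrize("seed", range(30))
def test_descriptors_match_bruteforce(seed):
    """Entropy, autoregulation and similarity agree with an independent
    recomputation on random networks."""
    f_dim = (0.0, 0.3, 0.6)[seed % 3]
    topo = sample_topology(TopologyParams(6, f_dim, 2.0, 0.5), seed)
    assert count_autoregulation(topo) == oracles.autoregulation_counts(topo)
    g = split_graph(topo)
    for src in range(6):
        for dst in range(6):
            if src != dst:
                assert pair_entropy(g, src, dst) == pytest.approx(
                    oracles.pair_entropy_bits(topo, src, dst)
                )


def test_regulation_entropy_monomeric_equals_unsplit():
    """Splitting is the identity on monomeric networks, so the per-node
    entropies equal a direct no-split computation."""
    topo = sample_topology(TopologyParams(6, 0.0, 2.0, 0.5), 17)
    ent = regulation_entropy(topo)
    for node in range(6):
        ref = np.mean([
            oracles.pair_entropy_bits(topo, other, node)
            for other in range(6) if other != node
        ])
        assert ent[node] == pytest.approx(ref)
    assert np.all(ent >= 0) and np.all(ent <= 1)


def test_similarity_reference_values():
    # identical regulator target sets -> 1; disjoint -> 0; {a,b} vs {b,c} -> 1/3
    t1 = NetworkTopology(
        3, frozenset(),
        frozenset({(0, 1, SIGN_ACT), (0, 2, SIGN_ACT),
                   (1, 1, SIGN_ACT), (1, 2, SIGN_ACT), (2, 0, SIGN_ACT)}),
    )
    # regulators 0 and 1 share {(1,+),(2,+)} exactly
    _, mx = interaction_similarity(t1, kind="regulatory")
    assert mx == pytest.approx(1.0)
    t2 = NetworkTopology(
        4, frozenset(),
        frozenset({(0, 0, SIGN_ACT), (0, 1, SIGN_ACT),
                   (1, 1, SIGN_ACT), (1, 2, SIGN_ACT), (2, 3, SIGN_ACT)}),
    )
    # targets of 0: {0,1}; of 1: {1,2} -> 1 shared, 2 different -> 1/3
    sims = []
    for a, b in [({(0, SIGN_ACT), (1, SIGN_ACT)}, {(1, SIGN_ACT), (2, SIGN_ACT)})]:
        sims.append(len(a & b) / (len(a ^ b) + len(a & b)))
    assert sims[0] == pytest.approx(1 / 3)
    mean, mx = interaction_similarity(t2, kind="regulatory")
    assert 0.0 <= mean <= mx <= 1.0


@pytest.mark.parametrize("kind", ["dimer", "regulatory", "both"])
@pytest.mark.parametrize("seed", range(5))
def test_similarity_bounds_and_symmetry(kind, seed):
    topo = sample_topology(TopologyParams(6, 0.6, 4.0, 0.5), seed)
    mean, mx = interaction_similarity(topo, kind=kind)
    assert 0.0 <= mean <= mx <= 1.0


def test_regulator_classes():
    d = (0, 1)
    topo = NetworkTopology(
        3, frozenset({d, (1, 2)}),
        frozenset({(d, 0, SIGN_REP), (d, 1, SIGN_REP), ((1, 2), 2, SIGN_ACT)}),
    )
    assert regulator_class(topo, d) == PURE_REP
    assert regulator_class(topo, (1, 2)) == PURE_ACT
    mixed = NetworkTopology(
        2, frozenset(),
        frozenset({(0, 0, SIGN_ACT), (0, 1, SIGN_REP), (1, 1, SIGN_ACT)}),
    )
    assert regulator_class(mixed, 0) == MIXED
    # an edgeless dimer only sequesters its subunits
    lonely = NetworkTopology(
        3, frozenset({d, (2, 2)}),
        frozenset({(d, g, SIGN_ACT) for g in range(3)}),
    )
    assert regulator_class(lonely, (2, 2)) == NO_EDGES
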