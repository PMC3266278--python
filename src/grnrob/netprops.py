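"""Topological descriptors: regulation entropy, autoregulation, redundancy.

All descriptors operate on the *split* regulatory graph in which each
dimer-level edge is replaced by two monomer-level branches: a dimer A-B
regulating gene g contributes edges A->g and B->g carrying the dimer edge's
sign.  The split graph is a multigraph — a homodimer A-A regulating g yields
two parallel A->g edges, and both branches of a dimer count as distinct
paths.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from .topology import SIGN_ACT, SIGN_REP, NetworkTopology, Regulator

__all__ = [
    "split_graph",
    "pair_entropy",
    "regulation_entropy",
    "count_autoregulation",
    "interaction_similarity",
    "regulator_class",
    "PURE_ACT",
    "PURE_REP",
    "MIXED",
]

PURE_ACT = "pure_activator"
PURE_REP = "pure_repressor"
MIXED = "mixed"
NO_EDGES = "none"


def split_graph(topo: NetworkTopology) -> nx.MultiDiGraph:
    """Monomer-level signed multigraph obtained by splitting dimer regulators."""
    g = nx.MultiDiGraph()
    g.add_nodes_from(range(topo.n_prot))
    for r, tgt, sign in topo.sorted_edges():
        subunits = (r,) if isinstance(r, int) else tuple(r)
        for u in subunits:
            g.add_edge(u, tgt, sign=sign)
    return g


def _binary_entropy(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return float(-p * np.log2(p) - (1 - p) * np.log2(1 - p))


def pair_entropy(g: nx.MultiDiGraph, src: int, dst: int) -> float:
    """Sign entropy (bits) over all simple regulatory paths ``src -> dst``.

    A path is positive when it traverses an even number of repressing edges,
    negative otherwise; the entropy is the binary entropy of the resulting
    sign fractions.  No path at all gives 0.
    """
    n_pos = n_neg = 0
    for path in nx.all_simple_edge_paths(g, src, dst):
        n_rep = sum(1 for (u, v, k) in path if g.edges[u, v, k]["sign"] == SIGN_REP)
        if n_rep % 2 == 0:
            n_pos += 1
        else:
            n_neg += 1
    total = n_pos + n_neg
    if total == 0:
        return 0.0
    return _binary_entropy(n_pos / total)


def regulation_entropy(topo: NetworkTopology) -> np.ndarray:
    """Per-node regulation entropy: the mean, over all other nodes, of the
    path-sign entropy of that node's regulation by the other node."""
    g = split_graph(topo)
    n = topo.n_prot
    out = np.zeros(n)
    for node in range(n):
        vals = [pair_entropy(g, other, node) for other in range(n) if other != node]
        out[node] = float(np.mean(vals)) if vals else 0.0
    return out


def count_autoregulation(topo: NetworkTopology) -> tuple:
    """Counts of direct activating / repressing self-edges on the split graph.

    A dimer A-B regulating both A and B contributes two autoregulatory
    interactions; multiplicity counts (a homodimer A-A regulating A adds 2).
    """
    g = split_graph(topo)
    n_act = n_rep = 0
    for u, v, data in g.edges(data=True):
        if u == v:
            if data["sign"] == SIGN_ACT:
                n_act += 1
            else:
                n_rep += 1
    return n_act, n_rep


def _dimer_partner_set(topo: NetworkTopology, p: int) -> set:
    out = set()
    for i, j in topo.dimers:
        if i == p:
            out.add(("ppi", j))
        if j == p:
            out.add(("ppi", i))
    return out


def _split_reg_set(topo: NetworkTopology, p: int) -> set:
    out = set()
    for r, tgt, sign in topo.reg_edges:
        subunits = {r} if isinstance(r, int) else set(r)
        if p in subunits:
            out.add(("reg", tgt, sign))
    return out


def interaction_similarity(topo: NetworkTopology, kind: str = "both") -> tuple:
    """Mean and maximum pairwise interaction similarity (redundancy proxy).

    Similarity of two interaction sets is ``|shared| / (|different| +
    |shared|)`` — the Jaccard index — and is 0 when both sets are empty.
    ``kind='regulatory'`` compares the active regulators by their signed
    target sets; ``kind='dimer'`` compares proteins by their dimerization
    partners; ``kind='both'`` compares proteins by the union of partner set
    and split regulatory targets.
    """
    if kind == "regulatory":
        entities = topo.regulators
        sets = [set((g, s) for _, g, s in topo.edges_of(r)) for r in entities]
    elif kind == "dimer":
        entities = topo.proteins
        sets = [_dimer_partner_set(topo, p) for p in entities]
    elif kind == "both":
        entities = topo.proteins
        sets = [
            _dimer_partner_set(topo, p) | _split_reg_set(topo, p)
            for p in entities
        ]
    else:
        raise ValueError(f"unknown kind {kind!r}")
    if len(entities) < 2:
        raise ValueError("need at least two entities to compare")
    sims = []
    for a, b in itertools.combinations(sets, 2):
        union = len(a | b)
        sims.append(len(a & b) / union if union else 0.0)
    return float(np.mean(sims)), float(np.max(sims))


def regulator_class(topo: NetworkTopology, regulator: Regulator) -> str:
    """Classify a regulator by the signs of all its regulatory interactions:
    pure repressor, pure activator, or mixed.  A dimer that happens to carry
    no regulatory edge (it only sequesters its subunits) is classed ``none``
    and excluded from sign-based comparisons."""
    signs = {s for _, _, s in topo.edges_of(regulator)}
    if not signs:
        return NO_EDGES
    if signs == {SIGN_ACT}:
        return PURE_ACT
    if signs == {SIGN_REP}:
        return PURE_REP
    return MIXED
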