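"""Random gene-regulatory network topologies with dimerizing transcription factors.

A network over ``n_prot`` proteins consists of

* a set of transcription-factor dimers (unordered protein pairs, homodimers
  allowed), and
* signed regulatory edges from a *regulator* to a target gene.  In dimeric
  networks the regulators are the dimers; in purely monomeric networks
  (``f_dim = 0``) the monomers regulate directly.

Topologies are sampled by independent Bernoulli draws: each of the
``n(n+1)/2`` candidate dimers is included with probability ``f_dim`` and each
(regulator, gene) pair carries a regulatory edge with probability
``f_regint / n_regulators``, so the expected in-degree per gene equals
``f_regint``.  Every gene is guaranteed at least one incoming regulatory edge
(orphan genes are repaired with a single uniformly chosen regulator).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "SIGN_ACT",
    "SIGN_REP",
    "Regulator",
    "TopologyParams",
    "NetworkTopology",
    "MutationCandidates",
    "sample_topology",
    "enumerate_mutation_candidates",
    "topology_to_tsv",
    "topology_from_tsv",
    "topology_to_json",
    "topology_from_json",
]

SIGN_ACT = 1
SIGN_REP = -1

#: A regulator is either a monomer (protein index) or a dimer (ordered pair
#: ``(i, j)`` with ``i <= j``).
Regulator = Union[int, tuple]

# presets used in the simulation study; any in-range value is accepted
PRESET_F_DIM = (0.0, 0.3, 0.6)
PRESET_F_REGINT = (2.0, 4.0)
PRESET_F_ACT = (0.25, 0.5, 0.75)


@dataclass(frozen=True)
class TopologyParams:
    """Ensemble-level topology parameters.

    Parameters
    ----------
    n_prot:
        Number of proteins (genes); the study uses 6.
    f_dim:
        Target fraction of realized dimers out of all ``n(n+1)/2`` candidate
        pairs (homodimers included).
    f_regint:
        Mean number of regulators per target gene.
    f_act:
        Probability that a regulatory edge is activating (else repressing).
    """

    n_prot: int = 6
    f_dim: float = 0.3
    f_regint: float = 2.0
    f_act: float = 0.5

    def __post_init__(self) -> None:
        if self.n_prot < 2:
            raise ValueError("n_prot must be >= 2")
        if not 0.0 <= self.f_dim <= 1.0:
            raise ValueError("f_dim must be in [0, 1]")
        if self.f_regint <= 0:
            raise ValueError("f_regint must be > 0")
        if not 0.0 <= self.f_act <= 1.0:
            raise ValueError("f_act must be in [0, 1]")

    @property
    def n_candidate_dimers(self) -> int:
        return (self.n_prot * self.n_prot + self.n_prot) // 2


def _norm_dimer(i: int, j: int) -> tuple:
    return (i, j) if i <= j else (j, i)


def _regulator_key(r: Regulator) -> tuple:
    return (r,) if isinstance(r, int) else tuple(r)


@dataclass(frozen=True)
class NetworkTopology:
    """A concrete sampled network.

    ``reg_edges`` is a frozenset of ``(regulator, gene, sign)`` triples with
    sign in ``{SIGN_ACT, SIGN_REP}``.  At most one edge exists per
    (regulator, gene) pair, so Hill parameters can be keyed on the pair.
    """

    n_prot: int
    dimers: frozenset = field(default_factory=frozenset)
    reg_edges: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for d in self.dimers:
            i, j = d
            if not (0 <= i <= j < self.n_prot):
                raise ValueError(f"malformed dimer {d}")
        seen_pairs = set()
        for r, g, s in self.reg_edges:
            if s not in (SIGN_ACT, SIGN_REP):
                raise ValueError(f"bad sign {s}")
            if not 0 <= g < self.n_prot:
                raise ValueError(f"bad target gene {g}")
            if not isinstance(r, int):
                if tuple(r) not in self.dimers:
                    raise ValueError(f"regulator {r} is not a network dimer")
            if (r, g) in seen_pairs:
                raise ValueError(f"duplicate regulatory pair {(r, g)}")
            seen_pairs.add((r, g))

    def unregulated_genes(self) -> list:
        """Genes with no incoming regulatory edge.

        Freshly sampled topologies never have any (the sampler repairs
        orphans), but a regulatory mutation may legitimately strip a gene of
        its only regulator — such genes simply decay to zero expression.
        """
        regulated = {g for _, g, _ in self.reg_edges}
        return [g for g in range(self.n_prot) if g not in regulated]

    # -- derived views ----------------------------------------------------
    @property
    def proteins(self) -> list:
        return list(range(self.n_prot))

    @property
    def is_monomeric(self) -> bool:
        return len(self.dimers) == 0

    @property
    def regulators(self) -> list:
        """Active regulator set: sorted dimers, or all monomers if none."""
        if self.dimers:
            return sorted(self.dimers)
        return list(range(self.n_prot))

    @property
    def n_dim(self) -> int:
        return len(self.dimers)

    @property
    def realized_f_dim(self) -> float:
        n = self.n_prot
        return self.n_dim / (0.5 * n * n + 0.5 * n)

    def sorted_edges(self) -> list:
        return sorted(self.reg_edges, key=lambda e: (e[1], _regulator_key(e[0]), e[2]))

    def edges_of(self, regulator: Regulator) -> list:
        r = regulator if isinstance(regulator, int) else tuple(regulator)
        return [e for e in self.sorted_edges() if e[0] == r]

    def targets_of(self, regulator: Regulator) -> set:
        return {g for _, g, _ in self.edges_of(regulator)}


def sample_topology(
    params: TopologyParams, seed, max_retries: int = 1000
) -> NetworkTopology:
    """Draw one random topology.

    Bernoulli-samples the dimer set and the regulatory edges, then repairs
    orphan genes with one uniformly chosen regulator (sign drawn from
    ``f_act``).  If ``f_dim > 0`` but no dimer is realized the whole draw is
    repeated, up to ``max_retries`` times.  Deterministic given the seed
    (``seed`` may be an int, a ``SeedSequence`` or a ``Generator``).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = params.n_prot
    candidates = [(i, j) for i in range(n) for j in range(i, n)]
    for _ in range(max_retries):
        mask = rng.random(len(candidates)) < params.f_dim
        dimers = {c for c, m in zip(candidates, mask) if m}
        if params.f_dim > 0 and not dimers:
            continue
        regulators: list = sorted(dimers) if dimers else list(range(n))
        p_edge = min(1.0, params.f_regint / len(regulators))
        edges = set()
        for r in regulators:
            for g in range(n):
                if rng.random() < p_edge:
                    sign = SIGN_ACT if rng.random() < params.f_act else SIGN_REP
                    edges.add((r, g, sign))
        regulated = {g for _, g, _ in edges}
        for g in range(n):  # minimal orphan repair
            if g not in regulated:
                r = regulators[int(rng.integers(len(regulators)))]
                sign = SIGN_ACT if rng.random() < params.f_act else SIGN_REP
                edges.add((r, g, sign))
        topo = NetworkTopology(n, frozenset(dimers), frozenset(edges))
        assert not topo.unregulated_genes()
        return topo
    raise RuntimeError(
        f"no dimer realized in {max_retries} draws at f_dim={params.f_dim}"
    )


@dataclass
class MutationCandidates:
    """Exhaustive lists of legal structure-preserving mutations.

    ``ppi_swaps``: pairs ``(old_dimer, new_dimer)`` where the new dimer shares
    one protein with the old one and is absent from the network.
    ``reg_swaps``: triples ``(regulator, old_target, new_target)`` where the
    regulator does not yet regulate ``new_target``.  An empty list flags a
    saturated network (no legal mutation of that type).
    """

    ppi_swaps: list = field(default_factory=list)
    reg_swaps: list = field(default_factory=list)

    @property
    def ppi_saturated(self) -> bool:
        return len(self.ppi_swaps) == 0

    @property
    def reg_saturated(self) -> bool:
        return len(self.reg_swaps) == 0


def enumerate_mutation_candidates(topo: NetworkTopology) -> MutationCandidates:
    """List every legal dimer swap and every legal regulatory retarget."""
    ppi = []
    for d in sorted(topo.dimers):
        seen = set()
        for anchor in set(d):
            for c in range(topo.n_prot):
                new = _norm_dimer(anchor, c)
                if new == d or new in topo.dimers or new in seen:
                    continue
                seen.add(new)
                ppi.append((d, new))
    reg = []
    for r, g, _ in sorted(
        topo.reg_edges, key=lambda e: (_regulator_key(e[0]), e[1], e[2])
    ):
        targets = topo.targets_of(r)
        for g_new in range(topo.n_prot):
            if g_new not in targets:
                reg.append((r, g, g_new))
    return MutationCandidates(ppi_swaps=ppi, reg_swaps=reg)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_SIGN_CHAR = {SIGN_ACT: "+", SIGN_REP: "-"}
_CHAR_SIGN = {"+": SIGN_ACT, "-": SIGN_REP}


def _reg_str(r: Regulator) -> str:
    return str(r) if isinstance(r, int) else f"{r[0]}:{r[1]}"


def _reg_parse(s: str) -> Regulator:
    if ":" in s:
        i, j = s.split(":")
        return (int(i), int(j))
    return int(s)


def topology_to_tsv(topo: NetworkTopology) -> str:
    """Line-oriented TSV: a ``[dimers]`` section then an ``[edges]`` section."""
    lines = [f"# n_prot\t{topo.n_prot}", "[dimers]"]
    lines += [f"{i}\t{j}" for i, j in sorted(topo.dimers)]
    lines.append("[edges]")
    lines += [
        f"{_reg_str(r)}\t{g}\t{_SIGN_CHAR[s]}" for r, g, s in topo.sorted_edges()
    ]
    return "\n".join(lines) + "\n"


def topology_from_tsv(text: str) -> NetworkTopology:
    n_prot = None
    dimers, edges = set(), set()
    section = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("# n_prot"):
            n_prot = int(line.split("\t")[1])
        elif line == "[dimers]":
            section = "dimers"
        elif line == "[edges]":
            section = "edges"
        elif section == "dimers":
            i, j = line.split("\t")
            dimers.add((int(i), int(j)))
        elif section == "edges":
            r, g, s = line.split("\t")
            edges.add((_reg_parse(r), int(g), _CHAR_SIGN[s]))
    if n_prot is None:
        raise ValueError("missing '# n_prot' header line")
    return NetworkTopology(n_prot, frozenset(dimers), frozenset(edges))


def topology_to_json(
    topo: NetworkTopology, params: TopologyParams | None = None, seed=None
) -> str:
    obj = {
        "n_prot": topo.n_prot,
        "dimers": sorted(list(d) for d in topo.dimers),
        "reg_edges": [
            [_reg_str(r), g, _SIGN_CHAR[s]] for r, g, s in topo.sorted_edges()
        ],
    }
    if params is not None:
        obj["params"] = {
            "n_prot": params.n_prot,
            "f_dim": params.f_dim,
            "f_regint": params.f_regint,
            "f_act": params.f_act,
        }
    if seed is not None:
        obj["seed"] = seed
    return json.dumps(obj, indent=1)


def topology_from_json(text: str):
    """Return ``(topology, params_or_None, seed_or_None)``."""
    obj = json.loads(text)
    topo = NetworkTopology(
        obj["n_prot"],
        frozenset(tuple(d) for d in obj["dimers"]),
        frozenset(
            (_reg_parse(r), int(g), _CHAR_SIGN[s]) for r, g, s in obj["reg_edges"]
        ),
    )
    params = None
    if "params" in obj:
        params = TopologyParams(**obj["params"])
    return topo, params, obj.get("seed")
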