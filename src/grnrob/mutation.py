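"""Structure-changing mutations that preserve interaction counts.

Two operators are defined, both keeping the number of interactions fixed so
wildtype and mutant are directly comparable:

* **PPI mutation** — an existing dimer A-B is replaced by a dimer A-C that
  shares one subunit and is absent from the network; the new dimer inherits
  every regulatory edge of the old one, with the same sign and Hill
  parameters.
* **Regulatory mutation** — one regulator->gene edge is retargeted to a gene
  the regulator did not yet regulate; sign and Hill parameters move with the
  edge, and the dimer set is untouched.

For purely monomeric networks only regulatory mutations apply.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dynamics import KineticParams
from .topology import (
    MutationCandidates,
    NetworkTopology,
    Regulator,
    enumerate_mutation_candidates,
)

__all__ = ["MutationRecord", "AppliedMutation", "mutate_ppi", "mutate_regulatory",
           "random_mutation"]


@dataclass
class MutationRecord:
    """Bookkeeping for one applied mutation (``d_mut`` filled after the
    mutant has been simulated and scored)."""

    mtype: str  # "ppi" | "regulatory"
    edited_from: tuple
    edited_to: tuple
    affected_regulator: Regulator
    d_mut: float | None = None
    classification: str | None = None


@dataclass
class AppliedMutation:
    """A mutant network instance plus the species correspondence to its
    parent (identity except for the swapped dimer, for PPI mutations)."""

    topo: NetworkTopology
    params: KineticParams
    record: MutationRecord
    species_map: dict = field(default_factory=dict)  # parent species -> mutant species


def _copy_params(params: KineticParams) -> KineticParams:
    return replace(params, b=dict(params.b), K=dict(params.K))


def mutate_ppi(
    topo: NetworkTopology, params: KineticParams, which: tuple
) -> AppliedMutation:
    """Apply the dimer swap ``which = (old_dimer, new_dimer)``.

    The regulatory adjacency is preserved up to relabelling ``old -> new``;
    all Hill parameters carry over.
    """
    old, new = which
    old, new = tuple(old), tuple(new)
    if old not in topo.dimers:
        raise ValueError(f"{old} is not a dimer of the network")
    if new in topo.dimers:
        raise ValueError(f"swap target {new} already present")
    if not set(old) & set(new):
        raise ValueError("swap must keep one shared protein")
    dimers = (set(topo.dimers) - {old}) | {new}
    edges = {
        ((new if r == old else r), g, s) for r, g, s in topo.reg_edges
    }
    mut_params = _copy_params(params)
    for store in (mut_params.b, mut_params.K):
        for (r, g) in list(store):
            if r == old:
                store[(new, g)] = store.pop((r, g))
    mut_topo = NetworkTopology(topo.n_prot, frozenset(dimers), frozenset(edges))
    species_map = {s: s for s in range(topo.n_prot)}
    for d in topo.dimers:
        species_map[d] = new if d == old else d
    rec = MutationRecord("ppi", old, new, affected_regulator=old)
    return AppliedMutation(mut_topo, mut_params, rec, species_map)


def mutate_regulatory(
    topo: NetworkTopology, params: KineticParams, which: tuple
) -> AppliedMutation:
    """Apply the edge retarget ``which = (regulator, old_target, new_target)``."""
    r, g_old, g_new = which
    r = r if isinstance(r, int) else tuple(r)
    matching = [e for e in topo.reg_edges if e[0] == r and e[1] == g_old]
    if not matching:
        raise ValueError(f"no edge from {r} to gene {g_old}")
    if g_new in topo.targets_of(r):
        raise ValueError(f"{r} already regulates gene {g_new}")
    (_, _, sign) = matching[0]
    edges = (set(topo.reg_edges) - {(r, g_old, sign)}) | {(r, g_new, sign)}
    mut_params = _copy_params(params)
    for store in (mut_params.b, mut_params.K):
        store[(r, g_new)] = store.pop((r, g_old))
    mut_topo = NetworkTopology(topo.n_prot, topo.dimers, frozenset(edges))
    species_map = {s: s for s in range(topo.n_prot)}
    species_map.update({d: d for d in topo.dimers})
    rec = MutationRecord("regulatory", (r, g_old, sign), (r, g_new, sign), r)
    return AppliedMutation(mut_topo, mut_params, rec, species_map)


def random_mutation(
    topo: NetworkTopology,
    params: KineticParams,
    mtype: str,
    rng: np.random.Generator,
    candidates: MutationCandidates | None = None,
) -> AppliedMutation | None:
    """Apply one uniformly chosen mutation of the given type.

    Returns ``None`` when the candidate list is empty (saturated network, or
    a PPI mutation requested on a monomeric network).
    """
    if candidates is None:
        candidates = enumerate_mutation_candidates(topo)
    pool = candidates.ppi_swaps if mtype == "ppi" else candidates.reg_swaps
    if mtype == "ppi" and topo.is_monomeric:
        return None
    if not pool:
        return None
    which = pool[int(rng.integers(len(pool)))]
    if mtype == "ppi":
        return mutate_ppi(topo, params, which)
    return mutate_regulatory(topo, params, which)
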