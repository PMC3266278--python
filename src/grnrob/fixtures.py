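"""Synthetic fixtures: hand-solvable networks and planted conservation data.

Everything here is generated, seed-pinned stand-in data — no external
databases or downloads.  The toy networks have closed-form steady states
used as oracles in the test suite; the conservation fixture writes a
synthetic protein/DNA structure plus homolog alignments with a planted
conservation difference at the DNA-contact positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dynamics import GAMMA_MONO, KineticParams
from .topology import SIGN_ACT, SIGN_REP, NetworkTopology

__all__ = [
    "TOY_NETWORKS",
    "make_toy_network",
    "ConservationFixture",
    "make_conservation_fixture",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# toy networks with closed-form steady states
# ---------------------------------------------------------------------------

def _const_act():
    """Gene 1 driven by a self-sustaining activator (gene 0).

    Gene 0 activates itself with a near-saturating Hill term, settling at
    x0* = b00/gamma - K00; gene 1 then settles at the Hill production over
    decay balance, approaching b10/gamma at saturation.
    """
    topo = NetworkTopology(
        2,
        frozenset(),
        frozenset({(0, 0, SIGN_ACT), (0, 1, SIGN_ACT)}),
    )
    b = {(0, 0): 2400.0, (0, 1): 400.0}
    K = {(0, 0): 10.0, (0, 1): 10.0}
    params = KineticParams(b=b, K=K)
    g = GAMMA_MONO
    x0 = b[(0, 0)] / g - K[(0, 0)]
    x1 = b[(0, 1)] * x0 / (K[(0, 1)] + x0) / g
    return topo, params, {
        "steady_state": np.array([x0, x1]),
        "saturation_limit": b[(0, 1)] / g,
    }


def _dimer_pair():
    """One dimer, used to check detailed balance of the dimer equation.

    With gamma_dim = 0 and the monomers held fixed, the dimer equation is in
    equilibrium exactly at x01 = (k_on / k_off) * x0 * x1.
    """
    d = (0, 1)
    topo = NetworkTopology(
        2,
        frozenset({d}),
        frozenset({(d, 0, SIGN_ACT), (d, 1, SIGN_ACT)}),
    )
    params = KineticParams(
        k_on=1.0, gamma_dim=0.0,
        b={(d, 0): 100.0, (d, 1): 100.0},
        K={(d, 0): 50.0, (d, 1): 50.0},
    )
    return topo, params, {
        "equilibrium_ratio": params.k_on / params.k_off,
    }


def _repression_cascade():
    """Gene 0 sustains itself and represses gene 1 (two-gene cascade)."""
    topo = NetworkTopology(
        2,
        frozenset(),
        frozenset({(0, 0, SIGN_ACT), (0, 1, SIGN_REP)}),
    )
    b = {(0, 0): 2400.0, (0, 1): 400.0}
    K = {(0, 0): 10.0, (0, 1): 100.0}
    params = KineticParams(b=b, K=K)
    g = GAMMA_MONO
    x0 = b[(0, 0)] / g - K[(0, 0)]
    x1 = b[(0, 1)] * K[(0, 1)] / (K[(0, 1)] + x0) / g
    return topo, params, {"steady_state": np.array([x0, x1])}


def _mixed_paths():
    """Three monomers whose 0->2 paths have opposite signs.

    Paths from node 0 to node 2: the direct repressing edge (negative) and
    the activating route through node 1 (positive) — a 50/50 sign split, so
    the pair's regulation entropy is exactly 1 bit.
    """
    edges = {
        (0, 1, SIGN_ACT),
        (1, 2, SIGN_ACT),
        (0, 2, SIGN_REP),
        (2, 0, SIGN_ACT),
    }
    topo = NetworkTopology(3, frozenset(), frozenset(edges))
    b = {(r, g): 100.0 for r, g, _ in edges}
    K = {(r, g): 50.0 for r, g, _ in edges}
    params = KineticParams(b=b, K=K)
    return topo, params, {"pair_entropy_bits": (0, 2, 1.0)}


TOY_NETWORKS = {
    "const_act": _const_act,
    "dimer_pair": _dimer_pair,
    "repression_cascade": _repression_cascade,
    "mixed_paths": _mixed_paths,
}


def make_toy_network(name: str):
    """Return ``(topology, params, expected)`` for a registered toy network."""
    try:
        factory = TOY_NETWORKS[name]
    except KeyError:
        raise KeyError(
            f"unknown toy network {name!r}; known: {sorted(TOY_NETWORKS)}"
        ) from None
    return factory()


# ---------------------------------------------------------------------------
# synthetic conservation fixture (structure + homolog alignments)
# ---------------------------------------------------------------------------

def _pdb_atom(serial, name, resname, chain, resseq, xyz, element):
    x, y, z = xyz
    return (
        f"ATOM  {serial:5d} {name:^4s}{'':1s}{resname:>3s} {chain:1s}"
        f"{resseq:4d}{'':1s}   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


@dataclass
class ConservationFixture:
    """Synthetic structure + alignments with a planted conservation shift."""

    pdb_text: str
    alignments: dict  # group name -> list of aligned sequences
    contact_positions: list  # residue indices (1-based) near the DNA
    shift: float

    def write(self, out_dir) -> dict:
        """Write ``synthetic_tf.pdb`` and one FASTA per group; returns the
        paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        pdb = out / "synthetic_tf.pdb"
        pdb.write_text(self.pdb_text)
        paths["pdb"] = pdb
        for group, seqs in self.alignments.items():
            fa = out / f"synthetic_{group}_homologs.fasta"
            fa.write_text(
                "".join(f">{group}_sp{i}\n{s}\n" for i, s in enumerate(seqs))
            )
            paths[group] = fa
        return paths


def make_conservation_fixture(
    shift: float,
    rng=None,
    n_residues: int = 120,
    n_contact: int = 30,
    n_species: int = 20,
    base_sub_rate: float = 0.5,
) -> ConservationFixture:
    """Generate a synthetic TF structure and two homolog alignment groups.

    The protein backbone (CA atoms) runs along the x axis at 3.8 Angstrom
    spacing; a DNA strand of phosphate atoms lies 5 Angstrom away alongside
    the first ``n_contact`` residues, so exactly those residues contact DNA
    at the 10 Angstrom cutoff.  Each group's alignment substitutes the
    consensus residue with per-column probability ``base_sub_rate``, except
    at contact positions of the "dimeric" group where the rate is reduced by
    the factor ``exp(-shift)`` — planting higher conservation there.  With
    ``shift = 0`` the two groups are exchangeable.
    """
    if shift < 0:
        raise ValueError("shift must be >= 0")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    # two-segment backbone: the DNA-binding stretch lies alongside the
    # strand, the rest is displaced well beyond the cutoff
    lines, serial = [], 1
    for i in range(n_residues):
        y = 0.0 if i < n_contact else 50.0
        lines.append(_pdb_atom(serial, "CA", "ALA", "A", i + 1,
                               (3.8 * i, y, 0.0), "C"))
        serial += 1
    for i in range(n_contact):
        lines.append(_pdb_atom(serial, "P", "DA", "B", i + 1,
                               (3.8 * i, 5.0, 0.0), "P"))
        serial += 1
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"

    contact = list(range(1, n_contact + 1))
    aa = np.array(list(AMINO_ACIDS))
    alignments = {}
    for group in ("dimeric", "monomeric"):
        consensus = rng.choice(len(aa), size=n_residues)
        rates = np.full(n_residues, base_sub_rate)
        if group == "dimeric":
            rates[:n_contact] *= np.exp(-shift)
        seqs = []
        for _ in range(n_species):
            res = consensus.copy()
            mutate = rng.random(n_residues) < rates
            res[mutate] = rng.integers(len(aa), size=int(mutate.sum()))
            seqs.append("".join(aa[res]))
        alignments[group] = seqs
    return ConservationFixture(pdb_text, alignments, contact, shift)
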