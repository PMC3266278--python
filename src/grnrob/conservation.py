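"""Structure/conservation kernels for comparing monomeric and dimeric TFs.

The downstream question: are DNA-contacting residues of dimeric
transcription factors more conserved than those of monomeric ones?  Three
kernels support it:

* contact detection — a residue contacts DNA when any of its heavy atoms
  lies within a distance cutoff (default 10 Angstrom) of any DNA atom;
* per-column Shannon entropy of a homolog alignment (one sequence per
  species), low entropy meaning high conservation;
* a two-sample Kolmogorov-Smirnov comparison of pooled per-residue entropy
  values between the dimeric and monomeric groups.

Assembly of real TF sets (interaction databases, structure mapping, BLAST
homolog searches) is deliberately outside these kernels; see
:func:`homolog_search_stub`.  Synthetic fixtures exercising the kernels are
generated by :mod:`grnrob.fixtures`.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial import cKDTree
from scipy.stats import ks_2samp

__all__ = [
    "DNA_RESNAMES",
    "ResidueContactSet",
    "contact_residues",
    "load_structure_coords",
    "contact_residues_from_pdb",
    "column_entropy",
    "alignment_entropy",
    "pick_one_per_species",
    "compare_groups",
    "homolog_search_stub",
]

DNA_RESNAMES = {"DA", "DC", "DG", "DT", "DU", "A", "C", "G", "T", "U"}
GAP_CHARS = set("-.")
DEFAULT_CUTOFF = 10.0  # Angstrom
MAX_GAP_FRACTION = 0.5


@dataclass
class ResidueContactSet:
    """Per-residue DNA-contact flags at a given distance cutoff."""

    flags: dict  # residue id -> bool
    cutoff: float

    @property
    def contacting(self) -> list:
        return sorted(r for r, f in self.flags.items() if f)

    @property
    def non_contacting(self) -> list:
        return sorted(r for r, f in self.flags.items() if not f)


def contact_residues(
    protein_coords,
    protein_residue_ids,
    dna_coords,
    cutoff: float = DEFAULT_CUTOFF,
) -> ResidueContactSet:
    """Flag residues with any atom within ``cutoff`` of any DNA atom.

    ``protein_coords`` is an (n_atoms, 3) array, ``protein_residue_ids`` the
    parallel residue identifier per atom, ``dna_coords`` an (m_atoms, 3)
    array.
    """
    prot = np.asarray(protein_coords, dtype=float).reshape(-1, 3)
    dna = np.asarray(dna_coords, dtype=float).reshape(-1, 3)
    if dna.shape[0] == 0:
        raise ValueError("empty DNA coordinate set")
    if prot.shape[0] != len(protein_residue_ids):
        raise ValueError("one residue id per protein atom required")
    dmin, _ = cKDTree(dna).query(prot, k=1)
    flags: dict = {}
    for rid, d in zip(protein_residue_ids, dmin):
        flags[rid] = flags.get(rid, False) or (d <= cutoff)
    return ResidueContactSet(flags, cutoff)


def load_structure_coords(path):
    """Split a PDB file into protein and DNA heavy-atom coordinates.

    Returns ``(protein_coords, protein_residue_ids, dna_coords)``.  Residues
    are classified as DNA by residue name; hydrogens are ignored.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # fixture PDBs are minimal
        structure = PDBParser(QUIET=True).get_structure("s", str(path))
    prot_xyz, prot_rid, dna_xyz = [], [], []
    for model in structure:
        for chain in model:
            for residue in chain:
                is_dna = residue.get_resname().strip() in DNA_RESNAMES
                rid = (chain.id, residue.get_id()[1])
                for atom in residue:
                    if atom.element == "H":
                        continue
                    if is_dna:
                        dna_xyz.append(atom.coord)
                    else:
                        prot_xyz.append(atom.coord)
                        prot_rid.append(rid)
        break  # first model only
    return (
        np.array(prot_xyz, dtype=float).reshape(-1, 3),
        prot_rid,
        np.array(dna_xyz, dtype=float).reshape(-1, 3),
    )


def contact_residues_from_pdb(path, cutoff: float = DEFAULT_CUTOFF) -> ResidueContactSet:
    prot, rid, dna = load_structure_coords(path)
    return contact_residues(prot, rid, dna, cutoff)


def column_entropy(column, gap_chars=GAP_CHARS) -> float:
    """Shannon entropy (bits) of one alignment column, gaps excluded.

    Returns ``nan`` for an all-gap column (undefined)."""
    residues = [c.upper() for c in column if c not in gap_chars]
    if not residues:
        return float("nan")
    counts = Counter(residues)
    total = len(residues)
    return -sum(
        (c / total) * math.log2(c / total) for c in counts.values()
    )


def alignment_entropy(
    sequences, max_gap_fraction: float = MAX_GAP_FRACTION
) -> np.ndarray:
    """Per-column entropy profile of an alignment (list of equal-length
    strings).  Columns with more than ``max_gap_fraction`` gaps are skipped
    (``nan``)."""
    if not sequences:
        raise ValueError("empty alignment")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("sequences must be aligned (equal length)")
    out = np.empty(length)
    for i in range(length):
        col = [s[i] for s in sequences]
        gap_frac = sum(c in GAP_CHARS for c in col) / len(col)
        out[i] = float("nan") if gap_frac > max_gap_fraction else column_entropy(col)
    return out


def pick_one_per_species(records: dict, rng=None) -> list:
    """Reduce homolog sets to one randomly chosen sequence per species.

    ``records`` maps a species label to the list of that species' sequences;
    returns the selected sequences in sorted-species order.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    out = []
    for species in sorted(records):
        seqs = records[species]
        if not seqs:
            continue
        out.append(seqs[int(rng.integers(len(seqs)))])
    return out


def compare_groups(entropies_dimeric, entropies_monomeric):
    """Two-sample KS test on pooled per-residue entropy values.

    Returns ``(statistic, p_value)``.  Lower dimeric entropies (higher
    conservation) are the expected direction for DNA-contacting residues;
    running the same comparison on non-contacting residues is the control.
    """
    a = np.asarray(entropies_dimeric, dtype=float)
    b = np.asarray(entropies_monomeric, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def homolog_search_stub(*args, **kwargs):
    """Placeholder for the homolog-acquisition pipeline.

    The real analysis maps transcription factors annotated with DNA-binding
    activity (GO:0003700) and known protein interactions to solved
    structures, then gathers homologs by BLAST against NR at E-value 1e-25,
    keeping one sequence per species.  That pipeline needs external
    databases and is out of scope here; tests and examples run on generated
    fixtures instead (:mod:`grnrob.fixtures`).
    """
    raise NotImplementedError(
        "database-backed homolog acquisition is not part of this package; "
        "use grnrob.fixtures.make_conservation_fixture for synthetic inputs"
    )
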