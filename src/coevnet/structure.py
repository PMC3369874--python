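"""Structural context for residue networks: contacts, domains, accuracy.

Couplings are statements about alignment positions; this module places them
on a crystal structure. Distances between residues are closest-heavy-atom
distances (crystal structures carry no hydrogens, so any present are
excluded for comparability). Domain boundaries follow the four-domain
architecture of the 463-residue reference enzyme: domain 1 residues 1–154,
domain 2 155–256, domain 3 257–368, domain 4 369–463, with the shared
boundary residues (154, 256, 368) assigned to the lower-numbered domain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1
from scipy.spatial.distance import cdist

from .errors import (
    EmptyInputError,
    MissingChainError,
    MissingResidueError,
    UndefinedAccuracyError,
)

#: (domain, first_residue, last_residue); boundary residues belong to the
#: lower-numbered domain.
DOMAIN_RANGES = ((1, 1, 154), (2, 155, 256), (3, 257, 368), (4, 369, 463))


@dataclass
class StructureModel:
    """Heavy-atom coordinates of one chain, keyed by author residue number."""

    chain_id: str
    residues: dict[int, np.ndarray]
    atom_names: dict[int, list[str]] = field(default_factory=dict)
    resnames: dict[int, str] = field(default_factory=dict)

    def __contains__(self, resnum: int) -> bool:
        return resnum in self.residues

    def coords(self, resnum: int) -> np.ndarray:
        try:
            return self.residues[resnum]
        except KeyError:
            raise MissingResidueError(
                f"residue {resnum} not resolved in chain {self.chain_id!r}"
            )


def read_structure(path, chain: str = "A") -> StructureModel:
    """Parse PDB ATOM records of one chain into a :class:`StructureModel`.

    Only altloc blank/'A' atoms are kept; hydrogens (and deuteriums) are
    excluded; hetero residues and waters are skipped.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise EmptyInputError(f"no models/ATOM records in {path}")
    chain_ids = [c.id for c in model]
    if chain not in chain_ids:
        raise MissingChainError(
            f"chain {chain!r} not in {path} (available: {chain_ids})"
        )
    residues: dict[int, np.ndarray] = {}
    atom_names: dict[int, list[str]] = {}
    resnames: dict[int, str] = {}
    for res in model[chain]:
        hetflag, resseq, _ = res.id
        if hetflag.strip():
            continue
        coords, names = [], []
        for atom in res.get_unpacked_list():
            if atom.get_altloc() not in (" ", "A"):
                continue
            if atom.element in ("H", "D"):
                continue
            coords.append(atom.coord)
            names.append(atom.get_name())
        if coords:
            residues[resseq] = np.asarray(coords, dtype=float)
            atom_names[resseq] = names
            resnames[resseq] = res.get_resname()
    if not residues:
        raise EmptyInputError(f"no usable ATOM records for chain {chain!r} in {path}")
    return StructureModel(chain_id=chain, residues=residues,
                          atom_names=atom_names, resnames=resnames)


def min_atom_distance(m: StructureModel, res_i: int, res_j: int) -> float:
    """Minimum Euclidean distance (Å) over all atom pairs of two residues."""
    return float(cdist(m.coords(res_i), m.coords(res_j)).min())


def contact_map(m: StructureModel, positions) -> dict[tuple[int, int], float]:
    """Closest-atom distances for every unordered pair of ``positions``."""
    positions = sorted(set(positions))
    out: dict[tuple[int, int], float] = {}
    for a_idx, i in enumerate(positions):
        for j in positions[a_idx + 1:]:
            out[(i, j)] = min_atom_distance(m, i, j)
    return out


def assign_domain(ref_pos: int) -> int:
    """Domain (1–4) of a reference residue number; errors outside 1..463."""
    for dom, lo, hi in DOMAIN_RANGES:
        if lo <= ref_pos <= hi:
            return dom
    raise ValueError(f"residue number {ref_pos} outside 1..463")


def contact_accuracy(couplings, m: StructureModel, cutoff: float = 8.0) -> float:
    """Fraction of couplings whose closest-atom distance is <= ``cutoff`` Å.

    Couplings with an unresolved residue are skipped with a warning; if none
    are resolvable the accuracy is undefined.
    """
    resolved = 0
    close = 0
    skipped = []
    for i, j in couplings:
        if i not in m or j not in m:
            skipped.append((i, j))
            continue
        resolved += 1
        if min_atom_distance(m, i, j) <= cutoff:
            close += 1
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} coupling(s) with unresolved residues: "
            f"{skipped[:5]}{'...' if len(skipped) > 5 else ''}",
            stacklevel=2,
        )
    if resolved == 0:
        raise UndefinedAccuracyError("no coupling could be resolved on the structure")
    return close / resolved


def sequence_mismatches(m: StructureModel, ref_seq: str) -> list[tuple[int, str, str]]:
    """Positions where the structure's residue identity disagrees with ``ref_seq``.

    ``ref_seq`` is the ungapped reference sequence; residue number ``p``
    corresponds to ``ref_seq[p - 1]``. Returns (position, reference_aa,
    structure_aa) triples; mismatches are reported, never silently skipped.
    """
    out = []
    for resnum, resname in sorted(m.resnames.items()):
        if not 1 <= resnum <= len(ref_seq):
            continue
        struct_aa = protein_letters_3to1.get(resname.upper(), "X")
        if struct_aa != ref_seq[resnum - 1]:
            out.append((resnum, ref_seq[resnum - 1], struct_aa))
    return out
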