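import itertools

import numpy as np
import pytest

from coevnet.msa import Alignment


@pytest.fixture
def small_alignment():
    """Six diverse rows over eight columns, with gaps."""
    return Alignment([
        ("s1", "ACDEFG-K"),
        ("s2", "ACDEYGHK"),
        ("s3", "ACDWFG-K"),
        ("s4", "AC-EFGHK"),
        ("s5", "ACDEFAHK"),
        ("s6", "GCDEFGHK"),
    ])


def brute_force_maximal_cliques(g, min_size=2):
    """Independent oracle: test every vertex subset for completeness/maximality."""
    nodes = sorted(g.nodes)
    edges = {frozenset(e) for e in g.edges}

    def is_complete(sub):
        return all(frozenset(p) in edges for p in itertools.combinations(sub, 2))

    complete = [
        frozenset(sub)
        for r in range(1, len(nodes) + 1)
        for sub in itertools.combinations(nodes, r)
        if is_complete(sub)
    ]
    maximal = [
        c for c in complete
        if not any(c < other for other in complete)
    ]
    return sorted((c for c in maximal if len(c) >= min_size),
                  key=lambda c: (-len(c), tuple(sorted(c))))


@pytest.fixture
def brute_cliques():
    return brute_force_maximal_cliques


def _pdb_atom_line(serial, name, resname, chain, resseq, x, y, z,
                   element=None, altloc=" "):
    element = element or name[0]
    name_fmt = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:5d} {name_fmt}{altloc}{resname:>3s} {chain}{resseq:4d}"
        f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
    )


def write_pdb(path, residues, chain="A"):
    """Write a minimal PDB file.

    ``residues``: list of (resseq, resname, [(atom_name, x, y, z), ...]) or
    (resseq, resname, atoms, altloc) tuples.
    """
    lines = []
    serial = 1
    for entry in residues:
        resseq, resname, atoms = entry[:3]
        altloc = entry[3] if len(entry) > 3 else " "
        for (name, x, y, z) in atoms:
            lines.append(_pdb_atom_line(serial, name, resname, chain, resseq,
                                        x, y, z, altloc=altloc))
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def pdb_writer():
    return write_pdb
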