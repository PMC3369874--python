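"""Residue networks from reproducible couplings: maximal cliques and histograms.

A coupling set defines a simple undirected graph on residue positions. A
maximal clique in this graph is a set of residues that all pairwise covary
and cannot be extended — the densest notion of a coevolving residue network.
Enumeration uses the Bron–Kerbosch algorithm with pivoting (networkx); the
worst case is exponential, so a configurable node-count guard protects
interactive use. Joint-identity histograms summarize which residue-type
combinations actually occur at a pair of positions.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np

from .errors import DegenerateHistogramError
from .msa import AMINO_ACIDS, GAP_CODE, Alignment

#: Guard for the exponential worst case of clique enumeration.
MAX_CLIQUE_NODES = 5000


def build_graph(couplings) -> nx.Graph:
    """Simple undirected graph whose nodes are the coupling endpoints."""
    g = nx.Graph()
    g.add_edges_from((int(i), int(j)) for i, j in couplings)
    return g


def _sort_key(clique: frozenset):
    return (-len(clique), tuple(sorted(clique)))


def maximal_cliques(g: nx.Graph, min_size: int = 2,
                    max_nodes: int = MAX_CLIQUE_NODES) -> list[frozenset]:
    """All maximal cliques of ``g`` with at least ``min_size`` members.

    Returned largest-first, ties ordered by sorted member tuple, so the
    output is deterministic for a given edge set.
    """
    if g.number_of_nodes() > max_nodes:
        raise ValueError(
            f"graph has {g.number_of_nodes()} nodes, above the "
            f"max_nodes={max_nodes} guard for clique enumeration"
        )
    cliques = [frozenset(c) for c in nx.find_cliques(g) if len(c) >= min_size]
    return sorted(cliques, key=_sort_key)


def top_cliques(cliques: list[frozenset], n_top: int = 5) -> tuple[list[frozenset], set]:
    """The ``n_top`` largest cliques and the union of their members.

    Size ties are broken by lexicographic member order. If fewer cliques
    exist than requested, all are returned with a warning.
    """
    ranked = sorted((frozenset(c) for c in cliques), key=_sort_key)
    if len(ranked) < n_top:
        warnings.warn(
            f"only {len(ranked)} cliques available, fewer than n_top={n_top}",
            stacklevel=2,
        )
        selected = ranked
    else:
        selected = ranked[:n_top]
    union: set = set()
    for c in selected:
        union |= c
    return selected, union


def neighbor_list(selected: list[frozenset]) -> dict[int, set]:
    """Per-position union of co-members over the selected cliques."""
    out: dict[int, set] = {}
    for clique in selected:
        for p in clique:
            out.setdefault(p, set()).update(clique - {p})
    return out


def joint_identity_histogram(
    aln: Alignment,
    i: int,
    j: int,
    floor: float = 0.05,
) -> dict[tuple[str, str], float]:
    """Joint residue-identity frequencies for positions ``i`` and ``j``.

    Positions are 1-based (column index + 1, i.e. reference numbering on a
    reference-truncated alignment). Rows gapped in either column are
    dropped; cells below ``floor`` are removed and the remainder is
    renormalized to sum to 1 — in that order, so a dominant cell can end up
    at exactly 1.0.
    """
    xc = aln.codes[:, i - 1]
    xd = aln.codes[:, j - 1]
    both = (xc != GAP_CODE) & (xd != GAP_CODE)
    xc, xd = xc[both], xd[both]
    n = len(xc)
    if n == 0:
        raise DegenerateHistogramError(
            f"positions {i} and {j} share no mutually non-gapped rows"
        )
    pairs, counts = np.unique(xc.astype(np.int64) * 21 + xd, return_counts=True)
    freq = {
        (AMINO_ACIDS[p // 21], AMINO_ACIDS[p % 21]): c / n
        for p, c in zip(pairs.tolist(), counts.tolist())
    }
    surviving = {cell: f for cell, f in freq.items() if f >= floor}
    if not surviving:
        raise DegenerateHistogramError(
            f"no joint identity at positions {i},{j} reaches the {floor:.0%} floor"
        )
    total = sum(surviving.values())
    return {cell: f / total for cell, f in surviving.items()}


def verify_clique(g: nx.Graph, clique) -> bool:
    """True iff ``clique`` is complete in ``g`` and maximal (no extension)."""
    members = set(clique)
    for u in members:
        if not members - {u} <= set(g.neighbors(u)):
            return False
    candidates = set(g.nodes) - members
    for v in candidates:
        if members <= set(g.neighbors(v)):
            return False
    return True
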