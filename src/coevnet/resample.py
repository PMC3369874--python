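"""Split-half consensus resampling of coevolution scores.

Raw pair scores from a single alignment are sensitive to which sequences
happen to be included. The protocol here converts them into a reproducibility
percentage: each iteration draws a random subset of sequences (default 300),
halves it into two disjoint 150-sequence "splits", scores each split with the
bivariate Z-score, takes each split's top-k couplings (k defaults to one less
than the number of eligible positions, generalizing 462 picks out of 463
positions), and records the *consensus* — couplings present in both splits'
top-k. Over many iterations (default 100) each pair accumulates a count of
0..iterations; only pairs in the consensus of every iteration (100%
reproducible) feed the downstream network analysis.

Couplings are labeled with 1-based positions (column index + 1), matching
reference residue numbering when the alignment has been truncated to a
reference sequence.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coupling import (
    GAP_THRESHOLD,
    PairScoreMatrix,
    eligible_positions,
    nmi_matrix,
    znmi_matrix,
)
from .errors import ConfigError, InsufficientDataError
from .msa import Alignment

logger = logging.getLogger(__name__)

#: A coupling set: unordered pairs of 1-based positions, stored as (i, j), i < j.
CouplingSet = frozenset


def pair_universe_size(n_positions: int) -> int:
    """Number of unordered column pairs over ``n_positions`` eligible positions."""
    return n_positions * (n_positions - 1) // 2


def sample_and_split(
    aln: Alignment,
    subset_size: int = 300,
    seed=None,
    rng: np.random.Generator | None = None,
) -> tuple[Alignment, Alignment]:
    """Draw ``subset_size`` sequences at random and halve them into two splits.

    The two splits are disjoint and each of size ``subset_size // 2``.
    Sampling permutes row indices with a seeded generator, so the outcome
    depends only on the seed and the row order of ``aln``.
    """
    if subset_size % 2 != 0:
        raise ConfigError(f"subset_size must be even, got {subset_size}")
    if aln.n_seqs < subset_size:
        raise InsufficientDataError(
            f"alignment has {aln.n_seqs} sequences, need >= {subset_size}"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.permutation(aln.n_seqs)[:subset_size]
    half = subset_size // 2
    return aln.subset_rows(idx[:half]), aln.subset_rows(idx[half:])


def top_couplings(z: PairScoreMatrix, k: int) -> CouplingSet:
    """The ``k`` highest-scoring pairs of a score matrix.

    Boundary ties are broken deterministically by ascending ``(i, j)``
    position order. Pairs are returned as 1-based ``(i, j)`` tuples with
    ``i < j``.
    """
    L = z.n_positions
    iu, ju = np.triu_indices(L, 1)
    scores = z.values[iu, ju]
    n_pairs = len(scores)
    if k > n_pairs:
        raise ConfigError(f"k={k} exceeds the {n_pairs} scored pairs")
    pos_i = z.positions[iu] + 1
    pos_j = z.positions[ju] + 1
    order = np.lexsort((pos_j, pos_i, -scores))[:k]
    return frozenset(zip(pos_i[order].tolist(), pos_j[order].tolist()))


def consensus(set_a: CouplingSet, set_b: CouplingSet, k: int) -> tuple[CouplingSet, float]:
    """Intersection of two top-k sets and its size as a fraction of ``k``."""
    inter = frozenset(set_a) & frozenset(set_b)
    return inter, len(inter) / k


@dataclass
class ReproducibilityMatrix:
    """Per-pair consensus counts accumulated over the resampling protocol."""

    counts: dict[tuple[int, int], int]
    iterations: int
    k: int
    subset_size: int
    consensus_ratios: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Sparse (pos_i, pos_j, count) table, 1-based positions."""
        rows = sorted(self.counts.items())
        return pd.DataFrame(
            [(i, j, c) for (i, j), c in rows],
            columns=["pos_i", "pos_j", "count"],
        )


def _split_top_couplings(split: Alignment, positions, k: int,
                         combine: str) -> CouplingSet:
    nmi = nmi_matrix(split, positions=positions)
    var = np.nanvar(nmi.values, axis=1)
    degenerate = np.nonzero(var == 0.0)[0]
    if len(degenerate):
        cols = nmi.positions[degenerate].tolist()
        warnings.warn(
            f"dropping {len(cols)} zero-variance column(s) from split ranking: {cols}",
            stacklevel=3,
        )
        keep = np.nonzero(var > 0.0)[0]
        nmi = nmi.take(keep)
    z = znmi_matrix(nmi, combine=combine)
    return top_couplings(z, k)


def reproducibility_protocol(
    aln: Alignment,
    iterations: int = 100,
    subset_size: int = 300,
    k: int | None = None,
    seed: int = 0,
    gap_threshold: float = GAP_THRESHOLD,
    combine: str = "mean",
) -> ReproducibilityMatrix:
    """Run the full split-half consensus protocol.

    The eligible-position universe (and hence the pair universe and the
    default ``k`` = eligible positions - 1) is fixed once on the full
    alignment, so every split ranks the same pairs regardless of how gaps
    fall within it. One master seed drives the whole run; per-iteration
    generators are spawned from it by counter, so results are reproducible
    and each iteration can be replayed in isolation. Columns whose NMI
    background variance is zero within a split are dropped from that
    split's ranking with a warning.
    """
    elig = eligible_positions(aln, gap_threshold)
    if k is None:
        k = len(elig) - 1
    if k < 1:
        raise ConfigError("k must be at least 1")
    children = np.random.SeedSequence(seed).spawn(iterations)
    counts: Counter = Counter()
    ratios: list[float] = []
    for it in range(iterations):
        rng = np.random.default_rng(children[it])
        split_a, split_b = sample_and_split(aln, subset_size=subset_size, rng=rng)
        top_a = _split_top_couplings(split_a, elig, k, combine)
        top_b = _split_top_couplings(split_b, elig, k, combine)
        cons, ratio = consensus(top_a, top_b, k)
        counts.update(cons)
        ratios.append(ratio)
        logger.debug("iteration %d: consensus ratio %.3f", it, ratio)
    return ReproducibilityMatrix(
        counts=dict(counts),
        iterations=iterations,
        k=k,
        subset_size=subset_size,
        consensus_ratios=ratios,
    )


def fully_reproducible(r: ReproducibilityMatrix) -> CouplingSet:
    """Pairs present in the consensus of every iteration."""
    return frozenset(p for p, c in r.counts.items() if c == r.iterations)


def degree_profile(couplings: CouplingSet) -> dict[int, int]:
    """Number of couplings incident to each position (positions absent -> 0)."""
    deg: Counter = Counter()
    for i, j in couplings:
        deg[i] += 1
        deg[j] += 1
    return dict(deg)
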