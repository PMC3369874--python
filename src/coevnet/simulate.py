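"""Synthetic data with the statistical structure the analysis assumes.

Three generators cover the pipeline end to end without any downloads:

* :func:`generate_msa` — alignments with conserved columns, independently
  varying background columns, and planted coevolving column groups. Rows are
  sampled independently (a star tree with per-site mutation, not a realistic
  phylogeny); within a coupled group each row draws one joint state and each
  member column emits its state's residue with probability ``coupling``,
  otherwise a background residue — so all within-group pairs covary, i.e.
  the planted groups are clique-like by construction.
* :func:`generate_paralog_mixture` — two sub-families from diverged
  consensus sequences, for exercising the spectral split.
* :func:`generate_kinetic_data` — Michaelis–Menten initial rates with
  multiplicative Gaussian noise (constant assay CV), truncated at -90% so
  rates stay positive.

Defaults mirror the study conditions: family-scale alignments (465 rows x
463 columns), substrate concentrations spanning 10–800 µM around the
wild-type Km of 28 µM, and duplicate/triplicate assays at ~5% CV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .msa import AMINO_ACIDS, GAP_CODE, Alignment, codes_to_str

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class CoupledGroup:
    """A planted group of covarying columns.

    ``members`` are 0-based column indices; ``states`` are strings of length
    ``len(members)`` giving each joint state's residue per member column;
    ``probs`` are the joint-state probabilities (uniform when omitted);
    ``coupling`` in [0, 1] is the per-cell probability of emitting the joint
    state's residue rather than a background residue — 1 means deterministic
    joint states.
    """

    members: tuple[int, ...]
    states: tuple[str, ...]
    probs: tuple[float, ...] | None = None
    coupling: float = 1.0

    def __post_init__(self):
        if len(set(self.members)) != len(self.members):
            raise ConfigError("coupled group has repeated member columns")
        if len(self.states) < 2:
            raise ConfigError("a coupled group needs at least two joint states")
        for s in self.states:
            if len(s) != len(self.members):
                raise ConfigError(
                    f"joint state {s!r} does not cover {len(self.members)} members"
                )
            if any(ch not in _AA_INDEX for ch in s):
                raise ConfigError(f"joint state {s!r} has non-standard residues")
        if self.probs is not None:
            if len(self.probs) != len(self.states):
                raise ConfigError("probs and states differ in length")
            if abs(sum(self.probs) - 1.0) > 1e-9 or min(self.probs) < 0:
                raise ConfigError("probs must be a probability vector")
        if not 0.0 <= self.coupling <= 1.0:
            raise ConfigError("coupling must be in [0, 1]")


@dataclass
class MsaSpec:
    """Specification of a synthetic alignment.

    Columns not covered by ``conserved`` or a coupled group vary
    independently, drawing from ``background`` (uniform over the 20 amino
    acids by default) or a per-column profile in ``profiles``. Gaps are
    inserted per cell at ``gap_rate`` after residue emission.
    """

    n_seqs: int = 465
    n_cols: int = 463
    coupled_groups: tuple[CoupledGroup, ...] = ()
    conserved: dict[int, str] = field(default_factory=dict)
    profiles: dict[int, np.ndarray] = field(default_factory=dict)
    background: np.ndarray | None = None
    gap_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_seqs < 1 or self.n_cols < 1:
            raise ConfigError("n_seqs and n_cols must be positive")
        if not 0.0 <= self.gap_rate < 1.0:
            raise ConfigError("gap_rate must be in [0, 1)")
        seen: set[int] = set()
        for g in self.coupled_groups:
            if max(g.members) >= self.n_cols or min(g.members) < 0:
                raise ConfigError("coupled group member outside column range")
            if seen & set(g.members):
                raise ConfigError("coupled groups must be disjoint")
            seen |= set(g.members)
        for c, aa in self.conserved.items():
            if not 0 <= c < self.n_cols:
                raise ConfigError(f"conserved column {c} outside range")
            if c in seen:
                raise ConfigError(f"column {c} is both conserved and coupled")
            if aa not in _AA_INDEX:
                raise ConfigError(f"conserved residue {aa!r} is not standard")


def generate_msa(spec: MsaSpec) -> Alignment:
    """Sample an alignment from an :class:`MsaSpec`; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    n, L = spec.n_seqs, spec.n_cols
    bg = spec.background
    if bg is None:
        bg = np.full(20, 1.0 / 20.0)
    bg = np.asarray(bg, dtype=float)
    bg = bg / bg.sum()

    X = rng.choice(20, size=(n, L), p=bg).astype(np.int8)
    for c, profile in spec.profiles.items():
        p = np.asarray(profile, dtype=float)
        X[:, c] = rng.choice(20, size=n, p=p / p.sum())
    for c, aa in spec.conserved.items():
        X[:, c] = _AA_INDEX[aa]
    for g in spec.coupled_groups:
        state_codes = np.array(
            [[_AA_INDEX[ch] for ch in s] for s in g.states], dtype=np.int8
        )
        drawn = rng.choice(len(g.states), size=n, p=g.probs)
        for m_idx, col in enumerate(g.members):
            emit = rng.random(n) < g.coupling
            X[emit, col] = state_codes[drawn[emit], m_idx]
    if spec.gap_rate > 0:
        X[rng.random((n, L)) < spec.gap_rate] = GAP_CODE
    width = len(str(n))
    return Alignment(
        (f"seq{r:0{width}d}", codes_to_str(X[r])) for r in range(n)
    )


def generate_paralog_mixture(
    n_a: int,
    n_b: int,
    divergence: float,
    seed: int = 0,
    n_cols: int = 200,
    within_mutation: float = 0.08,
) -> tuple[Alignment, np.ndarray]:
    """Two sub-families from consensus sequences diverged at a column fraction.

    Family consensuses differ at ``round(divergence * n_cols)`` randomly
    chosen columns; each row then mutates each cell of its family consensus
    with probability ``within_mutation`` (to a uniformly random residue), so
    within-family identity is roughly ``(1 - within_mutation)**2`` plus a
    small coincidence term (~0.85 at the default). Returns the alignment and
    the true family labels (0 for family A, 1 for B).
    """
    if not 0.0 <= divergence <= 1.0:
        raise ConfigError("divergence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    cons_a = rng.choice(20, size=n_cols).astype(np.int8)
    cons_b = cons_a.copy()
    n_div = int(round(divergence * n_cols))
    div_sites = rng.choice(n_cols, size=n_div, replace=False)
    # shift to a guaranteed-different residue at diverged sites
    cons_b[div_sites] = (cons_b[div_sites] + 1 + rng.integers(0, 19, n_div)) % 20

    rows = []
    labels = []
    for fam, (cons, count) in enumerate((( cons_a, n_a), (cons_b, n_b))):
        for _ in range(count):
            row = cons.copy()
            mut = rng.random(n_cols) < within_mutation
            row[mut] = rng.choice(20, size=int(mut.sum()))
            rows.append(row)
            labels.append(fam)
    width = len(str(len(rows)))
    aln = Alignment(
        (f"{'fam_a' if lab == 0 else 'fam_b'}_{i:0{width}d}", codes_to_str(r))
        for i, (r, lab) in enumerate(zip(rows, labels))
    )
    return aln, np.array(labels)


@dataclass
class KineticSimSpec:
    """Michaelis–Menten assay simulation (defaults: wild-type-like enzyme)."""

    kcat: float = 6.96      # s^-1
    km: float = 28.0        # µM
    e0: float = 0.1         # µM enzyme
    s_grid: tuple[float, ...] = (10, 25, 50, 100, 200, 400, 600, 800)  # µM
    cv: float = 0.05        # multiplicative noise coefficient
    replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if min(self.kcat, self.km, self.e0) <= 0:
            raise ConfigError("kcat, Km and E0 must be positive")
        if len(self.s_grid) < 4:
            raise ConfigError("need at least 4 substrate concentrations")
        if min(self.s_grid) <= 0:
            raise ConfigError("substrate concentrations must be positive")
        if self.cv < 0 or self.replicates < 1:
            raise ConfigError("cv must be >= 0 and replicates >= 1")


def generate_kinetic_data(spec: KineticSimSpec) -> pd.DataFrame:
    """Simulated initial rates: columns (S, v, replicate).

    ``v = kcat * E0 * S / (Km + S) * (1 + eps)`` with ``eps ~ N(0, cv^2)``
    truncated below at -0.9.
    """
    rng = np.random.default_rng(spec.seed)
    s = np.asarray(spec.s_grid, dtype=float)
    v0 = spec.kcat * spec.e0 * s / (spec.km + s)
    frames = []
    for rep in range(spec.replicates):
        eps = np.maximum(rng.normal(0.0, spec.cv, size=len(s)), -0.9) if spec.cv > 0 \
            else np.zeros(len(s))
        frames.append(pd.DataFrame({"S": s, "v": v0 * (1.0 + eps), "replicate": rep}))
    return pd.concat(frames, ignore_index=True)
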