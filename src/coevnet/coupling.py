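"""Mutual-information coevolution scores: MI, NMI and the bivariate Z-score.

All entropies use log base 20, so single-column entropy lies in [0, 1] and
joint entropy in [0, 2]. For a column pair (c, d):

* ``H_cd`` is the entropy of the joint residue distribution over the rows
  where *both* columns are non-gap (complete-pair deletion);
* ``MI_cd = H_c + H_d - H_cd`` with the marginals taken over that same row
  subset, so MI is exactly 0 for a factorizing joint distribution;
* ``NMI_cd = MI_cd / H_cd`` in [0, 1], which removes the strong entropy
  dependence of raw MI (NMI of a pair of fully conserved columns is defined
  as 0);
* the bivariate Z-score standardizes ``NMI_cd`` against column-specific
  background distributions: each column ``i`` gets the mean ``mu_i`` and
  variance ``var_i`` of its NMI values against all other columns, a pair is
  assigned ``mu_ij = (mu_i + mu_j)/2`` and ``var_ij = (var_i + var_j)/4``
  (the mean of two independent column-level normals), and
  ``Z_ij = (NMI_ij - mu_ij) / sqrt(var_ij)``.

Only columns less than 10% gapped are eligible for the pair matrix; heavily
gapped columns are reported as absent, not as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .errors import UndefinedEntropyError, ZeroVarianceError
from .msa import GAP_CODE, _LUT, Alignment

_LOG20 = math.log(20.0)

#: Default per-column gap-fraction eligibility threshold (strict "<").
GAP_THRESHOLD = 0.10


@dataclass
class PairScoreMatrix:
    """Symmetric score matrix over a set of eligible alignment columns.

    ``positions`` are 0-based column indices into the source alignment;
    ``values`` is a dense symmetric matrix aligned with ``positions`` whose
    diagonal is NaN (self-pairs are excluded from every ranking); ``kind``
    is one of ``{"MI", "NMI", "ZNMI"}``.
    """

    positions: np.ndarray
    values: np.ndarray
    kind: str

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def take(self, idx) -> "PairScoreMatrix":
        idx = np.asarray(list(idx), dtype=np.int64)
        return PairScoreMatrix(
            positions=self.positions[idx],
            values=self.values[np.ix_(idx, idx)],
            kind=self.kind,
        )


@dataclass(frozen=True)
class ColumnNmiStats:
    """Background NMI statistics of one column (self-pair excluded)."""

    col: int
    mu: float
    var: float


def _as_codes(col) -> np.ndarray:
    if isinstance(col, str):
        return _LUT[np.frombuffer(col.upper().encode(), dtype=np.uint8)]
    return np.asarray(col, dtype=np.int8)


def eligible_positions(aln: Alignment, gap_threshold: float = GAP_THRESHOLD) -> np.ndarray:
    """0-based indices of columns with gap fraction strictly below the threshold."""
    return np.nonzero(aln.gap_fractions() < gap_threshold)[0]


# ---------------------------------------------------------------------------
# Scalar operations (reference path for single pairs)
# ---------------------------------------------------------------------------

def scalar_column_entropy(col) -> float:
    """Entropy (log base 20) of one column over its non-gap rows."""
    codes = _as_codes(col)
    codes = codes[codes != GAP_CODE]
    if codes.size == 0:
        raise UndefinedEntropyError("column is entirely gapped")
    counts = np.bincount(codes, minlength=20).astype(float)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum() / _LOG20) + 0.0  # avoid -0.0


def joint_entropy(col_c, col_d) -> float:
    """Joint entropy (log base 20) over rows where both columns are non-gap."""
    xc, xd = _as_codes(col_c), _as_codes(col_d)
    both = (xc != GAP_CODE) & (xd != GAP_CODE)
    if not both.any():
        raise UndefinedEntropyError("no mutually non-gapped rows for the pair")
    joint = xc[both].astype(np.int64) * 21 + xd[both]
    counts = np.bincount(joint).astype(float)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum() / _LOG20) + 0.0  # avoid -0.0


def mutual_information(h_c: float, h_d: float, h_cd: float) -> float:
    """``MI = H_c + H_d - H_cd``; inputs must share one row subset."""
    return h_c + h_d - h_cd


def normalized_mi(mi: float, h_cd: float) -> float:
    """``NMI = MI / H_cd``; defined as 0 when both columns are conserved."""
    if h_cd == 0.0:
        return 0.0
    return mi / h_cd


def pair_mi(col_c, col_d) -> tuple[float, float, float]:
    """(MI, NMI, H_cd) for one column pair with complete-pair deletion.

    Marginal entropies are recomputed on the mutually non-gapped row subset
    so that independence gives MI of exactly zero.
    """
    xc, xd = _as_codes(col_c), _as_codes(col_d)
    both = (xc != GAP_CODE) & (xd != GAP_CODE)
    if not both.any():
        raise UndefinedEntropyError("no mutually non-gapped rows for the pair")
    h_c = scalar_column_entropy(xc[both])
    h_d = scalar_column_entropy(xd[both])
    h_cd = joint_entropy(xc[both], xd[both])
    mi = mutual_information(h_c, h_d, h_cd)
    return mi, normalized_mi(mi, h_cd), h_cd


# ---------------------------------------------------------------------------
# Dense all-pairs computation
# ---------------------------------------------------------------------------

def nmi_matrix(
    aln: Alignment,
    positions: np.ndarray | None = None,
    gap_threshold: float = GAP_THRESHOLD,
) -> PairScoreMatrix:
    """All-pairs NMI over the eligible columns of ``aln``.

    Joint counts for every pair are obtained with one rank-20 one-hot matrix
    product, which also yields the pair-specific marginals (complete-pair
    deletion falls out of zeroed gap rows). Memory scales as
    ``(20 * n_positions)**2`` in float32.
    """
    if positions is None:
        positions = eligible_positions(aln, gap_threshold)
    positions = np.asarray(positions, dtype=np.int64)
    L = len(positions)
    if L < 2:
        raise ValueError("need at least two eligible columns")
    sub = aln.codes[:, positions]
    n = sub.shape[0]

    onehot = np.zeros((n, L * 20), dtype=np.float32)
    rows, cols = np.nonzero(sub != GAP_CODE)
    onehot[rows, cols * 20 + sub[rows, cols]] = 1.0

    # float32 gemm for speed; counts are exact integers (< 2**24), so the
    # cast back to float64 makes the entropy arithmetic fully double-precision
    C = (onehot.T @ onehot).astype(np.float64).reshape(L, 20, L, 20)
    npair = C.sum(axis=(1, 3))
    off_diag = ~np.eye(L, dtype=bool)
    if np.any(npair[off_diag] == 0):
        i, j = np.argwhere((npair == 0) & off_diag)[0]
        raise UndefinedEntropyError(
            f"columns {positions[i]} and {positions[j]} share no "
            "mutually non-gapped rows"
        )
    npair = np.maximum(npair, 1.0)

    P = C / npair[:, None, :, None]
    H_cd = -xlogy(P, P).sum(axis=(1, 3)) / _LOG20
    marg_c = C.sum(axis=3) / npair[:, None, :]
    H_c = -xlogy(marg_c, marg_c).sum(axis=1) / _LOG20
    marg_d = C.sum(axis=1) / npair[:, :, None]
    H_d = -xlogy(marg_d, marg_d).sum(axis=2) / _LOG20

    MI = np.maximum(H_c + H_d - H_cd, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        NMI = np.where(H_cd > 0, MI / np.maximum(H_cd, 1e-30), 0.0)
    NMI = np.clip(NMI, 0.0, 1.0).astype(np.float64)
    NMI = (NMI + NMI.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(NMI, np.nan)
    return PairScoreMatrix(positions=positions, values=NMI, kind="NMI")


def column_nmi_stats(nmi: PairScoreMatrix) -> list[ColumnNmiStats]:
    """Per-column mean/variance of NMI values, self-pair excluded."""
    mu = np.nanmean(nmi.values, axis=1)
    var = np.nanvar(nmi.values, axis=1)
    return [
        ColumnNmiStats(col=int(c), mu=float(m), var=float(v))
        for c, m, v in zip(nmi.positions, mu, var)
    ]


def znmi_matrix(nmi: PairScoreMatrix, combine: str = "mean") -> PairScoreMatrix:
    """Standardize an NMI matrix into bivariate Z-scores.

    ``combine`` selects how the two column-level normal backgrounds are
    merged into one pair background:

    * ``"mean"`` (default): ``mu_ij = (mu_i + mu_j)/2``,
      ``var_ij = (var_i + var_j)/4`` — the distribution of the mean of two
      independent column-level normals;
    * ``"precision"``: precision-weighted product of the two normals,
      ``mu_ij = (mu_i var_j + mu_j var_i)/(var_i + var_j)``,
      ``var_ij = var_i var_j/(var_i + var_j)``.

    Pair rankings are insensitive to the global scale difference between the
    rules. Raises :class:`ZeroVarianceError` when any pair's combined
    variance is zero (two columns with degenerate NMI backgrounds).
    """
    if nmi.kind != "NMI":
        raise ValueError(f"expected an NMI matrix, got kind={nmi.kind!r}")
    if nmi.n_positions < 3:
        raise ValueError("Z-scoring needs at least 3 eligible columns")
    mu = np.nanmean(nmi.values, axis=1)
    var = np.nanvar(nmi.values, axis=1)
    degenerate = np.nonzero(var == 0.0)[0]
    if len(degenerate) >= 2:
        cols = nmi.positions[degenerate].tolist()
        raise ZeroVarianceError(
            f"columns {cols} have zero NMI background variance; "
            "drop them before Z-scoring"
        )
    if combine == "mean":
        mu_ij = (mu[:, None] + mu[None, :]) / 2.0
        var_ij = (var[:, None] + var[None, :]) / 4.0
    elif combine == "precision":
        tot = var[:, None] + var[None, :]
        mu_ij = (mu[:, None] * var[None, :] + mu[None, :] * var[:, None]) / tot
        var_ij = var[:, None] * var[None, :] / tot
    else:
        raise ValueError(f"unknown combine rule {combine!r}")
    Z = (nmi.values - mu_ij) / np.sqrt(var_ij)
    Z = (Z + Z.T) / 2.0
    np.fill_diagonal(Z, np.nan)
    return PairScoreMatrix(positions=nmi.positions, values=Z, kind="ZNMI")


def znmi_from_alignment(
    aln: Alignment,
    gap_threshold: float = GAP_THRESHOLD,
    combine: str = "mean",
) -> PairScoreMatrix:
    """Convenience wrapper: eligible columns -> NMI -> ZNMI."""
    return znmi_matrix(nmi_matrix(aln, gap_threshold=gap_threshold), combine=combine)
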