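"""Separate two mixed paralog sub-families by spectral clustering.

Protein families retrieved by name search frequently mix two closely related
sub-families (here: the target mutase family and its similar-length paralog),
and coevolution scores computed on such a mixture partly reflect the family
split rather than within-family covariation. The procedure:

1. pairwise identity -> distance matrix ``d = 1 - identity``;
2. local-scale normalization: each sequence's scale is the mean distance to
   its ``n/2`` nearest neighbors, and each entry is divided by the *product*
   of the two row scales (this damps oscillations in cluster variance when
   the two families have different internal diversity);
3. two-way spectral partition of the affinity graph ``exp(-d'^2)`` using the
   symmetric normalized Laplacian's Fiedler vector, refined by 2-means on the
   one-dimensional spectral embedding.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg
from sklearn.cluster import KMeans

from .errors import DegenerateScaleError, UndefinedIdentityError
from .msa import GAP_CODE, Alignment

#: Floor added to affinities so the graph is never disconnected numerically.
AFFINITY_FLOOR = 1e-12


def identity_distance_matrix(aln: Alignment) -> np.ndarray:
    """Symmetric (n, n) matrix of ``1 - pairwise_identity`` with zero diagonal."""
    X = aln.codes
    n = aln.n_seqs
    nongap = X != GAP_CODE
    D = np.zeros((n, n))
    for i in range(n):
        both = nongap[i] & nongap[i:]
        counts = both.sum(axis=1)
        if np.any(counts == 0):
            j = int(i + np.nonzero(counts == 0)[0][0])
            raise UndefinedIdentityError(
                f"sequences {aln.ids[i]!r} and {aln.ids[j]!r} share no "
                "mutually non-gapped columns"
            )
        matches = ((X[i] == X[i:]) & both).sum(axis=1)
        D[i, i:] = 1.0 - matches / counts
    D = np.triu(D, 1)
    return D + D.T


def local_scale_normalize(D: np.ndarray) -> np.ndarray:
    """Divide each distance by the product of its two rows' local scales.

    The local scale of row ``a`` is the mean of its ``floor(n/2)`` smallest
    off-diagonal distances. Raises :class:`DegenerateScaleError` when a row's
    scale is zero (a sequence with ``n/2`` exact duplicates).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 4:
        raise ValueError("local-scale normalization needs at least 4 sequences")
    k = n // 2
    off = np.sort(D + np.diag(np.full(n, np.inf)), axis=1)[:, :k]
    m = off.mean(axis=1)
    if np.any(m == 0):
        bad = np.nonzero(m == 0)[0].tolist()
        raise DegenerateScaleError(
            f"zero local scale for rows {bad}; too many duplicate sequences"
        )
    out = D / np.outer(m, m)
    np.fill_diagonal(out, 0.0)
    return out


def spectral_bipartition(D: np.ndarray, seed: int = 0) -> np.ndarray:
    """Two-way partition of sequences from a (normalized) distance matrix.

    Affinity is the Gaussian kernel ``exp(-(d'/sigma)^2)`` with the bandwidth
    ``sigma`` set to the median off-diagonal distance (locally normalized
    distances are far above 1, so a unit bandwidth would underflow every
    affinity to zero), plus a small additive floor so the graph is never
    numerically disconnected. The embedding is the Fiedler vector of the
    symmetric normalized Laplacian, refined with a seeded 2-means. Returns
    an array of labels in {0, 1}; label identity is arbitrary (anchor a
    known sequence to name the clusters).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 4:
        raise ValueError("spectral bipartition needs at least 4 sequences")
    sigma = float(np.median(D[~np.eye(n, dtype=bool)]))
    if sigma <= 0:
        sigma = 1.0
    A = np.exp(-((D / sigma) ** 2)) + AFFINITY_FLOOR
    np.fill_diagonal(A, 0.0)
    deg = A.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(deg)
    L = np.eye(n) - (A * inv_sqrt[:, None]) * inv_sqrt[None, :]
    # second-smallest eigenvector of L_sym
    _, vecs = scipy.linalg.eigh(L, subset_by_index=(0, 1))
    fiedler = inv_sqrt * vecs[:, 1]
    km = KMeans(n_clusters=2, n_init=10, random_state=int(seed))
    labels = km.fit_predict(fiedler.reshape(-1, 1))
    if labels.min() == labels.max():  # pragma: no cover - defensive
        labels = (fiedler > np.median(fiedler)).astype(int)
    return labels.astype(int)


def cluster_paralogs(aln: Alignment, anchor_id: str, seed: int = 0):
    """Full sub-family split: returns (anchor-family Alignment, other Alignment, labels).

    The cluster containing ``anchor_id`` (e.g. a biochemically annotated
    member of the family of interest) is returned first.
    """
    D = local_scale_normalize(identity_distance_matrix(aln))
    labels = spectral_bipartition(D, seed=seed)
    anchor_idx = aln.ids.index(anchor_id)
    anchor_label = labels[anchor_idx]
    keep = [i for i in range(aln.n_seqs) if labels[i] == anchor_label]
    drop = [i for i in range(aln.n_seqs) if labels[i] != anchor_label]
    return aln.subset_rows(keep), aln.subset_rows(drop), labels
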