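"""Multiple sequence alignment container, filtering and per-column profiling.

The alignment model is deliberately small: rows of equal-length sequences over
the 20 standard amino acids plus the gap character ``-``. Column conservation
is scored with Shannon entropy in log base 20, so a fully conserved column
scores 0 and a column where all twenty residue types occur at equal frequency
scores 1. Gap characters never enter the frequency estimates; residue
frequencies are always taken over the non-gap rows of a column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentShapeError,
    EmptyInputError,
    MissingReferenceError,
    UndefinedEntropyError,
    UndefinedIdentityError,
)

#: The 20 standard amino acids, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
#: Integer code used for the gap state (amino acids are coded 0..19).
GAP_CODE = 20

_AA_TO_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_AA_TO_CODE[GAP] = GAP_CODE

_DECODE = np.frombuffer((AMINO_ACIDS + GAP).encode(), dtype=np.uint8)

# Lookup table over all byte values: standard residues map to 0..19, the gap
# and every non-standard letter (B, Z, X, U, J, O, ...) map to GAP_CODE.
_LUT = np.full(256, GAP_CODE, dtype=np.int8)
for _aa, _code in _AA_TO_CODE.items():
    _LUT[ord(_aa)] = _code
    _LUT[ord(_aa.lower())] = _code
_LUT[ord(".")] = GAP_CODE

_LOG20 = math.log(20.0)


def normalize_sequence(seq: str) -> str:
    """Uppercase ``seq`` and map non-standard residue letters to the gap.

    Ambiguity and rare codes (B, Z, X, U, J, O) carry no information for a
    20-letter entropy scale, so they are treated as missing data.
    """
    codes = _LUT[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    return _DECODE[codes].tobytes().decode()


def codes_to_str(codes: np.ndarray) -> str:
    return _DECODE[np.asarray(codes, dtype=np.int64)].tobytes().decode()


class Alignment:
    """An in-memory protein multiple sequence alignment.

    Parameters
    ----------
    records:
        Iterable of ``(id, aligned_sequence)`` pairs. Sequences must all have
        the same length, use only the 20 standard amino acids plus ``-``, and
        ids must be unique.
    """

    def __init__(self, records):
        recs = [(str(i), str(s)) for i, s in records]
        if not recs:
            raise EmptyInputError("alignment has no records")
        lengths = {len(s) for _, s in recs}
        if len(lengths) != 1:
            raise AlignmentShapeError(
                f"aligned sequences have differing lengths: {sorted(lengths)}"
            )
        ids = [i for i, _ in recs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in alignment")
        allowed = set(AMINO_ACIDS + GAP)
        for i, s in recs:
            bad = set(s) - allowed
            if bad:
                raise ValueError(
                    f"sequence {i!r} contains non-alignment characters {sorted(bad)}; "
                    "use read_fasta_alignment/normalize_sequence to clean input"
                )
        self.ids: list[str] = ids
        self.seqs: list[str] = [s for _, s in recs]
        self._codes: np.ndarray | None = None

    # -- basic shape -------------------------------------------------------
    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    @property
    def n_cols(self) -> int:
        return len(self.seqs[0])

    @property
    def records(self) -> list[tuple[str, str]]:
        return list(zip(self.ids, self.seqs))

    def __len__(self) -> int:
        return self.n_seqs

    def __eq__(self, other) -> bool:
        return isinstance(other, Alignment) and self.records == other.records

    def __repr__(self) -> str:
        return f"Alignment(n_seqs={self.n_seqs}, n_cols={self.n_cols})"

    @property
    def codes(self) -> np.ndarray:
        """(n_seqs, n_cols) int8 matrix; residues 0..19, gap 20. Cached."""
        if self._codes is None:
            buf = np.frombuffer("".join(self.seqs).encode(), dtype=np.uint8)
            self._codes = _LUT[buf].reshape(self.n_seqs, self.n_cols).copy()
        return self._codes

    # -- derived views -----------------------------------------------------
    def row(self, seq_id: str) -> str:
        try:
            return self.seqs[self.ids.index(seq_id)]
        except ValueError:
            raise MissingReferenceError(f"sequence id {seq_id!r} not in alignment")

    def subset_rows(self, indices) -> "Alignment":
        indices = list(indices)
        return Alignment((self.ids[i], self.seqs[i]) for i in indices)

    def take_columns(self, cols) -> "Alignment":
        cols = np.asarray(list(cols), dtype=np.int64)
        sub = self.codes[:, cols]
        return Alignment(
            (i, codes_to_str(row)) for i, row in zip(self.ids, sub)
        )

    def gap_fractions(self) -> np.ndarray:
        """Per-column fraction of gap characters."""
        return (self.codes == GAP_CODE).mean(axis=0)


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta_alignment(path) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Non-standard residue letters are mapped to the gap character. Raises
    :class:`EmptyInputError` for a file with no records and
    :class:`AlignmentShapeError` when sequence lengths differ.
    """
    records = [(rec.id, normalize_sequence(str(rec.seq)))
               for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    return Alignment(records)


def write_fasta_alignment(aln: Alignment, path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=i, description="") for i, s in aln.records),
        str(path),
        "fasta-2line",
    )


# ---------------------------------------------------------------------------
# Sequence-level filters
# ---------------------------------------------------------------------------

def filter_by_length(seqs, min_len: int = 400, max_len: int = 500):
    """Keep ungapped sequences with ``min_len <= len <= max_len``.

    Both boundaries are inclusive: only sequences strictly shorter than
    ``min_len`` or strictly longer than ``max_len`` are removed. Accepts
    either bare sequences or ``(id, seq)`` pairs; order is preserved.
    """
    out = []
    for item in seqs:
        seq = item[1] if isinstance(item, tuple) else item
        if min_len <= len(seq) <= max_len:
            out.append(item)
    return out


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical residues over columns where *both* rows are non-gap."""
    if len(a) != len(b):
        raise AlignmentShapeError("sequences have different aligned lengths")
    xa = _LUT[np.frombuffer(a.upper().encode(), dtype=np.uint8)]
    xb = _LUT[np.frombuffer(b.upper().encode(), dtype=np.uint8)]
    both = (xa != GAP_CODE) & (xb != GAP_CODE)
    n = int(both.sum())
    if n == 0:
        raise UndefinedIdentityError("no mutually non-gapped columns")
    return float((xa[both] == xb[both]).sum()) / n


def deduplicate_by_identity(aln: Alignment, cutoff: float = 0.90) -> Alignment:
    """Greedy redundancy removal in input order.

    A sequence is kept iff its identity to every previously kept sequence is
    <= ``cutoff``. Deterministic; no retained pair exceeds the cutoff. A pair
    with no mutually non-gapped columns is treated as identity 0 here (they
    cannot be redundant).
    """
    X = aln.codes
    nongap = X != GAP_CODE
    kept: list[int] = []
    for i in range(aln.n_seqs):
        redundant = False
        for j in kept:
            both = nongap[i] & nongap[j]
            n = int(both.sum())
            if n == 0:
                continue
            ident = float((X[i, both] == X[j, both]).sum()) / n
            if ident > cutoff:
                redundant = True
                break
        if not redundant:
            kept.append(i)
    return aln.subset_rows(kept)


# ---------------------------------------------------------------------------
# Reference truncation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceMap:
    """Maps columns of a reference-truncated alignment to reference numbering.

    ``col_to_refpos[c]`` gives the 1-based residue number in the ungapped
    reference sequence for 0-based column ``c`` of the truncated alignment;
    ``source_columns[c]`` is the column index in the original alignment.
    """

    ref_id: str
    source_columns: tuple[int, ...]

    @property
    def col_to_refpos(self) -> dict[int, int]:
        return {c: c + 1 for c in range(len(self.source_columns))}

    def refpos(self, col: int) -> int:
        if not 0 <= col < len(self.source_columns):
            raise IndexError(f"column {col} outside reference map")
        return col + 1

    def __len__(self) -> int:
        return len(self.source_columns)


def truncate_to_reference(aln: Alignment, ref_id: str) -> tuple[Alignment, ReferenceMap]:
    """Drop every column where the reference sequence is gapped.

    Returns the truncated alignment together with a :class:`ReferenceMap`
    assigning 1-based reference residue numbers to the surviving columns.
    """
    ref = aln.row(ref_id)  # raises MissingReferenceError
    cols = tuple(c for c, ch in enumerate(ref) if ch != GAP)
    return aln.take_columns(cols), ReferenceMap(ref_id=ref_id, source_columns=cols)


# ---------------------------------------------------------------------------
# Column profiles and entropy
# ---------------------------------------------------------------------------

@dataclass
class ColumnProfile:
    """Residue composition of one alignment column."""

    col_index: int
    counts: dict[str, int]
    gap_fraction: float
    entropy: float = field(default=float("nan"))


def entropy_from_counts(counts) -> float:
    """Shannon entropy (log base 20) of amino-acid counts; gaps excluded.

    ``counts`` may be a dict keyed by residue letter or a length-20 array in
    :data:`AMINO_ACIDS` order.
    """
    if isinstance(counts, dict):
        vec = np.array([counts.get(aa, 0) for aa in AMINO_ACIDS], dtype=float)
    else:
        vec = np.asarray(counts, dtype=float)
    total = vec.sum()
    if total <= 0:
        raise UndefinedEntropyError("column has no non-gap residues")
    p = vec[vec > 0] / total
    return float(-(p * np.log(p)).sum() / _LOG20) + 0.0  # avoid -0.0


def column_profile(aln: Alignment, col: int) -> ColumnProfile:
    codes = aln.codes[:, col]
    counts = np.bincount(codes, minlength=21)
    gap_fraction = counts[GAP_CODE] / aln.n_seqs
    prof = ColumnProfile(
        col_index=col,
        counts={aa: int(counts[i]) for i, aa in enumerate(AMINO_ACIDS) if counts[i]},
        gap_fraction=float(gap_fraction),
    )
    if counts[:GAP_CODE].sum() > 0:
        prof.entropy = entropy_from_counts(counts[:GAP_CODE])
    return prof


def column_entropy(profile) -> float:
    """Entropy of a :class:`ColumnProfile` (or a raw counts mapping/array)."""
    if isinstance(profile, ColumnProfile):
        if math.isnan(profile.entropy):
            return entropy_from_counts(profile.counts)
        return profile.entropy
    return entropy_from_counts(profile)


def conservation_profile(aln: Alignment, gap_cutoff: float = 0.10) -> np.ndarray:
    """Per-column conservation score in [0, 1].

    Columns more than ``gap_cutoff`` gapped (strictly) are assigned 1.0 —
    heavily gapped positions carry no usable conservation signal and are
    displayed as maximally variable. All other columns score their residue
    entropy on the log-20 scale.
    """
    X = aln.codes
    out = np.empty(aln.n_cols)
    gapfrac = aln.gap_fractions()
    for c in range(aln.n_cols):
        if gapfrac[c] > gap_cutoff:
            out[c] = 1.0
        else:
            counts = np.bincount(X[:, c], minlength=21)[:GAP_CODE]
            out[c] = entropy_from_counts(counts)
    return out
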