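"""Normalized Hamming distances and the rare-to-nearest-modal distance sample.

The sequence-space picture: every OTU representative sequence is a point in a
hypothetical L-dimensional space; the distance between two OTUs i and j is the
fraction of alignment columns at which their base labels differ,

    H_ij = (1/L) * sum_a [1 - delta(S_a^i, S_a^j)],

with delta the Kronecker delta over position labels. For two sequences whose
free (non-conserved) columns are independent and uniform over the four bases,
E[H] = 3(L - M)/(4L) when M columns are conserved across the community.

Each rare OTU is assigned to its nearest modal OTU (a Voronoi construction in
sequence space); the resulting vector {E_k} of minimal distances is the object
whose shape — bell-shaped near the neutral mean, concentrated near zero, or
multimodal — discriminates neutral, niche and hybrid assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentLengthError,
    AlphabetError,
    DegeneratePartitionError,
    InsufficientDataError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .io import AlignedOtuTable

#: Alphabet of aligned 16S representatives. Gap and N are distinct labels:
#: under the Kronecker delta they match only themselves, which keeps L fixed.
ALPHABET = "ACGT-N"

_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _ch in enumerate(ALPHABET):
    _CODES[ord(_ch)] = _i


def encode_sequences(sequences: Sequence[str]) -> np.ndarray:
    """Encode equal-length aligned sequences as a (n, L) uint8 matrix."""
    if not sequences:
        raise InsufficientDataError("no sequences to encode")
    L = len(sequences[0])
    for seq in sequences:
        if len(seq) != L:
            raise AlignmentLengthError(
                f"sequences of length {len(seq)} and {L} in the same alignment"
            )
    raw = np.frombuffer("".join(sequences).encode("ascii"), dtype=np.uint8)
    codes = _CODES[raw].reshape(len(sequences), L)
    if (codes == 255).any():
        row, col = np.argwhere(codes == 255)[0]
        raise AlphabetError(
            f"illegal character {sequences[row][col]!r} at column {col}"
        )
    return codes


def normalized_hamming(seq_i: str, seq_j: str) -> float:
    """Fraction of positions at which two equal-length sequences differ.

    Exact integer mismatch count divided by L; symmetric; zero iff identical.
    """
    if len(seq_i) != len(seq_j):
        raise AlignmentLengthError(
            f"cannot compare sequences of lengths {len(seq_i)} and {len(seq_j)}"
        )
    if len(seq_i) == 0:
        raise AlignmentLengthError("cannot compare empty sequences")
    mismatches = sum(a != b for a, b in zip(seq_i, seq_j))
    return mismatches / len(seq_i)


def conserved_column_count(sequences: Sequence[str] | np.ndarray) -> int:
    """Number of alignment columns with an identical label in every sequence."""
    if isinstance(sequences, np.ndarray):
        matrix = sequences
    else:
        sequences = list(sequences)
        if len(sequences) < 2:
            raise InsufficientDataError(
                "conserved columns need at least 2 sequences"
            )
        matrix = encode_sequences(sequences)
    if matrix.shape[0] < 2:
        raise InsufficientDataError("conserved columns need at least 2 sequences")
    return int((matrix == matrix[0]).all(axis=0).sum())


def expected_neutral_mean(L: int, M: int) -> float:
    """Neutral expectation 3(L-M)/(4L) of the pairwise distance.

    With no conserved columns this is 3/4 — the chance that two uniformly
    random bases differ. M conserved columns contribute zero mismatches and
    deflate the mean accordingly.
    """
    if L < 1:
        raise ValueError(f"alignment length must be >= 1, got {L}")
    if not 0 <= M <= L:
        raise ValueError(f"conserved count M={M} outside [0, L={L}]")
    return 3.0 * (L - M) / (4.0 * L)


@dataclass
class ModalRarePartition:
    """Split of a community into modal (abundant) and rare OTUs at threshold k."""

    modal_ids: set
    rare_ids: set
    k: float
    mode: str

    def __post_init__(self) -> None:
        if self.modal_ids & self.rare_ids:
            raise ValueError("modal and rare sets overlap")


def partition_modal_rare(
    table: "AlignedOtuTable",
    k: float = 0.05,
    mode: str = "fraction_of_total",
) -> ModalRarePartition:
    """Classify OTUs as modal or rare at abundance threshold ``k``.

    ``fraction_of_total`` compares each count against ``k`` times the total
    read count (relative abundance, the default); ``fraction_of_max`` against
    ``k`` times the largest single count. Raises
    :class:`DegeneratePartitionError` when either side is empty, since the
    nearest-distance construction then has no meaning.
    """
    if not 0.0 < k < 1.0:
        raise ValueError(f"k must lie in (0, 1), got {k}")
    if mode not in ("fraction_of_total", "fraction_of_max"):
        raise ValueError(f"unknown threshold mode {mode!r}")
    if table.abundances is None:
        raise ValueError("table has no abundances; read the abundance table first")
    counts = np.asarray(table.abundances, dtype=float)
    denom = counts.sum() if mode == "fraction_of_total" else counts.max()
    relative = counts / denom
    modal_mask = relative >= k
    modal = {i for i, m in zip(table.otu_ids, modal_mask) if m}
    rare = {i for i, m in zip(table.otu_ids, modal_mask) if not m}
    if not modal:
        raise DegeneratePartitionError(
            f"no OTU reaches the modal threshold k={k} ({mode})"
        )
    if not rare:
        raise DegeneratePartitionError(
            f"every OTU reaches the modal threshold k={k} ({mode}); "
            "no rare OTUs to analyze"
        )
    return ModalRarePartition(modal_ids=modal, rare_ids=rare, k=k, mode=mode)


@dataclass
class NearestDistanceSample:
    """The vector {E_k}: one nearest-modal distance per rare OTU."""

    sample_id: str
    rare_otu_ids: list
    nearest_modal_ids: list
    values: np.ndarray
    L: int
    M: int
    expected_neutral_mean: float
    n_modal: int = 0

    @property
    def n(self) -> int:
        return len(self.values)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rare_otu_id": self.rare_otu_ids,
                "nearest_modal_otu_id": self.nearest_modal_ids,
                "distance": self.values,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def nearest_modal_distances(
    table: "AlignedOtuTable", partition: ModalRarePartition
) -> NearestDistanceSample:
    """For every rare OTU, the minimal normalized Hamming distance to a modal OTU.

    Ties in the argmin are broken toward the lexicographically smallest modal
    id; the distance value itself is unaffected. M is computed over all
    sequences in the sample (modal and rare together), since conservation is a
    property of the marker gene, not of an abundance class.
    """
    modal_ids = sorted(partition.modal_ids)
    rare_ids = [i for i in table.otu_ids if i in partition.rare_ids]
    if not modal_ids or not rare_ids:
        raise DegeneratePartitionError("partition has an empty side")

    matrix = encode_sequences(table.sequences)
    index = {otu_id: row for row, otu_id in enumerate(table.otu_ids)}
    modal_m = matrix[[index[i] for i in modal_ids]]
    rare_m = matrix[[index[i] for i in rare_ids]]
    L = table.length
    M = conserved_column_count(matrix)

    # exact integer mismatch counts; chunk the rare axis to bound memory
    n_rare = rare_m.shape[0]
    chunk = max(1, int(5e7) // max(1, modal_m.shape[0] * L))
    best = np.empty(n_rare, dtype=np.int64)
    argbest = np.empty(n_rare, dtype=np.int64)
    for start in range(0, n_rare, chunk):
        block = rare_m[start : start + chunk]
        mism = (block[:, None, :] != modal_m[None, :, :]).sum(axis=2)
        best[start : start + chunk] = mism.min(axis=1)
        argbest[start : start + chunk] = mism.argmin(axis=1)

    return NearestDistanceSample(
        sample_id=table.sample_id,
        rare_otu_ids=list(rare_ids),
        nearest_modal_ids=[modal_ids[j] for j in argbest],
        values=best / L,
        L=L,
        M=M,
        expected_neutral_mean=expected_neutral_mean(L, M),
        n_modal=len(modal_ids),
    )


def mean_pairwise_distance(sequences: Sequence[str] | np.ndarray) -> float:
    """Mean normalized Hamming distance over all unordered pairs."""
    matrix = (
        sequences
        if isinstance(sequences, np.ndarray)
        else encode_sequences(list(sequences))
    )
    n, L = matrix.shape
    if n < 2:
        raise InsufficientDataError("pairwise mean needs at least 2 sequences")
    total = 0
    for i in range(n - 1):
        total += int((matrix[i + 1 :] != matrix[i]).sum())
    return total / (n * (n - 1) / 2 * L)
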