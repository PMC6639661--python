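"""Readers and writers: aligned FASTA, abundance/group TSVs, call results.

The distance analysis needs pre-trimmed, equal-length aligned representative
sequences — the reader validates that rather than guessing trim coordinates.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, replace
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .errors import (
    AlignmentLengthError,
    AlphabetError,
    DuplicateIdError,
    EmptyInputError,
    MissingAbundanceError,
)
from .multimodality import CommunityAssemblyCall

ALPHABET = frozenset("ACGT-N")


@dataclass
class AlignedOtuTable:
    """One sample's OTU representatives: ids, aligned sequences, read counts.

    Invariants enforced on construction: unique ids, equal sequence lengths,
    alphabet {A, C, G, T, -, N} after uppercasing, positive integer counts
    aligned index-wise with ids (counts may be absent until the abundance
    table is read).
    """

    sample_id: str
    otu_ids: list
    sequences: list
    abundances: list | None = None

    def __post_init__(self) -> None:
        self.validate()

    @property
    def length(self) -> int:
        """Alignment length L."""
        return len(self.sequences[0])

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def validate(self) -> None:
        if not self.otu_ids:
            raise EmptyInputError("table contains no OTUs")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            seen, dupes = set(), set()
            for i in self.otu_ids:
                (dupes if i in seen else seen).add(i)
            raise DuplicateIdError(f"duplicate OTU ids: {sorted(dupes)}")
        if len(self.sequences) != len(self.otu_ids):
            raise ValueError("otu_ids and sequences differ in length")
        L = len(self.sequences[0])
        if L < 1:
            raise AlignmentLengthError("alignment length must be >= 1")
        for otu_id, seq in zip(self.otu_ids, self.sequences):
            if len(seq) != L:
                raise AlignmentLengthError(
                    f"record {otu_id!r} has length {len(seq)}, expected {L}"
                )
            bad = set(seq) - ALPHABET
            if bad:
                pos = next(i for i, ch in enumerate(seq) if ch in bad)
                raise AlphabetError(
                    f"record {otu_id!r}: illegal character {seq[pos]!r} "
                    f"at column {pos}"
                )
        if self.abundances is not None:
            if len(self.abundances) != len(self.otu_ids):
                raise ValueError("abundances and otu_ids differ in length")
            for otu_id, count in zip(self.otu_ids, self.abundances):
                if not isinstance(count, int) or isinstance(count, bool):
                    raise ValueError(
                        f"abundance for {otu_id!r} is not an integer: {count!r}"
                    )
                if count <= 0:
                    raise ValueError(
                        f"abundance for {otu_id!r} must be positive, got {count}"
                    )


def read_aligned_fasta(path, sample_id: str | None = None) -> AlignedOtuTable:
    """Read an aligned FASTA (wrapped or single-line) into an OTU table.

    Sequences are uppercased and U is mapped to T (RNA-coded 16S); 'N' and
    '-' are kept as distinct labels. Abundances are attached separately by
    :func:`read_abundance_table`.
    """
    path = pathlib.Path(path)
    otu_ids, sequences = [], []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper().replace("U", "T")
        if sequences and len(seq) != len(sequences[0]):
            raise AlignmentLengthError(
                f"record {record.id!r} has length {len(seq)}, expected "
                f"{len(sequences[0])}; input must be a trimmed alignment"
            )
        bad = set(seq) - ALPHABET
        if bad:
            pos = next(i for i, ch in enumerate(seq) if ch in bad)
            raise AlphabetError(
                f"record {record.id!r}: illegal character {seq[pos]!r} "
                f"at column {pos}"
            )
        otu_ids.append(record.id)
        sequences.append(seq)
    if not otu_ids:
        raise EmptyInputError(f"no FASTA records in {path}")
    return AlignedOtuTable(
        sample_id=sample_id or path.stem,
        otu_ids=otu_ids,
        sequences=sequences,
        abundances=None,
    )


def read_abundance_table(path, table: AlignedOtuTable) -> AlignedOtuTable:
    """Fill a table's abundances from a TSV with header ``otu_id\\tcount``.

    Every FASTA id must be present with a positive integer count; ids in the
    TSV absent from the FASTA are ignored (abundance tables often cover a
    whole study).
    """
    df = pd.read_csv(path, sep="\t", dtype={"otu_id": str})
    missing_cols = {"otu_id", "count"} - set(df.columns)
    if missing_cols:
        raise ValueError(f"abundance table lacks columns: {sorted(missing_cols)}")
    if df["otu_id"].duplicated().any():
        dupes = sorted(df.loc[df["otu_id"].duplicated(), "otu_id"].unique())
        raise DuplicateIdError(f"duplicate otu_id rows in abundance table: {dupes}")
    counts = {}
    for otu_id, raw in zip(df["otu_id"], df["count"]):
        value = float(raw)
        if not value.is_integer():
            raise ValueError(f"count for {otu_id!r} is not an integer: {raw!r}")
        counts[otu_id] = int(value)
    abundances = []
    for otu_id in table.otu_ids:
        if otu_id not in counts:
            raise MissingAbundanceError(
                f"OTU {otu_id!r} has no row in the abundance table"
            )
        if counts[otu_id] <= 0:
            raise ValueError(
                f"count for {otu_id!r} must be positive, got {counts[otu_id]}"
            )
        abundances.append(counts[otu_id])
    return replace(table, abundances=abundances)


@dataclass
class GroupTable:
    """Mapping sample_id -> group label for the cohort comparison."""

    groups: dict

    def __post_init__(self) -> None:
        if not self.groups:
            raise EmptyInputError("group table is empty")

    @property
    def labels(self) -> list:
        return sorted(set(self.groups.values()))

    def __getitem__(self, sample_id: str) -> str:
        return self.groups[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.groups


def read_group_table(path) -> GroupTable:
    """Read a TSV with header ``sample_id\\tgroup``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"group table lacks columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"].unique())
        raise DuplicateIdError(f"duplicate sample ids in group table: {dupes}")
    return GroupTable(groups=dict(zip(df["sample_id"], df["group"])))


def write_call_results(calls: Iterable[CommunityAssemblyCall], path) -> None:
    """Write classification calls as a JSON array (one object per sample)."""
    calls = list(calls)
    if not calls:
        raise EmptyInputError("no calls to write")
    with open(path, "w") as fh:
        json.dump([c.to_dict() for c in calls], fh, indent=2)
        fh.write("\n")


def read_call_results(path) -> list:
    """Read back calls written by :func:`write_call_results` (lossless)."""
    with open(path) as fh:
        records = json.load(fh)
    return [CommunityAssemblyCall.from_dict(r) for r in records]


def write_calls_tsv(calls: Iterable[CommunityAssemblyCall], path) -> None:
    """Flat TSV mirror of the JSON results, one row per sample."""
    calls = list(calls)
    if not calls:
        raise EmptyInputError("no calls to write")
    rows = []
    for c in calls:
        rows.append(
            {
                "sample_id": c.sample_id,
                "classification": c.classification,
                "p_value": c.silverman.p_value if c.silverman else None,
                "h_crit": c.silverman.h_crit if c.silverman else None,
                "seed": c.silverman.seed if c.silverman else None,
                "primary_mode_location": c.primary_mode_location,
                "expected_neutral_mean": c.expected_neutral_mean,
                "n_rare": c.n_rare,
                "n_modal": c.n_modal,
                "sufficient_data": c.sufficient_data,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
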