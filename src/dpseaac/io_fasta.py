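"""FASTA input/output and benchmark cleaning filters.

Protein sequences are held as :class:`ProteinRecord` objects over the 20
standard one-letter amino acid codes. Labeled training sets pair an
ordered record list with +1 (DNA-binding) / -1 (non-binding) labels and
can be assembled either from two FASTA files (positives and negatives)
or from one FASTA plus a two-column id/label TSV.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import FastaFormatError

#: The 20 standard amino acids, alphabetical one-letter order.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
STANDARD_AA_SET = frozenset(STANDARD_AA)

#: Codes treated as "unknown residue" by the benchmark filter: the
#: ambiguity/unusual codes plus alignment characters.
UNKNOWN_CODES = frozenset("XBZUOJ*-")

#: Length cutoff below which a chain is considered a fragment.
DEFAULT_MIN_LENGTH = 50


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a free-text identifier.

    The sequence is stored uppercased; construction does not validate the
    alphabet (filtering and encoding do), so records can carry raw PDB
    chains with ambiguity codes through the cleaning step.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.seq)

    def is_standard(self) -> bool:
        """True when every residue is one of the 20 standard codes."""
        return set(self.seq) <= STANDARD_AA_SET


@dataclass
class RejectedRecord:
    """A record removed by :func:`filter_benchmark`, with the reason."""

    record: ProteinRecord
    reason: str  # "too_short" | "unknown_residue"


@dataclass
class LabeledDataset:
    """Ordered records with parallel +1/-1 labels."""

    records: list[ProteinRecord]
    labels: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.records) != len(self.labels):
            raise ValueError(
                f"{len(self.records)} records but {len(self.labels)} labels"
            )
        bad = sorted({l for l in self.labels} - {+1, -1})
        if bad:
            raise ValueError(f"labels must be +1/-1, got {bad}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_positive(self) -> int:
        return sum(1 for l in self.labels if l == +1)

    @property
    def n_negative(self) -> int:
        return sum(1 for l in self.labels if l == -1)

    def check_two_classes(self) -> None:
        """Raise unless both classes are present (required for training)."""
        if self.n_positive == 0 or self.n_negative == 0:
            raise ValueError(
                "dataset must contain both classes: "
                f"{self.n_positive} positive, {self.n_negative} negative"
            )

    @classmethod
    def from_fasta_pair(cls, pos_path, neg_path) -> "LabeledDataset":
        """Build from two FASTA files: DNA-binding, then non-binding."""
        pos = read_fasta(pos_path)
        neg = read_fasta(neg_path)
        return cls(pos + neg, [+1] * len(pos) + [-1] * len(neg))

    @classmethod
    def from_fasta_tsv(cls, fasta_path, tsv_path) -> "LabeledDataset":
        """Build from one FASTA plus a two-column (id, label) TSV.

        Labels must be 1/-1 (a leading '+' is accepted). Records missing
        from the TSV raise; extra TSV ids are ignored.
        """
        records = read_fasta(fasta_path)
        label_by_id: dict[str, int] = {}
        with open(tsv_path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                if len(row) < 2:
                    raise ValueError(f"label TSV row with <2 columns: {row!r}")
                label_by_id[row[0]] = int(row[1].lstrip("+"))
        try:
            labels = [label_by_id[r.id] for r in records]
        except KeyError as e:
            raise ValueError(f"no label for record id {e.args[0]!r}") from None
        return cls(records, labels)


def read_fasta(path) -> list[ProteinRecord]:
    """Read a multi-record protein FASTA file.

    Sequence lines are concatenated, whitespace stripped and letters
    uppercased. Raises :class:`FastaFormatError` on an empty file, a
    first non-blank line not starting with ``>``, or sequence characters
    outside A-Z.
    """
    path = Path(path)
    with open(path) as fh:
        text = fh.read()
    stripped = text.strip()
    if not stripped:
        raise FastaFormatError(f"{path}: empty FASTA file")
    if not stripped.startswith(">"):
        raise FastaFormatError(f"{path}: first line does not start with '>'")
    records = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = "".join(str(rec.seq).split()).upper()
            if not seq:
                raise FastaFormatError(f"{path}: record {rec.id!r} has no sequence")
            bad = sorted(set(seq) - set("ABCDEFGHIJKLMNOPQRSTUVWXYZ"))
            if bad:
                raise FastaFormatError(
                    f"{path}: record {rec.id!r} contains non-letter "
                    f"characters {bad}"
                )
            records.append(ProteinRecord(id=rec.id, seq=seq))
    return records


def write_fasta(records: Sequence[ProteinRecord], path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width``."""
    if not records:
        raise ValueError("refusing to write an empty FASTA file")
    seqrecords = [
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


def write_labels_tsv(dataset: LabeledDataset, path) -> None:
    """Write the (id, label) TSV companion of a labeled dataset."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for rec, lab in zip(dataset.records, dataset.labels):
            w.writerow([rec.id, lab])


def filter_benchmark(
    records: Iterable[ProteinRecord], min_length: int = DEFAULT_MIN_LENGTH
) -> tuple[list[ProteinRecord], list[RejectedRecord]]:
    """Apply benchmark cleaning: drop fragments and unknown residues.

    Chains shorter than ``min_length`` are rejected as ``too_short``
    (likely fragments); chains containing any residue outside the 20
    standard codes — 'X' and the other ambiguity/unusual codes — are
    rejected as ``unknown_residue``. Returns ``(kept, rejected)``; the
    two lists partition the input and filtering never raises on content.

    Sequence-identity redundancy reduction (PISCES/BLASTCLUST style) is
    deliberately out of scope; run such tools upstream.
    """
    if min_length < 1:
        raise ValueError(f"min_length must be >= 1, got {min_length}")
    kept: list[ProteinRecord] = []
    rejected: list[RejectedRecord] = []
    for rec in records:
        if len(rec) < min_length:
            rejected.append(RejectedRecord(rec, "too_short"))
        elif not rec.is_standard():
            rejected.append(RejectedRecord(rec, "unknown_residue"))
        else:
            kept.append(rec)
    return kept, rejected
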