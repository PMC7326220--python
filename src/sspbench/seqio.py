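"""FASTA input/output with stable record ordering.

Target datasets for PSSM generation (UniRef-style collections) are modelled
as ordered lists of sequence records.  Order matters because downstream
reduction steps (length sorting, greedy clustering, seeded sampling) must be
reproducible from the input file alone.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

__all__ = ["SequenceRecord", "SequenceDataset", "read_fasta", "write_fasta"]


@dataclass(frozen=True)
class SequenceRecord:
    """A single protein sequence.

    Parameters
    ----------
    id : str
        Accession, unique within a dataset (FASTA header token up to the
        first whitespace).
    description : str
        Remainder of the header line (may be empty).
    residues : str
        Uppercase amino-acid string.  The 20 standard letters plus the
        ambiguity codes X, B, Z, U, O, J are accepted.
    """

    id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: residues must be non-empty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SequenceDataset:
    """Ordered collection of :class:`SequenceRecord` with unique ids.

    The cardinality of this collection is the target dataset size (the
    number of proteins PSI-BLAST would search when building a PSSM).
    """

    records: list[SequenceRecord] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id: {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def _open_text(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path, label: str | None = None) -> SequenceDataset:
    """Read a (possibly gzipped) FASTA file into a :class:`SequenceDataset`.

    One record per ``>`` header; sequence bodies may be wrapped over any
    number of lines and are concatenated and uppercased.  Input order is
    preserved.  Duplicate ids and content before the first header are hard
    errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    with _open_text(path) as fh:
        # reject leading garbage: Biopython silently skips it
        for line in fh:
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ValueError(f"{path}: content before first '>' header")
            break
    with _open_text(path) as fh:
        for bio in SeqIO.parse(fh, "fasta"):
            desc = bio.description
            if desc.startswith(bio.id):
                desc = desc[len(bio.id):].strip()
            records.append(
                SequenceRecord(id=bio.id, description=desc,
                               residues=str(bio.seq).upper())
            )
    ds = SequenceDataset(records=records, label=label or path.name)
    return ds


def write_fasta(dataset: SequenceDataset, path: str | Path, wrap: int = 60) -> Path:
    """Write a dataset to FASTA with a fixed line wrap.

    Round-trip stable: ``read_fasta(write_fasta(d))`` reproduces ids,
    descriptions, residues and order.
    """
    if wrap < 1:
        raise ValueError("wrap must be a positive integer")
    path = Path(path)
    bio_records = [
        _BioRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in dataset
    ]
    with _open_text(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(bio_records)
    return path
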