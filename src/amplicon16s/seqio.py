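"""FASTQ/FASTA records and streaming I/O (gzip transparent).

Records keep the quality string in its Sanger Phred+33 on-disk encoding;
:attr:`SequenceRecord.quals` decodes it to integer scores on demand. This
keeps tens of thousands of 1.5 kb nanopore reads cheap to hold in memory.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "SequenceRecord",
    "ParseError",
    "read_fastq",
    "read_fasta",
    "write_fastq",
    "write_fasta",
    "revcomp",
]

_COMPLEMENT = str.maketrans(
    "ACGTUMRWSYKVHDBNacgtumrwsykvhdbn",
    "TGCAAKYWSRMBDHVNtgcaakywsrmbdhvn",
)


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware, case-preserving."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Malformed or truncated sequence file."""


@dataclass
class SequenceRecord:
    """One read or reference sequence with optional per-base quality.

    ``qual`` is the Phred+33 encoded string (``None`` for FASTA records);
    lowercase bases in ``seq`` mark masked (low-complexity) positions.
    """

    id: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self):
        if self.qual is not None:
            if len(self.qual) != len(self.seq):
                raise ParseError(
                    f"record {self.id!r}: quality length {len(self.qual)} "
                    f"!= sequence length {len(self.seq)}"
                )
            q = self.quals
            if len(q) and (q.min() < 0 or q.max() > 93):
                raise ParseError(f"record {self.id!r}: Phred score out of [0, 93]")

    @property
    def quals(self) -> np.ndarray:
        """Per-base Phred scores as an int array (empty if no quality)."""
        if self.qual is None:
            return np.empty(0, dtype=np.int16)
        return np.frombuffer(self.qual.encode("ascii"), dtype=np.uint8).astype(
            np.int16
        ) - 33

    def __len__(self) -> int:
        return len(self.seq)


def _open(path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path) -> Iterator[SequenceRecord]:
    """Stream records from a 4-line Sanger Phred+33 FASTQ file."""
    with _open(path, "r") as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                yield SequenceRecord(title.split()[0], seq, qual)
        except ValueError as exc:  # Biopython signals truncation/mismatch
            raise ParseError(str(exc)) from exc


def read_fasta(path) -> Iterator[SequenceRecord]:
    with _open(path, "r") as fh:
        for title, seq in SimpleFastaParser(fh):
            yield SequenceRecord(title.split()[0], seq)


def write_fastq(records: Iterable[SequenceRecord], path) -> int:
    """Write 4-line FASTQ; returns the number of records written."""
    n = 0
    with _open(path, "w") as fh:
        for rec in records:
            if rec.qual is None:
                raise ValueError(f"record {rec.id!r} has no quality string")
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{rec.qual}\n")
            n += 1
    return n


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 80) -> int:
    n = 0
    with _open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")
            n += 1
    return n
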