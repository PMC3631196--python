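"""Shared sequence helpers and light-weight FASTA/FASTQ I/O."""

from __future__ import annotations

import os
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAATGCAA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def to_dna(seq: str) -> str:
    """Uppercase and transliterate U -> T (miRBase mature FASTA is RNA)."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | os.PathLike, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def read_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str]]:
    """Yield (read id, sequence); qualities are checked for presence only."""
    with open(path) as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq.upper()


def write_fastq(path: str | os.PathLike, records: Iterable[tuple[str, str]]) -> None:
    """Write 4-line FASTQ with constant Phred-40 qualities ('I')."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
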