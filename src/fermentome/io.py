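"""Lightweight sequence records and FASTA/FASTQ file handling.

FASTQ parsing goes through Biopython's ``FastqGeneralIterator``; FASTA
through ``Bio.SeqIO``. Records travel through the pipeline as plain
``Read`` objects so that in-memory runs avoid file round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_COMPLEMENT = str.maketrans("ACGTRYKMBVDHNacgtrykmbvdhn", "TGCAYRMKVBHDNtgcayrmkvbhdn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Read:
    """One sequencing read: id, bases, Phred+33 quality string."""

    id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"{self.id}: sequence/quality length mismatch")

    def __len__(self) -> int:
        return len(self.seq)


def read_fastq(path) -> Iterator[Read]:
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield Read(title.split()[0], seq, qual)


def write_fastq(path, reads: Iterable[Read]) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")
            n += 1
    return n


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: dict[str, str]) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
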