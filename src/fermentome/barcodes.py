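"""Inline barcode/spacer/primer schemes for two-sided ITS amplicon tagging.

Each amplicon carries, at both ends, an 8-bp sample barcode, a 0-3 bp
phasing spacer and the ITS PCR primer. The default scheme uses four
Nextera-style index sequences (N701-N704) combined with the fungal ITS
primer pair BITS/B58S3.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

BITS_FORWARD_PRIMER = "ACCTGCGGARGGATCA"
B58S3_REVERSE_PRIMER = "GAGATCCRTTGYTRAAAGTT"

ILLUMINA_ADAPTER_3P = "AGATCGGAAG"
ILLUMINA_ADAPTER_5P = "CTTCCGATCT"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "K": "GT", "M": "AC",
    "S": "CG", "W": "AT", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal lengths")
    return sum(x != y for x, y in zip(a, b))


def matches_iupac(seq: str, pattern: str) -> bool:
    """True if ``seq`` is compatible with an IUPAC-degenerate ``pattern``."""
    return len(seq) == len(pattern) and all(
        s in IUPAC.get(p, p) for s, p in zip(seq, pattern)
    )


def iupac_mismatches(seq: str, pattern: str) -> int:
    """Positions of ``seq`` incompatible with an IUPAC-degenerate pattern."""
    if len(seq) != len(pattern):
        raise ValueError("iupac_mismatches needs equal lengths")
    return sum(s not in IUPAC.get(p, p) for s, p in zip(seq, pattern))


@dataclass(frozen=True)
class SchemeEntry:
    sample_id: str
    fwd_barcode: str
    fwd_spacer: str
    rev_barcode: str
    rev_spacer: str
    fwd_primer: str = BITS_FORWARD_PRIMER
    rev_primer: str = B58S3_REVERSE_PRIMER

    @property
    def prefix_length(self) -> int:
        """Bases to strip from the 5' end of a merged read."""
        return len(self.fwd_barcode) + len(self.fwd_spacer) + len(self.fwd_primer)

    @property
    def suffix_length(self) -> int:
        """Bases to strip from the 3' end of a merged read."""
        return len(self.rev_barcode) + len(self.rev_spacer) + len(self.rev_primer)


class BarcodeScheme:
    """Validated list of :class:`SchemeEntry`.

    Barcodes must be 8 bp and any two distinct barcodes within the same
    end (forward pool, reverse pool) must differ at >= 3 positions so that
    1-mismatch assignment can never be ambiguous.
    """

    BARCODE_LENGTH = 8
    MIN_PAIRWISE_DISTANCE = 3

    def __init__(self, entries: list[SchemeEntry]):
        if not entries:
            raise ValueError("scheme needs at least one entry")
        ids = [e.sample_id for e in entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in scheme")
        for pool_name, pool in (
            ("forward", [e.fwd_barcode for e in entries]),
            ("reverse", [e.rev_barcode for e in entries]),
        ):
            for bc in pool:
                if len(bc) != self.BARCODE_LENGTH:
                    raise ValueError(f"{pool_name} barcode {bc!r} is not 8 bp")
            distinct = sorted(set(pool))
            for i, a in enumerate(distinct):
                for b in distinct[i + 1:]:
                    if hamming(a, b) < self.MIN_PAIRWISE_DISTANCE:
                        raise ValueError(
                            f"{pool_name} barcodes {a!r}/{b!r} closer than "
                            f"Hamming {self.MIN_PAIRWISE_DISTANCE}"
                        )
            for sp in (
                [e.fwd_spacer for e in entries]
                + [e.rev_spacer for e in entries]
            ):
                if not 0 <= len(sp) <= 3:
                    raise ValueError("spacers must be 0-3 bp")
        self.entries = list(entries)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def sample_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries]

    # ---- TSV round trip -------------------------------------------------

    _COLUMNS = (
        "sample_id", "fwd_barcode", "fwd_spacer",
        "rev_barcode", "rev_spacer", "fwd_primer", "rev_primer",
    )

    def to_tsv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(self._COLUMNS)
            for e in self.entries:
                w.writerow([getattr(e, c) for c in self._COLUMNS])

    @classmethod
    def from_tsv(cls, path) -> "BarcodeScheme":
        entries = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                entries.append(SchemeEntry(**{c: row[c] or "" for c in cls._COLUMNS}))
        return cls(entries)


_DEFAULT_INDEXES = [
    ("N701", "TAAGGCGA", ""),
    ("N702", "CGTACTAG", "C"),
    ("N703", "AGGCAGAA", "TC"),
    ("N704", "TCCTGAGC", "ATC"),
]


def default_scheme(n_samples: int = 4) -> BarcodeScheme:
    """Four-sample scheme: each sample uses the same index at both ends."""
    if not 1 <= n_samples <= len(_DEFAULT_INDEXES):
        raise ValueError(f"n_samples must be in 1..{len(_DEFAULT_INDEXES)}")
    entries = [
        SchemeEntry(
            sample_id=name,
            fwd_barcode=bc,
            fwd_spacer=spacer,
            rev_barcode=bc,
            rev_spacer=spacer,
        )
        for name, bc, spacer in _DEFAULT_INDEXES[:n_samples]
    ]
    return BarcodeScheme(entries)
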