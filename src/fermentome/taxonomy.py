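"""Consensus taxonomy assignment of OTU representatives against an ITS
reference database.

The classifier follows the uclust-style consensus procedure: collect up to
``max_accepts`` references whose global-alignment identity to the query is
at least ``min_similarity`` (0.98), then walk the lineage rank by rank from
domain downward, keeping a rank label only while the most frequent label
among the accepted references reaches ``min_consensus_fraction`` (0.4) AND
is the unique mode; the lineage is truncated at the first rank failing
either condition. No accepted reference at all yields ``"Unassigned"``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import edlib

from .cluster import OTUTable
from .io import read_fasta


@dataclass
class ReferenceDB:
    """ITS reference sequences with rank-delimited lineages."""

    seqs: dict[str, str]        # reference id -> sequence
    lineages: dict[str, str]    # reference id -> "k__...;p__...;...;s__..."

    def __post_init__(self) -> None:
        if not self.seqs:
            raise ValueError("reference database is empty")
        missing = set(self.seqs) - set(self.lineages)
        if missing:
            raise ValueError(f"references without lineage: {sorted(missing)[:3]}")

    @classmethod
    def from_files(cls, fasta_path, taxonomy_tsv_path) -> "ReferenceDB":
        seqs = read_fasta(fasta_path)
        lineages: dict[str, str] = {}
        with open(taxonomy_tsv_path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                ref_id, lineage = line.split("\t")[:2]
                lineages[ref_id] = lineage
        return cls(seqs=seqs, lineages=lineages)

    @classmethod
    def from_reference_set(cls, refs) -> "ReferenceDB":
        """Build from a simulator :class:`~fermentome.simulate.ReferenceSet`."""
        ids = {sp: sp.replace(" ", "_") for sp in refs.its}
        return cls(
            seqs={ids[sp]: seq for sp, seq in refs.its.items()},
            lineages={ids[sp]: refs.taxonomy[sp] for sp in refs.its},
        )


def global_identity(a: str, b: str) -> float:
    """Global (end-to-end) alignment identity: 1 - edits / max length."""
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def assign_taxonomy(
    seq: str,
    db: ReferenceDB,
    min_similarity: float = 0.98,
    max_accepts: int = 10,
    min_consensus_fraction: float = 0.4,
) -> str:
    accepts: list[tuple[float, str]] = []
    for ref_id, ref_seq in db.seqs.items():
        ident = global_identity(seq, ref_seq)
        if ident >= min_similarity:
            accepts.append((ident, ref_id))
    if not accepts:
        return "Unassigned"
    accepts.sort(key=lambda t: (-t[0], t[1]))
    accepts = accepts[:max_accepts]

    lineages = [
        [part.strip() for part in db.lineages[ref_id].split(";")]
        for _, ref_id in accepts
    ]
    n = len(lineages)
    depth = max(len(lin) for lin in lineages)
    consensus: list[str] = []
    for rank in range(depth):
        labels = [lin[rank] for lin in lineages if len(lin) > rank]
        counts = Counter(labels)
        top, top_count = counts.most_common(1)[0]
        unique_mode = sum(1 for c in counts.values() if c == top_count) == 1
        if top_count / n >= min_consensus_fraction and unique_mode:
            consensus.append(top)
        else:
            break
    return ";".join(consensus) if consensus else "Unassigned"


def assign_all(
    table: OTUTable,
    db: ReferenceDB,
    min_similarity: float = 0.98,
    max_accepts: int = 10,
    min_consensus_fraction: float = 0.4,
) -> OTUTable:
    """Annotate every OTU in place with its consensus lineage."""
    for otu in table.otus:
        otu.taxonomy = assign_taxonomy(
            otu.seq, db, min_similarity, max_accepts, min_consensus_fraction
        )
    return table
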