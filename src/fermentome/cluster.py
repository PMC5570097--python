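"""OTU clustering: connected components of the <=d edit-distance graph.

Dereplicated sequences are linked whenever their Levenshtein distance
(substitutions + indels) is at most ``d`` (default 1, the single-linkage
swarm-style radius); clusters are the connected components of that graph.
Cluster abundance sums member counts, the representative is the most
abundant member (ties: lexicographically smallest md5 key), and clusters
below ``min_size`` total reads are discarded after clustering.

For d=1 candidate neighbour pairs are found in near-linear time with a
deletion-signature index: two sequences are within one edit only if they
share either their full sequence hash or a single-deletion hash, so equal
hashes nominate candidate pairs which are then verified with a banded
alignment (edlib, k=1). Hashes are 64-bit polynomial rolling hashes; a
collision can only nominate a spurious candidate, never a spurious link.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .amplicon import DereplicatedSet

_HASH_BASE = np.uint64(1099511628211)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _signature_hashes(seqs: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """64-bit hashes of each sequence and of all its single-deletion
    variants, consistent across sequence lengths.

    Returns (hashes, owners): flat arrays where ``owners[i]`` is the index
    of the sequence that produced ``hashes[i]``.
    """
    all_hashes: list[np.ndarray] = []
    all_owners: list[np.ndarray] = []
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)
    with np.errstate(over="ignore"):
        for length, idxs in by_len.items():
            S = np.frombuffer(
                "".join(seqs[i] for i in idxs).encode(), np.uint8
            ).reshape(len(idxs), length).astype(np.uint64)
            n = len(idxs)
            owners = np.asarray(idxs, dtype=np.int64)
            # prefix hashes P[:, i] = h(s[:i]); suffix values with
            # full-string positional weights T[:, i] = sum_{j>=i} s_j b^(L-1-j)
            P = np.zeros((n, length + 1), dtype=np.uint64)
            T = np.zeros((n, length + 1), dtype=np.uint64)
            powers = np.empty(length, dtype=np.uint64)
            p = np.uint64(1)
            for j in range(length):
                powers[j] = p
                p = p * _HASH_BASE
            for j in range(length):
                P[:, j + 1] = P[:, j] * _HASH_BASE + S[:, j]
            for j in range(length - 1, -1, -1):
                T[:, j] = T[:, j + 1] + S[:, j] * powers[length - 1 - j]
            all_hashes.append(P[:, length])
            all_owners.append(owners)
            if length >= 1:
                del_h = (P[:, :length] * powers[length - 1::-1][None, :]
                         + T[:, 1:length + 1])
                all_hashes.append(del_h.ravel())
                all_owners.append(np.repeat(owners, length))
    return np.concatenate(all_hashes), np.concatenate(all_owners)


def _candidate_pairs(hashes: np.ndarray, owners: np.ndarray) -> set[tuple[int, int]]:
    order = np.argsort(hashes, kind="stable")
    h = hashes[order]
    o = owners[order]
    boundaries = np.flatnonzero(np.diff(h)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(h)]))
    pairs: set[tuple[int, int]] = set()
    for s, e in zip(starts, ends):
        if e - s < 2:
            continue
        members = np.unique(o[s:e])
        for ai in range(len(members) - 1):
            a = int(members[ai])
            for bj in range(ai + 1, len(members)):
                b = int(members[bj])
                pairs.add((a, b))
    return pairs


def _within_d(a: str, b: str, d: int) -> bool:
    if abs(len(a) - len(b)) > d:
        return False
    return edlib.align(a, b, mode="NW", task="distance", k=d)["editDistance"] != -1


@dataclass
class OTURecord:
    key: str                      # md5 of the representative sequence
    seq: str                      # representative sequence
    total: int
    per_sample: dict[str, int]
    members: list[str]            # md5 keys of all member sequences
    taxonomy: str | None = None


@dataclass
class OTUTable:
    """Samples x OTUs abundance table with representative sequences."""

    otus: list[OTURecord]
    samples: list[str]
    discarded_total: int = 0      # reads in clusters below min_size
    member_to_otu: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.member_to_otu:
            self.member_to_otu = {
                m: o.key for o in self.otus for m in o.members
            }

    @property
    def total_count(self) -> int:
        return sum(o.total for o in self.otus)

    def to_dataframe(self) -> pd.DataFrame:
        """OTUs as rows (key-indexed), one count column per sample plus
        taxonomy — the tabular layout of standard OTU tables."""
        rows = []
        for o in self.otus:
            row = {"taxonomy": o.taxonomy or "Unassigned"}
            row.update({s: o.per_sample.get(s, 0) for s in self.samples})
            rows.append(row)
        df = pd.DataFrame(rows, index=[o.key for o in self.otus])
        df.index.name = "otu_id"
        return df

    def to_tsv(self, path) -> None:
        df = self.to_dataframe()
        cols = list(self.samples) + ["taxonomy"]
        df[cols].to_csv(path, sep="\t")

    def abundance_by_taxon(self, rank_prefix: str = "s__") -> pd.Series:
        """Total abundance summed over OTUs grouped by one lineage rank.

        ``rank_prefix`` selects the rank (e.g. ``"g__"`` or ``"s__"``);
        OTUs whose lineage lacks that rank group under ``"Unassigned"``.
        Rank values are returned with underscores replaced by spaces and
        the prefix removed (``s__Saccharomyces_cerevisiae`` ->
        ``Saccharomyces cerevisiae``).
        """
        out: dict[str, int] = {}
        for o in self.otus:
            label = "Unassigned"
            if o.taxonomy:
                for part in o.taxonomy.split(";"):
                    part = part.strip()
                    if part.startswith(rank_prefix) and len(part) > len(rank_prefix):
                        label = part[len(rank_prefix):].replace("_", " ")
                        break
            out[label] = out.get(label, 0) + o.total
        return pd.Series(out).sort_values(ascending=False)


def cluster_otus(
    derep: DereplicatedSet,
    d: int = 1,
    min_size: int = 10,
    fastidious: bool = False,
) -> OTUTable:
    """Cluster a dereplicated set into OTUs (see module docstring).

    ``fastidious=True`` additionally grafts each discarded micro-cluster
    (< 3 reads) onto the retained cluster whose representative is within
    edit distance 2 of its own representative, when one exists.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    if not derep.records:
        return OTUTable(otus=[], samples=list(derep.samples))
    recs = derep.ordered()
    seqs = [r.seq for r in recs]
    n = len(recs)
    uf = _UnionFind(n)
    if d == 1:
        hashes, owners = _signature_hashes(seqs)
        for a, b in _candidate_pairs(hashes, owners):
            if _within_d(seqs[a], seqs[b], 1):
                uf.union(a, b)
    else:
        for i in range(n):
            for j in range(i + 1, n):
                if _within_d(seqs[i], seqs[j], d):
                    uf.union(i, j)

    components: dict[int, list[int]] = {}
    for i in range(n):
        components.setdefault(uf.find(i), []).append(i)

    clusters = []
    for members in components.values():
        total = sum(recs[i].total for i in members)
        rep = min(members, key=lambda i: (-recs[i].total, recs[i].key))
        clusters.append((total, rep, members))

    kept = [c for c in clusters if c[0] >= min_size]
    small = [c for c in clusters if c[0] < min_size]

    if fastidious and kept:
        still_small = []
        for total, rep, members in small:
            if total < 3:
                target = None
                for kt, krep, kmembers in sorted(
                    kept, key=lambda c: (-c[0], recs[c[1]].key)
                ):
                    if _within_d(seqs[rep], seqs[krep], 2):
                        target = (kt, krep, kmembers)
                        break
                if target is not None:
                    target[2].extend(members)
                    kept = [
                        (kt + total, krep, kmembers)
                        if krep == target[1] else (kt, krep, kmembers)
                        for kt, krep, kmembers in kept
                    ]
                    continue
            still_small.append((total, rep, members))
        small = still_small

    discarded = sum(c[0] for c in small)
    otus = []
    for total, rep, members in kept:
        total = sum(recs[i].total for i in members)
        per_sample: dict[str, int] = {}
        for i in members:
            for s, c in recs[i].per_sample.items():
                per_sample[s] = per_sample.get(s, 0) + c
        otus.append(
            OTURecord(
                key=recs[rep].key,
                seq=recs[rep].seq,
                total=total,
                per_sample=per_sample,
                members=[recs[i].key for i in members],
            )
        )
    otus.sort(key=lambda o: (-o.total, o.key))
    return OTUTable(otus=otus, samples=list(derep.samples), discarded_total=discarded)


def combine_samples(
    per_sample_dereps: dict[str, DereplicatedSet],
    table: OTUTable,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Map independently dereplicated samples onto a global OTU table.

    Each sample's records are matched by md5 key to the global cluster
    membership; counts of keys absent from every retained OTU are reported
    per sample as unmapped.
    """
    sample_ids = list(per_sample_dereps)
    counts = pd.DataFrame(
        0, index=[o.key for o in table.otus], columns=sample_ids, dtype=np.int64
    )
    unmapped: dict[str, int] = {}
    for sample, derep in per_sample_dereps.items():
        missing = 0
        for rec in derep.records.values():
            otu_key = table.member_to_otu.get(rec.key)
            if otu_key is None:
                missing += rec.total
            else:
                counts.loc[otu_key, sample] += rec.total
        unmapped[sample] = missing
    counts.index.name = "otu_id"
    return counts, unmapped


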