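"""Reference-based shotgun abundance estimation.

Pipeline: host filtering (a pair survives only when neither mate aligns to
the host genome) -> mapping to the community reference set with a minimal
ungapped seed-and-extend aligner -> 10-kb windowing -> per-window read
counts and mean read identity (``id_factor``) -> per-species summaries
(mean / median / adjusted mean with the >=20 % window-occupancy rule) ->
per-million normalisation against the total reads of the sample.

The built-in mapper indexes references by k-mer seeds (default k=21) and
is adequate for the i.i.d. synthetic genomes this package generates;
real-data users can instead ingest externally produced SAM via
:func:`read_alignments_sam`. A read whose best placement is tied across
two or more locations is excluded as non-unique (the mapping-quality
analog); a read with no placement at or below the mismatch ceiling goes to
the unaligned pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .io import Read, revcomp

DEFAULT_WINDOW = 10_000
DEFAULT_KMER = 21
DEFAULT_MAX_MISMATCH_FRAC = 0.1
DEFAULT_MAX_INSERT = 1500


@dataclass
class AlignmentRecord:
    """A mapped read: half-open interval on a target plus mismatch count."""

    read_id: str
    target: str
    start: int
    end: int
    mismatches: int
    read_length: int
    unique: bool = True
    mate_id: str | None = None
    reverse: bool = False

    @property
    def identity(self) -> float:
        return 1.0 - self.mismatches / self.read_length


@dataclass(frozen=True)
class Window:
    target: str
    start: int
    end: int


# ---------------------------------------------------------------------------
# Mapper
# ---------------------------------------------------------------------------


class ReferenceIndex:
    """k-mer seed index over a set of reference sequences."""

    def __init__(self, references: dict[str, str], k: int = DEFAULT_KMER,
                 exclude: Sequence[str] = ()):
        if len(set(references)) != len(references):
            raise ValueError("duplicate reference ids")
        self.k = k
        self.names: list[str] = []
        self.encoded: list[np.ndarray] = []
        self.lengths: dict[str, int] = {}
        self.seeds: dict[bytes, list[tuple[int, int]]] = {}
        for name, seq in references.items():
            if name in exclude:
                continue
            if not seq:
                raise ValueError(f"empty reference {name!r}")
            ridx = len(self.names)
            self.names.append(name)
            enc = np.frombuffer(seq.upper().encode(), np.uint8).copy()
            self.encoded.append(enc)
            self.lengths[name] = len(seq)
            raw = seq.upper().encode()
            for pos in range(len(raw) - k + 1):
                self.seeds.setdefault(raw[pos:pos + k], []).append((ridx, pos))

    def _placements(self, raw: bytes, enc: np.ndarray,
                    max_mm: int) -> list[tuple[int, int, int]]:
        """Candidate (mismatches, ref_idx, start) found via tiled seeds."""
        L = len(raw)
        k = self.k
        if L < k:
            return []
        offsets = list(range(0, L - k + 1, k))
        if offsets[-1] != L - k:
            offsets.append(L - k)
        seen: set[tuple[int, int]] = set()
        out: list[tuple[int, int, int]] = []
        for off in offsets:
            for ridx, pos in self.seeds.get(raw[off:off + k], ()):
                start = pos - off
                if start < 0 or (ridx, start) in seen:
                    continue
                seen.add((ridx, start))
                ref = self.encoded[ridx]
                if start + L > len(ref):
                    continue
                mm = int(np.count_nonzero(ref[start:start + L] != enc))
                if mm <= max_mm:
                    out.append((mm, ridx, start))
        return out

    def map_read(
        self, read: Read, max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC
    ) -> AlignmentRecord | None:
        """Best ungapped end-to-end placement over both strands.

        Returns ``None`` for unaligned reads; a record with
        ``unique=False`` when the best placement is tied across >= 2
        locations (such reads must be excluded from coverage).
        """
        L = len(read.seq)
        max_mm = int(max_mismatch_frac * L)
        fwd_raw = read.seq.upper().encode()
        rc = revcomp(read.seq.upper())
        cands: list[tuple[int, int, int, bool]] = []
        for raw, is_rc in ((fwd_raw, False), (rc.encode(), True)):
            enc = np.frombuffer(raw, np.uint8)
            cands.extend(
                (mm, ridx, start, is_rc)
                for mm, ridx, start in self._placements(raw, enc, max_mm)
            )
        if not cands:
            return None
        cands.sort(key=lambda c: c[0])
        mm, ridx, start, is_rc = cands[0]
        tied = len(cands) > 1 and cands[1][0] == mm
        return AlignmentRecord(
            read_id=read.id,
            target=self.names[ridx],
            start=start,
            end=start + L,
            mismatches=mm,
            read_length=L,
            unique=not tied,
            reverse=is_rc,
        )


def map_reads(
    reads: Iterable[Read],
    index: ReferenceIndex,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> tuple[list[AlignmentRecord], list[Read]]:
    """Map single reads; returns (records incl. non-unique, unaligned pool)."""
    records: list[AlignmentRecord] = []
    unaligned: list[Read] = []
    for read in reads:
        rec = index.map_read(read, max_mismatch_frac)
        if rec is None:
            unaligned.append(read)
        else:
            records.append(rec)
    return records, unaligned


def map_pairs(
    fwd: Sequence[Read],
    rev: Sequence[Read],
    index: ReferenceIndex,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
    max_insert: int = DEFAULT_MAX_INSERT,
) -> tuple[list[AlignmentRecord], list[Read], int]:
    """Map mate pairs with a concordance filter.

    Pairs with both mates placed must sit on the same target, in opposite
    orientations, within ``max_insert``; discordant pairs are dropped
    entirely. A mate whose partner is unaligned is kept. Returns
    (unique concordant records, unaligned pool, n_discordant_pairs).
    """
    if len(fwd) != len(rev):
        raise ValueError("mate lists differ in length")
    records: list[AlignmentRecord] = []
    unaligned: list[Read] = []
    discordant = 0
    for f, r in zip(fwd, rev):
        fa = index.map_read(f, max_mismatch_frac)
        ra = index.map_read(r, max_mismatch_frac)
        if fa is None:
            unaligned.append(f)
        if ra is None:
            unaligned.append(r)
        if fa is not None and ra is not None:
            lo = min(fa.start, ra.start)
            hi = max(fa.end, ra.end)
            if (fa.target != ra.target or fa.reverse == ra.reverse
                    or hi - lo > max_insert):
                discordant += 1
                continue
            fa.mate_id, ra.mate_id = ra.read_id, fa.read_id
        for rec in (fa, ra):
            if rec is not None and rec.unique:
                records.append(rec)
    return records, unaligned, discordant


def host_filter(
    fwd: Sequence[Read],
    rev: Sequence[Read],
    host_index: ReferenceIndex,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> tuple[list[Read], list[Read], float]:
    """Retain only pairs where NEITHER mate aligns to the host.

    Mates are tested unpaired; a missing mate counts as failing to align.
    Returns (kept forward mates, kept reverse mates, removed fraction).
    """
    if len(fwd) != len(rev):
        raise ValueError("mate lists differ in length")
    keep_f: list[Read] = []
    keep_r: list[Read] = []
    for f, r in zip(fwd, rev):
        hit = False
        for mate in (f, r):
            if mate is not None and host_index.map_read(mate, max_mismatch_frac):
                hit = True
                break
        if not hit:
            keep_f.append(f)
            keep_r.append(r)
    total = len(fwd)
    removed_fraction = (total - len(keep_f)) / total if total else 0.0
    return keep_f, keep_r, removed_fraction


# ---------------------------------------------------------------------------
# SAM ingest
# ---------------------------------------------------------------------------


def read_alignments_sam(path) -> list[AlignmentRecord]:
    """Ingest externally produced alignments (SAM, ungapped, NM tag).

    Primary mapped records only; the NM tag supplies the mismatch count.
    """
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            length = aln.query_length or aln.infer_query_length() or 0
            if length == 0:
                continue
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    target=aln.reference_name,
                    start=aln.reference_start,
                    end=aln.reference_start + length,
                    mismatches=int(aln.get_tag("NM")) if aln.has_tag("NM") else 0,
                    read_length=length,
                    unique=True,
                    reverse=aln.is_reverse,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Windows and summaries
# ---------------------------------------------------------------------------


def make_windows(
    reference_lengths: dict[str, int], width: int = DEFAULT_WINDOW
) -> dict[str, list[Window]]:
    """Half-open tiling of each reference; trailing remainder kept short."""
    if width <= 0:
        raise ValueError("window width must be > 0")
    out: dict[str, list[Window]] = {}
    for name, length in reference_lengths.items():
        if length <= 0:
            raise ValueError(f"reference {name!r} has non-positive length")
        out[name] = [
            Window(name, s, min(s + width, length))
            for s in range(0, length, width)
        ]
    return out


def window_profiles(
    alignments: Iterable[AlignmentRecord],
    windows: dict[str, list[Window]],
    width: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Per-window read count and mean read identity.

    A read increments every window its interval overlaps by >= 1 base, so
    a boundary-spanning read counts in both adjacent windows. Only unique
    alignments may be passed. ``id_factor`` is NaN for empty windows.
    """
    counts = {t: np.zeros(len(ws), dtype=np.int64) for t, ws in windows.items()}
    id_sum = {t: np.zeros(len(ws)) for t, ws in windows.items()}
    for rec in alignments:
        if rec.target not in windows:
            raise KeyError(f"alignment to unknown target {rec.target!r}")
        if not rec.unique:
            continue
        first = rec.start // width
        last = (rec.end - 1) // width
        last = min(last, len(windows[rec.target]) - 1)
        for w in range(first, last + 1):
            counts[rec.target][w] += 1
            id_sum[rec.target][w] += rec.identity
    rows = []
    for target, ws in windows.items():
        c = counts[target]
        idf = np.where(c > 0, id_sum[target] / np.maximum(c, 1), np.nan)
        for i, win in enumerate(ws):
            rows.append((target, win.start, win.end, int(c[i]), idf[i]))
    return pd.DataFrame(
        rows, columns=["target", "start", "end", "count", "id_factor"]
    )


def window_coverage(
    alignments: Iterable[AlignmentRecord],
    windows: dict[str, list[Window]],
    width: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Per-window read counts (columns: target, start, end, count)."""
    return window_profiles(alignments, windows, width)[
        ["target", "start", "end", "count"]
    ]


def window_identity(
    alignments: Iterable[AlignmentRecord],
    windows: dict[str, list[Window]],
    width: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Per-window mean read identity (NaN where no reads)."""
    return window_profiles(alignments, windows, width)[
        ["target", "start", "end", "id_factor"]
    ]


def species_summary(
    profiles: pd.DataFrame,
    species_of: dict[str, str] | None = None,
    breadth_threshold: float = 0.2,
) -> pd.DataFrame:
    """Per-species abundance summaries over ALL windows (zeros included).

    ``species_of`` maps target id -> species; identity by default. The
    adjusted mean keeps the mean only when at least ``breadth_threshold``
    of the species' windows contain >= 1 read, else 0 — this suppresses
    spurious estimates driven by a few high-count windows.
    """
    if profiles.empty:
        raise ValueError("no windows: species summary undefined")
    df = profiles.copy()
    mapping = species_of or {}
    df["species"] = df["target"].map(lambda t: mapping.get(t, t))
    rows = []
    for species, grp in df.groupby("species", sort=False):
        counts = grp["count"].to_numpy()
        mean = float(counts.mean())
        median = float(np.median(counts))
        breadth = float((counts >= 1).mean())
        adjusted = mean if breadth >= breadth_threshold else 0.0
        with np.errstate(invalid="ignore"):
            hit = grp.loc[grp["count"] > 0]
            mean_identity = (
                float((hit["id_factor"] * hit["count"]).sum() / hit["count"].sum())
                if len(hit) else float("nan")
            )
        rows.append((species, len(grp), mean, median, adjusted, breadth, mean_identity))
    out = pd.DataFrame(
        rows,
        columns=[
            "species", "n_windows", "mean", "median",
            "adjusted_mean", "breadth", "mean_identity",
        ],
    ).set_index("species")
    return out


def normalize_abundance(adjusted_mean: float, total_sample_reads: int) -> float:
    """Reads per million sample reads per 10-kb window.

    ``total_sample_reads`` is counted BEFORE host filtering and includes
    unaligned reads.
    """
    if total_sample_reads <= 0:
        raise ValueError("total_sample_reads must be > 0")
    return adjusted_mean * 1e6 / total_sample_reads
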