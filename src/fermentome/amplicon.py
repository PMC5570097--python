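"""ITS amplicon read preparation: quality trimming, pair merging, residual
adapter removal, inline-barcode demultiplexing and dereplication.

The stage order mirrors the standard two-sided inline-barcode amplicon
protocol: 3' quality trim -> merge mates into synthetic reads (outies
allowed) -> strip residual sequencing adapters -> split by the barcode
combination at both ends -> dereplicate to md5-keyed unique sequences.
Every stage conserves read counts exactly (kept + rejected = input).
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .barcodes import (
    BarcodeScheme,
    ILLUMINA_ADAPTER_3P,
    ILLUMINA_ADAPTER_5P,
    hamming,
    iupac_mismatches,
)
from .io import Read, revcomp


# ---------------------------------------------------------------------------
# Quality trimming
# ---------------------------------------------------------------------------


def quality_trim(read: Read, trailing_q: int = 20, min_len: int = 50) -> Read | None:
    """Trim low-quality bases from the 3' end; reject short survivors.

    Bases are removed from the 3' end while the terminal base quality is
    below ``trailing_q`` (Phred+33). Returns ``None`` when the trimmed read
    is shorter than ``min_len``.
    """
    cutoff = 33 + trailing_q
    q = read.qual
    end = len(q)
    while end > 0 and ord(q[end - 1]) < cutoff:
        end -= 1
    if end < min_len:
        return None
    if end == len(q):
        return read
    return Read(read.id, read.seq[:end], read.qual[:end])


def quality_trim_batch(
    reads: list[Read], trailing_q: int = 20, min_len: int = 50
) -> tuple[list[Read | None], int]:
    """Vectorised pass over many reads; returns (records, n_rejected).

    Rejected positions hold ``None`` so mate pairing stays positional.
    """
    cutoff = bytes([33 + trailing_q])
    out: list[Read | None] = []
    rejected = 0
    for r in reads:
        if min(r.qual.encode()) >= cutoff[0]:
            out.append(r)
            continue
        t = quality_trim(r, trailing_q, min_len)
        if t is None:
            rejected += 1
        out.append(t)
    return out, rejected


# ---------------------------------------------------------------------------
# Pair merging
# ---------------------------------------------------------------------------

def _enc_many(seqs: list[str], length: int) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode(), np.uint8).reshape(-1, length)


def merge_pairs_batch(
    fwd: list[Read],
    rev: list[Read],
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.25,
) -> tuple[list[Read | None], int]:
    """Merge each mate pair into a synthetic read by best ungapped overlap.

    The reverse mate is reverse-complemented and slid against the forward
    mate over every offset giving >= ``min_overlap`` overlapping bases,
    including negative ("outie") offsets where the sequenced insert is
    shorter than the read length. The offset maximising
    ``matches - mismatches`` wins (ties keep the smallest offset); offsets
    whose mismatch fraction exceeds ``max_mismatch_frac`` are disallowed.
    Disagreeing overlap bases take the higher-quality call (tie: forward).
    Innie merges keep the non-overlapping flanks; outie merges keep only
    the overlap (the dangling ends are adapter read-through).

    Pairs are processed in same-length groups so the offset scan runs as
    whole-array comparisons. Returns positional results (``None`` =
    no qualifying overlap) and the rejection count.
    """
    if len(fwd) != len(rev):
        raise ValueError("forward/reverse lists differ in length")
    results: list[Read | None] = [None] * len(fwd)
    groups: dict[tuple[int, int], list[int]] = {}
    for i, (f, r) in enumerate(zip(fwd, rev)):
        if f is None or r is None or len(f) == 0 or len(r) == 0:
            continue
        groups.setdefault((len(f), len(r)), []).append(i)

    for (lf, lr), idxs in groups.items():
        F = _enc_many([fwd[i].seq for i in idxs], lf)
        R = _enc_many([revcomp(rev[i].seq) for i in idxs], lr)
        QF = _enc_many([fwd[i].qual for i in idxs], lf)
        QR = _enc_many([rev[i].qual[::-1] for i in idxs], lr)
        n = len(idxs)
        best_score = np.full(n, -(10 ** 9), dtype=np.int64)
        best_s = np.zeros(n, dtype=np.int64)
        found = np.zeros(n, dtype=bool)
        for s in range(-(lr - min_overlap), lf - min_overlap + 1):
            a0, a1 = max(0, s), min(lf, s + lr)
            ov = a1 - a0
            if ov < min_overlap:
                continue
            mm = np.count_nonzero(F[:, a0:a1] != R[:, a0 - s:a1 - s], axis=1)
            score = ov - 2 * mm
            ok = mm <= max_mismatch_frac * ov
            better = ok & (score > best_score)
            best_score[better] = score[better]
            best_s[better] = s
            found |= better
        for j, i in enumerate(idxs):
            if not found[j]:
                continue
            s = int(best_s[j])
            a0, a1 = max(0, s), min(lf, s + lr)
            fseg, rseg = F[j, a0:a1], R[j, a0 - s:a1 - s]
            qfseg, qrseg = QF[j, a0:a1], QR[j, a0 - s:a1 - s]
            take_r = (fseg != rseg) & (qrseg > qfseg)
            cons = np.where(take_r, rseg, fseg).astype(np.uint8)
            qcons = np.maximum(qfseg, qrseg)
            if s >= 0:
                seq = (F[j, :a0].tobytes() + cons.tobytes()
                       + R[j, a1 - s:].tobytes()).decode()
                qual = (QF[j, :a0].tobytes() + qcons.tobytes()
                        + QR[j, a1 - s:].tobytes()).decode()
            else:  # outie: keep the overlap only
                seq = cons.tobytes().decode()
                qual = qcons.tobytes().decode()
            rid = fwd[i].id
            rid = rid[:-2] if rid.endswith(("/1", "/2")) else rid
            results[i] = Read(rid, seq, qual)
    rejected = sum(r is None for r in results)
    return results, rejected


def merge_pairs(
    fwd: Read,
    rev: Read,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.25,
) -> Read | None:
    """Single-pair convenience wrapper around :func:`merge_pairs_batch`."""
    return merge_pairs_batch([fwd], [rev], min_overlap, max_mismatch_frac)[0][0]


# ---------------------------------------------------------------------------
# Residual adapter trimming
# ---------------------------------------------------------------------------


def trim_residual_adapters(
    read: Read,
    adapter_5p: str = ILLUMINA_ADAPTER_5P,
    adapter_3p: str = ILLUMINA_ADAPTER_3P,
    error_rate: float = 0.1,
    min_overlap: int = 6,
) -> Read:
    """Remove residual adapter overlaps at either end of a merged read.

    A read prefix matching a suffix of ``adapter_5p`` (or a read suffix
    matching a prefix of ``adapter_3p``) over >= ``min_overlap`` bases and
    with a mismatch fraction <= ``error_rate`` is removed. The longest
    qualifying overlap at each end wins; no match leaves the read unchanged.
    """
    seq, qual = read.seq, read.qual
    for k in range(min(len(seq), len(adapter_5p)), min_overlap - 1, -1):
        if hamming(seq[:k], adapter_5p[-k:]) <= error_rate * k:
            seq, qual = seq[k:], qual[k:]
            break
    for k in range(min(len(seq), len(adapter_3p)), min_overlap - 1, -1):
        if hamming(seq[-k:], adapter_3p[:k]) <= error_rate * k:
            seq, qual = seq[:-k], qual[:-k]
            break
    if seq is read.seq:
        return read
    return Read(read.id, seq, qual)


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------


@dataclass
class DemuxRead:
    """A demultiplexed merged read with the stripped context retained, so
    that ``prefix + read.seq + suffix`` reconstructs the assigned read."""

    read: Read
    sample_id: str
    prefix: str
    suffix: str
    reverse_complemented: bool = False


@dataclass
class DemuxResult:
    by_sample: dict[str, list[DemuxRead]]
    unassigned: list[Read]

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.by_sample.values())


_PRIMER_MISMATCH_FRAC = 0.2


def _match_entries(seq: str, scheme: BarcodeScheme, max_mismatch: int) -> list:
    """Entries whose barcode pair AND primer context match the read.

    The primer check (IUPAC-aware, <= 20 % mismatches) is what determines
    read orientation: schemes that reuse one index at both ends have
    identical barcodes either way round, so only the asymmetric primers
    can distinguish a read from its reverse complement.
    """
    head, tail = seq[:8], revcomp(seq[-8:])
    out = []
    for e in scheme:
        if (hamming(head, e.fwd_barcode) > max_mismatch
                or hamming(tail, e.rev_barcode) > max_mismatch):
            continue
        if len(seq) < e.prefix_length + e.suffix_length:
            continue
        fp_start = 8 + len(e.fwd_spacer)
        fp = seq[fp_start:fp_start + len(e.fwd_primer)]
        rp_end = len(seq) - 8 - len(e.rev_spacer)
        rp = revcomp(seq[rp_end - len(e.rev_primer):rp_end])
        if (iupac_mismatches(fp, e.fwd_primer)
                <= _PRIMER_MISMATCH_FRAC * len(e.fwd_primer)
                and iupac_mismatches(rp, e.rev_primer)
                <= _PRIMER_MISMATCH_FRAC * len(e.rev_primer)):
            out.append(e)
    return out


def demultiplex(
    reads: list[Read],
    scheme: BarcodeScheme,
    max_mismatch: int = 1,
) -> DemuxResult:
    """Assign merged reads to samples by the barcode pair at both ends.

    A read is assigned when exactly one scheme entry matches its forward
    AND reverse barcode within ``max_mismatch`` Hamming distance; the
    reverse-complemented orientation is tried when the forward orientation
    matches nothing (two-sided barcoding leaves orientation ambiguous after
    merging). Barcodes, spacers and primers are stripped from both ends.
    Ambiguous, unmatched or too-short reads land in ``unassigned``.
    """
    by_sample: dict[str, list[DemuxRead]] = {e.sample_id: [] for e in scheme}
    unassigned: list[Read] = []
    for read in reads:
        if read is None:
            continue
        assigned = False
        for flipped in (False, True):
            seq = revcomp(read.seq) if flipped else read.seq
            if len(seq) < 16:
                break
            matches = _match_entries(seq, scheme, max_mismatch)
            if len(matches) == 0:
                continue
            if len(matches) > 1:
                break  # ambiguous
            e = matches[0]
            p, s = e.prefix_length, e.suffix_length
            if len(seq) <= p + s:
                break  # nothing left after stripping
            qual = read.qual[::-1] if flipped else read.qual
            by_sample[e.sample_id].append(
                DemuxRead(
                    read=Read(read.id, seq[p:len(seq) - s], qual[p:len(seq) - s]),
                    sample_id=e.sample_id,
                    prefix=seq[:p],
                    suffix=seq[len(seq) - s:],
                    reverse_complemented=flipped,
                )
            )
            assigned = True
            break
        if not assigned:
            unassigned.append(read)
    return DemuxResult(by_sample=by_sample, unassigned=unassigned)


# ---------------------------------------------------------------------------
# Dereplication
# ---------------------------------------------------------------------------


def md5_key(seq: str) -> str:
    """Stable OTU key: md5 hex digest of the uppercased sequence."""
    return hashlib.md5(seq.upper().encode()).hexdigest()


@dataclass
class DerepRecord:
    key: str
    seq: str
    total: int
    per_sample: Counter = field(default_factory=Counter)


@dataclass
class DereplicatedSet:
    """Unique sequences keyed by md5, ordered by (-total count, key)."""

    records: dict[str, DerepRecord]
    samples: list[str]

    def ordered(self) -> list[DerepRecord]:
        return sorted(self.records.values(), key=lambda r: (-r.total, r.key))

    @property
    def total_count(self) -> int:
        return sum(r.total for r in self.records.values())


def dereplicate(reads_by_sample: dict[str, list]) -> DereplicatedSet:
    """Collapse identical full-length sequences, keeping per-sample counts.

    Accepts per-sample lists of :class:`DemuxRead`, :class:`Read` or plain
    strings; sequences are uppercased before hashing.
    """
    records: dict[str, DerepRecord] = {}
    for sample, reads in reads_by_sample.items():
        for item in reads:
            seq = item if isinstance(item, str) else (
                item.read.seq if isinstance(item, DemuxRead) else item.seq
            )
            seq = seq.upper()
            key = md5_key(seq)
            rec = records.get(key)
            if rec is None:
                rec = records[key] = DerepRecord(key=key, seq=seq, total=0)
            rec.total += 1
            rec.per_sample[sample] += 1
    return DereplicatedSet(records=records, samples=list(reads_by_sample))
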