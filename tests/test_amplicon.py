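"""ITS read preparation: trimming, merging, demultiplexing, dereplication."""

import hashlib
import random

import pytest

import fermentome as fm
from fermentome.amplicon import DereplicatedSet, quality_trim_batch
from fermentome.io import Read, revcomp

Q35 = chr(33 + 35)
Q15 = chr(33 + 15)


def _read(seq, qual=None, rid="r"):
    return Read(rid, seq, qual if qual is not None else Q35 * len(seq))


def _random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestQualityTrim:
    def test_low_quality_tail_removed(self):
        r = _read("A" * 100, Q35 * 90 + Q15 * 10)
        t = fm.quality_trim(r, trailing_q=20, min_len=50)
        assert len(t) == 90

    def test_short_after_trim_rejected(self):
        r = _read("A" * 55, Q35 * 49 + Q15 * 6)
        assert fm.quality_trim(r, trailing_q=20, min_len=50) is None

    def test_high_quality_read_untouched(self):
        r = _read("ACGT" * 30)
        assert fm.quality_trim(r) is r

    def test_internal_low_quality_kept(self):
        # trimming is 3'-anchored: an internal dip does not trigger it
        r = _read("A" * 100, Q35 * 40 + Q15 * 10 + Q35 * 50)
        assert fm.quality_trim(r) is r

    def test_batch_matches_scalar(self):
        reads = [
            _read("A" * 100, Q35 * 90 + Q15 * 10),
            _read("C" * 60, Q35 * 40 + Q15 * 20),
            _read("G" * 80),
        ]
        batch, rejected = quality_trim_batch(reads)
        scalar = [fm.quality_trim(r) for r in reads]
        assert rejected == sum(s is None for s in scalar)
        assert [None if b is None else b.seq for b in batch] == [
            None if s is None else s.seq for s in scalar
        ]


class TestMergePairs:
    def test_exact_innie_overlap(self):
        rng = random.Random(1)
        frag = _random_seq(rng, 150)
        fwd = _read(frag[:100], rid="p/1")
        rev = _read(revcomp(frag[50:]), rid="p/2")
        merged = fm.merge_pairs(fwd, rev)
        assert merged.seq == frag

    def test_outie_keeps_overlap_only(self):
        # reverse-complemented mate starts 10 bases before the forward mate
        rng = random.Random(2)
        frag = _random_seq(rng, 100)
        fwd = _read(frag[10:90], rid="p/1")
        rev = _read(revcomp(frag[0:80]), rid="p/2")
        merged = fm.merge_pairs(fwd, rev)
        assert merged.seq == frag[10:80]

    def test_short_insert_after_adapter_trim(self):
        # 80 bp insert sequenced fully from both sides: full-length overlap
        rng = random.Random(3)
        frag = _random_seq(rng, 80)
        merged = fm.merge_pairs(_read(frag), _read(revcomp(frag)))
        assert merged.seq == frag

    def test_mismatch_resolved_by_quality(self):
        frag = "ACGTACGTACGTACGTACGT"
        fwd_seq = "T" + frag[1:]  # error at position 0 of the forward mate
        fwd = _read(fwd_seq, chr(33 + 2) + Q35 * 19)
        rev = _read(revcomp(frag), Q35 * 20)
        merged = fm.merge_pairs(fwd, rev, min_overlap=10)
        assert merged.seq == frag

    def test_unrelated_mates_rejected_matches_offset_scan_oracle(self):
        rng = random.Random(4)
        a, b = _random_seq(rng, 100), _random_seq(rng, 100)
        fwd, rev = _read(a), _read(b)
        min_ov, max_frac = 10, 0.25
        # independent exhaustive offset scan
        bprime = revcomp(b)
        qualifying = []
        for s in range(-(len(bprime) - min_ov), len(a) - min_ov + 1):
            lo, hi = max(0, s), min(len(a), s + len(bprime))
            ov = hi - lo
            if ov < min_ov:
                continue
            mm = sum(
                a[i] != bprime[i - s] for i in range(lo, hi)
            )
            if mm <= max_frac * ov:
                qualifying.append(s)
        assert not qualifying
        assert fm.merge_pairs(fwd, rev, min_ov, max_frac) is None

    def test_empty_mate_rejected(self):
        merged, rejected = fm.merge_pairs_batch([_read("ACGTACGTACGT")], [None])
        assert merged == [None] and rejected == 1


class TestAdapterTrim:
    def test_5p_prefix_removed(self):
        r = _read("CTTCCGATCT" + "ACGT" * 10)
        assert fm.trim_residual_adapters(r).seq == "ACGT" * 10

    def test_3p_with_one_mismatch_removed(self):
        adapter = "AGATCGGAAG"
        noisy = "AGATCGGTAG"  # one mismatch over 10 bases = 0.1, allowed
        r = _read("ACGT" * 10 + noisy)
        assert fm.trim_residual_adapters(r).seq == "ACGT" * 10

    def test_below_min_overlap_unchanged(self):
        r = _read("ACGT" * 10 + "AGATC")  # 5-base adapter fragment
        assert fm.trim_residual_adapters(r).seq == r.seq


class TestDemultiplex:
    def _merged_read(self, entry, core, rid="m"):
        seq = (
            entry.fwd_barcode + entry.fwd_spacer + entry.fwd_primer.replace("R", "A")
            + core
            + revcomp(entry.rev_primer.replace("R", "A").replace("Y", "C"))
            + revcomp(entry.rev_spacer) + revcomp(entry.rev_barcode)
        )
        return _read(seq, rid=rid)

    def test_exact_barcodes_assign(self):
        scheme = fm.default_scheme()
        core = "ACGT" * 20
        r = self._merged_read(scheme.entries[0], core)
        result = fm.demultiplex([r], scheme)
        assert len(result.by_sample["N701"]) == 1
        assert result.by_sample["N701"][0].read.seq == core

    def test_one_mismatch_still_assigned(self):
        scheme = fm.default_scheme()
        core = "ACGT" * 20
        r = self._merged_read(scheme.entries[0], core)
        seq = "A" + r.seq[1:]  # TAAGGCGA -> AAAGGCGA, distance 1
        result = fm.demultiplex([_read(seq)], scheme)
        assert len(result.by_sample["N701"]) == 1

    def test_two_mismatches_unassigned(self):
        scheme = fm.default_scheme()
        core = "ACGT" * 20
        r = self._merged_read(scheme.entries[0], core)
        seq = "AG" + r.seq[2:]  # two barcode mismatches
        result = fm.demultiplex([_read(seq)], scheme)
        assert result.n_assigned == 0 and len(result.unassigned) == 1

    def test_reverse_complemented_read_assigned(self):
        scheme = fm.default_scheme()
        core = "ACGT" * 20
        r = self._merged_read(scheme.entries[1], core)
        result = fm.demultiplex([_read(revcomp(r.seq))], scheme)
        [dr] = result.by_sample["N702"]
        assert dr.reverse_complemented and dr.read.seq == core

    def test_stripping_is_involutive(self):
        scheme = fm.default_scheme()
        core = "ACGTTGCA" * 12
        for entry in scheme:
            r = self._merged_read(entry, core)
            [dr] = fm.demultiplex([r], scheme).by_sample[entry.sample_id]
            assert dr.prefix + dr.read.seq + dr.suffix == r.seq

    def test_count_conservation(self, two_taxon_design, two_taxon_refs):
        fwd, rev, _ = fm.simulate_its_reads(
            two_taxon_design, two_taxon_refs, 400, error_rate=0.02, seed=13
        )
        merged, rejected = fm.merge_pairs_batch(fwd, rev)
        synthetic = [m for m in merged if m is not None]
        result = fm.demultiplex(synthetic, fm.default_scheme())
        assert result.n_assigned + len(result.unassigned) == len(synthetic)
        assert len(synthetic) + rejected == 400


class TestDereplicate:
    def test_collapse_and_counts(self):
        derep = fm.dereplicate({"s1": ["ACGT", "ACGT", "AAAA"]})
        ordered = derep.ordered()
        assert [r.total for r in ordered] == [2, 1]
        assert ordered[0].seq == "ACGT"

    def test_cross_sample_conservation(self):
        derep = fm.dereplicate({"s1": ["ACGT"], "s2": ["ACGT", "ACGT"]})
        [rec] = derep.records.values()
        assert rec.total == 3
        assert rec.per_sample == {"s1": 1, "s2": 2}

    def test_key_is_md5_of_uppercased_sequence(self):
        derep = fm.dereplicate({"s1": ["acgtACGT"]})
        [key] = derep.records
        assert key == hashlib.md5(b"ACGTACGT").hexdigest()
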