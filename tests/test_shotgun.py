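"""Shotgun branch: mapping, host filtering, windowing, species summaries."""

import random

import numpy as np
import pandas as pd
import pysam
import pytest

import fermentome as fm
from fermentome.io import Read, revcomp
from fermentome.shotgun import ReferenceIndex, window_profiles

Q35 = chr(33 + 35)


def _read(seq, rid="r"):
    return Read(rid, seq, Q35 * len(seq))


def _random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture
def genome():
    return _random_seq(random.Random(31), 5_000)


@pytest.fixture
def index(genome):
    return ReferenceIndex({"gA": genome})


class TestMapper:
    def test_verbatim_read_maps_uniquely(self, genome, index):
        rec = index.map_read(_read(genome[1000:1100]))
        assert (rec.target, rec.start, rec.end) == ("gA", 1000, 1100)
        assert rec.mismatches == 0 and rec.unique

    def test_reverse_strand_read_maps(self, genome, index):
        rec = index.map_read(_read(revcomp(genome[2000:2100])))
        assert (rec.start, rec.end, rec.reverse) == (2000, 2100, True)

    def test_duplicated_sequence_flagged_non_unique(self, genome):
        # identical segment present in two references
        index = ReferenceIndex({"gA": genome, "gB": genome[:2000]})
        rec = index.map_read(_read(genome[500:600]))
        assert rec is not None and not rec.unique

    def test_substitutions_counted(self, genome, index):
        seq = list(genome[3000:3100])
        seq[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[10]]
        seq[50] = {"A": "G", "C": "T", "G": "A", "T": "C"}[seq[50]]
        rec = index.map_read(_read("".join(seq)))
        assert rec.mismatches == 2
        assert rec.identity == pytest.approx(0.98)

    def test_too_many_mismatches_unaligned(self, genome, index):
        rng = random.Random(32)
        seq = list(genome[100:200])
        for p in rng.sample(range(100), 15):
            seq[p] = rng.choice([b for b in "ACGT" if b != seq[p]])
        assert index.map_read(_read("".join(seq)), max_mismatch_frac=0.1) is None

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            ReferenceIndex({"gA": ""})


class TestHostFilter:
    def test_host_matching_pair_removed(self, genome):
        rng = random.Random(33)
        host = _random_seq(rng, 3_000)
        host_index = ReferenceIndex({"host": host})
        community_pair = (_read(genome[0:100]), _read(revcomp(genome[150:250])))
        host_pair = (_read(host[0:100]), _read(revcomp(genome[150:250])))
        keep_f, keep_r, frac = fm.host_filter(
            [community_pair[0], host_pair[0]],
            [community_pair[1], host_pair[1]],
            host_index,
        )
        assert len(keep_f) == 1
        assert frac == pytest.approx(0.5)

    def test_all_host_input_removed_entirely(self):
        rng = random.Random(34)
        host = _random_seq(rng, 3_000)
        host_index = ReferenceIndex({"host": host})
        fwd = [_read(host[i:i + 100]) for i in range(0, 300, 100)]
        rev = [_read(revcomp(host[i + 150:i + 250])) for i in range(0, 300, 100)]
        keep_f, _, frac = fm.host_filter(fwd, rev, host_index)
        assert keep_f == [] and frac == 1.0


class TestWindows:
    def test_tiling_with_remainder(self):
        windows = fm.make_windows({"gA": 25_000})["gA"]
        assert [(w.start, w.end) for w in windows] == [
            (0, 10_000), (10_000, 20_000), (20_000, 25_000)
        ]

    def test_exact_and_short_single_windows(self):
        assert len(fm.make_windows({"gA": 10_000})["gA"]) == 1
        [w] = fm.make_windows({"gA": 9_999})["gA"]
        assert (w.start, w.end) == (0, 9_999)

    def test_boundary_spanning_read_counts_twice(self):
        windows = fm.make_windows({"gA": 20_000})
        rec = fm.AlignmentRecord("r1", "gA", 9_990, 10_090, 0, 100)
        prof = window_profiles([rec], windows)
        assert prof["count"].tolist() == [1, 1]

    def test_counts_conserve_window_overlaps(self):
        rng = random.Random(35)
        windows = fm.make_windows({"gA": 30_000})
        recs = []
        expected = 0
        for i in range(200):
            start = rng.randrange(0, 29_900)
            rec = fm.AlignmentRecord(f"r{i}", "gA", start, start + 100, 0, 100)
            recs.append(rec)
            expected += len({start // 10_000, (start + 99) // 10_000})
        prof = window_profiles(recs, windows)
        assert prof["count"].sum() == expected

    def test_identity_factor_mean(self):
        windows = fm.make_windows({"gA": 10_000})
        recs = [
            fm.AlignmentRecord("r1", "gA", 0, 100, 1, 100),
            fm.AlignmentRecord("r2", "gA", 200, 300, 3, 100),
        ]
        prof = window_profiles(recs, windows)
        assert prof["id_factor"].iloc[0] == pytest.approx(0.98)

    def test_unknown_target_is_hard_failure(self):
        windows = fm.make_windows({"gA": 10_000})
        rec = fm.AlignmentRecord("r1", "gZ", 0, 100, 0, 100)
        with pytest.raises(KeyError):
            window_profiles([rec], windows)


def _profiles_from_counts(counts):
    return pd.DataFrame(
        {
            "target": "sp1",
            "start": np.arange(len(counts)) * 10_000,
            "end": (np.arange(len(counts)) + 1) * 10_000,
            "count": counts,
            "id_factor": [1.0 if c else np.nan for c in counts],
        }
    )


class TestSpeciesSummary:
    def test_low_breadth_zeroes_adjusted_mean(self):
        summary = fm.species_summary(
            _profiles_from_counts([30, 0, 0, 0, 0, 0, 0, 0, 0, 0])
        )
        row = summary.loc["sp1"]
        assert row["breadth"] == pytest.approx(0.1)
        assert row["adjusted_mean"] == 0.0
        assert row["mean"] == pytest.approx(3.0)

    def test_sufficient_breadth_keeps_mean(self):
        summary = fm.species_summary(
            _profiles_from_counts([5, 5, 5, 5, 0, 0, 0, 0, 0, 0])
        )
        row = summary.loc["sp1"]
        assert row["breadth"] == pytest.approx(0.4)
        assert row["adjusted_mean"] == pytest.approx(2.0)

    def test_uniform_coverage(self):
        summary = fm.species_summary(_profiles_from_counts([7] * 10))
        row = summary.loc["sp1"]
        assert row["mean"] == row["median"] == row["adjusted_mean"] == 7.0


class TestNormalize:
    def test_per_million_arithmetic(self):
        assert fm.normalize_abundance(3.0, 1_500_000) == pytest.approx(2.0)

    def test_zero_stays_zero(self):
        assert fm.normalize_abundance(0.0, 10_000) == 0.0

    def test_doubling_total_halves_value(self):
        assert fm.normalize_abundance(4.0, 2_000_000) == pytest.approx(
            fm.normalize_abundance(4.0, 1_000_000) / 2
        )

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            fm.normalize_abundance(1.0, 0)


class TestSamIngest:
    def test_roundtrip_via_pysam(self, tmp_path, genome):
        header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6"}, "SQ": [{"SN": "gA", "LN": len(genome)}]}
        )
        path = tmp_path / "toy.sam"
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            a = pysam.AlignedSegment(header)
            a.query_name = "r1"
            a.query_sequence = genome[100:200]
            a.reference_id = 0
            a.reference_start = 100
            a.cigarstring = "100M"
            a.query_qualities = pysam.qualitystring_to_array(Q35 * 100)
            a.set_tag("NM", 2)
            out.write(a)
        [rec] = fm.read_alignments_sam(path)
        assert (rec.target, rec.start, rec.end, rec.mismatches) == ("gA", 100, 200, 2)
        assert rec.identity == pytest.approx(0.98)
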