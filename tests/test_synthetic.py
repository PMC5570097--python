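"""Synthetic-community generator: references, amplicon and shotgun reads."""

import edlib
import numpy as np
import pytest

import fermentome as fm
from fermentome.design import HOST_LABEL

from conftest import LINEAGE_A, LINEAGE_B


def _single_taxon_design(copies=3, genome=50_000):
    return fm.MockDesign(
        taxa=[
            fm.TaxonSpec(
                label="Saccharomyces cerevisiae",
                strain="S1",
                cells=1e6,
                genome_length=genome,
                its_copy_number=copies,
                taxonomy=LINEAGE_A,
            )
        ],
        seed=5,
        name="solo",
    )


class TestBuildReferences:
    def test_its_copies_embedded(self):
        refs = fm.build_references(_single_taxon_design(copies=3))
        genome = refs.genomes["Saccharomyces cerevisiae"]
        its = refs.its["Saccharomyces cerevisiae"]
        assert len(genome) == 50_000
        assert genome.count(its) == 3

    def test_inter_taxon_identity_below_threshold(self, two_taxon_refs):
        seqs = list(two_taxon_refs.its.values())
        d = edlib.align(seqs[0], seqs[1], mode="NW", task="distance")["editDistance"]
        identity = 1 - d / max(len(seqs[0]), len(seqs[1]))
        assert identity < 0.9

    def test_same_seed_byte_identical(self, two_taxon_design, tmp_path):
        a = fm.build_references(two_taxon_design)
        b = fm.build_references(two_taxon_design)
        a.write(tmp_path / "a")
        b.write(tmp_path / "b")
        for name in ("genomes.fasta", "its_refs.fasta", "host.fasta"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_genome_too_small_rejected(self):
        design = _single_taxon_design(copies=30, genome=1_000)
        with pytest.raises(ValueError, match="cannot host"):
            fm.build_references(design, its_length=150)

    def test_strains_share_species_genome(self):
        design = fm.control_mix(1, seed=3)
        refs = fm.build_references(design)
        assert len(refs.genomes) == len(design.species()) == 6
        assert len(design.taxa) == 7


class TestSimulateIts:
    def test_single_taxon_degenerate_multinomial(self):
        design = _single_taxon_design()
        refs = fm.build_references(design)
        _, _, truth = fm.simulate_its_reads(design, refs, 500, seed=1)
        counts = truth.counts()
        assert counts == {"Saccharomyces cerevisiae": 500}
        assert sum(truth.proportions.values()) == pytest.approx(1.0)

    def test_amp_bias_shifts_proportions(self, two_taxon_design):
        taxa = [
            fm.TaxonSpec(**{**t.__dict__, "amp_bias": b})
            for t, b in zip(two_taxon_design.taxa, [10.0, 1.0])
        ]
        design = fm.MockDesign(taxa=taxa, seed=11, name="biased")
        refs = fm.build_references(design)
        n = 10_000
        _, _, truth = fm.simulate_its_reads(design, refs, n, seed=2)
        p = 10 / 11
        se = np.sqrt(p * (1 - p) / n)
        observed = truth.counts()["Saccharomyces cerevisiae"] / n
        assert abs(observed - p) <= 3 * se

    def test_zero_error_reads_reconstruct_templates(self, two_taxon_design, two_taxon_refs):
        fwd, rev, truth = fm.simulate_its_reads(
            two_taxon_design, two_taxon_refs, 200, error_rate=0.0, seed=3
        )
        merged, rejected = fm.merge_pairs_batch(fwd, rev)
        assert rejected == 0
        demux = fm.demultiplex(merged, fm.default_scheme())
        assert len(demux.unassigned) == 0
        templates = set(two_taxon_refs.its.values())
        for reads in demux.by_sample.values():
            for dr in reads:
                assert dr.read.seq in templates

    def test_error_rate_bounds_enforced(self, two_taxon_design, two_taxon_refs):
        with pytest.raises(ValueError, match="error_rate"):
            fm.simulate_its_reads(
                two_taxon_design, two_taxon_refs, 10, error_rate=0.5, seed=1
            )

    def test_same_seed_identical_fastq(self, two_taxon_design, two_taxon_refs, tmp_path):
        out = []
        for run in range(2):
            fwd, rev, _ = fm.simulate_its_reads(
                two_taxon_design, two_taxon_refs, 50, seed=9
            )
            path = tmp_path / f"r{run}.fastq"
            fm.write_fastq(path, fwd + rev)
            out.append(path.read_bytes())
        assert out[0] == out[1]


class TestSimulateShotgun:
    def test_genome_length_weighting(self):
        taxa = [
            fm.TaxonSpec(label="Saccharomyces cerevisiae", strain="A",
                         cells=1e6, genome_length=50_000, taxonomy=LINEAGE_A),
            fm.TaxonSpec(label="Hanseniaspora uvarum", strain="B",
                         cells=1e6, genome_length=5_000, taxonomy=LINEAGE_B),
        ]
        design = fm.MockDesign(taxa=taxa, seed=4, name="weighted")
        refs = fm.build_references(design, its_length=150)
        n = 10_000
        _, _, truth = fm.simulate_shotgun_reads(design, refs, n, seed=5)
        p = 10 / 11
        se = np.sqrt(p * (1 - p) / n)
        share = truth.counts()["Saccharomyces cerevisiae"] / n
        assert abs(share - p) <= 3 * se

    def test_host_fraction_binomial(self, two_taxon_design):
        design = fm.MockDesign(
            taxa=two_taxon_design.taxa, host_fraction=0.01, seed=11, name="hosty"
        )
        refs = fm.build_references(design)
        n = 100_000
        _, _, truth = fm.simulate_shotgun_reads(design, refs, n, seed=6)
        n_host = truth.counts()[HOST_LABEL]
        se = np.sqrt(n * 0.01 * 0.99)
        assert abs(n_host - 1000) <= 3 * se

    def test_counts_sum_exactly(self, two_taxon_design, two_taxon_refs):
        _, _, truth = fm.simulate_shotgun_reads(
            two_taxon_design, two_taxon_refs, 777, seed=7
        )
        assert sum(truth.counts().values()) == 777
        assert sum(truth.proportions.values()) == pytest.approx(1.0)

    def test_zero_pairs_is_valid_empty(self, two_taxon_design, two_taxon_refs):
        fwd, rev, truth = fm.simulate_shotgun_reads(
            two_taxon_design, two_taxon_refs, 0, seed=8
        )
        assert fwd == [] and rev == [] and truth.read_sources == {}

    def test_error_rate_sets_mean_identity(self, two_taxon_design, two_taxon_refs):
        fwd, rev, _ = fm.simulate_shotgun_reads(
            two_taxon_design, two_taxon_refs, 2_000, error_rate=0.01, seed=9
        )
        index = fm.ReferenceIndex(two_taxon_refs.genomes)
        records, _, _ = fm.map_pairs(fwd, rev, index)
        mean_identity = np.mean([r.identity for r in records])
        assert mean_identity == pytest.approx(0.99, abs=0.003)
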