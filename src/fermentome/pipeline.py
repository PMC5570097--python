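"""End-to-end pipeline orchestration.

Two branches mirror the two assays:

* :func:`run_its_pipeline` — raw ITS amplicon mate pairs -> quality trim ->
  merge -> residual-adapter trim -> demultiplex -> dereplicate -> cluster
  -> taxonomy -> OTU table.
* :func:`run_shotgun_pipeline` — raw shotgun mate pairs -> host filter ->
  map -> 10-kb windows -> per-species summaries with per-million
  normalisation.

:func:`mock_community_experiment` runs both branches on simulated reads
from a mock design and returns the per-platform observed/expected bias
reports — the complete bias-quantification experiment in one call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .amplicon import (
    DemuxResult,
    dereplicate,
    demultiplex,
    merge_pairs_batch,
    quality_trim_batch,
    trim_residual_adapters,
)
from .barcodes import BarcodeScheme, default_scheme
from .cluster import OTUTable, cluster_otus
from .compare import BiasReport, mock_ratios
from .design import ANCHOR_SPECIES, MockDesign
from .io import Read
from .shotgun import (
    ReferenceIndex,
    host_filter,
    make_windows,
    map_pairs,
    normalize_abundance,
    species_summary,
    window_profiles,
)
from .simulate import (
    ReferenceSet,
    build_references,
    simulate_its_reads,
    simulate_shotgun_reads,
)
from .taxonomy import ReferenceDB, assign_all


@dataclass
class ItsResult:
    otu_table: OTUTable
    demux: DemuxResult
    stats: dict = field(default_factory=dict)

    def species_abundance(self) -> pd.Series:
        """Total OTU counts grouped by assigned species."""
        return self.otu_table.abundance_by_taxon("s__")


def run_its_pipeline(
    fwd: list[Read],
    rev: list[Read],
    scheme: BarcodeScheme,
    ref_db: ReferenceDB,
    *,
    trailing_q: int = 20,
    min_len: int = 50,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.25,
    barcode_mismatch: int = 1,
    d: int = 1,
    min_size: int = 10,
    min_similarity: float = 0.98,
    max_accepts: int = 10,
    min_consensus_fraction: float = 0.4,
    fastidious: bool = False,
) -> ItsResult:
    n_pairs = len(fwd)
    tf, rej_f = quality_trim_batch(fwd, trailing_q, min_len)
    tr, rej_r = quality_trim_batch(rev, trailing_q, min_len)
    qt_rejected_pairs = sum(
        1 for f, r in zip(tf, tr) if f is None or r is None
    )
    merged, merge_rejected = merge_pairs_batch(
        tf, tr, min_overlap=min_overlap, max_mismatch_frac=max_mismatch_frac
    )
    merge_rejected -= qt_rejected_pairs  # those never reached the merger
    synthetic = [
        trim_residual_adapters(m) for m in merged if m is not None
    ]
    demux = demultiplex(synthetic, scheme, max_mismatch=barcode_mismatch)
    derep = dereplicate(demux.by_sample)
    table = cluster_otus(derep, d=d, min_size=min_size, fastidious=fastidious)
    assign_all(
        table, ref_db,
        min_similarity=min_similarity,
        max_accepts=max_accepts,
        min_consensus_fraction=min_consensus_fraction,
    )
    stats = {
        "n_pairs": n_pairs,
        "quality_rejected_pairs": qt_rejected_pairs,
        "merge_rejected_pairs": merge_rejected,
        "n_merged": len(synthetic),
        "n_assigned": demux.n_assigned,
        "n_unassigned": len(demux.unassigned),
        "n_unique": len(derep.records),
        "discarded_small_clusters": table.discarded_total,
        "n_otus": len(table.otus),
    }
    return ItsResult(otu_table=table, demux=demux, stats=stats)


@dataclass
class ShotgunResult:
    species: pd.DataFrame        # per-species summaries + normalized column
    profiles: pd.DataFrame       # per-window counts and id_factor
    unaligned: list[Read]
    stats: dict = field(default_factory=dict)

    def species_abundance(self) -> pd.Series:
        """Normalized adjusted-mean abundance per species."""
        return self.species["normalized"]


def run_shotgun_pipeline(
    fwd: list[Read],
    rev: list[Read],
    references: dict[str, str],
    host: str | None = None,
    *,
    k: int = 21,
    window: int = 10_000,
    breadth_threshold: float = 0.2,
    max_mismatch_frac: float = 0.1,
    max_insert: int = 1500,
    exclude: tuple[str, ...] = (),
    species_of: dict[str, str] | None = None,
) -> ShotgunResult:
    total_reads = len(fwd) + len(rev)  # before any filtering
    removed_fraction = 0.0
    if host:
        host_index = ReferenceIndex({"host": host}, k=k)
        fwd, rev, removed_fraction = host_filter(
            fwd, rev, host_index, max_mismatch_frac
        )
    index = ReferenceIndex(references, k=k, exclude=exclude)
    records, unaligned, discordant = map_pairs(
        fwd, rev, index, max_mismatch_frac, max_insert
    )
    windows = make_windows(index.lengths, window)
    profiles = window_profiles(records, windows, window)
    species = species_summary(profiles, species_of, breadth_threshold)
    species["normalized"] = [
        normalize_abundance(v, total_reads) for v in species["adjusted_mean"]
    ]
    stats = {
        "total_reads": total_reads,
        "host_removed_fraction": removed_fraction,
        "n_mapped": len(records),
        "n_unaligned": len(unaligned),
        "n_discordant_pairs": discordant,
    }
    return ShotgunResult(
        species=species, profiles=profiles, unaligned=unaligned, stats=stats
    )


@dataclass
class MockExperiment:
    its: ItsResult
    shotgun: ShotgunResult
    its_report: BiasReport
    shotgun_report: BiasReport
    refs: ReferenceSet


def mock_community_experiment(
    design: MockDesign,
    *,
    n_its_pairs: int = 50_000,
    n_shotgun_pairs: int = 50_000,
    error_rate: float = 0.01,
    seed: int = 1,
    anchor: str = ANCHOR_SPECIES,
    refs: ReferenceSet | None = None,
    scheme: BarcodeScheme | None = None,
) -> MockExperiment:
    """Simulate a mock community and quantify per-platform bias.

    Runs the full ITS and shotgun branches on freshly simulated reads and
    compares both observed abundance tables to the design's cell counts
    via :func:`~fermentome.compare.mock_ratios`. Distinct seeds are
    derived for the two simulators from ``seed``.
    """
    refs = refs or build_references(design)
    scheme = scheme or default_scheme()
    ref_db = ReferenceDB.from_reference_set(refs)

    fwd_i, rev_i, _ = simulate_its_reads(
        design, refs, n_its_pairs,
        error_rate=error_rate, scheme=scheme, seed=2 * seed + 1,
    )
    its_result = run_its_pipeline(fwd_i, rev_i, scheme, ref_db)

    fwd_s, rev_s, _ = simulate_shotgun_reads(
        design, refs, n_shotgun_pairs,
        error_rate=error_rate, seed=2 * seed + 2,
    )
    shotgun_result = run_shotgun_pipeline(
        fwd_s, rev_s, refs.genomes, host=refs.host
    )

    its_obs = its_result.species_abundance()
    sg_obs = shotgun_result.species_abundance()
    its_report = mock_ratios(its_obs, design, anchor=anchor, platform="ITS")
    sg_report = mock_ratios(sg_obs, design, anchor=anchor, platform="shotgun")
    return MockExperiment(
        its=its_result,
        shotgun=shotgun_result,
        its_report=its_report,
        shotgun_report=sg_report,
        refs=refs,
    )
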