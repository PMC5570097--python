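"""Mock-community designs: the ground-truth description of a control population.

A :class:`MockDesign` lists the strains mixed into a control population
together with everything the simulator needs to emit reads with a known
answer: cell counts, genome lengths, ribosomal ITS copy numbers, and a
per-taxon multiplicative ITS amplification bias (1.0 = unbiased).

Two built-in designs (:func:`control_mix`) reproduce the cell-count layout
of a published two-mix wine-yeast benchmark: seven strains, six species,
cell counts spanning five orders of magnitude (1e3 to 1e8 cells).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")


@dataclass(frozen=True)
class TaxonSpec:
    """One strain in a mock community.

    ``label`` is the species name; several strains may share a label, in
    which case they also share a reference genome and ITS sequence (real
    conspecific strains are indistinguishable at ITS resolution).
    """

    label: str
    strain: str
    cells: float
    genome_length: int
    its_copy_number: int = 8
    amp_bias: float = 1.0
    taxonomy: str = ""

    def __post_init__(self) -> None:
        if self.cells <= 0:
            raise ValueError(f"{self.strain}: cell count must be > 0")
        if self.genome_length <= 0:
            raise ValueError(f"{self.strain}: genome_length must be > 0")
        if self.its_copy_number < 1:
            raise ValueError(f"{self.strain}: its_copy_number must be >= 1")
        if not (math.isfinite(self.amp_bias) and self.amp_bias > 0):
            raise ValueError(f"{self.strain}: amp_bias must be finite and > 0")


@dataclass
class MockDesign:
    """A control population plus simulation context (host fraction, seed)."""

    taxa: list[TaxonSpec]
    host_fraction: float = 0.0
    seed: int = 0
    name: str = "mock"

    def __post_init__(self) -> None:
        if not self.taxa:
            raise ValueError("design needs at least one taxon")
        if not 0.0 <= self.host_fraction < 1.0:
            raise ValueError("host_fraction must be in [0, 1)")
        # strains sharing a species label share one genome, so the genome
        # description must be consistent across them
        per_species: dict[str, TaxonSpec] = {}
        for t in self.taxa:
            prev = per_species.setdefault(t.label, t)
            if (prev.genome_length, prev.its_copy_number, prev.taxonomy) != (
                t.genome_length,
                t.its_copy_number,
                t.taxonomy,
            ):
                raise ValueError(
                    f"strains of {t.label!r} disagree on genome length, ITS "
                    "copy number or taxonomy"
                )

    # ---- species-level views -------------------------------------------

    def species(self) -> list[str]:
        """Unique species labels in first-appearance order."""
        seen: dict[str, None] = {}
        for t in self.taxa:
            seen.setdefault(t.label, None)
        return list(seen)

    def species_cells(self) -> dict[str, float]:
        """Total cells per species (strains pooled)."""
        out: dict[str, float] = {}
        for t in self.taxa:
            out[t.label] = out.get(t.label, 0.0) + t.cells
        return out

    def species_taxonomy(self) -> dict[str, str]:
        return {t.label: t.taxonomy for t in self.taxa}

    def species_genome_length(self) -> dict[str, int]:
        return {t.label: t.genome_length for t in self.taxa}

    def its_weights(self) -> dict[str, float]:
        """Per-species expected ITS amplicon weight: cells x copies x bias."""
        out: dict[str, float] = {}
        for t in self.taxa:
            w = t.cells * t.its_copy_number * t.amp_bias
            out[t.label] = out.get(t.label, 0.0) + w
        return out

    def shotgun_weights(self) -> dict[str, float]:
        """Per-species expected shotgun weight: cells x genome length.

        Amplification bias deliberately plays no role here: shotgun
        sequencing is the unbiased channel.
        """
        out: dict[str, float] = {}
        for t in self.taxa:
            out[t.label] = out.get(t.label, 0.0) + t.cells * t.genome_length
        return out

    def its_proportions(self) -> dict[str, float]:
        w = self.its_weights()
        tot = sum(w.values())
        return {k: v / tot for k, v in w.items()}

    def shotgun_proportions(self) -> dict[str, float]:
        """Community read proportions; the host fraction is carved out first."""
        w = self.shotgun_weights()
        tot = sum(w.values())
        comm = 1.0 - self.host_fraction
        out = {k: comm * v / tot for k, v in w.items()}
        if self.host_fraction > 0:
            out[HOST_LABEL] = self.host_fraction
        return out

    # ---- (de)serialisation ---------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "name": self.name,
            "seed": self.seed,
            "host_fraction": self.host_fraction,
            "taxa": [asdict(t) for t in self.taxa],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "MockDesign":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        taxa = [TaxonSpec(**t) for t in doc["taxa"]]
        return cls(
            taxa=taxa,
            host_fraction=float(doc.get("host_fraction", 0.0)),
            seed=int(doc.get("seed", 0)),
            name=str(doc.get("name", "mock")),
        )


HOST_LABEL = "host"


@dataclass
class GroundTruth:
    """Per-read provenance recorded by the simulators.

    ``proportions`` are the expected read proportions per source label;
    ``read_sources`` maps read (pair) id -> source label; ``read_samples``
    maps read id -> sample id (ITS only).
    """

    proportions: dict[str, float]
    read_sources: dict[str, str]
    read_samples: dict[str, str] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lbl in self.read_sources.values():
            out[lbl] = out.get(lbl, 0) + 1
        return out

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tsource\tsample\n")
            for rid, src in self.read_sources.items():
                fh.write(f"{rid}\t{src}\t{self.read_samples.get(rid, '')}\n")


# ---------------------------------------------------------------------------
# Built-in benchmark designs
# ---------------------------------------------------------------------------

_LINEAGES = {
    "Saccharomyces cerevisiae": (
        "k__Fungi;p__Ascomycota;c__Saccharomycetes;o__Saccharomycetales;"
        "f__Saccharomycetaceae;g__Saccharomyces;s__Saccharomyces_cerevisiae"
    ),
    "Metschnikowia pulcherrima": (
        "k__Fungi;p__Ascomycota;c__Saccharomycetes;o__Saccharomycetales;"
        "f__Metschnikowiaceae;g__Metschnikowia;s__Metschnikowia_pulcherrima"
    ),
    "Torulaspora delbrueckii": (
        "k__Fungi;p__Ascomycota;c__Saccharomycetes;o__Saccharomycetales;"
        "f__Saccharomycetaceae;g__Torulaspora;s__Torulaspora_delbrueckii"
    ),
    "Debaryomyces hansenii": (
        "k__Fungi;p__Ascomycota;c__Saccharomycetes;o__Saccharomycetales;"
        "f__Debaryomycetaceae;g__Debaryomyces;s__Debaryomyces_hansenii"
    ),
    "Saccharomyces uvarum": (
        "k__Fungi;p__Ascomycota;c__Saccharomycetes;o__Saccharomycetales;"
        "f__Saccharomycetaceae;g__Saccharomyces;s__Saccharomyces_uvarum"
    ),
    "Hanseniaspora uvarum": (
        "k__Fungi;p__Ascomycota;c__Saccharomycetes;o__Saccharomycetales;"
        "f__Saccharomycodaceae;g__Hanseniaspora;s__Hanseniaspora_uvarum"
    ),
}

# desk-scale genome lengths: roughly 1/100 of the real assemblies, so a
# 10-kb windowing still yields ~9-15 windows per genome
_GENOME_KB = {
    "Saccharomyces cerevisiae": 121_000,
    "Metschnikowia pulcherrima": 153_000,
    "Torulaspora delbrueckii": 93_000,
    "Debaryomyces hansenii": 124_000,
    "Saccharomyces uvarum": 116_000,
    "Hanseniaspora uvarum": 88_000,
}

# (strain, species, cells in mix 1, cells in mix 2)
_BENCH_STRAINS = [
    ("AWRI796", "Saccharomyces cerevisiae", 1e6, 1e8),
    ("AWRI1498", "Saccharomyces cerevisiae", 1e4, 1e8),
    ("AWRI1149", "Metschnikowia pulcherrima", 1e4, 1e6),
    ("AWRI1152", "Torulaspora delbrueckii", 1e6, 1e5),
    ("AWRI1157", "Debaryomyces hansenii", 1e7, 1e3),
    ("AWRI1176", "Saccharomyces uvarum", 1e3, 1e5),
    ("AWRI1274", "Hanseniaspora uvarum", 1e8, 1e4),
]

ANCHOR_SPECIES = "Saccharomyces cerevisiae"


def control_mix(
    mix: int,
    *,
    amp_bias: Mapping[str, float] | None = None,
    its_copy_number: int = 8,
    host_fraction: float = 0.0,
    seed: int = 0,
) -> MockDesign:
    """Built-in benchmark mock community (mix 1 or mix 2).

    Seven wine-yeast strains at the benchmark cell counts. By default the
    community is unbiased (all ``amp_bias`` 1.0, equal ITS copy number);
    pass ``amp_bias={"Metschnikowia pulcherrima": 10.0}`` to emulate a
    taxon-specific amplicon bias.
    """
    if mix not in (1, 2):
        raise ValueError("mix must be 1 or 2")
    bias = dict(amp_bias or {})
    taxa = []
    for strain, species, c1, c2 in _BENCH_STRAINS:
        taxa.append(
            TaxonSpec(
                label=species,
                strain=strain,
                cells=c1 if mix == 1 else c2,
                genome_length=_GENOME_KB[species],
                its_copy_number=its_copy_number,
                amp_bias=bias.pop(species, 1.0),
                taxonomy=_LINEAGES[species],
            )
        )
    if bias:
        raise ValueError(f"amp_bias given for unknown species: {sorted(bias)}")
    return MockDesign(
        taxa=taxa, host_fraction=host_fraction, seed=seed, name=f"control_mix_{mix}"
    )
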