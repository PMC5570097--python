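"""Simulation-based validation studies.

Two standard experiments over the built-in mock designs:

* :func:`recovery_cases` — unbiased communities: how far do the pipeline's
  observed/expected ratios stray from 1 for every taxon with enough
  expected reads?
* :func:`bias_recovery` — a community with a known ITS amplification bias
  on one taxon: does the cross-platform ratio-of-ratios recover it?

Both return plain tables/lists so callers can apply whatever acceptance
bound they need.
"""

from __future__ import annotations

import math
from typing import Sequence

import pandas as pd

from .compare import estimate_bias_factor
from .design import ANCHOR_SPECIES, MockDesign, TaxonSpec, control_mix, _GENOME_KB, _LINEAGES
from .pipeline import mock_community_experiment

DEVIATION_CAP = 999.0  # stands in for an infinite deviation (ratio 0)


def expected_pairs(design: MockDesign, platform: str, n_pairs: int) -> dict[str, float]:
    """Expected read-pair count per species on one platform."""
    w = design.its_weights() if platform == "ITS" else design.shotgun_weights()
    tot = sum(w.values())
    scale = n_pairs * (1.0 - design.host_fraction if platform == "shotgun" else 1.0)
    return {sp: scale * v / tot for sp, v in w.items()}


def _deviation(ratio: float) -> float:
    if ratio <= 0 or not math.isfinite(ratio):
        return DEVIATION_CAP
    return max(ratio, 1.0 / ratio)


def recovery_cases(
    designs: Sequence[MockDesign],
    seeds: Sequence[int],
    *,
    n_its_pairs: int = 50_000,
    n_shotgun_pairs: int = 50_000,
    error_rate: float = 0.01,
    min_expected: float = 100.0,
    anchor: str = ANCHOR_SPECIES,
) -> pd.DataFrame:
    """Run the full two-platform experiment per (design, seed).

    One row per (design, seed, non-anchor taxon) where at least one
    platform expects >= ``min_expected`` read pairs for the taxon;
    ``deviation`` is the worst fold departure from ratio 1 over the
    platforms that meet the expectation threshold (the anchor is excluded
    — its ratio is 1 by construction).
    """
    rows = []
    for design in designs:
        exp_its = expected_pairs(design, "ITS", n_its_pairs)
        exp_sg = expected_pairs(design, "shotgun", n_shotgun_pairs)
        for seed in seeds:
            exp = mock_community_experiment(
                design,
                n_its_pairs=n_its_pairs,
                n_shotgun_pairs=n_shotgun_pairs,
                error_rate=error_rate,
                seed=seed,
                anchor=anchor,
            )
            for sp in design.species():
                if sp == anchor:
                    continue
                platforms = []
                if exp_its[sp] >= min_expected:
                    platforms.append(exp.its_report.table.loc[sp, "ratio"])
                if exp_sg[sp] >= min_expected:
                    platforms.append(exp.shotgun_report.table.loc[sp, "ratio"])
                if not platforms:
                    continue
                rows.append(
                    {
                        "design": design.name,
                        "seed": seed,
                        "species": sp,
                        "its_ratio": exp.its_report.table.loc[sp, "ratio"],
                        "shotgun_ratio": exp.shotgun_report.table.loc[sp, "ratio"],
                        "deviation": max(_deviation(r) for r in platforms),
                    }
                )
    return pd.DataFrame(rows)


def deviation_quantile(cases: pd.DataFrame, q: float = 0.9) -> float:
    """Smallest fold bound satisfied by at least a fraction ``q`` of cases."""
    devs = sorted(cases["deviation"])
    idx = max(0, math.ceil(q * len(devs)) - 1)
    return float(devs[idx])


def bias_design(
    bias: float,
    *,
    biased_species: str = "Metschnikowia pulcherrima",
    seed: int = 0,
) -> MockDesign:
    """Three equal-abundance species with an ITS amplification bias on one.

    Equal cell counts put ample reads behind every taxon on both
    platforms, isolating the bias estimate from sampling noise.
    """
    species = [ANCHOR_SPECIES, biased_species, "Hanseniaspora uvarum"]
    taxa = [
        TaxonSpec(
            label=sp,
            strain=f"SYN{i + 1}",
            cells=1e6,
            genome_length=_GENOME_KB[sp],
            amp_bias=bias if sp == biased_species else 1.0,
            taxonomy=_LINEAGES[sp],
        )
        for i, sp in enumerate(species)
    ]
    return MockDesign(taxa=taxa, seed=seed, name=f"bias_{bias:g}")


def bias_recovery(
    bias: float,
    seeds: Sequence[int],
    *,
    n_its_pairs: int = 50_000,
    n_shotgun_pairs: int = 50_000,
    error_rate: float = 0.01,
    biased_species: str = "Metschnikowia pulcherrima",
) -> list[float]:
    """Estimated ITS/shotgun fold bias per seeded run."""
    design = bias_design(bias, biased_species=biased_species)
    estimates = []
    for seed in seeds:
        exp = mock_community_experiment(
            design,
            n_its_pairs=n_its_pairs,
            n_shotgun_pairs=n_shotgun_pairs,
            error_rate=error_rate,
            seed=seed,
        )
        est = estimate_bias_factor(exp.its_report, exp.shotgun_report, biased_species)
        estimates.append(float("nan") if est is None else est)
    return estimates


def benchmark_designs(seed: int = 0) -> list[MockDesign]:
    """Both built-in control mixes, unbiased, for recovery studies."""
    return [control_mix(1, seed=seed), control_mix(2, seed=seed + 1)]
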