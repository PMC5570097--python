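"""Cross-platform comparison of ITS-amplicon and shotgun abundances.

The central analysis: both platforms are scaled so that the anchor species
(*Saccharomyces cerevisiae*) sits at 10^6 (i.e. a theoretical 100 %
abundance), observed/expected ratios against the mock-community design are
internally normalised so the anchor's ratio is exactly 1, and taxa whose
ratio leaves the fold window are flagged as biased. The ITS/shotgun ratio
of ratios estimates the multiplicative amplicon bias factor for a taxon —
the correction to divide its ITS abundances by.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .design import ANCHOR_SPECIES, MockDesign

ANCHOR_SCALE = 1e6


@dataclass
class ScaledTable:
    """Per-taxon abundances scaled so the anchor taxon equals 10^6."""

    platform: str
    values: pd.Series
    anchor: str


def scale_to_anchor(
    table: Mapping[str, float] | pd.Series,
    anchor: str = ANCHOR_SPECIES,
    platform: str = "",
) -> ScaledTable:
    values = pd.Series(dict(table), dtype=float)
    if anchor not in values or values[anchor] <= 0:
        raise ValueError(f"anchor taxon {anchor!r} absent or non-positive")
    scaled = values * (ANCHOR_SCALE / values[anchor])
    return ScaledTable(platform=platform, values=scaled, anchor=anchor)


@dataclass
class BiasReport:
    """Observed/expected ratios, internally normalised to the anchor = 1."""

    platform: str
    anchor: str
    table: pd.DataFrame          # index taxon; expected, observed, ratio
    unexpected: dict[str, float] = field(default_factory=dict)
    fold_threshold: float | None = None

    @property
    def ratios(self) -> pd.Series:
        return self.table["ratio"]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")

    def to_json(self, path) -> None:
        doc = {
            "platform": self.platform,
            "anchor": self.anchor,
            "fold_threshold": self.fold_threshold,
            "taxa": self.table.reset_index().to_dict(orient="records"),
            "unexpected": self.unexpected,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)


def mock_ratios(
    observed: Mapping[str, float] | pd.Series,
    design: MockDesign | Mapping[str, float],
    anchor: str = ANCHOR_SPECIES,
    platform: str = "",
) -> BiasReport:
    """Observed/expected abundance ratios against a mock design.

    Expected abundance per species is the total cell count added to the
    mix (conspecific strains pooled). Raw ratios ``observed/expected`` are
    divided by the anchor's raw ratio, so the anchor reports exactly 1 and
    any overall scale factor on the observed values cancels. A taxon
    observed at 0 with expected > 0 reports ratio 0; observed taxa absent
    from the design are listed separately without a ratio.
    """
    expected = (
        design.species_cells() if isinstance(design, MockDesign) else dict(design)
    )
    obs = {k: float(v) for k, v in dict(observed).items()}
    if anchor not in expected:
        raise ValueError(f"anchor taxon {anchor!r} not in design")
    anchor_obs = obs.get(anchor, 0.0)
    if anchor_obs <= 0:
        raise ValueError(f"anchor taxon {anchor!r} not observed")
    anchor_raw = anchor_obs / expected[anchor]

    rows = {}
    for taxon, exp in expected.items():
        o = obs.get(taxon, 0.0)
        ratio = (o / exp) / anchor_raw if o > 0 else 0.0
        rows[taxon] = {"expected": exp, "observed": o, "ratio": ratio}
    unexpected = {t: v for t, v in obs.items() if t not in expected and v > 0}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "taxon"
    return BiasReport(
        platform=platform, anchor=anchor, table=table, unexpected=unexpected
    )


def flag_bias(report: BiasReport, fold_threshold: float = 5.0) -> list[str]:
    """Taxa whose ratio leaves ``[1/threshold, threshold]``.

    The rule is symmetric (over- and under-estimates flag alike) and a
    ratio of 0 with expected > 0 is always flagged.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    flagged = []
    for taxon, row in report.table.iterrows():
        r = row["ratio"]
        if (r == 0 and row["expected"] > 0) or (
            r > 0 and (r > fold_threshold or r < 1 / fold_threshold)
        ):
            flagged.append(taxon)
    report.table["flagged"] = report.table.index.isin(flagged)
    report.fold_threshold = fold_threshold
    return flagged


@dataclass
class AgreementResult:
    r_squared: float | None
    fold_differences: pd.Series          # ITS / shotgun, shared positive taxa
    single_platform_taxa: dict[str, str]  # taxon -> platform where positive
    n_shared: int
    reason: str | None = None


def platform_agreement(
    its: ScaledTable, shotgun: ScaledTable
) -> AgreementResult:
    """Squared correlation of log10 scaled abundances across platforms.

    Only taxa positive on both platforms enter the regression (zeros are
    reported separately, not pseudocounted); fewer than 3 shared positive
    taxa leaves R^2 undefined.
    """
    a, b = its.values, shotgun.values
    taxa = a.index.union(b.index)
    a = a.reindex(taxa, fill_value=0.0)
    b = b.reindex(taxa, fill_value=0.0)
    shared = taxa[(a > 0) & (b > 0)]
    single = {}
    for t in taxa:
        if (a[t] > 0) != (b[t] > 0):
            single[t] = its.platform or "ITS" if a[t] > 0 else (
                shotgun.platform or "shotgun"
            )
    folds = (a[shared] / b[shared]).rename("fold_difference")
    if len(shared) < 3:
        return AgreementResult(
            r_squared=None, fold_differences=folds,
            single_platform_taxa=single, n_shared=len(shared),
            reason="fewer than 3 taxa positive on both platforms",
        )
    x = np.log10(b[shared].to_numpy())
    y = np.log10(a[shared].to_numpy())
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        r2 = 1.0 if np.allclose(x - x.mean(), y - y.mean()) else None
        return AgreementResult(
            r_squared=r2, fold_differences=folds,
            single_platform_taxa=single, n_shared=len(shared),
            reason=None if r2 is not None else "degenerate (constant) values",
        )
    fit = stats.linregress(x, y)
    return AgreementResult(
        r_squared=float(fit.rvalue ** 2),
        fold_differences=folds,
        single_platform_taxa=single,
        n_shared=len(shared),
    )


def estimate_bias_factor(
    its_report: BiasReport,
    shotgun_report: BiasReport,
    taxon: str,
) -> float | None:
    """ITS/shotgun fold bias for one taxon: ratio_ITS / ratio_shotgun.

    This is the multiplicative correction factor to divide the taxon's ITS
    abundances by. Returns ``None`` (undefined) when the shotgun ratio is 0.
    """
    if taxon not in its_report.table.index or taxon not in shotgun_report.table.index:
        raise KeyError(f"taxon {taxon!r} missing from a report")
    r_its = its_report.table.loc[taxon, "ratio"]
    r_sg = shotgun_report.table.loc[taxon, "ratio"]
    if r_sg == 0:
        return None
    return float(r_its / r_sg)
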