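import numpy as np
import pytest
from hypothesis import settings

from fermentome import MockDesign, TaxonSpec, build_references

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

LINEAGE_A = (
    "k__Fungi;p__Ascomycota;c__Saccharomycetes;o__Saccharomycetales;"
    "f__Saccharomycetaceae;g__Saccharomyces;s__Saccharomyces_cerevisiae"
)
LINEAGE_B = (
    "k__Fungi;p__Ascomycota;c__Saccharomycetes;o__Saccharomycetales;"
    "f__Saccharomycodaceae;g__Hanseniaspora;s__Hanseniaspora_uvarum"
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def two_taxon_design():
    """Small two-species community for fast unit tests."""
    return MockDesign(
        taxa=[
            TaxonSpec(
                label="Saccharomyces cerevisiae",
                strain="S1",
                cells=1e6,
                genome_length=30_000,
                its_copy_number=3,
                taxonomy=LINEAGE_A,
            ),
            TaxonSpec(
                label="Hanseniaspora uvarum",
                strain="H1",
                cells=1e6,
                genome_length=25_000,
                its_copy_number=3,
                taxonomy=LINEAGE_B,
            ),
        ],
        seed=11,
        name="tiny",
    )


@pytest.fixture
def two_taxon_refs(two_taxon_design):
    return build_references(two_taxon_design, host_length=20_000)
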