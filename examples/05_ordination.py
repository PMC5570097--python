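"""Community succession seen through Bray-Curtis + PCoA.

Builds a small abundance table emulating a fermentation time course —
early samples dominated by apiculate yeasts, late samples by
Saccharomyces — and embeds the samples with classical scaling on
Bray-Curtis dissimilarities, overlaying per-taxon axis weightings.
"""

import pandas as pd

import fermentome as fm

table = pd.DataFrame(
    {
        "D0_a": [5, 420, 380, 160, 2],
        "D0_b": [8, 390, 405, 140, 3],
        "D1_a": [160, 260, 200, 60, 1],
        "D1_b": [150, 285, 170, 75, 2],
        "D2_a": [700, 60, 30, 10, 0],
        "D3_a": [940, 5, 2, 1, 0],
    },
    index=[
        "Saccharomyces", "Hanseniaspora", "Metschnikowia",
        "Aureobasidium", "Rhodotorula",
    ],
)

reduced = fm.top_n_taxa(table, 30)
dm = fm.dissimilarity_matrix(reduced)
print("Bray-Curtis dissimilarities:")
print(dm.round(3).to_string())

ordination = fm.pcoa(dm, k=2)
print("\nPCoA coordinates (axis1 separates early from late ferment):")
print(ordination.coordinates.round(3).to_string())
print("eigenvalues:", [round(float(v), 3) for v in ordination.eigenvalues])

w = fm.taxon_weightings(reduced, ordination)
print("\ntaxon weightings (covariance with each axis, unit-max scaled):")
print(w.round(3).to_string())
print("\nTaxa loading opposite to Saccharomyces on axis1 are the early-"
      "\nferment community; node_size is total abundance for plotting.")
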