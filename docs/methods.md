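# Methods

This note documents the models, conventions and numerical choices behind
`fermentome`, in the order data flows through the package.

## Synthetic-community generator

The generator exists so that every pipeline stage can be exercised with
exact ground truth. A `MockDesign` lists strains with cell counts, genome
lengths, ribosomal ITS copy numbers and a multiplicative ITS
amplification bias (`amp_bias`, 1 = unbiased). The two built-in
`control_mix` designs reproduce a published two-mix wine-yeast benchmark
layout: seven strains of six species with cell counts spanning
1e3–1e8.

**Genomes.** One genome per *species* (conspecific strains share it, as
they are indistinguishable at both assay resolutions), drawn i.i.d.
uniform over {A,C,G,T}. This makes k-mers essentially unique, so a
minimal seed-and-extend mapper is adequate — by construction, not by
accident. Desk-scale lengths are roughly 1/100 of the real assemblies
(88–153 kb), keeping 9–15 windows per genome under the 10-kb tiling.
`its_copy_number` identical ITS copies (default 8) are embedded at
evenly blocked random positions; a genome too short to host its copies
is rejected with an explanatory error.

**ITS references.** One random ITS core per species (default 150 bp, a
realistic short fungal ITS amplicon), redrawn until all inter-species
identities are < 0.9 so classification at the 0.98 similarity threshold
is unambiguous. Strains of one species share the ITS sequence.

**ITS amplicons.** Pair counts per strain are multinomial with weights
`cells × its_copy_number × amp_bias`. Each amplicon is
`barcode | spacer | primer | ITS | rc(primer) | rc(spacer) | rc(barcode)`
with the sample entry drawn uniformly from the barcode scheme and
IUPAC-degenerate primer positions resolved per molecule. Mates of 150 bp
read the amplicon from both ends (Illumina adapter bases pad reads that
run past a short amplicon).

**Shotgun reads.** Pair counts per species are multinomial with weights
`cells × genome_length` over `1 − host_fraction` of the pairs; the rest
come from a generated host (grapevine-like) genome (default 120 kb).
No `amp_bias` term enters — the shotgun channel is deliberately the
unbiased one. Fragment starts are uniform, insert sizes normal
(350 ± 35 bp, clipped to ≥ read length, so adapter read-through is not
modelled in this channel), reads 2 × 100 bp.

**Error model.** Substitutions only, i.i.d. per base (default 1 %);
no indels, chimeras, PCR duplicates or position-dependent quality. Base
qualities are constant Q40 except an optional linearly decaying 3' tail
(down to Q2) used to exercise quality trimming. Every function that
consumes randomness takes an explicit integer seed, and identical seeds
give byte-identical FASTA/FASTQ.

What the generator does **not** emulate — and what passing tests
therefore cannot show about real data: phylogenetically similar ITS
sequences (real congeners can exceed 0.98 identity and merge into one
OTU), length-variable ITS regions, conserved primer-site context inside
real genomes, repeat structure that defeats unique mapping, and
platform-specific error spectra. The recovery studies validate the
pipeline's arithmetic and its statistical behaviour under the stated
model, not classifier performance on real UNITE-scale databases.

## ITS amplicon branch

* **Quality trimming** removes 3' bases while the terminal quality is
  below Q20 and rejects reads shorter than 50 bp afterwards. Internal
  dips are left alone (the rule is 3'-anchored).
* **Merging** slides the reverse-complemented mate over every ungapped
  offset with ≥ 10 overlapping bases, including negative offsets
  ("outies", inserts shorter than the read length). The offset
  maximising `matches − mismatches` wins; ties keep the smallest offset;
  offsets with mismatch fraction > 0.25 are disallowed. Disagreements
  take the higher-quality base (ties: forward). Innie merges keep the
  flanks; outie merges keep only the overlap, since the dangling ends
  are adapter read-through. Pairs are processed in same-length groups as
  whole-array comparisons, which is what makes a 50,000-pair merge take
  seconds rather than minutes.
* **Residual adapter trimming** removes the longest read prefix matching
  a suffix of `CTTCCGATCT`, and read suffix matching a prefix of
  `AGATCGGAAG`, over ≥ 6 bases at ≤ 10 % mismatches — an end-anchored
  simplification of general adapter trimming, sufficient for merged
  amplicons.
* **Demultiplexing** assigns a read to the unique scheme entry whose
  forward AND reverse 8-bp barcodes match within 1 mismatch. Because
  merged reads have ambiguous orientation and the default scheme reuses
  one index at both ends, barcodes alone cannot orient a read: the
  primer context (IUPAC-aware, ≤ 20 % mismatches) is verified as part of
  matching, and the reverse-complemented orientation is tried when the
  forward orientation matches nothing. Barcodes, spacers and primers are
  stripped; the stripped context is retained so assignment is exactly
  invertible. Scheme validation requires ≥ 3 pairwise Hamming distance
  between distinct barcodes within each end, making 1-mismatch
  assignment unambiguous by construction.
* **Dereplication** collapses identical uppercased sequences; the record
  key is the md5 hex digest of the sequence, giving cross-experiment
  stable OTU names. Ordering is (descending count, then key).
* **Clustering** defines OTUs as connected components of the graph
  linking dereplicated sequences at Levenshtein distance ≤ d (default
  d = 1, the single-linkage swarm-style radius). Candidate neighbour
  pairs are found with a deletion-signature index: two sequences are
  within one edit only if they share their full-sequence hash or a
  single-deletion hash, so sequences are bucketed by 64-bit polynomial
  hashes of the sequence and of all its single-deletion variants, and
  bucket pairs are verified with a banded alignment (edlib, k = 1). Hash
  collisions can only nominate candidates, never create links. Cluster
  abundance sums member counts; the representative is the most abundant
  member (ties: smallest key); clusters under `min_size = 10` total
  reads are discarded after clustering. An optional "fastidious" flag
  grafts discarded micro-clusters (< 3 reads) onto a retained cluster
  whose representative lies within distance 2; it is off by default and
  not part of the validated contract.
* **Taxonomy** follows the uclust-style consensus: up to 10 references
  at ≥ 0.98 global-alignment identity (edlib NW; identity
  `1 − edits/max(len)`), then rank-by-rank majority with the label kept
  only while its fraction is ≥ 0.4 *and* it is the unique mode — the
  fraction parameter alone leaves ties undefined, so ties truncate to
  the parent rank. No accepted reference yields `Unassigned`.

Read counts are conserved exactly at every stage
(kept + rejected = input), and the clustering equals a brute-force
connected-components oracle on randomized instances — both are asserted
in the test suite.

## Shotgun branch

* **Host filtering** retains a pair only when *neither* mate aligns to
  the host genome; a missing mate counts as failing to align.
* **Mapping** is a minimal ungapped seed-and-extend aligner: 21-mer
  seeds tiled across the read (both strands), each seed hit extended
  end-to-end with vectorised mismatch counting, acceptance at ≤ 10 %
  mismatches. A best placement tied across ≥ 2 locations marks the read
  non-unique and excludes it from coverage — the testable essence of a
  mapping-quality cutoff, whose exact semantics are aligner-specific.
  Pairs with both mates placed must be concordant (same target, opposite
  strands, insert ≤ 1500 bp) or the pair is dropped; a mate whose
  partner is unaligned is kept. This mapper is adequate for the i.i.d.
  synthetic genomes; real-data users should ingest externally produced
  SAM via `read_alignments_sam` (primary records, NM tag). A
  per-reference exclude list supports dropping high-copy sequences such
  as mitochondria.
* **Windows** tile each reference half-open at 10 kb with a short
  trailing remainder. A read increments every window it overlaps by
  ≥ 1 base, so boundary-spanning reads count in both windows (matching
  the overlap semantics of standard coverage counting); each aligned
  mate counts as one read. `id_factor` is the mean over contributing
  reads of `1 − mismatches/read_length`, undefined (NaN) for empty
  windows.
* **Species summaries** take mean and median over *all* windows of a
  species (zero-count windows included; window read counts, not
  per-base depth), `breadth` = fraction of windows with ≥ 1 read, and
  the adjusted mean = mean if breadth ≥ 0.2 else 0. Normalisation is
  `adjusted_mean × 10^6 / total_sample_reads`, with the total counted
  before host filtering and including unaligned reads.

## Cross-platform comparison

Tables scale so the anchor species (*S. cerevisiae*) equals 1e6 — a
theoretical 100 % abundance — making ITS fragment counts and per-window
shotgun abundances directly comparable. Observed/expected ratios divide
by the anchor's raw ratio (anchor ≡ 1; the normalisation makes ratios
invariant to any global scale on the observed table, which is asserted
as a property test). Expected abundance pools conspecific strains' cells
since neither assay separates them. Flagging is symmetric
(`r > f` or `r < 1/f`; `r = 0` with expected > 0 always flags); defaults
are f = 2 for reporting and f = 5 for headline calls. Platform agreement
is the R² of an ordinary least-squares fit on log10 scaled abundances
over taxa positive on both platforms — zeros are excluded and reported
separately, not pseudocounted, a documented convention rather than a
claim about how any particular published figure was computed. The bias
factor is `ratio_ITS / ratio_shotgun`, undefined when the shotgun ratio
is 0.

## Community structure

Bray–Curtis dissimilarity `1 − 2Σmin/(Σu+Σv)` (undefined for two
all-zero profiles) over the top-N (default 30) taxa by total abundance,
ties broken lexicographically with input row order preserved. PCoA is
classical scaling: double-centre `−d²/2`, eigendecompose, scale
eigenvectors by √eigenvalue. Bray–Curtis matrices are generally
non-Euclidean, so negative eigenvalues occur; they are reported but
excluded from coordinates, with no Lingoes/Cailliez correction by
default — the simplest defensible convention. Axis signs are fixed by
making the first nonzero coordinate of each axis positive. Taxon
weightings are covariances between taxon abundance and axis coordinates,
rescaled per axis to unit maximum absolute value; node sizes are total
abundances. Abundances are used as given — no rarefaction.

## Validation studies and problem sizes

Two simulation studies back the package's claims, both run by
`scripts/acceptance.py` and/or the test suite at sizes chosen to give
stable statistics at desk scale:

* **Unbiased recovery** — both control-mix designs, all `amp_bias` = 1,
  equal copy numbers, 50,000 ITS + 50,000 shotgun pairs, five seeds,
  1 % error. For every non-anchor taxon with ≥ 100 expected read pairs
  on a platform, the deviation `max(r, 1/r)` is recorded; the headline
  statistic is the fold bound that ≥ 90 % of (taxon, seed) cases meet.
  Error-generated singleton sequences fall below the minimum OTU size
  and are discarded, slightly and *differentially* shrinking rare taxa
  (fewer one-error intermediates connect their two-error reads), which
  is the main driver of residual deviation — it stays well inside
  2-fold at these depths.
* **Bias recovery** — a three-species equal-cell design with
  `amp_bias = 10` on *Metschnikowia pulcherrima*, ten seeds at the same
  depths; the ratio-of-ratios estimator recovers the factor within
  2-fold in ≥ 9/10 runs.

## Degenerate inputs and tie-breaks (summary)

Empty mate → merge rejection counted separately; ambiguous or unmatched
barcodes → `unassigned` bin; zero accepted references → `Unassigned`;
anchor absent/zero → hard failure naming the anchor; two all-zero
profiles → explicit error; `k` above the available positive eigenvalues
→ truncation with a warning; zero-read species windows → mean 0, NaN
identity. All orderings (dereplication, clusters, accepts, top-N) break
ties by (higher abundance, then lexicographic key/name) for determinism.

## Known limitations

The mapper and classifier are deliberately minimal and should not be
pointed at real genomes; ingest external SAM instead. The amplicon
branch models substitution errors only, so indel-rich platforms would
need the clustering radius reconsidered. Correction factors estimated
from mocks are emitted but never automatically applied to external
tables. R² on real published datasets is not claimed to be reproduced
exactly, since the published computation's zero-handling and scale are
not fully specified.
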