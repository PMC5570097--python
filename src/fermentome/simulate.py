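"""Synthetic-community sequencing simulator.

Generates, from a :class:`~fermentome.design.MockDesign`, everything the
analysis pipeline consumes: reference genomes with embedded ribosomal ITS
repeats, an ITS reference database with lineages, biased ITS amplicon read
pairs, and shotgun read pairs with a host-contaminant fraction — all with
per-read ground truth.

Model choices
-------------
* Genomes are i.i.d. uniform over {A,C,G,T}; k-mers are effectively unique,
  which is what makes a minimal seed-and-extend mapper adequate.
* ITS amplicon counts per strain are multinomial with weights
  ``cells x its_copy_number x amp_bias``; shotgun pair counts use
  ``cells x genome_length`` (no bias term — shotgun is the unbiased channel).
* Errors are substitutions only, i.i.d. per base.
* Base qualities are constant Q40, with an optional decaying 3' tail to
  exercise quality trimming.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .barcodes import BarcodeScheme, ILLUMINA_ADAPTER_3P, IUPAC, default_scheme
from .design import HOST_LABEL, GroundTruth, MockDesign
from .io import ensure_dir, revcomp, write_fasta, Read

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

MAX_ERROR_RATE = 0.2


def _rand_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _identity(a: str, b: str) -> float:
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def _instantiate_primer(primer: str, rng: np.random.Generator) -> str:
    """Resolve IUPAC-degenerate positions to a concrete base."""
    out = []
    for ch in primer:
        opts = IUPAC.get(ch, ch)
        out.append(opts if len(opts) == 1 else opts[int(rng.integers(len(opts)))])
    return "".join(out)


def _add_errors(mat: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitution errors: each erroneous base moves to a different base."""
    if error_rate <= 0:
        return mat
    mask = rng.random(mat.shape) < error_rate
    shift = rng.integers(1, 4, size=mat.shape, dtype=np.uint8)
    out = mat.copy()
    out[mask] = (out[mask] + shift[mask]) % 4
    return out


def _matrix_to_reads(mat: np.ndarray, ids: list[str], qual: str) -> list[Read]:
    big = _BASES[mat].tobytes()
    length = mat.shape[1]
    return [
        Read(rid, big[i * length:(i + 1) * length].decode(), qual)
        for i, rid in enumerate(ids)
    ]


def _quality_string(length: int, tail: int) -> str:
    """Constant Q40, with an optional linearly decaying tail down to Q2."""
    if tail <= 0 or tail > length:
        return chr(33 + 40) * length
    head = chr(33 + 40) * (length - tail)
    quals = np.linspace(18, 2, tail).astype(int)
    return head + "".join(chr(33 + q) for q in quals)


# ---------------------------------------------------------------------------
# References
# ---------------------------------------------------------------------------


@dataclass
class ReferenceSet:
    """Genomes + ITS reference database generated for one design."""

    genomes: dict[str, str]           # species -> genome sequence
    its: dict[str, str]               # species -> ITS core sequence
    taxonomy: dict[str, str]          # species -> rank-delimited lineage
    host: str                         # host (grapevine-like) genome
    its_length: int
    host_name: str = "host_plant"
    its_positions: dict[str, list[int]] = field(default_factory=dict)

    def genome_lengths(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.genomes.items()}

    def write(self, outdir) -> None:
        out = ensure_dir(outdir)
        write_fasta(out / "genomes.fasta",
                    {k.replace(" ", "_"): v for k, v in self.genomes.items()})
        write_fasta(out / "host.fasta", {self.host_name: self.host})
        write_fasta(out / "its_refs.fasta",
                    {k.replace(" ", "_"): v for k, v in self.its.items()})
        with open(out / "its_taxonomy.tsv", "w") as fh:
            for sp, lin in self.taxonomy.items():
                fh.write(f"{sp.replace(' ', '_')}\t{lin}\n")


MAX_INTER_TAXON_ITS_IDENTITY = 0.9


def build_references(
    design: MockDesign,
    *,
    its_length: int = 150,
    host_length: int = 120_000,
    seed: int | None = None,
) -> ReferenceSet:
    """Generate one genome per species with embedded ITS repeats.

    Each species gets a random genome of the designed length carrying
    ``its_copy_number`` identical copies of its ITS core, plus one entry in
    the ITS reference database. ITS sequences are redrawn until every
    inter-species pairwise identity is < 0.9, so taxonomy assignment at the
    0.98 similarity threshold is unambiguous. Identical seeds give
    byte-identical output.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    species = design.species()
    copy_num = {t.label: t.its_copy_number for t in design.taxa}
    glen = design.species_genome_length()

    for sp in species:
        if glen[sp] < copy_num[sp] * its_length:
            raise ValueError(
                f"{sp}: genome of {glen[sp]} bp cannot host "
                f"{copy_num[sp]} ITS copies of {its_length} bp"
            )

    its: dict[str, str] = {}
    for sp in species:
        for _attempt in range(100):
            cand = _decode(_rand_bases(rng, its_length))
            if all(_identity(cand, prev) < MAX_INTER_TAXON_ITS_IDENTITY
                   for prev in its.values()):
                its[sp] = cand
                break
        else:  # pragma: no cover - astronomically unlikely for random seqs
            raise RuntimeError(f"could not draw a distinct ITS for {sp}")

    genomes: dict[str, str] = {}
    positions: dict[str, list[int]] = {}
    for sp in species:
        g = _rand_bases(rng, glen[sp])
        its_arr = _encode(its[sp])
        copies = copy_num[sp]
        block = glen[sp] // copies
        starts = []
        for i in range(copies):
            offset = int(rng.integers(0, block - its_length + 1))
            start = i * block + offset
            g[start:start + its_length] = its_arr
            starts.append(start)
        genomes[sp] = _decode(g)
        positions[sp] = starts

    host = _decode(_rand_bases(rng, host_length))
    return ReferenceSet(
        genomes=genomes,
        its=its,
        taxonomy=design.species_taxonomy(),
        host=host,
        its_length=its_length,
        its_positions=positions,
    )


# ---------------------------------------------------------------------------
# ITS amplicon simulation
# ---------------------------------------------------------------------------


def simulate_its_reads(
    design: MockDesign,
    refs: ReferenceSet,
    n_pairs: int,
    *,
    error_rate: float = 0.01,
    scheme: BarcodeScheme | None = None,
    read_length: int = 150,
    quality_tail: int = 0,
    seed: int = 0,
) -> tuple[list[Read], list[Read], GroundTruth]:
    """Simulate paired ITS amplicon reads with inline barcodes.

    Per-strain pair counts are multinomial with weights
    ``cells x its_copy_number x amp_bias``. Each amplicon is
    ``barcode|spacer|primer|ITS|rc(primer)|rc(spacer)|rc(barcode)``; mates
    read the amplicon from both ends (padded with Illumina adapter sequence
    when the amplicon is shorter than the read length) and then receive
    i.i.d. substitution errors.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be > 0")
    if not 0.0 <= error_rate <= MAX_ERROR_RATE:
        raise ValueError(f"error_rate must be in [0, {MAX_ERROR_RATE}]")
    for t in design.taxa:
        if t.genome_length < 10 * read_length:
            raise ValueError(f"{t.label}: genome_length < 10 x read length")
    scheme = scheme or default_scheme()
    rng = np.random.default_rng(seed)

    weights = np.array(
        [t.cells * t.its_copy_number * t.amp_bias for t in design.taxa], float
    )
    counts = rng.multinomial(n_pairs, weights / weights.sum())
    entry_idx = rng.integers(0, len(scheme), size=n_pairs)

    fwd_seqs: list[str] = []
    rev_seqs: list[str] = []
    sources: dict[str, str] = {}
    samples: dict[str, str] = {}
    ids: list[str] = []
    i = 0
    for strain, c in zip(design.taxa, counts):
        core = refs.its[strain.label]
        for _ in range(int(c)):
            e = scheme.entries[int(entry_idx[i])]
            fp = _instantiate_primer(e.fwd_primer, rng)
            rp = _instantiate_primer(e.rev_primer, rng)
            amplicon = (
                e.fwd_barcode + e.fwd_spacer + fp + core
                + revcomp(rp) + revcomp(e.rev_spacer) + revcomp(e.rev_barcode)
            )
            fwd = amplicon
            rev = revcomp(amplicon)
            if len(amplicon) < read_length:
                pad = (ILLUMINA_ADAPTER_3P * read_length)
                fwd = (fwd + pad)[:read_length]
                rev = (rev + pad)[:read_length]
            rid = f"{design.name}_its_{i}"
            ids.append(rid)
            sources[rid] = strain.label
            samples[rid] = e.sample_id
            fwd_seqs.append(fwd[:read_length])
            rev_seqs.append(rev[:read_length])
            i += 1

    fmat = _add_errors(
        _CODE[np.frombuffer("".join(fwd_seqs).encode(), np.uint8)].reshape(-1, read_length),
        error_rate, rng,
    )
    rmat = _add_errors(
        _CODE[np.frombuffer("".join(rev_seqs).encode(), np.uint8)].reshape(-1, read_length),
        error_rate, rng,
    )
    qual = _quality_string(read_length, quality_tail)
    fwd_reads = _matrix_to_reads(fmat, [f"{r}/1" for r in ids], qual)
    rev_reads = _matrix_to_reads(rmat, [f"{r}/2" for r in ids], qual)

    props = design.its_proportions()
    truth = GroundTruth(proportions=props, read_sources=sources, read_samples=samples)
    return fwd_reads, rev_reads, truth


# ---------------------------------------------------------------------------
# Shotgun simulation
# ---------------------------------------------------------------------------


def simulate_shotgun_reads(
    design: MockDesign,
    refs: ReferenceSet,
    n_pairs: int,
    *,
    error_rate: float = 0.01,
    read_length: int = 100,
    insert_mean: int = 350,
    insert_sd: float = 35.0,
    seed: int = 0,
) -> tuple[list[Read], list[Read], GroundTruth]:
    """Simulate paired shotgun reads, host contamination included.

    Pair counts per species are multinomial with weights
    ``cells x genome_length`` over ``1 - host_fraction`` of the pairs; the
    remaining ``host_fraction`` is drawn from the generated host genome.
    Fragment starts are uniform; insert sizes are normal, clipped to
    ``[read_length, genome length]``.
    """
    if n_pairs < 0:
        raise ValueError("n_pairs must be >= 0")
    if not 0.0 <= error_rate <= MAX_ERROR_RATE:
        raise ValueError(f"error_rate must be in [0, {MAX_ERROR_RATE}]")
    rng = np.random.default_rng(seed)
    props = design.shotgun_proportions()
    labels = list(props)
    if n_pairs == 0:
        return [], [], GroundTruth(proportions=props, read_sources={})

    counts = rng.multinomial(n_pairs, np.array([props[k] for k in labels]))
    encoded = {sp: _encode(g) for sp, g in refs.genomes.items()}
    encoded[HOST_LABEL] = _encode(refs.host)

    fparts, rparts, ids, sources = [], [], [], {}
    i = 0
    for label, c in zip(labels, counts):
        c = int(c)
        if c == 0:
            continue
        g = encoded[label]
        L = len(g)
        inserts = np.clip(
            np.rint(rng.normal(insert_mean, insert_sd, size=c)).astype(np.int64),
            read_length, L,
        )
        starts = np.floor(rng.random(c) * (L - inserts + 1)).astype(np.int64)
        fidx = starts[:, None] + np.arange(read_length)
        ridx = (starts + inserts - 1)[:, None] - np.arange(read_length)
        fparts.append(g[fidx])
        rparts.append((3 - g[ridx]).astype(np.uint8))  # reverse complement
        for _ in range(c):
            rid = f"{design.name}_sg_{i}"
            ids.append(rid)
            sources[rid] = label
            i += 1

    fmat = _add_errors(np.vstack(fparts), error_rate, rng)
    rmat = _add_errors(np.vstack(rparts), error_rate, rng)
    qual = _quality_string(read_length, 0)
    fwd_reads = _matrix_to_reads(fmat, [f"{r}/1" for r in ids], qual)
    rev_reads = _matrix_to_reads(rmat, [f"{r}/2" for r in ids], qual)
    truth = GroundTruth(proportions=props, read_sources=sources)
    return fwd_reads, rev_reads, truth
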