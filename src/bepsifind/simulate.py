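"""Synthetic genomes, annotations and small-RNA libraries with planted truth.

The generator emulates the structure of the study system: a genome carrying
convergently transcribed gene pairs in several geometries (3'-overlapping,
gapped with the gap bridgeable or not by a 300-nt polymerase-readthrough
zone, antisense genes nested inside a host intron, and tandem same-strand
controls), plus transposon consensus families and single-stranded miRNA
source loci.  Condition-specific libraries are drawn multinomially:
"dependent" siRNA loci lose a configurable fold (default 8x) in the
export-factor shutdown condition, every siRNA source loses a global fold in
the dicer-null condition, and the rescue condition equals wild type.  siRNA
reads are 21-mers sampled uniformly from each pair's duplex window — the
interval where both transcripts (including readthrough) can anneal — with
strand Bernoulli(0.5); miRNA reads are fixed-sense.  Each read records
whether the simulated molecule carries a 3'-terminal 2'-O-methyl group
(siRNA classes yes, miRNA no), which governs survival of simulated periodate
oxidation; the pipeline never reads this flag.

Ground truth (locus coordinates, geometry, planted multipliers, per-read
methylation) is serialized alongside every dataset for recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotation import GeneRecord, GenomicInterval
from .binding import BindingCurve, fraction_bound
from .reads import ExactIndex, SmallRNARead, reverse_complement

CONDITIONS = ("wt", "blanks_shutdown", "dcr2_shutdown", "rescue")
_COND_SEED = {c: i + 1 for i, c in enumerate(CONDITIONS)}

GEOMETRIES = ("overlapping", "gapped_near", "gapped_far", "nested", "tandem")
# geometries whose pairs are recoverable by region compilation at ext=300
RECOVERABLE = {"overlapping", "gapped_near", "nested"}

# Illumina TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class ScenarioConfig:
    """Study-condition parameters for one synthetic scenario.

    Defaults describe the reference scenario: 100 recoverable convergent
    loci (60 overlapping, 30 bridgeably gapped, 10 intron-nested), 20 of
    them dependent on the export factor at 8-fold, a 10-fold global
    reduction of all siRNA sources in the dicer-null condition, and
    one million reads per library split roughly 40/35/25 between
    convergent-locus siRNAs, transposon siRNAs and miRNAs.
    """

    seed: int = 0
    chrom_id: str = "chrSim"
    genome_len: int | None = None  # optional floor; layout dictates the minimum
    n_overlapping: int = 60
    n_gapped_near: int = 30  # gap <= 300 nt: readthrough bridges it
    n_gapped_far: int = 5  # gap > 300 nt: no duplex, never recovered
    n_nested: int = 10
    n_tandem: int = 5  # same-strand control, no duplex
    n_dependent_loci: int = 20
    dependent_fold: float = 8.0
    dcr2_global_fold: float = 10.0
    n_te_families: int = 8
    te_len_range: tuple[int, int] = (1000, 7000)
    mirna_count: int = 30
    read_depth: int = 1_000_000
    sirna_fraction: float = 0.40
    te_fraction: float = 0.35
    mirna_fraction: float = 0.25
    oxidation_survival_unmethylated: float = 0.05
    adapter: str = DEFAULT_ADAPTER
    raw_read_length: int = 34
    gene_len_range: tuple[int, int] = (800, 2000)
    spacer: int = 500  # > extension, so adjacent blocks never pair
    locus_weight_sigma: float = 0.8

    def __post_init__(self) -> None:
        if self.n_dependent_loci > self.n_recoverable:
            raise ValueError("dependent loci must be a subset of recoverable loci")
        if not 0.0 <= self.oxidation_survival_unmethylated <= 1.0:
            raise ValueError("oxidation survival must be in [0, 1]")
        if self.dependent_fold < 1 or self.dcr2_global_fold < 1:
            raise ValueError("fold changes must be >= 1")
        fr = self.sirna_fraction + self.te_fraction + self.mirna_fraction
        if abs(fr - 1.0) > 1e-9:
            raise ValueError(f"class fractions sum to {fr}, expected 1")

    @property
    def n_recoverable(self) -> int:
        return self.n_overlapping + self.n_gapped_near + self.n_nested


@dataclass
class PlantedLocus:
    """Ground truth for one planted gene pair."""

    locus_id: str
    geometry: str
    anchor: GeneRecord
    partner: GeneRecord
    duplex_window: GenomicInterval | None  # None when no duplex forms
    base_weight: float
    dependent: bool

    @property
    def recoverable(self) -> bool:
        return self.geometry in RECOVERABLE

    @property
    def region_key(self) -> str:
        return f"{self.anchor.gene_id}|{self.partner.gene_id}"


@dataclass
class GroundTruth:
    """Planted truth, serialized next to every dataset; never read by the
    pipeline modules."""

    seed: int
    loci: list[PlantedLocus]
    mirna_weights: dict[str, float]
    te_weights: dict[str, float]
    chrom_len: int

    @property
    def dependent_keys(self) -> set[str]:
        return {l.region_key for l in self.loci if l.dependent}

    @property
    def recoverable_keys(self) -> set[str]:
        return {l.region_key for l in self.loci if l.recoverable}

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            raise TypeError(type(o).__name__)

        return json.dumps(dataclasses.asdict(self), default=enc, indent=1)


@dataclass
class Reference:
    """All pipeline inputs for one scenario, in memory."""

    genome: Mapping[str, str]
    genes: list[GeneRecord]
    te_seqs: Mapping[str, str]
    mirna_seqs: Mapping[str, str]
    truth: GroundTruth
    _index_cache: dict[int, ExactIndex] = field(default_factory=dict, repr=False)

    def genome_index(self, k: int = 21) -> ExactIndex:
        if k not in self._index_cache:
            self._index_cache[k] = ExactIndex(self.genome, k)
        return self._index_cache[k]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------

def _duplex_window(
    chrom: str, anchor: GeneRecord, partner: GeneRecord, ext: int = 300
) -> GenomicInterval | None:
    """Intersection of each gene's body-plus-3'-readthrough, if any."""
    a_start, a_end = anchor.start - 1, anchor.end + ext
    b_start, b_end = partner.start - 1 - ext, partner.end
    start, end = max(a_start, b_start), min(a_end, b_end)
    if end - start < 21:
        return None
    return GenomicInterval(chrom, start, end)


def make_reference(config: ScenarioConfig) -> Reference:
    """Build genome, annotation, TE and miRNA references with planted truth.

    Gene-pair blocks are laid out sequentially with a spacer wider than the
    3' extension, so region compilation recovers exactly the planted
    overlapping / bridgeably-gapped / nested pairs and nothing else.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    chrom = config.chrom_id
    glo, ghi = config.gene_len_range

    geometries = (
        ["overlapping"] * config.n_overlapping
        + ["gapped_near"] * config.n_gapped_near
        + ["nested"] * config.n_nested
        + ["gapped_far"] * config.n_gapped_far
        + ["tandem"] * config.n_tandem
    )

    genes: list[GeneRecord] = []
    loci: list[PlantedLocus] = []
    cursor = config.spacer
    for i, geom in enumerate(geometries):
        la = int(rng.integers(glo, ghi + 1))
        lb = int(rng.integers(glo, ghi + 1))
        if geom == "overlapping":
            ov = int(rng.integers(50, 301))
            a0, b0 = cursor, cursor + la - ov
        elif geom == "gapped_near":
            gap = int(rng.integers(20, 281))
            a0, b0 = cursor, cursor + la + gap
        elif geom == "gapped_far":
            gap = int(rng.integers(320, 501))
            a0, b0 = cursor, cursor + la + gap
        elif geom == "nested":
            la = int(rng.integers(2500, 3501))
            lb = int(rng.integers(500, 801))
            a0 = cursor
            b0 = cursor + int(rng.integers(200, la - lb - 200 + 1))
        else:  # tandem: both plus strand, no duplex possible
            gap = int(rng.integers(20, 201))
            a0, b0 = cursor, cursor + la + gap
        partner_strand = "+" if geom == "tandem" else "-"
        anchor = GeneRecord(f"SYNG{i:04d}A", chrom, a0 + 1, a0 + la, "+")
        partner = GeneRecord(f"SYNG{i:04d}B", chrom, b0 + 1, b0 + lb, partner_strand)
        genes.extend([anchor, partner])
        window = (
            _duplex_window(chrom, anchor, partner) if geom in RECOVERABLE else None
        )
        if geom in RECOVERABLE and window is None:
            raise ValueError(f"geometry {geom} produced no duplex window (block {i})")
        loci.append(
            PlantedLocus(
                locus_id=f"locus{i:04d}",
                geometry=geom,
                anchor=anchor,
                partner=partner,
                duplex_window=window,
                base_weight=float(rng.lognormal(0.0, config.locus_weight_sigma)),
                dependent=False,
            )
        )
        cursor = max(anchor.end, partner.end) + config.spacer

    # miRNA source loci in a dedicated zone downstream of all gene blocks
    mirna_positions: dict[str, int] = {}
    for m in range(config.mirna_count):
        mirna_positions[f"mir-syn-{m:03d}"] = cursor
        cursor += 21 + 100

    required_len = cursor + config.spacer
    chrom_len = max(required_len, config.genome_len or 0)
    if config.genome_len is not None and config.genome_len < required_len:
        raise ValueError(
            f"genome_len {config.genome_len} too short for layout ({required_len} nt)"
        )
    genome_seq = _random_seq(rng, chrom_len)
    genome = {chrom: genome_seq}
    mirna_seqs = {
        name: genome_seq[pos : pos + 21] for name, pos in mirna_positions.items()
    }

    te_lo, te_hi = config.te_len_range
    te_seqs = {
        f"TE-family-{j:02d}": _random_seq(rng, int(rng.integers(te_lo, te_hi + 1)))
        for j in range(config.n_te_families)
    }

    recoverable_idx = [i for i, l in enumerate(loci) if l.recoverable]
    dep_idx = rng.choice(recoverable_idx, size=config.n_dependent_loci, replace=False)
    for i in dep_idx:
        loci[i].dependent = True

    mirna_weights = {
        name: float(rng.lognormal(0.0, 1.0)) for name in mirna_seqs
    }
    te_weights = {name: float(rng.lognormal(0.0, 0.8)) for name in te_seqs}

    truth = GroundTruth(
        seed=config.seed,
        loci=loci,
        mirna_weights=mirna_weights,
        te_weights=te_weights,
        chrom_len=chrom_len,
    )
    return Reference(genome, genes, te_seqs, mirna_seqs, truth)


# ---------------------------------------------------------------------------
# Library simulation
# ---------------------------------------------------------------------------

def _condition_multiplier(locus: PlantedLocus, condition: str, config: ScenarioConfig) -> float:
    if condition == "blanks_shutdown" and locus.dependent:
        return 1.0 / config.dependent_fold
    if condition == "dcr2_shutdown":
        return 1.0 / config.dcr2_global_fold
    return 1.0


def simulate_library(
    config: ScenarioConfig,
    ref: Reference,
    condition: str,
    seed: int | None = None,
) -> list[SmallRNARead]:
    """Draw one condition's small-RNA library (raw, adapter-bearing reads).

    Read counts per source are multinomial at the configured depth, with
    per-source expectations scaled by the condition multipliers.  Sampled
    genomic 21-mers are rejected (and redrawn) if they occur more than once
    in the genome, so planted reads survive unique-mapping.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    if config.read_depth == 0:
        return []
    ss = (
        np.random.SeedSequence([config.seed, _COND_SEED[condition]])
        if seed is None
        else np.random.SeedSequence(seed)
    )
    rng = np.random.default_rng(ss)
    genome_seq = ref.genome[config.chrom_id]
    index = ref.genome_index(21)

    active = [l for l in ref.truth.loci if l.duplex_window is not None]
    locus_w = np.array([l.base_weight for l in active])
    locus_w = (
        config.sirna_fraction
        * locus_w
        / locus_w.sum()
        * np.array([_condition_multiplier(l, condition, config) for l in active])
    )
    te_names = list(ref.te_seqs)
    te_w = np.array([ref.truth.te_weights[n] for n in te_names])
    te_w = config.te_fraction * te_w / te_w.sum()
    if condition == "dcr2_shutdown":
        te_w = te_w / config.dcr2_global_fold
    mir_names = list(ref.mirna_seqs)
    mir_w = np.array([ref.truth.mirna_weights[n] for n in mir_names])
    mir_w = config.mirna_fraction * mir_w / mir_w.sum()

    weights = np.concatenate([locus_w, te_w, mir_w])
    counts = rng.multinomial(config.read_depth, weights / weights.sum())

    reads: list[SmallRNARead] = []
    serial = 0

    def emit(insert: str, methylated: bool) -> None:
        nonlocal serial
        raw = (insert + config.adapter)[: config.raw_read_length]
        reads.append(SmallRNARead(f"{condition}_{serial:07d}", raw, methylated))
        serial += 1

    n_rejected = 0
    pos_iter = iter(())
    for src, n in zip(active, counts[: len(active)]):
        w = src.duplex_window
        if n == 0:
            continue
        positions = rng.integers(w.start, w.end - 21 + 1, size=n)
        strands = rng.random(n) < 0.5
        for pos, sense in zip(positions, strands):
            seq = genome_seq[pos : pos + 21]
            tries = 0
            while index.n_occurrences(seq) != 1 and tries < 50:
                pos = int(rng.integers(w.start, w.end - 21 + 1))
                seq = genome_seq[pos : pos + 21]
                tries += 1
                n_rejected += 1
            emit(seq if sense else reverse_complement(seq), True)
    off = len(active)
    for name, n in zip(te_names, counts[off : off + len(te_names)]):
        cons = ref.te_seqs[name]
        if n == 0:
            continue
        positions = rng.integers(0, len(cons) - 21 + 1, size=n)
        strands = rng.random(n) < 0.5
        for pos, sense in zip(positions, strands):
            seq = cons[pos : pos + 21]
            emit(seq if sense else reverse_complement(seq), True)
    off += len(te_names)
    for name, n in zip(mir_names, counts[off:]):
        seq = ref.mirna_seqs[name]
        for _ in range(n):
            emit(seq, False)
    if n_rejected:
        import logging

        logging.getLogger(__name__).debug(
            "%s: %d non-unique 21-mers resampled", condition, n_rejected
        )
    return reads


def simulate_oxidation(
    reads: Sequence[SmallRNARead],
    survival_unmethylated: float,
    seed: int,
) -> list[SmallRNARead]:
    """Periodate oxidation: methylated reads survive; unmethylated survive
    with probability ``survival_unmethylated`` (independent Bernoulli)."""
    if not 0.0 <= survival_unmethylated <= 1.0:
        raise ValueError("survival must be in [0, 1]")
    rng = np.random.default_rng(seed)
    keep = rng.random(len(reads)) < survival_unmethylated
    return [
        r
        for r, k in zip(reads, keep)
        if r.methylated_3p or (not r.methylated_3p and k)
    ]


# ---------------------------------------------------------------------------
# Anisotropy titrations
# ---------------------------------------------------------------------------

def dilution_series(top_nM: float = 4000.0, n: int = 12, factor: float = 2.0) -> list[float]:
    """n-point serial dilution from ``top_nM``, ascending."""
    return sorted(top_nM / factor**i for i in range(n))


def simulate_anisotropy(
    kd: float,
    r_free: float = 0.05,
    r_bound: float = 0.20,
    ligand_nM: float = 20.0,
    conc_series: Sequence[float] | None = None,
    noise_sd: float = 0.005,
    n_replicates: int = 3,
    seed: int = 0,
) -> list[BindingCurve]:
    """Seeded noisy titration curves from the ligand-depletion model."""
    conc = np.asarray(
        conc_series if conc_series is not None else dilution_series(), dtype=float
    )
    rng = np.random.default_rng(seed)
    curves = []
    for rep in range(n_replicates):
        model = r_free + (r_bound - r_free) * fraction_bound(conc, ligand_nM, kd)
        noisy = model + rng.normal(0.0, noise_sd, size=conc.size) if noise_sd > 0 else model
        curves.append(
            BindingCurve(
                protein_conc=tuple(float(c) for c in conc),
                anisotropy=tuple(float(a) for a in noisy),
                ligand_conc=ligand_nM,
                label=f"replicate-{rep + 1}",
            )
        )
    return curves


# ---------------------------------------------------------------------------
# Writers (text formats only)
# ---------------------------------------------------------------------------

def write_reference(ref: Reference, outdir: str | Path, config: ScenarioConfig) -> dict[str, Path]:
    """Serialize the reference to FASTA / GFF3 / JSON files; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "genes.gff3",
        "te": outdir / "te_consensus.fa",
        "mirna": outdir / "mirna.fa",
        "truth": outdir / "ground_truth.json",
    }
    _write_fasta(ref.genome, paths["genome"])
    _write_fasta(ref.te_seqs, paths["te"])
    _write_fasta(ref.mirna_seqs, paths["mirna"])
    with open(paths["annotation"], "w") as fh:
        fh.write("##gff-version 3\n")
        for g in ref.genes:
            fh.write(
                f"{g.seqid}\tFlyBase\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};Name={g.gene_id}\n"
            )
            fh.write(
                f"{g.seqid}\tFlyBase\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}-RA;Parent={g.gene_id}\n"
            )
    paths["truth"].write_text(ref.truth.to_json())
    return paths


def _write_fasta(seqs: Mapping[str, str], path: Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
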