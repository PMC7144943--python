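"""Per-region read counting, ppm normalization, and library class composition.

Counts are split by orientation relative to the region's reference strand
(the plus-strand anchor gene for convergent regions; the gene's own strand
for per-gene regions).  Normalization is parts per million (ppm) relative to
the library's genome-matching read count, so libraries of different
sequencing depth are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .annotation import ConvergentRegion, Region
from .reads import AlignmentHit, SmallRNARead, reverse_complement


@dataclass
class LocusQuant:
    """Per-region, per-library counts; ``ppm`` is filled once the library
    denominator is known."""

    region_key: str
    library_id: str
    count_total: int = 0
    count_sense: int = 0
    count_antisense: int = 0
    ppm: float | None = None

    def validate(self) -> None:
        if self.count_total != self.count_sense + self.count_antisense:
            raise AssertionError(f"count split inconsistent for {self.region_key}")


@dataclass(frozen=True)
class ClassComposition:
    """Fractions of classified reads per small-RNA class; fractions sum to 1."""

    library_id: str
    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions sum to {total}, expected 1")


def _as_regions(regions: Iterable[Region | ConvergentRegion]) -> list[Region]:
    return [r.to_region() if isinstance(r, ConvergentRegion) else r for r in regions]


def count_in_regions(
    hits: Sequence[AlignmentHit],
    regions: Iterable[Region | ConvergentRegion],
    library_id: str,
) -> list[LocusQuant]:
    """Count hits per region, split by orientation.

    A hit is counted for every region it overlaps by >= 1 bp — a hit spanning
    two overlapping regions increments both.  "Sense" means the hit strand
    equals the region's strand.  Every input region gets a LocusQuant, zeros
    included, in input order.
    """
    regs = _as_regions(regions)
    quants = [LocusQuant(r.key, library_id) for r in regs]
    trees: dict[str, IntervalTree] = {}
    for i, r in enumerate(regs):
        trees.setdefault(r.seqid, IntervalTree())[r.start : r.end] = i
    for h in hits:
        tree = trees.get(h.seqid)
        if tree is None:
            continue
        for iv in tree.overlap(h.start, h.end):
            q = quants[iv.data]
            q.count_total += 1
            if h.strand == regs[iv.data].strand:
                q.count_sense += 1
            else:
                q.count_antisense += 1
    return quants


def to_ppm(count: int | float, denominator: int | float) -> float:
    """Parts per million: count / denominator * 1e6."""
    if denominator <= 0:
        raise ValueError("ppm denominator must be > 0")
    return count / denominator * 1e6


def attach_ppm(quants: Iterable[LocusQuant], denominator: int) -> list[LocusQuant]:
    """Fill the ppm field of each quant from the library denominator."""
    out = list(quants)
    for q in out:
        q.ppm = to_ppm(q.count_total, denominator)
    return out


def _matches_reference(seq: str, searchable: list[tuple[str, str]]) -> bool:
    return any(seq in fwd or seq in rc for fwd, rc in searchable)


def classify_reads(
    reads: Sequence[SmallRNARead],
    mirna_seqs: Mapping[str, str],
    te_seqs: Mapping[str, str],
) -> dict[str, int]:
    """Assign each read to the first matching class: miRNA > TE > other.

    Matching is exact substring on either strand, as in TE filtering.  The
    miRNA reference takes precedence because it is the more specific one.
    Returns read counts per class.
    """
    mirna_search = [
        (s.upper(), reverse_complement(s.upper())) for s in mirna_seqs.values()
    ]
    te_search = [(s.upper(), reverse_complement(s.upper())) for s in te_seqs.values()]
    counts = {"miRNA": 0, "TE": 0, "other": 0}
    cache: dict[str, str] = {}
    for r in reads:
        seq = r.sequence
        cls = cache.get(seq)
        if cls is None:
            if "N" in seq:
                cls = "other"
            elif _matches_reference(seq, mirna_search):
                cls = "miRNA"
            elif _matches_reference(seq, te_search):
                cls = "TE"
            else:
                cls = "other"
            cache[seq] = cls
        counts[cls] += 1
    return counts


def class_composition(
    reads: Sequence[SmallRNARead],
    mirna_seqs: Mapping[str, str],
    te_seqs: Mapping[str, str],
    library_id: str = "",
) -> ClassComposition:
    """Fraction of reads per class {miRNA, TE, other} for one library."""
    if not reads:
        raise ValueError("cannot compute class composition of an empty library")
    counts = classify_reads(reads, mirna_seqs, te_seqs)
    total = sum(counts.values())
    return ClassComposition(library_id, {c: n / total for c, n in counts.items()})
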