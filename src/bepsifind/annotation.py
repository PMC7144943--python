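"""Compile convergent-transcription candidate regions from a gene annotation.

Convergently transcribed gene pairs (cis-NAT arrangements) can produce
double-stranded RNA between their nascent transcripts, including the unstable
readthrough stretch downstream of the annotated polyadenylation site.  This
module turns a GFF3 gene annotation into the non-redundant list of candidate
regions used for siRNA locus quantification: every plus-strand gene whose body
plus a fixed 3' extension (default 300 nt) overlaps the unextended body of a
minus-strand gene by at least one base.  A second region mode extends every
gene symmetrically on both sides (default 150 nt) for annotation-wide scans.

All internal arithmetic is 0-based half-open; GFF3 (1-based inclusive) and
BED (0-based half-open) conversions happen at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

GENE_FEATURE = "gene"
DEFAULT_EXTENSION_NT = 300
DEFAULT_FLANK_NT = 150


class GFFParseError(ValueError):
    """Raised for a structurally malformed GFF3 line (reports the line number)."""


class BEDParseError(ValueError):
    """Raised for malformed or coordinate-inverted BED records."""


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene, coordinates 1-based inclusive as read from GFF3."""

    gene_id: str
    seqid: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be nonempty")
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval, optionally stranded."""

    seqid: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seqid == other.seqid
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class ConvergentRegion:
    """A sense-anchored candidate region.

    ``anchor_id`` is the plus-strand gene; ``interval`` spans the anchor body
    plus its 3' extension (or the body alone in body-only mode).  The
    minus-strand partner's unextended body overlaps the anchor's extended
    window by >= 1 bp.
    """

    anchor_id: str
    partner_id: str
    interval: GenomicInterval
    extension_nt: int = DEFAULT_EXTENSION_NT

    @property
    def key(self) -> str:
        return f"{self.anchor_id}|{self.partner_id}"

    def to_region(self) -> "Region":
        return Region(
            key=self.key,
            seqid=self.interval.seqid,
            start=self.interval.start,
            end=self.interval.end,
            strand="+",
        )


@dataclass(frozen=True)
class Region:
    """Generic named, stranded counting region (0-based half-open)."""

    key: str
    seqid: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"region {self.key}: start {self.start} >= end {self.end}")


# ---------------------------------------------------------------------------
# GFF3 parsing
# ---------------------------------------------------------------------------

def _parse_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in attr_field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            attrs[k] = v
    return attrs


def parse_gene_annotation(
    stream: IO[str] | Iterable[str],
    source: str | None = "FlyBase",
    exclude_attr: str = "parent_type",
) -> list[GeneRecord]:
    """Extract gene records from a GFF3 stream.

    Keeps lines whose feature type is ``gene``, whose source column matches
    ``source`` (pass ``None`` to accept any source), and whose attribute
    column does not contain ``exclude_attr`` (parented analysis features in
    FlyBase-style annotations carry a ``parent_type`` attribute).  The gene ID
    is taken from the ``ID=`` attribute, falling back to the raw attribute
    string.  Coordinates stay 1-based inclusive as read.

    Records with an unknown strand character are rejected with a warning.
    Structurally malformed lines raise :class:`GFFParseError` naming the line.
    """
    genes: list[GeneRecord] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise GFFParseError(
                f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
            )
        seqid, src, ftype, start_s, end_s, _score, strand, _phase, attr_field = fields[:9]
        if ftype != GENE_FEATURE:
            continue
        if source is not None and src != source:
            continue
        if exclude_attr and exclude_attr in attr_field:
            continue
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise GFFParseError(f"line {lineno}: non-integer coordinates") from exc
        if start > end:
            raise GFFParseError(f"line {lineno}: start {start} > end {end}")
        if strand not in ("+", "-"):
            logger.warning(
                "line %d: gene with unknown strand %r rejected", lineno, strand
            )
            continue
        attrs = _parse_attributes(attr_field)
        gene_id = attrs.get("ID", attr_field)
        genes.append(GeneRecord(gene_id, seqid, start, end, strand))
    return genes


# ---------------------------------------------------------------------------
# Region construction
# ---------------------------------------------------------------------------

def extend_three_prime(
    gene: GeneRecord, ext_nt: int, chrom_len: int | None = None
) -> GenomicInterval:
    """Extend a gene downstream (strand-aware) by ``ext_nt``, 0-based half-open.

    A plus-strand gene grows past its end; a minus-strand gene grows below its
    start.  The result is clamped to ``[0, chrom_len)`` when the chromosome
    length is known (clamping is silent, logged at debug level).
    """
    if ext_nt < 0:
        raise ValueError("ext_nt must be >= 0")
    start0 = gene.start - 1
    if gene.strand == "+":
        start, end = start0, gene.end + ext_nt
    else:
        start, end = start0 - ext_nt, gene.end
    if start < 0:
        logger.debug("gene %s: extension clamped at chromosome origin", gene.gene_id)
        start = 0
    if chrom_len is not None and end > chrom_len:
        logger.debug("gene %s: extension clamped at chromosome end", gene.gene_id)
        end = chrom_len
    return GenomicInterval(gene.seqid, start, end, gene.strand)


def find_convergent_regions(
    genes: Iterable[GeneRecord],
    ext_nt: int = DEFAULT_EXTENSION_NT,
    chrom_lens: Mapping[str, int] | None = None,
    min_overlap: int = 1,
    region_mode: str = "extended",
) -> list[ConvergentRegion]:
    """Find all convergent (+/-) gene pairs whose transcripts can form dsRNA.

    A pair is retained when the plus-strand anchor, extended ``ext_nt``
    downstream, overlaps the unextended body of a minus-strand gene on the
    same chromosome by at least ``min_overlap`` bp.  Restricting anchors to
    the plus strand makes the pair list non-redundant (each overlap would
    otherwise be reported once from each gene).  One region is emitted per
    distinct (anchor, partner) pair — a gene with two antisense partners
    yields two regions.

    ``region_mode`` selects whether the emitted counting interval is the
    anchor's extended window (``"extended"``, default — the window actually
    searched) or the anchor body alone (``"body"``).
    """
    if region_mode not in ("extended", "body"):
        raise ValueError(f"unknown region_mode {region_mode!r}")
    plus = [g for g in genes if g.strand == "+"]
    minus_by_seqid: dict[str, list[GeneRecord]] = {}
    for g in genes:
        if g.strand == "-":
            minus_by_seqid.setdefault(g.seqid, []).append(g)

    regions: list[ConvergentRegion] = []
    for anchor in plus:
        chrom_len = chrom_lens.get(anchor.seqid) if chrom_lens else None
        window = extend_three_prime(anchor, ext_nt, chrom_len)
        if region_mode == "body":
            interval = GenomicInterval(anchor.seqid, anchor.start - 1, anchor.end, "+")
        else:
            interval = GenomicInterval(window.seqid, window.start, window.end, "+")
        for partner in minus_by_seqid.get(anchor.seqid, ()):
            body_start, body_end = partner.start - 1, partner.end
            overlap = min(window.end, body_end) - max(window.start, body_start)
            if overlap >= min_overlap:
                regions.append(
                    ConvergentRegion(anchor.gene_id, partner.gene_id, interval, ext_nt)
                )
    regions.sort(
        key=lambda r: (r.interval.seqid, r.interval.start, r.anchor_id, r.partner_id)
    )
    return regions


def per_gene_regions(
    genes: Iterable[GeneRecord],
    flank_nt: int = DEFAULT_FLANK_NT,
    chrom_lens: Mapping[str, int] | None = None,
) -> list[Region]:
    """One stranded counting region per gene, extended ``flank_nt`` on both sides.

    Used for the annotation-wide (testes-style) analysis where every gene,
    not only convergent pairs, is scanned for siRNA coverage.
    """
    if flank_nt < 0:
        raise ValueError("flank_nt must be >= 0")
    out = []
    for g in genes:
        chrom_len = chrom_lens.get(g.seqid) if chrom_lens else None
        start = max(0, g.start - 1 - flank_nt)
        end = g.end + flank_nt
        if chrom_len is not None:
            end = min(end, chrom_len)
        out.append(Region(g.gene_id, g.seqid, start, end, g.strand))
    out.sort(key=lambda r: (r.seqid, r.start, r.key))
    return out


# ---------------------------------------------------------------------------
# BED6 I/O
# ---------------------------------------------------------------------------

def write_bed(regions: Iterable[Region | ConvergentRegion], handle: IO[str]) -> None:
    """Write regions as BED6 (name column carries the region key, score 0)."""
    for r in regions:
        if isinstance(r, ConvergentRegion):
            r = r.to_region()
        handle.write(
            f"{r.seqid}\t{r.start}\t{r.end}\t{r.key}\t0\t{r.strand}\n"
        )


def read_bed(handle: IO[str] | Iterable[str]) -> list[Region]:
    """Read BED6 regions written by :func:`write_bed`."""
    out: list[Region] = []
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise BEDParseError(f"line {lineno}: expected >= 6 fields")
        seqid, start_s, end_s, name, _score, strand = fields[:6]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise BEDParseError(f"line {lineno}: non-integer coordinates") from exc
        if start >= end:
            raise BEDParseError(f"line {lineno}: inverted coordinates {start} >= {end}")
        out.append(Region(name, seqid, start, end, strand))
    return out
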