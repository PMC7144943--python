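"""Small-RNA read processing: trimming, size selection, TE filtering, mapping.

The locus-level analyses in this package work on a strictly reduced read set:
3'-adapter-trimmed reads, size-selected to the siRNA length class (21-mers),
purged of anything matching a transposon consensus exactly on either strand,
and mapped to the genome with no mismatches, keeping only reads that occur at
exactly one genomic position across both strands.  Exactness makes a k-mer
hash index sufficient for mapping — no alignment heuristics are involved.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERLAP = 5
SIRNA_LENGTH = 21

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SmallRNARead:
    """One small-RNA read.

    ``methylated_3p`` is synthetic-data provenance (whether the simulated
    molecule carried the 2'-O-methyl mark that protects it from periodate
    oxidation).  Pipeline decisions never read it.
    """

    read_id: str
    sequence: str
    methylated_3p: bool | None = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentHit:
    """A uniquely placed exact match (0-based half-open on the forward strand).

    For a minus-strand hit, ``start`` is the forward-strand start of the
    reverse-complement occurrence, so [start, end) always delimits the matched
    reference substring.
    """

    read_id: str
    seqid: str
    start: int
    end: int
    strand: str


@dataclass
class LibraryStats:
    """Read-funnel counts for one library; each stage is <= its predecessor."""

    library_id: str
    total_reads: int = 0
    reads_after_trim: int = 0
    reads_in_size_range: int = 0
    te_matching: int = 0
    genome_matching: int = 0
    uniquely_mapping: int = 0

    def check_funnel(self) -> None:
        retained = self.reads_in_size_range - self.te_matching
        if not (
            self.total_reads >= self.reads_after_trim >= self.reads_in_size_range
            and retained >= self.genome_matching >= self.uniquely_mapping >= 0
        ):
            raise AssertionError(f"funnel monotonicity violated: {self}")


# ---------------------------------------------------------------------------
# FASTQ I/O
# ---------------------------------------------------------------------------

def read_fastq(handle: IO[str]) -> list[SmallRNARead]:
    """Read a FASTQ stream into SmallRNARead records (qualities discarded)."""
    return [
        SmallRNARead(title.split()[0], seq.upper())
        for title, seq, _qual in FastqGeneralIterator(handle)
    ]


def write_fastq(reads: Iterable[SmallRNARead], handle: IO[str]) -> None:
    for r in reads:
        handle.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


# ---------------------------------------------------------------------------
# Trimming and size selection
# ---------------------------------------------------------------------------

def trim_adapter(
    read: SmallRNARead, adapter: str, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> tuple[SmallRNARead, bool]:
    """Remove the 3' adapter by exact match; returns (read, trimmed_flag).

    The suffix starting at the leftmost exact occurrence of the full adapter
    is removed.  If only a proper adapter prefix (>= ``min_overlap`` nt)
    terminates the read, that suffix is removed instead.  Reads without a
    match pass through unchanged, flagged untrimmed.
    """
    if not adapter:
        raise ValueError("adapter must be nonempty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    seq = read.sequence
    pos = seq.find(adapter)
    if pos != -1:
        return SmallRNARead(read.read_id, seq[:pos], read.methylated_3p), True
    max_prefix = min(len(adapter) - 1, len(seq))
    for plen in range(max_prefix, min_overlap - 1, -1):
        if seq.endswith(adapter[:plen]):
            return SmallRNARead(read.read_id, seq[:-plen], read.methylated_3p), True
    return read, False


def size_select(
    reads: Iterable[SmallRNARead], min_len: int, max_len: int
) -> list[SmallRNARead]:
    """Keep reads with min_len <= length <= max_len."""
    if not (1 <= min_len <= max_len):
        raise ValueError("need 1 <= min_len <= max_len")
    return [r for r in reads if min_len <= len(r.sequence) <= max_len]


# ---------------------------------------------------------------------------
# Transposon-consensus filtering
# ---------------------------------------------------------------------------

def _consensus_kmer_sets(
    te_seqs: Mapping[str, str], lengths: Iterable[int]
) -> dict[int, set[str]]:
    """All k-mers (both strands) present in any consensus, per read length."""
    sets: dict[int, set[str]] = {}
    for k in set(lengths):
        kmers: set[str] = set()
        for seq in te_seqs.values():
            seq = seq.upper()
            rc = reverse_complement(seq)
            for s in (seq, rc):
                kmers.update(s[i : i + k] for i in range(len(s) - k + 1))
        sets[k] = kmers
    return sets


def filter_te_matching(
    reads: Sequence[SmallRNARead], te_seqs: Mapping[str, str]
) -> tuple[list[SmallRNARead], list[SmallRNARead]]:
    """Partition reads into (te_matching, retained).

    A read matches iff its sequence occurs exactly as a substring of any
    consensus on either strand.  Reads containing N never match (exactness).
    """
    if not te_seqs:
        raise ValueError("transposon consensus set must be nonempty")
    kmer_sets = _consensus_kmer_sets(te_seqs, (len(r.sequence) for r in reads))
    te, retained = [], []
    for r in reads:
        seq = r.sequence
        if "N" not in seq and seq in kmer_sets[len(seq)]:
            te.append(r)
        else:
            retained.append(r)
    return te, retained


def assign_to_te_families(
    reads: Sequence[SmallRNARead], te_seqs: Mapping[str, str]
) -> dict[str, int]:
    """Per-consensus read totals for the TE-siRNA class analysis.

    A read matching several consensi is counted for every one of them
    (multi-family reads are not fractionally split).
    """
    counts = {name: 0 for name in te_seqs}
    searchable = {
        name: (seq.upper(), reverse_complement(seq.upper()))
        for name, seq in te_seqs.items()
    }
    by_seq = Counter(r.sequence for r in reads if "N" not in r.sequence)
    for seq, n in by_seq.items():
        for name, (fwd, rc) in searchable.items():
            if seq in fwd or seq in rc:
                counts[name] += n
    return counts


# ---------------------------------------------------------------------------
# Exact-match unique mapping
# ---------------------------------------------------------------------------

class ExactIndex:
    """Hash index of every forward-strand k-mer of a reference.

    A minus-strand occurrence of a read is a forward occurrence of its
    reverse complement, so indexing the forward strand once covers both
    orientations.  For odd k a k-mer can never equal its own reverse
    complement, so one position is never double-counted as + and -.
    """

    def __init__(self, reference: Mapping[str, str], k: int):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = {}
        for seqid, seq in reference.items():
            seq = seq.upper()
            idx = self._index
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                idx.setdefault(kmer, []).append((seqid, i))

    def lookup(self, seq: str) -> list[tuple[str, int, str]]:
        """All occurrences of ``seq`` across both strands: (seqid, start0, strand)."""
        hits = [(sid, s, "+") for sid, s in self._index.get(seq, ())]
        hits += [
            (sid, s, "-") for sid, s in self._index.get(reverse_complement(seq), ())
        ]
        return hits

    def n_occurrences(self, seq: str) -> int:
        return len(self._index.get(seq, ())) + len(
            self._index.get(reverse_complement(seq), ())
        )


def map_unique(
    reads: Sequence[SmallRNARead], index: ExactIndex
) -> list[AlignmentHit]:
    """Report reads with exactly one exact occurrence across both genome strands.

    Reads of a length other than the index k cannot match and are skipped;
    reads containing N are unmappable under exactness and are skipped with a
    debug log.
    """
    # cache per distinct sequence: libraries are dominated by repeated reads
    placement: dict[str, tuple[str, int, str] | None] = {}
    hits: list[AlignmentHit] = []
    k = index.k
    for r in reads:
        seq = r.sequence
        if len(seq) != k:
            continue
        if "N" in seq:
            logger.debug("read %s contains N, skipped", r.read_id)
            continue
        if seq not in placement:
            occ = index.lookup(seq)
            placement[seq] = occ[0] if len(occ) == 1 else None
        placed = placement[seq]
        if placed is not None:
            seqid, start, strand = placed
            hits.append(AlignmentHit(r.read_id, seqid, start, start + k, strand))
    return hits


def count_genome_matching(reads: Sequence[SmallRNARead], index: ExactIndex) -> int:
    """Number of reads with >= 1 exact genomic occurrence (ppm denominator).

    Multi-mappers count once; reads with N or off-length reads count zero.
    """
    k = index.k
    matched: dict[str, bool] = {}
    n = 0
    for r in reads:
        seq = r.sequence
        if len(seq) != k or "N" in seq:
            continue
        if seq not in matched:
            matched[seq] = index.n_occurrences(seq) > 0
        if matched[seq]:
            n += 1
    return n
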