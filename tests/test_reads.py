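"""Read processing: trimming, size selection, TE filtering, exact mapping."""

import io

import numpy as np
import pytest

from bepsifind.reads import (
    AlignmentHit,
    ExactIndex,
    LibraryStats,
    SmallRNARead,
    count_genome_matching,
    filter_te_matching,
    map_unique,
    read_fastq,
    reverse_complement,
    size_select,
    trim_adapter,
    write_fastq,
)
from .conftest import naive_occurrences

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"
INSERT = "ACGTACGTACGTACGTACGTA"  # 21 nt


class TestTrimAdapter:
    def test_full_adapter_removed(self):
        read = SmallRNARead("r1", INSERT + ADAPTER)
        trimmed, flag = trim_adapter(read, ADAPTER)
        assert flag and trimmed.sequence == INSERT

    def test_partial_adapter_prefix_removed(self):
        read = SmallRNARead("r1", INSERT + ADAPTER[:6])
        trimmed, flag = trim_adapter(read, ADAPTER, min_overlap=5)
        assert flag and trimmed.sequence == INSERT

    def test_prefix_below_min_overlap_kept(self):
        read = SmallRNARead("r1", INSERT + ADAPTER[:4])
        trimmed, flag = trim_adapter(read, ADAPTER, min_overlap=5)
        assert not flag and trimmed.sequence == INSERT + ADAPTER[:4]

    def test_read_without_adapter_flagged_untrimmed(self):
        read = SmallRNARead("r1", INSERT)
        trimmed, flag = trim_adapter(read, ADAPTER)
        assert not flag and trimmed is read

    def test_leftmost_occurrence_wins(self):
        seq = "AAA" + ADAPTER + "CCC" + ADAPTER
        trimmed, flag = trim_adapter(SmallRNARead("r", seq), ADAPTER)
        assert flag and trimmed.sequence == "AAA"


class TestSizeSelect:
    def test_exact_window(self):
        reads = [SmallRNARead(f"r{n}", "A" * n) for n in (20, 21, 22)]
        kept = size_select(reads, 21, 21)
        assert [r.read_id for r in kept] == ["r21"]

    def test_mixed_pool_window(self):
        reads = [SmallRNARead(f"r{n}", "A" * n) for n in range(18, 27)]
        kept = size_select(reads, 20, 23)
        assert sorted(len(r.sequence) for r in kept) == [20, 21, 22, 23]


class TestTEFilter:
    @pytest.fixture
    def consensus(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 2000))
        return {"TE1": seq}

    def test_forward_substring_matches(self, consensus):
        read = SmallRNARead("r", consensus["TE1"][10:31])
        te, retained = filter_te_matching([read], consensus)
        assert te == [read] and retained == []

    def test_reverse_complement_substring_matches(self, consensus):
        sub = consensus["TE1"][100:121]
        read = SmallRNARead("r", reverse_complement(sub))
        te, retained = filter_te_matching([read], consensus)
        # cross-check against a direct scan of both strands
        rc_cons = reverse_complement(consensus["TE1"])
        assert read.sequence in rc_cons or read.sequence in consensus["TE1"]
        assert te == [read]

    def test_absent_read_retained_and_n_never_matches(self, consensus):
        clean = SmallRNARead("clean", "ACGT" * 5 + "A")
        with_n = SmallRNARead("n", consensus["TE1"][10:30] + "N")
        te, retained = filter_te_matching([clean, with_n], consensus)
        assert te == [] and retained == [clean, with_n]

    def test_partition_and_idempotence(self, consensus):
        rng = np.random.default_rng(6)
        reads = [
            SmallRNARead(f"te{i}", consensus["TE1"][i : i + 21]) for i in range(50)
        ] + [
            SmallRNARead(f"bg{i}", "".join(rng.choice(list("ACGT"), 21)))
            for i in range(50)
        ]
        te, retained = filter_te_matching(reads, consensus)
        assert len(te) + len(retained) == len(reads)
        assert set(r.read_id for r in te).isdisjoint(r.read_id for r in retained)
        te2, _ = filter_te_matching(retained, consensus)
        assert te2 == []


@pytest.fixture(scope="module")
def random_genome():
    rng = np.random.default_rng(11)
    return {"chrA": "".join(rng.choice(list("ACGT"), 100_000))}


class TestMapUnique:
    def test_planted_read_found_at_position(self, random_genome):
        index = ExactIndex(random_genome, 21)
        seq = random_genome["chrA"][5000:5021]
        hits = map_unique([SmallRNARead("r", seq)], index)
        assert hits == [AlignmentHit("r", "chrA", 5000, 5021, "+")]

    def test_duplicated_read_suppressed(self):
        rng = np.random.default_rng(12)
        base = "".join(rng.choice(list("ACGT"), 5000))
        probe = base[100:121]
        genome = {"chrA": base + "T" * 50 + probe}
        index = ExactIndex(genome, 21)
        assert map_unique([SmallRNARead("r", probe)], index) == []

    def test_reverse_complement_trap_counts_both_strands(self):
        rng = np.random.default_rng(13)
        base = "".join(rng.choice(list("ACGT"), 5000))
        probe = base[200:221]
        genome = {"chrA": base + "G" * 50 + reverse_complement(probe)}
        index = ExactIndex(genome, 21)
        # two occurrences counting both strands -> not unique
        assert map_unique([SmallRNARead("r", probe)], index) == []
        assert index.n_occurrences(probe) == 2

    def test_minus_hit_round_trips_to_read(self, random_genome):
        index = ExactIndex(random_genome, 21)
        sub = random_genome["chrA"][700:721]
        read = SmallRNARead("r", reverse_complement(sub))
        (hit,) = map_unique([read], index)
        assert hit.strand == "-"
        ref = random_genome["chrA"][hit.start : hit.end]
        assert reverse_complement(ref) == read.sequence

    def test_agrees_with_naive_scan_on_random_and_planted_reads(self, random_genome):
        rng = np.random.default_rng(14)
        index = ExactIndex(random_genome, 21)
        chrom = random_genome["chrA"]
        reads = []
        for i in range(100):
            pos = int(rng.integers(0, len(chrom) - 21))
            seq = chrom[pos : pos + 21]
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            reads.append(SmallRNARead(f"p{i}", seq))
        reads += [
            SmallRNARead(f"x{i}", "".join(rng.choice(list("ACGT"), 21)))
            for i in range(100)
        ]
        hits = {h.read_id: (h.seqid, h.start, h.strand) for h in map_unique(reads, index)}
        for r in reads:
            occ = naive_occurrences(r.sequence, random_genome)
            if len(occ) == 1:
                assert hits[r.read_id] == occ[0]
            else:
                assert r.read_id not in hits


class TestCountGenomeMatching:
    def test_planted_counted_multimapper_once_random_zero(self, random_genome):
        index = ExactIndex(random_genome, 21)
        chrom = random_genome["chrA"]
        planted = [SmallRNARead(f"p{i}", chrom[i * 40 : i * 40 + 21]) for i in range(20)]
        assert count_genome_matching(planted, index) == 20
        rng = np.random.default_rng(15)
        randoms = [
            SmallRNARead(f"x{i}", "".join(rng.choice(list("ACGT"), 21)))
            for i in range(200)
        ]
        n_random = count_genome_matching(randoms, index)
        assert n_random <= 1  # expected ~0 for k=21 vs 100 kb


class TestLibraryStatsAndFastq:
    def test_funnel_violation_detected(self):
        stats = LibraryStats("lib", total_reads=10, reads_after_trim=12)
        with pytest.raises(AssertionError):
            stats.check_funnel()

    def test_fastq_round_trip(self):
        reads = [SmallRNARead("a", "ACGT"), SmallRNARead("b", "GGGCC")]
        buf = io.StringIO()
        write_fastq(reads, buf)
        back = read_fastq(io.StringIO(buf.getvalue()))
        assert [(r.read_id, r.sequence) for r in back] == [
            ("a", "ACGT"), ("b", "GGGCC"),
        ]
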