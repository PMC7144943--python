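"""Region compilation: GFF parsing, strand-aware extension, convergent pairs."""

import io
import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bepsifind.annotation import (
    BEDParseError,
    GeneRecord,
    GFFParseError,
    extend_three_prime,
    find_convergent_regions,
    parse_gene_annotation,
    per_gene_regions,
    read_bed,
    write_bed,
)
from .conftest import brute_force_convergent_pairs

TOY_GFF = """\
##gff-version 3
chr1\tFlyBase\tgene\t100\t200\t.\t+\t.\tID=g1;Name=geneA
chr1\tFlyBase\tmRNA\t100\t200\t.\t+\t.\tID=g1-RA;Parent=g1
chr1\tFlyBase\texon\t100\t150\t.\t+\t.\tID=g1-E1;Parent=g1-RA
"""


class TestParseGeneAnnotation:
    def test_only_gene_features_survive(self):
        genes = parse_gene_annotation(io.StringIO(TOY_GFF))
        assert len(genes) == 1
        assert genes[0] == GeneRecord("g1", "chr1", 100, 200, "+")

    def test_field_mapping_keeps_one_based_coordinates(self):
        line = "chr1\tsrc\tgene\t100\t200\t.\t+\t.\tID=g1\n"
        (g,) = parse_gene_annotation(io.StringIO(line), source=None)
        assert (g.gene_id, g.seqid, g.start, g.end, g.strand) == (
            "g1", "chr1", 100, 200, "+",
        )

    def test_unknown_strand_rejected_with_warning(self, caplog):
        lines = "".join(
            f"chr1\tFlyBase\tgene\t{i * 1000}\t{i * 1000 + 100}\t.\t{s}\t.\tID=g{i}\n"
            for i, s in enumerate(["+", "-", ".", "+", "?", "-"], start=1)
        )
        with caplog.at_level(logging.WARNING):
            genes = parse_gene_annotation(io.StringIO(lines))
        assert len(genes) == 4
        assert sum("unknown strand" in r.message for r in caplog.records) == 2

    def test_malformed_line_names_line_number(self):
        bad = "chr1\tFlyBase\tgene\t100\n"
        with pytest.raises(GFFParseError, match="line 1"):
            parse_gene_annotation(io.StringIO(bad))
        with pytest.raises(GFFParseError, match="line 2"):
            parse_gene_annotation(
                io.StringIO("# header\nchr1\tFlyBase\tgene\tX\t200\t.\t+\t.\tID=g\n")
            )

    def test_parent_type_and_source_filters(self):
        lines = (
            "chr1\tFlyBase\tgene\t100\t200\t.\t+\t.\tID=g1\n"
            "chr1\tFlyBase\tgene\t300\t400\t.\t+\t.\tID=g2;parent_type=mRNA\n"
            "chr1\tOtherDB\tgene\t500\t600\t.\t+\t.\tID=g3\n"
        )
        genes = parse_gene_annotation(io.StringIO(lines))
        assert [g.gene_id for g in genes] == ["g1"]
        genes_any = parse_gene_annotation(io.StringIO(lines), source=None)
        assert [g.gene_id for g in genes_any] == ["g1", "g3"]

    def test_id_fallback_to_attribute_string(self):
        line = "chr1\tFlyBase\tgene\t1\t10\t.\t+\t.\tgeneid g9\n"
        (g,) = parse_gene_annotation(io.StringIO(line))
        assert g.gene_id == "geneid g9"


class TestExtendThreePrime:
    @pytest.mark.parametrize(
        "gene, ext, expected",
        [
            (GeneRecord("a", "c", 101, 200, "+"), 300, (100, 500)),
            (GeneRecord("b", "c", 1001, 2000, "-"), 300, (700, 2000)),
            (GeneRecord("d", "c", 50, 120, "-"), 300, (0, 120)),
        ],
    )
    def test_strand_aware_extension(self, gene, ext, expected):
        iv = extend_three_prime(gene, ext)
        assert (iv.start, iv.end) == expected

    def test_clamped_at_chromosome_end(self):
        iv = extend_three_prime(GeneRecord("a", "c", 901, 950, "+"), 300, chrom_len=1000)
        assert (iv.start, iv.end) == (900, 1000)


class TestFindConvergentRegions:
    def test_overlapping_three_prime_ends(self):
        genes = [
            GeneRecord("A", "c", 100, 500, "+"),
            GeneRecord("B", "c", 450, 900, "-"),
        ]
        regions = find_convergent_regions(genes, 300)
        assert len(regions) == 1
        r = regions[0]
        assert (r.anchor_id, r.partner_id) == ("A", "B")
        assert (r.interval.start, r.interval.end) == (99, 800)

    @pytest.mark.parametrize("gap, expected_n", [(250, 1), (301, 0)])
    def test_extension_bridges_small_gaps_only(self, gap, expected_n):
        genes = [
            GeneRecord("A", "c", 100, 400, "+"),
            GeneRecord("B", "c", 400 + gap + 1, 900 + gap, "-"),
        ]
        regions = find_convergent_regions(genes, 300)
        assert len(regions) == expected_n
        assert brute_force_convergent_pairs(genes, 300) == {
            (r.anchor_id, r.partner_id) for r in regions
        }

    def test_same_strand_overlap_yields_nothing(self):
        genes = [
            GeneRecord("A", "c", 100, 500, "+"),
            GeneRecord("B", "c", 300, 900, "+"),
        ]
        assert find_convergent_regions(genes, 300) == []

    def test_antisense_gene_nested_in_host_intron(self):
        # gene-body overlap suffices; exon structure is ignored
        genes = [
            GeneRecord("host", "c", 1000, 9000, "+"),
            GeneRecord("nested", "c", 3000, 3800, "-"),
        ]
        regions = find_convergent_regions(genes, 300)
        assert [(r.anchor_id, r.partner_id) for r in regions] == [("host", "nested")]
        assert brute_force_convergent_pairs(genes, 300) == {("host", "nested")}

    def test_body_only_region_mode(self):
        genes = [
            GeneRecord("A", "c", 100, 500, "+"),
            GeneRecord("B", "c", 450, 900, "-"),
        ]
        (r,) = find_convergent_regions(genes, 300, region_mode="body")
        assert (r.interval.start, r.interval.end) == (99, 500)

    def test_multiple_partners_yield_multiple_regions(self):
        genes = [
            GeneRecord("A", "c", 100, 2000, "+"),
            GeneRecord("B1", "c", 500, 900, "-"),
            GeneRecord("B2", "c", 1200, 1600, "-"),
        ]
        regions = find_convergent_regions(genes, 300)
        assert {(r.anchor_id, r.partner_id) for r in regions} == {
            ("A", "B1"), ("A", "B2"),
        }


def _random_genes(rng: np.random.Generator, n: int) -> list[GeneRecord]:
    genes = []
    for i in range(n):
        seqid = f"chr{rng.integers(1, 3)}"
        start = int(rng.integers(1, 20_000))
        length = int(rng.integers(50, 3000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneRecord(f"g{i}", seqid, start, start + length, strand))
    return genes


class TestRegionProperties:
    def test_matches_brute_force_oracle_on_random_annotations(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            genes = _random_genes(rng, int(rng.integers(2, 120)))
            ext = int(rng.integers(0, 500))
            found = {
                (r.anchor_id, r.partner_id)
                for r in find_convergent_regions(genes, ext)
            }
            assert found == brute_force_convergent_pairs(genes, ext)

    @settings(max_examples=40, derandomize=True)
    @given(st.integers(0, 400), st.integers(0, 400), st.data())
    def test_region_set_monotone_in_extension(self, e1, e2, data):
        lo, hi = sorted((e1, e2))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        genes = _random_genes(rng, 40)
        small = {
            (r.anchor_id, r.partner_id) for r in find_convergent_regions(genes, lo)
        }
        large = {
            (r.anchor_id, r.partner_id) for r in find_convergent_regions(genes, hi)
        }
        assert small <= large

    def test_every_partner_overlaps_extended_anchor(self):
        rng = np.random.default_rng(7)
        genes = _random_genes(rng, 150)
        by_id = {g.gene_id: g for g in genes}
        for r in find_convergent_regions(genes, 300):
            partner = by_id[r.partner_id]
            assert min(r.interval.end, partner.end) - max(
                r.interval.start, partner.start - 1
            ) >= 1


class TestPerGeneRegions:
    def test_symmetric_flank(self):
        (r,) = per_gene_regions([GeneRecord("g", "c", 1001, 2000, "+")], 150)
        assert (r.start, r.end, r.strand) == (850, 2150, "+")

    def test_zero_flank_is_identity(self):
        (r,) = per_gene_regions([GeneRecord("g", "c", 1001, 2000, "-")], 0)
        assert (r.start, r.end) == (1000, 2000)

    def test_clamped_at_chromosome_bounds(self):
        (r,) = per_gene_regions(
            [GeneRecord("g", "c", 51, 950, "+")], 150, chrom_lens={"c": 1000}
        )
        assert (r.start, r.end) == (0, 1000)


class TestBedIO:
    def test_round_trip_is_identity(self):
        genes = [
            GeneRecord("A", "c", 100, 500, "+"),
            GeneRecord("B", "c", 450, 900, "-"),
        ]
        regions = [r.to_region() for r in find_convergent_regions(genes, 300)]
        buf = io.StringIO()
        write_bed(regions, buf)
        assert read_bed(io.StringIO(buf.getvalue())) == regions

    def test_empty_list_gives_empty_file(self):
        buf = io.StringIO()
        write_bed([], buf)
        assert buf.getvalue() == ""
        assert read_bed(io.StringIO("")) == []

    def test_inverted_coordinates_rejected(self):
        with pytest.raises(BEDParseError, match="line 1"):
            read_bed(io.StringIO("c\t500\t100\tx\t0\t+\n"))
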