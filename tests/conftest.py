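"""Shared fixtures: oracle helpers, a small scenario for unit-level checks,
and the full-depth reference scenario (run once per session)."""

from __future__ import annotations

import pytest

from bepsifind import ScenarioConfig, run_pipeline
from bepsifind.annotation import GeneRecord
from bepsifind.reads import reverse_complement


def brute_force_convergent_pairs(
    genes: list[GeneRecord], ext_nt: int
) -> set[tuple[str, str]]:
    """O(n^2) oracle: all (+ anchor, - partner) pairs where the anchor's
    3'-extended interval overlaps the partner's unextended body by >= 1 bp."""
    pairs = set()
    for a in genes:
        if a.strand != "+":
            continue
        a_start, a_end = a.start - 1, a.end + ext_nt
        for b in genes:
            if b.strand != "-" or b.seqid != a.seqid:
                continue
            b_start, b_end = b.start - 1, b.end
            if min(a_end, b_end) - max(a_start, b_start) >= 1:
                pairs.add((a.gene_id, b.gene_id))
    return pairs


def naive_occurrences(read_seq: str, genome: dict[str, str]) -> list[tuple[str, int, str]]:
    """Full-scan oracle: every exact occurrence of a read on either strand."""
    occ = []
    rc = reverse_complement(read_seq)
    for seqid, seq in genome.items():
        for target, strand in ((read_seq, "+"), (rc, "-")):
            start = seq.find(target)
            while start != -1:
                occ.append((seqid, start, strand))
                start = seq.find(target, start + 1)
    return occ


SMALL_CONFIG = ScenarioConfig(
    seed=3,
    read_depth=60_000,
    n_overlapping=12,
    n_gapped_near=6,
    n_nested=4,
    n_gapped_far=2,
    n_tandem=2,
    n_dependent_loci=5,
    n_te_families=4,
    mirna_count=10,
)

# The reference scenario: defaults are the study conditions
# (100 recoverable convergent loci, 20 dependent at 8-fold, 1e6 reads/library).
FULL_CONFIG = ScenarioConfig(seed=11)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """Reduced scenario pipeline run shared by fast integration tests."""
    outdir = tmp_path_factory.mktemp("small_run")
    return run_pipeline(SMALL_CONFIG, outdir, conditions=("wt", "blanks_shutdown"))


@pytest.fixture(scope="session")
def full_run(tmp_path_factory):
    """Full-depth reference scenario (one million reads per library)."""
    outdir = tmp_path_factory.mktemp("full_run")
    return run_pipeline(FULL_CONFIG, outdir, conditions=("wt", "blanks_shutdown"))
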