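"""End-to-end orchestration: regions -> process -> quantify -> classify ->
loading-state, with run manifests and a plain-text report.

Every stage writes its tabular output under the run directory so each number
in the report can be recomputed from the stage files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .annotation import find_convergent_regions, write_bed
from .classify import (
    classify_dependent,
    default_pseudo_ppm,
    locus_calls,
    scatter_table,
    sense_fraction,
)
from .loading import retention_by_class
from .quantify import attach_ppm, classify_reads, count_in_regions, to_ppm
from .reads import (
    ExactIndex,
    LibraryStats,
    SmallRNARead,
    count_genome_matching,
    filter_te_matching,
    map_unique,
    size_select,
    trim_adapter,
    write_fastq,
)
from .simulate import (
    Reference,
    ScenarioConfig,
    make_reference,
    simulate_library,
    simulate_oxidation,
    write_reference,
)

logger = logging.getLogger(__name__)

# report class labels: classifier classes mapped to the domain nomenclature
CLASS_LABELS = {"miRNA": "miRNA", "TE": "TE_siRNA", "other": "bepsiRNA"}


def process_library(
    reads: Sequence[SmallRNARead],
    index: ExactIndex,
    te_seqs: Mapping[str, str],
    adapter: str,
    library_id: str,
    min_len: int = 21,
    max_len: int = 21,
):
    """Trim, size-select, TE-filter and uniquely map one library.

    Returns (hits, stats, filtered_reads, denominator): ``filtered_reads``
    is the size-selected, TE-free read set and ``denominator`` its
    genome-matching count (the ppm denominator).
    """
    stats = LibraryStats(library_id, total_reads=len(reads))
    trimmed = []
    for r in reads:
        t, was_trimmed = trim_adapter(r, adapter)
        if was_trimmed:
            trimmed.append(t)
    stats.reads_after_trim = len(trimmed)
    sized = size_select(trimmed, min_len, max_len)
    stats.reads_in_size_range = len(sized)
    te_reads, retained = filter_te_matching(sized, te_seqs)
    stats.te_matching = len(te_reads)
    stats.genome_matching = count_genome_matching(retained, index)
    hits = map_unique(retained, index)
    stats.uniquely_mapping = len(hits)
    stats.check_funnel()
    logger.info(
        "%s: %d raw -> %d trimmed -> %d sized -> %d TE removed -> "
        "%d genome-matching -> %d unique",
        library_id,
        stats.total_reads,
        stats.reads_after_trim,
        stats.reads_in_size_range,
        stats.te_matching,
        stats.genome_matching,
        stats.uniquely_mapping,
    )
    return hits, stats, retained, stats.genome_matching


def run_pipeline(
    config: ScenarioConfig,
    outdir: str | Path,
    conditions: Sequence[str] = ("wt", "blanks_shutdown"),
    ref_cond: str = "wt",
    test_cond: str = "blanks_shutdown",
    oxidize: str | None = "wt",
    write_fastq_files: bool = False,
) -> dict:
    """Simulate a scenario and run every analysis stage on it.

    Produces, under ``outdir``: the reference inputs, the candidate-region
    BED, per-library funnel stats and FASTQ (optional), the region x library
    quant matrix, the dependence calls, sense fractions, the loading-state
    retention table, a JSON summary and a run manifest.
    """
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if test_cond not in conditions or ref_cond not in conditions:
        raise ValueError("ref_cond and test_cond must be among the simulated conditions")

    ref = make_reference(config)
    input_paths = write_reference(ref, outdir / "inputs", config)

    regions = find_convergent_regions(
        ref.genes, chrom_lens={c: len(s) for c, s in ref.genome.items()}
    )
    with open(outdir / "regions.bed", "w") as fh:
        write_bed(regions, fh)

    index = ref.genome_index(21)
    hits_by_cond, stats_rows, denominators = {}, [], {}
    raw_by_cond = {}
    for cond in conditions:
        raw = simulate_library(config, ref, cond)
        raw_by_cond[cond] = raw
        if write_fastq_files:
            with open(outdir / f"{cond}.fastq", "w") as fh:
                write_fastq(raw, fh)
        hits, stats, _, denom = process_library(
            raw, index, ref.te_seqs, config.adapter, cond
        )
        hits_by_cond[cond] = hits
        denominators[cond] = denom
        stats_rows.append(dataclasses.asdict(stats))
    pd.DataFrame(stats_rows).to_csv(outdir / "library_stats.tsv", sep="\t", index=False)

    quants_by_cond = {
        cond: attach_ppm(
            count_in_regions(hits_by_cond[cond], regions, cond), denominators[cond]
        )
        for cond in conditions
    }
    quant_rows = [
        dataclasses.asdict(q) for cond in conditions for q in quants_by_cond[cond]
    ]
    pd.DataFrame(quant_rows).to_csv(outdir / "quants.tsv", sep="\t", index=False)

    ppm_table = {
        r.key: {cond: quants_by_cond[cond][i].ppm for cond in conditions}
        for i, r in enumerate(regions)
    }
    pseudo = default_pseudo_ppm([denominators[ref_cond], denominators[test_cond]])
    dependent = classify_dependent(
        ppm_table, ref_cond, test_cond, pseudo_ppm=pseudo
    )
    calls = locus_calls(ppm_table, ref_cond, test_cond, pseudo_ppm=pseudo)
    sense = {
        r.key: sense_fraction(
            {cond: quants_by_cond[cond][i] for cond in conditions},
            use_library=ref_cond,
        )
        for i, r in enumerate(regions)
    }
    calls_df = pd.DataFrame(
        [
            {
                "region_key": c.region_key,
                **{f"ppm_{k}": v for k, v in c.ppm_by_condition.items()},
                "ratio": c.ratio,
                "expressed": c.expressed,
                "dependent": c.dependent,
                "sense_fraction_ref": sense[c.region_key],
            }
            for c in calls
        ]
    )
    calls_df.to_csv(outdir / "locus_calls.tsv", sep="\t", index=False)
    scatter_table(ppm_table, ref_cond, test_cond).to_csv(
        outdir / f"scatter_{ref_cond}_vs_{test_cond}.tsv", sep="\t", index=False
    )

    retention = None
    if oxidize is not None:
        retention = loading_analysis(
            config, ref, raw_by_cond[oxidize], library_id=oxidize
        )
        pd.DataFrame([dataclasses.asdict(r) for r in retention]).to_csv(
            outdir / "retention.tsv", sep="\t", index=False
        )

    summary = {
        "n_genes": len(ref.genes),
        "n_regions": len(regions),
        "n_distinct_anchors": len({r.anchor_id for r in regions}),
        "n_expressed": int((calls_df["expressed"]).sum()),
        "n_dependent": len(dependent),
        "dependent_regions": sorted(dependent),
        "denominators": denominators,
        "pseudo_ppm": pseudo,
        "elapsed_s": round(time.time() - t0, 2),
    }
    if retention is not None:
        summary["retention"] = {
            r.class_id: r.retention for r in retention
        }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))

    manifest = {
        "tool": "bepsifind",
        "version": __version__,
        "subcommand": "run",
        "parameters": dataclasses.asdict(config),
        "seed": config.seed,
        "conditions": list(conditions),
        "input_digests": {
            name: _sha256(path) for name, path in input_paths.items()
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    return {
        "reference": ref,
        "regions": regions,
        "quants_by_cond": quants_by_cond,
        "ppm_table": ppm_table,
        "dependent": dependent,
        "calls": calls,
        "sense_fractions": sense,
        "retention": retention,
        "stats": stats_rows,
        "summary": summary,
        "outdir": outdir,
    }


def loading_analysis(
    config: ScenarioConfig,
    ref: Reference,
    raw_reads: Sequence[SmallRNARead],
    library_id: str = "wt",
):
    """Oxidize one library in silico and compute per-class retention.

    Both the untreated and the oxidized read sets are trimmed, size-selected
    and classified identically, and per-class ppm uses the untreated
    library's genome-matching denominator for both (a shared denominator, so
    retention reports survival rather than composition shift).
    """
    oxidized_raw = simulate_oxidation(
        raw_reads, config.oxidation_survival_unmethylated, seed=config.seed + 7
    )

    def prepare(reads):
        trimmed = []
        for r in reads:
            t, ok = trim_adapter(r, config.adapter)
            if ok:
                trimmed.append(t)
        return size_select(trimmed, 21, 21)

    untreated = prepare(raw_reads)
    oxidized = prepare(oxidized_raw)
    index = ref.genome_index(21)
    denom = count_genome_matching(
        [r for r in untreated], index
    )
    counts_unt = classify_reads(untreated, ref.mirna_seqs, ref.te_seqs)
    counts_oxi = classify_reads(oxidized, ref.mirna_seqs, ref.te_seqs)
    ppm_unt = {
        CLASS_LABELS[c]: to_ppm(n, denom) for c, n in counts_unt.items()
    }
    ppm_oxi = {
        CLASS_LABELS[c]: to_ppm(n, denom) for c, n in counts_oxi.items()
    }
    return retention_by_class(ppm_unt, ppm_oxi)


def report(results: Mapping) -> str:
    """Human-readable run summary; every number also lives in a stage TSV."""
    lines = ["bepsifind run report", "====================", ""]
    s = results.get("summary", {})
    lines.append(f"genes annotated:        {s.get('n_genes', 0)}")
    lines.append(f"candidate regions:      {s.get('n_regions', 0)}")
    lines.append(f"distinct anchors:       {s.get('n_distinct_anchors', 0)}")
    lines.append(f"expressed (> ppm floor): {s.get('n_expressed', 0)}")
    lines.append(f"dependent (ratio >= 5):  {s.get('n_dependent', 0)}")
    stats = results.get("stats") or []
    if stats:
        lines.append("")
        lines.append("library funnels:")
        for row in stats:
            lines.append(
                "  {library_id}: total={total_reads} trimmed={reads_after_trim} "
                "sized={reads_in_size_range} TE={te_matching} "
                "genome={genome_matching} unique={uniquely_mapping}".format(**row)
            )
    retention = results.get("retention")
    if retention:
        lines.append("")
        lines.append("loading state (oxidation retention per class):")
        for r in retention:
            val = "undefined" if r.retention is None else f"{r.retention:.3f}"
            lines.append(f"  {r.class_id}: {val}")
    sense = results.get("sense_fractions") or {}
    defined = [f for f in sense.values() if f is not None]
    if defined:
        lines.append("")
        lines.append(
            f"sense fraction (defined at {len(defined)} loci): "
            f"median {pd.Series(defined).median():.3f}"
        )
    lines.append("")
    return "\n".join(lines)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
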