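"""Genotype-dependence classification and duplex-signature statistics.

A locus is called dependent on a factor when its siRNA output drops at least
``ratio_cutoff``-fold (default 5) between a reference library (e.g. wild
type) and a test library (e.g. factor shutdown), among loci that are
expressed above a ppm floor in the reference.  A small pseudocount keeps the
ratio finite when the test library has zero reads — loci silenced completely
in the test condition then rank at the top instead of erroring out.

The duplex signature is the sense fraction: siRNAs derived from a dsRNA
precursor map in roughly equal amounts to both strands (fraction near 0.5),
whereas degradation products of structured single-stranded RNAs map almost
exclusively in sense orientation.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .quantify import LocusQuant
from .reads import AlignmentHit

DEFAULT_RATIO_CUTOFF = 5.0
DEFAULT_MIN_PPM = 5.0
DEFAULT_MIN_READS = 10
DEFAULT_SIRNA_BAND = (0.2, 0.8)


@dataclass
class LocusCall:
    """Classification result for one region."""

    region_key: str
    ppm_by_condition: Mapping[str, float]
    ratio: float
    expressed: bool
    dependent: bool
    sense_fraction: float | None = None
    sirna_like: bool | None = None


def expression_filter(
    ppm_by_region: Mapping[str, float], min_ppm: float = DEFAULT_MIN_PPM
) -> set[str]:
    """Regions whose reference-condition ppm is strictly above ``min_ppm``."""
    return {k for k, ppm in ppm_by_region.items() if ppm > min_ppm}


def dependence_ratio(ppm_ref: float, ppm_test: float, pseudo_ppm: float) -> float:
    """(ppm_ref + pseudo) / (ppm_test + pseudo); finite for ppm_test = 0."""
    if pseudo_ppm <= 0:
        raise ValueError("pseudo_ppm must be > 0")
    return (ppm_ref + pseudo_ppm) / (ppm_test + pseudo_ppm)


def default_pseudo_ppm(denominators: Iterable[int]) -> float:
    """ppm value of a single read in the smallest library of a comparison."""
    return 1e6 / min(denominators)


def classify_dependent(
    ppm_table: Mapping[str, Mapping[str, float]],
    ref_cond: str,
    test_cond: str,
    ratio_cutoff: float = DEFAULT_RATIO_CUTOFF,
    min_ppm: float = DEFAULT_MIN_PPM,
    pseudo_ppm: float = 1.0,
) -> set[str]:
    """Regions expressed in the reference whose ref/test ratio is >= cutoff.

    ``ppm_table`` maps region_key -> {condition: ppm}.  Deterministic given
    its inputs.
    """
    expressed = expression_filter(
        {k: conds[ref_cond] for k, conds in ppm_table.items()}, min_ppm
    )
    return {
        k
        for k in expressed
        if dependence_ratio(ppm_table[k][ref_cond], ppm_table[k][test_cond], pseudo_ppm)
        >= ratio_cutoff
    }


def locus_calls(
    ppm_table: Mapping[str, Mapping[str, float]],
    ref_cond: str,
    test_cond: str,
    ratio_cutoff: float = DEFAULT_RATIO_CUTOFF,
    min_ppm: float = DEFAULT_MIN_PPM,
    pseudo_ppm: float = 1.0,
) -> list[LocusCall]:
    """Full per-region call table (ratio, expressed, dependent)."""
    calls = []
    for key, conds in ppm_table.items():
        ratio = dependence_ratio(conds[ref_cond], conds[test_cond], pseudo_ppm)
        expressed = conds[ref_cond] > min_ppm
        calls.append(
            LocusCall(
                region_key=key,
                ppm_by_condition=dict(conds),
                ratio=ratio,
                expressed=expressed,
                dependent=expressed and ratio >= ratio_cutoff,
            )
        )
    return calls


def sense_fraction(
    quants_by_library: Mapping[str, LocusQuant],
    min_reads_per_library: int = DEFAULT_MIN_READS,
    use_library: str | None = None,
) -> float | None:
    """Fraction of a locus's reads mapping in sense orientation.

    Defined only when every library has at least ``min_reads_per_library``
    reads at the locus; returns None otherwise.  The fraction itself is
    computed from ``use_library`` (default: first library in mapping order).
    """
    if any(
        q.count_total < min_reads_per_library for q in quants_by_library.values()
    ):
        return None
    lib = use_library if use_library is not None else next(iter(quants_by_library))
    q = quants_by_library[lib]
    return q.count_sense / q.count_total


def classify_sirna_like(
    f: float, band: tuple[float, float] = DEFAULT_SIRNA_BAND
) -> bool:
    """True when the sense fraction sits in the duplex band (inclusive).

    Sense-only loci (f = 1), typical of structured ncRNA degradation
    products, fall outside the band and are excluded from the duplex class.
    """
    low, high = band
    return low <= f <= high


def _pct(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal, matching printed tables."""
    if denominator == 0:
        return 0.0
    pct = Decimal(numerator) / Decimal(denominator) * 100
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def overlap_stats(
    set_a: set[str], set_b: set[str], n_universe: int
) -> dict[str, float | int]:
    """Set overlap with percentages relative to the universe and each set."""
    common = set_a & set_b
    return {
        "nA": len(set_a),
        "nB": len(set_b),
        "n_common": len(common),
        "pct_of_universe_A": _pct(len(set_a), n_universe),
        "pct_of_universe_B": _pct(len(set_b), n_universe),
        "pct_common_of_A": _pct(len(common), len(set_a)),
        "pct_common_of_B": _pct(len(common), len(set_b)),
    }


def scatter_table(
    ppm_table: Mapping[str, Mapping[str, float]], cond_x: str, cond_y: str
) -> pd.DataFrame:
    """Plotting-ready table of per-region ppm in two conditions (no transform)."""
    rows = [
        {"region": key, f"ppm_{cond_x}": conds[cond_x], f"ppm_{cond_y}": conds[cond_y]}
        for key, conds in ppm_table.items()
    ]
    return pd.DataFrame(rows, columns=["region", f"ppm_{cond_x}", f"ppm_{cond_y}"])


def downsample_hits(
    hits: Sequence[AlignmentHit], n: int, seed: int
) -> list[AlignmentHit]:
    """Depth-matched subsampling: keep a seeded random subset of n hits.

    Optional guard against sequencing-depth bias in ratio comparisons: the
    deeper library is down-sampled to the shallower one before counting.
    """
    if n >= len(hits):
        return list(hits)
    rng = random.Random(seed)
    return rng.sample(list(hits), n)
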