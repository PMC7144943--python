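"""Argonaute-loading state from paired oxidized / untreated libraries.

Small RNAs loaded into Ago2 carry a 2'-O-methyl group on the 3'-terminal
ribose and therefore lack the vicinal diol attacked by periodate.  After
oxidation and beta-elimination, only the methylated (Ago2-loaded) species
survive library preparation; Ago1-loaded miRNAs and unloaded RNAs are
depleted.  Comparing per-class abundance between an untreated and an
oxidized library therefore reports the loading state of each class.

Retention is computed on ppm values; the two libraries must be normalized
against the same denominator so that retention reflects molecular survival
rather than composition shifts in the oxidized library.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

DEFAULT_PROTECTION_THRESHOLD = 0.5


@dataclass(frozen=True)
class RetentionReport:
    """Oxidation survival of one small-RNA class.

    ``retention`` is ppm_oxidized / ppm_untreated, or None (undefined) when
    the class is absent from the untreated library.
    """

    class_id: str
    ppm_untreated: float
    ppm_oxidized: float
    retention: float | None


def retention_by_class(
    ppm_untreated: Mapping[str, float],
    ppm_oxidized: Mapping[str, float],
) -> list[RetentionReport]:
    """One retention ratio per small-RNA class.

    Both inputs must cover the same classes (mismatched class maps raise) and
    must have been normalized with the same denominator.  Classes with zero
    untreated ppm are reported with retention None.
    """
    if set(ppm_untreated) != set(ppm_oxidized):
        raise ValueError(
            "class maps differ: "
            f"{sorted(set(ppm_untreated) ^ set(ppm_oxidized))}"
        )
    reports = []
    for cls in ppm_untreated:
        unt, oxi = ppm_untreated[cls], ppm_oxidized[cls]
        retention = oxi / unt if unt > 0 else None
        reports.append(RetentionReport(cls, unt, oxi, retention))
    return reports


def call_protected(
    report: RetentionReport, threshold: float = DEFAULT_PROTECTION_THRESHOLD
) -> bool:
    """Binary protection call: retention >= threshold means 2'-O-methylated.

    Undefined retention (class absent untreated) raises rather than guessing.
    """
    if report.retention is None:
        raise ValueError(f"retention undefined for class {report.class_id}")
    return report.retention >= threshold
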