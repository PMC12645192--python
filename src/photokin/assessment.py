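"""Greenness scoring and mineralization arithmetic.

Analytical eco-scale (100 minus penalty points, with the standard
classification bands), NEMI four-quadrant classification (PBT, hazard,
corrosivity via pH, waste mass), and total-organic-carbon loss with the
TC = TOC + IC consistency audit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "PenaltyLedger",
    "EcoScaleResult",
    "NemiInput",
    "NemiResult",
    "TOCRecord",
    "eco_scale_score",
    "nemi_classify",
    "toc_loss_percent",
    "tc_consistency",
]

#: Largest |TC - (TOC + IC)| accepted as consistent, ppb.
TC_AUDIT_TOLERANCE_PPB = 0.5


@dataclass(frozen=True)
class PenaltyLedger:
    """Eco-scale penalty points: (label, points) per reagent/instrument/waste item."""

    items: tuple[tuple[str, float], ...]
    method_label: str = ""

    def __post_init__(self) -> None:
        if any(pp < 0 for _, pp in self.items):
            raise ValueError("penalty points must be nonnegative")

    def total(self) -> float:
        return sum(pp for _, pp in self.items)


@dataclass(frozen=True)
class EcoScaleResult:
    score: float
    classification: str
    total_penalty: float


def eco_scale_score(ledger: PenaltyLedger) -> EcoScaleResult:
    """score = 100 - sum of penalty points.

    Classification: > 75 excellent green, 50-75 acceptable green, < 50
    inadequate. Totals above 100 floor the score at 0 with a warning.
    """
    total = ledger.total()
    score = 100.0 - total
    if score < 0:
        warnings.warn("penalty points exceed 100; score floored at 0")
        score = 0.0
    if score > 75:
        classification = "excellent green"
    elif score >= 50:
        classification = "acceptable green"
    else:
        classification = "inadequate"
    return EcoScaleResult(score=score, classification=classification, total_penalty=total)


@dataclass(frozen=True)
class NemiInput:
    uses_pbt: bool
    uses_hazardous: bool
    ph_of_method: float
    waste_grams: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ph_of_method <= 14.0:
            raise ValueError("pH must lie in [0, 14]")
        if self.waste_grams < 0:
            raise ValueError("waste mass must be nonnegative")


@dataclass(frozen=True)
class NemiResult:
    """Quadrant flags; True means the quadrant is green."""

    pbt_green: bool
    hazard_green: bool
    corrosivity_green: bool
    waste_green: bool

    def all_green(self) -> bool:
        return self.pbt_green and self.hazard_green and self.corrosivity_green and self.waste_green


def nemi_classify(inputs: NemiInput) -> NemiResult:
    """Four-quadrant NEMI label.

    Green iff: no PBT materials; no hazardous chemicals; 2.0 <= pH <= 12.0
    (non-corrosive); waste strictly below 50 g.
    """
    return NemiResult(
        pbt_green=not inputs.uses_pbt,
        hazard_green=not inputs.uses_hazardous,
        corrosivity_green=2.0 <= inputs.ph_of_method <= 12.0,
        waste_green=inputs.waste_grams < 50.0,
    )


@dataclass(frozen=True)
class TOCRecord:
    """Carbon concentrations (ppb) before and after irradiation."""

    label: str
    toc_before: float
    ic_before: float
    tc_before: float
    toc_after: float
    ic_after: float
    tc_after: float


def toc_loss_percent(record: TOCRecord) -> float:
    """Mineralization: 100 (TOC_before - TOC_after) / TOC_before.

    A post-irradiation TOC above the initial value returns a negative loss
    with a warning rather than an error.
    """
    if not record.toc_before > 0:
        raise ValueError("TOC before irradiation must be positive")
    loss = 100.0 * (record.toc_before - record.toc_after) / record.toc_before
    if loss < 0:
        warnings.warn(f"TOC increased after irradiation for {record.label!r}")
    return loss


def tc_consistency(record: TOCRecord) -> tuple[float, float, bool]:
    """Residuals TC - (TOC + IC) before and after, and the audit verdict.

    The audit passes when both |residuals| are at most 0.5 ppb.
    """
    before = record.tc_before - (record.toc_before + record.ic_before)
    after = record.tc_after - (record.toc_after + record.ic_after)
    ok = abs(before) <= TC_AUDIT_TOLERANCE_PPB and abs(after) <= TC_AUDIT_TOLERANCE_PPB
    return before, after, ok
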