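"""Calibration of metric scoring standards against imperial consumption.

The metric standard for maximum score of each food-group, protein, and dairy
component is set so that a reference cohort's metric consumption fulfils the
same proportion of it as its imperial consumption fulfils of the imperial
standard:

    metric standard = mean metric consumption x imperial standard
                      / mean imperial consumption      (all per 1000 kcal)

Purely nutrient-based components (fatty acids, sodium, added sugars,
saturated fats) are already metric and pass through unchanged. The refined
grains minimum-score threshold is derived from the calibrated maximum-score
threshold and the imperial min/max ratio. Final standards are rounded half
away from zero — to the nearest gram equivalent for food-group components and
to one decimal place for the protein and dairy components; intermediates stay
unrounded.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .components import (
    GRAM_EQUIVALENT_COMPONENTS,
    NUTRIENT_EQUIVALENT_COMPONENTS,
    Component,
)
from .standards import HEI_2015, ComponentStandard, ScoringStandards

__all__ = [
    "PairedConsumption",
    "CalibratedStandard",
    "CalibrationResult",
    "calibrate_component",
    "calibrate_refined_grains_min",
    "calibrate_all",
    "round_half_away",
]

#: Components whose standards are derived by calibration (vs passed through).
CALIBRATED_COMPONENTS: tuple[Component, ...] = tuple(
    c
    for c in Component
    if c in GRAM_EQUIVALENT_COMPONENTS or c in NUTRIENT_EQUIVALENT_COMPONENTS
)

_METRIC_UNITS = {
    Component.DAIRY: "mg calcium/1000 kcal",
    Component.TOTAL_PROTEIN_FOODS: "g protein/1000 kcal",
    Component.SEAFOOD_PLANT_PROTEINS: "g protein/1000 kcal",
}


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (5 always rounds up in magnitude).

    Works on the decimal representation, so values like 0.715 round to 0.72
    rather than falling victim to binary floating-point representation.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


class UncalibratableComponentError(ValueError):
    """Mean imperial consumption is zero: no proportion can be carried over."""


@dataclass(frozen=True)
class PairedConsumption:
    """Cohort mean consumption of one component on both unit systems."""

    component: Component
    mean_imperial: float
    mean_metric: float
    n_subjects: int

    def __post_init__(self) -> None:
        if self.mean_imperial < 0 or self.mean_metric < 0:
            raise ValueError("mean consumption must be non-negative")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


@dataclass(frozen=True)
class CalibratedStandard:
    component: Component
    metric_standard_for_max: float
    metric_standard_for_min: float | None
    rounding: str  # "integer_gram" or "one_decimal"


def _rounding_for(component: Component) -> tuple[str, int]:
    if component in NUTRIENT_EQUIVALENT_COMPONENTS:
        return "one_decimal", 1
    return "integer_gram", 0


def calibrate_component(
    pc: PairedConsumption, imperial_standard_for_max: float
) -> CalibratedStandard:
    """Carry the cohort's fulfilment proportion from imperial to metric units.

    Rounding is applied once, to the final standard: nearest integer gram
    equivalent for food-group components, one decimal for protein and dairy.
    """
    if pc.mean_imperial <= 0:
        raise UncalibratableComponentError(
            f"{pc.component}: mean imperial consumption is zero"
        )
    raw = pc.mean_metric * imperial_standard_for_max / pc.mean_imperial
    rounding, decimals = _rounding_for(pc.component)
    return CalibratedStandard(
        pc.component, round_half_away(raw, decimals), None, rounding
    )


def calibrate_refined_grains_min(
    metric_standard_for_max: float, imperial_min: float, imperial_max: float
) -> float:
    """Metric minimum-score threshold from the calibrated maximum-score
    threshold and the imperial min/max ratio, rounded to the nearest gram."""
    if min(metric_standard_for_max, imperial_min, imperial_max) <= 0:
        raise ValueError("all inputs must be positive")
    return round_half_away(metric_standard_for_max * imperial_min / imperial_max)


@dataclass
class CalibrationResult:
    """Calibrated metric standards plus the consumption means behind them."""

    standards: ScoringStandards
    paired: dict[Component, PairedConsumption]

    def summary(self) -> pd.DataFrame:
        rows = []
        for c in Component:
            cs = self.standards[c]
            pc = self.paired.get(c)
            rows.append(
                {
                    "component": c.value,
                    "max_points": cs.max_points,
                    "mean_imperial": pc.mean_imperial if pc else None,
                    "mean_metric": pc.mean_metric if pc else None,
                    "standard_for_max": cs.standard_for_max,
                    "standard_for_min": cs.standard_for_min,
                    "unit": cs.unit,
                }
            )
        return pd.DataFrame(rows)


def calibrate_all(
    imperial_densities: pd.DataFrame,
    metric_densities: pd.DataFrame,
    imperial_standards: ScoringStandards = HEI_2015,
    standards_id: str = "mhei2015-calibrated",
) -> CalibrationResult:
    """Derive a complete metric standards set from paired per-subject density
    tables (one column per component, one row per subject, shared subject_id).

    Cohort means are simple arithmetic means of the per-subject densities;
    they stay unrounded until the final standard is rounded.
    """
    for df, label in ((imperial_densities, "imperial"), (metric_densities, "metric")):
        if "subject_id" not in df.columns:
            raise ValueError(f"{label} table: missing subject_id column")
    imp = imperial_densities.set_index("subject_id").sort_index()
    met = metric_densities.set_index("subject_id").sort_index()
    if set(imp.index) != set(met.index):
        raise ValueError("imperial and metric tables cover different subjects")

    components: dict[Component, ComponentStandard] = {}
    paired: dict[Component, PairedConsumption] = {}
    for c in Component:
        imp_cs = imperial_standards[c]
        if c not in CALIBRATED_COMPONENTS:
            # nutrient-only components are already metric: copy unchanged
            components[c] = imp_cs
            continue
        if c.value not in imp.columns or c.value not in met.columns:
            raise UncalibratableComponentError(f"{c}: missing consumption column")
        pc = PairedConsumption(
            c,
            float(imp[c.value].mean()),
            float(met[c.value].mean()),
            n_subjects=len(imp),
        )
        paired[c] = pc
        cal = calibrate_component(pc, imp_cs.standard_for_max)
        std_min = None
        if c is Component.REFINED_GRAINS:
            std_min = calibrate_refined_grains_min(
                cal.metric_standard_for_max,
                imp_cs.standard_for_min,
                imp_cs.standard_for_max,
            )
        components[c] = ComponentStandard(
            imp_cs.max_points,
            cal.metric_standard_for_max,
            std_min,
            _METRIC_UNITS.get(c, "g eq/1000 kcal"),
        )
    return CalibrationResult(ScoringStandards(standards_id, components), paired)
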