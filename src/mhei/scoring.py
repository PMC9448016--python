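"""Per-1000-kcal component densities and 13-component index scoring.

All component scores are linear between the standard for minimum and maximum
score, capped at the component's maximum points:

* adequacy — ``max_points x min(1, density / standard_for_max)``; zero intake
  scores zero;
* moderation — full points at or below ``standard_for_max``, zero at or above
  ``standard_for_min``, linear between;
* fatty acids — the (PUFA+MUFA)/SFA ratio, full points at >= 2.5, zero at
  <= 1.2.

Densities are computed per 1000 kcal, which makes the index invariant to
total energy intake. Multi-day records are pooled: intake and energy are
summed over the available days before dividing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .codes import LegumeAllocation
from .components import (
    ADEQUACY,
    ALL_COMPONENTS,
    MODERATION,
    Component,
)
from .database import FoodDatabase
from .equivalents import Recipe, food_profile, menu_equivalents
from .standards import ScoringStandards

__all__ = [
    "IntakeRecord",
    "ComponentDensities",
    "IndexScore",
    "component_densities",
    "score_adequacy",
    "score_moderation",
    "score_fatty_acids",
    "total_score",
    "percent_of_standard",
    "read_intakes",
    "score_cohort",
    "score_density_table",
]

KCAL_PER_G_SUGAR = 4.0
KCAL_PER_G_FAT = 9.0


@dataclass(frozen=True)
class IntakeRecord:
    """One person-day of consumption: (food or menu id, grams) items."""

    subject_id: str
    day: int
    items: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if self.day < 1:
            raise ValueError("day must be >= 1")
        for fid, g in self.items:
            if g < 0:
                raise ValueError(f"negative grams for {fid!r}")


@dataclass
class ComponentDensities:
    """Per-1000-kcal densities for one subject's pooled records.

    ``values`` holds, per component: g equivalents (fruit/vegetable/grain
    components), g protein, mg calcium, the dimensionless fatty-acid ratio,
    g sodium, and % of energy for added sugars and saturated fats. The
    fatty-acid entry is ``inf`` when unsaturated fat is consumed with zero
    saturated fat, and ``nan`` when no fat at all is consumed.
    """

    subject_id: str
    values: dict[Component, float] = field(default_factory=dict)
    total_energy_kcal: float = 0.0

    @property
    def zero_energy(self) -> bool:
        return self.total_energy_kcal <= 0

    def get(self, component: Component) -> float:
        return self.values.get(component, 0.0)


def component_densities(
    records: list[IntakeRecord],
    db: FoodDatabase,
    recipes: dict[str, Recipe] | None = None,
    legume_allocation: LegumeAllocation = LegumeAllocation.PROTEIN_AND_VEGETABLES,
) -> ComponentDensities:
    """Pool a subject's records and convert totals to per-1000-kcal densities."""
    if not records:
        raise ValueError("at least one intake record is required")
    subject = records[0].subject_id
    recipes = recipes or {}

    comp_totals = {c: 0.0 for c in ALL_COMPONENTS}
    nutrients = {
        "energy_kcal": 0.0,
        "pufa_g": 0.0,
        "mufa_g": 0.0,
        "sfa_g": 0.0,
        "added_sugars_g": 0.0,
        "sodium_mg": 0.0,
    }
    for rec in records:
        if rec.subject_id != subject:
            raise ValueError("records belong to different subjects")
        for item_id, grams in rec.items:
            if item_id in db:
                profile = food_profile(db[item_id], db, legume_allocation)
            elif item_id in recipes:
                profile = menu_equivalents(recipes[item_id], db, legume_allocation)
            else:
                raise KeyError(f"item {item_id!r} not in database or recipe table")
            scale = grams / 100.0
            for c, v in profile.components.items():
                comp_totals[c] += scale * v
            for k in nutrients:
                nutrients[k] += scale * profile.nutrients[k]

    energy = nutrients["energy_kcal"]
    dens = ComponentDensities(subject, total_energy_kcal=energy)
    if energy <= 0:
        return dens  # zero-energy flag; densities undefined, scored as zero
    per_1000 = 1000.0 / energy
    for c in ALL_COMPONENTS:
        if c in (
            Component.FATTY_ACIDS,
            Component.SODIUM,
            Component.ADDED_SUGARS,
            Component.SATURATED_FATS,
        ):
            continue
        dens.values[c] = comp_totals[c] * per_1000

    sfa, unsat = nutrients["sfa_g"], nutrients["pufa_g"] + nutrients["mufa_g"]
    if sfa > 0:
        dens.values[Component.FATTY_ACIDS] = unsat / sfa
    elif unsat > 0:
        dens.values[Component.FATTY_ACIDS] = math.inf
    else:
        dens.values[Component.FATTY_ACIDS] = math.nan
    dens.values[Component.SODIUM] = nutrients["sodium_mg"] / 1000.0 * per_1000
    dens.values[Component.ADDED_SUGARS] = (
        nutrients["added_sugars_g"] * KCAL_PER_G_SUGAR / energy * 100.0
    )
    dens.values[Component.SATURATED_FATS] = (
        nutrients["sfa_g"] * KCAL_PER_G_FAT / energy * 100.0
    )
    return dens


def score_adequacy(density: float, standard_for_max: float, max_points: float) -> float:
    """Proportional adequacy score, 0 at zero intake, capped at max_points."""
    if density < 0:
        raise ValueError("density must be non-negative")
    if standard_for_max <= 0:
        raise ValueError("standard must be positive")
    return max_points * min(1.0, density / standard_for_max)


def score_moderation(
    density: float,
    standard_for_max: float,
    standard_for_min: float,
    max_points: float,
) -> float:
    """Moderation score: full at/below the max-score threshold, zero at/above
    the min-score threshold, linear between."""
    if standard_for_min <= standard_for_max:
        raise ValueError("standard_for_min must exceed standard_for_max")
    if density <= standard_for_max:
        return max_points
    if density >= standard_for_min:
        return 0.0
    return max_points * (standard_for_min - density) / (standard_for_min - standard_for_max)


def score_fatty_acids(
    ratio: float,
    max_points: float = 10.0,
    standard_for_max: float = 2.5,
    standard_for_min: float = 1.2,
) -> float:
    """Score the (PUFA+MUFA)/SFA ratio: 10 at >= 2.5, 0 at <= 1.2, linear
    between. ``nan`` (no fat consumed at all) scores 0; ``inf`` (unsaturated
    fat with zero saturated fat) scores the maximum."""
    if math.isnan(ratio):
        return 0.0
    if ratio >= standard_for_max:
        return max_points
    if ratio <= standard_for_min:
        return 0.0
    return max_points * (ratio - standard_for_min) / (standard_for_max - standard_for_min)


@dataclass
class IndexScore:
    """Component and total scores for one subject under one set of standards."""

    subject_id: str
    component_scores: dict[Component, float]
    total: float
    standards_id: str

    def summary(self) -> pd.DataFrame:
        rows = [
            {"component": c.value, "score": self.component_scores[c]}
            for c in ALL_COMPONENTS
        ]
        rows.append({"component": "total", "score": self.total})
        return pd.DataFrame(rows)


def total_score(densities: ComponentDensities, standards: ScoringStandards) -> IndexScore:
    """Score all 13 components and sum. Zero-energy subjects score 0 on every
    component (densities are undefined)."""
    scores: dict[Component, float] = {}
    if densities.zero_energy:
        scores = {c: 0.0 for c in ALL_COMPONENTS}
        return IndexScore(densities.subject_id, scores, 0.0, standards.standards_id)
    for c in ADEQUACY:
        cs = standards[c]
        if c is Component.FATTY_ACIDS:
            scores[c] = score_fatty_acids(
                densities.get(c), cs.max_points, cs.standard_for_max, cs.standard_for_min
            )
        else:
            scores[c] = score_adequacy(densities.get(c), cs.standard_for_max, cs.max_points)
    for c in MODERATION:
        cs = standards[c]
        scores[c] = score_moderation(
            densities.get(c), cs.standard_for_max, cs.standard_for_min, cs.max_points
        )
    return IndexScore(
        densities.subject_id, scores, sum(scores.values()), standards.standards_id
    )


def percent_of_standard(
    densities: ComponentDensities, standards: ScoringStandards
) -> dict[Component, float]:
    """Percent compliance per component, for radar-style exports.

    Adequacy: 100 x min(1, density/standard) — overconsumption is capped at
    100. Moderation and fatty acids: score as a percentage of maximum points.
    """
    score = total_score(densities, standards)
    out: dict[Component, float] = {}
    for c in ALL_COMPONENTS:
        cs = standards[c]
        if c in MODERATION or c is Component.FATTY_ACIDS:
            out[c] = 100.0 * score.component_scores[c] / cs.max_points
        elif densities.zero_energy:
            out[c] = 0.0
        else:
            out[c] = 100.0 * min(1.0, densities.get(c) / cs.standard_for_max)
    return out


def read_intakes(path: str | Path) -> pd.DataFrame:
    """Load an intake CSV with columns subject_id, day, food_id, grams."""
    df = pd.read_csv(path, dtype={"subject_id": str, "food_id": str})
    missing = [c for c in ("subject_id", "day", "food_id", "grams") if c not in df.columns]
    if missing:
        raise ValueError(f"intake table {path}: missing columns {missing}")
    return df


def intake_records(df: pd.DataFrame) -> dict[str, list[IntakeRecord]]:
    """Group an intake table into per-subject lists of day records."""
    out: dict[str, list[IntakeRecord]] = {}
    for (subject, day), grp in df.groupby(["subject_id", "day"], sort=True):
        out.setdefault(str(subject), []).append(
            IntakeRecord(
                str(subject),
                int(day),
                tuple(zip(grp["food_id"], grp["grams"].astype(float))),
            )
        )
    return out


def score_cohort(
    intakes: pd.DataFrame,
    db: FoodDatabase,
    standards: ScoringStandards,
    recipes: dict[str, Recipe] | None = None,
    legume_allocation: LegumeAllocation = LegumeAllocation.PROTEIN_AND_VEGETABLES,
) -> pd.DataFrame:
    """Score every subject in an intake table; one row per subject with 13
    component columns, total, and the standards id."""
    rows = []
    for subject, records in intake_records(intakes).items():
        dens = component_densities(records, db, recipes, legume_allocation)
        score = total_score(dens, standards)
        rows.append(
            {
                "subject_id": subject,
                **{c.value: score.component_scores[c] for c in ALL_COMPONENTS},
                "total": score.total,
                "standards_id": score.standards_id,
            }
        )
    cols = ["subject_id"] + [c.value for c in ALL_COMPONENTS] + ["total", "standards_id"]
    return pd.DataFrame(rows, columns=cols)


def score_density_table(
    densities: pd.DataFrame, standards: ScoringStandards
) -> pd.DataFrame:
    """Score a table of precomputed per-subject densities (one column per
    component, e.g. an FPED-style cup/ounce-equivalent summary for imperial
    scoring). A ``total_energy_kcal`` column, if present, marks zero-energy
    subjects; otherwise all rows are assumed scorable."""
    rows = []
    for _, row in densities.iterrows():
        dens = ComponentDensities(
            str(row["subject_id"]),
            {c: float(row[c.value]) for c in ALL_COMPONENTS if c.value in row.index},
            total_energy_kcal=float(row.get("total_energy_kcal", 1.0)),
        )
        score = total_score(dens, standards)
        rows.append(
            {
                "subject_id": dens.subject_id,
                **{c.value: score.component_scores[c] for c in ALL_COMPONENTS},
                "total": score.total,
                "standards_id": score.standards_id,
            }
        )
    cols = ["subject_id"] + [c.value for c in ALL_COMPONENTS] + ["total", "standards_id"]
    return pd.DataFrame(rows, columns=cols)
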