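"""Synthetic fixtures: food databases, recipes, and intake cohorts.

Every other module is testable without any external download. The generator
produces structurally realistic data — raw/processed food pairs with known
energy-density ratios, cooked/uncooked legume pairs, protein and dairy foods
with known protein and calcium contents, and cohorts of person-day intake
records whose per-1000-kcal component densities are known exactly by
construction (the ground truth is emitted alongside the records).

Cohort intakes are composed from "staple" foods with clean compositions: each
staple drives exactly one group of components, so target densities translate
into gram amounts by simple arithmetic. Nutrient targets (added sugars,
fatty acids, sodium) are hit with single-nutrient filler foods, and a pure
energy filler tops intake up to the target energy. What this does not
emulate: the mixed compositions, correlated nutrient patterns and day-to-day
variance of real dietary recalls.

All randomness flows from one integer seed through fixed stream offsets
(food db = 0, cohort = 1, paired consumption = 2), so any artifact is
reproducible independently of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CALIBRATED_COMPONENTS
from .codes import FoodCode
from .components import Component
from .database import FoodDatabase, FoodRecord
from .standards import MHEI_2015, ScoringStandards

__all__ = ["CohortSpec", "make_food_db", "make_cohort", "make_paired_consumption"]

_STREAM_FOOD_DB = 0
_STREAM_COHORT = 1
_STREAM_PAIRED = 2


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


class ImpossibleProfileError(ValueError):
    """The requested density targets cannot fit in the target energy."""


# ---------------------------------------------------------------------------
# staple foods: clean compositions the cohort builder relies on
# ---------------------------------------------------------------------------

def _staples() -> list[FoodRecord]:
    def rec(food_id, name, code, energy=0.0, protein=0.0, calcium=0.0, pufa=0.0,
            mufa=0.0, sfa=0.0, sugars=0.0, sodium=0.0):
        return FoodRecord(food_id, name, code, energy, protein, calcium, pufa,
                          mufa, sfa, sugars, sodium)

    return [
        rec("staple_juice", "fruit juice (staple)", FoodCode("F", "J", 0, 0), energy=45),
        rec("staple_fruit", "whole fruit (staple)", FoodCode("F", "O", 0, 0), energy=52),
        rec("staple_darkgreen", "dark green vegetable (staple)", FoodCode("V", "D", 0, 0), energy=23),
        rec("staple_othveg", "other vegetable (staple)", FoodCode("V", "O", 0, 0), energy=25),
        rec("staple_wholegrain", "whole grain (staple)", FoodCode("G", "W", 0, 0), energy=340),
        rec("staple_refgrain", "refined grain (staple)", FoodCode("G", "R", 0, 0), energy=350),
        rec("staple_meat", "meat (staple)", FoodCode("P", "M"), energy=150, protein=25),
        rec("staple_seafood", "seafood (staple)", FoodCode("P", "S"), energy=100, protein=20),
        rec("staple_milk", "milk (staple)", FoodCode("D", "M"), energy=60, calcium=120),
        rec("filler_sugar", "added sugar filler", FoodCode("X"), energy=400, sugars=100),
        rec("filler_sfa", "saturated fat filler", FoodCode("X"), energy=900, sfa=100),
        rec("filler_mufa", "unsaturated fat filler", FoodCode("X"), energy=900, mufa=100),
        rec("filler_salt", "sodium filler", FoodCode("X"), sodium=40000),
        rec("filler_energy", "energy filler", FoodCode("X"), energy=400),
        rec("water", "water", FoodCode("X")),
    ]


# plausible raw energy-density ranges (kcal/100 g) per (type, group)
_ENERGY_RANGES = {
    ("F", "J"): (35, 60), ("F", "C"): (30, 60), ("F", "O"): (45, 90),
    ("V", "D"): (15, 40), ("V", "R"): (20, 50), ("V", "S"): (70, 110),
    ("V", "O"): (15, 45),
    ("G", "W"): (330, 380), ("G", "R"): (340, 380),
}
_LEGUME_COOKED_ENERGY = (90, 140)


def make_food_db(seed: int, n_per_group: int = 2) -> FoodDatabase:
    """A validating food database covering every code group.

    Fruit/vegetable/grain groups get raw + processed pairs whose processing
    factor equals a drawn energy-density ratio; the legume group gets
    cooked/uncooked pairs (uncooked denser); protein and dairy groups get
    foods with known protein and calcium contents; plus the staple and filler
    foods the cohort builder uses. Deterministic under the seed.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = _rng(seed, _STREAM_FOOD_DB)
    records = _staples()

    for (t, g), (lo, hi) in _ENERGY_RANGES.items():
        for i in range(1, n_per_group + 1):
            raw_energy = float(rng.uniform(lo, hi))
            ratio = float(rng.uniform(1.2, 6.0))
            base = f"{t}{g}{i:02d}".lower()
            records.append(
                FoodRecord(f"{base}0", f"synthetic {t}{g} item {i} raw",
                           FoodCode(t, g, i, 0), raw_energy,
                           sodium_mg_per_100g=float(rng.uniform(0, 30)))
            )
            records.append(
                FoodRecord(f"{base}1", f"synthetic {t}{g} item {i} processed",
                           FoodCode(t, g, i, 1), raw_energy * ratio,
                           sodium_mg_per_100g=float(rng.uniform(0, 200)))
            )
    # legumes: cooked (state 1) is the unity reference, uncooked denser
    for i in range(1, n_per_group + 1):
        cooked_energy = float(rng.uniform(*_LEGUME_COOKED_ENERGY))
        ratio = float(rng.uniform(2.2, 3.6))
        protein_cooked = float(rng.uniform(6, 10))
        records.append(
            FoodRecord(f"vl{i:02d}1", f"synthetic legume {i} cooked",
                       FoodCode("V", "L", i, 1), cooked_energy,
                       protein_g_per_100g=protein_cooked)
        )
        records.append(
            FoodRecord(f"vl{i:02d}0", f"synthetic legume {i} uncooked",
                       FoodCode("V", "L", i, 0), cooked_energy * ratio,
                       protein_g_per_100g=protein_cooked * ratio)
        )
    for g in "MUESNYL":
        for i in range(n_per_group):
            protein = float(rng.uniform(5, 30))
            fat = float(rng.uniform(0, min(40.0, 100 - protein)))
            sfa = fat * float(rng.uniform(0.2, 0.6))
            mufa = (fat - sfa) * float(rng.uniform(0.3, 0.8))
            pufa = fat - sfa - mufa
            records.append(
                FoodRecord(f"p{g.lower()}_{i}", f"synthetic protein food {g}{i}",
                           FoodCode("P", g),
                           energy_kcal_per_100g=protein * 4 + fat * 9,
                           protein_g_per_100g=protein, pufa_g_per_100g=pufa,
                           mufa_g_per_100g=mufa, sfa_g_per_100g=sfa,
                           sodium_mg_per_100g=float(rng.uniform(30, 500)))
            )
    for g in "MYCO":
        for i in range(n_per_group):
            calcium = float(rng.uniform(50, 800))
            records.append(
                FoodRecord(f"d{g.lower()}_{i}", f"synthetic dairy food {g}{i}",
                           FoodCode("D", g),
                           energy_kcal_per_100g=float(rng.uniform(40, 350)),
                           protein_g_per_100g=float(rng.uniform(3, 25)),
                           calcium_mg_per_100g=calcium,
                           sfa_g_per_100g=float(rng.uniform(0, 15)))
            )
    return FoodDatabase.from_records(records)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: metric densities at which every component scores its maximum
_NEAR_MAX_TARGETS: dict[Component, float] = {
    c: MHEI_2015[c].standard_for_max for c in Component
}
#: densities at which every component scores zero
_NEAR_MIN_TARGETS: dict[Component, float] = {
    **{c: 0.0 for c in Component},
    Component.REFINED_GRAINS: MHEI_2015[Component.REFINED_GRAINS].standard_for_min,
    Component.SODIUM: MHEI_2015[Component.SODIUM].standard_for_min,
    Component.ADDED_SUGARS: MHEI_2015[Component.ADDED_SUGARS].standard_for_min,
    Component.SATURATED_FATS: MHEI_2015[Component.SATURATED_FATS].standard_for_min,
    Component.FATTY_ACIDS: 0.0,  # all fat saturated
}


@dataclass
class CohortSpec:
    """Parameters of a synthetic intake cohort.

    ``profile`` selects the target score pattern: ``near_max`` places every
    density exactly at the metric standard for maximum score, ``near_min`` at
    (or beyond) the standard for minimum score, ``random`` scales each
    standard by the per-component multipliers with multiplicative lognormal
    noise. Defaults are deliberately tiny (n = 50, 2000 ± 300 kcal, noise
    sd 0.2) so a full test suite runs in seconds.
    """

    n_subjects: int = 50
    days: int = 1
    seed: int = 0
    profile: str = "random"
    multipliers: dict[Component, float] = field(default_factory=dict)
    noise_sd: float = 0.2
    energy_mean: float = 2000.0
    energy_sd: float = 300.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.days not in (1, 2):
            raise ValueError("days must be 1 or 2")
        if self.profile not in ("random", "near_max", "near_min"):
            raise ValueError(f"unknown profile {self.profile!r}")


_DEFAULT_MULTIPLIER = 0.6


def _subject_targets(spec: CohortSpec, rng: np.random.Generator) -> dict[Component, float]:
    if spec.profile == "near_max":
        return dict(_NEAR_MAX_TARGETS)
    if spec.profile == "near_min":
        return dict(_NEAR_MIN_TARGETS)
    targets: dict[Component, float] = {}
    for c in Component:
        m = spec.multipliers.get(c, _DEFAULT_MULTIPLIER)
        noise = float(rng.lognormal(-spec.noise_sd**2 / 2, spec.noise_sd)) if spec.noise_sd else 1.0
        targets[c] = MHEI_2015[c].standard_for_max * m * noise
    # consistency: subset components cannot exceed their parent
    targets[Component.WHOLE_FRUITS] = min(
        targets[Component.WHOLE_FRUITS], targets[Component.TOTAL_FRUITS]
    )
    targets[Component.GREENS_AND_BEANS] = min(
        targets[Component.GREENS_AND_BEANS], targets[Component.TOTAL_VEGETABLES]
    )
    targets[Component.SEAFOOD_PLANT_PROTEINS] = min(
        targets[Component.SEAFOOD_PLANT_PROTEINS], targets[Component.TOTAL_PROTEIN_FOODS]
    )
    return targets


def _compose_intake(
    targets: dict[Component, float], energy: float, db: FoodDatabase
) -> list[tuple[str, float]]:
    """Translate density targets (per 1000 kcal) into staple gram amounts."""
    k = energy / 1000.0  # scale densities to absolute amounts

    def density(c: Component) -> float:
        return targets[c]

    wf = density(Component.WHOLE_FRUITS)
    tf = density(Component.TOTAL_FRUITS)
    gb = density(Component.GREENS_AND_BEANS)
    tv = density(Component.TOTAL_VEGETABLES)
    spp = density(Component.SEAFOOD_PLANT_PROTEINS)
    tpf = density(Component.TOTAL_PROTEIN_FOODS)

    sugar_g = density(Component.ADDED_SUGARS) * energy / 100.0 / 4.0
    sfa_g = density(Component.SATURATED_FATS) * energy / 100.0 / 9.0
    mufa_g = density(Component.FATTY_ACIDS) * sfa_g
    sodium_mg = density(Component.SODIUM) * 1000.0 * k

    items = [
        ("staple_fruit", wf * k),
        ("staple_juice", (tf - wf) * k),
        ("staple_darkgreen", gb * k),
        ("staple_othveg", (tv - gb) * k),
        ("staple_wholegrain", density(Component.WHOLE_GRAINS) * k),
        ("staple_refgrain", density(Component.REFINED_GRAINS) * k),
        ("staple_seafood", spp * k * 100.0 / db["staple_seafood"].protein_g_per_100g),
        ("staple_meat", (tpf - spp) * k * 100.0 / db["staple_meat"].protein_g_per_100g),
        ("staple_milk", density(Component.DAIRY) * k * 100.0 / db["staple_milk"].calcium_mg_per_100g),
        ("filler_sugar", sugar_g),
        ("filler_sfa", sfa_g),
        ("filler_mufa", mufa_g),
        ("filler_salt", sodium_mg / db["filler_salt"].sodium_mg_per_100g * 100.0),
    ]
    consumed_energy = sum(g * db[fid].energy_kcal_per_100g / 100.0 for fid, g in items)
    deficit = energy - consumed_energy
    if deficit < -1e-6:
        raise ImpossibleProfileError(
            f"targets need {consumed_energy:.0f} kcal but only {energy:.0f} kcal allowed"
        )
    items.append(("filler_energy", max(0.0, deficit) * 100.0
                  / db["filler_energy"].energy_kcal_per_100g))
    return [(fid, g) for fid, g in items if g > 0]


def make_cohort(
    spec: CohortSpec, db: FoodDatabase
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate intake records and their exact ground-truth densities.

    Returns ``(intakes, ground_truth)``: the intake table in the scoring
    module's CSV schema (subject_id, day, food_id, grams), and one row per
    subject with every component density plus total energy — computed from
    the targets, not by re-running the pipeline.
    """
    rng = _rng(spec.seed, _STREAM_COHORT)
    intake_rows = []
    truth_rows = []
    for s in range(spec.n_subjects):
        subject = f"S{s:04d}"
        energy = float(np.clip(rng.normal(spec.energy_mean, spec.energy_sd), 1200, 4000))
        targets = _subject_targets(spec, rng)
        items = _compose_intake(targets, energy, db)
        # day split leaves pooled densities unchanged
        splits = [(1, 1.0)] if spec.days == 1 else [(1, 0.6), (2, 0.4)]
        for day, frac in splits:
            for fid, grams in items:
                intake_rows.append(
                    {"subject_id": subject, "day": day, "food_id": fid,
                     "grams": grams * frac}
                )
        truth_rows.append(
            {"subject_id": subject,
             **{c.value: targets[c] for c in Component},
             "total_energy_kcal": energy}
        )
    intakes = pd.DataFrame(intake_rows, columns=["subject_id", "day", "food_id", "grams"])
    truth = pd.DataFrame(truth_rows)
    return intakes, truth


# ---------------------------------------------------------------------------
# paired consumption tables for calibration
# ---------------------------------------------------------------------------

def make_paired_consumption(
    n_subjects: int,
    true_metric_standards: ScoringStandards,
    imperial_standards: ScoringStandards,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired imperial/metric per-subject density tables.

    Each subject fulfils a random proportion of every component's standard;
    the metric density fulfils the same proportion of the planted true metric
    standard, times mean-one lognormal noise. With ``noise_sd = 0`` the
    calibration must recover the planted standards exactly after rounding.
    """
    rng = _rng(seed, _STREAM_PAIRED)
    imp_rows, met_rows = [], []
    for s in range(n_subjects):
        subject = f"S{s:04d}"
        imp_row: dict = {"subject_id": subject}
        met_row: dict = {"subject_id": subject}
        for c in CALIBRATED_COMPONENTS:
            proportion = float(rng.uniform(0.2, 1.2))
            noise = (
                float(rng.lognormal(-noise_sd**2 / 2, noise_sd)) if noise_sd else 1.0
            )
            imp_row[c.value] = proportion * imperial_standards[c].standard_for_max
            met_row[c.value] = (
                proportion * true_metric_standards[c].standard_for_max * noise
            )
        imp_rows.append(imp_row)
        met_rows.append(met_row)
    return pd.DataFrame(imp_rows), pd.DataFrame(met_rows)
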