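"""Gram-equivalent and nutrient-equivalent computation.

The equivalent principle compensates for the change in energy density a food
undergoes through preparation. Raw fruits, vegetables and grains convert to
gram equivalents at factor 1; processed forms at the ratio of processed to raw
energy density (kcal per 100 g). Legumes are the one exception: the cooked
form is the unity reference, and the uncooked form carries a factor above one
reflecting its higher energy density.

Protein-food and dairy contributions are expressed at the nutrient level:
grams of protein and milligrams of calcium, with no processing factor.

Multi-ingredient menu items are decomposed through a recipe table of mass
fractions; where only paired cup-equivalent tables exist, the fractions are
reconstructed as the quotient of the menu's and the ingredient's
cup equivalents per 100 g.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

from .codes import PROCESSED, RAW, LegumeAllocation, component_of
from .components import (
    GRAM_EQUIVALENT_COMPONENTS,
    NUTRIENT_EQUIVALENT_COMPONENTS,
    Component,
)
from .database import FoodDatabase, FoodRecord

__all__ = [
    "FactorBasis",
    "EquivalentFactor",
    "Recipe",
    "EquivalentProfile",
    "processing_factor",
    "equivalent_factor",
    "gram_equivalents",
    "nutrient_equivalents",
    "food_profile",
    "menu_equivalents",
    "ingredient_fraction_from_cup_equivalents",
    "detect_recipe_discrepancies",
    "read_recipes",
    "recipes_from_cup_equivalents",
    "equivalents_table",
]

logger = logging.getLogger("mhei")

# nutrient fields carried alongside component amounts, per 100 g
NUTRIENT_FIELDS = (
    "energy_kcal",
    "protein_g",
    "calcium_mg",
    "pufa_g",
    "mufa_g",
    "sfa_g",
    "added_sugars_g",
    "sodium_mg",
)


class FactorBasis(str, Enum):
    RAW_UNITY = "raw_unity"
    ENERGY_DENSITY_RATIO = "energy_density_ratio"
    OVERRIDE = "override"


@dataclass(frozen=True)
class EquivalentFactor:
    """Gram equivalents per gram consumed for one food."""

    food_id: str
    factor: float
    basis: FactorBasis

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError(f"factor must be positive, got {self.factor}")
        if self.basis is FactorBasis.RAW_UNITY and self.factor != 1.0:
            raise ValueError("raw_unity basis implies factor 1")


@dataclass(frozen=True)
class Recipe:
    """Ingredient mass fractions of one multi-ingredient menu item.

    Fractions sum to at most 1 (+1e-9); any remainder is water or
    unclassified mass.
    """

    menu_id: str
    ingredients: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.ingredients)
        if total > 1 + 1e-9:
            raise ValueError(
                f"recipe {self.menu_id!r}: mass fractions sum to {total:.6g} > 1"
            )
        for fid, f in self.ingredients:
            if not 0 <= f <= 1:
                raise ValueError(
                    f"recipe {self.menu_id!r}: fraction {f} for {fid!r} outside [0, 1]"
                )


@dataclass
class EquivalentProfile:
    """Per-100-g component amounts (and nutrients) of a food or menu item.

    Units per component: g equivalents for the fruit, vegetable and grain
    components; g protein for the two protein components; mg calcium for
    dairy.
    """

    item_id: str
    components: dict[Component, float] = field(default_factory=dict)
    nutrients: dict[str, float] = field(
        default_factory=lambda: {k: 0.0 for k in NUTRIENT_FIELDS}
    )

    def get(self, component: Component) -> float:
        return self.components.get(component, 0.0)

    def check(self) -> None:
        for c, v in self.components.items():
            if v < 0:
                raise ValueError(f"{self.item_id}: negative amount for {c}")
        if self.get(Component.WHOLE_FRUITS) > self.get(Component.TOTAL_FRUITS) + 1e-9:
            raise ValueError(f"{self.item_id}: whole fruits exceed total fruits")
        if self.get(Component.GREENS_AND_BEANS) > self.get(Component.TOTAL_VEGETABLES) + 1e-9:
            raise ValueError(f"{self.item_id}: greens and beans exceed total vegetables")


class UndefinedFactorError(ZeroDivisionError):
    """Energy density of the reference form is zero: factor undefined."""


def processing_factor(processed: FoodRecord, raw: FoodRecord) -> EquivalentFactor:
    """Factor converting consumed grams to gram equivalents.

    Raw (state 0) foods are rated at factor 1. Processed foods at the ratio of
    processed to raw energy density. For the legume vegetable group the roles
    invert: the cooked ("processed") form is the unity reference and the
    uncooked form gets the energy-density ratio relative to it.
    """
    code = processed.code
    if code.item_key != raw.code.item_key:
        raise ValueError(
            f"{processed.food_id!r} and {raw.food_id!r} are not forms of the same item"
        )
    if code.is_legume_vegetable:
        # cooked (state 1) legumes score like raw vegetables: factor 1
        if code.processing_state == PROCESSED:
            return EquivalentFactor(processed.food_id, 1.0, FactorBasis.RAW_UNITY)
        cooked = raw  # caller passes the cooked reference in the `raw` slot
        if cooked.energy_kcal_per_100g <= 0:
            raise UndefinedFactorError(
                f"cooked reference {cooked.food_id!r} has zero energy density"
            )
        return EquivalentFactor(
            processed.food_id,
            processed.energy_kcal_per_100g / cooked.energy_kcal_per_100g,
            FactorBasis.ENERGY_DENSITY_RATIO,
        )
    if code.processing_state == RAW:
        return EquivalentFactor(processed.food_id, 1.0, FactorBasis.RAW_UNITY)
    if raw.energy_kcal_per_100g <= 0:
        raise UndefinedFactorError(
            f"raw reference {raw.food_id!r} has zero energy density"
        )
    return EquivalentFactor(
        processed.food_id,
        processed.energy_kcal_per_100g / raw.energy_kcal_per_100g,
        FactorBasis.ENERGY_DENSITY_RATIO,
    )


def equivalent_factor(record: FoodRecord, db: FoodDatabase) -> EquivalentFactor:
    """Resolve a food's factor against the database.

    Looks up the reference form (raw counterpart; cooked counterpart for
    uncooked legumes). A processed food with no resolvable reference uses its
    explicit ``factor_override`` when present, else factor 1 with a warning.
    """
    code = record.code
    if code.component_type not in "FVG":
        return EquivalentFactor(record.food_id, 1.0, FactorBasis.RAW_UNITY)
    if code.is_legume_vegetable:
        if code.processing_state == PROCESSED:
            return EquivalentFactor(record.food_id, 1.0, FactorBasis.RAW_UNITY)
        reference = db.counterpart(record, PROCESSED)
    elif code.processing_state == RAW:
        return EquivalentFactor(record.food_id, 1.0, FactorBasis.RAW_UNITY)
    else:
        reference = db.counterpart(record, RAW)
    if reference is None:
        if record.factor_override is not None:
            return EquivalentFactor(
                record.food_id, record.factor_override, FactorBasis.OVERRIDE
            )
        logger.warning(
            "food %s: no reference form for factor computation; using factor 1",
            record.food_id,
        )
        return EquivalentFactor(record.food_id, 1.0, FactorBasis.RAW_UNITY)
    return processing_factor(record, reference)


def gram_equivalents(
    amount_g: float,
    record: FoodRecord,
    db: FoodDatabase,
    legume_allocation: LegumeAllocation = LegumeAllocation.PROTEIN_AND_VEGETABLES,
) -> dict[Component, float]:
    """Gram-equivalent contributions of ``amount_g`` grams of one food.

    Credits amount x factor to every gram-equivalent component the food's code
    maps to; zero for X foods and for protein/dairy codes (those contribute at
    the nutrient level, see :func:`nutrient_equivalents`).
    """
    if amount_g < 0:
        raise ValueError("amount must be non-negative")
    code = record.code
    if code.component_type not in "FVG":
        return {}
    factor = equivalent_factor(record, db).factor
    geq = amount_g * factor
    comps = component_of(code, legume_allocation)
    return {
        c: geq
        for c in comps
        if c not in (Component.TOTAL_PROTEIN_FOODS, Component.SEAFOOD_PLANT_PROTEINS)
    }


def nutrient_equivalents(amount_g: float, record: FoodRecord) -> dict[Component, float]:
    """Protein-gram / calcium-milligram contributions of one P or D food.

    No processing factor applies: the nutrient content itself is the
    equivalent.
    """
    if amount_g < 0:
        raise ValueError("amount must be non-negative")
    code = record.code
    out: dict[Component, float] = {}
    if code.component_type == "P":
        protein = amount_g * record.protein_g_per_100g / 100.0
        for c in component_of(code):
            out[c] = protein
    elif code.component_type == "D":
        out[Component.DAIRY] = amount_g * record.calcium_mg_per_100g / 100.0
    else:
        raise ValueError(
            f"nutrient_equivalents applies to P/D foods, got {code.component_type!r}"
        )
    return out


def food_profile(
    record: FoodRecord,
    db: FoodDatabase,
    legume_allocation: LegumeAllocation = LegumeAllocation.PROTEIN_AND_VEGETABLES,
) -> EquivalentProfile:
    """Full per-100-g profile of a single food: components plus nutrients.

    Legume vegetables contribute gram equivalents to the vegetable components
    and protein grams (no factor) to the protein components when the
    allocation switch includes them.
    """
    code = record.code
    components: dict[Component, float] = {}
    if code.component_type in "FVG":
        components.update(gram_equivalents(100.0, record, db, legume_allocation))
        if code.is_legume_vegetable:
            protein = record.protein_g_per_100g
            for c in component_of(code, legume_allocation):
                if c in (
                    Component.TOTAL_PROTEIN_FOODS,
                    Component.SEAFOOD_PLANT_PROTEINS,
                ):
                    components[c] = protein
    elif code.component_type in "PD":
        components.update(nutrient_equivalents(100.0, record))
    nutrients = {
        "energy_kcal": record.energy_kcal_per_100g,
        "protein_g": record.protein_g_per_100g,
        "calcium_mg": record.calcium_mg_per_100g,
        "pufa_g": record.pufa_g_per_100g,
        "mufa_g": record.mufa_g_per_100g,
        "sfa_g": record.sfa_g_per_100g,
        "added_sugars_g": record.added_sugars_g_per_100g,
        "sodium_mg": record.sodium_mg_per_100g,
    }
    profile = EquivalentProfile(record.food_id, components, nutrients)
    profile.check()
    return profile


def menu_equivalents(
    recipe: Recipe,
    db: FoodDatabase,
    legume_allocation: LegumeAllocation = LegumeAllocation.PROTEIN_AND_VEGETABLES,
) -> EquivalentProfile:
    """Per-100-g profile of a menu item: the mass-fraction blend of its
    ingredients' profiles. Any unclassified remainder contributes nothing."""
    components: dict[Component, float] = {}
    nutrients = {k: 0.0 for k in NUTRIENT_FIELDS}
    for food_id, fraction in recipe.ingredients:
        if food_id not in db:
            raise KeyError(
                f"recipe {recipe.menu_id!r}: ingredient {food_id!r} not in database"
            )
        ing = food_profile(db[food_id], db, legume_allocation)
        for c, v in ing.components.items():
            components[c] = components.get(c, 0.0) + fraction * v
        for k in NUTRIENT_FIELDS:
            nutrients[k] += fraction * ing.nutrients[k]
    profile = EquivalentProfile(recipe.menu_id, components, nutrients)
    profile.check()
    return profile


def ingredient_fraction_from_cup_equivalents(
    menu_cupeq_per_100g: float, ingredient_cupeq_per_100g: float
) -> float:
    """Reconstruct an ingredient's mass fraction from paired cup equivalents.

    Both values are cup (or ounce) equivalents per 100 g in the same
    component; the fraction is their quotient. This recovers portions exactly
    when both the menu item and the ingredient are tabulated in equivalents.
    """
    if menu_cupeq_per_100g < 0:
        raise ValueError("menu cup equivalents must be non-negative")
    if ingredient_cupeq_per_100g <= 0:
        raise ZeroDivisionError(
            "ingredient cup equivalents must be positive to derive a fraction"
        )
    return menu_cupeq_per_100g / ingredient_cupeq_per_100g


@dataclass(frozen=True)
class Discrepancy:
    item_id: str
    component: Component
    declared: float
    recomputed: float

    @property
    def difference(self) -> float:
        return self.declared - self.recomputed


def detect_recipe_discrepancies(
    declared: EquivalentProfile,
    recomputed: EquivalentProfile,
    tol: float = 0.005,
) -> list[Discrepancy]:
    """Components where declared and recipe-recomputed values differ by more
    than ``tol`` (strict), i.e. by more than rounding can explain.

    The default 0.005 is half a rounding unit at two printed decimals.
    """
    if declared.item_id != recomputed.item_id:
        raise ValueError("profiles describe different items")
    out = []
    for c in sorted(
        set(declared.components) | set(recomputed.components), key=lambda c: c.value
    ):
        d, r = declared.get(c), recomputed.get(c)
        if abs(d - r) > tol:
            out.append(Discrepancy(declared.item_id, c, d, r))
    return out


def read_recipes(path: str | Path) -> dict[str, Recipe]:
    """Load a recipe CSV with columns menu_id, food_id, mass_fraction."""
    df = pd.read_csv(path, dtype={"menu_id": str, "food_id": str})
    missing = [c for c in ("menu_id", "food_id", "mass_fraction") if c not in df.columns]
    if missing:
        raise ValueError(f"recipe table {path}: missing columns {missing}")
    recipes = {}
    for menu_id, grp in df.groupby("menu_id", sort=True):
        recipes[menu_id] = Recipe(
            menu_id,
            tuple(zip(grp["food_id"], grp["mass_fraction"].astype(float))),
        )
    return recipes


def recipes_from_cup_equivalents(df: pd.DataFrame) -> dict[str, Recipe]:
    """Build recipes from a paired cup-equivalent table.

    Expects columns menu_id, ingredient_food_id, component,
    menu_cupeq_per_100g, ingredient_cupeq_per_100g; one row per
    (menu, ingredient) suffices, extra component rows are averaged.
    """
    required = [
        "menu_id",
        "ingredient_food_id",
        "menu_cupeq_per_100g",
        "ingredient_cupeq_per_100g",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cup-equivalent table: missing columns {missing}")
    recipes = {}
    for menu_id, grp in df.groupby("menu_id", sort=True):
        ingredients = []
        for fid, sub in grp.groupby("ingredient_food_id", sort=True):
            fracs = [
                ingredient_fraction_from_cup_equivalents(m, i)
                for m, i in zip(
                    sub["menu_cupeq_per_100g"], sub["ingredient_cupeq_per_100g"]
                )
            ]
            ingredients.append((fid, sum(fracs) / len(fracs)))
        recipes[menu_id] = Recipe(menu_id, tuple(ingredients))
    return recipes


def equivalents_table(
    db: FoodDatabase,
    recipes: dict[str, Recipe] | None = None,
    legume_allocation: LegumeAllocation = LegumeAllocation.PROTEIN_AND_VEGETABLES,
) -> pd.DataFrame:
    """Metric equivalents table: one row per food and menu item, one column
    per component amount per 100 g (the metric analogue of an FPED file)."""
    cols = [
        c
        for c in Component
        if c in GRAM_EQUIVALENT_COMPONENTS or c in NUTRIENT_EQUIVALENT_COMPONENTS
    ]
    rows = []
    for rec in db:
        profile = food_profile(rec, db, legume_allocation)
        rows.append({"item_id": rec.food_id, **{c.value: profile.get(c) for c in cols}})
    for menu_id in sorted(recipes or {}):
        profile = menu_equivalents(recipes[menu_id], db, legume_allocation)
        rows.append({"item_id": menu_id, **{c.value: profile.get(c) for c in cols}})
    return pd.DataFrame(rows)
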