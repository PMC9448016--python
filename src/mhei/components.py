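"""The 13 components of the HEI-2015 / mHEI-2015 and their point structure.

Nine adequacy components reward consumption up to a per-1000-kcal standard;
four moderation components penalise consumption above one. Maximum points
sum to 100 in both the imperial and the metric index.
"""

from __future__ import annotations

from enum import Enum


class Component(str, Enum):
    """One of the 13 diet-quality components."""

    TOTAL_FRUITS = "total_fruits"
    WHOLE_FRUITS = "whole_fruits"
    TOTAL_VEGETABLES = "total_vegetables"
    GREENS_AND_BEANS = "greens_and_beans"
    WHOLE_GRAINS = "whole_grains"
    DAIRY = "dairy"
    TOTAL_PROTEIN_FOODS = "total_protein_foods"
    SEAFOOD_PLANT_PROTEINS = "seafood_plant_proteins"
    FATTY_ACIDS = "fatty_acids"
    REFINED_GRAINS = "refined_grains"
    SODIUM = "sodium"
    ADDED_SUGARS = "added_sugars"
    SATURATED_FATS = "saturated_fats"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


ADEQUACY: tuple[Component, ...] = (
    Component.TOTAL_FRUITS,
    Component.WHOLE_FRUITS,
    Component.TOTAL_VEGETABLES,
    Component.GREENS_AND_BEANS,
    Component.WHOLE_GRAINS,
    Component.DAIRY,
    Component.TOTAL_PROTEIN_FOODS,
    Component.SEAFOOD_PLANT_PROTEINS,
    Component.FATTY_ACIDS,
)

MODERATION: tuple[Component, ...] = (
    Component.REFINED_GRAINS,
    Component.SODIUM,
    Component.ADDED_SUGARS,
    Component.SATURATED_FATS,
)

ALL_COMPONENTS: tuple[Component, ...] = ADEQUACY + MODERATION

#: Maximum attainable points per component (sums to 100).
MAX_POINTS: dict[Component, float] = {
    Component.TOTAL_FRUITS: 5,
    Component.WHOLE_FRUITS: 5,
    Component.TOTAL_VEGETABLES: 5,
    Component.GREENS_AND_BEANS: 5,
    Component.WHOLE_GRAINS: 10,
    Component.DAIRY: 10,
    Component.TOTAL_PROTEIN_FOODS: 5,
    Component.SEAFOOD_PLANT_PROTEINS: 5,
    Component.FATTY_ACIDS: 10,
    Component.REFINED_GRAINS: 10,
    Component.SODIUM: 10,
    Component.ADDED_SUGARS: 10,
    Component.SATURATED_FATS: 10,
}

#: Components whose densities are gram equivalents (food-group based, F/V/G).
GRAM_EQUIVALENT_COMPONENTS: frozenset[Component] = frozenset(
    {
        Component.TOTAL_FRUITS,
        Component.WHOLE_FRUITS,
        Component.TOTAL_VEGETABLES,
        Component.GREENS_AND_BEANS,
        Component.WHOLE_GRAINS,
        Component.REFINED_GRAINS,
    }
)

#: Components measured at the nutrient level in the metric index
#: (protein grams, calcium milligrams).
NUTRIENT_EQUIVALENT_COMPONENTS: frozenset[Component] = frozenset(
    {
        Component.TOTAL_PROTEIN_FOODS,
        Component.SEAFOOD_PLANT_PROTEINS,
        Component.DAIRY,
    }
)

#: Components identical between metric and imperial index (already metric units).
NUTRIENT_ONLY_COMPONENTS: frozenset[Component] = frozenset(
    {
        Component.FATTY_ACIDS,
        Component.SODIUM,
        Component.ADDED_SUGARS,
        Component.SATURATED_FATS,
    }
)
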