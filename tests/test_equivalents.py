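"""Gram equivalents, processing factors, recipes, and discrepancy detection."""

import logging

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mhei.calibration import round_half_away
from mhei.codes import FoodCode, parse_code
from mhei.components import Component
from mhei.database import FoodDatabase, FoodRecord
from mhei.equivalents import (
    EquivalentProfile,
    FactorBasis,
    Recipe,
    detect_recipe_discrepancies,
    equivalent_factor,
    food_profile,
    gram_equivalents,
    ingredient_fraction_from_cup_equivalents,
    menu_equivalents,
    nutrient_equivalents,
    processing_factor,
)


def _pair(raw_energy, processed_energy, t="F", g="C", item=1):
    raw = FoodRecord("raw", "raw form", FoodCode(t, g, item, 0), raw_energy)
    proc = FoodRecord("proc", "processed form", FoodCode(t, g, item, 1), processed_energy)
    return raw, proc


class TestProcessingFactor:
    def test_raw_food_factor_one(self):
        raw, _ = _pair(58, 290)
        f = processing_factor(raw, raw)
        assert f.factor == 1.0
        assert f.basis is FactorBasis.RAW_UNITY

    def test_dried_apple_energy_density_quotient(self):
        # drying concentrates energy 290/58 = 5x
        raw, dried = _pair(58, 290)
        f = processing_factor(dried, raw)
        assert f.factor == pytest.approx(5.0)
        assert f.basis is FactorBasis.ENERGY_DENSITY_RATIO

    def test_cooked_legume_is_unity_reference(self):
        cooked = FoodRecord("lentil_c", "lentils, cooked", FoodCode("V", "L", 1, 1), 116)
        uncooked = FoodRecord("lentil_u", "lentils, dry", FoodCode("V", "L", 1, 0), 352)
        assert processing_factor(cooked, uncooked).factor == 1.0
        # uncooked legumes: higher factor from their higher energy density
        f = processing_factor(uncooked, cooked)
        assert f.factor == pytest.approx(352 / 116)
        assert f.factor > 1

    def test_zero_raw_energy_density_undefined(self):
        raw, proc = _pair(0.0, 100)
        with pytest.raises(ZeroDivisionError):
            processing_factor(proc, raw)

    def test_mismatched_items_rejected(self):
        raw, _ = _pair(58, 290, item=1)
        _, other = _pair(58, 290, item=2)
        with pytest.raises(ValueError):
            processing_factor(other, raw)


class TestEquivalentFactorResolution:
    def test_missing_raw_counterpart_falls_back_to_one(self, caplog):
        rec = FoodRecord("orphan", "orphan", FoodCode("G", "R", 9, 1), 350)
        db = FoodDatabase.from_records([rec])
        with caplog.at_level(logging.WARNING, logger="mhei"):
            f = equivalent_factor(rec, db)
        assert f.factor == 1.0
        assert any("orphan" in r.message for r in caplog.records)

    def test_override_used_when_reference_missing(self):
        rec = FoodRecord("orphan", "orphan", FoodCode("G", "R", 9, 1), 350,
                         factor_override=3.4)
        db = FoodDatabase.from_records([rec])
        f = equivalent_factor(rec, db)
        assert f.factor == 3.4
        assert f.basis is FactorBasis.OVERRIDE


class TestGramEquivalents:
    def test_raw_strawberries_factor_one_identity(self, db):
        rec = FoodRecord("straw", "strawberries, raw", FoodCode("F", "C", 50, 0), 32)
        db2 = FoodDatabase.from_records([rec])
        out = gram_equivalents(150, rec, db2)
        assert out == {
            Component.TOTAL_FRUITS: 150,
            Component.WHOLE_FRUITS: 150,
        }

    def test_zero_amount_zero_contribution(self, db):
        for rec in db:
            if rec.code.component_type in "FVG":
                assert all(v == 0 for v in gram_equivalents(0, rec, db).values())
                break

    def test_processed_grain_scaled_by_factor(self):
        raw = FoodRecord("g0", "grain raw", FoodCode("G", "R", 1, 0), 100)
        proc = FoodRecord("g1", "grain processed", FoodCode("G", "R", 1, 1), 340)
        db = FoodDatabase.from_records([raw, proc])
        out = gram_equivalents(100, proc, db)
        assert out[Component.REFINED_GRAINS] == pytest.approx(340.0)

    def test_negative_amount_rejected(self, db):
        rec = next(iter(db))
        with pytest.raises(ValueError):
            gram_equivalents(-1, rec, db)


class TestNutrientEquivalents:
    def test_seafood_protein_credits_both_components(self):
        rec = FoodRecord("fish", "fish", FoodCode("P", "S"), 100, protein_g_per_100g=20)
        out = nutrient_equivalents(100, rec)
        assert out == {
            Component.TOTAL_PROTEIN_FOODS: 20,
            Component.SEAFOOD_PLANT_PROTEINS: 20,
        }

    def test_milk_calcium_scaled_by_amount(self):
        rec = FoodRecord("milk", "milk", FoodCode("D", "M"), 60,
                         calcium_mg_per_100g=120)
        assert nutrient_equivalents(250, rec) == {Component.DAIRY: 300.0}

    def test_zero_protein_food_contributes_nothing(self):
        rec = FoodRecord("gel", "gelatin-ish", FoodCode("P", "M"), 10)
        assert nutrient_equivalents(100, rec) == {Component.TOTAL_PROTEIN_FOODS: 0.0}

    def test_rejects_non_protein_dairy_codes(self):
        rec = FoodRecord("app", "apple", FoodCode("F", "C", 1, 0), 58)
        with pytest.raises(ValueError):
            nutrient_equivalents(100, rec)


class TestCupEquivalentFractions:
    def test_strawberry_yogurt_printed_fraction(self):
        # 0.03 berry cup eq per 100 g of yogurt vs 0.69 for raw strawberry
        frac = ingredient_fraction_from_cup_equivalents(0.03, 0.69)
        assert frac == pytest.approx(0.03 / 0.69)
        assert round(100 * frac, 1) == 4.3  # the 4.3% berry-fruit portion

    def test_zero_menu_gives_zero_fraction(self):
        assert ingredient_fraction_from_cup_equivalents(0.0, 0.69) == 0.0

    def test_identical_values_give_unit_fraction(self):
        assert ingredient_fraction_from_cup_equivalents(0.69, 0.69) == 1.0

    def test_zero_ingredient_undefined(self):
        with pytest.raises(ZeroDivisionError):
            ingredient_fraction_from_cup_equivalents(0.03, 0.0)


class TestMenuEquivalents:
    def test_strawberry_yogurt_berry_equivalents(self):
        strawberry = FoodRecord("straw", "strawberries, raw",
                                FoodCode("F", "C", 50, 0), 32)
        yog_base = FoodRecord("yog", "yogurt base", FoodCode("D", "Y"), 59,
                              calcium_mg_per_100g=110)
        db = FoodDatabase.from_records([strawberry, yog_base])
        frac = ingredient_fraction_from_cup_equivalents(0.03, 0.69)
        recipe = Recipe("strawberry_yogurt", (("straw", frac), ("yog", 1 - frac)))
        profile = menu_equivalents(recipe, db)
        assert round(profile.get(Component.WHOLE_FRUITS), 1) == 4.3
        assert round(profile.get(Component.TOTAL_FRUITS), 1) == 4.3

    def test_single_ingredient_recipe_equals_own_profile(self, db):
        for rec in list(db)[:20]:
            recipe = Recipe(rec.food_id, ((rec.food_id, 1.0),))
            menu = menu_equivalents(recipe, db)
            own = food_profile(rec, db)
            assert menu.components == pytest.approx(own.components)
            assert menu.nutrients == pytest.approx(own.nutrients)

    def test_empty_recipe_all_zero(self, db):
        profile = menu_equivalents(Recipe("nothing", ()), db)
        assert profile.components == {}
        assert all(v == 0 for v in profile.nutrients.values())

    def test_dangling_ingredient_names_menu_and_ingredient(self, db):
        recipe = Recipe("mystery_pie", (("no_such_food", 0.5),))
        with pytest.raises(KeyError, match="mystery_pie.*no_such_food"):
            menu_equivalents(recipe, db)

    def test_overweight_fractions_rejected(self):
        with pytest.raises(ValueError, match="mass fractions"):
            Recipe("m", (("a", 0.7), ("b", 0.7)))


class TestDiscrepancies:
    def _profiles(self):
        # declared table values vs a 50/50 recipe recomputation (cup eq/100 g)
        declared = EquivalentProfile(
            "lettuce_raw",
            {Component.GREENS_AND_BEANS: 0.00, Component.TOTAL_VEGETABLES: 0.91},
        )
        recomputed = EquivalentProfile(
            "lettuce_raw",
            {
                Component.GREENS_AND_BEANS: 0.5 * 1.43,
                Component.TOTAL_VEGETABLES: 0.5 * 0.91 + 0.5 * 1.43,
            },
        )
        return declared, recomputed

    def test_lettuce_recipe_flags_both_components(self):
        declared, recomputed = self._profiles()
        found = detect_recipe_discrepancies(declared, recomputed)
        assert {d.component for d in found} == {
            Component.GREENS_AND_BEANS,
            Component.TOTAL_VEGETABLES,
        }
        dark_green = next(d for d in found if d.component is Component.GREENS_AND_BEANS)
        assert round_half_away(dark_green.recomputed, 2) == 0.72

    def test_identical_profiles_clean(self):
        declared, _ = self._profiles()
        assert detect_recipe_discrepancies(declared, declared) == []

    def test_difference_exactly_at_tol_not_flagged(self):
        a = EquivalentProfile("m", {Component.TOTAL_VEGETABLES: 1.000})
        b = EquivalentProfile("m", {Component.TOTAL_VEGETABLES: 1.005})
        assert detect_recipe_discrepancies(a, b, tol=0.005) == []
        assert len(detect_recipe_discrepancies(a, b, tol=0.00499)) == 1


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------

@settings(deadline=None, max_examples=50, derandomize=True)
@given(a=st.floats(0, 1e4), b=st.floats(0, 1e4))
def test_linearity_of_equivalents(a, b):
    raw = FoodRecord("g0", "grain raw", FoodCode("G", "W", 1, 0), 100)
    proc = FoodRecord("g1", "grain processed", FoodCode("G", "W", 1, 1), 340)
    db = FoodDatabase.from_records([raw, proc])
    for rec in (raw, proc):
        ab = gram_equivalents(a + b, rec, db)
        ga, gb = gram_equivalents(a, rec, db), gram_equivalents(b, rec, db)
        for c in ab:
            assert ab[c] == pytest.approx(ga[c] + gb[c], rel=1e-9, abs=1e-9)


def test_raw_food_identity_and_factor_positivity(db):
    for rec in db:
        code = rec.code
        if code.component_type not in "FVG":
            continue
        f = equivalent_factor(rec, db)
        assert f.factor > 0
        if code.processing_state == 0 and not code.is_legume_vegetable:
            out = gram_equivalents(123.0, rec, db)
            assert all(v == pytest.approx(123.0) for v in out.values())
        # energy densification through processing implies factor > 1
        if (
            f.basis is FactorBasis.ENERGY_DENSITY_RATIO
            and not code.is_legume_vegetable
        ):
            raw = db.raw_counterpart(rec)
            if rec.energy_kcal_per_100g > raw.energy_kcal_per_100g:
                assert f.factor > 1
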