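"""Component densities and 13-component index scoring."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mhei.codes import FoodCode
from mhei.components import ADEQUACY, ALL_COMPONENTS, MODERATION, Component
from mhei.database import FoodDatabase, FoodRecord
from mhei.scoring import (
    ComponentDensities,
    IntakeRecord,
    component_densities,
    percent_of_standard,
    score_adequacy,
    score_fatty_acids,
    score_moderation,
    total_score,
)
from mhei.standards import HEI_2015, MHEI_2015


def _tiny_db():
    return FoodDatabase.from_records(
        [
            FoodRecord("veg", "vegetable", FoodCode("V", "O", 1, 0), 25.0),
            FoodRecord("sugar", "sugar", FoodCode("X"), 400.0,
                       added_sugars_g_per_100g=100.0),
            FoodRecord("fuel", "energy filler", FoodCode("X"), 400.0),
        ]
    )


def _record(items, subject="s1", day=1):
    return IntakeRecord(subject, day, tuple(items))


class TestComponentDensities:
    def test_direct_division_per_1000_kcal(self):
        # 320 g vegetables in a 2000-kcal day -> 160 g eq / 1000 kcal
        db = _tiny_db()
        veg_energy = 320 * 0.25
        fuel = (2000 - veg_energy) / 4.0
        dens = component_densities([_record([("veg", 320), ("fuel", fuel)])], db)
        assert dens.total_energy_kcal == pytest.approx(2000)
        assert dens.get(Component.TOTAL_VEGETABLES) == pytest.approx(160.0)

    def test_added_sugars_percent_of_energy(self):
        # 32.5 g added sugar at 4 kcal/g in 2000 kcal = 6.5 %E
        db = _tiny_db()
        sugar_energy = 32.5 * 4
        fuel = (2000 - sugar_energy) / 4.0
        dens = component_densities([_record([("sugar", 32.5), ("fuel", fuel)])], db)
        assert dens.get(Component.ADDED_SUGARS) == pytest.approx(6.5)

    def test_scale_invariance(self):
        db = _tiny_db()
        items = [("veg", 320), ("sugar", 30), ("fuel", 400)]
        d1 = component_densities([_record(items)], db)
        d2 = component_densities(
            [_record([(f, 2 * g) for f, g in items])], db
        )
        for c in ALL_COMPONENTS:
            v1, v2 = d1.get(c), d2.get(c)
            if math.isnan(v1):
                assert math.isnan(v2)
            else:
                assert v2 == pytest.approx(v1)

    def test_multi_day_records_pooled(self):
        db = _tiny_db()
        one_day = component_densities([_record([("veg", 320), ("fuel", 480)])], db)
        split = component_densities(
            [
                _record([("veg", 120), ("fuel", 300)], day=1),
                _record([("veg", 200), ("fuel", 180)], day=2),
            ],
            db,
        )
        assert split.get(Component.TOTAL_VEGETABLES) == pytest.approx(
            one_day.get(Component.TOTAL_VEGETABLES)
        )

    def test_zero_energy_flag(self):
        db = FoodDatabase.from_records(
            [FoodRecord("water", "water", FoodCode("X"), 0.0)]
        )
        dens = component_densities([_record([("water", 500)])], db)
        assert dens.zero_energy

    def test_unknown_item_raises(self):
        with pytest.raises(KeyError):
            component_densities([_record([("ghost", 10)])], _tiny_db())


class TestComponentScorers:
    def test_adequacy_at_standard_full_points(self):
        assert score_adequacy(141, 141, 5) == 5

    def test_adequacy_zero_intake_zero_points(self):
        assert score_adequacy(0, 141, 5) == 0

    def test_adequacy_linear_halfway(self):
        assert score_adequacy(70.5, 141, 5) == pytest.approx(2.5)

    def test_adequacy_capped_beyond_standard(self):
        assert score_adequacy(500, 141, 5) == 5

    @pytest.mark.parametrize(
        "density, expected", [(32, 10), (76, 0), (54, 5.0), (0, 10), (100, 0)]
    )
    def test_moderation_refined_grains_thresholds(self, density, expected):
        assert score_moderation(density, 32, 76, 10) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "ratio, expected",
        [(2.5, 10), (1.2, 0), (1.85, 5.0), (10, 10), (0.1, 0),
         (math.inf, 10), (math.nan, 0)],
    )
    def test_fatty_acid_ratio_scoring(self, ratio, expected):
        assert score_fatty_acids(ratio) == pytest.approx(expected)


def _densities_at_max(standards):
    values = {}
    for c in ADEQUACY:
        values[c] = standards[c].standard_for_max
    for c in MODERATION:
        values[c] = standards[c].standard_for_max
    return ComponentDensities("s", values, total_energy_kcal=2000)


class TestTotalScore:
    @pytest.mark.parametrize("standards", [MHEI_2015, HEI_2015], ids=lambda s: s.standards_id)
    def test_profile_at_every_standard_scores_100(self, standards):
        score = total_score(_densities_at_max(standards), standards)
        assert score.total == pytest.approx(100.0)

    def test_zero_intake_scores_zero(self):
        dens = ComponentDensities("s", {}, total_energy_kcal=0)
        score = total_score(dens, MHEI_2015)
        assert score.total == 0
        assert all(v == 0 for v in score.component_scores.values())

    def test_failing_one_five_point_component_gives_95(self):
        dens = _densities_at_max(MHEI_2015)
        dens.values[Component.TOTAL_FRUITS] = 0.0
        assert total_score(dens, MHEI_2015).total == pytest.approx(95.0)

    def test_component_scores_within_bounds(self, db, random_cohort):
        from mhei.scoring import intake_records

        intakes, _ = random_cohort
        for records in intake_records(intakes).values():
            score = total_score(component_densities(records, db), MHEI_2015)
            for c in ALL_COMPONENTS:
                assert 0 <= score.component_scores[c] <= MHEI_2015[c].max_points
            assert 0 <= score.total <= 100

    def test_summary_table_lists_all_components(self):
        score = total_score(_densities_at_max(MHEI_2015), MHEI_2015)
        table = score.summary()
        assert len(table) == 14
        assert table.iloc[-1]["score"] == pytest.approx(100.0)


class TestPercentOfStandard:
    def test_max_profile_all_100(self):
        pct = percent_of_standard(_densities_at_max(MHEI_2015), MHEI_2015)
        assert all(v == pytest.approx(100.0) for v in pct.values())

    def test_zero_densities_adequacy_0_moderation_100(self):
        dens = ComponentDensities(
            "s", {c: 0.0 for c in ALL_COMPONENTS}, total_energy_kcal=2000
        )
        pct = percent_of_standard(dens, MHEI_2015)
        for c in ADEQUACY:
            assert pct[c] == 0.0
        for c in MODERATION:
            assert pct[c] == 100.0

    def test_half_standard_adequacy_50_and_overconsumption_capped(self):
        dens = _densities_at_max(MHEI_2015)
        dens.values[Component.TOTAL_FRUITS] = MHEI_2015[
            Component.TOTAL_FRUITS
        ].standard_for_max / 2
        dens.values[Component.WHOLE_FRUITS] = dens.values[Component.TOTAL_FRUITS]
        dens.values[Component.TOTAL_VEGETABLES] *= 10  # overconsumption
        pct = percent_of_standard(dens, MHEI_2015)
        assert pct[Component.TOTAL_FRUITS] == pytest.approx(50.0)
        assert pct[Component.TOTAL_VEGETABLES] == pytest.approx(100.0)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    d1=st.floats(0, 500),
    d2=st.floats(0, 500),
    std=st.floats(1, 400),
)
def test_monotonicity_of_scorers(d1, d2, std):
    lo, hi = sorted((d1, d2))
    assert score_adequacy(lo, std, 5) <= score_adequacy(hi, std, 5)
    assert score_moderation(lo, std, std * 2, 10) >= score_moderation(hi, std, std * 2, 10)


def test_metric_imperial_structural_parity():
    """Same components, same max points; only thresholds and units differ."""
    for c in ALL_COMPONENTS:
        assert MHEI_2015[c].max_points == HEI_2015[c].max_points
    assert sum(MHEI_2015[c].max_points for c in ALL_COMPONENTS) == 100
    assert sum(HEI_2015[c].max_points for c in ALL_COMPONENTS) == 100
    # the nutrient-only components are identical rows
    for c in (Component.FATTY_ACIDS, Component.SODIUM, Component.ADDED_SUGARS,
              Component.SATURATED_FATS):
        assert MHEI_2015[c] == HEI_2015[c]
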