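"""The five operational item-selection criteria and the global rating rule."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ksirt.criteria import (
    NO, SOMEWHAT, YES, WEAK,
    CriteriaThresholds,
    CriterionRating,
    classify_archetype,
    classify_fixture,
    classify_item,
    classify_yes_count,
    criterion1_options_used,
    criterion2_rapid_increase,
    criterion3_region_ordering,
    criterion4_span,
    criterion5_slope,
    criterion_counts,
    modal_locations,
    select_short_form,
)
from ksirt.fixtures import load_criteria_fixture
from ksirt.grm import grm_option_probs, make_archetype
from ksirt.kernel import IccCurve, LatentGrid, OccSet, icc_from_occ
from ksirt.scale import panss

GRID = LatentGrid()
CODES7 = np.arange(1, 8)


def analytic_occ(kind_or_params, shift=0.0):
    item = make_archetype(kind_or_params, 7) if isinstance(kind_or_params, str) else kind_or_params
    if shift:
        from ksirt.grm import GrmItemParams

        item = GrmItemParams(item.a, tuple(np.asarray(item.b) + shift))
    probs = grm_option_probs(GRID.points, item)
    return OccSet("x", GRID, probs, CODES7, 0.2)


def subscale_t(occ):
    return 7 * icc_from_occ(occ).e  # 7 copies of the item as the subscale


class TestCriterion1:
    @pytest.mark.parametrize("emax, count, rating", [(6.2, 6, YES), (4.4, 4, NO)])
    def test_rounding_contract(self, emax, count, rating):
        e = np.linspace(1, emax, GRID.q)
        icc = IccCurve("x", GRID, e, np.zeros(GRID.q))
        assert criterion1_options_used(icc) == (count, rating)


class TestCriterion2:
    def test_ideal_rises_early(self):
        occ = analytic_occ("ideal")
        assert criterion2_rapid_increase(occ, subscale_t(occ)) == YES

    def test_flat_is_no(self):
        occ = analytic_occ("flat")
        assert criterion2_rapid_increase(occ, subscale_t(occ)) == NO

    def test_shifted_thresholds_somewhat(self):
        occ = analytic_occ("ideal", shift=1.5)
        assert criterion2_rapid_increase(occ, subscale_t(occ)) == SOMEWHAT


class TestCriterion3:
    def test_ideal_ordered(self):
        violations, rating = criterion3_region_ordering(analytic_occ("ideal"))
        assert (violations, rating) == (0, YES)

    def test_disordered_has_empty_regions(self):
        violations, rating = criterion3_region_ordering(
            analytic_occ("disordered_regions")
        )
        assert violations >= 1
        assert rating in (SOMEWHAT, NO)

    def test_degenerate_single_option_no(self):
        probs = np.tile(np.eye(7)[3], (GRID.q, 1))
        occ = OccSet("x", GRID, probs, CODES7, 0.2)
        violations, rating = criterion3_region_ordering(occ)
        assert violations == 6
        assert rating == NO

    def test_modal_locations_ordered_for_ideal(self):
        locs = modal_locations(analytic_occ("ideal"))
        assert np.all(np.diff(locs) > 0)


class TestCriterion4:
    def test_ideal_spans(self):
        occ = analytic_occ("ideal")
        displaced, rating = criterion4_span(occ, subscale_t(occ))
        assert (displaced, rating) == (0, YES)

    def test_degenerate_no(self):
        probs = np.tile(np.eye(7)[3], (GRID.q, 1))
        occ = OccSet("x", GRID, probs, CODES7, 0.2)
        displaced, rating = criterion4_span(occ, np.full(GRID.q, 28.0))
        assert displaced == 6
        assert rating == NO

    def test_collapsed_extreme_options_displaced(self):
        # both extreme option pairs are essentially never rated: four empty
        # supports on the observable range
        from ksirt.grm import GrmItemParams

        item = GrmItemParams(1.8, (-9.0, -8.0, -0.5, 0.5, 8.0, 9.0))
        occ = analytic_occ(item)
        ideal = analytic_occ("ideal")
        displaced, rating = criterion4_span(occ, subscale_t(ideal))
        assert displaced >= 4
        assert rating == NO


class TestCriterion5:
    @pytest.mark.parametrize(
        "slope, rating", [(0.510, YES), (0.382, NO), (0.40, YES), (0.399, NO)]
    )
    def test_threshold_inclusive(self, slope, rating):
        assert criterion5_slope(slope) == rating

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            criterion5_slope(float("nan"))


def make_ratings_tuple(r1, r2, r3, r4, r5):
    return (
        CriterionRating(1, r1),
        CriterionRating(2, r2),
        CriterionRating(3, r3),
        CriterionRating(4, r4),
        CriterionRating(5, r5),
    )


class TestGlobalRule:
    def test_paper_style_examples(self):
        good = classify_item(make_ratings_tuple(YES, SOMEWHAT, SOMEWHAT, YES, YES))
        assert (good.yes_count, good.rating) == (3, "Good")
        vg = classify_item(make_ratings_tuple(YES, YES, YES, YES, NO))
        assert (vg.yes_count, vg.rating) == (4, "Very Good")
        weak = classify_item(make_ratings_tuple(NO, NO, NO, NO, NO))
        assert weak.rating == WEAK and not weak.retained

    def test_somewhat_forbidden_where_binary(self):
        with pytest.raises(ValueError, match="never takes Somewhat"):
            CriterionRating(1, SOMEWHAT)

    def test_monotone_in_single_criterion_upgrades(self):
        """Improving one rating (No -> Somewhat -> Yes) never lowers the
        global class."""
        order = {WEAK: 0, "Good": 1, "Very Good": 2}
        levels = (NO, SOMEWHAT, YES)
        for combo in itertools.product(levels, repeat=5):
            base = sum(r == YES for r in combo)
            for i in range(5):
                for better in levels[levels.index(combo[i]) + 1:]:
                    upgraded = combo[:i] + (better,) + combo[i + 1:]
                    up = sum(r == YES for r in upgraded)
                    assert (
                        order[classify_yes_count(up)]
                        >= order[classify_yes_count(base)]
                    )


class TestFixtureClassification:
    def test_rule_reproduces_all_30_printed_ratings(self):
        table = classify_fixture(load_criteria_fixture())
        assert (table["derived_rating"] == table["rating"]).all()

    def test_retention_19_items_6_6_7(self):
        scale = panss()
        table = classify_fixture(load_criteria_fixture())
        short = select_short_form(table, scale)
        assert short.n_items == 19
        assert {s: len(v) for s, v in short.subscales.items()} == {
            "Positive": 6, "Negative": 6, "General": 7
        }
        assert "P7" not in short.items and "N5" not in short.items

    def test_seventeen_very_good_two_good(self):
        table = classify_fixture(load_criteria_fixture())
        counts = table["derived_rating"].value_counts()
        assert counts["Very Good"] == 17
        assert counts["Good"] == 2
        assert counts["Weak"] == 11

    def test_general_subscale_tallies(self):
        scale = panss()
        table = classify_fixture(load_criteria_fixture())
        assert criterion_counts(table, scale, "General", 2) == (7, 43.75)
        assert criterion_counts(table, scale, "General", 3) == (6, 37.50)
        assert criterion_counts(table, scale, "General", 4) == (9, 56.25)

    def test_nine_general_slopes_below_cut(self):
        fx = load_criteria_fixture()
        general = fx[fx["subscale"] == "General"]
        assert int((general["slope"] < 0.399).sum()) == 9

    def test_empty_subscale_errors(self):
        table = classify_fixture(load_criteria_fixture())
        with pytest.raises(ValueError):
            criterion_counts(table.iloc[0:0], panss(), "General", 2)


class TestSelectShortForm:
    def test_identity_when_all_retained(self, panss_scale):
        table = pd.DataFrame(
            {"item": panss_scale.items, "rating": "Very Good"}
        ).set_index("item", drop=False)
        assert select_short_form(table, panss_scale) == panss_scale

    def test_subset_preserves_partition(self, panss_scale):
        table = classify_fixture(load_criteria_fixture())
        short = select_short_form(table, panss_scale)
        for sub, its in short.subscales.items():
            assert set(its) <= set(panss_scale.subscales[sub])
            assert list(its) == [i for i in panss_scale.subscales[sub] if i in its]


class TestArchetypeClassification:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_ideal_very_good_flat_weak(self, seed):
        assert classify_archetype("ideal", n=3000, seed=seed)["rating"] == "Very Good"
        assert classify_archetype("flat", n=3000, seed=seed)["rating"] == WEAK
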