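"""Survey loading, pooling, relative covers and specialist classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fragweb import community
from fragweb.community import (
    DietEntry,
    TransectSurvey,
    assign_codes,
    classify,
    diet_from_frame,
    fragment_community,
    pool_abundances,
    relative_cover,
    surveys_from_frames,
)
from fragweb.errors import (
    CrossReferenceError,
    DegenerateTransectError,
    SchemaError,
    ValidationError,
)


def _covers_frame(rows):
    return pd.DataFrame(rows, columns=["fragment_id", "transect_id", "taxon", "cover_pct"])


def _counts_frame(rows):
    return pd.DataFrame(rows, columns=["fragment_id", "transect_id", "occasion", "taxon", "count"])


class TestLoadSurveys:
    def test_minimal_single_transect(self):
        covers = _covers_frame([("A", "1", "Bromus erecta", 30.0)])
        counts = _counts_frame([("A", "1", 1, "Adarrus multinotatus", 3)])
        surveys = surveys_from_frames(covers, counts)
        assert len(surveys) == 1
        s = surveys[0]
        assert s.plant_cover == {"Bromus erecta": 30.0}
        assert s.leafhopper_counts == {1: {"Adarrus multinotatus": 3}}

    def test_cover_out_of_bounds_names_row(self):
        covers = _covers_frame(
            [("A", "1", "Bromus erecta", 30.0), ("A", "1", "Carex flacca", 105.0)]
        )
        counts = _counts_frame([("A", "1", 1, "X y", 1)])
        with pytest.raises(ValidationError) as exc:
            surveys_from_frames(covers, counts)
        assert "row 1" in str(exc.value)
        assert "105" in str(exc.value)

    def test_missing_column_is_schema_error(self):
        covers = _covers_frame([("A", "1", "Bromus erecta", 30.0)]).drop(columns=["cover_pct"])
        with pytest.raises(SchemaError):
            surveys_from_frames(covers, _counts_frame([]))

    def test_unknown_fragment_in_counts(self):
        covers = _covers_frame([("A", "1", "Bromus erecta", 30.0)])
        counts = _counts_frame([("B", "1", 1, "X y", 1)])
        with pytest.raises(CrossReferenceError):
            surveys_from_frames(covers, counts)

    def test_fixture_yields_one_survey_per_transect(self, tiny_surveys):
        # 3 fragments x 6 transects
        assert len(tiny_surveys) == 18
        assert {s.fragment_id for s in tiny_surveys} == {"F1", "F2", "F3"}

    def test_bare_ground_and_litter_are_split_out(self):
        covers = _covers_frame(
            [
                ("A", "1", "Bromus erecta", 30.0),
                ("A", "1", community.BARE_GROUND, 5.0),
                ("A", "1", community.LITTER, 7.0),
            ]
        )
        (s,) = surveys_from_frames(covers, _counts_frame([("A", "1", 1, "X y", 1)]))
        assert s.bare_ground == 5.0 and s.litter == 7.0
        assert community.BARE_GROUND not in s.plant_cover


class TestPooling:
    def test_single_record_identity(self):
        s = TransectSurvey("A", "1", {}, leafhopper_counts={1: {"A b": 3}})
        assert pool_abundances([s]) == {"A b": 3}

    def test_zero_total_species_omitted(self):
        s = TransectSurvey("A", "1", {}, leafhopper_counts={1: {"A b": 0, "C d": 2}})
        assert pool_abundances([s]) == {"C d": 2}

    def test_mixed_fragments_rejected(self):
        surveys = [
            TransectSurvey("A", "1", {}, leafhopper_counts={1: {"A b": 1}}),
            TransectSurvey("B", "1", {}, leafhopper_counts={1: {"A b": 1}}),
        ]
        with pytest.raises(ValueError):
            pool_abundances(surveys)

    def test_random_grid_matches_bruteforce_sum(self):
        rng = np.random.default_rng(42)
        grid = rng.integers(0, 9, size=(6, 3, 4))  # transect x occasion x species
        species = [f"sp{k}" for k in range(4)]
        surveys = [
            TransectSurvey(
                "A", str(t + 1), {},
                leafhopper_counts={
                    o + 1: {species[k]: int(grid[t, o, k]) for k in range(4)}
                    for o in range(3)
                },
            )
            for t in range(6)
        ]
        expected = {
            species[k]: int(grid[:, :, k].sum())
            for k in range(4)
            if grid[:, :, k].sum() > 0
        }
        assert pool_abundances(surveys) == expected

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.permutations(list(range(6))))
    def test_pooling_is_order_independent(self, order):
        rng = np.random.default_rng(1)
        surveys = [
            TransectSurvey(
                "A", str(t), {},
                leafhopper_counts={1: {"A b": int(rng.integers(0, 5))}},
            )
            for t in range(6)
        ]
        assert pool_abundances(surveys) == pool_abundances([surveys[i] for i in order])


class TestRelativeCover:
    def test_direct_arithmetic(self):
        s = TransectSurvey("A", "1", {"x": 10.0, "y": 30.0}, bare_ground=5.0, litter=5.0)
        rc = relative_cover(s)
        assert rc["x"] == pytest.approx(10.0 / 50.0)

    def test_zero_cover_species_is_zero(self):
        s = TransectSurvey("A", "1", {"x": 0.0, "y": 30.0}, bare_ground=5.0, litter=5.0)
        assert relative_cover(s)["x"] == 0.0

    def test_zero_denominator_is_degenerate(self):
        with pytest.raises(DegenerateTransectError):
            relative_cover(TransectSurvey("A", "1", {}))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_fractions_plus_bare_and_litter_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        covers = {f"sp{k}": float(rng.uniform(0, 60)) for k in range(int(rng.integers(1, 8)))}
        s = TransectSurvey(
            "A", "1", covers,
            bare_ground=float(rng.uniform(0.1, 20)), litter=float(rng.uniform(0.1, 20)),
        )
        rc = relative_cover(s)
        denom = sum(covers.values()) + s.bare_ground + s.litter
        for taxon, value in rc.items():
            assert value == pytest.approx(covers[taxon] / denom, abs=1e-12)
        assert sum(rc.values()) + (s.bare_ground + s.litter) / denom == pytest.approx(1.0, abs=1e-12)


class TestFragmentCommunity:
    def test_mean_of_ratios_over_transects(self):
        s1 = TransectSurvey("A", "1", {"x": 10.0, "y": 30.0}, bare_ground=5.0, litter=5.0)
        s2 = TransectSurvey("A", "2", {"y": 50.0})  # x absent -> contributes 0
        fc = fragment_community([s1, s2])
        assert fc.mean_relative_cover["x"] == pytest.approx((0.2 + 0.0) / 2)

    def test_identical_transects_equal_single(self):
        s = TransectSurvey("A", "1", {"x": 10.0, "y": 30.0}, bare_ground=5.0, litter=5.0)
        twins = [TransectSurvey("A", str(t), dict(s.plant_cover), 5.0, 5.0) for t in range(1, 4)]
        fc = fragment_community(twins)
        rc = relative_cover(s)
        for taxon in rc:
            assert fc.mean_relative_cover[taxon] == pytest.approx(rc[taxon])

    def test_matches_explicit_loop_oracle(self, tiny_surveys):
        group = [s for s in tiny_surveys if s.fragment_id == "F1"]
        fc = fragment_community(group)
        taxa = {t for s in group for t in s.plant_cover}
        for taxon in taxa:
            acc = 0.0
            for s in group:
                denom = sum(s.plant_cover.values()) + s.bare_ground + s.litter
                acc += s.plant_cover.get(taxon, 0.0) / denom
            assert fc.mean_relative_cover[taxon] == pytest.approx(acc / len(group), abs=1e-12)
        assert fc.plant_richness == len(taxa)

    def test_all_degenerate_is_error(self):
        with pytest.raises(DegenerateTransectError):
            fragment_community([TransectSurvey("A", "1", {}), TransectSurvey("A", "2", {})])


class TestClassification:
    @pytest.mark.parametrize(
        "habitat,diet,expected",
        [
            (True, False, "specialist"),
            (False, True, "specialist"),
            (True, True, "specialist"),
            (False, False, "generalist"),
        ],
    )
    def test_specialist_iff_either_condition(self, habitat, diet, expected):
        entry = DietEntry("X y", habitat_condition=habitat, diet_condition=diet)
        assert classify(entry) == expected

    def test_every_entry_gets_exactly_one_label(self, tiny_diet):
        for entry in tiny_diet:
            assert classify(entry) in ("specialist", "generalist")


class TestDietTable:
    def test_diet_known_iff_food_listed(self, tiny_diet):
        for entry in tiny_diet:
            assert entry.diet_known == (len(entry.food_taxa) > 0)

    def test_monophagous_implies_single_food_taxon(self, tiny_diet):
        for entry in tiny_diet:
            if entry.monophagous:
                assert len(entry.food_taxa) == 1

    def test_inconsistent_monophagy_rejected(self):
        df = pd.DataFrame(
            [
                {"taxon": "A b", "food_taxon": "X y", "food_rank": "species",
                 "monophagous": True, "habitat_condition": False,
                 "diet_condition": False, "identified_to_species": True},
                {"taxon": "A b", "food_taxon": "Z w", "food_rank": "species",
                 "monophagous": True, "habitat_condition": False,
                 "diet_condition": False, "identified_to_species": True},
            ]
        )
        with pytest.raises(ValidationError):
            diet_from_frame(df)


class TestSpeciesCodes:
    def test_two_plus_two_letters(self):
        assert community.species_code("Bromus erecta") == "Brer"

    def test_collisions_get_digit_suffix(self):
        codes = assign_codes(["Bromus erecta", "Briza erecta", "Bromus erinaceus"])
        assert codes["Bromus erecta"] == "Brer"
        assert sorted(codes.values()) == ["Brer", "Brer1", "Brer2"]
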