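import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cescore.model_config import (
    Category,
    CountryProfile,
    InvalidInputError,
    Polarity,
    default_model,
    exposure_proportion,
)
from cescore.scoring_engine import (
    compute_severity,
    rank_countries,
    score_component,
    score_country,
    score_value,
    TierAssignment,
)
from cescore.threshold_derivation import TierThresholds


def thr(lower, upper, polarity=Polarity.HIGHER_IS_WORSE, name="x"):
    return TierThresholds(
        indicator=name,
        lower_cut=lower,
        upper_cut=upper,
        polarity=polarity,
        reference_n=50,
    )


class TestScoreValue:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (5.0, "Low-Moderate"),
            (10.0, "Low-Moderate"),  # exactly at lower cut -> less severe
            (15.0, "High"),
            (20.0, "High"),  # exactly at upper cut -> less severe
            (25.0, "Critical"),
        ],
    )
    def test_higher_is_worse_bands(self, value, expected):
        assert score_value(value, thr(10, 20)).label == expected

    @pytest.mark.parametrize(
        "value,expected",
        [
            (25.0, "Low-Moderate"),
            (20.0, "Low-Moderate"),  # at upper cut -> less severe
            (15.0, "High"),
            (10.0, "High"),  # at lower cut -> less severe
            (5.0, "Critical"),  # very low GNI is worst
        ],
    )
    def test_higher_is_better_mirrors(self, value, expected):
        t = thr(10, 20, Polarity.HIGHER_IS_BETTER)
        assert score_value(value, t).label == expected

    def test_numeric_values_follow_labels(self):
        assert score_value(25.0, thr(10, 20)) == TierAssignment("Critical", 3)

    @pytest.mark.parametrize("bad", [float("nan"), float("inf"), None])
    def test_non_finite_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            score_value(bad, thr(10, 20))


def make_thresholds(model):
    """Simple hand-set thresholds for every scored value."""
    out = {}
    for sv in model.all_scored_values():
        if sv.name.endswith("_prop"):
            out[sv.name] = thr(0.1, 0.3, sv.polarity, sv.name)
        elif sv.name in ("affected", "uprooted"):
            out[sv.name] = thr(1e4, 1e5, sv.polarity, sv.name)
        elif sv.name == "gni_per_capita":
            out[sv.name] = thr(800, 2000, sv.polarity, sv.name)
        elif sv.name == "adult_literacy":
            out[sv.name] = thr(40, 70, sv.polarity, sv.name)
        else:
            out[sv.name] = thr(10, 30, sv.polarity, sv.name)
    return out


@pytest.fixture(scope="module")
def hand_thresholds():
    return make_thresholds(default_model())


def profile_all_critical():
    return CountryProfile(
        country="worst",
        values={
            "gni_per_capita": 400,  # below lower cut, higher_is_better
            "u5mr": 200,
            "adult_literacy": 20,
            "underweight": 40,
        },
        population=1_000_000,
        affected=900_000,  # prop 0.9
        uprooted=800_000,
    )


def profile_all_low():
    return CountryProfile(
        country="best",
        values={
            "gni_per_capita": 5000,
            "u5mr": 5,
            "adult_literacy": 90,
            "underweight": 5,
        },
        population=10_000_000,
        affected=5_000,  # prop 5e-4
        uprooted=1_000,
    )


class TestScoreComponent:
    def test_all_critical_scores_twelve(self, model, hand_thresholds):
        for cat in Category:
            c = score_component(profile_all_critical(), cat, model, hand_thresholds)
            assert c.score == 12
            assert c.n_missing == 0

    def test_all_low_scores_four(self, model, hand_thresholds):
        for cat in Category:
            c = score_component(profile_all_low(), cat, model, hand_thresholds)
            assert c.score == 4

    def test_mixed_tiers_sum(self, model, hand_thresholds):
        p = CountryProfile(
            country="mid",
            values={
                "gni_per_capita": 5000,  # Low-Moderate (1)
                "u5mr": 20,  # High (2)
                "adult_literacy": 20,  # Critical (3)
                "underweight": 40,  # Critical (3)
            },
        )
        c = score_component(p, Category.VULNERABILITY, model, hand_thresholds)
        assert c.score == 9  # 1 + 2 + 3 + 3

    def test_matches_brute_force_recomputation(
        self, model, thresholds, scored_countries
    ):
        for p in scored_countries:
            for cat in Category:
                c = score_component(p, cat, model, thresholds)
                # independent path: score each value alone and sum
                total = 0
                for sv in model.scored_values(cat):
                    if sv.category is Category.VULNERABILITY:
                        raw = p.values.get(sv.name)
                    elif sv.name.endswith("_prop"):
                        raw = exposure_proportion(
                            getattr(p, sv.source), p.population
                        )
                    else:
                        raw = getattr(p, sv.source)
                    if raw is not None:
                        total += score_value(raw, thresholds[sv.name]).value
                assert c.score == total

    def test_missing_excluded_and_flagged(self, model, hand_thresholds):
        p = profile_all_critical()
        del p.values["u5mr"]
        c = score_component(p, Category.VULNERABILITY, model, hand_thresholds)
        assert c.score == 9
        assert c.n_missing == 1
        assert any("u5mr" in (vs.flag or "") for vs in c.value_scores)

    def test_missing_policy_critical_scores_worst_case(self, model, hand_thresholds):
        p = profile_all_critical()
        del p.values["u5mr"]
        c = score_component(
            p, Category.VULNERABILITY, model, hand_thresholds,
            missing_policy="critical",
        )
        assert c.score == 12
        assert c.n_missing == 1

    def test_missing_population_blocks_proportions_only(self, model, hand_thresholds):
        p = CountryProfile(
            country="nopop", affected=2_000_000, uprooted=1_500_000
        )
        c = score_component(p, Category.EXPOSURE, model, hand_thresholds)
        assert c.n_missing == 2  # the two proportion values
        assert c.score == 6  # absolute counts both Critical


class TestComputeSeverity:
    def test_sum_and_product_combiners(self, model, hand_thresholds):
        v = score_component(
            profile_all_critical(), Category.VULNERABILITY, model, hand_thresholds
        )
        e = score_component(
            profile_all_critical(), Category.EXPOSURE, model, hand_thresholds
        )
        assert compute_severity("w", v, e, "sum").severity == 24
        assert compute_severity("w", v, e, "product").severity == 144
        low_v = score_component(
            profile_all_low(), Category.VULNERABILITY, model, hand_thresholds
        )
        low_e = score_component(
            profile_all_low(), Category.EXPOSURE, model, hand_thresholds
        )
        assert compute_severity("b", low_v, low_e, "sum").severity == 8
        assert compute_severity("b", low_v, low_e, "product").severity == 16

    def test_bounds_on_complete_profiles(self, model, thresholds, scored_countries):
        for p in scored_countries:
            s = score_country(p, model, thresholds, combiner="sum")
            assert 8 <= s.severity <= 24
            s = score_country(p, model, thresholds, combiner="product")
            assert 16 <= s.severity <= 144

    def test_fully_missing_component_unsets_severity(self, model, hand_thresholds):
        p = CountryProfile(country="ghost", values=profile_all_low().values)
        r = score_country(p, model, hand_thresholds)
        assert r.severity is None
        assert not r.complete
        assert any("fully missing" in f for f in r.flags)

    def test_unknown_combiner_rejected(self, model, hand_thresholds):
        v = score_component(
            profile_all_low(), Category.VULNERABILITY, model, hand_thresholds
        )
        e = score_component(
            profile_all_low(), Category.EXPOSURE, model, hand_thresholds
        )
        with pytest.raises(InvalidInputError):
            compute_severity("x", v, e, "mean")


class TestRankCountries:
    def test_descending_by_severity(self, model, hand_thresholds):
        worst = score_country(profile_all_critical(), model, hand_thresholds)
        best = score_country(profile_all_low(), model, hand_thresholds)
        ranked = rank_countries([best, worst])
        assert [r.country for r in ranked] == ["worst", "best"]

    def test_tie_breaks_by_exposure_then_vulnerability_then_name(
        self, model, hand_thresholds
    ):
        # same severity 16, different split between components
        high_expo = profile_all_critical()
        high_expo.country = "expoheavy"
        high_expo.values = {
            "gni_per_capita": 5000, "u5mr": 5,
            "adult_literacy": 90, "underweight": 5,
        }  # v=4, e=12
        high_vuln = profile_all_critical()
        high_vuln.country = "vulnheavy"
        high_vuln.population = 10_000_000
        high_vuln.affected = 5_000
        high_vuln.uprooted = 1_000  # v=12, e=4
        r1 = score_country(high_expo, model, hand_thresholds)
        r2 = score_country(high_vuln, model, hand_thresholds)
        assert r1.severity == r2.severity == 16
        ranked = rank_countries([r2, r1])
        assert [r.country for r in ranked] == ["expoheavy", "vulnheavy"]

    def test_incomplete_results_rank_last(self, model, hand_thresholds):
        ghost = CountryProfile(
            country="ghost",
            population=1_000_000, affected=900_000, uprooted=800_000,
        )  # vulnerability fully missing but exposure maximal
        r_ghost = score_country(ghost, model, hand_thresholds)
        r_best = score_country(profile_all_low(), model, hand_thresholds)
        ranked = rank_countries([r_ghost, r_best])
        assert ranked[-1].country == "ghost"

    def test_invariant_to_input_order(self, model, thresholds, scored_countries):
        results = [score_country(p, model, thresholds) for p in scored_countries]
        a = rank_countries(results)
        b = rank_countries(results[::-1])
        assert [r.country for r in a] == [r.country for r in b]

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            rank_countries([])


# --- monotonicity property ----------------------------------------------

_MODEL = default_model()


@st.composite
def profile_and_thresholds(draw):
    rng_seed = draw(st.integers(0, 2**31 - 1))
    rng = np.random.default_rng(rng_seed)
    thresholds = {}
    for sv in _MODEL.all_scored_values():
        if sv.name.endswith("_prop"):
            cuts = np.sort(rng.uniform(0.0, 1.0, 2))
        elif sv.name in ("affected", "uprooted"):
            cuts = np.sort(rng.uniform(0, 5e6, 2))
        else:
            cuts = np.sort(rng.uniform(0, 100, 2))
        thresholds[sv.name] = thr(cuts[0], cuts[1], sv.polarity, sv.name)
    population = float(rng.integers(1_000_000, 50_000_000))
    affected = float(rng.integers(0, int(population)))
    uprooted = float(rng.integers(0, int(affected) + 1))
    profile = CountryProfile(
        country="P",
        values={
            i.name: float(rng.uniform(0, 100))
            for i in _MODEL.vulnerability_indicators
        },
        population=population,
        affected=affected,
        uprooted=uprooted,
    )
    return profile, thresholds


@settings(max_examples=300, derandomize=True, deadline=None)
@given(
    case=profile_and_thresholds(),
    target=st.sampled_from(
        ["gni_per_capita", "u5mr", "adult_literacy", "underweight",
         "affected", "uprooted"]
    ),
    step=st.floats(0.01, 0.5),
)
def test_worsening_one_indicator_never_decreases_severity(case, target, step):
    """Pushing any single indicator in its severe direction can only raise
    (or preserve) the combined severity."""
    profile, thresholds = case
    before = score_country(profile, _MODEL, thresholds, combiner="sum")
    worse = dataclasses.replace(profile)
    polarity = {i.name: i.polarity for i in _MODEL.indicators}[target]
    if target in ("affected", "uprooted"):
        room = profile.population - getattr(profile, target)
        setattr(worse, target, getattr(profile, target) + step * room)
        if target == "affected" and worse.affected < worse.uprooted:
            worse.uprooted = worse.affected
    elif polarity is Polarity.HIGHER_IS_WORSE:
        worse.values = {**profile.values, target: profile.values[target] * (1 + step)}
    else:
        worse.values = {**profile.values, target: profile.values[target] * (1 - step)}
    after = score_country(worse, _MODEL, thresholds, combiner="sum")
    assert after.severity >= before.severity
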