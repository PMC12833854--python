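import math

import pytest

from tgrkit.growth import fit_exponential
from tgrkit.model import InsufficientDataError, Study
from tgrkit.qc import (
    CONSERVATIVE,
    MODERATE,
    ULTRA_CONSERVATIVE,
    Criterion,
    HomogeneityConfig,
    Severity,
    apply_filter,
    assess_homogeneity,
    baseline_cv,
    detect_outliers,
    exclusion_recommendations,
    homogeneity_base_score,
    sample_size_factor,
    select_sensitivity,
)

from conftest import exponential_series, make_series


class TestBaselineCv:
    def test_equal_baselines_zero_cv(self):
        group = [make_series(f"m{i}", "g", [0, 1, 2], [100, 120, 150]) for i in range(4)]
        cv, n = baseline_cv(group)
        assert cv == 0.0
        assert n == 4

    def test_two_baselines(self):
        group = [
            make_series("m1", "g", [0, 1, 2], [100, 1, 1]),
            make_series("m2", "g", [0, 1, 2], [200, 1, 1]),
        ]
        cv, n = baseline_cv(group)
        assert cv == pytest.approx(100 * math.sqrt(5000) / 150, rel=1e-12)  # 47.14
        assert n == 2

    def test_nonpositive_baseline_excluded(self):
        group = [
            make_series("m1", "g", [0, 1, 2], [-1, 2, 3]),  # first POSITIVE is 2
            make_series("m2", "g", [0, 1, 2], [100, 1, 1]),
            make_series("m3", "g", [0, 1, 2], [100, 1, 1]),
        ]
        cv, n = baseline_cv(group[1:])
        assert (cv, n) == (0.0, 2)
        # an animal whose values are all nonpositive contributes nothing
        allneg = make_series("m4", "g", [0, 1], [-1, -2])
        cv, n = baseline_cv([allneg, group[1], group[2]])
        assert n == 2

    def test_no_positive_baselines(self):
        with pytest.raises(InsufficientDataError):
            baseline_cv([make_series("m1", "g", [0, 1], [-1, 0])])

    def test_empty_group(self):
        with pytest.raises(InsufficientDataError):
            baseline_cv([])


class TestHomogeneityScore:
    @pytest.mark.parametrize("cv,expected", [(0, 100), (10, 100), (15, 100),
                                             (20, 90), (30, 80), (80, 0), (35, 90)])
    def test_base_score_piecewise(self, cv, expected):
        assert homogeneity_base_score(cv) == expected

    def test_documented_discontinuity_at_pi(self):
        # verbatim formula: 80 at CV=30 but ~100 just above
        assert homogeneity_base_score(30.0) == 80.0
        assert homogeneity_base_score(30.0 + 1e-9) == pytest.approx(100.0)

    @pytest.mark.parametrize("n,expected", [(10, 1.0), (5, 1.0), (4, 0.9),
                                            (3, 0.9), (2, 0.72), (1, 0.72)])
    def test_sample_size_factor(self, n, expected):
        assert sample_size_factor(n) == pytest.approx(expected)

    def test_composition(self):
        group = [
            make_series("m1", "g", [0, 1], [100, 1]),
            make_series("m2", "g", [0, 1], [100, 1]),
            make_series("m3", "g", [0, 1], [100, 1]),
            make_series("m4", "g", [0, 1], [100, 1]),
        ]
        rep = assess_homogeneity(group, stage="pre_filter")
        assert rep.cv == 0
        assert rep.base_score == 100
        assert rep.factor == 0.9
        assert rep.score == 90
        assert rep.stage == "pre_filter"

    def test_config_validation(self):
        with pytest.raises(ValueError):
            HomogeneityConfig(epsilon=40, pi=30)


class TestSensitivitySelection:
    @pytest.mark.parametrize(
        "n,profile", [(4, ULTRA_CONSERVATIVE), (5, CONSERVATIVE),
                      (8, CONSERVATIVE), (10, CONSERVATIVE), (12, MODERATE)]
    )
    def test_detector_tiers(self, n, profile):
        assert select_sensitivity(n) is profile

    def test_multipliers(self):
        assert ULTRA_CONSERVATIVE.iqr_multiplier == 4.0
        assert CONSERVATIVE.iqr_multiplier == 3.0
        assert MODERATE.iqr_multiplier == 2.0

    @pytest.mark.parametrize(
        "n,profile", [(7, ULTRA_CONSERVATIVE), (8, CONSERVATIVE),
                      (12, CONSERVATIVE), (13, MODERATE)]
    )
    def test_coarse_preset(self, n, profile):
        assert select_sensitivity(n, preset="coarse") is profile


def _cohort(n=12, r=0.2, n0=100, days=(0, 1, 2, 3, 4, 5)):
    return Study(animals=[
        exponential_series(f"m{i}", "g", list(days), n0 * (1 + 0.05 * i), r)
        for i in range(n)
    ])


class TestDetector:
    def test_clean_cohort_no_flags(self):
        assert detect_outliers(_cohort()) == []

    def test_impossible_value(self):
        study = _cohort(n=4)
        study.animals[0].measurements[2].value = -1.0
        flags = detect_outliers(study)
        imp = [f for f in flags if f.criterion is Criterion.IMPOSSIBLE_VALUE]
        assert len(imp) == 1
        assert imp[0].severity is Severity.critical
        assert imp[0].animal_id == "m0"
        assert imp[0].day == 2

    def test_extreme_growth_moderate_tier(self):
        study = _cohort(n=12)  # moderate: limit 1000 %/day
        a = study.animals[0]
        a.measurements[3].value = a.measurements[2].value * 22  # 2100 %/day
        flags = detect_outliers(study)
        assert any(
            f.criterion is Criterion.EXTREME_GROWTH and f.animal_id == "m0"
            and f.day == 3 for f in flags
        )

    def test_extreme_growth_below_small_sample_limit_not_flagged(self):
        study = _cohort(n=4)  # ultra-conservative: limit 5000 %/day
        a = study.animals[0]
        a.measurements[3].value = a.measurements[2].value * 22
        flags = detect_outliers(study)
        assert not any(f.criterion is Criterion.EXTREME_GROWTH for f in flags)

    def test_extreme_decline(self):
        study = _cohort(n=12)  # decline limit 67 %/day
        a = study.animals[0]
        a.measurements[3].value = a.measurements[2].value * 0.2  # 80 %/day drop
        flags = detect_outliers(study)
        assert any(f.criterion is Criterion.EXTREME_DECLINE and f.day == 3
                   for f in flags)

    def test_intra_animal_spike(self):
        study = _cohort(n=12, days=tuple(range(10)))
        a = study.animals[5]
        a.measurements[4].value *= 10  # log residual ~ ln 10
        flags = detect_outliers(study)
        assert any(
            f.criterion is Criterion.INTRA_OUTLIER and f.animal_id == "m5"
            and f.day == 4 for f in flags
        )

    def test_group_outlier(self):
        study = _cohort(n=12)
        # same shape but hugely shifted baseline → off the group fence at each day
        study.animals[0].measurements[0].value *= 1e5
        flags = detect_outliers(study)
        assert any(
            f.criterion is Criterion.GROUP_OUTLIER and f.animal_id == "m0"
            and f.day == 0 for f in flags
        )

    def test_last_day_drop(self):
        study = _cohort(n=12)
        a = study.animals[0]
        a.measurements[-1].value = a.measurements[-2].value * 0.4  # 60 %/day
        flags = detect_outliers(study)
        assert any(f.criterion is Criterion.LAST_DAY_DROP and f.animal_id == "m0"
                   for f in flags)

    def test_last_day_drop_guard_prior_decline(self):
        study = _cohort(n=12)
        a = study.animals[0]
        a.measurements[2].value = a.measurements[1].value * 0.9  # earlier decline
        a.measurements[-1].value = a.measurements[-2].value * 0.4
        flags = detect_outliers(study)
        assert not any(f.criterion is Criterion.LAST_DAY_DROP for f in flags)

    def test_scale_invariance(self):
        study = _cohort(n=12, days=tuple(range(8)))
        study.animals[3].measurements[4].value *= 10
        flags1 = detect_outliers(study)
        scaled = study.copy()
        for a in scaled.animals:
            for m in a.measurements:
                m.value *= 7.3e4
        flags2 = detect_outliers(scaled)
        assert {(f.animal_id, f.day, f.criterion) for f in flags1} == {
            (f.animal_id, f.day, f.criterion) for f in flags2
        }

    def test_idempotent_on_filtered_study(self):
        study = _cohort(n=12, days=tuple(range(8)))
        study.animals[3].measurements[4].value *= 10
        flags = detect_outliers(study)
        filtered = apply_filter(study, flags, "point_level")
        reflags = detect_outliers(filtered)
        keys = {(f.animal_id, f.day, f.criterion) for f in flags}
        assert {(f.animal_id, f.day, f.criterion) for f in reflags} <= keys


class TestExclusionRecommendations:
    def test_multiple_indicators_required_for_small_samples(self):
        from tgrkit.qc import OutlierFlag

        group_of = {"m1": "g", "m2": "g"}
        profiles = {"g": ULTRA_CONSERVATIVE}
        one_medium = [OutlierFlag("m1", Criterion.GROUP_OUTLIER, Severity.medium, 2.0)]
        assert exclusion_recommendations(one_medium, profiles, group_of) == []
        one_critical = [OutlierFlag("m1", Criterion.IMPOSSIBLE_VALUE,
                                    Severity.critical, 2.0)]
        assert exclusion_recommendations(one_critical, profiles, group_of) == ["m1"]
        two_criteria = one_medium + [
            OutlierFlag("m1", Criterion.INTRA_OUTLIER, Severity.high, 3.0)]
        assert exclusion_recommendations(two_criteria, profiles, group_of) == ["m1"]
        # moderate profile: any flag suffices
        assert exclusion_recommendations(one_medium, {"g": MODERATE}, group_of) == ["m1"]


class TestApplyFilter:
    def test_complete_mode_identity(self):
        study = _cohort(n=5)
        study.animals[0].measurements[1].value = -1
        flags = detect_outliers(study)
        out = apply_filter(study, flags, "complete")
        assert [a.animal_id for a in out.animals] == [a.animal_id for a in study.animals]
        assert not any(m.excluded for a in out.animals for m in a.measurements)

    def test_point_level_keeps_animal_with_enough_points(self):
        study = _cohort(n=12, days=(0, 1, 2, 3, 4))
        study.animals[0].measurements[2].value = -1
        flags = detect_outliers(study)
        out = apply_filter(study, flags, "point_level")
        kept = next(a for a in out.animals if a.animal_id == "m0")
        assert len(kept.usable_measurements()) == 4

    def test_point_level_drops_animal_below_three_points(self):
        study = _cohort(n=12, days=(0, 1, 2, 3, 4))
        for i in (1, 2, 3):
            study.animals[0].measurements[i].value = -1
        flags = detect_outliers(study)
        out = apply_filter(study, flags, "point_level")
        assert "m0" not in [a.animal_id for a in out.animals]

    def test_animal_level_removes_flagged_animal(self):
        study = _cohort(n=12)
        study.animals[2].measurements[1].value = -1
        flags = detect_outliers(study)
        out = apply_filter(study, flags, "animal_level")
        assert "m2" not in [a.animal_id for a in out.animals]
        assert len(out.animals) == 11

    def test_severity_selection(self):
        study = _cohort(n=12)
        study.animals[0].measurements[-1].value = (
            study.animals[0].measurements[-2].value * 0.4
        )  # LAST_DAY_DROP, medium
        flags = detect_outliers(study)
        out = apply_filter(study, flags, "animal_level",
                           severities={Severity.critical})
        assert len(out.animals) == 12  # medium flag not selected

    def test_original_study_untouched(self):
        study = _cohort(n=12, days=(0, 1, 2, 3, 4))
        study.animals[0].measurements[2].value = -1
        flags = detect_outliers(study)
        apply_filter(study, flags, "point_level")
        assert not any(m.excluded for a in study.animals for m in a.measurements)

    def test_planted_spike_recovery(self):
        """Point-level filtering recovers the clean rate; complete analysis
        inflates the rate's relative standard error."""
        from tgrkit.simulate import GroupSpec, SyntheticSpec, simulate_cohort

        spec = SyntheticSpec(
            group_specs=[GroupSpec("g", 10, r_mean=0.25, r_sd=0.0)],
            schedule=list(range(0, 20, 2)),
            noise_cv=15.0,
            outlier_plan=[("spike", 4)],
            seed=5,
        )
        study, truth = simulate_cohort(spec)
        flags = detect_outliers(study)
        planted = set(truth.index[truth.anomalies != ""])
        assert planted <= {f.animal_id for f in flags}
        filtered = apply_filter(study, flags, "point_level")
        # cohort mean rate recovered within 2 standard errors of the mean
        import numpy as np

        rates = [fit_exponential(a).r for a in filtered.animals]
        sem = np.std(rates, ddof=1) / math.sqrt(len(rates))
        assert abs(np.mean(rates) - 0.25) < 2 * sem
        mean_rse = lambda st: sum(
            fit_exponential(a).rse_r for a in st.animals
        ) / len(st.animals)
        assert mean_rse(study) > mean_rse(filtered)
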