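import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import varctrl as vc
from conftest import random_study


def study_from_variances(variances, sizes):
    groups = [
        vc.GroupSummary(label=f"g{i}", n=n, s2=s2)
        for i, (n, s2) in enumerate(zip(sizes, variances))
    ]
    return vc.StudySummary(control=groups[0], treatments=tuple(groups[1:]))


class TestObservedStatistic:
    def test_published_variances_example_1(self):
        # statistic from the published (4 dp rounded) group variances
        study = study_from_variances([0.0520, 0.0389, 0.0250, 0.0075], [10] * 4)
        assert vc.observed_statistic(study) == pytest.approx(6.933, abs=5e-4)

    def test_published_variances_example_2(self):
        study = study_from_variances([0.8841, 0.8165, 2.4240], [6, 4, 5])
        assert vc.observed_statistic(study) == pytest.approx(1.0828, abs=5e-5)

    def test_identical_variances(self):
        study = study_from_variances([1.7, 1.7, 1.7], [8, 8, 8])
        assert vc.observed_statistic(study) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        study = study_from_variances([1.0, 0.0, 2.0], [5, 5, 5])
        with pytest.raises(ValueError, match="zero sample variance"):
            vc.observed_statistic(study)


class TestPlausibility:
    def test_example_1_value(self, testosterone_study):
        assert round(vc.mim_plausibility(testosterone_study), 4) == 0.0117

    def test_example_2_value(self, blood_study):
        # frozen against a 1e8-draw Monte-Carlo oracle and a second,
        # independent quadrature formulation (integrating over the minimum)
        assert vc.mim_plausibility(blood_study) == pytest.approx(0.6803346, abs=2e-6)

    def test_theta_limits(self, blood_study):
        assert vc.mim_plausibility(blood_study, 1e-9) == pytest.approx(1.0, abs=1e-8)
        assert vc.mim_plausibility(blood_study, 1e9) == pytest.approx(0.0, abs=1e-8)

    def test_theta_domain(self, blood_study):
        with pytest.raises(ValueError):
            vc.mim_plausibility(blood_study, 0.0)

    def test_k1_equals_one_sided_f_test(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n0, n1 = rng.integers(3, 30, size=2)
            study = study_from_variances(
                [float(rng.chisquare(5)), float(rng.chisquare(5))], [int(n0), int(n1)]
            )
            t = vc.observed_statistic(study)
            expected = stats.f.sf(t, n0 - 1, n1 - 1)
            assert vc.mim_plausibility(study) == pytest.approx(expected, abs=1e-7)


class TestDecision:
    def test_example_1_rejects(self, testosterone_study):
        res = vc.mim_test(testosterone_study, alpha=0.05)
        assert res.reject
        assert res.method == "MIM"

    def test_example_2_fails_to_reject(self, blood_study):
        assert not vc.mim_test(blood_study, alpha=0.05).reject

    def test_huge_statistic_rejects(self):
        study = study_from_variances([100.0, 1.0, 1.0], [10, 10, 10])
        res = vc.mim_test(study, alpha=0.05)
        assert res.plausibility < 1e-4
        assert res.reject

    def test_alpha_domain(self, blood_study):
        with pytest.raises(ValueError):
            vc.mim_test(blood_study, alpha=1.0)

    def test_result_consistency_enforced(self):
        with pytest.raises(ValueError):
            vc.TestResult(method="MIM", statistic=2.0, plausibility=0.4,
                          alpha=0.05, reject=True)


class TestCurve:
    def test_default_grid_spans_and_decreases(self, testosterone_study):
        curve = vc.plausibility_curve(testosterone_study)
        assert np.all(np.diff(curve.pl_values) <= 1e-12)
        assert curve.pl_values[0] > 0.99
        assert curve.pl_values[-1] < 0.01

    def test_passes_through_theta_one(self, testosterone_study):
        grid = np.array([0.5, 1.0, 2.0])
        curve = vc.plausibility_curve(testosterone_study, grid)
        assert curve.pl_values[1] == pytest.approx(
            vc.mim_plausibility(testosterone_study), abs=1e-6
        )

    def test_scale_invariance(self):
        base = study_from_variances([2.0, 1.5, 0.7], [8, 6, 9])
        scaled = study_from_variances([20.0, 15.0, 7.0], [8, 6, 9])
        grid = np.geomspace(0.05, 5, 50)
        c1 = vc.plausibility_curve(base, grid)
        c2 = vc.plausibility_curve(scaled, grid)
        assert np.allclose(c1.pl_values, c2.pl_values, atol=1e-12)

    def test_invalid_grids(self, blood_study):
        with pytest.raises(ValueError):
            vc.plausibility_curve(blood_study, np.array([]))
        with pytest.raises(ValueError):
            vc.plausibility_curve(blood_study, np.array([2.0, 1.0]))
        with pytest.raises(ValueError):
            vc.plausibility_curve(blood_study, np.array([-1.0, 1.0]))

    def test_k1_curve_matches_f_test_of_scaled_null(self):
        study = study_from_variances([1.3, 0.9], [10, 12])
        t = vc.observed_statistic(study)
        grid = np.geomspace(0.1, 5, 20)
        curve = vc.plausibility_curve(study, grid)
        expected = stats.f.sf(t * grid, 9, 11)
        assert np.allclose(curve.pl_values, expected, atol=1e-6)


class TestUpperBound:
    def test_defining_property(self, blood_study):
        bound = vc.mim_upper_bound(blood_study, 0.05)
        assert vc.mim_plausibility(blood_study, bound) == pytest.approx(0.05, abs=1e-6)

    def test_example_1_bound_below_one(self, testosterone_study):
        assert vc.mim_upper_bound(testosterone_study, 0.05) < 1.0

    def test_example_2_bound_above_one(self, blood_study):
        assert vc.mim_upper_bound(blood_study, 0.05) > 1.0


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 10_000), alpha=st.sampled_from([0.01, 0.05, 0.2]))
def test_duality_reject_iff_bound_below_one(seed, alpha):
    study = random_study(np.random.default_rng(seed))
    res = vc.mim_test(study, alpha)
    bound = vc.mim_upper_bound(study, alpha)
    assert res.reject == (bound < 1.0) or abs(bound - 1.0) < 1e-9


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 10_000), c=st.floats(0.01, 100))
def test_scale_invariance_of_decision(seed, c):
    study = random_study(np.random.default_rng(seed))
    scaled = vc.StudySummary(
        control=vc.GroupSummary(study.control.label, study.control.n, study.control.s2 * c),
        treatments=tuple(
            vc.GroupSummary(t.label, t.n, t.s2 * c) for t in study.treatments
        ),
    )
    assert vc.observed_statistic(scaled) == pytest.approx(vc.observed_statistic(study), rel=1e-12)
    assert vc.mim_plausibility(scaled) == pytest.approx(vc.mim_plausibility(study), abs=1e-9)
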