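"""Outcome layer: death/detection probabilities and quantile times."""

import math

import numpy as np
import pytest
from scipy import stats

from metastatic_bottleneck import (
    BottleneckPrior,
    OutcomeParams,
    QuantileQuery,
    conditioned_death_prob,
    conditioned_detection_kernel,
    cumulative_attempts,
    death_probability,
    detection_probability,
    metastasis_probability,
    predict_survival_curve,
    quantile_time_to_death,
    quantile_times_grid,
    time_of_diagnosis,
)


class TestMetastasisProbability:
    def test_zero_at_onset(self, growth150):
        assert metastasis_probability(0.0, 17.0, growth150) == 0.0

    def test_vanishes_for_severe_bottleneck(self, growth150):
        assert metastasis_probability(10.0, 500.0, growth150) == pytest.approx(0.0)

    @pytest.mark.parametrize("t, b", [(4.0, 15.0), (8.0, 17.0), (12.0, 20.0)])
    def test_equals_poisson_zero_class(self, growth150, t, b):
        lam = math.exp(-b) * cumulative_attempts(t, growth150)
        assert metastasis_probability(t, b, growth150) == pytest.approx(
            1.0 - stats.poisson.pmf(0, lam), rel=1e-9
        )


class TestConditionedProbabilities:
    def test_zero_at_window_start(self, params_point):
        d = 2.0
        td = time_of_diagnosis(d, params_point.growth)
        assert conditioned_death_prob(td - params_point.delta0, d, 17.0, params_point) == 0.0
        assert conditioned_detection_kernel(td - params_point.delta0, d, 17.0, params_point) == 0.0

    def test_all_metastases_removed_limit(self, params_point):
        p = params_point.with_(a=1e9)
        d = 2.0
        td = time_of_diagnosis(d, p.growth)
        assert conditioned_death_prob(td, d, 17.0, p) < 1e-6

    def test_nondecreasing_in_time(self, params_point):
        d, b = 2.0, 17.0
        td = time_of_diagnosis(d, params_point.growth)
        ts = np.linspace(td - params_point.delta0, td, 40)
        vals = [conditioned_death_prob(t, d, b, params_point) for t in ts]
        assert all(x <= y + 1e-15 for x, y in zip(vals, vals[1:]))

    def test_detection_kernel_dominates_death(self, params_point):
        # removal weight <= 1 pointwise => fewer lethal than total attempts
        d, b = 2.0, 17.0
        td = time_of_diagnosis(d, params_point.growth)
        for t in np.linspace(td - params_point.delta0 + 0.2, td, 7):
            assert conditioned_detection_kernel(t, d, b, params_point) >= (
                conditioned_death_prob(t, d, b, params_point)
            )

    def test_kernel_equals_death_when_removal_instant(self, params_point):
        p = params_point.with_(a=1e-9)
        d, b = 2.0, 17.0
        td = time_of_diagnosis(d, p.growth)
        assert conditioned_death_prob(td, d, b, p) == pytest.approx(
            conditioned_detection_kernel(td, d, b, p), rel=1e-6
        )

    def test_out_of_window_rejected(self, params_point):
        d = 2.0
        td = time_of_diagnosis(d, params_point.growth)
        with pytest.raises(ValueError):
            conditioned_death_prob(td + 1.0, d, 17.0, params_point)


class TestMarginalCurves:
    def test_point_prior_reproduces_conditioned_value(self, params_point):
        d = 2.0
        td = time_of_diagnosis(d, params_point.growth)
        assert death_probability(d, params_point) == pytest.approx(
            conditioned_death_prob(td, d, 17.0, params_point), rel=1e-12
        )

    def test_narrow_lognormal_converges_to_point(self, params_point):
        narrow = params_point.with_(
            prior=BottleneckPrior.lognormal(math.log(17.0), 1e-3)
        )
        for d in (1.0, 3.0):
            assert death_probability(d, narrow) == pytest.approx(
                death_probability(d, params_point), abs=1e-4
            )

    def test_quadrature_matches_monte_carlo(self, params_lognormal):
        rng = np.random.default_rng(1234)
        n = 200_000
        prior = params_lognormal.prior
        bs = prior.sample(rng, n)
        for d in (1.125, 2.625, 4.875):
            td = time_of_diagnosis(d, params_lognormal.growth)
            vals = np.array(
                [conditioned_death_prob(td, d, b, params_lognormal) for b in bs[:20_000]]
            )
            mc, se = vals.mean(), vals.std() / math.sqrt(vals.size)
            assert abs(death_probability(d, params_lognormal) - mc) < 3 * se

    def test_node_doubling_stability(self, params_lognormal):
        for d in (1.0, 4.0):
            v1 = death_probability(d, params_lognormal)
            v2 = death_probability(d, params_lognormal.with_(n_nodes=512))
            assert v2 == pytest.approx(v1, rel=1e-6, abs=1e-12)

    def test_detection_monotone_in_diameter(self, params_lognormal):
        ds = np.arange(0.625, 8.0, 0.5)
        vals = [detection_probability(d, params_lognormal) for d in ds]
        assert all(x <= y + 1e-12 for x, y in zip(vals, vals[1:]))
        assert all(0 <= v <= 1 for v in vals)

    def test_tiny_tumor_has_no_detectable_metastases(self, params_point):
        # a millimetre-scale tumor has shed too few cells to seed anything
        assert detection_probability(0.05, params_point) < 1e-4
        assert detection_probability(0.05, params_point) < 1e-3 * (
            detection_probability(2.0, params_point)
        )

    def test_death_exceeds_detection_in_fitted_regime(self, params_lognormal):
        for d in (0.875, 2.125, 4.625):
            assert death_probability(d, params_lognormal) > detection_probability(
                d, params_lognormal
            )


class TestQuantileTimes:
    def test_earliest_seeding_limit(self, params_lognormal):
        q = quantile_time_to_death(QuantileQuery(d=2.0, q=1e-7), params_lognormal)
        assert q == pytest.approx(params_lognormal.h, abs=1e-3)

    def test_latest_seeding_limit(self, params_lognormal):
        q = quantile_time_to_death(QuantileQuery(d=2.0, q=1 - 1e-9), params_lognormal)
        assert q == pytest.approx(
            params_lognormal.delta0 + params_lognormal.h, abs=1e-3
        )

    def test_monotone_in_quantile(self, params_lognormal):
        qs = np.linspace(0.05, 0.95, 10)
        times = quantile_times_grid([2.0], qs, params_lognormal)[0]
        assert all(x <= y + 1e-9 for x, y in zip(times, times[1:]))

    def test_detected_only_at_most_all_patients(self, params_lognormal):
        for d in (1.125, 2.625):
            q_all = quantile_time_to_death(QuantileQuery(d=d, q=0.5), params_lognormal)
            q_det = quantile_time_to_death(
                QuantileQuery(d=d, q=0.5, detected_only=True), params_lognormal
            )
            assert q_det <= q_all + 1e-9

    def test_detected_only_pinned_to_prolongation_when_lags_close(self, growth150):
        # delta1 -> delta0 leaves detected patients at a terminal stage:
        # their median time to death is the treatment prolongation h
        p = OutcomeParams(
            delta0=6.0, delta1=5.99, a=1.0, h=1.0,
            prior=BottleneckPrior.lognormal(math.log(17.0), 0.8), growth=growth150,
        )
        meds = quantile_times_grid(
            [0.875, 2.125, 4.875], [0.5], p, detected_only=True
        )[:, 0]
        assert np.all(np.abs(meds - p.h) < 0.02)
        assert meds.max() - meds.min() < 0.01  # flat in diameter

    def test_weightings_coincide_for_point_prior(self, params_point):
        for q in (0.25, 0.5, 0.9):
            qq = QuantileQuery(d=2.0, q=q)
            assert quantile_time_to_death(qq, params_point, weighting="posterior") == (
                pytest.approx(
                    quantile_time_to_death(qq, params_point, weighting="prior"),
                    abs=1e-6,
                )
            )

    def test_invalid_quantile_rejected(self):
        with pytest.raises(ValueError):
            QuantileQuery(d=1.0, q=1.5)


class TestSurvivalCurve:
    def test_starts_at_one_and_decreases(self, params_lognormal):
        grid = np.linspace(0.0, 8.0, 50)
        s = predict_survival_curve([2.0, 3.0], params_lognormal, grid)
        assert s[0] == pytest.approx(1.0)
        assert np.all(np.diff(s) <= 1e-12)

    def test_inverts_quantile_times(self, params_lognormal):
        # S(Q(q)) = 1 - q for a one-patient cohort
        for q in (0.2, 0.5, 0.8):
            t_q = quantile_time_to_death(QuantileQuery(d=2.0, q=q), params_lognormal)
            s = predict_survival_curve([2.0], params_lognormal, [t_q])[0]
            assert s == pytest.approx(1.0 - q, abs=1e-4)

    def test_duplicate_patients_change_nothing(self, params_lognormal):
        grid = np.linspace(0.0, 7.0, 20)
        one = predict_survival_curve([2.5], params_lognormal, grid)
        two = predict_survival_curve([2.5, 2.5], params_lognormal, grid)
        assert np.allclose(one, two)

    def test_empty_cohort_rejected(self, params_lognormal):
        with pytest.raises(ValueError):
            predict_survival_curve([], params_lognormal, [0.0, 1.0])


class TestParameterValidation:
    def test_lag_ordering_enforced(self, growth150):
        with pytest.raises(ValueError):
            OutcomeParams(
                delta0=3.0, delta1=4.0, a=1.0, h=0.5,
                prior=BottleneckPrior.point(17.0), growth=growth150,
            )

    def test_prior_validation(self):
        with pytest.raises(ValueError):
            BottleneckPrior.lognormal(2.0, -1.0)
        with pytest.raises(ValueError):
            BottleneckPrior.point(-5.0)

    def test_prior_median(self):
        assert BottleneckPrior.lognormal(math.log(17), 0.8).median == pytest.approx(17.0)
        assert BottleneckPrior.point(12.0).median == 12.0
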