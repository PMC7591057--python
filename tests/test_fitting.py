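"""Curve fitting: objective structure, recovery on noise-free curves,
reduced model, and held-out validation."""

import math

import numpy as np
import pytest

from metastatic_bottleneck import (
    BottleneckPrior,
    DiameterSummary,
    FitSpec,
    OutcomeCurveFitter,
    OutcomeParams,
    death_probability,
    detection_probability,
    quantile_times_grid,
    validate,
)
from metastatic_bottleneck.outcome import DEFAULT_QUANTILES

DIAMS = np.arange(0.625, 6.0, 0.5)


def analytic_summary(params, n=50_000, deaths=20_000):
    """Noise-free summary rows: curves evaluated, not sampled."""
    qt = quantile_times_grid(DIAMS, DEFAULT_QUANTILES, params)
    qt_det = quantile_times_grid(DIAMS, DEFAULT_QUANTILES, params, detected_only=True)
    rows = []
    for k, d in enumerate(DIAMS):
        death = death_probability(d, params)
        rows.append(
            DiameterSummary(
                bin_mid_cm=float(d),
                n=n,
                detection_freq=detection_probability(d, params),
                death_upper=death,
                death_lower=death,
                death_km=death,
                quantile_times=dict(zip(DEFAULT_QUANTILES, qt[k])),
                quantile_times_detected=dict(zip(DEFAULT_QUANTILES, qt_det[k])),
                n_cancer_deaths=deaths,
                n_detected_deaths=deaths // 3,
            )
        )
    return rows


class TestObjective:
    def test_zero_at_generating_truth(self, params_lognormal, growth150):
        # residual loss at truth comes only from the quantile-solver
        # tolerance (1e-4 y), far below one standard error per data point
        summ = analytic_summary(params_lognormal)
        fitter = OutcomeCurveFitter(growth150)
        assert fitter.objective(params_lognormal, summ) < 0.05

    def test_perturbing_lethality_lag_increases_loss(self, params_lognormal, growth150):
        summ = analytic_summary(params_lognormal)
        fitter = OutcomeCurveFitter(growth150)
        worse = params_lognormal.with_(delta0=params_lognormal.delta0 + 1.0)
        assert fitter.objective(worse, summ) > 1.0

    def test_detection_only_weighting(self, params_lognormal, growth150):
        summ = analytic_summary(params_lognormal)
        spec = FitSpec(quantile_weight=0.0)
        fitter = OutcomeCurveFitter(growth150, spec)
        tables = fitter._tables(summ)
        worse = params_lognormal.with_(delta1=params_lognormal.delta1 - 1.0)
        det_res, _ = fitter._residuals(worse, tables)
        expected = float(np.sum((det_res / tables["det_se"]) ** 2))
        assert fitter._objective_from_tables(worse, tables) == pytest.approx(expected)

    def test_empty_summary_rejected(self, growth150):
        empty = DiameterSummary(
            bin_mid_cm=1.0, n=3, detection_freq=math.nan, death_upper=math.nan,
            death_lower=math.nan, death_km=math.nan,
            quantile_times={0.5: math.nan}, quantile_times_detected={0.5: math.nan},
        )
        with pytest.raises(ValueError):
            OutcomeCurveFitter(growth150).objective(None, [empty])


class TestFit:
    def test_recovers_truth_from_noise_free_curves(self, params_lognormal, growth150):
        summ = analytic_summary(params_lognormal)
        spec = FitSpec(restarts=16, generations=150, seed=1)
        fitter = OutcomeCurveFitter(growth150, spec).fit(summ)
        p = fitter.params_
        assert p.delta0 == pytest.approx(params_lognormal.delta0, rel=0.10)
        assert p.delta1 == pytest.approx(params_lognormal.delta1, rel=0.10)
        assert p.h == pytest.approx(params_lognormal.h, rel=0.10)
        assert p.prior.median == pytest.approx(params_lognormal.prior.median, rel=0.15)
        assert fitter.converged_ in (True, False)
        stages = fitter.restart_table_["stage"]
        assert (stages == "polish").sum() == 1
        assert (stages == "evolve").sum() >= spec.restarts

    def test_reduced_model_on_nearly_homogeneous_data(self, growth150):
        truth = OutcomeParams(
            delta0=6.0, delta1=5.5, a=1.0, h=1.0,
            prior=BottleneckPrior.lognormal(math.log(17.0), 0.01), growth=growth150,
        )
        summ = analytic_summary(truth)
        spec = FitSpec(restarts=12, generations=120, seed=2)
        fitter = OutcomeCurveFitter(growth150, spec, reduced=True).fit(summ)
        assert fitter.params_.prior.kind == "point"
        assert fitter.params_.prior.b0 == pytest.approx(17.0, rel=0.10)

    def test_optimum_is_stationary(self, params_lognormal, growth150):
        summ = analytic_summary(params_lognormal)
        spec = FitSpec(restarts=8, generations=40, seed=3)
        fitter = OutcomeCurveFitter(growth150, spec).fit(summ)
        assert fitter.objective(fitter.params_, summ) == pytest.approx(
            fitter.loss_, abs=1e-8
        )

    def test_unfitted_predict_raises(self, growth150):
        with pytest.raises(RuntimeError):
            OutcomeCurveFitter(growth150).predict_detection([1.0])


class TestEstimatorInterface:
    def test_get_set_params_round_trip(self, growth150):
        est = OutcomeCurveFitter(growth150)
        params = est.get_params()
        assert set(params) == {"growth", "spec", "reduced"}
        est.set_params(reduced=True)
        assert est.reduced is True
        with pytest.raises(ValueError):
            est.set_params(unknown_knob=1)


class TestValidate:
    def test_noise_free_predictions_inside_band(self, params_lognormal, growth150):
        summ = analytic_summary(params_lognormal)
        spec = FitSpec(restarts=6, generations=15, polish_maxfev=300, seed=4)
        fitter = OutcomeCurveFitter(growth150, spec).fit(summ)
        # validate at the generating truth: every bin must be inside
        from metastatic_bottleneck.fitting import FitResult

        result = FitResult(
            params=params_lognormal, loss=0.0, rmse_detection=0.0,
            rmse_quantiles={}, converged=True,
            restart_table=fitter.restart_table_, reduced=False,
        )
        report = validate(result, summ)
        assert report["frac_inside_band"] == 1.0
        assert report["rmse_death_km"] < 1e-9

    def test_report_is_deterministic_given_params(self, params_lognormal):
        from metastatic_bottleneck.fitting import FitResult
        import pandas as pd

        summ = analytic_summary(params_lognormal)
        result = FitResult(
            params=params_lognormal, loss=0.0, rmse_detection=0.0,
            rmse_quantiles={}, converged=True,
            restart_table=pd.DataFrame(), reduced=False,
        )
        r1 = validate(result, summ)
        r2 = validate(result, summ)
        assert r1["frac_inside_band"] == r2["frac_inside_band"]
        pd.testing.assert_frame_equal(r1["death_probability"], r2["death_probability"])
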