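"""Per-cancer parameter estimation from diameter-binned summaries.

The six free parameters (delta0, delta1, a, h, mu, sigma) — or the
reduced model's five (delta0, delta1, a, h, b0) — are estimated by
least squares on two curve families only: the metastasis-detection
probability versus diameter and the quantile times to death (eleven
quantiles) versus diameter.  The cancer-death estimators and the
detected-only quantile times are deliberately held out and used for
validation, mirroring how the model's death-probability prediction is
tested against registry data it was never fitted to.

The global stage is seeded differential evolution over the parameter
box (the truth basin is narrow relative to the box, so purely local
multi-starts are unreliable), followed by a bounded Powell polish from
the evolved optimum.  Residuals are weighted by their sampling standard
errors (binomial for detection frequencies, asymptotic order-statistic
for empirical quantiles), so the objective is an approximate chi-square
and probability-unit and year-unit residuals are commensurable.

``OutcomeCurveFitter`` is the estimator-style surface (``fit`` /
``predict_*`` / ``get_params`` / ``set_params``, fitted attributes with
a trailing underscore); the module-level ``objective``, ``fit`` and
``validate`` functions are thin wrappers over it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .growth import GrowthLaw
from .outcome import (
    DEFAULT_QUANTILES,
    BottleneckPrior,
    OutcomeParams,
    _marginal_curve,
    detection_probability,
    death_probability,
    quantile_times_grid,
)
from .summaries import DiameterSummary

__all__ = ["FitSpec", "FitResult", "OutcomeCurveFitter", "objective", "fit", "validate"]

_LOG2, _LOG200 = math.log(2.0), math.log(200.0)

#: Box bounds for the internal parameter vector.  delta1 is parametrized
#: as a fraction of delta0 so the ordering constraint is built in; the
#: location bound doubles as the log-b0 bound of the reduced model.
_BOUNDS = {
    "delta0": (0.5, 30.0),
    "ratio1": (0.05, 0.995),
    "a": (0.01, 1.0),
    "h": (0.0, 5.0),
    "mu": (_LOG2, _LOG200),
    "sigma": (0.02, 2.0),
}


@dataclass(frozen=True)
class FitSpec:
    """Configuration of the least-squares fit.

    ``restarts`` is the evolutionary population size (each member is an
    independently initialized search trajectory); ``generations`` caps
    the number of evolution steps and ``polish_maxfev`` the function
    evaluations of the final local polish.
    """

    quantiles: tuple[float, ...] = DEFAULT_QUANTILES
    detection_weight: float = 1.0
    quantile_weight: float = 1.0
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=lambda: dict(_BOUNDS))
    restarts: int = 16
    generations: int = 150
    tol: float = 0.01
    polish_maxfev: int = 2500
    seed: int = 0
    n_nodes: int = 192
    quantile_xtol: float = 1e-4

    def __post_init__(self) -> None:
        if self.restarts < 5:
            raise ValueError("restarts (population size) must be >= 5")
        for k, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"inconsistent bound for {k}: ({lo}, {hi})")


@dataclass(frozen=True)
class FitResult:
    """Best fit with per-curve goodness-of-fit and the restart table."""

    params: OutcomeParams
    loss: float
    rmse_detection: float
    rmse_quantiles: Mapping[float, float]
    converged: bool
    restart_table: pd.DataFrame
    reduced: bool


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (np.tanh(0.5 * z) + 1.0)


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


class OutcomeCurveFitter:
    """Least-squares estimator of the outcome-model parameters.

    Parameters
    ----------
    growth
        Primary-tumor growth law (cancer-specific, fixed during the fit).
    spec
        Fit configuration (quantiles, weights, bounds, restarts, seed).
    reduced
        Fit the homogeneous-bottleneck model (point mass b0) instead of
        the log-normal frailty.

    Attributes (after ``fit``)
    --------------------------
    params_ : OutcomeParams        best-fitting parameter set
    loss_ : float                  objective at the optimum
    rmse_detection_ : float        RMSE of the detection curve (probability)
    rmse_quantiles_ : dict         per-quantile RMSE (years)
    restart_table_ : DataFrame     final objective per population member + polish
    converged_ : bool              success flag of the winning optimizer stage
    result_ : FitResult            everything above, bundled
    """

    def __init__(
        self,
        growth: GrowthLaw,
        spec: FitSpec | None = None,
        reduced: bool = False,
    ) -> None:
        self.growth = growth
        self.spec = spec or FitSpec()
        self.reduced = reduced

    # -- sklearn-style plumbing -------------------------------------------
    def get_params(self, deep: bool = True) -> dict[str, Any]:
        return {"growth": self.growth, "spec": self.spec, "reduced": self.reduced}

    def set_params(self, **kwargs) -> "OutcomeCurveFitter":
        for k, v in kwargs.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- parameter vector <-> OutcomeParams --------------------------------
    @property
    def _names(self) -> list[str]:
        base = ["delta0", "ratio1", "a", "h", "mu"]
        return base if self.reduced else base + ["sigma"]

    def _box(self) -> tuple[np.ndarray, np.ndarray]:
        b = self.spec.bounds
        lo = np.array([b[k][0] for k in self._names])
        hi = np.array([b[k][1] for k in self._names])
        return lo, hi

    def _decode(self, z: np.ndarray) -> OutcomeParams:
        lo, hi = self._box()
        x = lo + (hi - lo) * _sigmoid(z)
        vals = dict(zip(self._names, x))
        prior = (
            BottleneckPrior.point(math.exp(vals["mu"]))
            if self.reduced
            else BottleneckPrior.lognormal(vals["mu"], vals["sigma"])
        )
        return OutcomeParams(
            delta0=vals["delta0"],
            delta1=vals["ratio1"] * vals["delta0"],
            a=vals["a"],
            h=vals["h"],
            prior=prior,
            growth=self.growth,
            n_nodes=self.spec.n_nodes,
        )

    def _encode(self, params: OutcomeParams) -> np.ndarray:
        lo, hi = self._box()
        vals = {
            "delta0": params.delta0,
            "ratio1": params.delta1 / params.delta0,
            "a": params.a,
            "h": params.h,
            "mu": (
                math.log(params.prior.b0)
                if params.prior.kind == "point"
                else params.prior.mu
            ),
        }
        if not self.reduced:
            vals["sigma"] = params.prior.sigma
        x = np.array([vals[k] for k in self._names])
        frac = np.clip((x - lo) / (hi - lo), 1e-9, 1.0 - 1e-9)
        return _logit(frac)

    # -- data marshalling ---------------------------------------------------
    @staticmethod
    def _quantile_se(row: np.ndarray, q: np.ndarray, m: int) -> np.ndarray:
        """Asymptotic SE of empirical quantiles: sqrt(q(1-q)/m)/f(x_q).

        The density at the quantile is estimated from the spacing of the
        neighbouring quantiles in the same row; spacings are floored so
        ties cannot produce zero standard errors.
        """
        hi = np.minimum(np.arange(q.size) + 1, q.size - 1)
        lo = np.maximum(np.arange(q.size) - 1, 0)
        dx = np.maximum(row[hi] - row[lo], 1e-3)
        dens = (q[hi] - q[lo]) / dx
        return np.maximum(np.sqrt(q * (1 - q) / m) / dens, 1e-3)

    def _tables(self, summary: Sequence[DiameterSummary]) -> dict[str, np.ndarray]:
        det_d, det_f, det_se = [], [], []
        for s in summary:
            if not math.isnan(s.detection_freq):
                det_d.append(s.bin_mid_cm)
                det_f.append(s.detection_freq)
                p = (s.detection_freq * s.n + 1.0) / (s.n + 2.0)  # shrunk SE
                det_se.append(math.sqrt(p * (1 - p) / s.n))
        q = np.asarray(self.spec.quantiles)
        qt_d, qt_rows, qt_se = [], [], []
        for s in summary:
            row = np.array([s.quantile_times.get(float(qq), math.nan) for qq in q])
            if not np.any(np.isnan(row)) and s.n_cancer_deaths > 0:
                qt_d.append(s.bin_mid_cm)
                qt_rows.append(row)
                qt_se.append(self._quantile_se(row, q, s.n_cancer_deaths))
        if not det_d and not qt_d:
            raise ValueError("summary contains no usable detection or quantile rows")
        return {
            "det_d": np.asarray(det_d),
            "det_f": np.asarray(det_f),
            "det_se": np.asarray(det_se),
            "qt_d": np.asarray(qt_d),
            "qt_obs": np.asarray(qt_rows, dtype=float).reshape(len(qt_d), -1),
            "qt_se": np.asarray(qt_se, dtype=float).reshape(len(qt_d), -1),
            "q": q,
        }

    def _residuals(
        self, params: OutcomeParams, tables: dict
    ) -> tuple[np.ndarray, np.ndarray]:
        det_res = (
            _marginal_curve(tables["det_d"], params, "detection") - tables["det_f"]
            if tables["det_d"].size
            else np.empty(0)
        )
        if tables["qt_d"].size:
            model = quantile_times_grid(
                tables["qt_d"], tables["q"], params, xtol=self.spec.quantile_xtol
            )
            qt_res = model - tables["qt_obs"]
        else:
            qt_res = np.empty((0, tables["q"].size))
        return det_res, qt_res

    def _objective_from_tables(self, params: OutcomeParams, tables: dict) -> float:
        det_res, qt_res = self._residuals(params, tables)
        loss = 0.0
        if det_res.size:
            loss += self.spec.detection_weight * float(
                np.sum((det_res / tables["det_se"]) ** 2)
            )
        if qt_res.size:
            loss += self.spec.quantile_weight * float(
                np.sum((qt_res / tables["qt_se"]) ** 2)
            )
        return loss

    def objective(
        self, params: OutcomeParams, summary: Sequence[DiameterSummary]
    ) -> float:
        """Standardized weighted sum of squared curve residuals.

        Detection and all-patients quantile curves only; death
        estimators and detected-only quantiles never enter the loss.
        """
        return self._objective_from_tables(params, self._tables(summary))

    # -- fitting ------------------------------------------------------------
    def fit(self, summary: Sequence[DiameterSummary]) -> "OutcomeCurveFitter":
        tables = self._tables(summary)
        lo, hi = self._box()

        def f_box(x: np.ndarray) -> float:
            try:
                params = self._decode(_logit(np.clip((x - lo) / (hi - lo),
                                                     1e-9, 1 - 1e-9)))
                return self._objective_from_tables(params, tables)
            except (ValueError, FloatingPointError):
                return 1e12

        evo = optimize.differential_evolution(
            f_box,
            bounds=list(zip(lo, hi)),
            seed=self.spec.seed,
            maxiter=self.spec.generations,
            popsize=self.spec.restarts,
            init="sobol",
            tol=self.spec.tol,
            polish=False,
        )
        rows = [
            {"member": int(k), "stage": "evolve", "loss": float(e)}
            for k, e in enumerate(np.sort(evo.population_energies))
        ]
        res = optimize.minimize(
            f_box, evo.x, method="Powell",
            bounds=list(zip(lo, hi)),
            options={"maxfev": self.spec.polish_maxfev, "xtol": 1e-8,
                     "ftol": 1e-10},
        )
        best = res if res.fun <= evo.fun else evo
        rows.append({"member": -1, "stage": "polish", "loss": float(best.fun)})
        if not np.isfinite(best.fun) or best.fun >= 1e12:
            raise RuntimeError(
                "optimization failed on every trajectory; restart table:\n"
                + pd.DataFrame(rows).to_string()
            )
        params = self._decode(
            _logit(np.clip((best.x - lo) / (hi - lo), 1e-9, 1 - 1e-9))
        )
        det_res, qt_res = self._residuals(params, tables)
        self.params_ = params
        self.loss_ = float(best.fun)
        self.rmse_detection_ = (
            float(np.sqrt(np.mean(det_res**2))) if det_res.size else math.nan
        )
        self.rmse_quantiles_ = {
            float(qq): float(np.sqrt(np.mean(qt_res[:, j] ** 2)))
            for j, qq in enumerate(tables["q"])
        } if qt_res.size else {}
        self.restart_table_ = pd.DataFrame(rows)
        self.converged_ = bool(best.success)
        self.result_ = FitResult(
            params=params,
            loss=self.loss_,
            rmse_detection=self.rmse_detection_,
            rmse_quantiles=self.rmse_quantiles_,
            converged=self.converged_,
            restart_table=self.restart_table_,
            reduced=self.reduced,
        )
        return self

    # -- prediction ---------------------------------------------------------
    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted; call fit() first")

    def predict_detection(self, diameters: Sequence[float]) -> np.ndarray:
        self._check_fitted()
        return np.array([detection_probability(d, self.params_) for d in diameters])

    def predict_death(self, diameters: Sequence[float]) -> np.ndarray:
        self._check_fitted()
        return np.array([death_probability(d, self.params_) for d in diameters])

    def predict_quantile_times(
        self, diameters: Sequence[float], quantiles: Sequence[float] | None = None,
        detected_only: bool = False,
    ) -> np.ndarray:
        self._check_fitted()
        q = quantiles if quantiles is not None else self.spec.quantiles
        return quantile_times_grid(diameters, q, self.params_,
                                   detected_only=detected_only)


# ---------------------------------------------------------------------------
# functional wrappers


def objective(
    params: OutcomeParams,
    summary: Sequence[DiameterSummary],
    spec: FitSpec | None = None,
) -> float:
    """Fit loss of ``params`` against a summary (see OutcomeCurveFitter)."""
    return OutcomeCurveFitter(params.growth, spec).objective(params, summary)


def fit(
    summary: Sequence[DiameterSummary],
    growth: GrowthLaw,
    spec: FitSpec | None = None,
    reduced: bool = False,
) -> FitResult:
    """Multi-start bounded fit; returns the bundled result object."""
    return OutcomeCurveFitter(growth, spec, reduced=reduced).fit(summary).result_


def validate(
    result: FitResult, summary: Sequence[DiameterSummary]
) -> dict[str, Any]:
    """Held-out validation of a fitted model; no refitting occurs.

    Compares (i) predicted death probability against the
    [lower, upper] estimator interval per bin, (ii) the predicted
    detected-only median time to death against the observed one, and
    reports the corresponding RMSEs.
    """
    params = result.params
    rows = []
    for s in summary:
        if math.isnan(s.death_lower):
            continue
        pred = death_probability(s.bin_mid_cm, params)
        # the band edges are themselves binomial estimates; allow each
        # edge its 2-SE sampling slack so sparse bins are judged fairly
        se_lo = math.sqrt(max(s.death_lower * (1 - s.death_lower), 0.0) / s.n)
        se_up = math.sqrt(max(s.death_upper * (1 - s.death_upper), 0.0) / s.n)
        inside = (
            s.death_lower - 2 * se_lo - 1e-12 <= pred <= s.death_upper + 2 * se_up + 1e-12
        )
        rows.append(
            {
                "bin_mid_cm": s.bin_mid_cm,
                "pred_death": pred,
                "death_lower": s.death_lower,
                "death_km": s.death_km,
                "death_upper": s.death_upper,
                "inside": bool(inside),
            }
        )
    death_table = pd.DataFrame(rows)
    det_rows = []
    for s in summary:
        obs = s.quantile_times_detected.get(0.5, math.nan)
        if math.isnan(obs):
            continue
        try:
            pred = quantile_times_grid([s.bin_mid_cm], [0.5], params,
                                       detected_only=True)[0, 0]
        except ValueError:
            continue
        det_rows.append(
            {"bin_mid_cm": s.bin_mid_cm, "pred_median_detected": pred,
             "obs_median_detected": obs}
        )
    det_table = pd.DataFrame(det_rows)
    report: dict[str, Any] = {
        "death_probability": death_table,
        "detected_median": det_table,
        "frac_inside_band": (
            float(death_table["inside"].mean()) if len(death_table) else math.nan
        ),
        "rmse_death_km": (
            float(np.sqrt(np.mean((death_table["pred_death"] - death_table["death_km"]) ** 2)))
            if len(death_table) else math.nan
        ),
        "rmse_detected_median": (
            float(np.sqrt(np.mean(
                (det_table["pred_median_detected"] - det_table["obs_median_detected"]) ** 2
            )))
            if len(det_table) else math.nan
        ),
    }
    return report
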