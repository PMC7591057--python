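"""Clinical-outcome layer: metastasis, death and detection probabilities
and quantile times to death as functions of tumor size at diagnosis.

A tumor diagnosed at diameter ``d`` has seeded ``N(t(d))`` attempts, each
succeeding with probability ``s_1(b) = exp(-b)``; successful counts are
Poisson, so the probability of at least one metastasis is
``M(t; b) = 1 - exp(-s_1(b) N(t))``.

Post-surgical outcome conditions on the patient being alive at diagnosis
(no successful metastasis before ``t(d) - delta0``) and on treatment
removing young metastases (a metastasis seeded at ``u`` escapes removal
with probability ``1 - exp(-(t(d) - u)/a)``).  The bottleneck severity
``b`` is a per-patient log-normal frailty; population curves marginalize
over it by Gauss-Legendre quadrature on the log-``b`` axis.

Quantile times to death among patients who die of cancer invert the
normalized conditional seeding-time distribution by bisection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np

from .growth import GrowthLaw, SeedingWindow, time_of_diagnosis, windowed_attempts

__all__ = [
    "BottleneckPrior",
    "OutcomeParams",
    "QuantileQuery",
    "DEFAULT_QUANTILES",
    "metastasis_probability",
    "conditioned_death_prob",
    "conditioned_detection_kernel",
    "death_probability",
    "detection_probability",
    "quantile_time_to_death",
    "quantile_times_grid",
    "predict_survival_curve",
]

#: Eleven evenly spaced fitting quantiles, symmetric around the median.
DEFAULT_QUANTILES: tuple[float, ...] = tuple(round(0.05 + 0.09 * k, 2) for k in range(11))

#: Default Gauss-Legendre node count for the log-normal marginalization.
#: The integrand switches sharply near b ~ ln N, so the wide mu +/- 8 sigma
#: interval needs a dense rule; 256 nodes is converged to ~1e-5.
DEFAULT_NODES = 256

#: Half-width of the quadrature interval on the log-b axis, in units of sigma.
_TAIL_SIGMAS = 8.0


@lru_cache(maxsize=16)
def _leggauss_cached(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.polynomial.legendre.leggauss(n)


@dataclass(frozen=True)
class BottleneckPrior:
    """Across-patient distribution of the bottleneck severity ``b``.

    Either log-normal with location ``mu`` and scale ``sigma`` (both on
    the log-cell axis; the median severity is ``exp(mu)``) or a point
    mass at ``b0`` (the reduced, homogeneous-bottleneck model).
    """

    kind: Literal["lognormal", "point"]
    mu: float | None = None
    sigma: float | None = None
    b0: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "lognormal":
            if self.mu is None or self.sigma is None or not (self.sigma > 0):
                raise ValueError("lognormal prior needs mu and sigma > 0")
        elif self.kind == "point":
            if self.b0 is None or not (self.b0 > 0):
                raise ValueError("point prior needs b0 > 0")
        else:
            raise ValueError(f"unknown prior kind {self.kind!r}")

    @classmethod
    def lognormal(cls, mu: float, sigma: float) -> "BottleneckPrior":
        return cls(kind="lognormal", mu=mu, sigma=sigma)

    @classmethod
    def point(cls, b0: float) -> "BottleneckPrior":
        return cls(kind="point", b0=b0)

    @property
    def median(self) -> float:
        return math.exp(self.mu) if self.kind == "lognormal" else self.b0

    def shifted(self, log_factor: float) -> "BottleneckPrior":
        """Prior with the median multiplied by ``exp(log_factor)``."""
        if self.kind == "point":
            return BottleneckPrior.point(self.b0 * math.exp(log_factor))
        return BottleneckPrior.lognormal(self.mu + log_factor, self.sigma)

    def nodes(self, n: int = DEFAULT_NODES) -> tuple[np.ndarray, np.ndarray]:
        """Quadrature nodes ``b_j`` and weights ``w_j`` for E_f[g(b)].

        Composite (4-panel) Gauss-Legendre on ``y = log b`` over
        ``mu +/- 8 sigma``; the mass outside is below 1e-15 and is
        neglected.  Panelling keeps the rule accurate for the sharply
        switching survival term even at moderate node counts.  A point
        prior returns a single unit-weight node.
        """
        if self.kind == "point":
            return np.array([self.b0]), np.array([1.0])
        panels = 4
        x, w = _leggauss_cached(max(n // panels, 4))
        edges = np.linspace(-_TAIL_SIGMAS, _TAIL_SIGMAS, panels + 1) * self.sigma + self.mu
        ys, ws = [], []
        for a, b in zip(edges[:-1], edges[1:]):
            half, mid = (b - a) / 2.0, (a + b) / 2.0
            y = mid + half * x
            dens = np.exp(-0.5 * ((y - self.mu) / self.sigma) ** 2) / (
                self.sigma * math.sqrt(2.0 * math.pi)
            )
            ys.append(np.exp(y))
            ws.append(w * half * dens)
        return np.concatenate(ys), np.concatenate(ws)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "point":
            return np.full(size, self.b0)
        return rng.lognormal(mean=self.mu, sigma=self.sigma, size=size)


@dataclass(frozen=True)
class OutcomeParams:
    """The per-cancer free parameters of the outcome model.

    delta0 : years from successful metastasis initiation to lethality
    delta1 : years from initiation to detectability (< delta0)
    a      : expected metastasis age (years) at which it becomes
             irremovable by systemic therapy
    h      : mean treatment-induced survival prolongation (years)
    prior  : bottleneck-severity frailty distribution
    growth : primary-tumor growth law
    """

    delta0: float
    delta1: float
    a: float
    h: float
    prior: BottleneckPrior
    growth: GrowthLaw
    n_nodes: int = DEFAULT_NODES

    def __post_init__(self) -> None:
        if not (0 < self.delta1 < self.delta0):
            raise ValueError(
                f"require 0 < delta1 < delta0, got delta1={self.delta1}, delta0={self.delta0}"
            )
        if not (self.a > 0):
            raise ValueError("a must be positive")
        if self.h < 0:
            raise ValueError("h must be non-negative")

    def with_(self, **changes) -> "OutcomeParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class QuantileQuery:
    """Quantile-time query: diameter, quantile, and patient subset."""

    d: float
    q: float
    detected_only: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.q < 1):
            raise ValueError("quantile q must lie in (0, 1)")
        if not (self.d > 0):
            raise ValueError("diameter must be positive")


# ---------------------------------------------------------------------------
# per-b (conditioned) probabilities


def metastasis_probability(t: float, b: float, growth: GrowthLaw) -> float:
    """P(at least one successful metastasis by time ``t``) for severity b.

    ``1 - exp(-s_1(b) N(t))``: the zero class of a Poisson count with
    mean ``s_1(b) N(t)``.
    """
    from .growth import cumulative_attempts

    if not (b > 0):
        raise ValueError("b must be positive")
    return -math.expm1(-math.exp(-b) * cumulative_attempts(t, growth))


def _window_bounds(d: float, params: OutcomeParams) -> tuple[float, float]:
    t_d = time_of_diagnosis(d, params.growth)
    return max(t_d - params.delta0, 0.0), t_d


def _conditioned_attempts(
    t: float, d: float, params: OutcomeParams, removal: bool
) -> float:
    lo, t_d = _window_bounds(d, params)
    if not (lo - 1e-12 <= t <= t_d + 1e-12):
        raise ValueError(
            f"t={t:.6g} outside the conditioning window [{lo:.6g}, {t_d:.6g}] "
            f"for d={d} cm"
        )
    t = min(max(t, lo), t_d)
    win = SeedingWindow(
        t_start=lo,
        t_end=t_d,
        treatment_time=t_d,
        removal_scale=params.a if removal else None,
    )
    return windowed_attempts(t, win, params.growth)


def conditioned_death_prob(t: float, d: float, b: float, params: OutcomeParams) -> float:
    """Cancer-death (irremovable-metastasis) probability by time ``t``.

    Conditions on no successful metastasis before ``t(d) - delta0`` and
    counts only attempts that escape treatment removal.
    """
    n = _conditioned_attempts(t, d, params, removal=True)
    return -math.expm1(-math.exp(-b) * n)


def conditioned_detection_kernel(
    t: float, d: float, b: float, params: OutcomeParams
) -> float:
    """Metastasis probability by ``t`` with removal disabled.

    Screening happens at diagnosis, before treatment, so detection does
    not depend on the removal scale ``a``.
    """
    n = _conditioned_attempts(t, d, params, removal=False)
    return -math.expm1(-math.exp(-b) * n)


# ---------------------------------------------------------------------------
# vectorized internals

def _attempts_pieces(params: OutcomeParams) -> tuple[float, float]:
    g = params.growth
    r = g.rate_per_year
    pref = g.attempts_per_year_at_1cm3 * g.initial_volume_cm3 ** (2.0 / 3.0)
    return pref, r


def _plain_attempts_np(x: np.ndarray, lo: float, params: OutcomeParams) -> np.ndarray:
    pref, r = _attempts_pieces(params)
    c = 2.0 * r / 3.0
    return pref / c * (np.exp(c * x) - math.exp(c * lo))


def _windowed_attempts_np(
    x: np.ndarray, lo: float, treat: float, a: float | None, params: OutcomeParams
) -> np.ndarray:
    """Vectorized N(x; a, delta0) over an array of evaluation times."""
    plain = _plain_attempts_np(x, lo, params)
    if a is None:
        return plain
    pref, r = _attempts_pieces(params)
    c = 2.0 * r / 3.0 + 1.0 / a
    removed = pref / c * (
        np.exp(c * x - treat / a) - math.exp(min(c * lo - treat / a, 700.0))
    )
    return np.maximum(plain - removed, 0.0)


def _met_prob_matrix(n_attempts: np.ndarray, b: np.ndarray) -> np.ndarray:
    """M = 1 - exp(-exp(-b) N) broadcast over attempts x severities."""
    return -np.expm1(-np.exp(-b)[np.newaxis, :] * n_attempts[:, np.newaxis])


# ---------------------------------------------------------------------------
# marginal curves


def _marginal_at(
    d: float, params: OutcomeParams, eval_time: float, removal: bool
) -> float:
    lo, t_d = _window_bounds(d, params)
    if eval_time <= lo:
        return 0.0
    b, w = params.prior.nodes(params.n_nodes)
    n = _windowed_attempts_np(
        np.array([eval_time]), lo, t_d, params.a if removal else None, params
    )
    return float((_met_prob_matrix(n, b) @ w)[0])


def death_probability(d: float, params: OutcomeParams) -> float:
    """Marginal cancer-death probability for diagnosis diameter ``d``."""
    lo, t_d = _window_bounds(d, params)
    return _marginal_at(d, params, t_d, removal=True)


def detection_probability(d: float, params: OutcomeParams) -> float:
    """Marginal probability of metastases detectable at diagnosis.

    Evaluates the removal-free kernel at ``t1(d) = t(d) - delta1``; small
    tumors whose seeding window has not yet opened score zero.
    """
    _, t_d = _window_bounds(d, params)
    return _marginal_at(d, params, t_d - params.delta1, removal=False)


def _marginal_curve(
    diameters: Sequence[float], params: OutcomeParams, kind: Literal["death", "detection"]
) -> np.ndarray:
    """Batch marginal death/detection probabilities over diameters."""
    b, w = params.prior.nodes(params.n_nodes)
    s1 = np.exp(-b)[np.newaxis, :]
    bounds = np.array([_window_bounds(d, params) for d in diameters])
    lo = bounds[:, 0][:, np.newaxis]
    t_d = bounds[:, 1][:, np.newaxis]
    if kind == "death":
        x, a = t_d, params.a
    else:
        x, a = t_d - params.delta1, None
    n = _windowed_attempts_batch(np.maximum(x, lo), lo, t_d, a, params)
    out = (-np.expm1(-s1 * n)) @ w
    return np.where(x[:, 0] <= lo[:, 0], 0.0, out)


# ---------------------------------------------------------------------------
# quantile times to death


def _windowed_attempts_batch(
    x: np.ndarray, lo: np.ndarray, treat: np.ndarray, a: float | None,
    params: OutcomeParams,
) -> np.ndarray:
    """N(x; a, delta0) broadcast over per-bin windows (closed form)."""
    pref, r = _attempts_pieces(params)
    c0 = 2.0 * r / 3.0
    plain = pref / c0 * (np.exp(c0 * x) - np.exp(c0 * lo))
    if a is None:
        return plain
    c = c0 + 1.0 / a
    removed = pref / c * (
        np.exp(c * x - treat / a) - np.exp(np.minimum(c * lo - treat / a, 700.0))
    )
    return np.maximum(plain - removed, 0.0)


def _quantile_roots_batch(
    diameters: Sequence[float],
    quantiles: Sequence[float],
    params: OutcomeParams,
    detected_only: bool,
    xtol: float = 1e-9,
    weighting: Literal["posterior", "prior"] = "posterior",
) -> np.ndarray:
    """Seeding-time quantile roots x_q, shape (n_diameters, n_quantiles).

    Solves G(x) = q by simultaneous bisection over all (diameter,
    quantile) pairs; G is continuous and non-decreasing in x on each
    bracket [lo_d, T_d].

    ``weighting`` selects the frailty treatment of the conditional
    seeding-time CDF among patients who die of cancer (with detectable
    metastases, for the detected-only variant):

    * ``"posterior"`` (default): G(x) = E_b[M(x)] / E_b[M(T)] — the
      severity distribution among dying patients is tilted toward weak
      bottlenecks by Bayes' rule, which is exactly the distribution the
      per-patient-frailty generative model produces;
    * ``"prior"``: G(x) = E_b[M(x)/M(T)] — the conditioning ratio taken
      inside the severity integral, i.e. every severity contributes its
      prior mass regardless of how likely it is to kill.
    """
    b, w = params.prior.nodes(params.n_nodes)
    s1 = np.exp(-b)[np.newaxis, np.newaxis, :]
    dd = np.asarray(diameters, dtype=float)
    q = np.asarray(quantiles, dtype=float)[np.newaxis, :]
    bounds = np.array([_window_bounds(d, params) for d in dd])
    lo = bounds[:, 0][:, np.newaxis, np.newaxis]
    t_d = bounds[:, 1][:, np.newaxis, np.newaxis]
    T = t_d - params.delta1 if detected_only else t_d
    if np.any(T <= lo):
        bad = dd[(T <= lo)[:, 0, 0]]
        raise ValueError(f"no attainable seeding window for diameter(s) {bad} cm")
    n_T = _windowed_attempts_batch(T, lo, t_d, params.a, params)
    lam_T = s1 * n_T
    m_T = -np.expm1(-lam_T)
    if weighting == "posterior":
        denom_marg = m_T @ w  # (nd, 1)
        if np.any(denom_marg <= 0):
            raise ValueError("zero marginal death probability; quantiles undefined")

        def g(x: np.ndarray) -> np.ndarray:
            n = _windowed_attempts_batch(x[..., np.newaxis], lo, t_d, params.a, params)
            return (-np.expm1(-s1 * n) @ w) / denom_marg

    else:
        tiny = lam_T < 1e-12

        def g(x: np.ndarray) -> np.ndarray:
            n = _windowed_attempts_batch(x[..., np.newaxis], lo, t_d, params.a, params)
            ratio = np.where(
                tiny,
                n / n_T,
                -np.expm1(-s1 * n) / np.where(m_T > 0, m_T, 1.0),
            )
            return ratio @ w

    shape = (dd.size, q.size)
    xlo = np.broadcast_to(lo[:, :, 0], shape).copy()
    xhi = np.broadcast_to(T[:, :, 0], shape).copy()
    for _ in range(int(np.ceil(np.log2(max(np.max(xhi - xlo) / xtol, 1.0)))) + 1):
        mid = 0.5 * (xlo + xhi)
        high = g(mid) >= q
        xhi = np.where(high, mid, xhi)
        xlo = np.where(high, xlo, mid)
    return 0.5 * (xlo + xhi)


def quantile_time_to_death(
    query: QuantileQuery,
    params: OutcomeParams,
    weighting: Literal["posterior", "prior"] = "posterior",
) -> float:
    """q-th quantile of post-diagnosis time to cancer death (years).

    Among patients who die of cancer (optionally restricted to those with
    metastases detectable at diagnosis): the seeding-time root ``x_q``
    plus the lethality lag ``delta0`` and treatment prolongation ``h``,
    counted from diagnosis ``t(d)``.  See ``_quantile_roots_batch`` for
    the frailty ``weighting`` choice.
    """
    x = _quantile_roots_batch(
        [query.d], [query.q], params, query.detected_only, weighting=weighting
    )[0, 0]
    t_d = time_of_diagnosis(query.d, params.growth)
    return float(x + params.delta0 - t_d + params.h)


def quantile_times_grid(
    diameters: Sequence[float],
    quantiles: Sequence[float],
    params: OutcomeParams,
    detected_only: bool = False,
    xtol: float = 1e-9,
    weighting: Literal["posterior", "prior"] = "posterior",
) -> np.ndarray:
    """Quantile times (rows: diameters, cols: quantiles), vectorized."""
    x = _quantile_roots_batch(
        diameters, quantiles, params, detected_only, xtol=xtol, weighting=weighting
    )
    t_d = np.array([time_of_diagnosis(d, params.growth) for d in diameters])
    return x + params.delta0 - t_d[:, np.newaxis] + params.h


def predict_survival_curve(
    diameters: Sequence[float],
    params: OutcomeParams,
    grid: Sequence[float],
) -> np.ndarray:
    """Cohort survival curve, conditional on death from cancer.

    For each patient, death time after diagnosis is ``x + delta0 + h -
    t(d)`` with ``x`` the (conditioned, removal-weighted) seeding time;
    its CDF is the normalized marginal used for quantile inversion.  The
    cohort curve averages the per-patient survival functions on ``grid``.
    """
    if len(diameters) == 0:
        raise ValueError("need at least one diameter")
    tau = np.asarray(grid, dtype=float)
    total = np.zeros_like(tau)
    b, w = params.prior.nodes(params.n_nodes)
    s1 = np.exp(-b)
    for d in diameters:
        lo, t_d = _window_bounds(d, params)
        n_T = _windowed_attempts_np(np.array([t_d]), lo, t_d, params.a, params)[0]
        denom = float((-np.expm1(-s1 * n_T)) @ w)
        if denom <= 0:
            raise ValueError(f"zero death probability at d={d} cm; curve undefined")
        x = np.clip(tau - params.delta0 - params.h + t_d, lo, t_d)
        n = _windowed_attempts_np(x, lo, t_d, params.a, params)
        cdf = (-np.expm1(-np.outer(n, s1)) @ w) / denom
        total += 1.0 - np.clip(cdf, 0.0, 1.0)
    return total / len(diameters)
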