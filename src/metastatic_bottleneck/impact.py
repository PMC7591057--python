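"""Predicted change in cancer-death probability under treatment changes.

Three scenarios are compared against the status quo, per fixed
bottleneck severity and marginalized over the severity distribution:

* ``surgery_delay``: the tumor keeps seeding for ``delay`` extra years
  before removal; death probability can only increase.
* ``chemo_boost``: systemic therapy removes more and larger metastases,
  modeled as multiplying the irremovability age ``a`` by ``c1 > 1``;
  death probability can only decrease.
* ``bottleneck_boost``: an intervention (e.g. a vaccine) strengthens the
  bottleneck by scaling the severity (or, marginally, the median of the
  severity distribution) by ``c2 > 1``; death probability decreases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .growth import time_of_diagnosis
from .outcome import BottleneckPrior, OutcomeParams, _marginal_at, _window_bounds

__all__ = ["Scenario", "impact_fixed_b", "impact_marginal", "impact_profile",
           "DEFAULT_DIAMETER_GRID", "DEFAULT_FIXED_B"]

#: Quarter-cm diameter lattice (bin midpoints) used for impact profiles.
DEFAULT_DIAMETER_GRID: tuple[float, ...] = tuple(
    round(0.125 + 0.25 * k, 3) for k in range(40)
)

#: Display set of fixed severities bracketing the 10-21-cell median range.
DEFAULT_FIXED_B: tuple[float, ...] = (12, 14, 16, 17, 18, 20)


@dataclass(frozen=True)
class Scenario:
    """One treatment-change scenario; exactly one knob is set."""

    kind: Literal["surgery_delay", "chemo_boost", "bottleneck_boost"]
    delay: float | None = None
    c1: float | None = None
    c2: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "surgery_delay":
            if self.delay is None or self.delay < 0 or self.c1 is not None or self.c2 is not None:
                raise ValueError("surgery_delay needs delay >= 0 (years) and no multipliers")
        elif self.kind == "chemo_boost":
            if self.c1 is None or not (self.c1 >= 1) or self.delay is not None or self.c2 is not None:
                raise ValueError("chemo_boost needs c1 >= 1 only")
        elif self.kind == "bottleneck_boost":
            if self.c2 is None or not (self.c2 >= 1) or self.delay is not None or self.c1 is not None:
                raise ValueError("bottleneck_boost needs c2 >= 1 only")
        else:
            raise ValueError(f"unknown scenario kind {self.kind!r}")


def _death_prob_point(d: float, b: float, params: OutcomeParams) -> float:
    """Conditioned death probability at diagnosis for fixed severity b."""
    p = params.with_(prior=BottleneckPrior.point(b))
    return _marginal_at(d, p, _window_bounds(d, p)[1], removal=True)


def _marginal_death_delayed(d: float, delay: float, params: OutcomeParams) -> float:
    # effective diagnosis at t(d) + delay: same tumor, longer seeding;
    # realized by a growth-equivalent diameter at the later time, which
    # shifts the conditioning window and treatment time together
    r = params.growth.rate_per_year
    # diameter after `delay` more years of exponential volume growth
    d_eff = d * math.exp(r * delay / 3.0)
    p = params.with_()
    return _marginal_at(d_eff, p, time_of_diagnosis(d_eff, p.growth), removal=True)


def impact_fixed_b(
    d: float, b: float, scenario: Scenario, params: OutcomeParams
) -> float:
    """Signed change in cancer-death probability for fixed severity ``b``."""
    if not (d > 0 and b > 0):
        raise ValueError("d and b must be positive")
    base = _death_prob_point(d, b, params)
    if scenario.kind == "surgery_delay":
        p = params.with_(prior=BottleneckPrior.point(b))
        return _marginal_death_delayed(d, scenario.delay, p) - base
    if scenario.kind == "chemo_boost":
        return _death_prob_point(d, b, params.with_(a=scenario.c1 * params.a)) - base
    return _death_prob_point(d, scenario.c2 * b, params) - base


def impact_marginal(d: float, scenario: Scenario, params: OutcomeParams) -> float:
    """Signed change in the marginal (severity-averaged) death probability."""
    if not (d > 0):
        raise ValueError("d must be positive")
    base = _marginal_at(d, params, _window_bounds(d, params)[1], removal=True)
    if scenario.kind == "surgery_delay":
        return _marginal_death_delayed(d, scenario.delay, params) - base
    if scenario.kind == "chemo_boost":
        p = params.with_(a=scenario.c1 * params.a)
        return _marginal_at(d, p, _window_bounds(d, p)[1], removal=True) - base
    if params.prior.kind == "point":
        raise ValueError(
            "bottleneck_boost on a point prior has no marginal form; "
            "use impact_fixed_b"
        )
    p = params.with_(prior=params.prior.shifted(math.log(scenario.c2)))
    return _marginal_at(d, p, _window_bounds(d, p)[1], removal=True) - base


def impact_profile(
    scenario: Scenario,
    params: OutcomeParams,
    diameters: Sequence[float] = DEFAULT_DIAMETER_GRID,
    fixed_b: Sequence[float] = DEFAULT_FIXED_B,
) -> pd.DataFrame:
    """Impact-vs-diameter table for fixed severities plus the marginal.

    Tidy frame with columns ``diameter_cm``, ``curve`` ("b=<value>" or
    "marginal"), ``impact``; the per-curve arg-max diameter is stored in
    ``DataFrame.attrs["argmax_diameter"]``.
    """
    if len(diameters) == 0:
        raise ValueError("need a non-empty diameter grid")
    rows = []
    for b in fixed_b:
        for d in diameters:
            rows.append(("b=%g" % b, d, impact_fixed_b(d, b, scenario, params)))
    if params.prior.kind == "lognormal" or scenario.kind != "bottleneck_boost":
        for d in diameters:
            rows.append(("marginal", d, impact_marginal(d, scenario, params)))
    out = pd.DataFrame(rows, columns=["curve", "diameter_cm", "impact"])
    argmax = {
        curve: grp.loc[grp["impact"].abs().idxmax(), "diameter_cm"]
        for curve, grp in out.groupby("curve")
    }
    out.attrs["argmax_diameter"] = argmax
    return out
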