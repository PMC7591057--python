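"""Reference study conditions for a generic solid carcinoma.

One bundled parameter set used by the documentation examples, the test
suite and the acceptance runs.  The values are chosen to be
representative of the fitted per-cancer ranges: doubling time 150 days,
metastasis-to-lethality lag delta0 = 6 y with detectability lag
delta1 = 5.5 y close below it, irremovability age a at its 1-year upper
bound, treatment prolongation h = 1 y, and a log-normal severity
distribution with median 17 cells (the most common fitted median) and
scale 0.8.  The synthetic-cohort defaults emulate a registry extract:
log-normal diameters with median 2 cm truncated to 0.2-10 cm,
other-cause mortality at a constant 1 %/year, administrative censoring
at 25 years.
"""

from __future__ import annotations

import math

from .cohort import CohortConfig, DiameterLaw
from .growth import GrowthLaw
from .outcome import BottleneckPrior, OutcomeParams

__all__ = ["demo_growth", "demo_params", "demo_cohort_config"]


def demo_growth() -> GrowthLaw:
    return GrowthLaw(doubling_time_days=150.0)


def demo_params(
    median_b: float = 17.0,
    sigma: float = 0.8,
    delta0: float = 6.0,
    delta1: float = 5.5,
    a: float = 1.0,
    h: float = 1.0,
) -> OutcomeParams:
    return OutcomeParams(
        delta0=delta0,
        delta1=delta1,
        a=a,
        h=h,
        prior=BottleneckPrior.lognormal(math.log(median_b), sigma),
        growth=demo_growth(),
    )


def demo_cohort_config(n_patients: int = 50_000, seed: int = 0) -> CohortConfig:
    return CohortConfig(
        n_patients=n_patients,
        outcome=demo_params(),
        diameter_law=DiameterLaw(median_cm=2.0, sigma_log=0.6, lo_cm=0.2, hi_cm=10.0),
        other_cause_hazard=0.01,
        follow_up_years=25.0,
        seed=seed,
    )
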