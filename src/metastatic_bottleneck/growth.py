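"""Primary-tumor kinetics and the cumulative count of seeding attempts.

The primary tumor is an exponentially growing sphere.  It sheds cells
from its surface into circulation; each shed cell extravasates into a
secondary site with probability ``p_e`` and there constitutes one
metastatic seeding attempt.  The shedding rate scales with tumor surface
area, i.e. with volume to the power 2/3, and is calibrated so that a
1-gram (1 cm^3, ~1e9 cells) tumor sheds ``shed_rate_at_1g`` cells per
day before extravasation.

All public times are in years (365.24 days), diameters in cm, volumes
in cm^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "DAYS_PER_YEAR",
    "GrowthLaw",
    "SeedingWindow",
    "cells_at_diameter",
    "diameter_at_cells",
    "time_of_diagnosis",
    "attempt_rate",
    "cumulative_attempts",
    "windowed_attempts",
]

DAYS_PER_YEAR = 365.24


@dataclass(frozen=True)
class GrowthLaw:
    """Exponential spherical growth plus surface shedding.

    Parameters
    ----------
    doubling_time_days
        Tumor volume doubling time ``D`` in days (cancer-specific).
    cell_density
        Cells per cm^3 of tumor tissue; 1e9 joins "1 gram ~ 1e9 cells"
        with unit tissue density (1 g = 1 cm^3).
    shed_rate_at_1g
        Cells shed per day by a 1-gram tumor (calibration point).
    extravasation_prob
        Probability ``p_e`` that a shed cell extravasates at a
        secondary site.
    initial_cells
        Tumor size at onset (t = 0); one founding cell by default.
    """

    doubling_time_days: float
    cell_density: float = 1e9
    shed_rate_at_1g: float = 1.5e5
    extravasation_prob: float = 0.8
    initial_cells: float = 1.0

    def __post_init__(self) -> None:
        if not (self.doubling_time_days > 0):
            raise ValueError("doubling_time_days must be positive")
        if not (0 < self.extravasation_prob <= 1):
            raise ValueError("extravasation_prob must be in (0, 1]")
        if not (self.cell_density > 0):
            raise ValueError("cell_density must be positive")
        if self.shed_rate_at_1g < 0:
            raise ValueError("shed_rate_at_1g must be non-negative")
        if not (self.initial_cells >= 1):
            raise ValueError("initial_cells must be >= 1")

    @property
    def rate_per_year(self) -> float:
        """Exponential growth rate r = ln(2) * 365.24 / D (per year)."""
        return math.log(2.0) * DAYS_PER_YEAR / self.doubling_time_days

    @property
    def initial_volume_cm3(self) -> float:
        return self.initial_cells / self.cell_density

    @property
    def attempts_per_year_at_1cm3(self) -> float:
        """Extravasated seeding attempts per year from a 1-cm^3 tumor."""
        return self.extravasation_prob * self.shed_rate_at_1g * DAYS_PER_YEAR


@dataclass(frozen=True)
class SeedingWindow:
    """Time window of seeding attempts that matter for an outcome.

    Attempts between ``t_start`` and ``t_end`` (years since tumor onset)
    are counted; ``treatment_time`` is the diagnosis/surgery time t(d).
    When ``removal_scale`` (the expected metastasis age ``a`` at which
    it becomes irremovable) is given, each attempt at time u is weighted
    by the probability 1 - exp(-(treatment_time - u)/a) that it is *not*
    removed by post-surgical treatment; ``removal_scale=None`` means no
    removal weighting (weight one).
    """

    t_start: float
    t_end: float
    treatment_time: float
    removal_scale: float | None = None

    def __post_init__(self) -> None:
        if not (self.t_start <= self.t_end <= self.treatment_time):
            raise ValueError(
                f"require t_start <= t_end <= treatment_time, got "
                f"({self.t_start}, {self.t_end}, {self.treatment_time})"
            )
        if self.removal_scale is not None and not (self.removal_scale > 0):
            raise ValueError("removal_scale must be positive when present")


def cells_at_diameter(d: float, law: GrowthLaw) -> float:
    """Cell count of a spherical tumor of diameter ``d`` cm."""
    if not (d > 0):
        raise ValueError(f"diameter must be positive, got {d}")
    return law.cell_density * math.pi * d**3 / 6.0


def diameter_at_cells(n: float, law: GrowthLaw) -> float:
    """Diameter (cm) of a spherical tumor of ``n`` cells (inverse map)."""
    if not (n > 0):
        raise ValueError("cell count must be positive")
    return (6.0 * n / (law.cell_density * math.pi)) ** (1.0 / 3.0)


def time_of_diagnosis(d: float, law: GrowthLaw) -> float:
    """Years from tumor onset until the tumor reaches diameter ``d`` cm."""
    n = cells_at_diameter(d, law)
    if n < law.initial_cells:
        raise ValueError(
            f"tumor of diameter {d} cm ({n:.3g} cells) is smaller than the "
            f"initial size of {law.initial_cells} cells"
        )
    return math.log(n / law.initial_cells) / law.rate_per_year


def attempt_rate(u: float, law: GrowthLaw) -> float:
    """Seeding-attempt rate (per year) ``u`` years after tumor onset.

    rate(u) = p_e * k * (V(u) / 1 cm^3)^(2/3) with V(u) the tumor volume
    and k the per-year shedding constant of a 1-cm^3 tumor.
    """
    if u < 0:
        raise ValueError("time since onset must be non-negative")
    v = law.initial_volume_cm3 * math.exp(law.rate_per_year * u)
    return law.attempts_per_year_at_1cm3 * v ** (2.0 / 3.0)


def cumulative_attempts(t: float, law: GrowthLaw) -> float:
    """Expected seeding attempts N(t) from onset to ``t`` years.

    Closed form of the integral of ``attempt_rate``:
    N(t) = p_e k V0^(2/3) * (3/(2r)) * (exp(2rt/3) - 1).
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    r = law.rate_per_year
    pref = law.attempts_per_year_at_1cm3 * law.initial_volume_cm3 ** (2.0 / 3.0)
    return pref * 1.5 / r * (math.exp(2.0 * r * t / 3.0) - 1.0)


def _attempts_between(t0: float, t1: float, law: GrowthLaw) -> float:
    return cumulative_attempts(t1, law) - cumulative_attempts(t0, law)


def windowed_attempts(t: float, window: SeedingWindow, law: GrowthLaw) -> float:
    """Expected irremovable attempts N(t; a, delta0) up to ``t`` years.

    Integrates ``attempt_rate(u) * w(u)`` over ``[max(t_start, 0), t]``
    with removal weight ``w(u) = 1 - exp(-(T - u)/a)`` (T the treatment
    time) when a removal scale is present, ``w = 1`` otherwise.  Both
    pieces have closed antiderivatives:

        integral of rate(u) exp(u/a) du
            = pref * exp(c u) / c,   c = 2r/3 + 1/a,

    so the weighted integral is the plain count minus
    ``pref * exp(-T/a) * (exp(c t) - exp(c t0)) / c``.
    """
    lo = max(window.t_start, 0.0)
    if not (lo <= t <= window.treatment_time + 1e-12):
        raise ValueError(
            f"t={t} outside the seeding window [{lo}, {window.treatment_time}]"
        )
    plain = _attempts_between(lo, t, law)
    a = window.removal_scale
    if a is None:
        return plain
    r = law.rate_per_year
    pref = law.attempts_per_year_at_1cm3 * law.initial_volume_cm3 ** (2.0 / 3.0)
    c = 2.0 * r / 3.0 + 1.0 / a
    # removed-mass integral: pref * e^{-T/a} * (e^{c t} - e^{c lo}) / c,
    # computed as exp(c u - T/a) termwise to avoid overflow at tiny a
    removed = pref / c * (
        math.exp(c * t - window.treatment_time / a)
        - math.exp(c * lo - window.treatment_time / a)
    )
    return max(plain - removed, 0.0)
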