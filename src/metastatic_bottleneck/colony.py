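"""Inhomogeneous birth-death process of metastatic colony initiation.

A newly seeded colony of ``i`` tumor cells at a secondary site grows or
shrinks one cell at a time.  The per-cell proliferation-to-death rate
ratio increases with colony size (an Allee effect): ``lambda_i / mu_i =
i / b``, where ``b`` is the *bottleneck severity*.  Only this ratio is
identifiable from extinction probabilities, so the process is represented
by its embedded jump chain with upward jump probability

    p_i = (i/b) / (1 + i/b) = i / (i + b).

Colonies below the critical size ``ceil(b)`` are subcritical and usually
go extinct; above it they are supercritical.  The survival (non-extinction)
probability starting from ``i`` cells has the closed form
``s_i(b) = F_Pois(i - 1; b)``, the Poisson CDF with mean ``b``; in
particular a single seeded cell survives with probability
``s_1(b) = exp(-b)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ColonyLaw",
    "ColonyTrajectory",
    "jump_probability",
    "survival_probability",
    "critical_size",
    "simulate_colony",
    "simulate_survival_fraction",
]


@dataclass(frozen=True)
class ColonyLaw:
    """Bottleneck severity ``b`` (cells) defining the colony jump chain."""

    b: float

    def __post_init__(self) -> None:
        if not (self.b > 0):
            raise ValueError(f"bottleneck severity b must be positive, got {self.b}")


@dataclass(frozen=True)
class ColonyTrajectory:
    """One Monte-Carlo realization of the colony size chain.

    ``sizes`` records the colony size after every jump (starting at the
    initial size); consecutive entries differ by exactly one cell.  The
    walk is absorbed at 0 (``extinct``) or declared ``survived`` on
    reaching ``cap`` cells, far above the critical size.
    """

    sizes: Sequence[int]
    outcome: Literal["extinct", "survived"]
    cap: int

    def __post_init__(self) -> None:
        last = self.sizes[-1]
        if self.outcome == "extinct" and last != 0:
            raise ValueError("extinct trajectory must end at size 0")
        if self.outcome == "survived" and last < self.cap:
            raise ValueError("survived trajectory must end at or above cap")


def _check_size(i: int) -> None:
    if not (isinstance(i, (int, np.integer)) and not isinstance(i, bool)) or i < 1:
        raise ValueError(f"colony size must be an integer >= 1, got {i!r}")


def jump_probability(i: int, law: ColonyLaw) -> float:
    """Probability that a colony of ``i`` cells grows to ``i + 1``.

    Equals ``i / (i + b)``; crosses 1/2 exactly at ``i = b``.
    """
    _check_size(i)
    return i / (i + law.b)


def survival_probability(i: int, law: ColonyLaw) -> float:
    """Probability that a colony of ``i`` cells never goes extinct.

    ``s_i(b) = F_Pois(i - 1; b)``; at ``i = 1`` this is ``exp(-b)``.
    """
    _check_size(i)
    return float(stats.poisson.cdf(i - 1, law.b))


def critical_size(law: ColonyLaw) -> int:
    """Critical colony size ``ceil(b)`` at which survival odds flip."""
    return int(ceil(law.b))


def default_cap(law: ColonyLaw) -> int:
    """Default survival-declaration threshold: 50 times the critical size."""
    return 50 * critical_size(law)


def simulate_colony(
    i0: int,
    law: ColonyLaw,
    cap: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> ColonyTrajectory:
    """Simulate one colony from ``i0`` cells until extinction or ``cap``.

    The embedded discrete chain steps +1 with probability ``p_i`` and -1
    otherwise; only the ratio ``lambda_i/mu_i`` matters for the outcome,
    so no continuous-time clock is attached.
    """
    _check_size(i0)
    if cap is None:
        cap = default_cap(law)
    if cap <= critical_size(law):
        raise ValueError(
            f"cap={cap} must exceed the critical size {critical_size(law)}; "
            "survival declaration below it is unreliable"
        )
    rng = np.random.default_rng(seed)
    sizes = [i0]
    i = i0
    while 0 < i < cap:
        p = i / (i + law.b)
        i += 1 if rng.random() < p else -1
        sizes.append(i)
    return ColonyTrajectory(
        sizes=sizes, outcome="extinct" if i == 0 else "survived", cap=cap
    )


def simulate_survival_fraction(
    i0: int,
    law: ColonyLaw,
    replicates: int,
    cap: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Empirical survival fraction over many colonies (vectorized walkers).

    All replicates advance in lockstep; each batch of jumps is drawn at
    once and walkers are retired as they hit 0 or ``cap``.  Used as the
    Monte-Carlo oracle for the analytic ``survival_probability``.
    """
    _check_size(i0)
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if cap is None:
        cap = default_cap(law)
    if cap <= critical_size(law):
        raise ValueError(f"cap={cap} must exceed the critical size {critical_size(law)}")
    rng = np.random.default_rng(seed)
    sizes = np.full(replicates, i0, dtype=np.int64)
    active = np.ones(replicates, dtype=bool)
    survived = np.zeros(replicates, dtype=bool)
    while active.any():
        i = sizes[active]
        up = rng.random(i.size) < i / (i + law.b)
        i = np.where(up, i + 1, i - 1)
        sizes[active] = i
        done_up = i >= cap
        done_dn = i <= 0
        idx = np.flatnonzero(active)
        survived[idx[done_up]] = True
        active[idx[done_up | done_dn]] = False
    return float(survived.mean())
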