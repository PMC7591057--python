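"""Per-cancer run configuration: YAML/JSON round-tripping of the model
objects, with strict (unknown-key-rejecting) parsing.

A run config bundles the growth law, outcome parameters, fit spec and
cohort-generator settings for one cancer type under one root seed;
every stage of the pipeline derives its randomness from named
substreams of that seed.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .cohort import CohortConfig, DiameterLaw
from .fitting import FitSpec
from .growth import GrowthLaw
from .outcome import BottleneckPrior, OutcomeParams

__all__ = ["RunConfig", "load_config", "save_config", "substream_seed"]


def _strict(d: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where} config")


def growth_from_dict(d: Mapping[str, Any]) -> GrowthLaw:
    _strict(d, {"doubling_time_days", "cell_density", "shed_rate_at_1g",
                "extravasation_prob", "initial_cells"}, "growth")
    return GrowthLaw(**d)


def growth_to_dict(g: GrowthLaw) -> dict[str, Any]:
    return {
        "doubling_time_days": g.doubling_time_days,
        "cell_density": g.cell_density,
        "shed_rate_at_1g": g.shed_rate_at_1g,
        "extravasation_prob": g.extravasation_prob,
        "initial_cells": g.initial_cells,
    }


def prior_from_dict(d: Mapping[str, Any]) -> BottleneckPrior:
    _strict(d, {"kind", "mu", "sigma", "b0"}, "prior")
    return BottleneckPrior(**d)


def prior_to_dict(p: BottleneckPrior) -> dict[str, Any]:
    if p.kind == "point":
        return {"kind": "point", "b0": p.b0}
    return {"kind": "lognormal", "mu": p.mu, "sigma": p.sigma}


def outcome_from_dict(d: Mapping[str, Any], growth: GrowthLaw) -> OutcomeParams:
    _strict(d, {"delta0", "delta1", "a", "h", "prior", "n_nodes"}, "outcome")
    d = dict(d)
    prior = prior_from_dict(d.pop("prior"))
    return OutcomeParams(prior=prior, growth=growth, **d)


def outcome_to_dict(p: OutcomeParams) -> dict[str, Any]:
    return {
        "delta0": p.delta0, "delta1": p.delta1, "a": p.a, "h": p.h,
        "prior": prior_to_dict(p.prior), "n_nodes": p.n_nodes,
    }


def fitspec_from_dict(d: Mapping[str, Any]) -> FitSpec:
    allowed = {"quantiles", "detection_weight", "quantile_weight", "restarts",
               "generations", "tol", "polish_maxfev", "seed", "n_nodes",
               "quantile_xtol"}
    _strict(d, allowed, "fit")
    d = dict(d)
    if "quantiles" in d:
        d["quantiles"] = tuple(d["quantiles"])
    return FitSpec(**d)


def fitspec_to_dict(s: FitSpec) -> dict[str, Any]:
    return {
        "quantiles": list(s.quantiles),
        "detection_weight": s.detection_weight,
        "quantile_weight": s.quantile_weight,
        "restarts": s.restarts,
        "generations": s.generations,
        "tol": s.tol,
        "polish_maxfev": s.polish_maxfev,
        "seed": s.seed,
        "n_nodes": s.n_nodes,
        "quantile_xtol": s.quantile_xtol,
    }


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs, serializable to YAML."""

    cancer_label: str
    growth: GrowthLaw
    outcome: OutcomeParams
    fit: FitSpec = field(default_factory=FitSpec)
    n_patients: int = 50_000
    diameter_law: DiameterLaw = field(default_factory=DiameterLaw)
    other_cause_hazard: float = 0.01
    follow_up_years: float = 20.0
    seed: int = 0
    output_dir: str = "out"
    log_level: str = "INFO"

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            n_patients=self.n_patients,
            outcome=self.outcome,
            diameter_law=self.diameter_law,
            other_cause_hazard=self.other_cause_hazard,
            follow_up_years=self.follow_up_years,
            seed=substream_seed(self.seed, "synthesize"),
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "cancer_label": self.cancer_label,
            "growth": growth_to_dict(self.growth),
            "outcome": outcome_to_dict(self.outcome),
            "fit": fitspec_to_dict(self.fit),
            "cohort": {
                "n_patients": self.n_patients,
                "diameter_law": {
                    "median_cm": self.diameter_law.median_cm,
                    "sigma_log": self.diameter_law.sigma_log,
                    "lo_cm": self.diameter_law.lo_cm,
                    "hi_cm": self.diameter_law.hi_cm,
                },
                "other_cause_hazard": self.other_cause_hazard,
                "follow_up_years": self.follow_up_years,
            },
            "seed": self.seed,
            "output_dir": self.output_dir,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        _strict(d, {"cancer_label", "growth", "outcome", "fit", "cohort",
                    "seed", "output_dir", "log_level"}, "run")
        growth = growth_from_dict(d["growth"])
        outcome = outcome_from_dict(d["outcome"], growth)
        fitspec = fitspec_from_dict(d.get("fit", {}))
        cohort = dict(d.get("cohort", {}))
        _strict(cohort, {"n_patients", "diameter_law", "other_cause_hazard",
                         "follow_up_years"}, "cohort")
        dl = dict(cohort.get("diameter_law", {}))
        _strict(dl, {"median_cm", "sigma_log", "lo_cm", "hi_cm"}, "diameter_law")
        return cls(
            cancer_label=d["cancer_label"],
            growth=growth,
            outcome=outcome,
            fit=fitspec,
            n_patients=cohort.get("n_patients", 50_000),
            diameter_law=DiameterLaw(**dl),
            other_cause_hazard=cohort.get("other_cause_hazard", 0.01),
            follow_up_years=cohort.get("follow_up_years", 20.0),
            seed=d.get("seed", 0),
            output_dir=d.get("output_dir", "out"),
            log_level=d.get("log_level", "INFO"),
        )

    def digest(self) -> str:
        """Stable hash of the canonical serialized form."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def substream_seed(root_seed: int, name: str) -> int:
    """Deterministic per-stage seed derived from the root seed (< 2^31)."""
    h = hashlib.sha256(f"{root_seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)
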