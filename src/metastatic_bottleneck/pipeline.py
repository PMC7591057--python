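"""Stage runner: synthesize -> summarize -> fit -> validate / impact /
predict, with a manifest recording seeds, hashes and artifact paths.

Rerunning with the same config reproduces identical CSV/JSON artifacts;
every stage reads only artifacts listed in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import generate_cohort, read_cohort_csv, write_cohort_csv
from .config import RunConfig, outcome_to_dict, substream_seed
from .fitting import FitResult, OutcomeCurveFitter, validate
from .impact import Scenario, impact_profile
from .outcome import OutcomeParams, predict_survival_curve
from .summaries import BinScheme, summarize, write_summary_csv

__all__ = ["run_pipeline", "STAGES"]

STAGES = ("synthesize", "summarize", "fit", "validate", "impact", "predict")

log = logging.getLogger("metastatic_bottleneck")


class DependencyError(RuntimeError):
    """A stage was requested before the stage that feeds it."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _need(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"stage '{needed_by}' needs the output of stage '{stage}' "
            f"({path.name}); run it first or include it in --stages"
        )
    return path


def _fit_result_to_dict(result: FitResult, config: RunConfig) -> dict:
    return {
        "cancer_label": config.cancer_label,
        "config_digest": config.digest(),
        "seed": config.seed,
        "reduced": result.reduced,
        "params": outcome_to_dict(result.params),
        "loss": result.loss,
        "rmse_detection": result.rmse_detection,
        "rmse_quantiles": {str(k): v for k, v in result.rmse_quantiles.items()},
        "converged": result.converged,
        "restart_table": result.restart_table.to_dict(orient="records"),
    }


def _load_fitted_params(out: Path, config: RunConfig) -> OutcomeParams:
    """Fitted params if the fit stage ran, else the configured ones."""
    fit_path = out / "fit.json"
    if fit_path.exists():
        from .config import outcome_from_dict

        blob = json.loads(fit_path.read_text())
        return outcome_from_dict(blob["params"], config.growth)
    return config.outcome


def run_pipeline(
    config: RunConfig,
    stages: Sequence[str] = STAGES,
    reduced: bool = False,
    scenarios: Sequence[Scenario] | None = None,
) -> dict:
    """Execute the requested stages in canonical order; return the manifest."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s) {sorted(unknown)}")
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, dict] = {}

    def record(stage: str, *paths: Path) -> None:
        artifacts[stage] = {p.name: _sha256(p) for p in paths}

    if "synthesize" in stages:
        cc = config.cohort_config()
        log.info("synthesize: %d patients, seed %d", cc.n_patients, cc.seed)
        cohort = generate_cohort(cc, with_truth=True)
        write_cohort_csv(cohort, out / "cohort.csv")
        record("synthesize", out / "cohort.csv")

    if "summarize" in stages:
        path = _need(out / "cohort.csv", "synthesize", "summarize")
        cohort = read_cohort_csv(path)
        summary = summarize(cohort, BinScheme(), horizon=config.follow_up_years)
        write_summary_csv(summary, out / "summary.csv")
        record("summarize", out / "summary.csv")

    if "fit" in stages:
        _need(out / "cohort.csv", "synthesize", "fit")
        _need(out / "summary.csv", "summarize", "fit")
        cohort = read_cohort_csv(out / "cohort.csv")
        summary = summarize(cohort, BinScheme(), horizon=config.follow_up_years)
        spec = config.fit
        if spec.seed == 0:
            from dataclasses import replace

            spec = replace(spec, seed=substream_seed(config.seed, "fit"))
        fitter = OutcomeCurveFitter(config.growth, spec, reduced=reduced).fit(summary)
        (out / "fit.json").write_text(
            json.dumps(_fit_result_to_dict(fitter.result_, config), indent=2)
        )
        record("fit", out / "fit.json")

    if "validate" in stages:
        _need(out / "fit.json", "fit", "validate")
        _need(out / "cohort.csv", "synthesize", "validate")
        cohort = read_cohort_csv(out / "cohort.csv")
        summary = summarize(cohort, BinScheme(), horizon=config.follow_up_years)
        blob = json.loads((out / "fit.json").read_text())
        from .config import outcome_from_dict

        params = outcome_from_dict(blob["params"], config.growth)
        result = FitResult(
            params=params, loss=blob["loss"],
            rmse_detection=blob["rmse_detection"],
            rmse_quantiles={float(k): v for k, v in blob["rmse_quantiles"].items()},
            converged=blob["converged"],
            restart_table=pd.DataFrame(blob["restart_table"]),
            reduced=blob["reduced"],
        )
        report = validate(result, summary)
        payload = {
            "frac_inside_band": report["frac_inside_band"],
            "rmse_death_km": report["rmse_death_km"],
            "rmse_detected_median": report["rmse_detected_median"],
            "death_probability": report["death_probability"].to_dict(orient="records"),
            "detected_median": report["detected_median"].to_dict(orient="records"),
        }
        (out / "validation.json").write_text(json.dumps(payload, indent=2))
        record("validate", out / "validation.json")

    if "impact" in stages:
        params = _load_fitted_params(out, config)
        scen = scenarios or (
            Scenario(kind="surgery_delay", delay=16 / 52.18),
            Scenario(kind="chemo_boost", c1=1.2),
            Scenario(kind="bottleneck_boost", c2=1.2),
        )
        frames = []
        for s in scen:
            prof = impact_profile(s, params)
            prof.insert(0, "scenario", s.kind)
            frames.append(prof)
        pd.concat(frames).to_csv(out / "impact.csv", index=False, float_format="%.10g")
        record("impact", out / "impact.csv")

    if "predict" in stages:
        params = _load_fitted_params(out, config)
        path = _need(out / "cohort.csv", "synthesize", "predict")
        cohort = read_cohort_csv(path)
        diam = [p.diameter_cm for p in cohort[:500]]
        grid = np.linspace(0.0, params.delta0 + params.h, 200)
        surv = predict_survival_curve(diam, params, grid)
        pd.DataFrame({"time_years": grid, "survival": surv}).to_csv(
            out / "survival.csv", index=False, float_format="%.10g"
        )
        record("predict", out / "survival.csv")

    manifest = {
        "cancer_label": config.cancer_label,
        "config_digest": config.digest(),
        "seed": config.seed,
        "stages": list(stages),
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
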