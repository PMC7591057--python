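"""Diameter-binned cohort summaries and monotone-trend screening.

A patient-level cohort is reduced to the per-diameter-bin statistics the
model is fitted to and validated against: metastasis-detection
frequency, three cancer-death estimators that bracket the unobservable
cause-specific death probability (upper bound: all deaths count; lower
bound: other-cause deaths count as alive; Kaplan-Meier: other-cause
deaths censored), and empirical quantile times to death among cancer
deaths (all patients and the detected-at-diagnosis subset).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .cohort import PatientRecord
from .outcome import DEFAULT_QUANTILES

__all__ = [
    "BinScheme",
    "DiameterSummary",
    "summarize",
    "summary_to_frame",
    "write_summary_csv",
    "read_summary_frame",
    "trend_test",
]


@dataclass(frozen=True)
class BinScheme:
    """Diameter bins of fixed width with midpoints on a regular lattice.

    Defaults give quarter-cm bins with midpoints 0.125, 0.375, ... cm.
    ``min_occupancy`` patients (and ``min_deaths`` cancer deaths for
    quantile rows) are required before a statistic is reported; sparse
    bins yield missing values, never fabricated numbers.
    """

    width_cm: float = 0.25
    origin_cm: float = 0.0
    min_occupancy: int = 20
    min_deaths: int = 10

    def bin_mid(self, d: np.ndarray) -> np.ndarray:
        idx = np.floor((d - self.origin_cm) / self.width_cm)
        return self.origin_cm + (idx + 0.5) * self.width_cm


@dataclass(frozen=True)
class DiameterSummary:
    """Per-bin summary statistics.

    ``n_cancer_deaths`` / ``n_detected_deaths`` are the sample sizes
    behind the (all-patients / detected-subset) quantile times; they let
    downstream fits weight empirical quantiles by their sampling error.
    """

    bin_mid_cm: float
    n: int
    detection_freq: float
    death_upper: float
    death_lower: float
    death_km: float
    quantile_times: Mapping[float, float]
    quantile_times_detected: Mapping[float, float]
    n_cancer_deaths: int = 0
    n_detected_deaths: int = 0


def _km_death_prob(times: np.ndarray, is_cancer: np.ndarray, horizon: float) -> float:
    """1 - S(horizon) by product-limit, other deaths/censoring censored."""
    km = KaplanMeierFitter()
    km.fit(times, event_observed=is_cancer)
    return float(1.0 - km.predict(horizon))


def summarize(
    cohort: Sequence[PatientRecord],
    bins: BinScheme | None = None,
    quantiles: Sequence[float] = DEFAULT_QUANTILES,
    horizon: float | None = None,
) -> list[DiameterSummary]:
    """Reduce a cohort to per-diameter-bin summaries.

    ``horizon`` (years) is the evaluation time of the Kaplan-Meier death
    probability; defaults to the largest observed time.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    bins = bins or BinScheme()
    df = pd.DataFrame(
        {
            "d": [p.diameter_cm for p in cohort],
            "det": [p.met_detected for p in cohort],
            "event": [p.event for p in cohort],
            "t": [p.time_years for p in cohort],
        }
    )
    df["mid"] = bins.bin_mid(df["d"].to_numpy())
    if horizon is None:
        horizon = float(df["t"].max())
    out: list[DiameterSummary] = []
    for mid, grp in df.groupby("mid", sort=True):
        n = len(grp)
        if n < bins.min_occupancy:
            out.append(
                DiameterSummary(
                    bin_mid_cm=float(mid), n=n,
                    detection_freq=math.nan, death_upper=math.nan,
                    death_lower=math.nan, death_km=math.nan,
                    quantile_times={q: math.nan for q in quantiles},
                    quantile_times_detected={q: math.nan for q in quantiles},
                    n_cancer_deaths=0, n_detected_deaths=0,
                )
            )
            continue
        is_cancer = (grp["event"] == "cancer_death").to_numpy()
        any_death = is_cancer | (grp["event"] == "other_death").to_numpy()
        times = grp["t"].to_numpy()
        death_upper = float(any_death.mean())
        death_lower = float(is_cancer.mean())
        death_km = _km_death_prob(times, is_cancer, horizon)
        cancer_times = times[is_cancer]
        det_times = times[is_cancer & grp["det"].to_numpy()]

        def qmap(ts: np.ndarray) -> dict[float, float]:
            if ts.size < bins.min_deaths:
                return {q: math.nan for q in quantiles}
            return {q: float(np.quantile(ts, q)) for q in quantiles}

        out.append(
            DiameterSummary(
                bin_mid_cm=float(mid), n=n,
                detection_freq=float(grp["det"].mean()),
                death_upper=death_upper, death_lower=death_lower,
                death_km=death_km,
                quantile_times=qmap(cancer_times),
                quantile_times_detected=qmap(det_times),
                n_cancer_deaths=int(cancer_times.size),
                n_detected_deaths=int(det_times.size),
            )
        )
    return out


def summary_to_frame(summary: Sequence[DiameterSummary]) -> pd.DataFrame:
    """Tidy frame keyed by (bin_mid_cm, statistic, quantile)."""
    rows = []
    for s in summary:
        for name, val in (
            ("n", s.n),
            ("n_cancer_deaths", s.n_cancer_deaths),
            ("n_detected_deaths", s.n_detected_deaths),
            ("detection_freq", s.detection_freq),
            ("death_upper", s.death_upper),
            ("death_lower", s.death_lower),
            ("death_km", s.death_km),
        ):
            rows.append((s.bin_mid_cm, name, math.nan, val))
        for q, v in s.quantile_times.items():
            rows.append((s.bin_mid_cm, "quantile_time", q, v))
        for q, v in s.quantile_times_detected.items():
            rows.append((s.bin_mid_cm, "quantile_time_detected", q, v))
    return pd.DataFrame(rows, columns=["bin_mid_cm", "statistic", "quantile", "value"])


def write_summary_csv(summary: Sequence[DiameterSummary], path) -> None:
    summary_to_frame(summary).to_csv(path, index=False, float_format="%.10g")


def read_summary_frame(path) -> pd.DataFrame:
    return pd.read_csv(path)


def trend_test(values: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Kendall trend test with tie correction.

    Returns ``(S, p)``: the Kendall score ``S = sum sign(x_j - x_i)``
    over ordered pairs, and the two-sided p-value from the
    continuity-corrected normal approximation with the tie-adjusted
    variance.  Requires at least four non-missing points.
    """
    x = np.asarray([v for v in values if not (isinstance(v, float) and math.isnan(v))],
                   dtype=float)
    n = x.size
    if n < 4:
        raise ValueError(f"trend test needs >= 4 non-missing values, got {n}")
    diffs = np.sign(x[np.newaxis, :] - x[:, np.newaxis])
    s = float(np.triu(diffs, k=1).sum())
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var <= 0:
        return s, 1.0
    z = (s - np.sign(s)) / math.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return s, min(p, 1.0)
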