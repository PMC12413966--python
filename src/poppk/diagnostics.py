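"""Predictive-performance metrics, goodness-of-fit and distribution summaries.

Fold-error metrics follow the conventional definitions:

    PE_i  = 100 * (pred_i - obs_i) / obs_i          (percent, signed)
    MPE   = mean(PE_i)                              (bias, percent)
    AFE   = 10 ** mean(log10(pred_i / obs_i))       (geometric-mean fold bias)
    AAFE  = 10 ** mean(|log10(pred_i / obs_i)|)     (geometric-mean fold precision)

so that uniform +10% over-prediction gives MPE = +10 and AFE = 1.1, and a
symmetric pair of 2-fold errors gives AFE = 1 but AAFE = 2. Predictive
performance is conventionally accepted when AFE and AAFE fall inside the
0.8-1.25-fold band (endpoints inclusive; AAFE >= 1 makes its lower bound
vacuous).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset_io import Dataset
from .errors import ValidationError
from .estimation import ESTIMATED_PARAMS, IndividualFit, PopulationModel
from .model_core import PKParameters, concentrations_at

BAND_LOWER = 0.8
BAND_UPPER = 1.25


@dataclass
class MetricsResult:
    """Fold-error and percentage-error summary over paired obs/pred vectors."""

    pe: np.ndarray  # per-observation percentage error
    mpe: float
    afe: float
    aafe: float
    n: int


@dataclass
class BandCheck:
    """Outcome of the 0.8-1.25-fold acceptance band check."""

    passed: bool
    afe_in_band: bool
    aafe_in_band: bool
    lower: float = BAND_LOWER
    upper: float = BAND_UPPER

    def report(self) -> str:
        verdict = "PASS" if self.passed else "FAIL"
        return (
            f"{verdict}: AFE in [{self.lower}, {self.upper}]: {self.afe_in_band}; "
            f"AAFE <= {self.upper}: {self.aafe_in_band}"
        )


@dataclass
class GOFRecord:
    """One observation with its population and individual predictions."""

    subject_id: str
    time: float
    dv: float
    pred: float  # typical-parameter prediction
    ipred: float  # MAP individual prediction
    residual: float  # dv - ipred
    weighted_residual: float  # residual / (a + b*ipred)


def accuracy_metrics(obs: Sequence[float], pred: Sequence[float]) -> MetricsResult:
    """Fold-error metrics for paired positive observation/prediction vectors."""
    o = np.asarray(obs, dtype=float)
    p = np.asarray(pred, dtype=float)
    if o.ndim != 1 or o.shape != p.shape or o.size == 0:
        raise ValidationError("obs and pred must be equal-length 1-D sequences of length >= 1")
    if np.any(o <= 0) or np.any(p <= 0):
        raise ValidationError("obs and pred must be strictly positive (log fold errors)")
    pe = 100.0 * (p - o) / o
    logr = np.log10(p / o)
    return MetricsResult(
        pe=pe,
        mpe=float(np.mean(pe)),
        afe=float(10.0 ** np.mean(logr)),
        aafe=float(10.0 ** np.mean(np.abs(logr))),
        n=o.size,
    )


def acceptance_band_check(metrics: MetricsResult,
                          lower: float = BAND_LOWER, upper: float = BAND_UPPER) -> BandCheck:
    """Inclusive band check: pass iff lower <= AFE <= upper and AAFE <= upper."""
    afe_in = lower <= metrics.afe <= upper
    aafe_in = lower <= metrics.aafe <= upper
    return BandCheck(passed=afe_in and aafe_in, afe_in_band=afe_in, aafe_in_band=aafe_in,
                     lower=lower, upper=upper)


def gof_records(
    dataset: Dataset,
    population: PopulationModel,
    individual_fits: Iterable[IndividualFit],
) -> list[GOFRecord]:
    """Per-observation PRED/IPRED/residual table for goodness-of-fit plots."""
    fits: Mapping[str, IndividualFit] = {f.subject_id: f for f in individual_fits}
    missing = [s.id for s in dataset.subjects if s.id not in fits]
    if missing:
        raise ValidationError(f"no individual fit for subjects {missing}")
    records: list[GOFRecord] = []
    for subj in dataset.subjects:
        if not subj.observations:
            continue
        fit = fits[subj.id]
        times = subj.observation_times
        pred = concentrations_at(population.typical, subj.doses, times)
        ipred = concentrations_at(fit.individual_params, subj.doses, times)
        g = population.error.sd(ipred)
        for o, pr, ip, sd in zip(subj.observations, pred, ipred, g):
            resid = o.dv - ip
            records.append(
                GOFRecord(
                    subject_id=subj.id, time=o.time, dv=o.dv, pred=float(pr),
                    ipred=float(ip), residual=float(resid),
                    weighted_residual=float(resid / sd),
                )
            )
    return records


def gof_frame(records: Iterable[GOFRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def eta_and_density_summary(
    individual_fits: Iterable[IndividualFit],
    draws: Iterable[PKParameters] | None = None,
    bins: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summaries of the estimated etas and of simulated parameter densities.

    Returns ``(eta_summary, density)``: one row per estimated parameter with
    mean/SD/quantiles of eta across subjects, and a log-scale histogram table
    (parameter, bin_left, bin_right, count) for the parameter draws (empty
    when ``draws`` is None).
    """
    fits = list(individual_fits)
    if not fits:
        raise ValidationError("at least one individual fit is required")
    rows = []
    for name in ESTIMATED_PARAMS:
        values = np.array([f.eta.get(name, 0.0) for f in fits])
        rows.append(
            {
                "parameter": name,
                "n": values.size,
                "mean": float(np.mean(values)),
                "sd": float(np.std(values, ddof=1)) if values.size > 1 else 0.0,
                "q05": float(np.quantile(values, 0.05)),
                "median": float(np.quantile(values, 0.5)),
                "q95": float(np.quantile(values, 0.95)),
            }
        )
    eta_summary = pd.DataFrame(rows)

    density_rows = []
    if draws is not None:
        draw_list = list(draws)
        for name in ESTIMATED_PARAMS:
            values = np.log([getattr(p, name) for p in draw_list])
            counts, edges = np.histogram(values, bins=bins)
            for c, left, right in zip(counts, edges[:-1], edges[1:]):
                density_rows.append(
                    {"parameter": name, "bin_left": float(left),
                     "bin_right": float(right), "count": int(c)}
                )
    density = pd.DataFrame(density_rows,
                           columns=["parameter", "bin_left", "bin_right", "count"])
    return eta_summary, density
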