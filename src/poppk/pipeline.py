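"""End-to-end analysis orchestration with persisted per-stage artifacts.

Stages run in order: data -> fit -> map -> vpc -> project -> metrics. Each
stage reads only artifacts persisted by earlier stages (plus the config), so
any stage can be re-run from disk and reproduce its outputs. All numeric
exports are CSV; fit and MAP results are additionally persisted as JSON so
later stages can reload them without refitting.
"""
from __future__ import annotations

import json
import logging
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .dataset_io import Dataset, read_dataset, write_dataset
from .diagnostics import (
    acceptance_band_check,
    accuracy_metrics,
    eta_and_density_summary,
    gof_frame,
    gof_records,
)
from .errors import ValidationError
from .estimation import (
    ESTIMATED_PARAMS,
    FitResult,
    IndividualFit,
    PopulationModel,
    map_estimate,
    pooled_fit,
)
from .model_core import MG_TO_UG, ConcentrationProfile, PKParameters, concentrations_at, terminal_halflife
from .population_sim import (
    ScenarioSpec,
    draw_individuals,
    project_scenario,
    simulate_population,
    vpc_overlay,
)
from .synthetic_data import generate_dataset

logger = logging.getLogger("poppk")

_PARAM_UNITS = {"cl": "mL/day/kg", "q": "mL/day/kg", "vc": "mL/kg", "vp": "mL/kg",
                "vm": "ug/day/kg", "km": "ug/mL"}


def _outdir(config: RunConfig) -> Path:
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    return out


def stage_data(config: RunConfig) -> Dataset:
    """Load the study dataset, or generate and persist a synthetic one."""
    out = _outdir(config)
    if config.dataset == "synthetic":
        dataset, sidecar = generate_dataset(config.design, config.truth)
        write_dataset(dataset, out / "dataset.csv")
        sidecar.to_csv(out / "truth.csv", index=False)
        logger.info("generated synthetic dataset: %d subjects, %d observations",
                    len(dataset.subjects), dataset.n_observations)
    else:
        dataset = read_dataset(config.dataset)
        write_dataset(dataset, out / "dataset.csv")
        logger.info("read dataset %s: %d subjects", config.dataset, len(dataset.subjects))
    return dataset


def stage_fit(config: RunConfig, dataset: Dataset) -> FitResult:
    """Pooled fit; persists fit.json and a fit_report.csv table."""
    out = _outdir(config)
    fit = pooled_fit(dataset, init=config.initials, bounds=config.bounds,
                     error_model=config.error)
    payload = {
        "estimates": {n: getattr(fit.estimates, n) for n in ("cl", "q", "vc", "vp", "vm", "km")},
        "se": fit.se,
        "ofv": fit.ofv,
        "converged": fit.converged,
        "n_obs": fit.n_obs,
    }
    (out / "fit.json").write_text(json.dumps(payload, indent=2))
    report = pd.DataFrame(
        [
            {
                "parameter": n,
                "initial": getattr(config.initials, n),
                "estimate": getattr(fit.estimates, n),
                "se": fit.se.get(n, 0.0),
                "unit": _PARAM_UNITS[n],
            }
            for n in ("vc", "vp", "cl", "q")
        ]
    )
    report.to_csv(out / "fit_report.csv", index=False)
    logger.info("pooled fit: ofv=%.4f, estimates=%s", fit.ofv, payload["estimates"])
    return fit


def load_fit(outdir) -> FitResult:
    payload = json.loads((Path(outdir) / "fit.json").read_text())
    return FitResult(
        estimates=PKParameters(**payload["estimates"]),
        se=payload["se"], ofv=payload["ofv"],
        converged=payload["converged"], n_obs=payload["n_obs"],
    )


def _population(config: RunConfig, fit: FitResult) -> PopulationModel:
    return PopulationModel(
        typical=fit.estimates,
        omega2={n: config.map_omega2 for n in ESTIMATED_PARAMS},
        error=config.error,
        bounds=config.bounds,
    )


def stage_map(config: RunConfig, dataset: Dataset, fit: FitResult) -> list[IndividualFit]:
    """MAP-Bayes estimation per subject; persists etas and an eta summary."""
    out = _outdir(config)
    population = _population(config, fit)
    fits = [map_estimate(s, population) for s in dataset.subjects]
    payload = [
        {
            "subject_id": f.subject_id,
            "eta": f.eta,
            "params": {n: getattr(f.individual_params, n) for n in ("cl", "q", "vc", "vp", "vm", "km")},
            "ofv": f.ofv,
        }
        for f in fits
    ]
    (out / "individual_fits.json").write_text(json.dumps(payload, indent=2))
    eta_summary, _ = eta_and_density_summary(fits)
    eta_summary.to_csv(out / "eta_summary.csv", index=False)
    logger.info("MAP estimation done for %d subjects", len(fits))
    return fits


def load_individual_fits(outdir, dataset: Dataset) -> list[IndividualFit]:
    payload = json.loads((Path(outdir) / "individual_fits.json").read_text())
    fits = []
    for entry in payload:
        params = PKParameters(**entry["params"])
        subj = dataset.subject(entry["subject_id"])
        times = subj.observation_times
        ipred = ConcentrationProfile(
            np.asarray(times, dtype=float), concentrations_at(params, subj.doses, times)
        ) if times else ConcentrationProfile(np.array([0.0]), np.array([0.0]))
        fits.append(IndividualFit(entry["subject_id"], entry["eta"], params, ipred, entry["ofv"]))
    return fits


def stage_vpc(config: RunConfig, dataset: Dataset, fit: FitResult):
    """Monte-Carlo VPC at the reference dose; persists ribbons and overlay."""
    out = _outdir(config)
    population = _population(config, fit)
    times = np.unique(np.concatenate([
        np.asarray(s.observation_times, dtype=float) for s in dataset.subjects
    ]))
    reference_ug = config.reference_dose_mg * MG_TO_UG
    doses = [type(dataset.subjects[0].doses[0])(time=0.0, amount=reference_ug)]
    sim = simulate_population(population, doses, times, n=config.sim_n,
                              seed=config.seed, with_residual=True)
    vpc = vpc_overlay(sim, dataset, reference_ug)
    vpc.to_frame().to_csv(out / "vpc.csv", index=False)
    vpc.observed_frame().to_csv(out / "vpc_observed.csv", index=False)
    logger.info("VPC: %d simulated subjects at %g mg/kg over %d time points",
                config.sim_n, config.reference_dose_mg, times.size)
    return vpc


def stage_project(config: RunConfig, fit: FitResult) -> pd.DataFrame:
    """Dosing-scenario projections, one per clearance multiplier."""
    out = _outdir(config)
    rows = []
    for multiplier in config.cl_multipliers:
        spec = ScenarioSpec(
            dose=config.scenario.dose, interval=config.scenario.interval,
            n_doses=config.scenario.n_doses, horizon=config.scenario.horizon,
            cl_multiplier=multiplier,
        )
        result = project_scenario(fit.estimates, spec)
        result.profile.to_frame().to_csv(out / f"scenario_cl_x{multiplier:g}.csv", index=False)
        projected = fit.estimates.replace(cl=fit.estimates.cl * multiplier)
        rows.append(
            {
                "cl_multiplier": multiplier,
                "cl": projected.cl,
                "auc_0_28": result.auc_0_28,
                "terminal_halflife": terminal_halflife(projected),
            }
        )
        logger.info("scenario cl x %g: AUC(0-28)=%.2f", multiplier, result.auc_0_28)
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "scenario_summary.csv", index=False)
    return summary


def stage_metrics(config: RunConfig, dataset: Dataset, fit: FitResult,
                  fits: list[IndividualFit], use_pred: bool = False) -> pd.DataFrame:
    """Fold-error metrics, GOF table and parameter-density export.

    Metrics compare observations with IPRED (individual predictions) by
    default; ``use_pred`` switches to the population prediction.
    """
    out = _outdir(config)
    population = _population(config, fit)
    records = gof_records(dataset, population, fits)
    gof = gof_frame(records)
    gof.to_csv(out / "gof.csv", index=False)

    pred_col = "pred" if use_pred else "ipred"
    metrics = accuracy_metrics(gof["dv"].to_numpy(), gof[pred_col].to_numpy())
    band = acceptance_band_check(metrics)
    table = pd.DataFrame(
        [{"afe": metrics.afe, "aafe": metrics.aafe, "mpe": metrics.mpe,
          "n": metrics.n, "band_pass": band.passed}]
    )
    table.to_csv(out / "metrics.csv", index=False)

    draws = draw_individuals(population, n=config.sim_n, seed=config.seed + 1)
    _, density = eta_and_density_summary(fits, draws)
    density.to_csv(out / "density.csv", index=False)
    logger.info("metrics (%s): AFE=%.3f AAFE=%.3f MPE=%.2f -> %s",
                pred_col.upper(), metrics.afe, metrics.aafe, metrics.mpe, band.report())
    return table


def run_analysis(config: RunConfig) -> Path:
    """Run all stages in order and write a manifest; returns the output dir."""
    out = _outdir(config)
    log_handler = logging.FileHandler(out / "run.log")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)

    timings: list[tuple[str, float]] = []

    def timed(name, fn, *args, **kwargs):
        t0 = _time.perf_counter()
        logger.info("stage %s: start", name)
        try:
            result = fn(*args, **kwargs)
        except Exception:
            logger.exception("stage %s failed", name)
            raise ValidationError(f"pipeline stage {name!r} failed (partial outputs kept in {out})")
        timings.append((name, _time.perf_counter() - t0))
        return result

    try:
        dataset = timed("data", stage_data, config)
        fit = timed("fit", stage_fit, config, dataset)
        fits = timed("map", stage_map, config, dataset, fit)
        timed("vpc", stage_vpc, config, dataset, fit)
        timed("project", stage_project, config, fit)
        timed("metrics", stage_metrics, config, dataset, fit, fits)
    finally:
        _write_manifest(config, out, timings)
        logger.removeHandler(log_handler)
        log_handler.close()
    return out


def _write_manifest(config: RunConfig, out: Path, timings) -> None:
    import scipy

    lines = [
        f"poppk {__version__}",
        f"numpy {np.__version__}, scipy {scipy.__version__}, pandas {pd.__version__}",
        f"seed: {config.seed}",
        "config:",
    ]
    lines += ["  " + line for line in json.dumps(config.to_dict(), indent=2).splitlines()]
    lines.append("stage wall times (s):")
    lines += [f"  {name}: {dt:.3f}" for name, dt in timings]
    (out / "manifest.txt").write_text("\n".join(lines) + "\n")
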