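"""Run configuration: a single YAML file describing the whole analysis.

Example
-------
::

    dataset: synthetic          # or a path to a study CSV
    design:
      n_subjects: 6
      dose_groups: [[10, 3], [100, 3]]
      sampling_times: [0.25, 1, 3, 7, 14, 21, 28]
    truth:                      # generating truth for synthetic data
      cl: 7.02
      q: 50.55
      vc: 49.86
      vp: 33.14
      omega2: 0.09
    initials: {cl: 5, q: 10, vc: 40, vp: 40}
    bounds:   {cl: [1, 30], q: [1, 100], vc: [10, 200], vp: [10, 200]}
    error:    {a: 0.01, b: 0.1}
    map:      {omega2: 0.09}
    simulation: {n: 1000, reference_dose: 10.0}   # dose in mg/kg
    scenario:
      dose: 10.0                # mg/kg
      interval: 7
      n_doses: 4
      horizon: 28
      cl_multipliers: [1.0, 0.5]
    seed: 20240601
    out: runs/demo

Every block is optional; omitted values fall back to the defaults above.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ValidationError
from .estimation import (
    DEFAULT_BOUNDS,
    DEFAULT_INITIALS,
    DEFAULT_OMEGA2,
    ESTIMATED_PARAMS,
    ResidualErrorModel,
)
from .model_core import PKParameters
from .population_sim import ScenarioSpec
from .synthetic_data import REFERENCE_PARAMS, StudyDesign, TruthSpec


@dataclass
class RunConfig:
    """Validated configuration for :func:`poppk.pipeline.run_analysis`."""

    dataset: str = "synthetic"
    design: StudyDesign = field(default_factory=StudyDesign)
    truth: TruthSpec = field(default_factory=TruthSpec)
    initials: PKParameters = DEFAULT_INITIALS
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    error: ResidualErrorModel = field(default_factory=ResidualErrorModel)
    map_omega2: float = DEFAULT_OMEGA2
    sim_n: int = 1000
    reference_dose_mg: float = 10.0
    scenario: ScenarioSpec = field(default_factory=ScenarioSpec)
    cl_multipliers: tuple[float, ...] = (1.0, 0.5)
    seed: int = 20240601
    out: str = "runs/out"

    def __post_init__(self) -> None:
        if self.dataset != "synthetic" and not Path(self.dataset).exists():
            raise ValidationError(f"dataset path does not exist: {self.dataset}")
        if self.sim_n < 2:
            raise ValidationError("simulation n must be >= 2")
        if self.reference_dose_mg <= 0:
            raise ValidationError("reference dose must be > 0")
        if self.seed < 0:
            raise ValidationError("seed must be non-negative")
        if not self.cl_multipliers or any(m <= 0 for m in self.cl_multipliers):
            raise ValidationError("cl_multipliers must be positive")
        if self.map_omega2 < 0:
            raise ValidationError("map omega2 must be >= 0")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        raw = dict(raw or {})
        kwargs: dict = {}
        if "dataset" in raw:
            kwargs["dataset"] = str(raw["dataset"])

        if "design" in raw:
            d = raw["design"]
            kwargs["design"] = StudyDesign(
                n_subjects=int(d.get("n_subjects", 6)),
                dose_groups=tuple((float(g[0]), int(g[1])) for g in d.get("dose_groups", [(10, 3), (100, 3)])),
                sampling_times=tuple(float(t) for t in d.get("sampling_times", (0.25, 1, 3, 7, 14, 21, 28))),
            )

        if "truth" in raw:
            t = raw["truth"]
            typical = PKParameters(
                cl=float(t.get("cl", REFERENCE_PARAMS.cl)),
                q=float(t.get("q", REFERENCE_PARAMS.q)),
                vc=float(t.get("vc", REFERENCE_PARAMS.vc)),
                vp=float(t.get("vp", REFERENCE_PARAMS.vp)),
            )
            omega2 = t.get("omega2", DEFAULT_OMEGA2)
            if not isinstance(omega2, Mapping):
                omega2 = {n: float(omega2) for n in ESTIMATED_PARAMS}
            err = t.get("error", {})
            a, b = float(err.get("a", 0.01)), float(err.get("b", 0.1))
            kwargs["truth"] = TruthSpec(
                typical=typical,
                omega2=dict(omega2),
                # a = b = 0 means noise-free generation
                error=None if a == 0 and b == 0 else ResidualErrorModel(a=a, b=b),
                seed=int(t.get("seed", raw.get("seed", 20240601))),
            )

        if "initials" in raw:
            i = raw["initials"]
            kwargs["initials"] = DEFAULT_INITIALS.replace(
                **{k: float(v) for k, v in i.items() if k in ("cl", "q", "vc", "vp", "vm", "km")}
            )
        if "bounds" in raw:
            kwargs["bounds"] = dict(
                DEFAULT_BOUNDS,
                **{k: (float(v[0]), float(v[1])) for k, v in raw["bounds"].items()},
            )
        if "error" in raw:
            e = raw["error"]
            kwargs["error"] = ResidualErrorModel(a=float(e.get("a", 0.01)), b=float(e.get("b", 0.1)))
        if "map" in raw:
            kwargs["map_omega2"] = float(raw["map"].get("omega2", DEFAULT_OMEGA2))
        if "simulation" in raw:
            s = raw["simulation"]
            kwargs["sim_n"] = int(s.get("n", 1000))
            kwargs["reference_dose_mg"] = float(s.get("reference_dose", 10.0))
        if "scenario" in raw:
            s = dict(raw["scenario"])
            kwargs["cl_multipliers"] = tuple(float(m) for m in s.pop("cl_multipliers", (1.0, 0.5)))
            kwargs["scenario"] = ScenarioSpec(
                dose=float(s.get("dose", 10.0)),
                interval=float(s.get("interval", 7.0)),
                n_doses=int(s.get("n_doses", 4)),
                horizon=float(s.get("horizon", 28.0)),
            )
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        if "out" in raw:
            kwargs["out"] = str(raw["out"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw or {})

    def to_dict(self) -> dict:
        return {
            "dataset": self.dataset,
            "design": {
                "n_subjects": self.design.n_subjects,
                "dose_groups": [list(g) for g in self.design.dose_groups],
                "sampling_times": list(self.design.sampling_times),
            },
            "truth": {
                "cl": self.truth.typical.cl, "q": self.truth.typical.q,
                "vc": self.truth.typical.vc, "vp": self.truth.typical.vp,
                "omega2": dict(self.truth.omega2),
                "error": ({"a": self.truth.error.a, "b": self.truth.error.b}
                          if self.truth.error else {"a": 0.0, "b": 0.0}),
                "seed": self.truth.seed,
            },
            "initials": {n: getattr(self.initials, n) for n in ("cl", "q", "vc", "vp", "vm", "km")},
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "error": {"a": self.error.a, "b": self.error.b},
            "map": {"omega2": self.map_omega2},
            "simulation": {"n": self.sim_n, "reference_dose": self.reference_dose_mg},
            "scenario": {
                "dose": self.scenario.dose, "interval": self.scenario.interval,
                "n_doses": self.scenario.n_doses, "horizon": self.scenario.horizon,
                "cl_multipliers": list(self.cl_multipliers),
            },
            "seed": self.seed,
            "out": self.out,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
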