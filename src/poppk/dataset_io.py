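"""Read/write the NONMEM-style study dataset and dose-normalize observations.

The on-disk dialect is a comma-separated file with header
``ID,TIME,AMT,DV,EVID,MDV,CMT[,GROUP]``:

* ``EVID = 1`` rows are dosing events (``AMT`` in ug/kg, ``DV`` written ``.``),
* ``EVID = 0`` rows are observations (``DV`` in ug/mL, ``AMT`` written ``.``),
* ``CMT = 1`` (central) is the only supported compartment,
* ``GROUP`` is an optional dose-group label; when absent it is inferred from
  the subject's first dose amount (e.g. 10000 ug/kg -> ``"10mg"``).

Unknown extra columns are ignored on read. Floats are serialized with
``repr`` so that a write/read round trip reproduces the dataset bit-exactly.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import FormatError, ValidationError
from .model_core import MG_TO_UG, DoseEvent

REQUIRED_COLUMNS = ("ID", "TIME", "AMT", "DV", "EVID", "MDV", "CMT")
MISSING = "."


def group_label(amount_ug: float) -> str:
    """Dose-group label from a dose amount in ug/kg, e.g. 10000 -> '10mg'."""
    return f"{amount_ug / MG_TO_UG:g}mg"


@dataclass(frozen=True)
class Observation:
    """One measured central concentration."""

    time: float
    dv: float  # ug/mL
    dose_group: str | None = None

    def __post_init__(self) -> None:
        if not (self.time >= 0):
            raise ValidationError(f"observation time must be >= 0, got {self.time}")
        if not (self.dv > 0):
            raise ValidationError(f"observed concentration must be > 0, got {self.dv}")


@dataclass
class SubjectRecord:
    """Dosing events plus observations for one subject.

    Observations are kept sorted by time; observations without a dose-group
    label inherit one inferred from the subject's first dose.
    """

    id: str
    doses: list[DoseEvent]
    observations: list[Observation]

    def __post_init__(self) -> None:
        if not self.doses:
            raise ValidationError(f"subject {self.id!r} has no dose events")
        self.doses = sorted(self.doses, key=lambda d: d.time)
        obs = sorted(self.observations, key=lambda o: o.time)
        label = group_label(self.doses[0].amount)
        self.observations = [
            o if o.dose_group is not None else Observation(o.time, o.dv, label)
            for o in obs
        ]

    @property
    def observation_times(self):
        return [o.time for o in self.observations]

    @property
    def dv(self):
        return [o.dv for o in self.observations]


@dataclass
class Dataset:
    """The study: a list of subjects plus the reference dose for normalization."""

    subjects: list[SubjectRecord]
    reference_dose: float | None = None  # ug/kg

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"subject ids are not unique: {ids}")

    @property
    def n_observations(self) -> int:
        return sum(len(s.observations) for s in self.subjects)

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.id == subject_id:
                return s
        raise ValidationError(f"unknown subject id {subject_id!r}")


def _parse_float(raw: str, what: str, row_no: int) -> float:
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise ValidationError(f"row {row_no}: non-numeric {what} value {raw!r}") from None


def read_dataset(path) -> Dataset:
    """Parse a study CSV in the dialect documented in the module docstring."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in frame.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    has_group = "GROUP" in frame.columns

    order: list[str] = []
    doses: dict[str, list[DoseEvent]] = {}
    observations: dict[str, list[Observation]] = {}
    for row_no, row in enumerate(frame.itertuples(index=False), start=2):
        sid = str(row.ID)
        if sid not in doses:
            order.append(sid)
            doses[sid] = []
            observations[sid] = []
        time = _parse_float(row.TIME, "TIME", row_no)
        evid = str(row.EVID).strip()
        if evid == "1":
            amt = _parse_float(row.AMT, "AMT", row_no)
            if amt <= 0:
                raise ValidationError(f"row {row_no}: dose row with AMT <= 0 ({amt})")
            doses[sid].append(DoseEvent(time=time, amount=amt))
        elif evid == "0":
            dv = _parse_float(row.DV, "DV", row_no)
            group = str(row.GROUP) if has_group and str(row.GROUP) not in ("", MISSING) else None
            observations[sid].append(Observation(time=time, dv=dv, dose_group=group))
        else:
            raise ValidationError(f"row {row_no}: unsupported EVID {evid!r} (expected 0 or 1)")
        cmt = str(row.CMT).strip()
        if cmt not in ("1", "1.0"):
            raise ValidationError(
                f"row {row_no}: only the central compartment (CMT=1) is supported, got {cmt!r}"
            )
    subjects = [SubjectRecord(sid, doses[sid], observations[sid]) for sid in order]
    return Dataset(subjects=subjects)


def write_dataset(dataset: Dataset, path) -> None:
    """Write a dataset in the exact dialect :func:`read_dataset` accepts."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(REQUIRED_COLUMNS) + ["GROUP"])
        for subj in dataset.subjects:
            label = group_label(subj.doses[0].amount)
            for d in subj.doses:
                writer.writerow([subj.id, repr(d.time), repr(d.amount), MISSING, 1, 1, 1, label])
            for o in subj.observations:
                writer.writerow(
                    [subj.id, repr(o.time), MISSING, repr(o.dv), 0, 0, 1, o.dose_group]
                )


def dose_normalize(
    observations: Iterable[Observation], actual_dose: float, reference_dose: float
) -> list[Observation]:
    """Scale observed concentrations from ``actual_dose`` to ``reference_dose``.

    Valid under the linear model, where concentration is proportional to dose:
    each ``dv`` is multiplied by ``reference_dose / actual_dose``.
    """
    if not (actual_dose > 0):
        raise ValidationError(f"actual_dose must be > 0, got {actual_dose}")
    if not (reference_dose > 0):
        raise ValidationError(f"reference_dose must be > 0, got {reference_dose}")
    factor = reference_dose / actual_dose
    return [Observation(o.time, o.dv * factor, o.dose_group) for o in observations]
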