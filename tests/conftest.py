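import numpy as np
import pytest

from poppk import (
    REFERENCE_PARAMS,
    Dataset,
    DoseEvent,
    Observation,
    PKParameters,
    ResidualErrorModel,
    SubjectRecord,
)


@pytest.fixture
def ref_params() -> PKParameters:
    """Pooled reference parameter set (per-kg units) used throughout."""
    return REFERENCE_PARAMS


@pytest.fixture
def weekly_doses() -> tuple[DoseEvent, ...]:
    """10 mg/kg IV bolus weekly for 4 weeks."""
    return tuple(DoseEvent.from_mg(time=7.0 * k, amount_mg=10.0) for k in range(4))


@pytest.fixture
def default_error() -> ResidualErrorModel:
    return ResidualErrorModel()


@pytest.fixture
def toy_subject() -> SubjectRecord:
    """One-compartment-ish subject with a handful of clean observations."""
    params = PKParameters(cl=5.0, q=0.0, vc=40.0, vp=30.0)
    doses = [DoseEvent(time=0.0, amount=10000.0)]
    times = [0.25, 1.0, 3.0, 7.0, 14.0]
    from poppk import concentrations_at

    conc = concentrations_at(params, doses, times)
    observations = [Observation(time=t, dv=float(c)) for t, c in zip(times, conc)]
    return SubjectRecord("T1", doses, observations)


@pytest.fixture
def noisefree_dataset(ref_params) -> Dataset:
    """Six rich-sampled subjects simulated exactly at the reference truth."""
    from poppk import StudyDesign, TruthSpec, generate_dataset

    design = StudyDesign(
        n_subjects=6,
        dose_groups=((10.0, 3), (100.0, 3)),
        sampling_times=(0.25, 0.5, 1.0, 2.0, 3.0, 5.0, 7.0, 10.0, 14.0, 21.0, 28.0),
    )
    truth = TruthSpec(typical=ref_params, omega2={}, error=None, seed=0)
    dataset, _ = generate_dataset(design, truth)
    return dataset
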