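import numpy as np
import pytest

from ftvmri import DCEStudy, Timepoint


DEFAULT_TIMES = (-10.0, 60.0, 150.0, 420.0)


def make_study(volumes, phase_times=DEFAULT_TIMES, spacing=(1.0, 1.0, 1.5),
               patient_id="P000", timepoint=Timepoint.BL) -> DCEStudy:
    return DCEStudy(patient_id=patient_id, timepoint=timepoint,
                    volumes=np.asarray(volumes, dtype=float),
                    phase_times_s=phase_times, voxel_spacing_mm=spacing)


def random_study(rng, shape=(8, 8, 4), n_phases=4, lo=50.0, hi=200.0):
    """Random positive-intensity study on the default 4-phase timing."""
    vols = rng.uniform(lo, hi, size=(n_phases, *shape))
    return make_study(vols)


@pytest.fixture
def rng():
    return np.random.default_rng(20231025)


@pytest.fixture
def study_factory():
    return make_study
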