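import pytest

import pupilbreadth as pb
from pupilbreadth.preprocess import PreprocParams

# Desk-scale study conditions: traces generated directly at 100 Hz (the
# paper-equivalent post-downsampling rate), analyzed without further
# downsampling.  The mm coefficients invert the generator's au mapping.
DESK_PREPROC = dict(downsample_factor=1, mm_coeff_a=1 / 500.0, mm_coeff_b=-2.0)


def desk_pupil_params(**overrides):
    kw = dict(sampling_rate_hz=100.0)
    kw.update(overrides)
    return pb.PupilGenParams(**kw)


@pytest.fixture(scope="session")
def desk_dataset():
    """10-participant exp1 cohort at 100 Hz (raw samples + trials)."""
    pupil = desk_pupil_params()
    return pb.generate_dataset(10, "exp1", None, pupil, seed=3,
                               trace_duration_ms=3100.0)


@pytest.fixture(scope="session")
def desk_processed(desk_dataset):
    """The desk cohort run through the full preprocessing chain."""
    samples, trials = desk_dataset
    params = PreprocParams(**DESK_PREPROC)
    return pb.run_preprocessing(samples, trials, params)
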