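import numpy as np
import pytest

from pergss.preprocess import AveragedTrace
from pergss.stats import average_eyes
from pergss.stimulus import StimulusCondition
from pergss.synthetic import CohortDesign, SweepNoiseModel, generate_cohort_table


@pytest.fixture
def quiet_noise() -> SweepNoiseModel:
    """Default sweep geometry with every noise source off."""
    return SweepNoiseModel().quiet()


@pytest.fixture
def cohort_records():
    """One default synthetic cohort (24 subjects, 2 eyes, 8 conditions)."""
    records, truth = generate_cohort_table(CohortDesign(seed=3))
    return records, truth


@pytest.fixture
def eye_averaged(cohort_records):
    records, _ = cohort_records
    return average_eyes(records)


def make_trace(samples, fs=500.0, sweep_length_s=0.96, rate=12.5) -> AveragedTrace:
    """Wrap a raw sample vector as an AveragedTrace for spectral tests."""
    return AveragedTrace(
        samples=np.asarray(samples, dtype=float), sampling_rate_hz=fs,
        sweep_length_s=sweep_length_s,
        condition=StimulusCondition(0.8, rate), n_sweeps_used=1,
        n_sweeps_rejected=0)


def sinusoid(amplitude, freq_hz, phase=0.0, fs=500.0, n=480):
    t = np.arange(n) / fs
    return amplitude * np.sin(2 * np.pi * freq_hz * t + phase)
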