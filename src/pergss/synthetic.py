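"""Synthetic steady-state PERG cohorts with known ground truth.

The generator emulates the cohort structure the analysis assumes — two
groups of 12 subjects, two eyes, four check sizes x two reversal rates —
at two levels:

* **cohort tables**: per subject/eye/condition true amplitudes (μV) and
  response times (ms), drawn from a group x condition mean/SD model with a
  shared per-subject random effect (within-subject correlation across
  conditions) and independent eye-level jitter;
* **sweep blocks**: fixed-length voltage sweeps realizing one cell's true
  amplitude and response time as a single sinusoid at the reversal rate,
  plus affine baseline drift, white noise and occasional single-sample
  artifact spikes large enough to trip the 120 μV rejection rule.

The signal model is deliberately minimal — one sinusoid at the fundamental
— because the analysis reads only the fundamental DFT bin.  The default
mean/SD tables are the reference group summaries in :mod:`pergss.reference`;
the per-cell SD there is interpreted as the *total* between-subject SD of
the eye-averaged measure, of which the shared subject effect is one
component (see docs/methods.md for the variance decomposition).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import reference
from .stimulus import StimulusCondition
from .sweep_io import SweepArchive, SweepBlock

DEFAULT_CONDITIONS = tuple(
    StimulusCondition(cs, rr)
    for cs in reference.CHECK_SIZES_DEG
    for rr in reference.REVERSAL_RATES_RPS
)

_MODEL_COLUMNS = ["group", "check_size_deg", "reversal_rate_rps", "mean", "sd"]


@dataclass(frozen=True)
class SweepNoiseModel:
    """Sweep-level noise: white noise, affine drift, artifact spikes.

    The recording hardware's sampling rate is not part of the protocol
    definition; 500 Hz gives an integer 480 samples per 960 ms sweep and a
    Nyquist frequency well above the 40 Hz analysis band.
    """

    sampling_rate_hz: float = 500.0
    sweep_length_s: float = 0.96
    white_noise_sd_uV: float = 20.0
    drift_intercept_sd_uV: float = 5.0
    drift_slope_sd_uV_per_s: float = 5.0
    artifact_rate: float = 0.0
    artifact_amplitude_uV: float = 200.0

    def __post_init__(self) -> None:
        n = self.sampling_rate_hz * self.sweep_length_s
        if abs(n - round(n)) > 1e-9 or round(n) < 2:
            raise ValueError(
                f"sampling_rate_hz x sweep_length_s = {n} must be an integer >= 2"
            )
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError(f"artifact_rate must be in [0, 1], got {self.artifact_rate}")
        for name in ("white_noise_sd_uV", "drift_intercept_sd_uV",
                     "drift_slope_sd_uV_per_s", "artifact_amplitude_uV"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_samples(self) -> int:
        return round(self.sampling_rate_hz * self.sweep_length_s)

    def quiet(self) -> "SweepNoiseModel":
        """Copy with all noise sources switched off (noiseless round trips)."""
        return replace(
            self,
            white_noise_sd_uV=0.0,
            drift_intercept_sd_uV=0.0,
            drift_slope_sd_uV_per_s=0.0,
            artifact_rate=0.0,
        )


def _model_table(summary: pd.DataFrame, groups: tuple[str, str],
                 patient_scale: float | None = None) -> pd.DataFrame:
    """Build a group x condition mean/SD model from a reference posthoc table."""
    rows = []
    control, patient = groups
    for _, r in summary.iterrows():
        rows.append((control, r.check_size_deg, r.reversal_rate_rps,
                     r.control_mean, r.control_sd))
        if patient_scale is None:
            rows.append((patient, r.check_size_deg, r.reversal_rate_rps,
                         r.patient_mean, r.patient_sd))
        else:
            rows.append((patient, r.check_size_deg, r.reversal_rate_rps,
                         r.control_mean * patient_scale, r.control_sd))
    return pd.DataFrame(rows, columns=_MODEL_COLUMNS)


@dataclass
class CohortDesign:
    """Cohort structure plus the amplitude and response-time models.

    ``amplitude_model`` / ``time_model`` hold one row per group x condition
    with the mean and the total between-subject SD of the eye-averaged
    measure.  ``*_subject_sd`` is the shared additive subject effect (the
    within-subject correlation knob) and ``*_eye_sd`` the per-eye jitter;
    the independent per-cell noise SD is derived so the total matches the
    model SD: ``cell² = max(0, sd² − subject_sd² − eye_sd²/2)``.
    """

    n_per_group: int = reference.N_PER_GROUP
    groups: tuple[str, str] = ("control", "patient")
    eyes: tuple[str, ...] = ("left", "right")
    conditions: tuple[StimulusCondition, ...] = DEFAULT_CONDITIONS
    amplitude_model: pd.DataFrame = field(
        default_factory=lambda: _model_table(
            reference.amplitude_posthoc_table(), ("control", "patient")))
    time_model: pd.DataFrame = field(
        default_factory=lambda: _model_table(
            reference.time_posthoc_table(), ("control", "patient")))
    amplitude_subject_sd_uV: float = 0.3
    amplitude_eye_sd_uV: float = 0.2
    time_subject_sd_ms: float = 1.5
    time_eye_sd_ms: float = 0.5
    amplitude_floor_uV: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ValueError(f"n_per_group must be >= 1, got {self.n_per_group}")
        if len(self.eyes) < 1:
            raise ValueError("at least one eye required")
        for name, model in (("amplitude_model", self.amplitude_model),
                            ("time_model", self.time_model)):
            missing = [c for c in _MODEL_COLUMNS if c not in model.columns]
            if missing:
                raise ValueError(f"{name} lacks columns {missing}")
            if (model["mean"] <= 0).any():
                raise ValueError(f"{name}: all means must be > 0")
            if (model["sd"] < 0).any():
                raise ValueError(f"{name}: SDs must be >= 0")
            keyed = model.set_index(["group", "check_size_deg", "reversal_rate_rps"])
            if keyed.index.has_duplicates:
                raise ValueError(f"{name}: duplicate group x condition rows")
            for g in self.groups:
                for c in self.conditions:
                    key = (g, c.check_size_deg, c.reversal_rate_rps)
                    if key not in keyed.index:
                        raise ValueError(f"{name}: unspecified cell {key}")

    def _lookup(self, model: pd.DataFrame) -> dict:
        keyed = model.set_index(["group", "check_size_deg", "reversal_rate_rps"])
        return {k: (row["mean"], row["sd"]) for k, row in keyed.iterrows()}


def null_design(**kwargs) -> CohortDesign:
    """Design with identical models for both groups (control rows everywhere)."""
    return CohortDesign(
        amplitude_model=_model_table(reference.amplitude_posthoc_table(),
                                     ("control", "patient"), patient_scale=1.0),
        time_model=_model_table(reference.time_posthoc_table(),
                                ("control", "patient"), patient_scale=1.0),
        **kwargs,
    )


def uniform_deficit_design(deficit_fraction: float = 0.2, **kwargs) -> CohortDesign:
    """Design whose patient amplitude means are uniformly reduced by ``deficit_fraction``.

    SDs stay at the control values in every cell, so the only group
    difference is the amplitude scale.
    """
    return CohortDesign(
        amplitude_model=_model_table(reference.amplitude_posthoc_table(),
                                     ("control", "patient"),
                                     patient_scale=1.0 - deficit_fraction),
        time_model=_model_table(reference.time_posthoc_table(),
                                ("control", "patient"), patient_scale=1.0),
        **kwargs,
    )


def _cell_sd(total_sd: float, subject_sd: float, eye_sd: float, n_eyes: int) -> float:
    return math.sqrt(max(0.0, total_sd**2 - subject_sd**2 - eye_sd**2 / n_eyes))


def generate_cohort_table(
    design: CohortDesign, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort of true per subject/eye/condition amplitudes and times.

    Returns ``(records, truth)``: one record per subject x eye x condition,
    and the configured ground-truth group x condition means alongside.
    Identical design (including seed) -> identical output.
    """
    design.validate()
    rng = np.random.default_rng(design.seed) if rng is None else rng
    amp_lut = design._lookup(design.amplitude_model)
    time_lut = design._lookup(design.time_model)
    n_eyes = len(design.eyes)

    rows = []
    for group in design.groups:
        for i in range(design.n_per_group):
            subject = f"{group[:3]}{i + 1:02d}"
            u_amp = rng.normal(0.0, design.amplitude_subject_sd_uV)
            u_time = rng.normal(0.0, design.time_subject_sd_ms)
            for cond in design.conditions:
                key = (group, cond.check_size_deg, cond.reversal_rate_rps)
                amp_mean, amp_sd = amp_lut[key]
                t_mean, t_sd = time_lut[key]
                cell_amp = rng.normal(
                    0.0, _cell_sd(amp_sd, design.amplitude_subject_sd_uV,
                                  design.amplitude_eye_sd_uV, n_eyes))
                cell_time = rng.normal(
                    0.0, _cell_sd(t_sd, design.time_subject_sd_ms,
                                  design.time_eye_sd_ms, n_eyes))
                for eye in design.eyes:
                    amp = (amp_mean + u_amp + cell_amp
                           + rng.normal(0.0, design.amplitude_eye_sd_uV))
                    t = (t_mean + u_time + cell_time
                         + rng.normal(0.0, design.time_eye_sd_ms))
                    rows.append((subject, group, eye, cond.check_size_deg,
                                 cond.reversal_rate_rps,
                                 max(design.amplitude_floor_uV, amp), t))
    records = pd.DataFrame(
        rows, columns=["subject", "group", "eye", "check_size_deg",
                       "reversal_rate_rps", "amplitude_uV", "response_time_ms"])

    truth = pd.merge(
        design.amplitude_model.rename(columns={"mean": "amplitude_mean_uV",
                                               "sd": "amplitude_sd_uV"}),
        design.time_model.rename(columns={"mean": "time_mean_ms",
                                          "sd": "time_sd_ms"}),
        on=["group", "check_size_deg", "reversal_rate_rps"],
        validate="one_to_one",
    )
    return records, truth


def generate_sweep_block(
    amplitude_uV: float,
    response_time_ms: float,
    condition: StimulusCondition,
    noise: SweepNoiseModel,
    n_sweeps: int = 100,
    seed: int | np.random.Generator = 0,
    subject_id: str = "s01",
    group: str = "control",
    eye: str = "left",
) -> SweepBlock:
    """Realize one cell as raw sweeps.

    Each sweep is ``A·sin(2πf·t + φ) + (a + b·t) + white noise
    [+ artifact spike]`` with ``f`` the reversal rate and
    ``φ = −2πf·(response_time_ms/1000)``: a response delayed by ``t_r``
    lags the stimulus by that phase.  With all noise off, the preprocessing
    + spectral + timing stages recover ``amplitude_uV`` and (modulo whole
    stimulus cycles) ``response_time_ms`` exactly.
    """
    if amplitude_uV < 0:
        raise ValueError("amplitude_uV must be >= 0")
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = noise.n_samples
    t = np.arange(n) / noise.sampling_rate_hz
    f = condition.frequency_hz
    phi = -2.0 * np.pi * f * (response_time_ms / 1000.0)
    clean = amplitude_uV * np.sin(2.0 * np.pi * f * t + phi)

    sweeps = np.tile(clean, (n_sweeps, 1))
    if noise.drift_intercept_sd_uV > 0 or noise.drift_slope_sd_uV_per_s > 0:
        a = rng.normal(0.0, noise.drift_intercept_sd_uV, size=n_sweeps)
        b = rng.normal(0.0, noise.drift_slope_sd_uV_per_s, size=n_sweeps)
        sweeps += a[:, None] + b[:, None] * t[None, :]
    if noise.white_noise_sd_uV > 0:
        sweeps += rng.normal(0.0, noise.white_noise_sd_uV, size=(n_sweeps, n))
    if noise.artifact_rate > 0:
        hit = rng.random(n_sweeps) < noise.artifact_rate
        pos = rng.integers(0, n, size=n_sweeps)
        sign = rng.choice([-1.0, 1.0], size=n_sweeps)
        for i in np.flatnonzero(hit):
            sweeps[i, pos[i]] += sign[i] * noise.artifact_amplitude_uV

    return SweepBlock(
        subject_id=subject_id, group=group, eye=eye, condition=condition,
        sampling_rate_hz=noise.sampling_rate_hz,
        sweep_length_s=noise.sweep_length_s, sweeps=sweeps,
        extra={"true_amplitude_uV": amplitude_uV,
               "true_response_time_ms": response_time_ms},
    )


def generate_sweep_archive(
    design: CohortDesign,
    noise: SweepNoiseModel,
    n_sweeps: int = 100,
    rng: np.random.Generator | None = None,
) -> tuple[SweepArchive, pd.DataFrame, pd.DataFrame]:
    """Generate a full cohort of sweep blocks.

    Returns ``(archive, records, truth)`` where ``records`` is the
    sweep-level ground truth table from :func:`generate_cohort_table`.
    """
    rng = np.random.default_rng(design.seed) if rng is None else rng
    records, truth = generate_cohort_table(design, rng=rng)
    blocks = []
    for row in records.itertuples():
        blocks.append(
            generate_sweep_block(
                amplitude_uV=row.amplitude_uV,
                response_time_ms=row.response_time_ms,
                condition=StimulusCondition(row.check_size_deg, row.reversal_rate_rps),
                noise=noise, n_sweeps=n_sweeps, seed=rng,
                subject_id=row.subject, group=row.group, eye=row.eye,
            )
        )
    archive = SweepArchive(
        blocks=blocks,
        provenance={"generator": "pergss.synthetic", "n_sweeps": n_sweeps,
                    "seed": design.seed},
    )
    return archive, records, truth
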