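"""Fourier extraction of the steady-state response at the reversal rate.

Amplitudes use the *peak* convention: a trace ``A·sin(2πft + φ)`` whose
frequency sits exactly on DFT bin ``k`` yields amplitude ``A`` via
``2·|X_k|/N``.  The reported phase is the sine-convention phase ``φ``
itself (the DFT argument plus π/2, wrapped to (−π, π]), chosen so that a
response delayed by ``t_r`` ms carries phase ``−2πf·t_r/1000`` and the
generator -> analysis round trip is exact; :mod:`pergss.timing` relies on
this convention.

The noise estimate is the mean amplitude of the two bins directly adjacent
to the analysis bin — off-response frequencies that carry only background
noise because the sweep holds a whole number of response cycles.  The
noise-corrected amplitude subtracts that estimate (linearly by default,
floored at zero; a power-domain variant is provided).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .preprocess import AveragedTrace


@dataclass(frozen=True)
class SpectralComponent:
    """The steady-state response measured at one analysis frequency."""

    frequency_hz: float
    bin_index: int
    amplitude_uV: float
    phase_rad: float
    noise_uV: float
    corrected_amplitude_uV: float
    snr: float


def _wrap_phase(phi: float) -> float:
    """Map a phase to the half-open interval (−π, π]."""
    wrapped = math.remainder(phi, 2.0 * math.pi)  # (-π, π], ties to even
    if wrapped <= -math.pi:
        wrapped += 2.0 * math.pi
    return wrapped


def _bin_amplitude(spec: np.ndarray, n: int, k: int) -> float:
    return 2.0 * abs(spec[k]) / n


def fourier_component(
    trace: AveragedTrace, frequency_hz: float
) -> tuple[float, float, int]:
    """Amplitude (μV, peak), sine-phase (rad) and bin index at ``frequency_hz``.

    The frequency must be bin aligned (``frequency x sweep_length`` an
    integer ``k`` with ``1 <= k < N/2``); exact for bin-aligned sinusoids.
    """
    n = trace.n_samples
    k_float = frequency_hz * trace.sweep_length_s
    k = round(k_float)
    if abs(k_float - k) > 1e-9 or not 1 <= k < n / 2:
        lo = math.floor(k_float) / trace.sweep_length_s
        hi = (math.floor(k_float) + 1) / trace.sweep_length_s
        raise ValueError(
            f"{frequency_hz:g} Hz is not a valid analysis bin for a "
            f"{trace.sweep_length_s:g} s sweep of {n} samples; nearest bin-aligned "
            f"frequencies are {lo:g} and {hi:g} Hz")
    spec = np.fft.rfft(trace.samples)
    amplitude = _bin_amplitude(spec, n, k)
    phase = _wrap_phase(float(np.angle(spec[k])) + math.pi / 2.0)
    return amplitude, phase, k


def noise_estimate(trace: AveragedTrace, frequency_hz: float) -> float:
    """Mean amplitude (same peak convention) of the two directly adjacent bins."""
    _, _, k = fourier_component(trace, frequency_hz)
    if k - 1 < 1:
        raise ValueError(
            f"no noise estimate at bin {k}: the lower adjacent bin would be DC")
    n = trace.n_samples
    spec = np.fft.rfft(trace.samples)
    return 0.5 * (_bin_amplitude(spec, n, k - 1) + _bin_amplitude(spec, n, k + 1))


def noise_correct(amplitude_uV: float, noise_uV: float, method: str = "linear") -> float:
    """Remove the background-noise contribution from a measured amplitude.

    ``linear``: max(0, amplitude − noise).  ``power``:
    sqrt(max(0, amplitude² − noise²)), subtraction in the power domain.
    """
    if amplitude_uV < 0 or noise_uV < 0:
        raise ValueError("amplitude and noise must be >= 0")
    if method == "linear":
        return max(0.0, amplitude_uV - noise_uV)
    if method == "power":
        return math.sqrt(max(0.0, amplitude_uV**2 - noise_uV**2))
    raise ValueError(f"unknown noise correction method: {method!r}")


def snr(amplitude_uV: float, noise_uV: float) -> float:
    """Signal-to-noise ratio amplitude/noise.

    Returns ``inf`` when noise is zero but signal is present (noiseless
    fixtures) and 0 when both vanish.
    """
    if noise_uV < 0:
        raise ValueError("noise_uV must be >= 0")
    if noise_uV == 0.0:
        return math.inf if amplitude_uV > 0 else 0.0
    return amplitude_uV / noise_uV


def analyze_trace(
    trace: AveragedTrace, noise_method: str = "linear"
) -> SpectralComponent:
    """Full spectral measurement of a trace at its condition's fundamental."""
    f = trace.condition.frequency_hz
    amplitude, phase, k = fourier_component(trace, f)
    noise = noise_estimate(trace, f)
    corrected = noise_correct(amplitude, noise, noise_method)
    return SpectralComponent(
        frequency_hz=f, bin_index=k, amplitude_uV=amplitude, phase_rad=phase,
        noise_uV=noise, corrected_amplitude_uV=corrected,
        snr=snr(amplitude, noise))
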