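"""Artifact rejection, averaging, brick-wall filtering and detrending."""

import numpy as np
import pytest

from pergss.preprocess import (average_sweeps, detrend_linear, lowpass_filter,
                               preprocess_block, reject_artifacts)
from pergss.stimulus import StimulusCondition
from pergss.sweep_io import SweepBlock
from conftest import make_trace, sinusoid


def _block(sweeps):
    return SweepBlock(subject_id="s", group="control", eye="left",
                      condition=StimulusCondition(0.8, 12.5),
                      sampling_rate_hz=500.0, sweep_length_s=0.96,
                      sweeps=np.asarray(sweeps, dtype=float))


class TestArtifactRejection:
    def test_threshold_rule(self):
        ok = np.zeros(480)
        spike_pos = np.zeros(480); spike_pos[100] = 121.0
        spike_neg = np.zeros(480); spike_neg[7] = -121.0
        edge = np.full(480, 120.0)
        kept, n_rej = reject_artifacts(_block([ok, spike_pos, edge, spike_neg]))
        assert n_rej == 2
        np.testing.assert_array_equal(kept, np.stack([ok, edge]))

    def test_order_preserved(self):
        sweeps = np.arange(5)[:, None] * np.ones((5, 480))
        sweeps[2, 3] = 500.0
        kept, _ = reject_artifacts(_block(sweeps))
        assert list(kept[:, 0]) == [0.0, 1.0, 3.0, 4.0]

    def test_all_rejected_errors(self):
        with pytest.raises(ValueError, match="threshold"):
            reject_artifacts(_block(np.full((3, 480), 200.0)))

    def test_peak_to_peak_option(self):
        sweep = np.zeros(480)
        sweep[0], sweep[1] = 70.0, -70.0  # pp = 140 > 120, max |v| = 70 <= 120
        _, n_abs = reject_artifacts(_block([sweep]), criterion="absolute")
        assert n_abs == 0
        with pytest.raises(ValueError):  # the single sweep gets rejected
            reject_artifacts(_block([sweep]), criterion="peak_to_peak")


class TestAveraging:
    def test_pointwise_mean(self):
        out = average_sweeps(np.stack([np.zeros(480), np.full(480, 2.0)]))
        np.testing.assert_array_equal(out, np.ones(480))

    def test_single_sweep_identity(self):
        s = sinusoid(2.0, 12.5)
        np.testing.assert_array_equal(average_sweeps(s[None, :]), s)

    def test_identical_sinusoids_average_to_themselves(self):
        s = sinusoid(1.5, 18.75)
        out = average_sweeps(np.tile(s, (10, 1)))
        np.testing.assert_allclose(out, s, atol=1e-12)


class TestLowpass:
    def test_passband_identity(self):
        trace = make_trace(sinusoid(2.0, 12.5))
        out = lowpass_filter(trace, 40.0)
        np.testing.assert_allclose(out.samples, trace.samples, atol=1e-10)

    def test_stopband_removal_of_bin_aligned_tone(self):
        """12.5 + 62.5 Hz mix (both bin aligned): only 12.5 Hz survives."""
        lo = sinusoid(2.0, 12.5, phase=0.3)
        hi = sinusoid(1.0, 62.5, phase=-1.1)  # bin 60, above the 40 Hz cutoff
        out = lowpass_filter(make_trace(lo + hi), 40.0)
        np.testing.assert_allclose(out.samples, lo, atol=1e-10)

    def test_matches_direct_reconstruction_from_retained_bins(self):
        """Oracle: the filter equals rebuilding the trace from bins <= cutoff,
        including for non-bin-aligned interference (e.g. 60 Hz mains)."""
        x = sinusoid(2.0, 12.5, phase=0.3) + sinusoid(1.0, 60.0, phase=-1.1)
        out = lowpass_filter(make_trace(x), 40.0)
        spec = np.fft.rfft(x)
        freqs = np.fft.rfftfreq(480, d=1 / 500.0)
        spec[freqs > 40.0] = 0.0
        np.testing.assert_allclose(out.samples, np.fft.irfft(spec, n=480),
                                   atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        trace = make_trace(rng.normal(size=480))
        once = lowpass_filter(trace, 40.0)
        twice = lowpass_filter(once, 40.0)
        np.testing.assert_allclose(twice.samples, once.samples, atol=1e-12)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_filter(make_trace(np.zeros(480)), 250.0)


class TestDetrend:
    def test_affine_annihilation(self):
        t = np.arange(480) / 500.0
        for method in ("protect", "ols"):
            out = detrend_linear(make_trace(3.0 - 2.5 * t), method=method)
            np.testing.assert_allclose(out.samples, 0.0, atol=1e-9)

    def test_protect_preserves_fundamental_exactly(self):
        """Drifted sinusoid: the response-aware fit removes only the drift."""
        t = np.arange(480) / 500.0
        s = sinusoid(2.0, 12.5, phase=0.7)
        out = detrend_linear(make_trace(s + 4.0 + 3.0 * t))
        np.testing.assert_allclose(out.samples, s, atol=1e-9)

    def test_ols_recovers_drifted_amplitude_within_half_pct(self):
        """Plain OLS detrending leaves a small fundamental-bin bias, bounded
        by the line/sinusoid non-orthogonality over a finite window."""
        from pergss.spectral import fourier_component

        t = np.arange(480) / 500.0
        s = sinusoid(2.0, 12.5, phase=0.7)
        out = detrend_linear(make_trace(s + 4.0 + 3.0 * t), method="ols")
        amp, _, _ = fourier_component(out, 12.5)
        assert abs(amp - 2.0) / 2.0 <= 5e-3

    def test_ols_zero_mean_and_slope(self):
        rng = np.random.default_rng(3)
        out = detrend_linear(make_trace(rng.normal(size=480)), method="ols")
        t = np.arange(480) / 500.0
        assert abs(out.samples.mean()) < 1e-9
        slope = np.polyfit(t, out.samples, 1)[0]
        assert abs(slope) < 1e-9

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        trace = make_trace(rng.normal(size=480))
        for method in ("protect", "ols"):
            once = detrend_linear(trace, method=method)
            twice = detrend_linear(once, method=method)
            np.testing.assert_allclose(twice.samples, once.samples, atol=1e-9)


def test_filter_detrend_order_irrelevant_for_the_measurement():
    """Stage order only matters through Gibbs ringing of the subtracted
    drift; at the analysis bin the two orders agree, exactly so when no
    drift is present."""
    from pergss.spectral import fourier_component

    s = sinusoid(2.0, 12.5, phase=0.7)
    # drift-free: full-trace agreement to machine precision
    trace = make_trace(s)
    fd = detrend_linear(lowpass_filter(trace, 40.0))
    df_ = lowpass_filter(detrend_linear(trace), 40.0)
    np.testing.assert_allclose(fd.samples, df_.samples, atol=1e-12)
    # strong drift (3 μV/s): analysis-bin measurement agrees closely
    t = np.arange(480) / 500.0
    drifted = make_trace(s + 4.0 + 3.0 * t)
    fd = detrend_linear(lowpass_filter(drifted, 40.0))
    df_ = lowpass_filter(detrend_linear(drifted), 40.0)
    amp1, ph1, _ = fourier_component(fd, 12.5)
    amp2, ph2, _ = fourier_component(df_, 12.5)
    assert abs(amp1 - amp2) < 2e-3
    assert abs(ph1 - ph2) < 1e-3


def test_composite_pipeline_amplitude_preserving(quiet_noise):
    """Noiseless bin-aligned input passes through preprocessing unchanged."""
    from pergss.synthetic import generate_sweep_block
    from pergss.spectral import fourier_component

    cond = StimulusCondition(0.8, 18.75)
    block = generate_sweep_block(1.7, 48.0, cond, quiet_noise, n_sweeps=4, seed=0)
    with pytest.warns(UserWarning, match="artifact-free"):
        trace = preprocess_block(block)
    amp, _, _ = fourier_component(trace, 18.75)
    assert abs(amp - 1.7) < 1e-12
    assert trace.n_sweeps_used == 4
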