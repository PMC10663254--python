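import numpy as np
import pytest

from slowwave.containers import EvokedTrialSet
from slowwave.synthetic import SlowOscParams, simulate_slow_oscillation

FS = 5000.0


@pytest.fixture(scope="session")
def slow_osc_sim():
    """A 60 s high-SNR slow-oscillation simulation with ground truth."""
    params = SlowOscParams(duration=60.0, seed=11)
    return simulate_slow_oscillation(params)


def make_trialset(waveform_uv, fs=FS, intensity_ua=100.0, n_trials=1,
                  noise_sd=0.0, seed=0, baseline_ms=100.0):
    """Wrap a hand-built post-stimulus waveform into an EvokedTrialSet.

    ``waveform_uv`` is defined on a [-baseline_ms, 700) ms time axis at
    ``fs``; optional i.i.d. noise is added per trial.
    """
    dt = 1000.0 / fs
    t_ms = np.arange(-baseline_ms, 700.0, dt)
    w = np.asarray(waveform_uv, dtype=float)
    assert w.size == t_ms.size
    rng = np.random.default_rng(seed)
    epochs = w[None, None, :] + noise_sd * rng.standard_normal(
        (n_trials, 1, t_ms.size))
    return EvokedTrialSet(epochs=epochs, times_ms=t_ms, sampling_rate=fs,
                          intensity_ua=intensity_ua)


def times_ms(fs=FS, baseline_ms=100.0):
    return np.arange(-baseline_ms, 700.0, 1000.0 / fs)


def triangle_waveform(fs=FS, onset_ms=5.0, rise_ms=10.0, fall_ms=10.0,
                      peak_uv=100.0, baseline_ms=100.0):
    """Triangular deflection rising from exactly zero at ``onset_ms``."""
    t = times_ms(fs, baseline_ms)
    w = np.zeros_like(t)
    apex = onset_ms + rise_ms
    end = apex + fall_ms
    up = (t >= onset_ms) & (t < apex)
    dn = (t >= apex) & (t <= end)
    w[up] = (t[up] - onset_ms) * peak_uv / rise_ms
    w[dn] = peak_uv * (1 - (t[dn] - apex) / fall_ms)
    return t, w


def gaussian_bumps(components, fs=FS, baseline_ms=100.0):
    """Sum of (polarity, latency_ms, amplitude_uv, fwhm_ms) bumps."""
    t = times_ms(fs, baseline_ms)
    w = np.zeros_like(t)
    for pol, lat, amp, fwhm in components:
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        w += pol * amp * np.exp(-0.5 * ((t - lat) / sigma) ** 2)
    w[t < 0] = 0.0
    return t, w
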