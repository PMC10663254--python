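"""Seeded synthetic LFP and evoked-response generators with ground truth.

The slow-oscillation generator emulates the signal structure that the
Up/Down detector relies on: alternating active (Up) and silent (Down)
epochs in which a 200–1500 Hz broadband component (the multi-unit-activity
surrogate) is amplified by a fixed gain, band-limited gamma activity is
added, and the low-frequency LFP deflects, all riding on a 1/f background.
State durations are drawn from a truncated normal so that every realized
state is detectable yet the minimum-duration filter can still be exercised
by lowering the floor.

The evoked generator plants a deterministic multi-component template
(scaled by a saturating intensity gain) into noisy trials, mirroring the
50-pulse, 0.1 Hz stimulation protocol; the array generator spreads one
template over a multielectrode grid with exponential amplitude decay.

Every generator is a pure function of its parameters and seed; ground
truth (state labels, interval tables, noiseless templates) is exported
alongside the signal so recovery can be verified sample by sample.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d
from scipy.stats import truncnorm

from .containers import EvokedTrialSet, LfpRecording, ValidationError

__all__ = [
    "SlowOscParams",
    "GroundTruth",
    "StimulusProtocol",
    "EvokedComponent",
    "EvokedShapeParams",
    "ArrayGeometry",
    "simulate_slow_oscillation",
    "simulate_evoked_trials",
    "simulate_array_recording",
    "labels_to_intervals",
    "intervals_to_labels",
]


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class SlowOscParams:
    """Parameters of the synthetic slow-oscillation recording.

    Durations are seconds, amplitudes µV (RMS for the noise components).
    ``up_mua_gain`` multiplies the amplitude of the 200–1500 Hz broadband
    component during Up states relative to its Down-state baseline
    ``mua_base_amp``; a detectable recording needs gain > 1.
    """

    sampling_rate: float = 5000.0
    duration: float = 60.0
    up_dur_mean: float = 0.5
    up_dur_sd: float = 0.2
    down_dur_mean: float = 0.5
    down_dur_sd: float = 0.2
    duration_floor: float = 0.1
    up_mua_gain: float = 4.0
    mua_base_amp: float = 5.0
    up_gamma_amp: float = 10.0
    lfp_up_offset: float = -100.0
    background_1f_amp: float = 50.0
    noise_sd: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        vals = {
            "sampling_rate": self.sampling_rate,
            "duration": self.duration,
            "up_dur_mean": self.up_dur_mean,
            "up_dur_sd": self.up_dur_sd,
            "down_dur_mean": self.down_dur_mean,
            "down_dur_sd": self.down_dur_sd,
            "duration_floor": self.duration_floor,
            "up_mua_gain": self.up_mua_gain,
            "mua_base_amp": self.mua_base_amp,
            "up_gamma_amp": self.up_gamma_amp,
            "background_1f_amp": self.background_1f_amp,
            "noise_sd": self.noise_sd,
        }
        for name, v in vals.items():
            if not np.isfinite(v):
                raise ValidationError(f"{name} must be finite, got {v}")
            if name != "lfp_up_offset" and v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")
        if not np.isfinite(self.lfp_up_offset):
            raise ValidationError("lfp_up_offset must be finite")
        if self.sampling_rate <= 2 * 1500.0:
            raise ValidationError(
                "sampling_rate must exceed 3000 Hz so the 200-1500 Hz band "
                "is representable"
            )
        if self.duration <= 0:
            raise ValidationError("duration must be positive")


@dataclass
class GroundTruth:
    """Simulator-emitted truth: per-sample labels plus the interval table."""

    state_labels: np.ndarray  # 1 = Up, 0 = Down, one entry per sample
    intervals: list[tuple[int, float, float]]  # (state, start_s, end_s)
    generator_params: SlowOscParams

    def mean_true_duration(self, state: int) -> float:
        durs = [e - s for st, s, e in self.intervals if st == state]
        return float(np.mean(durs)) if durs else float("nan")


@dataclass
class StimulusProtocol:
    """Single-pulse electrical stimulation protocol."""

    n_pulses: int = 50
    pulse_width_ms: float = 0.3
    rate_hz: float = 0.1
    intensities_ua: tuple[float, ...] = tuple(range(40, 321, 40))

    @classmethod
    def striatal(cls) -> "StimulusProtocol":
        """40–320 µA in 40 µA steps (thalamo-striatal protocol)."""
        return cls(intensities_ua=tuple(range(40, 321, 40)))

    @classmethod
    def cortical(cls) -> "StimulusProtocol":
        """20–160 µA in 20 µA steps (thalamo-cortical protocol)."""
        return cls(intensities_ua=tuple(range(20, 161, 20)))

    def validate(self) -> None:
        if self.n_pulses < 1:
            raise ValidationError("n_pulses must be >= 1")
        if self.rate_hz <= 0:
            raise ValidationError("rate_hz must be positive")
        ints = np.asarray(self.intensities_ua, dtype=float)
        if ints.size and not np.all(np.diff(ints) > 0):
            raise ValidationError("intensities must be strictly increasing")


@dataclass
class EvokedComponent:
    """One deflection of the evoked template: a Gaussian bump.

    ``width_ms`` is the full width at half maximum; ``polarity`` is +1/-1.
    """

    polarity: int
    peak_latency_ms: float
    peak_amplitude_uv: float
    width_ms: float

    def validate(self) -> None:
        if self.polarity not in (-1, 1):
            raise ValidationError("polarity must be +1 or -1")
        if self.peak_latency_ms <= 0:
            raise ValidationError("peak latency must be positive")
        if self.width_ms <= 0:
            raise ValidationError("width must be positive")
        if self.peak_amplitude_uv < 0:
            raise ValidationError("peak amplitude must be >= 0 (use polarity)")


@dataclass
class EvokedShapeParams:
    """Evoked template shape and trial-noise model.

    ``intensity_scaling`` parametrizes a saturating Hill gain
    ``g(I) = h(I)/h(ref)`` with ``h(I) = 1 / (1 + (half/I)**slope)`` —
    logistic in log-intensity, monotone non-decreasing, anchored to 1 at
    the reference intensity so component amplitudes are in µV at that
    intensity.
    """

    components: list[EvokedComponent] = field(
        default_factory=lambda: [
            EvokedComponent(-1, 12.0, 50.0, 6.0),
            EvokedComponent(+1, 25.0, 30.0, 8.0),
        ]
    )
    intensity_scaling: dict = field(
        default_factory=lambda: {"ref_ua": 160.0, "half_ua": 80.0, "slope": 2.0}
    )
    trial_noise_sd: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        for c in self.components:
            c.validate()
        if self.trial_noise_sd < 0:
            raise ValidationError("trial_noise_sd must be >= 0")
        if self.intensity_scaling["slope"] < 0:
            raise ValidationError("intensity gain must be monotone (slope >= 0)")

    def gain(self, intensity_ua: float) -> float:
        s = self.intensity_scaling
        h = lambda i: 1.0 / (1.0 + (s["half_ua"] / i) ** s["slope"])  # noqa: E731
        return h(float(intensity_ua)) / h(s["ref_ua"])

    def template(self, times_ms: np.ndarray) -> np.ndarray:
        """Noiseless template at the reference intensity."""
        w = np.zeros_like(times_ms, dtype=float)
        for c in self.components:
            sigma = c.width_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            w += (
                c.polarity
                * c.peak_amplitude_uv
                * np.exp(-0.5 * ((times_ms - c.peak_latency_ms) / sigma) ** 2)
            )
        return w


@dataclass
class ArrayGeometry:
    """Planar multielectrode array layout (coordinates in µm)."""

    n_channels: int = 32
    pitch_um: float = 550.0
    layout: np.ndarray | None = None  # (n_channels, 2) coordinates

    def __post_init__(self) -> None:
        if self.layout is None:
            # 4 x 8 grid, row-major channel order
            rows, cols = 4, int(np.ceil(self.n_channels / 4))
            coords = [
                (c * self.pitch_um, r * self.pitch_um)
                for r in range(rows)
                for c in range(cols)
            ][: self.n_channels]
            self.layout = np.asarray(coords, dtype=float)
        else:
            self.layout = np.asarray(self.layout, dtype=float)
        if self.layout.shape != (self.n_channels, 2):
            raise ValidationError("layout must be (n_channels, 2)")
        if len({tuple(xy) for xy in self.layout}) != self.n_channels:
            raise ValidationError("channel coordinates must be unique")

    def distances_from(self, channel: int) -> np.ndarray:
        return np.linalg.norm(self.layout - self.layout[channel], axis=1)


# ---------------------------------------------------------------------------
# label/interval bookkeeping


def labels_to_intervals(
    labels: np.ndarray, sampling_rate: float
) -> list[tuple[int, float, float]]:
    """Run-length encode a binary label vector into (state, start_s, end_s).

    Intervals are half-open in seconds and tile the record exactly.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return [
        (int(labels[s]), s / sampling_rate, e / sampling_rate)
        for s, e in zip(starts, ends)
    ]


def intervals_to_labels(
    intervals: list[tuple[int, float, float]], n_samples: int, sampling_rate: float
) -> np.ndarray:
    labels = np.zeros(n_samples, dtype=np.int8)
    for state, start, end in intervals:
        i0 = int(round(start * sampling_rate))
        i1 = int(round(end * sampling_rate))
        labels[i0:i1] = state
    return labels


# ---------------------------------------------------------------------------
# slow-oscillation generator


def _draw_duration(
    rng: np.random.Generator, mean: float, sd: float, floor: float
) -> float:
    """Truncated-normal duration draw; degenerate parameters give 0."""
    if sd == 0:
        return mean if mean >= floor else 0.0
    a = (floor - mean) / sd
    return float(truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-RMS noise with 1/f amplitude spectrum (pink), DC removed."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    x = np.fft.irfft(spec * scale, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _bandpassed_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-passed with a zero-phase 4th-order filter."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def simulate_slow_oscillation(
    params: SlowOscParams,
) -> tuple[LfpRecording, GroundTruth]:
    """Generate a seeded slow-oscillation LFP recording with ground truth.

    The recording alternates Down and Up epochs (starting Down) whose
    durations are truncated-normal draws. During Up samples the broadband
    200–1500 Hz component is ``up_mua_gain`` times its Down amplitude,
    gamma-band (30–100 Hz) noise of RMS ``up_gamma_amp`` is added, and the
    LFP deflects by ``lfp_up_offset`` (smoothed so the deflection stays
    low-frequency). Identical parameters and seed give bit-identical
    output.
    """
    params.validate()
    fs = params.sampling_rate
    n = int(round(params.duration * fs))

    streams = np.random.SeedSequence(params.seed).spawn(5)
    rng_dur, rng_mua, rng_gamma, rng_white, rng_pink = (
        np.random.default_rng(s) for s in streams
    )

    # --- alternating state schedule ------------------------------------
    metadata: dict = {"warnings": []}
    mean_cycle = params.up_dur_mean + params.down_dur_mean
    if mean_cycle > 0 and params.duration < mean_cycle:
        metadata["warnings"].append("duration shorter than one mean cycle")

    edges: list[tuple[int, int, int]] = []  # (state, i0, i1) in samples
    t_idx = 0
    state = 0  # start in Down
    zero_draws = 0
    while t_idx < n:
        if state == 1:
            dur = _draw_duration(
                rng_dur, params.up_dur_mean, params.up_dur_sd, params.duration_floor
            )
        else:
            dur = _draw_duration(
                rng_dur, params.down_dur_mean, params.down_dur_sd, params.duration_floor
            )
        n_state = int(round(dur * fs))
        if n_state > 0:
            zero_draws = 0
            i1 = min(t_idx + n_state, n)
            edges.append((state, t_idx, i1))
            t_idx = i1
        else:
            # degenerate parameters (e.g. all-Down recording); if neither
            # state can produce samples, fill the remainder with Down
            zero_draws += 1
            if zero_draws >= 2:
                edges.append((0, t_idx, n))
                break
        state = 1 - state

    labels = np.zeros(n, dtype=np.int8)
    for st, i0, i1 in edges:
        labels[i0:i1] = st
    # merge consecutive same-state entries (possible around zero draws)
    intervals = labels_to_intervals(labels, fs)

    up_env = labels.astype(float)

    # --- signal components ----------------------------------------------
    mua = _bandpassed_noise(rng_mua, n, fs, (200.0, 1500.0))
    mua_amp = params.mua_base_amp * (
        1.0 + (params.up_mua_gain - 1.0) * up_env
    )
    gamma = _bandpassed_noise(rng_gamma, n, fs, (30.0, 100.0))
    offset_env = gaussian_filter1d(up_env, sigma=max(1.0, 0.010 * fs))

    x = (
        params.background_1f_amp * _one_over_f_noise(rng_pink, n, fs)
        + params.noise_sd * rng_white.standard_normal(n)
        + mua_amp * mua
        + params.up_gamma_amp * up_env * gamma
        + params.lfp_up_offset * offset_env
    )

    rec = LfpRecording(
        samples=x,
        sampling_rate=fs,
        metadata={**metadata, "generator": "simulate_slow_oscillation",
                  "seed": params.seed},
    )
    truth = GroundTruth(state_labels=labels, intervals=intervals,
                        generator_params=params)
    return rec, truth


# ---------------------------------------------------------------------------
# evoked generators


def simulate_evoked_trials(
    protocol: StimulusProtocol,
    shape: EvokedShapeParams,
    sampling_rate: float = 5000.0,
    baseline_ms: float = 100.0,
    post_ms: float = 700.0,
) -> list[EvokedTrialSet]:
    """Generate one noisy trial set per stimulation intensity.

    Each epoch is the deterministic template (components scaled by the
    intensity gain) plus i.i.d. Gaussian noise. Epochs run over
    ``[-baseline_ms, post_ms)`` relative to stimulus onset and must fit
    inside the inter-stimulus interval.
    """
    protocol.validate()
    shape.validate()
    isi_ms = 1000.0 / protocol.rate_hz
    if baseline_ms + post_ms > isi_ms:
        raise ValidationError(
            f"epoch window {baseline_ms + post_ms:.0f} ms exceeds the "
            f"{isi_ms:.0f} ms inter-stimulus interval"
        )
    if post_ms < 600.0:
        warnings.warn("post-stimulus span < 600 ms: long-lasting metrics "
                      "will not be computable", stacklevel=2)

    dt = 1000.0 / sampling_rate
    times_ms = np.arange(-baseline_ms, post_ms, dt)
    template = shape.template(times_ms)
    template[times_ms < 0] = 0.0  # nothing evoked before the stimulus

    out: list[EvokedTrialSet] = []
    child_seeds = np.random.SeedSequence(shape.seed).spawn(
        len(protocol.intensities_ua)
    )
    for intensity, ss in zip(protocol.intensities_ua, child_seeds):
        rng = np.random.default_rng(ss)
        g = shape.gain(intensity)
        noise = shape.trial_noise_sd * rng.standard_normal(
            (protocol.n_pulses, 1, times_ms.size)
        )
        epochs = g * template[np.newaxis, np.newaxis, :] + noise
        out.append(
            EvokedTrialSet(
                epochs=epochs,
                times_ms=times_ms,
                sampling_rate=sampling_rate,
                intensity_ua=float(intensity),
                protocol=protocol,
                truth={
                    "template": g * template,
                    "gain": g,
                    "components": shape.components,
                    "noise_sd": shape.trial_noise_sd,
                    "seed": shape.seed,
                },
            )
        )
    return out


def simulate_array_recording(
    geometry: ArrayGeometry,
    source_channel: int,
    decay_length_um: float,
    base: EvokedTrialSet,
) -> EvokedTrialSet:
    """Spread a single-channel trial set over a multielectrode array.

    Channel *k*'s noiseless template is the base template attenuated by
    ``exp(-distance(k, source) / decay_length_um)``; trial noise is drawn
    independently per channel.
    """
    if decay_length_um <= 0:
        raise ValidationError("decay_length_um must be positive")
    if not (0 <= source_channel < geometry.n_channels):
        raise ValidationError("source_channel outside the array layout")
    if "template" not in base.truth:
        raise ValidationError("base trial set carries no template ground truth")

    template = np.asarray(base.truth["template"], dtype=float)
    atten = np.exp(-geometry.distances_from(source_channel) / decay_length_um)
    templates = atten[:, np.newaxis] * template[np.newaxis, :]

    noise_sd = float(base.truth.get("noise_sd", 0.0))
    seed = int(base.truth.get("seed", 0))
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, 9173, int(base.intensity_ua)])
    )
    epochs = templates[np.newaxis, :, :] + noise_sd * rng.standard_normal(
        (base.n_trials, geometry.n_channels, template.size)
    )
    return EvokedTrialSet(
        epochs=epochs,
        times_ms=base.times_ms,
        sampling_rate=base.sampling_rate,
        intensity_ua=base.intensity_ua,
        protocol=base.protocol,
        truth={
            **base.truth,
            "templates": templates,
            "attenuation": atten,
            "source_channel": source_channel,
            "decay_length_um": decay_length_um,
        },
    )
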