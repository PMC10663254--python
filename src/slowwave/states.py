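"""Up/Down state detection and spectral analysis of slow-oscillation LFP.

The detector builds a z-score normalized multivariate time series from
three features of one LFP channel — the raw signal, a log-scaled estimate
of 200–1500 Hz power (the multi-unit-activity or MUA surrogate), and the
envelope of the variance of the gamma-filtered LFP — combines them
linearly by projecting on the first principal component, selects a
threshold from the bimodal distribution of the projection with a
two-component Gaussian mixture, binarizes, and enforces a minimum state
duration (80 ms by default) by iteratively merging sub-minimum intervals
into their surroundings.

Spectral analysis is Welch's method on the z-scored LFP (2 s window,
0.1 Hz bins) aggregated into the conventional alpha/beta/low-gamma/
high-gamma bands.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d
from sklearn.mixture import GaussianMixture

from .containers import LfpRecording, ValidationError
from .synthetic import labels_to_intervals

__all__ = [
    "FeatureMatrix",
    "ProjectionSeries",
    "ThresholdResult",
    "StateSegmentation",
    "StateStats",
    "PsdEstimate",
    "BandPowerSpec",
    "BistabilityError",
    "compute_log_mua",
    "compute_gamma_variance_envelope",
    "build_feature_matrix",
    "project_first_pc",
    "select_bimodal_threshold",
    "binarize_and_filter",
    "state_statistics",
    "welch_psd",
    "band_power",
    "segment_states",
    "StateDetectionResult",
]


class BistabilityError(ValueError):
    """The projection distribution shows no usable bimodality; the
    recording cannot be segmented into Up and Down states."""


# ---------------------------------------------------------------------------
# feature construction


def _bandpass(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def compute_log_mua(
    lfp: LfpRecording | np.ndarray,
    sampling_rate: float | None = None,
    band: tuple[float, float] = (200.0, 1500.0),
    power_window_s: float = 0.05,
    channel: int = 0,
    eps: float = 1e-10,
) -> np.ndarray:
    """Logarithmically scaled moving power of the band-passed LFP.

    The signal is band-passed (zero-phase 4th-order Butterworth), squared,
    averaged over ``power_window_s`` and natural-logged after flooring at
    ``eps`` (µV²), so the output is strictly finite and aligned sample by
    sample with the input. 200–1500 Hz power tracks nearby population
    firing and is the primary Up-state marker.
    """
    if isinstance(lfp, LfpRecording):
        x, fs = lfp.channel(channel), lfp.sampling_rate
    else:
        if sampling_rate is None:
            raise ValidationError("sampling_rate required for array input")
        x, fs = np.asarray(lfp, dtype=float), float(sampling_rate)
    if band[1] >= fs / 2:
        raise ValidationError(
            f"band upper edge {band[1]} Hz must be below Nyquist {fs / 2} Hz"
        )
    bp = _bandpass(x, fs, band)
    win = max(1, int(round(power_window_s * fs)))
    power = uniform_filter1d(bp**2, size=win, mode="nearest")
    return np.log(np.maximum(power, eps))


def compute_gamma_variance_envelope(
    lfp: LfpRecording | np.ndarray,
    sampling_rate: float | None = None,
    gamma_band: tuple[float, float] = (30.0, 100.0),
    var_window_s: float = 0.1,
    smooth_hz: float = 20.0,
    channel: int = 0,
) -> np.ndarray:
    """Envelope of the moving variance of the gamma-filtered LFP.

    Moving variance over ``var_window_s`` of the band-passed signal,
    smoothed by a zero-phase low-pass at ``smooth_hz``; non-negative and
    aligned with the input. The window must span at least three cycles of
    the lowest gamma frequency for the variance to be meaningful.
    """
    if isinstance(lfp, LfpRecording):
        x, fs = lfp.channel(channel), lfp.sampling_rate
    else:
        if sampling_rate is None:
            raise ValidationError("sampling_rate required for array input")
        x, fs = np.asarray(lfp, dtype=float), float(sampling_rate)
    if gamma_band[1] >= fs / 2:
        raise ValidationError("gamma band must lie below Nyquist")
    if var_window_s < 3.0 / gamma_band[0]:
        raise ValidationError(
            f"var_window_s={var_window_s} shorter than 3 cycles of "
            f"{gamma_band[0]} Hz"
        )
    bp = _bandpass(x, fs, gamma_band)
    win = max(1, int(round(var_window_s * fs)))
    mean = uniform_filter1d(bp, size=win, mode="nearest")
    var = uniform_filter1d(bp**2, size=win, mode="nearest") - mean**2
    var = np.maximum(var, 0.0)
    sos = signal.butter(4, smooth_hz, btype="lowpass", fs=fs, output="sos")
    env = signal.sosfiltfilt(sos, var)
    return np.maximum(env, 0.0)


@dataclass
class FeatureMatrix:
    """Time-aligned z-scored features: raw LFP, log-MUA, gamma variance."""

    z: np.ndarray  # (n_samples, 3)
    feature_rate: float
    step: int  # decimation factor relative to the source recording
    columns: tuple[str, str, str] = ("z_lfp", "z_logmua", "z_gammavar")


def build_feature_matrix(
    lfp_series: np.ndarray,
    logmua: np.ndarray,
    gammavar: np.ndarray,
    sampling_rate: float,
    feature_step_s: float = 0.005,
) -> FeatureMatrix:
    """Decimate the three feature series and z-score each column.

    The raw LFP is boxcar-smoothed over the decimation step before
    subsampling (crude anti-aliasing; the other two features are already
    smooth). Each column is z-scored over the full analyzed span, so any
    affine rescaling of an input leaves its column unchanged.
    """
    series = [np.asarray(s, dtype=float) for s in (lfp_series, logmua, gammavar)]
    n = series[0].size
    if any(s.size != n for s in series):
        raise ValidationError("feature series must share a common length")
    step = max(1, int(round(feature_step_s * sampling_rate)))
    if step > 1:
        series[0] = uniform_filter1d(series[0], size=step, mode="nearest")
    dec = [s[::step] for s in series]
    cols = []
    names = ("z_lfp", "z_logmua", "z_gammavar")
    for name, s in zip(names, dec):
        sd = np.std(s)
        if sd == 0 or not np.isfinite(sd):
            raise ValidationError(f"feature column {name} has zero variance")
        cols.append((s - np.mean(s)) / sd)
    return FeatureMatrix(
        z=np.column_stack(cols), feature_rate=sampling_rate / step, step=step
    )


# ---------------------------------------------------------------------------
# PCA combination and bimodal thresholding


@dataclass
class ProjectionSeries:
    """First-principal-component projection of the feature matrix."""

    pc1: np.ndarray
    loadings: np.ndarray  # unit-norm 3-vector
    explained_variance_fraction: float
    feature_rate: float
    step: int
    warnings: list[str] = field(default_factory=list)


def project_first_pc(fm: FeatureMatrix) -> ProjectionSeries:
    """Project the features onto the leading covariance eigenvector.

    The sign is fixed so pc1 correlates positively with the log-MUA
    column, making "high projection" mean "Up state" by convention. A
    rank-deficient covariance falls back to the dominant surviving
    direction with a warning flag.
    """
    z = fm.z
    cov = np.cov(z, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    warnings_: list[str] = []
    if np.sum(evals > 1e-12 * max(evals[0], 1.0)) < z.shape[1]:
        warnings_.append("rank-deficient feature covariance")
    v = evecs[:, 0]
    pc1 = z @ v
    if np.dot(pc1 - pc1.mean(), z[:, 1] - z[:, 1].mean()) < 0:
        v, pc1 = -v, -pc1
    total = float(np.sum(evals))
    evf = float(evals[0] / total) if total > 0 else 1.0
    return ProjectionSeries(
        pc1=pc1,
        loadings=v,
        explained_variance_fraction=evf,
        feature_rate=fm.feature_rate,
        step=fm.step,
        warnings=warnings_,
    )


@dataclass
class ThresholdResult:
    threshold: float
    separation_index: float  # Ashman's D of the fitted mixture
    means: tuple[float, float]
    sds: tuple[float, float]
    weights: tuple[float, float]


def select_bimodal_threshold(
    pc1: ProjectionSeries | np.ndarray,
    min_separation: float = 2.0,
    seed: int = 0,
) -> ThresholdResult:
    """Select the Up/Down threshold from the bimodal projection histogram.

    A two-component 1-D Gaussian mixture is fitted to the projection
    values; the threshold is the density-crossing point between the two
    component means (falling back to the midpoint when no crossing lies
    between them). Bimodality is quantified by Ashman's D
    ``sqrt(2)|m2-m1| / sqrt(s1^2+s2^2)``; D < ``min_separation`` (default
    2, the conventional cutoff for a resolvable two-mode mixture) raises
    :class:`BistabilityError`, signalling that the recording does not
    alternate between two states.
    """
    x = pc1.pc1 if isinstance(pc1, ProjectionSeries) else np.asarray(pc1, float)
    if x.size < 2:
        raise ValidationError("need at least 2 samples to fit a mixture")
    gm = GaussianMixture(n_components=2, n_init=3, random_state=seed)
    gm.fit(x.reshape(-1, 1))
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    lo, hi = np.argsort(means)
    m1, m2 = means[lo], means[hi]
    s1, s2 = sds[lo], sds[hi]
    w1, w2 = weights[lo], weights[hi]
    d = np.sqrt(2.0) * abs(m2 - m1) / np.sqrt(s1**2 + s2**2)
    if d < min_separation:
        raise BistabilityError(
            f"mixture separation index {d:.2f} below {min_separation}: the "
            "projection distribution is not bimodal; the recording does not "
            "appear bistable"
        )

    def diff(t: float) -> float:
        n1 = w1 / s1 * np.exp(-0.5 * ((t - m1) / s1) ** 2)
        n2 = w2 / s2 * np.exp(-0.5 * ((t - m2) / s2) ** 2)
        return n1 - n2

    a, b = m1, m2
    if diff(a) * diff(b) < 0:
        from scipy.optimize import brentq

        thr = float(brentq(diff, a, b))
    else:  # no crossing between the means
        thr = 0.5 * (m1 + m2)
    return ThresholdResult(
        threshold=thr,
        separation_index=float(d),
        means=(float(m1), float(m2)),
        sds=(float(s1), float(s2)),
        weights=(float(w1), float(w2)),
    )


# ---------------------------------------------------------------------------
# binarization and minimum-duration filtering


@dataclass
class StateSegmentation:
    """Binary Up/Down segmentation: per-sample labels + interval table."""

    labels: np.ndarray  # int8, 1 = Up, 0 = Down (at `rate`)
    rate: float
    intervals: list[tuple[int, float, float]]
    threshold_used: float
    min_duration: float = 0.080

    def interval_durations(self, state: int) -> np.ndarray:
        return np.array([e - s for st, s, e in self.intervals if st == state])


def _merge_short_intervals(
    runs: list[list[int]], min_samples: int
) -> list[list[int]]:
    """Iteratively absorb sub-minimum interior runs, shortest first.

    ``runs`` is a list of [state, i0, i1) sample runs in order. Runs at
    the record edges are exempt from the minimum. When an interior run is
    removed its two (equal-state) neighbours merge into one.
    """
    runs = [list(r) for r in runs]
    while True:
        candidates = [
            (r[2] - r[1], k)
            for k, r in enumerate(runs)
            if 0 < k < len(runs) - 1 and (r[2] - r[1]) < min_samples
        ]
        if not candidates:
            return runs
        _, k = min(candidates)  # shortest first, earliest on ties
        prev_run, nxt = runs[k - 1], runs[k + 1]
        merged = [prev_run[0], prev_run[1], nxt[2]]
        runs = runs[: k - 1] + [merged] + runs[k + 2 :]


def binarize_and_filter(
    detection_series: np.ndarray,
    threshold: float,
    rate: float,
    min_duration: float = 0.080,
) -> StateSegmentation:
    """Threshold the detection series and enforce the minimum duration.

    Samples at or above the threshold become Up (1), below become Down
    (0). Intervals shorter than ``min_duration`` (80 ms by default, the
    guard against random signal fluctuations) are then removed by
    iteratively merging the shortest sub-minimum interior interval into
    its surrounding state; boundary intervals truncated by the record
    edges are exempt. Raising the threshold can never increase the
    pre-filter Up time.
    """
    if min_duration <= 0:
        raise ValidationError("min_duration must be positive")
    if rate <= 0:
        raise ValidationError("rate must be positive")
    x = np.asarray(detection_series, dtype=float)
    raw = (x >= threshold).astype(np.int8)
    ivs = labels_to_intervals(raw, rate)
    runs = [
        [st, int(round(s * rate)), int(round(e * rate))] for st, s, e in ivs
    ]
    min_samples = int(np.ceil(min_duration * rate))
    runs = _merge_short_intervals(runs, min_samples)
    labels = np.zeros(x.size, dtype=np.int8)
    for st, i0, i1 in runs:
        labels[i0:i1] = st
    intervals = labels_to_intervals(labels, rate)
    return StateSegmentation(
        labels=labels,
        rate=rate,
        intervals=intervals,
        threshold_used=float(threshold),
        min_duration=float(min_duration),
    )


# ---------------------------------------------------------------------------
# state statistics


@dataclass
class StateStats:
    mean_up_duration: float  # s; NaN when no Up interval was detected
    mean_down_duration: float
    firing_rate_up: float  # mean log-MUA over Up samples (a.u.)
    firing_rate_down: float
    n_up: int
    n_down: int


def state_statistics(seg: StateSegmentation, logmua: np.ndarray) -> StateStats:
    """Mean state durations and mean log-MUA per state.

    ``logmua`` must be aligned with ``seg.labels`` (same rate and length).
    The mean log-MUA over the samples labelled 1 and 0 serves as the
    average firing-rate proxy for Up and Down states respectively. With
    zero intervals of a state the corresponding duration is NaN — an
    explicit "undefined" marker, never silently zero.
    """
    logmua = np.asarray(logmua, dtype=float)
    if logmua.size != seg.labels.size:
        raise ValidationError("logmua must align with the segmentation labels")
    up_d = seg.interval_durations(1)
    down_d = seg.interval_durations(0)
    up_mask = seg.labels == 1
    return StateStats(
        mean_up_duration=float(np.mean(up_d)) if up_d.size else float("nan"),
        mean_down_duration=float(np.mean(down_d)) if down_d.size else float("nan"),
        firing_rate_up=float(np.mean(logmua[up_mask])) if up_mask.any()
        else float("nan"),
        firing_rate_down=float(np.mean(logmua[~up_mask])) if (~up_mask).any()
        else float("nan"),
        n_up=int(up_d.size),
        n_down=int(down_d.size),
    )


# ---------------------------------------------------------------------------
# spectral analysis


@dataclass
class PsdEstimate:
    frequencies: np.ndarray  # Hz, uniform grid
    power: np.ndarray  # (z-scored-LFP units)^2 / Hz
    window_s: float
    bin_hz: float

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


def welch_psd(
    z_lfp: np.ndarray,
    sampling_rate: float,
    window_s: float = 2.0,
    bin_hz: float = 0.1,
) -> PsdEstimate:
    """Welch periodogram of the (typically z-scored) LFP.

    Hann-tapered 50%-overlapping segments of ``window_s`` seconds,
    zero-padded so the frequency grid has ``bin_hz`` spacing. The integral
    of the estimate over frequency approximates the signal variance.
    """
    x = np.asarray(z_lfp, dtype=float)
    nperseg = int(round(window_s * sampling_rate))
    if nperseg > x.size:
        raise ValidationError("window_s exceeds the record length")
    nfft = int(round(sampling_rate / bin_hz))
    if nfft < nperseg:
        raise ValidationError("bin_hz too coarse for the window length")
    freqs, pxx = signal.welch(
        x,
        fs=sampling_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        nfft=nfft,
        detrend=False,
        scaling="density",
    )
    return PsdEstimate(frequencies=freqs, power=pxx, window_s=window_s,
                       bin_hz=bin_hz)


@dataclass
class BandPowerSpec:
    """Named frequency bands (Hz, half-open [lo, hi))."""

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "alpha": (8.0, 12.0),
            "beta": (12.0, 30.0),
            "low_gamma": (30.0, 60.0),
            "high_gamma": (60.0, 100.0),
        }
    )

    def validate(self) -> None:
        edges = sorted(self.bands.values())
        for lo, hi in edges:
            if lo >= hi:
                raise ValidationError(f"band ({lo}, {hi}) has lower >= upper")
        for (lo1, hi1), (lo2, _) in zip(edges, edges[1:]):
            if lo2 < hi1:
                raise ValidationError("bands overlap beyond shared edges")


def band_power(psd: PsdEstimate, spec: BandPowerSpec | None = None) -> dict[str, float]:
    """Mean PSD per named band over half-open frequency intervals."""
    spec = spec or BandPowerSpec()
    spec.validate()
    out: dict[str, float] = {}
    fmax = psd.frequencies[-1] + psd.df
    for name, (lo, hi) in spec.bands.items():
        if hi > fmax:
            raise ValidationError(f"band {name} exceeds the PSD range")
        mask = (psd.frequencies >= lo) & (psd.frequencies < hi)
        if not mask.any():
            raise ValidationError(f"band {name} contains no frequency bins")
        out[name] = float(np.mean(psd.power[mask]))
    return out


# ---------------------------------------------------------------------------
# end-to-end detection


@dataclass
class StateDetectionResult:
    """Everything the multivariate detector produced for one channel."""

    segmentation: StateSegmentation  # at the feature rate
    full_rate_labels: np.ndarray  # upsampled back to the recording rate
    features: FeatureMatrix
    projection: ProjectionSeries
    threshold: ThresholdResult
    logmua_feature: np.ndarray  # decimated log-MUA, aligned with labels
    stats: StateStats


def segment_states(
    lfp: LfpRecording,
    channel: int = 0,
    min_duration: float = 0.080,
    detection_signal: str = "pc1",
    feature_step_s: float = 0.005,
    gamma_band: tuple[float, float] = (30.0, 100.0),
    mua_band: tuple[float, float] = (200.0, 1500.0),
    min_separation: float = 2.0,
    seed: int = 0,
) -> StateDetectionResult:
    """Run the full multivariate Up/Down detection on one channel.

    Features are built at a decimated rate, combined by PCA, thresholded
    at the Gaussian-mixture density crossing and duration-filtered.
    ``detection_signal`` selects which series is binarized: the PC1
    projection (default — the quantity whose bimodality justifies the
    threshold) or the z-scored log-MUA feature (the literal alternative
    reading); with ``"logmua"`` the threshold is still chosen from the
    bimodal distribution of that series.
    """
    if detection_signal not in ("pc1", "logmua"):
        raise ValidationError("detection_signal must be 'pc1' or 'logmua'")
    x = lfp.channel(channel)
    logmua = compute_log_mua(x, lfp.sampling_rate, band=mua_band)
    gammavar = compute_gamma_variance_envelope(
        x, lfp.sampling_rate, gamma_band=gamma_band
    )
    fm = build_feature_matrix(
        x, logmua, gammavar, lfp.sampling_rate, feature_step_s=feature_step_s
    )
    proj = project_first_pc(fm)
    series = proj.pc1 if detection_signal == "pc1" else fm.z[:, 1]
    thr = select_bimodal_threshold(series, min_separation=min_separation, seed=seed)
    seg = binarize_and_filter(
        series, thr.threshold, rate=fm.feature_rate, min_duration=min_duration
    )
    logmua_feature = logmua[:: fm.step]
    stats = state_statistics(seg, logmua_feature)
    full = np.repeat(seg.labels, fm.step)[: lfp.n_samples]
    if full.size < lfp.n_samples:  # pad the tail with the last label
        full = np.concatenate(
            [full, np.full(lfp.n_samples - full.size, seg.labels[-1], np.int8)]
        )
    return StateDetectionResult(
        segmentation=seg,
        full_rate_labels=full,
        features=fm,
        projection=proj,
        threshold=thr,
        logmua_feature=logmua_feature,
        stats=stats,
    )
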