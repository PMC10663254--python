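"""End-to-end pipeline: simulate -> detect/evoked analysis -> tables.

A single JSON-serializable :class:`RunConfig` holds the simulation
parameters and every analysis constant (80 ms minimum state duration,
20 µV / 3–50 ms peak criteria, 600 ms long-lasting window, 2 s / 0.1 Hz
Welch settings, the alpha/beta/low-gamma/high-gamma band edges, 50
pulses at 0.1 Hz). Config + seed fully determine every deterministic
stage; re-running an identical config reproduces identical output
checksums, recorded in a :class:`RunManifest`.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as swio
from .containers import ValidationError
from .evoked import analyze_evoked, intensity_response_curve, long_lasting_metrics
from .states import BandPowerSpec, band_power, segment_states, welch_psd
from .synthetic import (
    ArrayGeometry,
    EvokedShapeParams,
    SlowOscParams,
    StimulusProtocol,
    simulate_array_recording,
    simulate_evoked_trials,
    simulate_slow_oscillation,
)

__all__ = ["RunConfig", "RunManifest", "run_pipeline"]


@dataclass
class RunConfig:
    """Full pipeline configuration; defaults are the analysis constants."""

    seed: int = 0
    out_dir: str = "slowwave_out"
    # simulation blocks (None disables the stage)
    slow_osc: dict | None = field(default_factory=dict)
    evoked: dict | None = field(default_factory=dict)
    # analysis constants
    min_duration_ms: float = 80.0
    min_amp_uv: float = 20.0
    peak_window_ms: tuple[float, float] = (3.0, 50.0)
    long_window_ms: float = 600.0
    psd_window_s: float = 2.0
    psd_bin_hz: float = 0.1
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "alpha": (8.0, 12.0),
            "beta": (12.0, 30.0),
            "low_gamma": (30.0, 60.0),
            "high_gamma": (60.0, 100.0),
        }
    )
    n_pulses: int = 50
    stim_rate_hz: float = 0.1
    detection_signal: str = "pc1"
    baseline_window_ms: tuple[float, float] = (-100.0, 0.0)

    def validate(self) -> None:
        if self.min_duration_ms <= 0:
            raise ValidationError("min_duration_ms must be positive")
        if self.min_amp_uv < 0:
            raise ValidationError("min_amp_uv must be non-negative")
        if self.peak_window_ms[0] >= self.peak_window_ms[1]:
            raise ValidationError("peak_window_ms must be an increasing pair")
        if self.long_window_ms <= 0:
            raise ValidationError("long_window_ms must be positive")
        if self.psd_window_s <= 0 or self.psd_bin_hz <= 0:
            raise ValidationError("PSD window and bin size must be positive")
        if self.detection_signal not in ("pc1", "logmua"):
            raise ValidationError("detection_signal must be 'pc1' or 'logmua'")
        BandPowerSpec(bands={k: tuple(v) for k, v in self.bands.items()}).validate()

    # --- lossless JSON round-trip -------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["peak_window_ms"] = list(self.peak_window_ms)
        d["baseline_window_ms"] = list(self.baseline_window_ms)
        d["bands"] = {k: list(v) for k, v in self.bands.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "peak_window_ms" in d:
            d["peak_window_ms"] = tuple(d["peak_window_ms"])
        if "baseline_window_ms" in d:
            d["baseline_window_ms"] = tuple(d["baseline_window_ms"])
        if "bands" in d:
            d["bands"] = {k: tuple(v) for k, v in d["bands"].items()}
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, s: str) -> "RunConfig":
        return cls.from_dict(json.loads(s))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    checksums: dict[str, str]
    qc: dict
    started: float
    finished: float

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured stages in dependency order.

    Slow-oscillation stage: simulate, detect Up/Down states, write the
    segmentation/stats/PSD/band-power tables. Evoked stage: simulate the
    stimulation protocol, quantify peaks per intensity, write the metrics
    and intensity-curve tables, and run the long-lasting (600 ms)
    analysis on a 32-channel array spread of the highest intensity.
    """
    from . import __version__

    config.validate()  # fail before any stage runs
    started = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    qc: dict = {}
    files: list[Path] = []

    base_seed = int(config.seed) % (2**31 - 1)

    if config.slow_osc is not None:
        params = SlowOscParams(**{"seed": base_seed, **config.slow_osc})
        rec, truth = simulate_slow_oscillation(params)
        swio.save_recording(out / "recording.h5", rec)
        swio.intervals_to_csv(out / "true_intervals.csv", truth.intervals)

        res = segment_states(
            rec,
            min_duration=config.min_duration_ms / 1000.0,
            detection_signal=config.detection_signal,
            seed=base_seed,
        )
        swio.intervals_to_csv(out / "segmentation.csv", res.segmentation.intervals)
        stats = res.stats
        (out / "state_stats.json").write_text(
            json.dumps(
                {
                    "mean_up_duration_s": stats.mean_up_duration,
                    "mean_down_duration_s": stats.mean_down_duration,
                    "firing_rate_up": stats.firing_rate_up,
                    "firing_rate_down": stats.firing_rate_down,
                    "n_up": stats.n_up,
                    "n_down": stats.n_down,
                    "threshold": res.threshold.threshold,
                    "separation_index": res.threshold.separation_index,
                    "explained_variance_fraction":
                        res.projection.explained_variance_fraction,
                },
                sort_keys=True,
                indent=1,
            )
        )
        qc["separation_index"] = res.threshold.separation_index
        qc["detector_warnings"] = res.projection.warnings

        x = rec.channel(0)
        z = (x - x.mean()) / x.std()
        psd = welch_psd(z, rec.sampling_rate, config.psd_window_s,
                        config.psd_bin_hz)
        pd.DataFrame(
            {"frequency_hz": psd.frequencies, "power": psd.power}
        ).to_csv(out / "psd.csv", index=False)
        bp = band_power(psd, BandPowerSpec(
            bands={k: tuple(v) for k, v in config.bands.items()}))
        pd.DataFrame(
            [{"band": k, "lo_hz": config.bands[k][0],
              "hi_hz": config.bands[k][1], "power": v} for k, v in bp.items()]
        ).to_csv(out / "band_power.csv", index=False)
        files += [out / "recording.h5", out / "true_intervals.csv",
                  out / "segmentation.csv", out / "state_stats.json",
                  out / "psd.csv", out / "band_power.csv"]

    if config.evoked is not None:
        protocol = StimulusProtocol(
            n_pulses=config.n_pulses, rate_hz=config.stim_rate_hz,
            **config.evoked.get("protocol", {})
        )
        shape = EvokedShapeParams(
            **{"seed": base_seed + 1, **config.evoked.get("shape", {})}
        )
        trialsets = simulate_evoked_trials(protocol, shape)
        metrics_by_intensity = {
            ts.intensity_ua: analyze_evoked(
                ts,
                min_amp_uv=config.min_amp_uv,
                window_ms=config.peak_window_ms,
                baseline_window_ms=config.baseline_window_ms,
            )
            for ts in trialsets
        }
        rows = []
        for intensity, pms in metrics_by_intensity.items():
            for pm in pms:
                rows.append(
                    {
                        "channel": pm.channel,
                        "intensity_ua": intensity,
                        "pos_latency_ms": pm.pos_peak.latency_ms
                        if pm.pos_peak else np.nan,
                        "pos_value_uv": pm.pos_peak.value_uv
                        if pm.pos_peak else np.nan,
                        "neg_latency_ms": pm.neg_peak.latency_ms
                        if pm.neg_peak else np.nan,
                        "neg_value_uv": pm.neg_peak.value_uv
                        if pm.neg_peak else np.nan,
                        "amplitude_uv": max(
                            (p.amplitude_uv for p in (pm.pos_peak, pm.neg_peak)
                             if p and p.amplitude_uv is not None),
                            default=np.nan,
                        ),
                        "auc_uv_ms": max(
                            (p.auc_uv_ms for p in (pm.pos_peak, pm.neg_peak)
                             if p and p.auc_uv_ms is not None),
                            default=np.nan,
                        ),
                    }
                )
        pd.DataFrame(rows).to_csv(out / "evoked_metrics.csv", index=False)
        intensity_response_curve(metrics_by_intensity).to_csv(
            out / "intensity_curve.csv", index=False
        )

        geometry = ArrayGeometry()
        array_ts = simulate_array_recording(
            geometry, source_channel=0, decay_length_um=800.0,
            base=trialsets[-1]
        )
        ll = long_lasting_metrics(
            array_ts, window_ms=config.long_window_ms,
            baseline_window_ms=config.baseline_window_ms,
        )
        (out / "long_lasting.json").write_text(
            json.dumps(
                {
                    "auc_600": ll.auc_600,
                    "channel_spread": ll.channel_spread,
                    "temporal_sd": ll.temporal_sd,
                    "per_channel_auc": ll.per_channel_auc.tolist(),
                    "window_ms": ll.window_ms,
                    "intensity_ua": array_ts.intensity_ua,
                },
                sort_keys=True,
                indent=1,
            )
        )
        files += [out / "evoked_metrics.csv", out / "intensity_curve.csv",
                  out / "long_lasting.json"]

    manifest = RunManifest(
        config_hash=config.config_hash(),
        package_version=__version__,
        checksums={f.name: _sha256(f) for f in files},
        qc=qc,
        started=started,
        finished=time.time(),
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
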