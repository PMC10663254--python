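# slowwave

Analysis of in vivo slow-oscillation electrophysiology: multivariate
Up/Down state detection from local field potentials (LFP), spectral band
power, and quantification of stimulus-evoked thalamo-striatal /
thalamo-cortical responses — together with a seeded synthetic-data
simulator that exports ground truth, so every stage of the pipeline can
be verified without animal recordings.

It is written for electrophysiologists and methods developers who record
cortical or striatal LFP under deep anesthesia (slow-oscillation regime,
~1 Hz alternation of active *Up* and silent *Down* states) and need a
reproducible, scriptable version of the standard semi-manual analysis.

## The method

**Up/Down state detection.** For each LFP channel (5 kHz digitization,
0.1 Hz high-pass), three features are built on a common timeline:

* the raw LFP signal;
* log-MUA: a logarithmically scaled estimate of 200–1500 Hz LFP power
  (band-pass, square, 50 ms moving average, ε-floored log) — a proxy for
  local population firing;
* the envelope of the moving variance of the gamma-filtered
  (30–100 Hz) LFP.

The three series are z-score normalized, combined by principal component
analysis, and the projection on the first principal component
(sign-aligned with log-MUA) yields a bimodal distribution whose two modes
are Up and Down samples. A two-component Gaussian mixture is fitted; the
density crossing between the component means is the detection threshold,
and Ashman's D of the fit serves as a bimodality diagnostic (recordings
without bistability are rejected rather than mis-segmented). The
binarized signal is then cleaned by a minimum state duration of 80 ms:
sub-minimum intervals are iteratively merged, shortest first, into their
surrounding state. Outputs are per-sample labels, an interval table,
mean Up/Down durations and the mean log-MUA per state (firing-rate
proxy).

**Spectral analysis.** Welch PSD of the z-scored LFP (2 s Hann windows,
50% overlap, zero-padded to 0.1 Hz bins), aggregated into alpha
(8–12 Hz), beta (12–30 Hz), low-gamma (30–60 Hz) and high-gamma
(60–100 Hz) band power.

**Evoked responses.** Stimulation protocols deliver 50 single 0.3 ms
pulses at 0.1 Hz per intensity (40–320 µA striatal, 20–160 µA cortical).
Trials are averaged per channel and baseline-normalized (mean of the
pre-stimulus baseline set to 0). The first positive and first negative
peaks are detected subject to hard criteria — |amplitude| > 20 µV,
latency within 3–50 ms post-stimulus — with transition times bracketing
each deflection. Amplitude = |peak − first transition value|;
AUC = |∫ waveform| between the transitions (µV·ms). Long-lasting
responses are analyzed on per-channel baseline z-scored averages over a
600 ms post-stimulus window (per-channel |z| AUC, spread across the
32-channel array, and the channel-averaged trace's AUC and temporal SD).
Every detection carries a machine-readable QC record (prominence,
baseline SD, flags) replacing interactive visual review.

**Scalar quantifications and statistics.** Tracing input counts
normalized per starter neuron, dendritic spine density (spines/µm,
segments > 20 µm), Cavalieri volume (section spacing × Σ areas),
microdialysis percent-of-baseline (mean of 5 pre-drug fractions = 100%),
and the Benjamini–Hochberg step-up FDR procedure.

**Synthetic data.** `slowwave.synthetic` generates seeded recordings in
which Up epochs (truncated-normal durations) amplify a 200–1500 Hz
broadband component by a known gain, add 30–100 Hz gamma noise and a
low-frequency LFP deflection over a 1/f background; evoked trial sets
plant Gaussian-bump templates scaled by a saturating intensity gain; an
array generator spreads a template over a 32-channel, 550 µm-pitch grid
with exponential decay. Ground truth (labels, intervals, templates) is
exported for recovery testing.

## Worked example

```python
import numpy as np
from slowwave import SlowOscParams, simulate_slow_oscillation, segment_states

params = SlowOscParams(duration=60.0, seed=11)   # 60 s at 5 kHz
rec, truth = simulate_slow_oscillation(params)
res = segment_states(rec, seed=11)

agree = np.mean(res.full_rate_labels == truth.state_labels)
print(f"label agreement      {agree:.3f}")
print(f"mean Up duration     {res.stats.mean_up_duration:.3f} s "
      f"(truth {truth.mean_true_duration(1):.3f} s)")
print(f"separation index     {res.threshold.separation_index:.2f}")
print(f"firing-rate contrast {res.stats.firing_rate_up - res.stats.firing_rate_down:.2f}")
```

prints

```
label agreement      0.973
mean Up duration     0.530 s (truth 0.523 s)
separation index     3.70
firing-rate contrast 0.65
```

97% of samples are labelled identically to the simulator's ground truth;
the detected mean Up duration is within ~2% of the realized true mean;
Ashman's D ≈ 3.7 confirms a clearly bimodal PC1 projection; and the mean
log-MUA is ~0.6 log-units higher during Up than Down states. More
narrative scripts live in `examples/` (state detection, evoked peaks,
band power, FDR), and a thin CLI (`slowwave --help`) mirrors the
pipeline stages.

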