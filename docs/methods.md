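# Methods

This note documents the models, numerical choices and limitations behind
`slowwave`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic-data tests do and do not show
about real recordings.

## Signal model of the synthetic slow oscillation

`simulate_slow_oscillation` emulates the statistical structure that the
Up/Down detector exploits, not the biophysics that produces it. The
recording is a sum of independent components:

* **State schedule.** Alternating Down/Up epochs starting in Down.
  Durations are truncated-normal draws (floor 100 ms by default, just
  above the detector's 80 ms minimum so every generated state is in
  principle detectable; lowering the floor exercises the duration
  filter). No published duration distribution exists for this
  preparation at desk scale, so the law is a pragmatic choice: unimodal,
  positive, with independently controllable mean and spread per state.
  Defaults (0.5 s mean, 0.2 s SD for both states) give the ~1 Hz
  alternation characteristic of deep anesthesia.
* **Broadband MUA surrogate.** Gaussian white noise band-passed
  200–1500 Hz (4th-order zero-phase Butterworth), normalized to unit
  RMS, scaled to `mua_base_amp` (5 µV RMS) during Down and
  `up_mua_gain ×` that (gain 4) during Up. Band-passed noise matches the
  power band the detector measures without modeling spikes; the gain is
  applied as a sharp envelope so ground-truth labels align exactly with
  the power change.
* **Gamma surrogate.** Unit-RMS noise band-passed 30–100 Hz (the union
  of the conventional low/high gamma bands), added only during Up at
  `up_gamma_amp` (10 µV RMS).
* **LFP deflection.** A −100 µV offset during Up, smoothed with a 10 ms
  Gaussian kernel so the deflection is genuinely low-frequency.
* **Background.** 1/f-amplitude ("pink") noise at 50 µV RMS plus 5 µV
  white noise.

One top-level seed feeds a `SeedSequence` that spawns independent child
streams per component, so the duration schedule and each noise component
are reproducible in isolation; any `simulate_*` call is a pure function
of (parameters, seed).

What this generator does **not** emulate: travelling-wave structure
across channels, spike waveforms, non-stationary anesthesia depth,
movement or line-noise artifacts, and amplitude statistics fitted to any
real dataset (none are published for this preparation). Passing recovery
tests therefore demonstrates correctness of the *algorithmic chain* under
its stated assumptions, not field performance on arbitrary recordings.

## Up/Down detection

Features are computed at the full 5 kHz rate and decimated to a 5 ms
step before z-scoring (the raw-LFP feature is boxcar-smoothed over the
step first, as crude anti-aliasing). The 50 ms log-MUA power window
resolves 80 ms events while suppressing sample-level variance; the
100 ms gamma-variance window spans ≥3 cycles of 30 Hz; the envelope is a
20 Hz zero-phase low-pass of the moving variance. Log power is floored
at 10⁻¹⁰ µV² before the log so silent stretches stay finite.

PCA is an eigendecomposition of the 3×3 feature covariance. The sign of
PC1 is fixed by positive correlation with the z-scored log-MUA, so
"high" always means "Up". A rank-deficient covariance (possible on
degenerate synthetic inputs) falls back to the dominant surviving
direction with a warning flag.

The threshold comes from a two-component 1-D Gaussian mixture on the
detection series: the density-crossing point between the component means
(via Brent root-finding on the weighted density difference), falling
back to the midpoint of means when no crossing lies between them.
Bimodality is gated on Ashman's D = √2·|m₂−m₁|/√(s₁²+s₂²) with floor
2.0 — the conventional value at which two Gaussian modes are resolvable.
Below the floor the detector raises rather than segmenting noise; this
replaces the visual examination step of interactive workflows, as does
the QC report (separation index, explained-variance fraction, warnings)
attached to every result.

Which series is thresholded is configurable (`detection_signal`):
default is the PC1 projection, whose bimodality justifies the threshold;
`"logmua"` preserves the alternative reading in which the binary signal
marks samples where log-MUA exceeds the threshold. On synthetic data
both recover ground truth; PC1 is slightly more robust because it pools
all three features.

**Minimum-duration filter.** Raw binarization is cleaned by iteratively
removing the shortest sub-minimum *interior* interval (ties: earliest),
merging its equal-state neighbours, until none remain. Boundary
intervals truncated by the record edges are exempt — their true duration
is censored, so rejecting them on apparent duration would be wrong.
Shortest-first is chosen over left-to-right scanning because it is
order-independent: the result does not depend on where the scan starts.
The filter is verified exactly against a brute-force rescan-and-flip
oracle on random label sequences.

Intervals are half-open `[start, end)` in seconds throughout. Mean state
durations include the censored edge intervals (they are part of what a
per-recording mean describes); the recovery tests compare against the
equally-censored true mean. An absent state yields NaN durations plus a
zero count, never a silent zero.

## Spectral analysis

Welch's method with Hann windows, 50% overlap, 2 s segments zero-padded
to 10 s for the 0.1 Hz grid. Taper, overlap and padding are
implementation choices (only window length and bin size are canonical);
density scaling is used so the integral of the PSD approximates the
signal variance — the white-noise Parseval check in the tests verifies
this to ~0.1%. Band power is the *mean* PSD over half-open `[lo, hi)`
bands, making band values comparable across bands of unequal width; a
flat spectrum reports the same value in every band.

## Evoked-response quantification

Metrics are computed on the trial-averaged, baseline-normalized trace
(baseline window −100–0 ms: pre-stimulus, and long relative to the
smoothing span). The median trace is stored alongside for outlier
audits but never drives metrics.

**Peak search.** Candidate extrema are found on a 2 ms boxcar-smoothed
copy of the average — on a noisy average roughly every third raw sample
is a local extremum, which would pin "earliest local extremum above
threshold" to the 20 µV crossing rather than the actual peak. Each
candidate is refined to the raw-trace extremum within the half-window,
and the hard criteria (|value| > 20 µV, latency in 3–50 ms, which also
excludes the stimulus artifact) are enforced on the refined peak. "First"
means earliest in time satisfying the criteria, never largest. The
late-response window is a parameter (`window_ms`) for second-peak
analyses beyond 50 ms.

**Transitions.** Onset = latest pre-peak sample at which the raw
average's magnitude is ≤ max(2×baseline SD, ε); offset symmetric after
the peak. The criterion is tested on the raw (not smoothed) trace:
smoothing would smear a sharp onset earlier by half the smoothing
window, and on noiseless data any peak-proportional floor would bias the
transition value — and hence the amplitude — by that fraction. A
peak-fraction term (`onset_fraction`) is available for very drifty
baselines but defaults to 0. On a noiseless deflection rising from
exactly zero, the onset is the last zero sample; with noise the onset
lands within the flank segment where the signal clears 2×SD.

**Amplitude and AUC.** Amplitude = |waveform(peak) − waveform(onset)|;
AUC = |trapezoidal integral between onset and offset| in µV·ms. Both are
exactly linear in waveform scale and equivariant under time shifts;
the triangle and rectangle closed forms in the tests pin the
discretization error to below one sample's contribution. Missing
transitions leave metrics `None` with a QC flag.

**Long-lasting responses.** Per channel, the average is z-scored against
its own baseline mean/SD and |z| is integrated over 0–600 ms. The
across-array spread statistic is ambiguous between (a) the SD across
channels of per-channel AUCs and (b) the temporal SD of the
channel-averaged trace; both are computed (`channel_spread`,
`temporal_sd`) and reported side by side. A zero-variance baseline
(noiseless synthetic data only) falls back to mean subtraction with a QC
flag rather than dividing by zero.

**Synthetic evoked defaults.** The default template is a −50 µV bump at
12 ms (FWHM 6 ms) and a +30 µV bump at 25 ms (FWHM 8 ms) — an early
negative and later positive deflection as in thalamically evoked
responses, with widths chosen so the two components are temporally
resolvable (each component's tail contributes < 0.1% of the other's
amplitude at its latency; the planted parameters are then the true peak
parameters of the summed template). The intensity gain is a Hill
function of intensity (logistic in log-intensity), anchored to 1 at a
reference intensity (160 µA) and monotone by construction, giving the
saturating intensity–response curves typical of these protocols. The
array generator attenuates the template by exp(−distance/λ) on a
4×8 grid at 550 µm pitch with independent per-channel noise.

## Scalar quantifications and FDR

The four formulas (inputs per starter neuron, spines/µm with the
> 20 µm inclusion rule, Cavalieri spacing×Σareas, percent of the 5
pre-drug-fraction baseline) are implemented literally and tested against
hand arithmetic; short dendritic segments are flagged excluded rather
than raising, since exclusion is a data-selection rule, not an error.

Benjamini–Hochberg is the classical step-up rule with adjusted values
`min_{j≥i} m·p_(j)/j` capped at 1, stable-sorted so ties resolve by
original index; rejecting at level q is identical to `adjusted ≤ q`.
The level q is a parameter, not a constant: a published overall FDR
describes a dataset, not the procedure. p = 0 is rejected as invalid
input (floor upstream if needed). Correctness is pinned by an exhaustive
all-cutoffs oracle on short p-lists, a statsmodels cross-check, and an
all-null simulation verifying mean false discovery proportion ≤ q.

## Problem sizes and determinism

The verification suite runs entirely on synthetic data: 60–200 s
recordings at 5 kHz for detector recovery, 50-trial epoch sets, 1,000
random sequences for the filter oracle, 2,000 replicates × 100 tests for
FDR control — sizes at which Monte-Carlo error is far below the
tolerances being checked while a full run stays in the minutes range on
one CPU. The pipeline writes HDF5 with timestamp tracking disabled and
canonically sorted JSON, so identical config + seed reproduces
byte-identical outputs (verified by SHA-256 in the manifest).

## Known limitations

* The detector assumes a single channel; multi-channel recordings are
  segmented per channel (no wave-propagation or consensus segmentation).
* The GMM threshold assumes two modes; more complex anesthesia states
  (burst-suppression with three regimes) will be rejected by the
  bimodality gate rather than handled.
* The simulator's noise is stationary and Gaussian; robustness to
  artifacts and drift is untested by construction.
* Evoked templates are smooth bumps; multiphasic responses with strongly
  overlapping components will report the summed waveform's extrema,
  which is the observable quantity but not a per-component
  decomposition.
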