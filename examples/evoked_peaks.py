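"""Quantify evoked peaks across stimulation intensities.

Simulates the 50-pulse, 0.1 Hz protocol at six intensities, detects the
first negative and positive peaks (> 20 uV, 3-50 ms) on the
trial-averaged baseline-normalized responses, and prints the resulting
intensity-response curve.
"""
from slowwave import (
    EvokedShapeParams,
    StimulusProtocol,
    analyze_evoked,
    intensity_response_curve,
    simulate_evoked_trials,
)

protocol = StimulusProtocol(intensities_ua=tuple(range(40, 241, 40)))
shape = EvokedShapeParams(trial_noise_sd=5.0, seed=7)

metrics = {}
for ts in simulate_evoked_trials(protocol, shape):
    pm = analyze_evoked(ts)[0]
    metrics[ts.intensity_ua] = [pm]
    neg = (f"{pm.neg_peak.latency_ms:5.1f} ms {pm.neg_peak.value_uv:7.1f} uV"
           if pm.neg_peak else "   below criteria   ")
    print(f"{ts.intensity_ua:5.0f} uA  first negative peak: {neg}")

curve = intensity_response_curve(metrics)
print("\nchannel-max amplitude by intensity (uV):")
print(curve[curve.channel == -1][["intensity_ua", "amplitude_uv",
                                  "auc_uv_ms"]].to_string(index=False))
# Amplitude grows and saturates with intensity (Hill gain); at the
# lowest intensities the response stays under the 20 uV hard criterion
# and no peak is reported - absence is a valid, QC-flagged outcome.
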