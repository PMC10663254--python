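"""Scalar quantifications and Benjamini-Hochberg FDR on toy tables.

Each formula is exercised on a small hand-checkable input: tracing
counts per starter neuron, spine density with the segment-length
inclusion rule, Cavalieri volume, microdialysis percent-of-baseline,
and BH correction of a p-value list.
"""
from slowwave import (
    DendriteMeasure,
    DialysateSeries,
    SectionAreas,
    TracedInputCounts,
    benjamini_hochberg,
    cavalieri_volume,
    normalize_traced_inputs,
    percent_of_baseline,
    spine_density,
)

ratios = normalize_traced_inputs(
    TracedInputCounts(traced={"cortex": 30, "thalamus": 45}, starter_count=15))
print(f"traced inputs per starter neuron : {ratios}")

m = spine_density(DendriteMeasure(n_spines=30, segment_length_um=25.0))
short = spine_density(DendriteMeasure(n_spines=10, segment_length_um=15.0))
print(f"spine density                    : {m.density:.2f} spines/um "
      f"(15 um segment included: {short.included})")

vol = cavalieri_volume(SectionAreas([100.0, 200.0, 100.0], 40.0))
print(f"Cavalieri volume                 : {vol:.0f} um^3")

pct = percent_of_baseline(DialysateSeries([8, 10, 12, 10, 10, 20, 15]))
print(f"percent of baseline              : {[round(p) for p in pct]}")

res = benjamini_hochberg([0.001, 0.008, 0.039, 0.041, 0.20, 0.74], q=0.05)
print(f"BH at q=0.05                     : rejected {res.n_rejected}/6, "
      f"adjusted {[round(float(a), 3) for a in res.adjusted]}")
# The 5 pre-drug fractions average exactly 100%; BH rejects the tests
# whose adjusted (step-up) p-values stay at or below the chosen q.
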