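"""Measure phase-locking values from a synthetic neck-movement signal.

A head-movement trial is synthesized with controllable phase coupling at the
two metrical frequencies (1 Hz and 2 Hz at 120 bpm), then analyzed exactly as
real data would be: band-pass filter (+/- 0.3 Hz), Hilbert instantaneous
phase, and the circular mean of the phase difference against a canonical
reference sinusoid.  PLV ranges from 0 (no phase consistency) to 1 (perfect
locking); tighter phase coupling (larger kappa) raises the measured PLV.
"""

import numpy as np

import groovesync as gs

for label, kappa2 in [("loose (kappa=1)", 1.0), ("moderate (kappa=4)", 4.0),
                      ("locked (kappa=inf)", np.inf)]:
    params = gs.MovementSimParams(
        amplitude_1hz=1.5, amplitude_2hz=3.0, kappa_1hz=2.0, kappa_2hz=kappa2,
    )
    angle = gs.simulate_neck_angle(params, duration_s=16.0, sampling_rate=100.0, seed=7)
    plv1 = gs.plv_pipeline(angle, 1.0).plv
    plv2 = gs.plv_pipeline(angle, 2.0).plv
    print(f"{label:>20}: PLV1 = {plv1:.3f}   PLV2 = {plv2:.3f}")

print()
print("expected asymptotic PLV for kappa=4 (Bessel ratio I1/I0):",
      f"{gs.mean_resultant_length(4.0):.3f}")
print("(single 16-s trials are short, so weak-coupling PLVs sit above the")
print(" asymptote; see docs/methods.md on finite-sample resultant-length bias)")
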