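"""Sensor-level lateralization and the time-resolved factor regression.

Simulates one small group of subjects, computes planar-gradient
time–frequency power, builds the parieto-occipital alpha and motor beta
lateralization series, and runs the per-time-point regression on the
±1-coded factors with Bonferroni-corrected group t tests.
"""

import numpy as np

from trackosc import (
    EnvelopeParams,
    default_sources,
    generate_design,
    make_sensor_array,
    simulate_epochs,
)
from trackosc import spectral as sp
from trackosc import laterality as lat

N_SUBJECTS = 8
sensors = make_sensor_array(32)
sources = default_sources(EnvelopeParams())
groups = sp.sensor_groups(sensors)

po_coefs, m_coefs = [], []
for si in range(N_SUBJECTS):
    design = generate_design(1, 1, 4, seed=100 + si)
    design = design[design["R"] != 0].reset_index(drop=True)
    ep = simulate_epochs(design, sources, sensors=sensors, fs=100.0,
                         noise_sd=1.0, seed=100 + si)
    planar = sp.planar_transform(ep)
    labels = list(zip(design["A"], design["T"], design["R"]))
    tfr = sp.condition_mean_tfr(planar.data, ep.times_ms, labels,
                                freqs=np.arange(8.0, 25.0, 2.0))
    tfr = sp.relative_change(sp.combine_planar(tfr))
    po = sp.group_band_series(tfr, {k: groups[k] for k in ("PO-L", "PO-R")},
                              (8.0, 12.0))
    mo = sp.group_band_series(tfr, {k: groups[k] for k in ("M-L", "M-R")},
                              (16.0, 25.0))
    coding = np.array(tfr.obs_labels, dtype=float)
    for series, store in ((lat.lateralize(po["PO-L"], po["PO-R"]), po_coefs),
                          (lat.lateralize(mo["M-L"], mo["M-R"]), m_coefs)):
        series = np.where(np.isnan(series), 0.0, series)
        store.append(lat.fit_timepoint_regression(series, coding))
    times = tfr.times_ms

for name, coefs in (("PO alpha", po_coefs), ("M beta", m_coefs)):
    track = lat.group_coefficient_track(np.stack(coefs), times)
    print(f"\n{name} lateralization — significant windows "
          f"(per-test p < {track.per_test_alpha:.2e}):")
    for coef in ("b1_hand", "b2_target", "b3_response"):
        wins = ", ".join(f"{a:.0f}..{b:.0f} ms" for a, b in track.windows[coef])
        print(f"  {coef:12s}: {wins or 'none'}")

print("\nThe injected structure makes the motor beta lateralization track "
      "the actor's hand first (from ~427 ms), the endpoint target from "
      "~810 ms, and the cued response after the cue (1000 ms); the "
      "parieto-occipital alpha lateralization is target-locked from "
      "~500 ms.  Detected windows should overlap those supports.")
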