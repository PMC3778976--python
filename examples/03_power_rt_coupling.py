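"""Pre-cue beta lateralization predicts reaction time.

Simulates the coupling study (lateralized beta series + RTs sharing a
latent per-subject bias), runs the recode → normalize → correlate chain,
and prints the pooled pre-cue correlation with its p-value bin.
"""

import numpy as np

from trackosc import coupling_track, precue_r, simulate_coupling_study

study = simulate_coupling_study(n_subjects=12, seed=2)
track = coupling_track(study)

r_pre = precue_r(study)
print(f"pooled pre-cue (900–1000 ms) power–RT correlation: r = {r_pre:.2f} "
      f"(n = {12 * 4} subject × condition pairs)")

sel = (track.times_ms >= 0) & (track.times_ms <= 1200)
print("\ncorrelation track during stimulus presentation (every 200 ms):")
for t, r, pb in zip(track.times_ms[sel][::10], track.r[sel][::10],
                    track.p_bin[sel][::10]):
    print(f"  t = {t:6.0f} ms   r = {r:+.2f}   {pb}")

print("\nThe generator couples each subject's pre-cue motor-beta "
      "lateralization bias to their reaction times (population r "
      "calibrated to 0.6), so the estimated r should build up toward the "
      "response-cue onset at 1000 ms: stronger congruent-response bias, "
      "faster responses.")
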