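"""DICS beamforming: localize an oscillatory source and extract ROIs.

Plants a 10 Hz source at a known grid voxel (active 600–1100 ms only),
scans a 6 mm grid with the frequency-domain beamformer, and reports the
localization error.  Then builds a synthetic group t map with a planted
significant cluster and applies the ROI rules (≥4 connected significant
neighbors, mean |t| ≥ 2.6).
"""

import numpy as np

from trackosc import attach_lead_fields, build_grid, csd, dics_filters, make_sensor_array
from trackosc.beamformer import SourceMap, extract_roi_maxima
from trackosc.forward import lead_field

rng = np.random.default_rng(4)
sensors = make_sensor_array(24)
grid = attach_lead_fields(build_grid(spacing_mm=6.0, radius_mm=40.0), sensors)
print(f"grid: {grid.n_voxels} voxels at {grid.spacing_mm:.0f} mm spacing")

target = grid.voxels_mni[rng.integers(grid.n_voxels)]
g = lead_field(target, [0.0, 1.0, 0.0], sensors)
g /= np.sqrt(np.mean(g**2))

fs = 250.0
times = np.arange(-1000.0, 3000.0 + 1e-9, 1000.0 / fs)
env = ((times >= 600) & (times <= 1100)).astype(float)
data = rng.standard_normal((20, sensors.n_sensors, len(times)))
for i in range(20):
    wave = np.sqrt(2) * env * np.sin(2 * np.pi * 10 * times / 1000.0
                                     + rng.uniform(0, 2 * np.pi))
    data[i] += np.outer(g, wave)

C_act = csd(data, times, (8, 12), (600, 1100))
C_base = csd(data, times, (8, 12), (-500, 0))
_, _, w = dics_filters((C_act + C_base) / 2.0, grid.lead_fields)
p_act = np.real(np.einsum("ns,su,nu->n", w, C_act, np.conj(w)))
p_base = np.real(np.einsum("ns,su,nu->n", w, C_base, np.conj(w)))
best = grid.voxels_mni[np.argmax((p_act - p_base) / p_base)]
print(f"planted source at {target}, localized at {best} "
      f"(error {np.linalg.norm(best - target):.1f} mm; one grid step = 6 mm)")

# ROI extraction on a synthetic group statistic map
t_map = 0.5 * rng.standard_normal(grid.n_voxels)
flag = np.zeros(grid.n_voxels, dtype=bool)
near = np.linalg.norm(grid.voxels_mni - best, axis=1) < 10.0
t_map[near] = 4.0
flag[near] = True
rois = extract_roi_maxima(SourceMap(grid=grid, t=t_map,
                                    p=np.ones(grid.n_voxels), flag=flag))
for i, roi in enumerate(rois.rois, 1):
    print(f"ROI {i}: peak at {roi.mni_mm} (mirror {roi.mirror_mni_mm}), "
          f"cluster of {len(roi.cluster_voxels)} voxels, "
          f"mean |t| = {roi.mean_abs_t:.2f}")
print("Each retained maximum is paired with its mirrored contralateral "
      "coordinate, forming a bilateral ROI pair.")
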