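"""DICS beamformer, group contrasts, FDR/bootstrap, ROI extraction."""

import numpy as np
import pandas as pd
import pytest

from trackosc.beamformer import (
    SourceMap,
    aligned_lateralization,
    attach_lead_fields,
    build_grid,
    csd,
    dics_filters,
    extract_roi_maxima,
    fdr_and_bootstrap,
    group_lateralized_contrast,
    lat_roi_series,
    source_power_map,
)
from trackosc.experiments import _brute_force_rois, localization_run
from trackosc.forward import lead_field
from trackosc.simulate import Epochs

FS = 250.0
TIMES = np.arange(-1000.0, 3000.0 + 1e-9, 1000.0 / FS)


@pytest.fixture(scope="module")
def grid10(sensors24_module):
    return attach_lead_fields(build_grid(spacing_mm=10.0, radius_mm=45.0),
                              sensors24_module)


@pytest.fixture(scope="module")
def sensors24_module():
    from trackosc.forward import make_sensor_array
    return make_sensor_array(24)


class TestGrid:
    def test_spacing_and_mirror_partners(self):
        g = build_grid(spacing_mm=6.0, radius_mm=40.0)
        assert np.all(g.mirror_index >= 0)
        assert np.allclose(g.voxels_mni[g.mirror_index] * [-1, 1, 1],
                           g.voxels_mni)
        assert not np.any(g.voxels_mni[:, 0] == 0)  # no midline voxels
        xs = np.unique(g.voxels_mni[:, 0])
        assert np.allclose(np.diff(xs), 6.0)

    def test_lead_fields_finite(self, grid10):
        assert np.all(np.isfinite(grid10.lead_fields))


class TestCSD:
    def test_single_sensor_sinusoid_gives_real_positive_scalar(self):
        x = np.sin(2 * np.pi * 20.0 * TIMES / 1000.0)
        C = csd(x[None, None, :], TIMES, band=(18, 22), window=(0, 1000))
        assert C.shape == (1, 1)
        assert C[0, 0].real > 0
        assert abs(C[0, 0].imag) < 1e-12

    def test_identical_signals_give_rank_one_unit_coherence(self):
        x = np.sin(2 * np.pi * 10.0 * TIMES / 1000.0 + 0.4)
        data = np.stack([x, x])[None]
        C = csd(data, TIMES, band=(8, 12), window=(0, 1000))
        coh = np.abs(C[0, 1]) / np.sqrt(C[0, 0].real * C[1, 1].real)
        assert coh == pytest.approx(1.0, rel=1e-9)
        sv = np.linalg.svd(C, compute_uv=False)
        assert sv[1] < 1e-9 * sv[0]

    def test_independent_noise_off_diagonals_vanish_with_trials(self):
        rng = np.random.default_rng(0)
        ratios = []
        for n_trials in (20, 320):
            data = rng.standard_normal((n_trials, 2, len(TIMES)))
            C = csd(data, TIMES, band=(8, 12), window=(0, 1000))
            ratios.append(np.abs(C[0, 1]) / np.sqrt(C[0, 0].real * C[1, 1].real))
        assert ratios[1] < ratios[0]
        assert ratios[1] < 0.2

    def test_conjugate_symmetry_and_psd(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((10, 5, len(TIMES)))
        C = csd(data, TIMES, band=(16, 25), window=(600, 1100))
        assert np.allclose(C, C.conj().T)
        evals = np.linalg.eigvalsh(C)
        assert evals.min() > -1e-12 * evals.max()

    def test_window_shorter_than_one_cycle_rejected(self):
        data = np.zeros((1, 2, len(TIMES)))
        with pytest.raises(ValueError, match="cycle"):
            csd(data, TIMES, band=(8, 12), window=(0, 100))


class TestDICSFilters:
    def test_unit_gain_on_full_rank_lead_fields(self):
        rng = np.random.default_rng(2)
        C = np.cov(rng.standard_normal((16, 200))) + 0j
        L = rng.standard_normal((5, 16, 3))
        for lam in (0.0, 0.05, 0.1):
            W, _, _ = dics_filters(C, L, lam=lam)
            WL = np.einsum("nvs,nsw->nvw", W, L)
            assert np.abs(WL - np.eye(3)).max() < 1e-8

    def test_scalar_unit_gain_on_sphere_lead_fields(self, grid10):
        rng = np.random.default_rng(3)
        C = np.cov(rng.standard_normal((24, 400))) + 0j
        _, ori, w = dics_filters(C, grid10.lead_fields)
        gains = np.einsum("ns,nsv,nv->n", w, grid10.lead_fields, ori)
        assert np.abs(gains - 1).max() < 1e-8

    def test_large_lambda_limit_is_scaled_pseudoinverse(self):
        rng = np.random.default_rng(4)
        C = np.cov(rng.standard_normal((10, 100))) + 0j
        L = rng.standard_normal((1, 10, 3))
        W, _, _ = dics_filters(C, L, lam=1e9)
        pinv = np.linalg.pinv(L[0])
        assert np.allclose(W[0], pinv, rtol=1e-4, atol=1e-8)

    def test_localization_within_one_grid_step(self):
        errs = [localization_run(seed) for seed in range(5)]
        assert max(errs) <= 6.0


class TestSourcePowerMap:
    def test_stationary_data_map_near_zero(self, sensors24_module, grid10):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((120, 24, len(TIMES)))
        ep = Epochs(data, TIMES,
                    pd.DataFrame({"A": 1, "T": 1, "R": 1,
                                  "i": np.arange(120)}),
                    sensors24_module)
        vals, _ = source_power_map(ep, grid10, band=(8, 12))
        # no task modulation: map fluctuates around 0 within sampling error
        assert abs(vals.mean()) < 0.1
        assert np.abs(vals).max() < 0.5

    def test_doubling_gain_leaves_relative_map_unchanged(self, sensors24_module, grid10):
        rng = np.random.default_rng(6)
        data = rng.standard_normal((20, 24, len(TIMES)))
        meta = pd.DataFrame({"A": 1, "T": 1, "R": 1, "i": np.arange(20)})
        a, _ = source_power_map(Epochs(data, TIMES, meta, sensors24_module),
                                grid10, band=(8, 12))
        b, _ = source_power_map(Epochs(2 * data, TIMES, meta, sensors24_module),
                                grid10, band=(8, 12))
        assert np.allclose(a, b, rtol=1e-9)


class TestGroupContrast:
    conds = pd.DataFrame([(a, t, r) for a in (-1, 1) for t in (-1, 1)
                          for r in (-1, 1)], columns=["A", "T", "R"])

    def test_hemispherically_identical_maps_give_zero(self, grid10):
        rng = np.random.default_rng(7)
        base = rng.standard_normal((4, 8, grid10.n_voxels))
        sym = (base + base[:, :, grid10.mirror_index]) / 2.0
        vals = group_lateralized_contrast(sym, self.conds, grid10)
        assert np.allclose(vals, 0.0, atol=1e-12)

    def test_flipping_labels_negates_the_contrast(self, grid10):
        rng = np.random.default_rng(8)
        maps = rng.standard_normal((4, 8, grid10.n_voxels))
        flipped = self.conds.copy()
        for c in ("A", "T", "R"):
            flipped[c] = -flipped[c]
        a = group_lateralized_contrast(maps, self.conds, grid10)
        # flipping the labels while mirroring the maps reproduces -a
        maps_m = maps[:, :, grid10.mirror_index]
        b = group_lateralized_contrast(maps_m, flipped, grid10)
        assert np.allclose(b, a, atol=1e-12)
        c = group_lateralized_contrast(maps, flipped, grid10)
        assert np.allclose(c, -a, atol=1e-12)

    def test_aligned_lateralization_is_antisymmetric(self, grid10):
        rng = np.random.default_rng(9)
        maps = rng.standard_normal((2, grid10.n_voxels))
        a = aligned_lateralization(maps, np.array([1, -1]), grid10)
        assert np.allclose(a[:, grid10.mirror_index], -a, atol=1e-12)

    def test_planted_lateralized_effect_recovered_at_pm_coordinate(
            self, sensors24_module, grid10):
        """A stimulus-type-dependent lateralized power difference planted at
        the premotor coordinate (±18, −18, 64) peaks within one grid step."""
        rng = np.random.default_rng(10)
        target = grid10.voxels_mni[np.argmin(np.linalg.norm(
            grid10.voxels_mni - np.array([18.0, -18.0, 64.0]), axis=1))]
        ti = int(np.argmin(np.linalg.norm(grid10.voxels_mni - target, axis=1)))
        mi = int(grid10.mirror_index[ti])
        n_subj = 8
        maps = 0.05 * rng.standard_normal((n_subj, 8, grid10.n_voxels))
        straight = (self.conds["A"] != self.conds["T"]).to_numpy()
        for ci in range(8):
            side = self.conds["T"].iloc[ci]
            amp = 0.6 if straight[ci] else 0.2
            lo = ti if side > 0 else mi      # suppress contralateral to T
            maps[:, ci, lo] -= amp
        vals = group_lateralized_contrast(maps, self.conds, grid10,
                                          contrast="stimulus_type")
        t = vals.mean(axis=0) / (vals.std(axis=0, ddof=1) / np.sqrt(n_subj))
        peak = grid10.voxels_mni[int(np.argmax(np.abs(t)))]
        assert np.linalg.norm(np.abs(peak) - np.abs(target)) <= 10.0


class TestFDRBootstrap:
    def test_all_small_p_all_flagged(self, grid10):
        rng = np.random.default_rng(11)
        vals = 1.0 + 0.01 * rng.standard_normal((8, grid10.n_voxels))
        smap = fdr_and_bootstrap(vals, grid10, n_boot=50, seed=0)
        assert smap.flag.all()
        assert np.all(smap.ci_low <= smap.ci_high)

    def test_null_fdr_controlled(self, grid10):
        rng = np.random.default_rng(12)
        n_flagged = 0
        for _ in range(30):
            vals = rng.standard_normal((10, grid10.n_voxels))
            smap = fdr_and_bootstrap(vals, grid10, n_boot=1, seed=0)
            n_flagged += smap.flag.sum()
        # BH under the (true) null: P(any discovery) <= alpha
        assert n_flagged / 30 < 1.0

    def test_deterministic_given_seed(self, grid10):
        rng = np.random.default_rng(13)
        vals = rng.standard_normal((6, grid10.n_voxels))
        a = fdr_and_bootstrap(vals, grid10, n_boot=25, seed=42)
        b = fdr_and_bootstrap(vals, grid10, n_boot=25, seed=42)
        assert np.array_equal(a.ci_low, b.ci_low)

    def test_invalid_boot_count_rejected(self, grid10):
        with pytest.raises(ValueError):
            fdr_and_bootstrap(np.zeros((5, grid10.n_voxels)), grid10, n_boot=0)


class TestROIExtraction:
    def _map_with_component(self, grid, voxels, t_value):
        t = np.zeros(grid.n_voxels)
        flag = np.zeros(grid.n_voxels, dtype=bool)
        t[voxels] = t_value
        flag[voxels] = True
        return SourceMap(grid=grid, t=t, p=np.ones(grid.n_voxels), flag=flag)

    def _connected_chain(self, grid, n):
        """n face-connected voxel ids grown by BFS from a start voxel."""
        start = int(np.argmin(np.linalg.norm(
            grid.voxels_mni - np.array([15.0, -25.0, 15.0]), axis=1)))
        lookup = {tuple(ijk): i for i, ijk in enumerate(grid.ijk)}
        ids = [start]
        seen = {start}
        queue = [start]
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                   (0, 0, 1), (0, 0, -1)]
        while queue and len(ids) < n:
            cur = queue.pop(0)
            i, j, k = grid.ijk[cur]
            for di, dj, dk in offsets:
                nb = lookup.get((i + di, j + dj, k + dk))
                if nb is not None and nb not in seen:
                    seen.add(nb)
                    ids.append(nb)
                    queue.append(nb)
                    if len(ids) == n:
                        break
        assert len(ids) == n
        return ids

    def test_six_voxel_component_passing_both_rules(self, grid10):
        vox = self._connected_chain(grid10, 6)
        smap = self._map_with_component(grid10, vox, 3.0)
        rois = extract_roi_maxima(smap)
        assert len(rois) == 1
        assert rois.rois[0].voxel_id in vox
        assert np.allclose(rois.rois[0].mirror_mni_mm,
                           rois.rois[0].mni_mm * [-1, 1, 1])

    def test_small_component_rejected(self, grid10):
        vox = self._connected_chain(grid10, 3)
        rois = extract_roi_maxima(self._map_with_component(grid10, vox, 5.0))
        assert len(rois) == 0

    def test_low_mean_t_component_rejected(self, grid10):
        vox = self._connected_chain(grid10, 8)
        rois = extract_roi_maxima(self._map_with_component(grid10, vox, 2.5))
        assert len(rois) == 0

    def test_empty_flag_set_gives_empty_roiset(self, grid10):
        smap = SourceMap(grid=grid10, t=np.zeros(grid10.n_voxels),
                         p=np.ones(grid10.n_voxels),
                         flag=np.zeros(grid10.n_voxels, dtype=bool))
        assert len(extract_roi_maxima(smap)) == 0

    def test_matches_exhaustive_oracle_on_random_maps(self, grid10):
        rng = np.random.default_rng(14)
        for _ in range(25):
            flag = rng.random(grid10.n_voxels) < 0.15
            t = 3.0 * rng.standard_normal(grid10.n_voxels)
            smap = SourceMap(grid=grid10, t=t, p=np.ones(grid10.n_voxels),
                             flag=flag)
            got = sorted((r.voxel_id,
                          frozenset(int(v) for v in r.cluster_voxels))
                         for r in extract_roi_maxima(smap).rois)
            assert got == _brute_force_rois(flag, t, grid10)


class TestLatROISeries:
    def _epochs_with_left_source(self, sensors, rng, lateralized=True):
        src = np.array([-18.0, -18.0, 64.0])
        g = lead_field(src, [0.0, 1.0, 0.0], sensors)
        g = g / np.sqrt(np.mean(g ** 2))
        n_tr = 16
        data = 0.3 * rng.standard_normal((n_tr, sensors.n_sensors, len(TIMES)))
        # beta desynchronization: amplitude drops inside 400-1200 ms
        env = np.where((TIMES > 400) & (TIMES < 1200), 0.4, 1.0)
        for i in range(n_tr):
            ph = rng.uniform(0, 2 * np.pi)
            wave = env * np.sin(2 * np.pi * 20.0 * TIMES / 1000.0 + ph)
            data[i] += np.outer(g, wave)
            if not lateralized:
                g2 = lead_field(src * [-1, 1, 1], [0.0, 1.0, 0.0], sensors)
                g2 = g2 / np.sqrt(np.mean(g2 ** 2))
                data[i] += np.outer(g2, env * np.sin(
                    2 * np.pi * 20.0 * TIMES / 1000.0
                    + rng.uniform(0, 2 * np.pi)))
        meta = pd.DataFrame({"A": 1, "T": 1, "R": 1, "i": np.arange(n_tr)})
        return Epochs(data, TIMES, meta, sensors)

    def test_left_only_desynchronization_gives_negative_series(
            self, sensors24_module):
        ep = self._epochs_with_left_source(sensors24_module,
                                           np.random.default_rng(15))
        series, times, _ = lat_roi_series(
            ep, [-18.0, -18.0, 64.0], [18.0, -18.0, 64.0], band=(16.0, 25.0))
        win = (times > 600) & (times < 1000)
        assert np.nanmean(series[0, win]) < 0

    def test_swapping_pair_members_negates(self, sensors24_module):
        ep = self._epochs_with_left_source(sensors24_module,
                                           np.random.default_rng(16))
        a, _, _ = lat_roi_series(ep, [-18.0, -18.0, 64.0],
                                 [18.0, -18.0, 64.0], band=(16.0, 25.0))
        with pytest.raises(ValueError):
            lat_roi_series(ep, [18.0, -18.0, 64.0], [-18.0, -18.0, 64.0],
                           band=(16.0, 25.0))
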