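"""End-to-end orchestration: simulate → spectral → stats → source → report.

``run_pipeline`` executes the whole analysis for one configuration and
writes tidy TSV/JSON artifacts into the run directory.  All randomness
derives from ``config.seed`` through named ``SeedSequence`` children, so a
given (config, seed) pair reproduces byte-identical outputs.

The generative story ties behavior to physiology: each subject gets a
lateralization bias strength per response-congruency cell; that bias
scales the lateralized envelope components of the simulated sources *and*
enters the same trials' reaction times through the RT model's coupling
term, so the power–RT correlation the analysis estimates has a known
ground truth.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import beamformer as bf
from . import coupling as cp
from . import design as dz
from . import laterality as lat
from . import spectral as sp
from .config import RunConfig, config_to_dict, save_config, validate_config
from .io import roi_frame, source_map_frame, write_tsv
from .simulate import default_sources, make_sensor_array, simulate_epochs

logger = logging.getLogger(__name__)

#: canonical order of the 8 response-required conditions
RESPONSE_CONDITIONS = sorted(c for c in dz.CONDITIONS if c[2] != 0)
CELLS = cp.CONGRUENCY_CELLS


def _cell_of(t: int, r: int) -> int:
    return CELLS.index((t, r))


def derive_design(config: RunConfig, rng_children) -> tuple[pd.DataFrame, np.ndarray]:
    """Design + RTs + per-subject cell bias gains (n_subjects, 4)."""
    design = dz.generate_design(config.n_subjects, config.design.n_blocks,
                                config.design.reps_per_condition,
                                seed=rng_children[0])
    rng = np.random.default_rng(rng_children[1])
    cpar = config.coupling
    gains = np.exp(cpar.subject_gain_sd * rng.standard_normal((config.n_subjects, 1))
                   + cpar.cell_gain_sd * rng.standard_normal((config.n_subjects, 4)))
    cell_rt = cpar.rt_cell_sd * rng.standard_normal((config.n_subjects, 4))

    from .simulate import BetaEnvelope
    env = BetaEnvelope(hemisphere=+1, params=config.envelopes)
    t_pre = np.arange(cpar.precue_window[0], cpar.precue_window[1] + 1e-9, 20.0)
    d_pre = env.lateral_power(t_pre, A=0, T=1, R=0).mean()

    resp = design["R"] != 0
    subj_idx = design["subject"].to_numpy() - 1
    bias = np.zeros(len(design))
    cell_idx = np.zeros(len(design), dtype=int)
    rr = design.loc[resp]
    ci = np.array([_cell_of(t, r) for t, r in zip(rr["T"], rr["R"])])
    cell_idx[resp.to_numpy()] = ci
    bias[resp.to_numpy()] = (
        -2.0 * d_pre * rr["R"].to_numpy() * rr["T"].to_numpy()
        * gains[subj_idx[resp], ci]
        + cell_rt[subj_idx[resp], ci] / max(cpar.coupling_ms, 1e-9))
    rt_params = dz.RTGenParams(**{**config.rt.__dict__,
                                  "coupling": cpar.coupling_ms})
    design = dz.generate_rts(design, rt_params, beta_bias=bias,
                             seed=rng_children[2])
    return design, gains


def subject_epochs(config: RunConfig, design: pd.DataFrame, gains: np.ndarray,
                   subject: int, sensors, seed) -> "Epochs":
    """Simulate one subject's response-required trials."""
    rows = design[(design["subject"] == subject) & (design["R"] != 0)]
    lat_gain = np.array([gains[subject - 1, _cell_of(t, r)]
                         for t, r in zip(rows["T"], rows["R"])])
    sources = default_sources(config.envelopes)
    return simulate_epochs(rows, sources, sensors=sensors,
                           fs=config.sim.fs_hz, tmin_ms=config.sim.tmin_ms,
                           tmax_ms=config.sim.tmax_ms,
                           noise_sd=config.sim.noise_sd,
                           lat_gain=lat_gain, seed=seed)


def sensor_lateralized_series(config: RunConfig, epochs) -> dict:
    """Per-condition PO-alpha and M-beta lateralized series for one subject."""
    spc = config.spectral
    planar = sp.planar_transform(epochs, k=spc.planar_neighbors)
    labels = list(zip(epochs.metadata["A"], epochs.metadata["T"],
                      epochs.metadata["R"]))
    freqs = np.arange(spc.freq_min_hz, spc.freq_max_hz + 1e-9, spc.freq_step_hz)
    tfr = sp.condition_mean_tfr(planar.data, planar.times_ms, labels,
                                window_ms=spc.window_ms, step_ms=spc.step_ms,
                                freqs=freqs)
    tfr = sp.combine_planar(tfr)
    tfr = sp.relative_change(tfr, baseline=spc.baseline_ms)
    groups = sp.sensor_groups(epochs.sensors)
    po = sp.group_band_series(tfr, {k: groups[k] for k in ("PO-L", "PO-R")},
                              spc.alpha_band)
    mo = sp.group_band_series(tfr, {k: groups[k] for k in ("M-L", "M-R")},
                              spc.beta_band)
    return {
        "times": tfr.times_ms,
        "valid": tfr.valid,
        "cond_labels": tfr.obs_labels,
        "po_alpha_lat": lat.lateralize(po["PO-L"], po["PO-R"]),
        "m_beta_lat": lat.lateralize(mo["M-L"], mo["M-R"]),
        "po_left": po["PO-L"], "po_right": po["PO-R"],
        "m_left": mo["M-L"], "m_right": mo["M-R"],
    }


def collapse_to_cells(series: np.ndarray, cond_labels) -> np.ndarray:
    """Average the 8 condition series into the 4 (T, R) congruency cells."""
    out = np.empty((4,) + series.shape[1:])
    for ci, (t, r) in enumerate(CELLS):
        idx = [i for i, (a_, t_, r_) in enumerate(cond_labels)
               if (t_, r_) == (t, r)]
        out[ci] = series[idx].mean(axis=0)
    return out


def subject_cell_median_rt(design: pd.DataFrame, subject: int) -> np.ndarray:
    rows = design[(design["subject"] == subject) & (design["R"] != 0)]
    med = rows.groupby(["T", "R"])["rt_ms"].median()
    return np.array([med.loc[cell] for cell in CELLS])


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Run every stage; returns the run directory.

    Any stage failure aborts with a message naming the stage; partial
    outputs are kept and MANIFEST.json records the completion state.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "config.yaml")
    manifest = {"seed": config.seed, "stages": {}, "config": config_to_dict(config)}

    def _done(stage, t0):
        manifest["stages"][stage] = {"status": "ok",
                                     "seconds": round(time.time() - t0, 2)}
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=1))

    def _fail(stage, err):
        manifest["stages"][stage] = {"status": "failed", "error": str(err)}
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(4 + 2 * config.n_subjects)
    summary: dict = {}

    # ---- behavior ---------------------------------------------------------
    t0 = time.time()
    try:
        design, gains = derive_design(config, children[:3])
        write_tsv(design, out / "design.tsv")
        behav = dz.summarize_behavior(design)
        med = behav.medians.copy()
        med.columns = [f"A{a:+d}_T{t:+d}_R{r:+d}" for a, t, r in med.columns]
        write_tsv(med.reset_index(), out / "median_rt.tsv")
        write_tsv(behav.effects, out / "behavior_effects.tsv")
        eff = dict(zip(behav.effects["contrast"], behav.effects["effect_ms"]))
        fstat = dict(zip(behav.effects["contrast"], behav.effects["F"]))
        resp_rt = design.loc[design["R"] != 0, "rt_ms"]
        summary["behavior"] = {
            "grand_mean_rt_ms": float(resp_rt.mean()),
            "congruency_effect_ms": -float(eff["congruency"]),
            "stimulus_type_effect_ms": -float(eff["stimulus_type"]),
            "congruency_F": float(fstat["congruency"]),
            "n_conditions": len(dz.CONDITIONS),
            "n_response_conditions": len(RESPONSE_CONDITIONS),
        }
    except Exception as e:  # noqa: BLE001
        _fail("behavior", e)
    _done("behavior", t0)

    # ---- sensor level: simulate + spectral --------------------------------
    t0 = time.time()
    sensors = make_sensor_array(config.sim.n_sensors)
    po_lat, m_lat = [], []
    times = valid = cond_labels = None
    subj_ids = sorted(design["subject"].unique())
    try:
        for si, subject in enumerate(subj_ids):
            ep = subject_epochs(config, design, gains, subject, sensors,
                                seed=children[4 + si])
            if (config.sim.save_epochs == "all"
                    or (config.sim.save_epochs == "first" and si == 0)):
                ep.save(out / f"epochs_sub{subject:02d}.h5")
            res = sensor_lateralized_series(config, ep)
            po_lat.append(res["po_alpha_lat"])
            m_lat.append(res["m_beta_lat"])
            times, valid, cond_labels = res["times"], res["valid"], res["cond_labels"]
        po_lat = np.stack(po_lat)   # (n_subj, 8, n_times)
        m_lat = np.stack(m_lat)
        rows = []
        for si, subject in enumerate(subj_ids):
            for ci, (a, t_, r) in enumerate(cond_labels):
                for name, arr in (("PO", po_lat), ("M", m_lat)):
                    band = "alpha" if name == "PO" else "beta"
                    rows.append(pd.DataFrame({
                        "subject": subject, "A": a, "T": t_, "R": r,
                        "region_pair": name, "band": band,
                        "time_ms": times[valid],
                        "value": arr[si, ci, valid]}))
        write_tsv(pd.concat(rows, ignore_index=True),
                  out / "lateralized_series.tsv")
    except Exception as e:  # noqa: BLE001
        _fail("sensor", e)
    _done("sensor", t0)

    # ---- time-resolved regression -----------------------------------------
    t0 = time.time()
    try:
        coding = np.array(cond_labels, dtype=float)
        track_rows, window_rows = [], []
        summary["regression"] = {}
        for name, arr in (("PO", po_lat), ("M", m_lat)):
            band = "alpha" if name == "PO" else "beta"
            series = np.where(np.isnan(arr), 0.0, arr)
            coefs = lat.subject_regression_tracks(series, coding)
            track = lat.group_coefficient_track(
                coefs, times, alpha=config.stats.alpha,
                window=config.stats.window_ms,
                bonferroni_divisor=config.stats.bonferroni_divisor)
            for i, cname in enumerate(track.coef_names):
                track_rows.append(pd.DataFrame({
                    "band": band, "region_pair": name, "coefficient": cname,
                    "time_ms": track.times_ms,
                    "group_mean": track.coef_mean[i], "t": track.t[i],
                    "p": track.p[i],
                    "significant": track.significant[i].astype(int)}))
                for onset, offset in track.windows[cname]:
                    window_rows.append((band, name, cname, onset, offset))
            summary["regression"][f"{name}_{band}"] = {
                c: track.windows[c] for c in track.coef_names[1:]}
        write_tsv(pd.concat(track_rows, ignore_index=True),
                  out / "regression_track.tsv")
        write_tsv(pd.DataFrame(window_rows, columns=[
            "band", "region_pair", "coefficient", "onset_ms", "offset_ms"]),
            out / "regression_windows.tsv")
    except Exception as e:  # noqa: BLE001
        _fail("regression", e)
    _done("regression", t0)

    # ---- sensor-level power–RT coupling -----------------------------------
    t0 = time.time()
    try:
        xs, ys = [], []
        for si, subject in enumerate(subj_ids):
            cells = collapse_to_cells(m_lat[si], cond_labels)
            rec = np.stack([cp.congruency_recode(cells[ci], R=cell[1])
                            for ci, cell in enumerate(CELLS)])
            rec = np.where(np.isnan(rec), 0.0, rec)
            xs.append(cp.normalize_power(rec, times))
            ys.append(cp.normalized_median_rt(
                subject_cell_median_rt(design, subject)))
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        win = (times >= -500) & (times <= 2000) & valid
        track = cp.correlation_track(x[:, win], y, times[win])
        write_tsv(track.to_frame(), out / "correlation_track.tsv")
        pre = ((track.times_ms >= config.coupling.precue_window[0])
               & (track.times_ms <= config.coupling.precue_window[1]))
        summary["coupling"] = {
            "precue_r": float(np.nanmean(track.r[pre])),
            "n_pooled": track.n_obs,
        }
    except Exception as e:  # noqa: BLE001
        _fail("coupling", e)
    _done("coupling", t0)

    # ---- source level ------------------------------------------------------
    if config.source.run_source_stage:
        t0 = time.time()
        try:
            grid = bf.build_grid(config.source.grid_spacing_mm,
                                 config.source.mask_radius_mm)
            grid = bf.attach_lead_fields(grid, sensors)
            bands = {"alpha": config.spectral.alpha_band,
                     "beta": config.spectral.beta_band}
            subj_maps = {b: [] for b in bands}
            for si, subject in enumerate(subj_ids):
                ep = subject_epochs(config, design, gains, subject, sensors,
                                    seed=children[4 + si])
                labels = list(zip(ep.metadata["A"], ep.metadata["T"],
                                  ep.metadata["R"]))
                for bname, band in bands.items():
                    vals, map_labels = bf.source_power_map(
                        ep, grid, band, active=config.source.active_ms,
                        baseline=config.source.baseline_ms,
                        lam=config.source.lam, conditions=labels)
                    subj_maps[bname].append(vals)
            meta = pd.DataFrame(map_labels, columns=["A", "T", "R"])
            combined_flag = np.zeros(grid.n_voxels, dtype=bool)
            combined_t = np.zeros(grid.n_voxels)
            frames = []
            boot_children = np.random.SeedSequence(config.seed).spawn(1)[0].spawn(4)
            bi = 0
            for bname in bands:
                stack = np.stack(subj_maps[bname])
                for contrast in ("stimulus_type", "congruency"):
                    vals = bf.group_lateralized_contrast(stack, meta, grid,
                                                         contrast=contrast)
                    smap = bf.fdr_and_bootstrap(
                        vals, grid, alpha=config.source.fdr_alpha,
                        n_boot=config.source.n_boot, seed=boot_children[bi])
                    bi += 1
                    df = source_map_frame(smap)
                    df.insert(0, "band", bname)
                    df.insert(1, "contrast", contrast)
                    frames.append(df)
                    take = smap.flag & (np.abs(smap.t) > np.abs(combined_t))
                    combined_t[take] = smap.t[take]
                    combined_flag |= smap.flag
            write_tsv(pd.concat(frames, ignore_index=True),
                      out / "source_contrasts.tsv")
            combined = bf.SourceMap(grid=grid, t=combined_t,
                                    p=np.ones(grid.n_voxels),
                                    flag=combined_flag)
            rois = bf.extract_roi_maxima(
                combined, min_neighbors=config.source.min_neighbors,
                t_mean_min=config.source.t_mean_min)
            write_tsv(roi_frame(rois), out / "rois.tsv")
            summary["source"] = {
                "n_voxels": int(grid.n_voxels),
                "n_significant_voxels": int(combined_flag.sum()),
                "n_rois": len(rois),
                "n_bilateral_roi_coordinates": 2 * len(rois),
            }
        except Exception as e:  # noqa: BLE001
            _fail("source", e)
        _done("source", t0)

        # ---- ROI power–RT coupling ----------------------------------------
        t0 = time.time()
        try:
            roi_rows = []
            for ri, roi in enumerate(rois.rois, start=1):
                left = roi.mni_mm if roi.mni_mm[0] < 0 else roi.mirror_mni_mm
                right = roi.mni_mm if roi.mni_mm[0] > 0 else roi.mirror_mni_mm
                for bname, band in bands.items():
                    xs, ys = [], []
                    for si, subject in enumerate(subj_ids):
                        ep = subject_epochs(config, design, gains, subject,
                                            sensors, seed=children[4 + si])
                        labels = list(zip(ep.metadata["A"], ep.metadata["T"],
                                          ep.metadata["R"]))
                        series, stimes, slabels = bf.lat_roi_series(
                            ep, left, right, band, lam=config.source.lam,
                            baseline=config.source.baseline_ms,
                            conditions=labels,
                            window_ms=config.spectral.window_ms,
                            step_ms=config.spectral.step_ms)
                        cells = collapse_to_cells(series, slabels)
                        rec = np.stack([
                            cp.congruency_recode(cells[ci], R=cell[1])
                            for ci, cell in enumerate(CELLS)])
                        rec = np.where(np.isnan(rec), 0.0, rec)
                        xs.append(cp.normalize_power(rec, stimes))
                        ys.append(cp.normalized_median_rt(
                            subject_cell_median_rt(design, subject)))
                    x = np.concatenate(xs)
                    y = np.concatenate(ys)
                    sm, centers, _ = cp.moving_average(x, stimes)
                    track = cp.correlation_track(sm, y, centers)
                    df = track.to_frame(level="source",
                                        roi_or_group=f"ROI{ri}", band=bname)
                    roi_rows.append(df)
            if roi_rows:
                write_tsv(pd.concat(roi_rows, ignore_index=True),
                          out / "roi_correlation.tsv")
        except Exception as e:  # noqa: BLE001
            _fail("roi_coupling", e)
        _done("roi_coupling", t0)

    # ---- report ------------------------------------------------------------
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    manifest["stages"]["report"] = {"status": "ok"}
    (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=1))
    return out
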