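"""Frequency-domain (DICS-style) beamforming on a volumetric grid.

A linearly constrained minimum-variance spatial filter is computed per
voxel from the sensor cross-spectral density (CSD) of a band/window:

    W = (Lᵀ C⁻¹ L)⁻¹ Lᵀ C⁻¹ ,   C = Re(CSD) + λ·mean(diag)·I

with the unit-gain constraint W·L = I.  A fixed dipole orientation is the
dominant eigenvector of the 3×3 source CSD, giving a scalar filter per
voxel.  Source power contrasts (active 600–1100 ms vs baseline −500–0 ms,
as relative change) are compared between hemispheres within subject, then
tested across subjects, FDR-corrected (Benjamini–Hochberg) with
subject-level bootstrap confidence intervals; regional maxima passing the
connectivity (≥4 connected significant neighbors) and mean-|t| (≥2.6)
rules become bilateral ROIs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .forward import HEAD_CENTER_MNI, SensorArray, SphereModel, lead_field_matrix
from .simulate import Epochs
from .spectral import tfr_power, relative_change

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# source grid

@dataclass
class SourceGrid:
    """Regular 6 mm grid inside a spherical brain mask (MNI mm).

    The x coordinates sit at half-spacing offsets from the midline so
    every voxel has an exact mirror partner at (−x, y, z) and none lies on
    the midline.  ``ijk`` are integer raster indices for connectivity.
    """

    voxels_mni: np.ndarray
    spacing_mm: float
    ijk: np.ndarray
    shape: tuple[int, int, int]
    hemisphere: np.ndarray
    mirror_index: np.ndarray
    lead_fields: np.ndarray | None = None

    @property
    def n_voxels(self) -> int:
        return len(self.voxels_mni)

    def rasterize(self, values: np.ndarray, fill=np.nan) -> np.ndarray:
        vol = np.full(self.shape, fill, dtype=float)
        vol[tuple(self.ijk.T)] = values
        return vol


def build_grid(
    spacing_mm: float = 6.0,
    radius_mm: float = 80.0,
    center_mni: np.ndarray = HEAD_CENTER_MNI,
    head_model: SphereModel | None = None,
) -> SourceGrid:
    """Mirror-symmetric volumetric grid inside the spherical mask."""
    head_model = head_model or SphereModel()
    center_mni = np.asarray(center_mni, dtype=float)
    if center_mni[0] != 0:
        raise ValueError("mask center must lie on the midline (x = 0)")
    nx = int(np.floor(radius_mm / spacing_mm - 0.5)) + 1
    xs = (np.arange(-nx, nx) + 0.5) * spacing_mm
    nyz = int(np.floor(radius_mm / spacing_mm))
    ys = center_mni[1] + np.arange(-nyz, nyz + 1) * spacing_mm
    zs = center_mni[2] + np.arange(-nyz, nyz + 1) * spacing_mm
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    inside = np.linalg.norm(pts - center_mni, axis=1) <= radius_mm
    # keep strictly inside the conducting sphere so lead fields exist
    r_head = np.linalg.norm(head_model.mni_to_head(pts), axis=1)
    inside &= r_head < head_model.radius_m * 0.98
    vox = pts[inside]

    ii = np.round(vox[:, 0] / spacing_mm - 0.5).astype(int) + nx
    jj = np.round((vox[:, 1] - ys[0]) / spacing_mm).astype(int)
    kk = np.round((vox[:, 2] - zs[0]) / spacing_mm).astype(int)
    ijk = np.column_stack([ii, jj, kk])
    shape = (len(xs), len(ys), len(zs))

    key = {tuple(np.round(v, 3)): i for i, v in enumerate(vox)}
    mirror = np.full(len(vox), -1)
    for i, v in enumerate(vox):
        mirror[i] = key.get((round(-v[0], 3), round(v[1], 3), round(v[2], 3)), -1)
    if np.any(mirror < 0):  # cannot happen for this symmetric construction
        keep = mirror >= 0
        logger.warning("excluding %d voxels without mirror partners",
                       int((~keep).sum()))
        vox, ijk = vox[keep], ijk[keep]
        old_to_new = -np.ones(len(keep), dtype=int)
        old_to_new[keep] = np.arange(keep.sum())
        mirror = old_to_new[mirror[keep]]
    return SourceGrid(voxels_mni=vox, spacing_mm=spacing_mm, ijk=ijk,
                      shape=shape, hemisphere=np.sign(vox[:, 0]).astype(int),
                      mirror_index=mirror)


def attach_lead_fields(grid: SourceGrid, sensors: SensorArray,
                       head_model: SphereModel | None = None) -> SourceGrid:
    head_model = head_model or SphereModel()
    L = np.stack([lead_field_matrix(v, sensors, head_model)
                  for v in grid.voxels_mni])
    if not np.all(np.isfinite(L)):
        raise ValueError("non-finite lead fields on the grid")
    return replace(grid, lead_fields=L)


# --------------------------------------------------------------------------
# cross-spectral density and filters

def csd(
    data: np.ndarray,
    times_ms: np.ndarray,
    band: tuple[float, float],
    window: tuple[float, float],
) -> np.ndarray:
    """Sensor CSD: mean over trials and band frequencies of Hanning-tapered
    Fourier cross-products over the window.  ``data`` is (trials, sensors,
    samples); returns a conjugate-symmetric (sensors, sensors) matrix."""
    times_ms = np.asarray(times_ms, dtype=float)
    fs = 1000.0 / (times_ms[1] - times_ms[0])
    lo, hi = band
    if hi > fs / 2:
        raise ValueError(f"band {band} exceeds Nyquist ({fs / 2:.1f} Hz)")
    length_ms = window[1] - window[0]
    if length_ms < 1000.0 / lo:
        raise ValueError(
            f"window of {length_ms:g} ms is shorter than one cycle at {lo:g} Hz")
    m = (times_ms >= window[0]) & (times_ms <= window[1])
    seg = data[:, :, m]
    n_w = seg.shape[-1]
    rayleigh = fs / n_w
    freqs = np.arange(np.ceil(lo / rayleigh), np.floor(hi / rayleigh) + 1) * rayleigh
    if freqs.size == 0:
        freqs = np.array([(lo + hi) / 2.0])
    w = np.hanning(n_w)
    k = np.arange(n_w)
    kernel = (2.0 / w.sum()) * w[:, None] * np.exp(
        -2j * np.pi * freqs[None, :] * k[:, None] / fs)
    V = seg @ kernel  # (trials, sensors, n_freqs)
    C = np.einsum("tsf,tuf->su", V, np.conj(V)) / (V.shape[0] * V.shape[2])
    return C


def dics_filters(
    C: np.ndarray,
    lead_fields: np.ndarray,
    lam: float = 0.05,
    rank_rcond: float = 1e-7,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vector and fixed-orientation DICS filters for a stack of voxels.

    ``lead_fields`` is (n_voxels, n_sensors, 3).  Returns
    ``(W, ori, w_fixed)`` with shapes (n, 3, S), (n, 3), (n, S); the fixed
    orientation is the dominant eigenvector of the real 3×3 source CSD and
    satisfies the unit-gain constraint w·(L·ori) = 1.
    """
    L = np.asarray(lead_fields)
    if L.ndim == 2:
        L = L[None]
    Cr = np.real(C)
    n_sens = Cr.shape[0]
    Creg = Cr + lam * np.trace(Cr) / n_sens * np.eye(n_sens)
    try:
        Ci = np.linalg.inv(Creg)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            f"regularized CSD is singular ({e}); increase the regularization λ"
        ) from None
    CiL = np.einsum("su,nuv->nsv", Ci, L)          # (n, S, 3)
    G = np.einsum("nsv,nsw->nvw", L, CiL)          # (n, 3, 3)
    # Spherical head models have a magnetically silent (radial) dipole
    # direction, so G is rank-2 there: invert on the non-silent subspace
    # via an eigenvalue-thresholded pseudoinverse.  For full-rank lead
    # fields this is the exact inverse and W·L = I(3).
    evals, evecs = np.linalg.eigh(G)
    if np.any(evals[:, -1] <= 0):
        raise np.linalg.LinAlgError(
            "constrained matrix LᵀC⁻¹L is singular; increase the "
            "regularization λ")
    with np.errstate(divide="ignore"):
        inv_vals = np.where(evals > rank_rcond * evals[:, -1:], 1.0 / evals, 0.0)
    Gi = np.einsum("nvk,nk,nwk->nvw", evecs, inv_vals, evecs)
    W = np.einsum("nvw,nsw->nvs", Gi, CiL)         # (n, 3, S)
    S_src = np.einsum("nvs,su,nwu->nvw", W, C, np.conj(W))
    evals, evecs = np.linalg.eigh(np.real(S_src))
    ori = evecs[:, :, -1]                          # (n, 3)
    w_fixed = np.einsum("nv,nvs->ns", ori, W)
    if not np.all(np.isfinite(w_fixed)):
        raise np.linalg.LinAlgError(
            "non-finite spatial filter; increase the regularization λ")
    return W, ori, w_fixed


# --------------------------------------------------------------------------
# source maps and group statistics

@dataclass
class SourceMap:
    """Voxelwise statistics on a grid."""

    grid: SourceGrid
    t: np.ndarray | None = None
    p: np.ndarray | None = None
    flag: np.ndarray | None = None
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    subject_values: np.ndarray | None = None


def source_power_map(
    epochs: Epochs,
    grid: SourceGrid,
    band: tuple[float, float],
    active: tuple[float, float] = (600.0, 1100.0),
    baseline: tuple[float, float] = (-500.0, 0.0),
    lam: float = 0.05,
    conditions=None,
) -> tuple[np.ndarray, list]:
    """Per-condition relative source power change (active vs baseline).

    Filters are computed once from the combined active+baseline CSD over
    all trials (a common filter), then applied to condition-specific CSDs.
    Returns ``(values, labels)`` with values (n_conditions, n_voxels).
    """
    if grid.lead_fields is None:
        grid = attach_lead_fields(grid, epochs.sensors)
    data, times = epochs.data, epochs.times_ms
    C_act_all = csd(data, times, band, active)
    C_base_all = csd(data, times, band, baseline)
    try:
        _, _, w = dics_filters((C_act_all + C_base_all) / 2.0,
                               grid.lead_fields, lam=lam)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(f"DICS filter computation failed: {e}")

    if conditions is None:
        labels = ["all"]
        idx_sets = [np.arange(len(data))]
    else:
        conditions = np.asarray(conditions)
        labels = sorted(set(map(tuple, conditions)) if conditions.ndim > 1
                        else set(conditions))
        key = list(map(tuple, conditions)) if conditions.ndim > 1 else list(conditions)
        idx_sets = [np.array([i for i, kk in enumerate(key) if kk == u])
                    for u in labels]

    out = np.empty((len(labels), grid.n_voxels))
    for li, idx in enumerate(idx_sets):
        C_act = csd(data[idx], times, band, active)
        C_base = csd(data[idx], times, band, baseline)
        p_act = np.real(np.einsum("ns,su,nu->n", w, C_act, np.conj(w)))
        p_base = np.real(np.einsum("ns,su,nu->n", w, C_base, np.conj(w)))
        if np.any(p_base <= 0):
            bad = int(np.argmax(p_base <= 0))
            raise ValueError(f"non-positive baseline source power at voxel {bad}")
        out[li] = (p_act - p_base) / p_base
    return out, labels


def aligned_lateralization(
    maps: np.ndarray,
    sides: np.ndarray,
    grid: SourceGrid,
) -> np.ndarray:
    """Side-aligned hemispheric difference maps.

    ``maps`` is (n_conditions, n_voxels); ``sides`` gives each condition's
    label side (±1: endpoint target or response hand).  For each voxel the
    mirrored-partner difference is signed so that, at voxels contralateral
    to the label side, suppression (negative relative change) yields
    positive values.  The result is antisymmetric under mirroring.
    """
    maps = np.atleast_2d(maps)
    mirrored = maps[:, grid.mirror_index]
    return (np.asarray(sides, dtype=float)[:, None] * (mirrored - maps)) / 2.0


def group_lateralized_contrast(
    subject_maps: np.ndarray,
    cond_meta,
    grid: SourceGrid,
    contrast: str = "stimulus_type",
) -> np.ndarray:
    """Per-subject lateralized condition contrast values (n_subj, n_vox).

    ``subject_maps`` is (n_subjects, n_conditions, n_voxels) and
    ``cond_meta`` a DataFrame aligned to the condition axis with columns
    A, T, R (plus derived labels).  For ``"stimulus_type"`` the contrast is
    straight − crossed with sides given by the endpoint target; for
    ``"congruency"`` congruent − incongruent with sides given by the
    response hand.
    """
    import pandas as pd
    meta = pd.DataFrame(cond_meta).reset_index(drop=True)
    subject_maps = np.asarray(subject_maps)
    if subject_maps.ndim != 3:
        raise ValueError("subject_maps must be (n_subjects, n_conditions, n_voxels)")
    if subject_maps.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if contrast == "stimulus_type":
        sides = meta["T"].to_numpy(dtype=float)
        pos = (meta["A"] != meta["T"]).to_numpy()   # straight
        neg = ~pos
    elif contrast == "congruency":
        sides = meta["R"].to_numpy(dtype=float)
        pos = (meta["T"] == meta["R"]).to_numpy()   # congruent
        neg = ~pos
        if np.any(meta["R"] == 0):
            raise ValueError("no-response conditions cannot enter the "
                             "congruency contrast")
    else:
        raise ValueError(f"unknown contrast {contrast!r}")

    out = np.empty((subject_maps.shape[0], subject_maps.shape[2]))
    for s in range(subject_maps.shape[0]):
        a = aligned_lateralization(subject_maps[s], sides, grid)
        out[s] = a[pos].mean(axis=0) - a[neg].mean(axis=0)
    return out


def fdr_and_bootstrap(
    subject_values: np.ndarray,
    grid: SourceGrid,
    alpha: float = 0.05,
    n_boot: int = 500,
    seed: int | np.random.SeedSequence = 0,
) -> SourceMap:
    """Across-subject t map with BH-FDR flags and bootstrap CIs."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    x = np.asarray(subject_values, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[np.isnan(t)] = 0.0
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    flag = multipletests(p, alpha=alpha, method="fdr_bh")[0]

    rng = np.random.default_rng(
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed))
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = x[idx].mean(axis=1)  # (n_boot, n_vox)
    ci_low, ci_high = np.percentile(boot, [2.5, 97.5], axis=0)
    return SourceMap(grid=grid, t=t, p=p, flag=flag,
                     ci_low=ci_low, ci_high=ci_high, subject_values=x)


# --------------------------------------------------------------------------
# ROI extraction

@dataclass
class ROI:
    mni_mm: np.ndarray
    mirror_mni_mm: np.ndarray
    voxel_id: int
    cluster_voxels: np.ndarray
    mean_abs_t: float
    peak_t: float


@dataclass
class ROISet:
    rois: list[ROI] = field(default_factory=list)

    def __len__(self):
        return len(self.rois)

    def bilateral_coordinates(self) -> np.ndarray:
        """All ROI coordinates plus their mirrored partners (N_roi × 2)."""
        out = []
        for r in self.rois:
            out.append(r.mni_mm)
            out.append(r.mirror_mni_mm)
        return np.array(out)


def extract_roi_maxima(
    source_map: SourceMap,
    min_neighbors: int = 4,
    t_mean_min: float = 2.6,
    stat: str = "mean_abs",
) -> ROISet:
    """Regional maxima of significant connected components.

    A component of FDR-flagged voxels (6-connectivity on the grid) yields
    one ROI — at its global |t| maximum — if it contains the maximum plus
    at least ``min_neighbors`` other significant voxels and its component
    mean |t| (or |mean t| with ``stat="abs_mean"``) reaches ``t_mean_min``.
    Each ROI is paired with its mirrored contralateral coordinate even if
    that location is itself sub-threshold.
    """
    grid = source_map.grid
    flag = np.asarray(source_map.flag, dtype=bool)
    tvals = np.asarray(source_map.t, dtype=float)
    out = ROISet()
    if not flag.any():
        return out
    vol = np.zeros(grid.shape, dtype=bool)
    vol[tuple(grid.ijk.T)] = flag
    structure = ndimage.generate_binary_structure(3, 1)  # faces only
    labels, n_comp = ndimage.label(vol, structure=structure)
    comp_of_voxel = labels[tuple(grid.ijk.T)]
    for comp in range(1, n_comp + 1):
        members = np.flatnonzero(comp_of_voxel == comp)
        if len(members) < min_neighbors + 1:
            continue
        if stat == "mean_abs":
            score = float(np.mean(np.abs(tvals[members])))
        elif stat == "abs_mean":
            score = float(abs(np.mean(tvals[members])))
        else:
            raise ValueError(f"unknown component statistic {stat!r}")
        if score < t_mean_min:
            continue
        peak = members[np.argmax(np.abs(tvals[members]))]
        coord = grid.voxels_mni[peak]
        out.rois.append(ROI(
            mni_mm=coord,
            mirror_mni_mm=coord * np.array([-1.0, 1.0, 1.0]),
            voxel_id=int(peak),
            cluster_voxels=members,
            mean_abs_t=score,
            peak_t=float(tvals[peak]),
        ))
    out.rois.sort(key=lambda r: -abs(r.peak_t))
    return out


def lat_roi_series(
    epochs: Epochs,
    left_mni: np.ndarray,
    right_mni: np.ndarray,
    band: tuple[float, float],
    lam: float = 0.05,
    filter_window: tuple[float, float] | None = None,
    baseline: tuple[float, float] = (-500.0, 0.0),
    conditions=None,
    window_ms: float = 500.0,
    step_ms: float = 20.0,
) -> tuple[np.ndarray, np.ndarray, list]:
    """Lateralized baseline-corrected ROI power time series (left − right).

    Fixed-orientation DICS filters for the two ROI voxels are estimated
    from the band CSD over ``filter_window`` (default: the whole epoch);
    their virtual-channel outputs are turned into sliding-window band
    power, expressed as relative change to baseline, averaged by
    condition, and subtracted (left − right).
    Returns ``(series, times_ms, labels)`` with series (n_cond, n_times).
    """
    if np.asarray(left_mni)[0] >= 0 or np.asarray(right_mni)[0] <= 0:
        raise ValueError("expected a left (x<0) and a right (x>0) ROI")
    data, times = epochs.data, epochs.times_ms
    fw = filter_window or (float(times[0]), float(times[-1]))
    C = csd(data, times, band, fw)
    L = np.stack([lead_field_matrix(m, epochs.sensors)
                  for m in (left_mni, right_mni)])
    _, _, w = dics_filters(C, L, lam=lam)          # (2, n_sensors)
    virtual = np.einsum("rs,tsn->trn", w, data)    # (trials, 2, samples)

    freqs = np.arange(2.0, min(41.0, epochs.fs / 2) + 1e-9, 2.0)
    tfr = tfr_power(virtual, times, window_ms=window_ms, step_ms=step_ms,
                    freqs=freqs)
    tfr = relative_change(tfr, baseline=baseline)
    fidx = tfr.band_indices(band)
    band_pow = tfr.power[:, :, fidx, :].mean(axis=2)  # (trials, 2, n_times)

    if conditions is None:
        labels = ["all"]
        series = band_pow.mean(axis=0)[None, 0] - band_pow.mean(axis=0)[None, 1]
        return series, tfr.times_ms, labels
    conditions = np.asarray(conditions)
    labels = sorted(set(map(tuple, conditions)) if conditions.ndim > 1
                    else set(conditions))
    key = list(map(tuple, conditions)) if conditions.ndim > 1 else list(conditions)
    series = np.empty((len(labels), band_pow.shape[-1]))
    for li, u in enumerate(labels):
        idx = [i for i, kk in enumerate(key) if kk == u]
        m = band_pow[idx].mean(axis=0)
        series[li] = m[0] - m[1]
    return series, tfr.times_ms, labels
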