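"""Coupling between lateralized beta power and reaction time.

The analysis chain: group the 8 response-required conditions by response
congruency, recode lateralized beta series by cued-response side (×R, so a
response-congruent bias always points the same way), normalize each
subject's series by their maximum absolute power during stimulus
presentation (0–1000 ms), then correlate (Pearson) the pooled
subject × condition values with normalized median RT at every time point.
Source-level tracks are first smoothed with a 100 ms moving average at
50 ms steps and their p values binned into the five conventional
significance categories.

Normalized median RT: each subject's condition medians are z-scored within
subject (mean 0, sd 1), removing between-subject RT offsets just as the
power normalization removes gain differences.  (A divide-by-subject-mean
alternative is available via ``rt_norm="mean"``.)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import RTGenParams, generate_design, generate_rts
from .simulate import BetaEnvelope, EnvelopeParams

P_BINS = (("p<0.00001", 1e-5), ("p<0.0001", 1e-4),
          ("p<0.005", 5e-3), ("p<0.05", 5e-2))


def congruency_recode(series: np.ndarray, R: int) -> np.ndarray:
    """Multiply a condition's series by its cued-response side (±1)."""
    if R not in (-1, 1):
        raise ValueError("R must be -1 or +1 (no-response conditions are "
                         "excluded from the coupling analysis)")
    return R * np.asarray(series, dtype=float)


def normalize_power(
    series: np.ndarray,
    times_ms: np.ndarray,
    window: tuple[float, float] = (0.0, 1000.0),
) -> np.ndarray:
    """Divide one subject's series by their max |power| in the window.

    ``series`` is (n_conditions, n_times); the maximum is taken over all
    conditions and window time points, so the output is invariant to any
    positive gain applied to the subject's raw data.
    """
    series = np.asarray(series, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    m = (times_ms >= window[0]) & (times_ms <= window[1])
    denom = np.nanmax(np.abs(series[:, m]))
    if not denom > 0:
        raise ValueError("subject maximum power in the normalization window is 0")
    return series / denom


def normalized_median_rt(medians: np.ndarray, how: str = "zscore") -> np.ndarray:
    """Normalize one subject's condition medians (vector) across conditions."""
    medians = np.asarray(medians, dtype=float)
    if how == "zscore":
        sd = medians.std(ddof=1)
        if sd == 0:
            raise ValueError("zero variance across condition medians")
        return (medians - medians.mean()) / sd
    if how == "mean":
        return medians / medians.mean()
    raise ValueError(f"unknown RT normalization {how!r}")


def pearson_track(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and two-sided p at every time point.

    ``x`` is (n_obs, n_times) pooled observations, ``y`` is (n_obs,).
    Zero-variance time points yield NaN with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if y.shape != (n,):
        raise ValueError("y must have one value per observation")
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / (sx * sy)
    bad = (sx == 0) | (sy == 0)
    if np.any(bad):
        warnings.warn("zero variance at some time points: r undefined (NaN)",
                      stacklevel=2)
        r[bad] = np.nan
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(r)] = np.nan
    p[np.abs(r) == 1.0] = 0.0
    return r, p


def bin_pvalues(p: np.ndarray) -> np.ndarray:
    """Tightest satisfied threshold among the five conventional bins."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) & ~np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    out = np.full(p.shape, "n.s.", dtype=object)
    for label, thr in reversed(P_BINS):  # loosest first, tighten progressively
        out[p < thr] = label
    out[np.isnan(p)] = "n.s."
    return out


def moving_average(
    series: np.ndarray,
    times_ms: np.ndarray,
    window_ms: float = 100.0,
    step_ms: float = 50.0,
    span: tuple[float, float] = (0.0, 1650.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """100 ms moving mean at 50 ms steps (source-level smoothing).

    Returns (averaged, centers_ms, partial) where ``partial`` flags centers
    whose window was truncated at the span edges rather than dropped.
    """
    series = np.asarray(series, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    centers = np.arange(span[0], span[1] + 1e-9, step_ms)
    half = window_ms / 2.0
    out = np.full(series.shape[:-1] + (len(centers),), np.nan)
    partial = np.zeros(len(centers), dtype=bool)
    for i, c in enumerate(centers):
        lo, hi = max(c - half, span[0]), min(c + half, span[1])
        partial[i] = (c - half < span[0]) or (c + half > span[1])
        m = (times_ms >= lo) & (times_ms <= hi)
        if m.any():
            out[..., i] = np.nanmean(series[..., m], axis=-1)
    return out, centers, partial


@dataclass
class CorrelationTrack:
    """Pearson r/p series with binned significance labels."""

    times_ms: np.ndarray
    r: np.ndarray
    p: np.ndarray
    p_bin: np.ndarray
    n_obs: int

    def to_frame(self, level: str = "sensor", roi_or_group: str = "M-lat",
                 band: str = "beta") -> pd.DataFrame:
        return pd.DataFrame({
            "level": level, "roi_or_group": roi_or_group, "band": band,
            "time_ms": self.times_ms, "r": self.r, "p": self.p,
            "p_bin": self.p_bin,
        })


def correlation_track(x: np.ndarray, y: np.ndarray,
                      times_ms: np.ndarray) -> CorrelationTrack:
    r, p = pearson_track(x, y)
    return CorrelationTrack(times_ms=np.asarray(times_ms, dtype=float),
                            r=r, p=p, p_bin=bin_pvalues(p), n_obs=len(y))


# --------------------------------------------------------------------------
# summary-level coupling study generator

#: The four response-congruency cells as (T, R): ~LL, ~RR congruent;
#: ~LR, ~RL incongruent (first letter target side, second response side).
CONGRUENCY_CELLS = ((-1, -1), (1, 1), (-1, 1), (1, -1))


@dataclass
class CouplingParams:
    """Generator settings for the power–RT coupling study.

    ``subject_gain_sd``/``cell_gain_sd`` are lognormal sigmas of the
    subject- and cell-level lateralization bias strength; ``meas_noise_sd``
    is additive noise on the lateralized power series (relative-change
    units); ``coupling_ms`` converts the pre-cue bias into milliseconds of
    RT.  Defaults are calibrated so the population pre-cue power–RT
    correlation over subject × congruency-cell pairs is 0.60.
    """

    subject_gain_sd: float = 0.25
    cell_gain_sd: float = 0.35
    meas_noise_sd: float = 0.26
    rt_cell_sd: float = 20.0
    coupling_ms: float = 40.0
    precue_window: tuple[float, float] = (900.0, 1000.0)
    rt: RTGenParams = field(default_factory=RTGenParams)
    envelopes: EnvelopeParams = field(default_factory=EnvelopeParams)


@dataclass
class CouplingStudy:
    """Per-subject lateralized beta series and median RTs, by cell."""

    times_ms: np.ndarray
    lat_beta: np.ndarray        # (n_subjects, 4, n_times), raw L−R series
    median_rt: np.ndarray      # (n_subjects, 4)
    cells: tuple = CONGRUENCY_CELLS


def simulate_coupling_study(
    n_subjects: int = 12,
    n_blocks: int = 8,
    reps_per_condition: int = 10,
    params: CouplingParams | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> CouplingStudy:
    """Generate lateralized beta series and RTs with a shared bias.

    The lateralized series is the left-minus-right relative power implied
    by the beta envelope model (−2 × the signed lateral component), scaled
    by a subject × cell bias strength; the same pre-cue bias enters each
    trial's RT through ``generate_rts``'s coupling term, so power and
    behavior share a latent cause exactly as the analysis assumes.
    """
    params = params or CouplingParams()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child = ss.spawn(3)
    rng = np.random.default_rng(child[0])

    times = np.arange(-500.0, 2000.0 + 1e-9, 20.0)
    env = BetaEnvelope(hemisphere=+1, params=params.envelopes)
    # target-locked lateral profile for T=+1 (no hand/response components)
    prof = env.lateral_power(times, A=0, T=1, R=0)
    pre = (times >= params.precue_window[0]) & (times <= params.precue_window[1])
    d_pre = prof[pre].mean()

    gains = np.exp(
        params.subject_gain_sd * rng.standard_normal((n_subjects, 1))
        + params.cell_gain_sd * rng.standard_normal((n_subjects, 4)))

    design = generate_design(n_subjects, n_blocks, reps_per_condition,
                             seed=child[1])
    resp = design[design["R"] != 0].reset_index(drop=True)
    cell_of = {cell: i for i, cell in enumerate(CONGRUENCY_CELLS)}
    cell_idx = np.array([cell_of[(t, r)]
                         for t, r in zip(resp["T"], resp["R"])])
    subj_idx = resp["subject"].to_numpy() - 1
    # per-trial pre-cue bias: R × (L−R power) = −2·d_pre·(R·T)·gain, plus
    # cell-level RT variability not caused by the bias (in ms / coupling)
    cell_rt_offsets = params.rt_cell_sd * rng.standard_normal((n_subjects, 4))
    bias = (-2.0 * d_pre * resp["R"].to_numpy() * resp["T"].to_numpy()
            * gains[subj_idx, cell_idx]
            + cell_rt_offsets[subj_idx, cell_idx] / max(params.coupling_ms, 1e-9))
    rtp = params.rt
    rtp = RTGenParams(**{**rtp.__dict__, "coupling": params.coupling_ms})
    resp = generate_rts(resp, rtp, beta_bias=bias, seed=child[1])

    med = (resp.groupby(["subject", "T", "R"])["rt_ms"].median())
    median_rt = np.empty((n_subjects, 4))
    for s in range(n_subjects):
        for ci, (t, r) in enumerate(CONGRUENCY_CELLS):
            median_rt[s, ci] = med.loc[(s + 1, t, r)]

    lat = np.empty((n_subjects, 4, len(times)))
    noise = np.random.default_rng(child[2]).standard_normal(lat.shape)
    for ci, (t, r) in enumerate(CONGRUENCY_CELLS):
        lat[:, ci] = (-2.0 * t * prof[None, :] * gains[:, ci, None]
                      + params.meas_noise_sd * noise[:, ci])
    return CouplingStudy(times_ms=times, lat_beta=lat, median_rt=median_rt)


def coupling_track(study: CouplingStudy, rt_norm: str = "zscore") -> CorrelationTrack:
    """Recode, normalize, pool and correlate a coupling study end to end."""
    n_subj = study.lat_beta.shape[0]
    xs, ys = [], []
    for s in range(n_subj):
        rec = np.stack([
            congruency_recode(study.lat_beta[s, ci], R=cell[1])
            for ci, cell in enumerate(study.cells)
        ])
        xs.append(normalize_power(rec, study.times_ms))
        ys.append(normalized_median_rt(study.median_rt[s], how=rt_norm))
    x = np.concatenate(xs, axis=0)
    y = np.concatenate(ys, axis=0)
    return correlation_track(x, y, study.times_ms)


def precue_r(study: CouplingStudy,
             window: tuple[float, float] = (900.0, 1000.0),
             rt_norm: str = "zscore") -> float:
    """Pooled Pearson r between mean pre-cue recoded power and median RT."""
    track_window = (study.times_ms >= window[0]) & (study.times_ms <= window[1])
    n_subj = study.lat_beta.shape[0]
    xs, ys = [], []
    for s in range(n_subj):
        rec = np.stack([
            congruency_recode(study.lat_beta[s, ci], R=cell[1])
            for ci, cell in enumerate(study.cells)
        ])
        norm = normalize_power(rec, study.times_ms)
        xs.append(norm[:, track_window].mean(axis=1))
        ys.append(normalized_median_rt(study.median_rt[s], how=rt_norm))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    return float(stats.pearsonr(x, y).statistic)
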