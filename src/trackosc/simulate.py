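"""Synthetic epoched MEG with condition-dependent oscillatory sources.

Each trial is a sum of dipolar band-limited sources projected through the
single-sphere forward model, with per-trial random phase (so task power is
induced, not phase-locked) plus white sensor noise:

    x(t) = sum_s  g_s · a_s(t; A, T, R) · sin(2π f_s t + φ_trial,s) + noise

Amplitude envelopes ``a(t)`` are parameterized as piecewise-linear *power*
profiles relative to baseline (amplitude = base · sqrt(power)) and encode
the statistical structure the analysis is built to detect:

* parieto-occipital **alpha** (10 Hz, cuneus ±12,−84,22): a bilateral dip
  to −20% power at 275 ms, then a rebound (+40% from the minimum, peaking
  at 700 ms) in the hemisphere **ipsilateral** to the endpoint target T,
  with matching contralateral suppression; the lateralized part is scaled
  down on crossed trials;
* motor **beta** (20 Hz, dorsal premotor ±18,−18,64): a sustained bilateral
  desynchronization reaching −50% power around response onset (1450 ms),
  plus a lateralized suppression contralateral to the actor's moving hand
  early (from ~427 ms), to the target from ~810 ms, and to the cued
  response after the cue (1000 ms) — which reverses the lateralization on
  incongruent trials.

All landmark times and depths are configurable; the defaults are the
study conditions the rest of the package assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable
import json

import numpy as np
import pandas as pd
import h5py

from .forward import SensorArray, SphereModel, lead_field, make_sensor_array

_MIRROR = np.array([-1.0, 1.0, 1.0])


@dataclass
class EnvelopeParams:
    """Landmarks (ms) and depths (fractional power) of the source envelopes."""

    # parieto-occipital alpha
    alpha_dip_depth: float = 0.20     # bilateral dip: power 1 -> 0.8
    alpha_dip_time: float = 275.0
    alpha_rebound_gain: float = 0.40  # ipsilateral peak = (1-dip)*(1+gain)
    alpha_peak_time: float = 700.0
    alpha_lat_onset: float = 300.0
    alpha_hold_until: float = 1450.0
    alpha_recover_by: float = 2200.0
    crossed_scale: float = 0.5        # lateral alpha scaling on crossed trials
    # motor beta
    beta_depth: float = 0.50          # bilateral power at the minimum
    beta_min_time: float = 1450.0
    beta_recover_by: float = 2600.0
    beta_hand_onset: float = 427.0    # lateral component tracking A
    beta_hand_peak: float = 700.0
    beta_hand_depth: float = 0.08
    beta_target_onset: float = 810.0  # lateral component tracking T
    beta_target_depth: float = 0.12
    beta_cue_time: float = 1000.0     # response cue onset
    beta_response_depth: float = 0.15 # post-cue lateral component tracking R
    beta_response_time: float = 1450.0


def _pw(t: np.ndarray, points: list[tuple[float, float]]) -> np.ndarray:
    xs, ys = zip(*points)
    return np.interp(t, xs, ys)


@dataclass
class AlphaEnvelope:
    """Parieto-occipital alpha power envelope for one hemisphere (±1)."""

    hemisphere: int
    params: EnvelopeParams = field(default_factory=EnvelopeParams)

    def power(self, t_ms, A: int, T: int, R: int, lat_gain: float = 1.0):
        p = self.params
        t = np.asarray(t_ms, dtype=float)
        p_min = 1.0 - p.alpha_dip_depth
        p_ipsi = p_min * (1.0 + p.alpha_rebound_gain)
        lat_amp = (p_ipsi - p_min) / 2.0
        bil_peak = (p_ipsi + p_min) / 2.0
        bil = _pw(t, [(-1000, 1.0), (0, 1.0), (p.alpha_dip_time, p_min),
                      (p.alpha_peak_time, bil_peak), (p.alpha_hold_until, bil_peak),
                      (p.alpha_recover_by, 1.0), (3000, 1.0)])
        lat = _pw(t, [(-1000, 0.0), (p.alpha_lat_onset, 0.0),
                      (p.alpha_peak_time, lat_amp), (p.alpha_hold_until, lat_amp),
                      (p.alpha_recover_by, 0.0), (3000, 0.0)])
        scale = 1.0 if A != T else p.crossed_scale  # straight iff A != T
        return bil + self.hemisphere * T * lat * scale * lat_gain

    def __call__(self, t_ms, A, T, R, lat_gain: float = 1.0):
        return np.sqrt(np.maximum(self.power(t_ms, A, T, R, lat_gain), 0.02))


@dataclass
class BetaEnvelope:
    """Motor beta power envelope for one hemisphere (±1)."""

    hemisphere: int
    params: EnvelopeParams = field(default_factory=EnvelopeParams)

    def lateral_power(self, t_ms, A: int, T: int, R: int) -> np.ndarray:
        """Signed lateral power term for the right hemisphere (+h side).

        Positive values mean more power on the hemisphere matching the
        currently tracked side; the suppressed hemisphere is the one
        contralateral to that side.
        """
        p = self.params
        t = np.asarray(t_ms, dtype=float)
        d_hand = _pw(t, [(-1000, 0.0), (p.beta_hand_onset, 0.0),
                         (p.beta_hand_peak, p.beta_hand_depth),
                         (p.beta_target_onset, p.beta_hand_depth),
                         (p.beta_cue_time, 0.0), (3000, 0.0)])
        d_target = _pw(t, [(-1000, 0.0), (p.beta_target_onset, 0.0),
                           (p.beta_cue_time, p.beta_target_depth),
                           (p.beta_cue_time + 100, p.beta_target_depth),
                           (p.beta_cue_time + 300, 0.0), (3000, 0.0)])
        d_resp = _pw(t, [(-1000, 0.0), (p.beta_cue_time + 50, 0.0),
                         (p.beta_cue_time + 250, p.beta_response_depth),
                         (p.beta_response_time, p.beta_response_depth),
                         (p.beta_response_time + 250, 0.0), (3000, 0.0)])
        return A * d_hand + T * d_target + R * d_resp

    def power(self, t_ms, A: int, T: int, R: int, lat_gain: float = 1.0):
        p = self.params
        t = np.asarray(t_ms, dtype=float)
        bil = _pw(t, [(-1000, 1.0), (0, 1.0), (p.beta_min_time, p.beta_depth),
                      (p.beta_recover_by, 1.0), (3000, 1.0)])
        return bil + self.hemisphere * self.lateral_power(t, A, T, R) * lat_gain

    def __call__(self, t_ms, A, T, R, lat_gain: float = 1.0):
        return np.sqrt(np.maximum(self.power(t_ms, A, T, R, lat_gain), 0.02))


@dataclass
class SourceSpec:
    """One oscillatory source: location, orientation, carrier, envelope."""

    name: str
    mni_mm: np.ndarray
    orientation: np.ndarray          # unit dipole moment direction
    freq_hz: float
    envelope: Callable               # (t_ms, A, T, R, lat_gain) -> amplitude
    base_amp: float = 1.0            # dipole moment scale (arbitrary units)


def _tangential(r0_head: np.ndarray) -> np.ndarray:
    """A unit vector tangential to the sphere at the source location."""
    z = np.array([0.0, 0.0, 1.0])
    t = np.cross(z, r0_head)
    n = np.linalg.norm(t)
    if n < 1e-12:  # source on the z axis: any horizontal direction works
        return np.array([1.0, 0.0, 0.0])
    return t / n


def default_sources(
    params: EnvelopeParams | None = None,
    head_model: SphereModel | None = None,
    base_amp: float = 1.0,
) -> list[SourceSpec]:
    """The four default sources: bilateral PO alpha and motor beta pairs.

    Left/right partners are exact mirror images (position x → −x, moment
    q → −Mq, which reproduces the x-reflected field at mirrored sensors).
    """
    params = params or EnvelopeParams()
    head_model = head_model or SphereModel()
    out = []
    for name, mni, freq, env_cls in [
        ("alpha", np.array([12.0, -84.0, 22.0]), 10.0, AlphaEnvelope),
        ("beta", np.array([18.0, -18.0, 64.0]), 20.0, BetaEnvelope),
    ]:
        ori_r = _tangential(head_model.mni_to_head(mni))
        out.append(SourceSpec(f"{name}-R", mni, ori_r, freq,
                              env_cls(hemisphere=+1, params=params), base_amp))
        out.append(SourceSpec(f"{name}-L", mni * _MIRROR, -ori_r * _MIRROR, freq,
                              env_cls(hemisphere=-1, params=params), base_amp))
    return out


def mirror_sources(sources: list[SourceSpec]) -> list[SourceSpec]:
    """x-reflected source set (same order, so per-trial phases line up)."""
    out = []
    for s in sources:
        env = s.envelope
        if hasattr(env, "hemisphere"):
            env = replace(env, hemisphere=-env.hemisphere)
        out.append(replace(s, mni_mm=np.asarray(s.mni_mm) * _MIRROR,
                           orientation=-np.asarray(s.orientation) * _MIRROR,
                           envelope=env))
    return out


@dataclass
class Epochs:
    """Epoched sensor data: trials × sensors × samples, with metadata.

    ``times_ms`` covers −1000..+3000 ms by default; ``metadata`` has one
    row per trial with at least the A, T, R factor columns.
    """

    data: np.ndarray
    times_ms: np.ndarray
    metadata: pd.DataFrame
    sensors: SensorArray

    def __post_init__(self):
        if len(self.metadata) != len(self.data):
            raise ValueError("metadata length must equal trial count")

    @property
    def fs(self) -> float:
        return 1000.0 / (self.times_ms[1] - self.times_ms[0])

    def select(self, mask) -> "Epochs":
        mask = np.asarray(mask)
        return Epochs(self.data[mask], self.times_ms,
                      self.metadata.iloc[mask].reset_index(drop=True),
                      self.sensors)

    def save(self, path: str | Path) -> None:
        """HDF5 container plus a JSON sidecar with trial/sensor metadata."""
        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("times", data=self.times_ms)
            f.create_dataset("sensor_pos", data=self.sensors.positions)
            f.create_dataset("sensor_ori", data=self.sensors.orientations)
        sidecar = {
            "trials": json.loads(self.metadata.to_json(orient="records")),
            "sensor_group": list(map(str, self.sensors.group)),
            "sensor_hemisphere": [int(h) for h in self.sensors.hemisphere],
            "sensor_mirror_index": [int(i) for i in self.sensors.mirror_index],
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "Epochs":
        path = Path(path)
        with h5py.File(path, "r") as f:
            data = f["data"][:]
            times = f["times"][:]
            pos = f["sensor_pos"][:]
            ori = f["sensor_ori"][:]
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        sensors = SensorArray(
            positions=pos, orientations=ori,
            hemisphere=np.array(sidecar["sensor_hemisphere"]),
            group=np.array(sidecar["sensor_group"], dtype=object),
            mirror_index=np.array(sidecar["sensor_mirror_index"]),
        )
        meta = pd.DataFrame(sidecar["trials"])
        return cls(data, times, meta, sensors)


def simulate_epochs(
    design: pd.DataFrame,
    sources: list[SourceSpec],
    sensors: SensorArray | None = None,
    fs: float = 250.0,
    tmin_ms: float = -1000.0,
    tmax_ms: float = 3000.0,
    noise_sd: float = 1.0,
    head_model: SphereModel | None = None,
    lat_gain: np.ndarray | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> Epochs:
    """Project the sources through the forward model for every trial.

    ``design`` holds one row per trial (typically one subject's trials).
    ``lat_gain`` optionally scales each trial's lateralized envelope
    components (e.g. subject- or trial-level bias strength); default 1.
    Deterministic given ``seed``.
    """
    if len(design) == 0:
        raise ValueError("design is empty")
    if not sources:
        raise ValueError("no sources given")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    sensors = sensors if sensors is not None else make_sensor_array()
    head_model = head_model or SphereModel()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    n_samples = int(round((tmax_ms - tmin_ms) * fs / 1000.0)) + 1
    times = tmin_ms + np.arange(n_samples) * 1000.0 / fs
    n_trials = len(design)
    if lat_gain is None:
        lat_gain = np.ones(n_trials)
    lat_gain = np.asarray(lat_gain, dtype=float)
    if lat_gain.shape != (n_trials,):
        raise ValueError("lat_gain must have one entry per trial")

    gains = np.stack([
        lead_field(s.mni_mm, np.asarray(s.orientation) * s.base_amp,
                   sensors, head_model)
        for s in sources
    ])  # (n_sources, n_sensors)
    # normalize so a unit-amplitude source produces ~unit RMS sensor signal,
    # keeping noise_sd interpretable as a per-sample SNR knob
    gains /= np.sqrt(np.mean(gains**2, axis=1, keepdims=True))

    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_trials, len(sources)))
    data = np.zeros((n_trials, sensors.n_sensors, n_samples))
    A = design["A"].to_numpy()
    T = design["T"].to_numpy()
    R = design["R"].to_numpy()
    t_sec = times / 1000.0
    for k, src in enumerate(sources):
        carrier_base = 2.0 * np.pi * src.freq_hz * t_sec
        for i in range(n_trials):
            env = src.envelope(times, int(A[i]), int(T[i]), int(R[i]),
                               lat_gain=lat_gain[i])
            wave = env * np.sin(carrier_base + phases[i, k])
            data[i] += np.outer(gains[k], wave)
    if noise_sd > 0:
        data += noise_sd * rng.standard_normal(data.shape)

    meta = design.reset_index(drop=True).copy()
    return Epochs(data=data, times_ms=times, metadata=meta, sensors=sensors)
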