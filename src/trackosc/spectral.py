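"""Time–frequency power: planar gradients, Hanning TFR, baseline change.

The estimator is a sliding-window Fourier transform: a Hanning-tapered
500 ms window stepped every 20 ms, from −1000 to +3000 ms.  Output power is
normalized so a unit-amplitude sinusoid at a bin frequency yields power 1.
Windows that would extend past the epoch edges are flagged invalid (NaN),
never zero-padded.

Planar gradients: magnetometer data are converted to two tangential
spatial-derivative channels per sensor by fitting a local first-order
(linear) model of the field over each sensor's k nearest neighbors.  The
two derivative components are combined by *summing their power spectra*
after spectral estimation, the standard "combine planar" convention.
Spatially uniform fields therefore contribute nothing after the transform.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .simulate import Epochs

ALPHA_BAND = (8.0, 12.0)
BETA_BAND = (16.0, 25.0)

DEFAULT_FREQS = np.arange(2.0, 41.0, 2.0)


# --------------------------------------------------------------------------
# planar gradient transform

def _tangent_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    z = np.array([0.0, 0.0, 1.0])
    e1 = np.cross(z, normal)
    n = np.linalg.norm(e1)
    if n < 1e-9:  # sensor at the vertex: pick x as the first tangent
        e1 = np.array([1.0, 0.0, 0.0])
    else:
        e1 = e1 / n
    e2 = np.cross(normal, e1)
    return e1, e2


def planar_weights(sensors, k: int = 6) -> tuple[np.ndarray, np.ndarray]:
    """Weight matrices (W_du, W_dv) mapping sensor values to tangential
    derivatives at each sensor, from a local linear least-squares fit over
    the sensor itself and its k nearest neighbors."""
    pos = sensors.positions
    n = len(pos)
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} sensors for k={k} neighbors")
    d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
    W_du = np.zeros((n, n))
    W_dv = np.zeros((n, n))
    for i in range(n):
        nbr = np.argsort(d2[i])[: k + 1]  # includes i itself
        e1, e2 = _tangent_basis(sensors.orientations[i])
        rel = pos[nbr] - pos[i]
        # local model b0 + b1·u + b2·v + b3·w (w = normal offset), so
        # fields linear in space are differentiated exactly despite the
        # curvature of the sensor shell
        X = np.column_stack([np.ones(len(nbr)), rel @ e1, rel @ e2,
                             rel @ sensors.orientations[i]])
        sv = np.linalg.svd(X[:, :3], compute_uv=False)
        if sv[-1] < 1e-8 * sv[0]:
            raise ValueError(
                f"degenerate (collinear) neighbor geometry at sensor {i}")
        if np.linalg.matrix_rank(X, tol=1e-10 * np.abs(X).max()) < 4:
            X = X[:, :3]  # perfectly flat patch: drop the normal term
        pinv = np.linalg.pinv(X)  # rows: offset, d/du, d/dv[, d/dw]
        W_du[i, nbr] = pinv[1]
        W_dv[i, nbr] = pinv[2]
    return W_du, W_dv


def planar_transform(epochs: Epochs, k: int = 6) -> Epochs:
    """Return epochs whose channels are the 2n tangential derivatives.

    Channel layout: ``[du_0 .. du_{n-1}, dv_0 .. dv_{n-1}]``; combine the
    two halves at the power stage with :func:`combine_planar`.
    """
    W_du, W_dv = planar_weights(epochs.sensors, k=k)
    W = np.vstack([W_du, W_dv])  # (2n, n)
    data = np.einsum("cs,tsn->tcn", W, epochs.data)
    return Epochs(data=data, times_ms=epochs.times_ms,
                  metadata=epochs.metadata, sensors=epochs.sensors)


# --------------------------------------------------------------------------
# TFR estimation

@dataclass
class TFR:
    """Time–frequency power: (observation, channel, frequency, time).

    Observations are trials or conditions depending on provenance;
    ``valid`` flags output times whose full window fit inside the epoch
    (power is NaN elsewhere).  ``kind`` is ``"raw"`` or
    ``"relative_change"``.
    """

    power: np.ndarray
    freqs: np.ndarray
    times_ms: np.ndarray
    valid: np.ndarray
    kind: str = "raw"
    obs_labels: list | None = None

    @property
    def n_channels(self) -> int:
        return self.power.shape[1]

    def band_indices(self, band: tuple[float, float]) -> np.ndarray:
        lo, hi = band
        idx = np.flatnonzero((self.freqs >= lo) & (self.freqs <= hi))
        if idx.size == 0:
            raise ValueError(f"no frequency bins inside band {band}")
        return idx

    def time_indices(self, window: tuple[float, float],
                     require_valid: bool = True) -> np.ndarray:
        lo, hi = window
        m = (self.times_ms >= lo) & (self.times_ms <= hi)
        if require_valid:
            m &= self.valid
        idx = np.flatnonzero(m)
        if idx.size == 0:
            raise ValueError(f"no valid output times inside window {window}")
        return idx


def tfr_power(
    data: np.ndarray,
    times_ms: np.ndarray,
    window_ms: float = 500.0,
    step_ms: float = 20.0,
    freqs: np.ndarray | None = None,
    chunk: int = 16,
) -> TFR:
    """Hanning sliding-window power of ``data`` (n_obs, n_ch, n_samples).

    Power is ``|2/sum(w) * sum_k w_k x_k exp(-2πi f k / fs)|²`` for each
    window, i.e. squared amplitude of the tapered Fourier coefficient.
    Output times lie on the absolute ``step_ms`` grid; edge times whose
    window does not fit are NaN with ``valid=False``.
    """
    data = np.asarray(data)
    times_ms = np.asarray(times_ms, dtype=float)
    fs = 1000.0 / (times_ms[1] - times_ms[0])
    freqs = DEFAULT_FREQS.copy() if freqs is None else np.asarray(freqs, dtype=float)
    if np.any(freqs > fs / 2.0):
        raise ValueError(
            f"requested frequency above Nyquist ({fs / 2:.1f} Hz): "
            f"{freqs[freqs > fs / 2]}")

    n_w = int(round(window_ms * fs / 1000.0))
    if n_w < 2 or n_w > data.shape[-1]:
        raise ValueError("analysis window does not fit inside the epoch")
    t0, t_end = times_ms[0], times_ms[-1]
    out_times = np.arange(np.ceil(t0 / step_ms) * step_ms,
                          t_end + 1e-9, step_ms)
    center_idx = np.round((out_times - t0) * fs / 1000.0).astype(int)
    starts = center_idx - n_w // 2
    valid = (starts >= 0) & (starts + n_w <= data.shape[-1])

    w = np.hanning(n_w)
    k = np.arange(n_w)
    kernel = (2.0 / w.sum()) * w[:, None] * np.exp(
        -2j * np.pi * freqs[None, :] * k[:, None] / fs)  # (n_w, n_f)

    n_obs, n_ch = data.shape[0], data.shape[1]
    power = np.full((n_obs, n_ch, len(freqs), len(out_times)), np.nan)
    v_starts = starts[valid]
    gather = v_starts[:, None] + np.arange(n_w)[None, :]  # (n_valid, n_w)
    for lo in range(0, n_obs, chunk):
        hi = min(lo + chunk, n_obs)
        segs = data[lo:hi][:, :, gather]              # (c, ch, n_valid, n_w)
        coef = segs @ kernel                          # (c, ch, n_valid, n_f)
        power[lo:hi, :, :, valid] = np.abs(np.swapaxes(coef, -1, -2)) ** 2
    return TFR(power=power, freqs=freqs, times_ms=out_times, valid=valid)


def tfr_of_epochs(epochs: Epochs, planar: bool = True, k: int = 6,
                  **kwargs) -> TFR:
    """TFR of (optionally planar-transformed, planar-combined) epochs."""
    if planar:
        ep = planar_transform(epochs, k=k)
        tfr = tfr_power(ep.data, ep.times_ms, **kwargs)
        return combine_planar(tfr)
    return tfr_power(epochs.data, epochs.times_ms, **kwargs)


def combine_planar(tfr: TFR) -> TFR:
    """Sum the two derivative-component power estimates per sensor."""
    if tfr.power.shape[1] % 2:
        raise ValueError("channel count is odd; not a planar-gradient TFR")
    n = tfr.power.shape[1] // 2
    return replace(tfr, power=tfr.power[:, :n] + tfr.power[:, n:])


def condition_average(tfr: TFR, labels) -> TFR:
    """Average observations sharing a label; observations become conditions."""
    labels = np.asarray(labels)
    if len(labels) != tfr.power.shape[0]:
        raise ValueError("one label per observation required")
    uniq = sorted(set(map(tuple, labels)) if labels.ndim > 1 else set(labels))
    key = list(map(tuple, labels)) if labels.ndim > 1 else list(labels)
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN edges
        out = np.stack([
            np.nanmean(tfr.power[[i for i, kk in enumerate(key) if kk == u]],
                       axis=0)
            for u in uniq
        ])
    return replace(tfr, power=out, obs_labels=list(uniq))


def condition_mean_tfr(
    data: np.ndarray,
    times_ms: np.ndarray,
    labels,
    chunk: int = 8,
    **kwargs,
) -> TFR:
    """Trial-averaged raw TFR per condition, accumulated chunk-wise.

    Equivalent to ``condition_average(tfr_power(data, ...), labels)`` but
    never materializes the per-trial power array (memory stays bounded by
    ``chunk`` trials).
    """
    labels = np.asarray(labels)
    key = list(map(tuple, labels)) if labels.ndim > 1 else list(labels)
    uniq = sorted(set(key))
    out = None
    for li, u in enumerate(uniq):
        idx = np.array([i for i, kk in enumerate(key) if kk == u])
        acc = None
        for lo in range(0, len(idx), chunk):
            part = tfr_power(data[idx[lo:lo + chunk]], times_ms,
                             chunk=chunk, **kwargs)
            s = part.power.sum(axis=0)
            acc = s if acc is None else acc + s
            template = part
        if out is None:
            out = np.empty((len(uniq),) + acc.shape)
        out[li] = acc / len(idx)
    return replace(template, power=out, obs_labels=list(uniq))


def relative_change(tfr: TFR, baseline: tuple[float, float] = (-500.0, 0.0)) -> TFR:
    """Express power as (P(t) − P̄_base) / P̄_base per channel × frequency."""
    if tfr.kind != "raw":
        raise ValueError("relative_change expects raw power")
    bidx = tfr.time_indices(baseline)
    base = np.nanmean(tfr.power[..., bidx], axis=-1)  # (obs, ch, f)
    bad = ~(base > 0)
    if np.any(bad):
        obs, ch, fr = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive baseline power at observation {obs}, channel {ch}, "
            f"frequency {tfr.freqs[fr]:g} Hz")
    return replace(tfr, power=tfr.power / base[..., None] - 1.0,
                   kind="relative_change")


def group_band_series(
    tfr: TFR,
    groups: dict[str, np.ndarray],
    band: tuple[float, float],
) -> dict[str, np.ndarray]:
    """Mean relative-change power over group channels and band frequencies.

    Returns ``{group: (n_obs, n_times)}`` series on the TFR time grid.
    """
    fidx = tfr.band_indices(band)
    out = {}
    for name, ch in groups.items():
        ch = np.asarray(ch)
        if ch.size == 0:
            raise ValueError(f"group {name!r} is empty")
        out[name] = tfr.power[:, ch][:, :, fidx].mean(axis=(1, 2))
    return out


def sensor_groups(sensors) -> dict[str, np.ndarray]:
    """Indices of the four analysis sensor groups."""
    return {g: sensors.group_indices(g) for g in ("PO-L", "PO-R", "M-L", "M-R")}


def save_tfr(tfr: TFR, path) -> None:
    """Store a TFR under /tfr in an HDF5 file, with axes metadata."""
    import h5py
    import json as _json
    with h5py.File(path, "a") as f:
        if "tfr" in f:
            del f["tfr"]
        g = f.create_group("tfr")
        g.create_dataset("power", data=tfr.power)
        g.create_dataset("freqs", data=tfr.freqs)
        g.create_dataset("times_ms", data=tfr.times_ms)
        g.create_dataset("valid", data=tfr.valid)
        g.attrs["kind"] = tfr.kind
        if tfr.obs_labels is not None:
            g.attrs["obs_labels"] = _json.dumps(
                [list(map(float, np.atleast_1d(lb))) for lb in tfr.obs_labels])


def load_tfr(path) -> TFR:
    import h5py
    import json as _json
    with h5py.File(path, "r") as f:
        g = f["tfr"]
        labels = None
        if "obs_labels" in g.attrs:
            labels = [tuple(lb) for lb in _json.loads(g.attrs["obs_labels"])]
        return TFR(power=g["power"][:], freqs=g["freqs"][:],
                   times_ms=g["times_ms"][:], valid=g["valid"][:],
                   kind=g.attrs["kind"], obs_labels=labels)
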