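"""Synthetic sensor array and single-sphere magnetic forward model.

The head is modeled as a homogeneous conducting sphere.  For that geometry
the magnetic field of a current dipole outside the sphere has the Sarvas
closed form, which is what MEG sphere models use; crucially, radial dipoles
(and dipoles at the sphere center) are magnetically silent.

Coordinates: source positions are given in MNI mm; internally everything is
mapped into a head frame (meters) whose origin is the sphere center.  The
sphere center sits at MNI ``(0, −25, 15)`` mm so an 80 mm radius covers
parieto-occipital cortex; the x → −x mirror symmetry used throughout the
lateralization analysis is preserved because the center has x = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MU0_OVER_4PI = 1e-7  # magnetic constant / 4π, SI

#: MNI coordinates (mm) of the default mask/sphere center.
HEAD_CENTER_MNI = np.array([0.0, -25.0, 15.0])


@dataclass
class SphereModel:
    """Single homogeneous sphere conductor, head frame (origin = center)."""

    radius_m: float = 0.09
    center_mni_mm: np.ndarray = field(
        default_factory=lambda: HEAD_CENTER_MNI.copy())

    def mni_to_head(self, mni_mm: np.ndarray) -> np.ndarray:
        return (np.asarray(mni_mm, dtype=float) - self.center_mni_mm) / 1000.0


@dataclass
class SensorArray:
    """Magnetometer-like sensors on a spherical cap.

    positions/orientations are (n, 3) arrays in the head frame (meters);
    orientations are radial unit vectors.  ``hemisphere`` is −1/0/+1 for
    left/midline/right (sign of x) and ``group`` is one of
    ``PO-L, PO-R, M-L, M-R, other``.  The layout is exactly mirror
    symmetric: ``mirror_index[i]`` is the sensor at ``(−x, y, z)``.
    """

    positions: np.ndarray
    orientations: np.ndarray
    hemisphere: np.ndarray
    group: np.ndarray
    mirror_index: np.ndarray

    @property
    def n_sensors(self) -> int:
        return len(self.positions)

    def group_indices(self, name: str) -> np.ndarray:
        idx = np.flatnonzero(self.group == name)
        if idx.size == 0:
            raise ValueError(f"sensor group {name!r} is empty")
        return idx


def make_sensor_array(n_sensors: int = 80, radius_m: float = 0.12) -> SensorArray:
    """Build a mirror-symmetric spherical-cap magnetometer array.

    Sensors are laid out on rings of constant colatitude covering the upper
    head (down to ~100° from the vertex to include parieto-occipital
    coverage), half on each side of the midsagittal plane, with none exactly
    on x = 0.  Groups are geometric stand-ins for the usual data-driven
    cluster selection: ``PO-*`` are posterior-inferior sensors, ``M-*``
    central-superior lateral sensors.
    """
    if n_sensors < 8 or n_sensors % 2:
        raise ValueError("n_sensors must be an even number >= 8")
    # ring colatitudes (deg) and relative capacities ~ sin(theta)
    thetas = np.array([12.0, 34.0, 56.0, 78.0, 100.0])
    weights = np.sin(np.radians(thetas))
    half = n_sensors // 2
    counts = np.maximum(1, np.round(weights / weights.sum() * half).astype(int))
    while counts.sum() > half:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < half:
        counts[np.argmax(weights - counts / half)] += 1

    pos_right = []
    for theta_deg, m in zip(thetas, counts):
        th = np.radians(theta_deg)
        # m right-hemisphere azimuths in (−90°, 90°), avoiding the midline
        phis = np.radians(-90 + (np.arange(m) + 0.5) * 180.0 / m)
        for ph in phis:
            pos_right.append([
                radius_m * np.sin(th) * np.cos(ph),
                radius_m * np.sin(th) * np.sin(ph),
                radius_m * np.cos(th),
            ])
    pos_right = np.array(pos_right)
    pos_left = pos_right * np.array([-1.0, 1.0, 1.0])
    positions = np.vstack([pos_left, pos_right])
    mirror_index = np.concatenate([np.arange(half, 2 * half), np.arange(half)])

    orientations = positions / np.linalg.norm(positions, axis=1, keepdims=True)
    hemisphere = np.sign(positions[:, 0]).astype(int)

    u = positions / radius_m
    group = np.full(len(positions), "other", dtype=object)
    po = (u[:, 1] < -0.45) & (u[:, 2] < 0.55)
    mo = (u[:, 2] > 0.55) & (np.abs(u[:, 1]) < 0.45) & (np.abs(u[:, 0]) > 0.15)
    group[po & (hemisphere < 0)] = "PO-L"
    group[po & (hemisphere > 0)] = "PO-R"
    group[mo & (hemisphere < 0)] = "M-L"
    group[mo & (hemisphere > 0)] = "M-R"

    return SensorArray(positions=positions, orientations=orientations,
                       hemisphere=hemisphere, group=np.asarray(group),
                       mirror_index=mirror_index)


def _sarvas_field(r0: np.ndarray, q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Magnetic field (T) of a current dipole q (A·m) at r0, at points r.

    Sarvas closed form for a dipole inside a homogeneous conducting sphere
    centered at the origin; valid at field points outside the sphere.
    """
    r = np.atleast_2d(r)
    a_vec = r - r0                       # (n, 3)
    a = np.linalg.norm(a_vec, axis=1)
    rn = np.linalg.norm(r, axis=1)
    if np.any(a < 1e-12):
        raise ValueError("field point coincides with the source")
    ar = np.einsum("ij,ij->i", a_vec, r)
    F = a * (rn * a + rn**2 - r @ r0)
    gradF = (
        (a**2 / rn + ar / a + 2.0 * a + 2.0 * rn)[:, None] * r
        - (a + 2.0 * rn + ar / a)[:, None] * r0[None, :]
    )
    qxr0 = np.cross(q, r0)
    B = MU0_OVER_4PI / F[:, None] ** 2 * (
        F[:, None] * qxr0[None, :] - (r @ qxr0)[:, None] * gradF
    )
    return B


def lead_field(
    source_mni_mm: np.ndarray,
    moment: np.ndarray,
    sensors: SensorArray,
    head_model: SphereModel | None = None,
) -> np.ndarray:
    """Per-sensor gain of a dipole with the given moment (projected field).

    Linear in ``moment``.  Raises for a source at the sphere center (any
    dipole there is magnetically silent: the forward problem is degenerate)
    or outside the conducting sphere.
    """
    head_model = head_model or SphereModel()
    r0 = head_model.mni_to_head(source_mni_mm)
    rad = np.linalg.norm(r0)
    if rad < 1e-6:
        raise ValueError("source at sphere center: degenerate (silent) position")
    if rad >= head_model.radius_m:
        raise ValueError(
            f"source {np.asarray(source_mni_mm)} lies outside the conductor "
            f"sphere (|r| = {rad * 1000:.1f} mm >= {head_model.radius_m * 1000:.0f} mm)"
        )
    B = _sarvas_field(r0, np.asarray(moment, dtype=float), sensors.positions)
    return np.einsum("ij,ij->i", B, sensors.orientations)


def lead_field_matrix(
    source_mni_mm: np.ndarray,
    sensors: SensorArray,
    head_model: SphereModel | None = None,
) -> np.ndarray:
    """(n_sensors, 3) gain matrix for unit dipoles along x, y, z."""
    cols = [lead_field(source_mni_mm, e, sensors, head_model)
            for e in np.eye(3)]
    return np.stack(cols, axis=1)


def lead_field_matrices(
    sources_mni_mm: np.ndarray,
    sensors: SensorArray,
    head_model: SphereModel | None = None,
) -> np.ndarray:
    """(n_sources, n_sensors, 3) gain stack; vectorized over sources."""
    head_model = head_model or SphereModel()
    out = np.empty((len(sources_mni_mm), sensors.n_sensors, 3))
    for i, src in enumerate(sources_mni_mm):
        out[i] = lead_field_matrix(src, sensors, head_model)
    return out
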