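"""Synthetic multi-participant MEG: one jittered dipole in a conducting sphere.

Each simulated participant has a single equivalent current dipole (ECD)
whose location is drawn from an isotropic Gaussian (default SD 5 mm)
around a common MNI-style seed (52, -29, 13) mm.  The dipole is driven
with a 40 Hz sinusoid for 200 ms epochs (200 Hz sampling) and is active in
30 of 60 epochs; i.i.d. Gaussian white sensor noise of density
10 fT/sqrt(Hz) over an 80 Hz bandwidth (per-sample SD 10*sqrt(80) ~ 89.4 fT)
is added to every epoch.  All participants share one sensor array and one
single-sphere head model; only the source location/orientation and the
noise realisation differ.

The forward field is the Sarvas closed-form solution for a current dipole
inside a homogeneous conducting sphere.  Radial dipole components are
externally silent in this model, so the source basis is tangential.

Geometry: 275 radial magnetometers quasi-uniformly covering a spherical
cap (down to ~20 degrees below the equator) at 12 cm radius around a 9 cm
conducting sphere, standing in for a whole-head axial-gradiometer array.
MNI-style mm coordinates map to the head frame by a fixed translation, so
all mm distances are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

MU0_OVER_4PI = 1e-7  # T·m/A

#: fixed translation taking MNI-style mm to head-frame mm (head = mni - offset)
MNI_OFFSET_MM = np.array([0.0, -20.0, 20.0])

DEFAULT_SEED_MNI_MM = (52.0, -29.0, 13.0)


def mni_to_head_m(loc_mm) -> np.ndarray:
    """MNI-style mm -> head-frame metres (translation only; distances preserved)."""
    return (np.asarray(loc_mm, dtype=float) - MNI_OFFSET_MM) / 1000.0


def head_m_to_mni(loc_m) -> np.ndarray:
    return np.asarray(loc_m, dtype=float) * 1000.0 + MNI_OFFSET_MM


@dataclass
class SensorArray:
    """Radial magnetometer array on a spherical cap around the conducting sphere."""

    positions: np.ndarray      # (S, 3) m, head frame
    orientations: np.ndarray   # (S, 3) unit radial
    sphere_center: np.ndarray  # (3,) m
    sphere_radius: float       # m

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]


def default_sensor_array(n_channels: int = 275, array_radius: float = 0.12,
                         sphere_radius: float = 0.09,
                         min_z_fraction: float = -0.35) -> SensorArray:
    """Fibonacci-lattice cap of radial magnetometers (deterministic).

    Points are generated quasi-uniformly on the full sphere, sorted by
    descending z, and the top ``n_channels`` above ``min_z_fraction`` of
    the radius are kept — a helmet-like cap extending a little below the
    equator.
    """
    frac = (1.0 - min_z_fraction) / 2.0
    n_total = int(np.ceil(n_channels / frac)) + 8
    i = np.arange(n_total)
    z = 1.0 - 2.0 * (i + 0.5) / n_total
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    r_xy = np.sqrt(np.clip(1.0 - z ** 2, 0.0, None))
    pts = np.stack([r_xy * np.cos(phi), r_xy * np.sin(phi), z], axis=1)
    pts = pts[np.argsort(-pts[:, 2])][:n_channels]
    return SensorArray(positions=array_radius * pts, orientations=pts.copy(),
                       sphere_center=np.zeros(3), sphere_radius=sphere_radius)


def _sarvas_field(r0: np.ndarray, q: np.ndarray, sensors_m: np.ndarray) -> np.ndarray:
    """Magnetic field (T) of dipole moment ``q`` (A·m) at ``r0`` (m, sphere frame).

    Sarvas closed form for a homogeneous conducting sphere centred at the
    origin:  B = mu0/(4 pi F^2) (F q×r0 − (q×r0·r) ∇F).
    """
    r = sensors_m                       # (S, 3)
    a_vec = r - r0                      # (S, 3)
    a = np.linalg.norm(a_vec, axis=1)
    rn = np.linalg.norm(r, axis=1)
    if np.any(a < 1e-9):
        raise ValueError("sensor coincides with the dipole location")
    F = a * (rn * a + rn ** 2 - r @ r0)
    adotr = np.einsum("sj,sj->s", a_vec, r)
    gradF = ((a ** 2 / rn + adotr / a + 2.0 * a + 2.0 * rn)[:, None] * r
             - (a + 2.0 * rn + adotr / a)[:, None] * r0[None, :])
    qxr0 = np.cross(q, r0)
    B = (MU0_OVER_4PI / F[:, None] ** 2) * (F[:, None] * qxr0[None, :]
                                            - (r @ qxr0)[:, None] * gradF)
    return B


def tangential_basis(loc_m: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Two orthonormal tangential unit vectors at ``loc_m`` (rows of a 2×3 array)."""
    radial = np.asarray(loc_m, dtype=float) - center
    nr = np.linalg.norm(radial)
    if nr < 1e-9:
        # at the sphere centre every direction is "tangential" (field is zero)
        return np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    radial = radial / nr
    helper = np.array([0.0, 0.0, 1.0])
    if abs(radial @ helper) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(radial, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(radial, e1)
    return np.stack([e1, e2])


def sphere_leadfield(loc_mm, sensors: SensorArray,
                     in_mni: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Gain matrix (S×2, T per A·m) of a tangential ECD pair at ``loc_mm``.

    Returns ``(gains, basis)`` where ``basis`` (2×3) holds the tangential
    unit moments the two gain columns correspond to.  The dipole must lie
    strictly inside the conducting sphere and off its centre (a central
    or radial dipole produces no external field).
    """
    loc_m = mni_to_head_m(loc_mm) if in_mni else np.asarray(loc_mm, dtype=float)
    rel = loc_m - sensors.sphere_center
    depth = np.linalg.norm(rel)
    if depth >= sensors.sphere_radius - 1e-6:
        raise ValueError("dipole location outside (or on) the conducting sphere")
    if depth < 1e-6:
        raise ValueError("dipole at the sphere centre is externally silent")
    basis = tangential_basis(loc_m, sensors.sphere_center)
    pos = sensors.positions - sensors.sphere_center
    gains = np.empty((sensors.n_channels, 2))
    for j in range(2):
        B = _sarvas_field(rel, basis[j], pos)
        gains[:, j] = np.einsum("sj,sj->s", B, sensors.orientations)
    return gains, basis


def dipole_field(loc_mm, moment_vec_am2, sensors: SensorArray,
                 in_mni: bool = True) -> np.ndarray:
    """Sensor readings (T) for an arbitrary dipole moment vector (A·m)."""
    loc_m = mni_to_head_m(loc_mm) if in_mni else np.asarray(loc_mm, dtype=float)
    rel = loc_m - sensors.sphere_center
    B = _sarvas_field(rel, np.asarray(moment_vec_am2, dtype=float),
                      sensors.positions - sensors.sphere_center)
    return np.einsum("sj,sj->s", B, sensors.orientations)


@dataclass
class SimulationConfig:
    """All knobs of the group dipole simulation (defaults = study conditions)."""

    seed_location_mm: tuple = DEFAULT_SEED_MNI_MM
    jitter_sd_mm: float = 5.0
    moment_nam: float = 20.0              # dipole magnitude, nAm
    frequency_hz: float = 40.0
    fs_hz: float = 200.0
    epoch_length_s: float = 0.2
    n_epochs: int = 60
    n_active_epochs: int = 30
    noise_density_ft_sqrthz: float = 10.0
    bandwidth_hz: float = 80.0
    n_participants: int = 10
    n_channels: int = 275
    reference_orientation: tuple = (0.0, 1.0, 1.0)
    orientation_jitter_scale_mm: float = 25.0

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.fs_hz * self.epoch_length_s))

    @property
    def noise_sd_t(self) -> float:
        """Per-sample noise SD in tesla: density × sqrt(bandwidth)."""
        return self.noise_density_ft_sqrthz * 1e-15 * np.sqrt(self.bandwidth_hz)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        for key in ("seed_location_mm", "reference_orientation"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg


@dataclass
class DipoleSource:
    location_mm: np.ndarray    # MNI-style mm
    orientation: np.ndarray    # unit, tangential in the head frame
    moment_nam: float
    waveform: np.ndarray       # (samples,) unitless envelope in [-1, 1]
    active_epochs: np.ndarray  # epoch indices


@dataclass
class EpochedData:
    """Sensor data (T): epochs × channels × samples plus active/passive labels."""

    data: np.ndarray
    fs_hz: float
    active: np.ndarray  # bool per epoch

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


def draw_source(cfg: SimulationConfig, sensors: SensorArray,
                rng: np.random.Generator) -> DipoleSource:
    """Draw one participant's dipole: jittered location, tangential orientation.

    The orientation stands in for a cortical surface normal: a fixed
    reference direction is perturbed by the location jitter divided by
    ``orientation_jitter_scale_mm`` (so a 5 mm location shift tilts the
    normal by ~0.2 rad), then projected onto the tangential plane —
    radial moments are silent in a sphere — and normalised.
    """
    center = np.asarray(cfg.seed_location_mm, dtype=float)
    while True:
        jitter = rng.normal(0.0, cfg.jitter_sd_mm, size=3)
        loc_mm = center + jitter
        rel = mni_to_head_m(loc_mm) - sensors.sphere_center
        if 1e-4 < np.linalg.norm(rel) < sensors.sphere_radius - 5e-3:
            break
    ref = np.asarray(cfg.reference_orientation, dtype=float)
    ref = ref / np.linalg.norm(ref)
    tilted = ref + jitter / cfg.orientation_jitter_scale_mm
    radial = rel / np.linalg.norm(rel)
    tang = tilted - (tilted @ radial) * radial
    if np.linalg.norm(tang) < 1e-8:
        tang = tangential_basis(mni_to_head_m(loc_mm), sensors.sphere_center)[0]
    orientation = tang / np.linalg.norm(tang)
    t = np.arange(cfg.samples_per_epoch) / cfg.fs_hz
    waveform = np.sin(2.0 * np.pi * cfg.frequency_hz * t)
    active = np.arange(cfg.n_active_epochs)
    return DipoleSource(np.asarray(loc_mm), orientation, cfg.moment_nam,
                        waveform, active)


def simulate_participant(cfg: SimulationConfig, rng: np.random.Generator,
                         sensors: SensorArray | None = None
                         ) -> tuple[EpochedData, np.ndarray]:
    """One participant's epoched sensor data and the true source location (mm).

    Active epochs contain the dipole signal plus noise; passive epochs are
    pure noise.  ``moment_nam = 0`` yields pure noise everywhere.
    """
    if sensors is None:
        sensors = default_sensor_array(cfg.n_channels)
    src = draw_source(cfg, sensors, rng)
    S = sensors.n_channels
    n_s = cfg.samples_per_epoch
    data = rng.normal(0.0, cfg.noise_sd_t, size=(cfg.n_epochs, S, n_s))
    if cfg.moment_nam != 0.0:
        moment_vec = src.moment_nam * 1e-9 * src.orientation  # A·m
        topo = dipole_field(src.location_mm, moment_vec, sensors)  # (S,)
        data[src.active_epochs] += topo[None, :, None] * src.waveform[None, None, :]
    active = np.zeros(cfg.n_epochs, dtype=bool)
    active[src.active_epochs] = True
    return EpochedData(data, cfg.fs_hz, active), src.location_mm


def simulate_group(cfg: SimulationConfig, rng: np.random.Generator,
                   n_participants: int | None = None,
                   sensors: SensorArray | None = None):
    """Independent participants sharing one sensor array and head model."""
    if sensors is None:
        sensors = default_sensor_array(cfg.n_channels)
    n = n_participants if n_participants is not None else cfg.n_participants
    datasets, true_locs = [], []
    for _ in range(n):
        ds, loc = simulate_participant(cfg, rng, sensors)
        datasets.append(ds)
        true_locs.append(loc)
    return datasets, np.asarray(true_locs), sensors
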