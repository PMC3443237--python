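"""Scalar LCMV beamformer producing pseudo-t volumetric images.

The linearly constrained minimum variance (LCMV) beamformer estimates
source activity at a location θ as a weighted sum of the sensor signals,
minimising output power subject to unit gain at θ:

    W = C⁻¹ H (Hᵀ C⁻¹ H)⁻¹

with C the sensor covariance over the covariance window and H the
forward solution of a tangential ECD pair at θ.  The scalar variant picks
the source orientation η that maximises output SNR — the generalised
eigenvector of (HᵀC⁻¹H, HᵀC⁻²H) at the largest eigenvalue — and the image
value is a noise-normalised power difference (pseudo-t)

    T(θ) = (Wᵀ C_active W − Wᵀ C_control W) / (σ² Wᵀ W)

assembled on a regular mm grid inside the conducting sphere.  No
regularisation is applied by default (``mu = 0``): maximum spatial
resolution at the cost of noisy images, i.e. many peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .peaks import VolumetricImage
from .simulate import EpochedData, SensorArray, mni_to_head_m, sphere_leadfield


@dataclass
class CovarianceSet:
    """Full-window and per-state sensor covariances plus a noise-floor estimate."""

    C: np.ndarray
    C_active: np.ndarray
    C_control: np.ndarray
    sigma2_noise: float


def covariances(data: EpochedData, sigma2_noise: float | None = None
                ) -> CovarianceSet:
    """Sensor covariances over the full window and per state.

    A single covariance (active + passive epochs pooled) drives the
    weights; state covariances feed the pseudo-t difference.  If the
    noise variance is not supplied it is estimated as the mean sensor
    variance over passive (control) epochs.
    """
    ep, S, ns = data.data.shape

    def cov_of(sel):
        X = data.data[sel].transpose(1, 0, 2).reshape(S, -1)
        X = X - X.mean(axis=1, keepdims=True)
        return (X @ X.T) / (X.shape[1] - 1)

    C = cov_of(slice(None))
    Ca = cov_of(data.active)
    Cc = cov_of(~data.active)
    if sigma2_noise is None:
        sigma2_noise = float(np.trace(Cc) / S)
    return CovarianceSet(C, Ca, Cc, sigma2_noise)


def lcmv_weights(H: np.ndarray, C: np.ndarray, basis: np.ndarray | None = None,
                 mu: float = 0.0, c_inv: np.ndarray | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Unit-gain LCMV weights and the optimal source orientation at one voxel.

    ``H`` is the S×2 tangential gain matrix.  Orientation is the
    generalised eigenvector of (HᵀC⁻¹H, HᵀC⁻²H) with the largest
    eigenvalue (max output SNR); ``W = C⁻¹Hη`` rescaled so ``Wᵀ(Hη) = 1``.
    Returns ``(W, orientation)`` where the orientation is the 3-vector
    ``basis.T @ η`` when a tangential basis is given, else η itself.
    Raises :class:`numpy.linalg.LinAlgError` when HᵀC⁻¹H is singular
    (e.g. a voxel at the sphere centre) — callers mark the voxel invalid.
    """
    if c_inv is None:
        Creg = C + mu * np.trace(C) / C.shape[0] * np.eye(C.shape[0]) if mu else C
        c_inv = np.linalg.pinv(Creg, rcond=1e-12)
    CiH = c_inv @ H
    S1 = H.T @ CiH           # Hᵀ C⁻¹ H
    S2 = CiH.T @ CiH         # Hᵀ C⁻² H
    if np.linalg.cond(S1) > 1e12 or not np.all(np.isfinite(S1)):
        raise np.linalg.LinAlgError("singular leadfield Gram matrix")
    evals, evecs = linalg.eigh(S1, S2)
    eta = evecs[:, -1]
    gain_vec = H @ eta
    w = c_inv @ gain_vec
    denom = w @ gain_vec
    if abs(denom) < 1e-300:
        raise np.linalg.LinAlgError("zero unit-gain denominator")
    w = w / denom
    eta = eta / np.linalg.norm(eta)
    orientation = basis.T @ eta if basis is not None else eta
    return w, orientation


def source_grid(sensors: SensorArray, spacing_mm: float = 10.0,
                margin_mm: float = 10.0):
    """Regular MNI-space mm grid with a mask of voxels ≥ ``margin_mm`` inside the sphere.

    Returns ``(shape, affine, mask, coords_mm)`` where ``coords_mm`` lists
    the in-mask voxel centres (MNI-style mm) in C order.
    """
    from .simulate import MNI_OFFSET_MM

    R = sensors.sphere_radius * 1000.0
    center_mni = sensors.sphere_center * 1000.0 + MNI_OFFSET_MM
    half = spacing_mm * np.floor((R - margin_mm) / spacing_mm)
    axes = [center_mni[i] + np.arange(-half, half + spacing_mm, spacing_mm)
            for i in range(3)]
    shape = tuple(len(a) for a in axes)
    affine = np.diag([spacing_mm] * 3 + [1.0])
    affine[:3, 3] = [a[0] for a in axes]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1)
    dist = np.linalg.norm(pts - center_mni, axis=-1)
    mask = dist <= (R - margin_mm)
    coords = pts[mask]
    return shape, affine, mask, coords


def grid_leadfields(coords_mm: np.ndarray, sensors: SensorArray) -> np.ndarray:
    """Stacked S×2 gain matrices for every grid point (V, S, 2).

    Depends only on geometry, so one evaluation serves all participants.
    """
    V = coords_mm.shape[0]
    out = np.empty((V, sensors.n_channels, 2))
    for v in range(V):
        try:
            out[v], _ = sphere_leadfield(coords_mm[v], sensors)
        except ValueError:  # grid point at the (silent) sphere centre
            out[v] = 0.0
    return out


def pseudo_t_image(data: EpochedData, sensors: SensorArray,
                   spacing_mm: float = 10.0, mu: float = 0.0,
                   sigma2_noise: float | None = None,
                   leadfields: np.ndarray | None = None,
                   grid=None) -> VolumetricImage:
    """Whole-volume pseudo-t image of active-vs-control power change.

    A single covariance over the full window drives the weights at every
    in-mask voxel; σ² is the supplied (or passive-epoch estimated) sensor
    noise variance with an identity noise covariance.  Voxels where the
    weights are undefined are set to 0 and removed from the mask.
    """
    if grid is None:
        grid = source_grid(sensors, spacing_mm)
    shape, affine, mask, coords = grid
    if leadfields is None:
        leadfields = grid_leadfields(coords, sensors)
    covs = covariances(data, sigma2_noise)
    c_inv = np.linalg.pinv(covs.C, rcond=1e-12)

    V, S, _ = leadfields.shape
    Hflat = leadfields.reshape(V * S, 2)
    CiH = (c_inv @ Hflat.reshape(V, S, 2).transpose(1, 0, 2).reshape(S, -1))
    CiH = CiH.reshape(S, V, 2).transpose(1, 0, 2)          # (V, S, 2)
    S1 = np.einsum("vsi,vsj->vij", leadfields, CiH)        # HᵀC⁻¹H
    S2 = np.einsum("vsi,vsj->vij", CiH, CiH)               # HᵀC⁻²H

    tvals = np.zeros(V)
    valid = np.ones(V, dtype=bool)
    W = np.zeros((V, S))
    for v in range(V):
        try:
            evals, evecs = linalg.eigh(S1[v], S2[v])
        except (linalg.LinAlgError, ValueError):
            valid[v] = False
            continue
        eta = evecs[:, -1]
        gain_vec = leadfields[v] @ eta
        w = c_inv @ gain_vec
        denom = w @ gain_vec
        if not np.isfinite(denom) or abs(denom) < 1e-300:
            valid[v] = False
            continue
        W[v] = w / denom
    Pa = np.einsum("vs,st,vt->v", W, covs.C_active, W)
    Pc = np.einsum("vs,st,vt->v", W, covs.C_control, W)
    noise = covs.sigma2_noise * np.einsum("vs,vs->v", W, W)
    with np.errstate(invalid="ignore", divide="ignore"):
        tv = (Pa - Pc) / noise
    tvals[valid] = tv[valid]

    vol = np.zeros(shape)
    vol[mask] = tvals
    final_mask = mask.copy()
    final_mask[mask] = valid
    return VolumetricImage(vol, affine, final_mask)
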