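"""Spatial registration: rigid-body motion correction and affine co-registration.

Every incoming echo-planar volume is realigned to the session's reference
functional image (RFI) with a 6-parameter rigid-body fit maximising
normalised correlation, resampled with trilinear interpolation — the
standard real-time motion-correction recipe. A single 12-degree-of-freedom
affine fit registers the RFI to the reference anatomical image (RAI) once
per session, for display-space overlay only; all feedback computation stays
in RFI space.

Conventions
-----------
Transforms act in world (mm) coordinates, rotations about a configurable
centre (the RFI centre of mass by default). A transform ``T`` *moves the
image*: the resampled volume is ``out(x) = in(T^{-1} x)``. Consequently the
parameters returned by :func:`motion_correct` are the rigid motion that,
applied to the volume, aligns it with the reference — a volume whose
content slid +2 mm comes back with a fitted translation of −2 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize

from .volume import Volume

__all__ = [
    "RigidTransform",
    "AffineTransform",
    "register_affine",
    "motion_correct",
    "resample_rigid",
    "smooth",
    "RegistrationError",
]


class RegistrationError(RuntimeError):
    """Degenerate input or failed optimisation; carries the best cost seen."""

    def __init__(self, message: str, best_corr: float | None = None):
        self.best_corr = best_corr
        if best_corr is not None:
            message += f" (best normalised correlation: {best_corr:.4f})"
        super().__init__(message)


def _rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rx @ Ry @ Rz


@dataclass
class RigidTransform:
    """Six-parameter rigid-body motion: 3 rotations (rad), 3 translations (mm)."""

    rotations: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translations: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotations = np.asarray(self.rotations, dtype=float)
        self.translations = np.asarray(self.translations, dtype=float)

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.rotations, self.translations])

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_params(cls, p) -> "RigidTransform":
        p = np.asarray(p, dtype=float)
        return cls(rotations=p[:3], translations=p[3:6])

    def matrix(self, center: np.ndarray) -> np.ndarray:
        """Homogeneous 4x4 world-space matrix, rotation about ``center``."""
        R = _rotation_matrix(*self.rotations)
        center = np.asarray(center, dtype=float)
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = center - R @ center + self.translations
        return M

    def inverse(self, center: np.ndarray) -> "RigidTransform":
        """Rigid transform whose matrix is the inverse about the same centre."""
        center = np.asarray(center, dtype=float)
        Minv = np.linalg.inv(self.matrix(center))
        R = Minv[:3, :3]
        # Euler angles for the Rx@Ry@Rz convention used by _rotation_matrix
        ry = np.arcsin(np.clip(R[0, 2], -1.0, 1.0))
        rz = np.arctan2(-R[0, 1], R[0, 0])
        rx = np.arctan2(-R[1, 2], R[2, 2])
        t = Minv[:3, 3] - (center - R @ center)
        return RigidTransform(np.array([rx, ry, rz]), t)


@dataclass
class AffineTransform:
    """Full 12-DOF affine as a homogeneous 4x4 world-space matrix."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        if not np.allclose(self.matrix[3], [0, 0, 0, 1]):
            raise ValueError("last row of an affine must be (0,0,0,1)")

    def save_txt(self, path: str | Path) -> None:
        np.savetxt(str(path), self.matrix, fmt="%.10g")

    @classmethod
    def load_txt(cls, path: str | Path) -> "AffineTransform":
        return cls(np.loadtxt(str(path)))


def _affine_from_params(p: np.ndarray, center: np.ndarray) -> np.ndarray:
    """rot(3) + trans(3) + log-scale(3) + shear(3) -> 4x4 about ``center``."""
    R = _rotation_matrix(*p[:3])
    Z = np.diag(np.exp(p[6:9]))
    S = np.eye(3)
    S[0, 1], S[0, 2], S[1, 2] = p[9:12]
    A = R @ Z @ S
    M = np.eye(4)
    M[:3, :3] = A
    M[:3, 3] = center - A @ center + p[3:6]
    return M


def center_of_mass_world(vol: Volume) -> np.ndarray:
    """Intensity centre of mass in world (mm) coordinates."""
    w = np.clip(vol.data, 0, None)
    total = w.sum()
    if total <= 0:
        com_vox = (np.asarray(vol.shape) - 1) / 2.0
    else:
        com_vox = np.array(ndimage.center_of_mass(w))
    return vol.affine[:3, :3] @ com_vox + vol.affine[:3, 3]


def _resample_matrix(vol: Volume, world_matrix: np.ndarray) -> np.ndarray:
    """World transform -> voxel-space resampling matrix for affine_transform."""
    S = vol.affine
    return np.linalg.inv(S) @ np.linalg.inv(world_matrix) @ S


def resample_world(vol: Volume, world_matrix: np.ndarray, order: int = 1) -> Volume:
    """Apply a world-space transform to the image (out-of-field voxels → 0)."""
    M = _resample_matrix(vol, world_matrix)
    out = ndimage.affine_transform(
        vol.data, M[:3, :3], offset=M[:3, 3], order=order,
        mode="constant", cval=0.0,
    )
    return vol.with_data(out)


def resample_rigid(vol: Volume, t: RigidTransform, center: np.ndarray,
                   order: int = 1) -> Volume:
    return resample_world(vol, t.matrix(center), order=order)


def _normcorr(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def _check_nondegenerate(v: Volume, name: str) -> None:
    if np.ptp(v.data) == 0:
        raise RegistrationError(f"{name} volume is constant; cannot register")


# internal parameter scaling so one Nelder-Mead step means ~the same amount
# of image motion for every coordinate
_RIGID_SCALE = np.array([0.01, 0.01, 0.01, 1.0, 1.0, 1.0])


def _estimation_pair(moving: Volume, fixed: Volume, sigma: float):
    """Build the smoothed, spline-prefiltered image pair for cost evaluation.

    Two tricks make the normalised-correlation surface clean at sub-voxel
    scale. (1) Both images are Gaussian-smoothed (``sigma`` voxels) before
    comparison, otherwise interpolation's incidental noise averaging
    rewards small spurious transforms on noisy data. (2) Both sides are
    resampled through a constant half-voxel offset — the candidate
    transform composed with the offset on the moving side, the offset
    alone on the fixed side — so every candidate, including the identity,
    pays the same interpolation penalty; without this the exactly
    grid-aligned identity is artificially favoured. Estimation resampling
    is cubic spline; the returned moving image is pre-filtered so repeated
    evaluations skip the spline prefilter.
    """
    if sigma > 0:
        mdata = ndimage.gaussian_filter(moving.data, sigma)
        fdata = ndimage.gaussian_filter(fixed.data, sigma)
    else:
        mdata, fdata = moving.data, fixed.data
    S = np.eye(4)
    S[:3, 3] = 0.5 * fixed.voxel_sizes
    fixed_ref = resample_world(fixed.with_data(fdata), S, order=3).data
    moving_filt = ndimage.spline_filter(mdata, order=3)
    return moving_filt, fixed_ref, S


def _est_resample(moving_filt: np.ndarray, vol: Volume,
                  world_matrix: np.ndarray) -> np.ndarray:
    M = _resample_matrix(vol, world_matrix)
    return ndimage.affine_transform(
        moving_filt, M[:3, :3], offset=M[:3, 3], order=3,
        mode="constant", cval=0.0, prefilter=False)


def motion_correct(
    vol: Volume,
    rfi: Volume,
    center: np.ndarray | None = None,
    start: RigidTransform | None = None,
    xatol: float = 1e-3,
    maxiter: int = 600,
    est_smooth_sigma: float = 1.0,
) -> tuple[Volume, RigidTransform]:
    """Rigid-body realignment of ``vol`` to the reference functional image.

    Maximises normalised correlation over the 6 rigid parameters
    (Nelder-Mead from the identity, or from ``start`` when warm-starting a
    stream) and resamples with trilinear interpolation.

    Parameters are *estimated* on smoothed copies of both volumes through
    a symmetric half-voxel resampling offset (see :func:`_estimation_pair`
    for why), and the fitted transform is then applied to the raw volume
    with trilinear interpolation.
    """
    if vol.shape != rfi.shape:
        raise RegistrationError(
            f"shape mismatch: volume {vol.shape} vs RFI {rfi.shape}"
        )
    _check_nondegenerate(vol, "moving")
    _check_nondegenerate(rfi, "reference")
    if center is None:
        center = center_of_mass_world(rfi)

    moving_filt, fixed_ref, S = _estimation_pair(vol, rfi, est_smooth_sigma)
    q0 = (start.params if start is not None else np.zeros(6)) / _RIGID_SCALE

    def cost(q: np.ndarray) -> float:
        t = RigidTransform.from_params(q * _RIGID_SCALE)
        moved = _est_resample(moving_filt, vol, S @ t.matrix(center))
        return -_normcorr(moved, fixed_ref)

    simplex = np.vstack([q0, q0 + np.eye(6)])
    res = minimize(
        cost, q0, method="Nelder-Mead",
        options={"xatol": xatol, "fatol": 1e-9, "maxiter": maxiter,
                 "initial_simplex": simplex},
    )
    p_best = res.x * _RIGID_SCALE
    # keep the identity if optimisation could not beat it (already aligned)
    if -res.fun < -cost(np.zeros(6)):
        p_best = np.zeros(6)
    t = RigidTransform.from_params(p_best)
    corrected = resample_rigid(vol, t, center)
    return corrected, t


def register_affine(
    moving: Volume,
    fixed: Volume,
    min_corr: float = 0.2,
    maxiter: int = 2000,
    est_smooth_sigma: float = 1.0,
) -> AffineTransform:
    """One-shot 12-DOF affine co-registration (RFI → RAI), normcorr cost.

    Two-stage fit: rigid first, then all 12 parameters from the rigid
    optimum, estimated on smoothed copies (see :func:`motion_correct`).
    Raises :class:`RegistrationError` carrying the best correlation if the
    final fit is no better than chance (e.g. structureless input).
    """
    _check_nondegenerate(moving, "moving")
    _check_nondegenerate(fixed, "fixed")
    center = center_of_mass_world(fixed)
    scale = np.concatenate([_RIGID_SCALE, [0.02] * 3, [0.02] * 3])
    moving_filt, fixed_ref, S = _estimation_pair(moving, fixed, est_smooth_sigma)

    def cost(q: np.ndarray) -> float:
        p = np.zeros(12)
        p[: len(q)] = q * scale[: len(q)]
        M = _affine_from_params(p, center)
        moved = _est_resample(moving_filt, moving, S @ M)
        return -_normcorr(moved, fixed_ref)

    q = np.zeros(6)
    res6 = minimize(
        cost, q, method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-9, "maxiter": maxiter,
                 "initial_simplex": np.vstack([q, q + np.eye(6)])},
    )
    q12 = np.zeros(12)
    q12[:6] = res6.x
    res12 = minimize(
        cost, q12, method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": maxiter,
                 "initial_simplex": np.vstack([q12, q12 + 0.5 * np.eye(12)])},
    )
    best_corr = -res12.fun
    if best_corr < min_corr:
        raise RegistrationError(
            "affine registration did not converge to a meaningful alignment",
            best_corr=best_corr,
        )
    p = res12.x * scale
    return AffineTransform(_affine_from_params(p, center))


def smooth(vol: Volume, fwhm_mm: float) -> Volume:
    """Separable Gaussian smoothing with a full-width-half-maximum in mm.

    Per-axis sigma in voxels is ``(fwhm / voxel_size) / (2 sqrt(2 ln 2))``.
    ``fwhm_mm == 0`` returns the input unchanged.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return vol.with_data(vol.data.copy())
    sigmas = (fwhm_mm / vol.voxel_sizes) / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return vol.with_data(ndimage.gaussian_filter(vol.data, sigma=sigmas))
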