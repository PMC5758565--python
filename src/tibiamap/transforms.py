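"""Volume rotation, the rotation-sensitivity experiment, and
landmark-based rigid/affine 3-D registration.

Transforms are 4x4 homogeneous matrices acting on ``(z, y, x)`` vectors
in mm.  Rotation planes follow the micro-CT viewer convention:

* ``axial``    — the (x, z) plane (top view);
* ``sagittal`` — the (y, z) plane (lateral view);
* ``coronal``  — the (x, y) plane, i.e. within the slicing plane, which
  by construction cannot change slice image numbers.

Positive angles rotate the first named axis toward the second.  The
rotation center is the bone-mask centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .core_io import LandmarkSet, VolumeStack
from .landmarks import DetectionConfig, detect

__all__ = [
    "RotationSpec",
    "Transform3D",
    "rotate_volume",
    "rotation_sensitivity",
    "fit_rigid_landmarks",
    "fit_affine_landmarks",
    "apply_transform",
    "refine_rigid_ssd",
]

_PLANE_AXES = {"axial": (0, 2), "sagittal": (0, 1), "coronal": (1, 2)}


@dataclass
class RotationSpec:
    """A single-plane rotation about the bone centroid."""

    plane: str
    angle_deg: float
    order: int | None = None  # interpolation order; None = by volume kind

    def __post_init__(self):
        if self.plane not in _PLANE_AXES:
            raise ValueError(f"plane must be one of {sorted(_PLANE_AXES)}, got {self.plane!r}")
        if abs(self.angle_deg) > 45:
            raise ValueError(f"|angle| must be <= 45 deg, got {self.angle_deg}")


@dataclass
class Transform3D:
    """Rigid or affine map in mm with fiducial residuals.

    ``matrix`` maps homogeneous moving-space (z, y, x, 1) vectors into the
    fixed space.  ``fre_mm`` is the root-mean-square fiducial residual.
    """

    kind: str
    matrix: np.ndarray  # (4, 4)
    residuals_mm: np.ndarray | None = None  # per-landmark Euclidean residuals
    landmark_names: list[str] | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("matrix must be 4x4 homogeneous")
        if self.kind == "rigid":
            R = self.matrix[:3, :3]
            if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
                raise ValueError("rigid transform needs an orthonormal, det=+1 rotation block")

    @property
    def fre_mm(self) -> float:
        if self.residuals_mm is None:
            return np.nan
        return float(np.sqrt(np.mean(self.residuals_mm**2)))

    def apply_points(self, pts_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts_mm, float))
        return (self.matrix[:3, :3] @ pts.T).T + self.matrix[:3, 3]

    def inverse(self) -> "Transform3D":
        return Transform3D(self.kind, np.linalg.inv(self.matrix))

    @classmethod
    def identity(cls, kind: str = "rigid") -> "Transform3D":
        return cls(kind, np.eye(4))


def _resample(
    voxels: np.ndarray,
    matrix: np.ndarray,
    offset: np.ndarray,
    output_shape: tuple,
    kind: str,
    order: int | None = None,
) -> np.ndarray:
    """Affine pull-back resampling; label volumes use linearly interpolated
    per-label indicators followed by argmax (majority-style), which is
    label-safe but much less prone to staircase artifacts than plain
    nearest-neighbour sampling."""
    if kind != "label":
        return ndimage.affine_transform(
            voxels, matrix, offset=offset, output_shape=output_shape,
            order=1 if order is None else order, prefilter=False,
        )
    if order == 0:
        return ndimage.affine_transform(
            voxels, matrix, offset=offset, output_shape=output_shape, order=0
        )
    labels = np.unique(voxels)
    scores = np.zeros((len(labels),) + tuple(output_shape), dtype=np.float32)
    for i, lab in enumerate(labels):
        scores[i] = ndimage.affine_transform(
            (voxels == lab).astype(np.float32), matrix, offset=offset,
            output_shape=output_shape, order=1, prefilter=False,
        )
    out = labels[np.argmax(scores, axis=0)]
    return out.astype(voxels.dtype)


def _bone_centroid_mm(vol: VolumeStack) -> np.ndarray:
    mask = vol.voxels > 0
    if not mask.any():
        return np.array(vol.shape, float) / 2 * np.array(vol.spacing)
    idx = np.argwhere(mask)
    return idx.mean(axis=0) * np.array(vol.spacing)


def _rotation_matrix(plane: str, angle_deg: float) -> np.ndarray:
    a, b = _PLANE_AXES[plane]
    th = np.deg2rad(angle_deg)
    R = np.eye(3)
    R[a, a] = np.cos(th)
    R[b, b] = np.cos(th)
    R[a, b] = -np.sin(th)
    R[b, a] = np.sin(th)
    return R


def rotate_volume(vol: VolumeStack, spec: RotationSpec) -> VolumeStack:
    """Resample the volume rotated about its bone centroid.

    The output grid is padded so no bone voxel is cropped.  Labels use
    label-safe (indicator-argmax) interpolation, grayscale linear.
    """
    spacing = np.array(vol.spacing)
    R = _rotation_matrix(spec.plane, spec.angle_deg)
    center = _bone_centroid_mm(vol)

    # pad the two rotated axes enough to hold the rotated bounding box
    a, b = _PLANE_AXES[spec.plane]
    ext = np.array(vol.shape) * spacing
    s = abs(np.sin(np.deg2rad(spec.angle_deg)))
    pad = np.zeros(3, int)
    pad[a] = int(np.ceil(s * ext[b] / spacing[a])) + 2
    pad[b] = int(np.ceil(s * ext[a] / spacing[b])) + 2
    padded = np.pad(vol.voxels, [(p, p) for p in pad])
    center_idx = center / spacing + pad

    # pull-back: input_index = R^-1 (output_index - c) + c  (index space,
    # valid because spacing is per-axis diagonal)
    S = np.diag(spacing)
    M = np.linalg.inv(S) @ R.T @ S
    offset = center_idx - M @ center_idx
    out = _resample(padded, M, offset, padded.shape, vol.kind, order=spec.order)
    if vol.kind == "label":
        n_in, n_out = int((padded > 0).sum()), int((out > 0).sum())
        if n_in and abs(n_out - n_in) > 0.1 * n_in:
            raise RuntimeError("rotation lost more than 10% of foreground voxels")
    return VolumeStack(out, vol.spacing, side=vol.side, kind=vol.kind)


def rotation_sensitivity(
    vol: VolumeStack,
    angles=(-10.0, 0.0, 10.0),
    planes=("axial", "sagittal"),
    config: DetectionConfig | None = None,
) -> pd.DataFrame:
    """Relative RP2-RP4 positions under plane rotations, vs the 0 deg row.

    Returns one row per (plane, angle) with the detected relative
    positions (percent of the RP1-RP5 span) and their deltas against the
    unrotated stack.  Failed detections are recorded as missing rows, not
    raised.
    """
    base = detect(vol, config).relative
    rows = []
    for plane in planes:
        for angle in angles:
            rec = {"plane": plane, "angle_deg": float(angle)}
            try:
                rv = vol if angle == 0 else rotate_volume(vol, RotationSpec(plane, angle))
                rel = detect(rv, config).relative
                for k, name in ((1, "rp2"), (2, "rp3"), (3, "rp4")):
                    rec[f"{name}_rel"] = rel[k]
                    rec[f"{name}_delta"] = rel[k] - base[k]
            except Exception as exc:  # detection failure is data, not fatal
                rec["error"] = str(exc)
            rows.append(rec)
    return pd.DataFrame(rows)


def _paired(fixed: LandmarkSet, moving: LandmarkSet, min_n: int):
    names = [n for n in fixed.names if n in moving.names]
    if len(names) < min_n:
        raise ValueError(f"need >= {min_n} correspondences by name, got {len(names)}")
    return names, fixed.subset(names).mm, moving.subset(names).mm


def fit_rigid_landmarks(fixed: LandmarkSet, moving: LandmarkSet) -> Transform3D:
    """Least-squares rigid (rotation + translation) fit of named landmarks.

    Closed-form SVD (orthogonal Procrustes) with a reflection guard;
    minimizes sum ||T m_i - f_i||^2 over rotations with det = +1.
    """
    names, F, M = _paired(fixed, moving, 3)
    Fc, Mc = F - F.mean(0), M - M.mean(0)
    if np.linalg.matrix_rank(Mc, tol=1e-9) < 2 or np.linalg.matrix_rank(Fc, tol=1e-9) < 2:
        raise ValueError("landmarks are collinear; rigid fit is underdetermined")
    H = Mc.T @ Fc
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = F.mean(0) - R @ M.mean(0)
    mat = np.eye(4)
    mat[:3, :3] = R
    mat[:3, 3] = t
    res = np.linalg.norm((R @ M.T).T + t - F, axis=1)
    return Transform3D("rigid", mat, res, names)


def fit_affine_landmarks(fixed: LandmarkSet, moving: LandmarkSet) -> Transform3D:
    """Least-squares 12-parameter affine fit of named landmarks."""
    names, F, M = _paired(fixed, moving, 4)
    if np.linalg.matrix_rank(M - M.mean(0), tol=1e-9) < 3:
        raise ValueError(
            "landmarks are coplanar; the affine fit is underdetermined — add "
            "extra landmarks off the plane (e.g. the medial/lateral plateau "
            "ends on the RL3 section)"
        )
    A = np.hstack([M, np.ones((len(names), 1))])
    X, *_ = np.linalg.lstsq(A, F, rcond=None)
    mat = np.eye(4)
    mat[:3, :3] = X[:3].T
    mat[:3, 3] = X[3]
    res = np.linalg.norm(A @ X - F, axis=1)
    return Transform3D("affine", mat, res, names)


def apply_transform(vol: VolumeStack, t: Transform3D, reference: VolumeStack | None = None) -> VolumeStack:
    """Resample ``vol`` (moving) into the fixed frame of ``t``.

    The output grid is the reference volume's grid (or the input grid).
    Label volumes use nearest-neighbour interpolation.
    """
    ref = reference or vol
    A = t.matrix
    if abs(np.linalg.det(A[:3, :3])) < 1e-12:
        raise ValueError("singular transform cannot be applied")
    Ainv = np.linalg.inv(A)
    S_in = np.diag(vol.spacing)
    S_out = np.diag(ref.spacing)
    M = np.linalg.inv(S_in) @ Ainv[:3, :3] @ S_out
    offset = np.linalg.inv(S_in) @ Ainv[:3, 3]
    out = _resample(vol.voxels, M, offset, ref.shape, vol.kind)
    return VolumeStack(out.astype(vol.voxels.dtype), ref.spacing, side=vol.side, kind=vol.kind)


def _ssd(fixed: np.ndarray, moving_t: np.ndarray) -> float:
    d = fixed.astype(np.float32) - moving_t.astype(np.float32)
    return float(np.mean(d * d))


def refine_rigid_ssd(
    fixed: VolumeStack,
    moving: VolumeStack,
    init: Transform3D | None = None,
    levels: tuple[int, ...] = (4, 2, 1),
    maxiter: int = 60,
) -> Transform3D:
    """Local refinement of a rigid transform by sum-of-squared-differences.

    Derivative-free (Nelder-Mead) optimization of the 6 rigid parameters
    on a coarse-to-fine pyramid; the returned transform never has a higher
    full-resolution SSD than the initialization.
    """
    init = init or Transform3D.identity()
    if not (fixed.voxels > 0).any() or not (moving.voxels > 0).any():
        raise ValueError("SSD refinement needs non-empty overlapping volumes")
    center = _bone_centroid_mm(fixed)

    def compose(p: np.ndarray) -> Transform3D:
        rz, ry, rx, tz, ty, tx = p
        R = (
            _rotation_matrix("coronal", rx)
            @ _rotation_matrix("sagittal", ry)
            @ _rotation_matrix("axial", rz)
        )
        mat = np.eye(4)
        mat[:3, :3] = R
        mat[:3, 3] = np.array([tz, ty, tx]) + center - R @ center
        return Transform3D("rigid", mat @ init.matrix)

    def downsample(v: VolumeStack, f: int) -> VolumeStack:
        if f == 1:
            return v
        return VolumeStack(
            v.voxels[::f, ::f, ::f], tuple(s * f for s in v.spacing), side=v.side, kind=v.kind
        )

    def as_float(v: VolumeStack) -> np.ndarray:
        # labels enter the metric as a binary foreground mask so that the
        # cartilage label does not carry more weight than bone
        return (v.voxels > 0).astype(np.float32) if v.kind == "label" else v.voxels.astype(np.float32)

    p = np.zeros(6)
    for f in levels:
        fx, mv = downsample(fixed, f), downsample(moving, f)
        fx_arr = as_float(fx)
        mv_arr = as_float(mv)
        S_in = np.diag(mv.spacing)
        S_out = np.diag(fx.spacing)

        def cost(q):
            Ainv = np.linalg.inv(compose(q).matrix)
            M = np.linalg.inv(S_in) @ Ainv[:3, :3] @ S_out
            off = np.linalg.inv(S_in) @ Ainv[:3, 3]
            mt = ndimage.affine_transform(
                mv_arr, M, offset=off, output_shape=fx_arr.shape, order=1, prefilter=False
            )
            return _ssd(fx_arr, mt)

        res = optimize.minimize(
            cost,
            p,
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-9},
        )
        p = res.x

    final = compose(p)
    fg = as_float(fixed)
    ssd_init = _ssd(fg, as_float(apply_transform(moving, init, reference=fixed)))
    ssd_final = _ssd(fg, as_float(apply_transform(moving, final, reference=fixed)))
    if ssd_final > ssd_init:
        return Transform3D("rigid", init.matrix.copy())
    return final
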