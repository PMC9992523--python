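"""Native-space habenula analysis: AC-PC reorientation, ROI statistics and
volumetry.

The reorientation mirrors the manual-delineation workflow: maps are rotated
and translated so the anterior/posterior-commissure midpoint sits at the
origin with the AC-to-PC direction along the -y world axis, the ROI is
defined there, and the inverse rigid transform carries it back to native
space.  Statistics are then computed on the round-tripped masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "RigidTransform",
    "RoiStats",
    "VolumeReport",
    "acpc_transform",
    "resample",
    "roi_stats",
    "habenula_volumes",
]


@dataclass(frozen=True)
class RigidTransform:
    """World-space rigid transform ``x -> R x + t`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if r.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-8):
            raise ValueError("rotation determinant must be +1")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        r_inv = self.rotation.T
        return RigidTransform(r_inv, -r_inv @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Returns the transform ``self o other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m


@dataclass(frozen=True)
class RoiStats:
    """Mean/SD of one map inside one ROI."""

    map_name: str
    mean: float
    sd: float
    n_voxels: int
    volume_mm3: float


@dataclass(frozen=True)
class VolumeReport:
    left_mm3: float
    right_mm3: float
    mean_mm3: float
    normalized_pct: float


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector u onto unit vector v."""
    c = float(np.dot(u, v))
    axis = np.cross(u, v)
    s = float(np.linalg.norm(axis))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any axis orthogonal to u
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        k = perp
    else:
        k = axis / s
    angle = np.arctan2(s, c) if s >= 1e-12 else np.pi
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * kx + (1 - np.cos(angle)) * kx @ kx


def acpc_transform(ac: np.ndarray, pc: np.ndarray) -> RigidTransform:
    """Rigid transform placing the AC-PC midpoint at the origin with the
    AC-to-PC direction along the -y world axis."""
    ac = np.asarray(ac, dtype=float)
    pc = np.asarray(pc, dtype=float)
    d = pc - ac
    n = np.linalg.norm(d)
    if n < 1e-9:
        raise ValueError("AC and PC landmarks coincide")
    rot = _rotation_between(d / n, np.array([0.0, -1.0, 0.0]))
    mid = (ac + pc) / 2.0
    return RigidTransform(rot, -rot @ mid)


def resample(
    volume: np.ndarray,
    affine: np.ndarray,
    transform: RigidTransform,
    interpolation: str = "trilinear",
) -> np.ndarray:
    """Resample a volume under a world-space rigid transform, on its own grid.

    The output satisfies ``out(x_world) = in(T^-1 x_world)``; binary masks
    should use nearest-neighbour, maps trilinear.
    """
    if interpolation not in ("nearest", "trilinear"):
        raise ValueError("interpolation must be 'nearest' or 'trilinear'")
    order = 0 if interpolation == "nearest" else 1
    # voxel-space mapping: out_vox -> A^-1 T^-1 A out_vox
    vox = np.linalg.inv(affine) @ transform.inverse().matrix() @ affine
    was_bool = volume.dtype == bool
    out = ndimage.affine_transform(
        volume.astype(np.float64),
        vox[:3, :3],
        offset=vox[:3, 3],
        order=order,
        mode="constant",
        cval=0.0,
    )
    return out > 0.5 if was_bool else out


def roi_stats(
    map_volume: np.ndarray,
    mask: np.ndarray,
    voxel_size: float,
    map_name: str = "",
    ddof: int = 0,
) -> RoiStats:
    """Mean and SD (population by default) of a map within a mask."""
    if not mask.any():
        raise ValueError("empty ROI mask")
    vals = map_volume[mask]
    n = int(mask.sum())
    return RoiStats(
        map_name=map_name,
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=ddof)),
        n_voxels=n,
        volume_mm3=n * voxel_size ** 3,
    )


def brain_mask_from_probs(
    tissue_probs: dict[str, np.ndarray],
    threshold: float = 0.9,
    mode: str = "summed",
) -> np.ndarray:
    """Whole-brain mask from WM/GM/CSF probabilities.

    ``summed``: total WM+GM+CSF probability exceeds the threshold (default
    reading); ``union``: any single class exceeds it.
    """
    classes = ("wm", "gm", "csf")
    if mode == "summed":
        total = sum(tissue_probs[c] for c in classes)
        return total > threshold
    if mode == "union":
        out = np.zeros(next(iter(tissue_probs.values())).shape, dtype=bool)
        for c in classes:
            out |= tissue_probs[c] > threshold
        return out
    raise ValueError("mode must be 'summed' or 'union'")


def habenula_volumes(
    left_mask: np.ndarray,
    right_mask: np.ndarray,
    tissue_probs: dict[str, np.ndarray],
    voxel_size: float,
    threshold: float = 0.9,
    mode: str = "summed",
) -> VolumeReport:
    """Left/right/mean habenula volumes and the brain-normalised volume.

    The normalising brain mask is defined from the WM/GM/CSF probabilities
    (see :func:`brain_mask_from_probs`); the normalised volume is
    ``100 * (left + right) / brain`` in percent.
    """
    if (left_mask & right_mask).any():
        raise ValueError("left and right habenula masks overlap")
    vv = voxel_size ** 3
    brain = brain_mask_from_probs(tissue_probs, threshold=threshold, mode=mode)
    brain_vol = float(brain.sum()) * vv
    if brain_vol == 0:
        raise ValueError("empty brain mask")
    left = float(left_mask.sum()) * vv
    right = float(right_mask.sum()) * vv
    return VolumeReport(
        left_mm3=left,
        right_mm3=right,
        mean_mm3=(left + right) / 2.0,
        normalized_pct=100.0 * (left + right) / brain_vol,
    )
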