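"""Digital habenula phantoms and forward simulation of a multi-echo FLASH protocol.

The phantom is a labelled geometric model of the epithalamic neighbourhood:
a white-matter shell enclosing two grey-matter thalamic blocks separated by
a cerebrospinal-fluid slab (the third ventricle), with two small ellipsoidal
habenulae abutting the ventricle.  Each tissue class carries ground-truth
quantitative parameters (R1, R2*, PD, MTsat) so that every estimation stage
downstream can be validated against known truth.

The forward model is the steady-state spoiled gradient-echo (Ernst) signal
with mono-exponential decay over echo time.  Magnetisation-transfer weighting
is modelled as a fractional saturation of longitudinal magnetisation applied
once per TR; the realised saturation depends on the local transmit field
through the same empirical linear law that the MTsat estimator inverts, so
that the estimator chain is consistent with the generative model.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "TissueClassParams",
    "PhantomSpec",
    "FlashWeighting",
    "MtPulse",
    "AcquisitionProtocol",
    "SubjectTruth",
    "CalibrationPair",
    "EchoVolumeSet",
    "default_tissue_params",
    "default_protocol",
    "build_template",
    "sample_subject",
    "simulate_flash",
    "add_noise",
    "write_subject",
    "read_subject",
]

TISSUE_NAMES = ("wm", "gm", "csf", "habenula")
LABEL_BG, LABEL_WM, LABEL_GM, LABEL_CSF, LABEL_HAB = 0, 1, 2, 3, 4
LABEL_OF = {"wm": LABEL_WM, "gm": LABEL_GM, "csf": LABEL_CSF, "habenula": LABEL_HAB}

#: amplitude (arbitrary units) assigned to a tissue of 100 p.u. water content
AMPLITUDE_GAIN = 10.0

#: slope of the empirical linear dependence of the apparent MT saturation on
#: the transmit-field fraction; the estimator applies the inverse correction
MTSAT_B1_SLOPE = 0.4


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueClassParams:
    """Ground-truth quantitative parameters of one tissue class.

    Means are tissue-typical values; standard deviations describe
    between-subject variability of the tissue mean, not voxel noise.
    """

    name: str
    r1_mean: float      # 1/s
    r1_sd: float
    r2s_mean: float     # 1/s
    r2s_sd: float
    pd_mean: float      # percent units (water content)
    pd_sd: float
    mtsat_mean: float   # percent units
    mtsat_sd: float

    def __post_init__(self) -> None:
        if self.name not in TISSUE_NAMES:
            raise ValueError(f"unknown tissue class {self.name!r}")
        if self.r1_mean <= 0 or self.r2s_mean <= 0 or self.pd_mean <= 0:
            raise ValueError(f"{self.name}: R1, R2* and PD means must be > 0")
        if self.mtsat_mean < 0:
            raise ValueError(f"{self.name}: MTsat mean must be >= 0")
        if self.pd_mean > 100.0:
            raise ValueError(f"{self.name}: PD mean must be <= 100 p.u.")
        for sd in (self.r1_sd, self.r2s_sd, self.pd_sd, self.mtsat_sd):
            if sd < 0:
                raise ValueError(f"{self.name}: SDs must be >= 0")


def default_tissue_params() -> dict[str, TissueClassParams]:
    """Default tissue table.

    The habenula entries are the calibration point of the whole pipeline:
    cohort means and between-subject SDs of R1, R2*, PD and MTsat.  WM, GM
    and CSF use typical 3 T literature values; WM PD of 69 p.u. doubles as
    the proton-density calibration reference.
    """
    return {
        "wm": TissueClassParams("wm", 1.05, 0.04, 21.0, 1.0, 69.0, 1.5, 2.00, 0.10),
        "gm": TissueClassParams("gm", 0.70, 0.03, 16.0, 1.0, 83.0, 1.5, 0.90, 0.08),
        "csf": TissueClassParams("csf", 0.25, 0.02, 1.5, 0.3, 100.0, 0.0, 0.0, 0.0),
        "habenula": TissueClassParams(
            "habenula", 0.86, 0.03, 19.11, 1.87, 76.21, 1.52, 1.05, 0.08
        ),
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Configuration of the synthetic cohort."""

    grid_dims: tuple[int, int, int] = (48, 64, 48)
    voxel_size: float = 0.8                 # mm, isotropic
    cohort_size: int = 26
    habenula_volume_mean: float = 19.26     # mm^3, per-side mean
    habenula_volume_sd: float = 2.03        # mm^3, between-subject SD
    tissue_params: dict[str, TissueClassParams] = field(
        default_factory=default_tissue_params
    )
    deformation_amplitude: float = 1.2      # mm, max displacement of the warp
    misalignment_sd: float = 0.4            # mm, residual registration error
    noise_sigma: float | None = None        # signal units; overrides target_snr
    target_snr: float = 100.0               # mean brain signal / noise SD
    noise_model: str = "rician"             # "rician" | "gaussian"
    master_seed: int = 1

    def __post_init__(self) -> None:
        if len(self.grid_dims) != 3 or any(d < 16 for d in self.grid_dims):
            raise ValueError("grid_dims must be three axes, each >= 16")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be >= 1")
        if self.habenula_volume_mean <= 0:
            raise ValueError("habenula_volume_mean must be > 0")
        if self.habenula_volume_sd < 0:
            raise ValueError("habenula_volume_sd must be >= 0")
        if self.noise_sigma is not None and self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_model not in ("rician", "gaussian"):
            raise ValueError("noise_model must be 'rician' or 'gaussian'")
        missing = set(TISSUE_NAMES) - set(self.tissue_params)
        if missing:
            raise ValueError(f"tissue_params missing classes: {sorted(missing)}")

    @property
    def voxel_volume(self) -> float:
        return self.voxel_size ** 3

    @property
    def affine(self) -> np.ndarray:
        """Voxel-to-world affine with the grid centre at the world origin."""
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        aff[:3, 3] = -self.voxel_size * (np.asarray(self.grid_dims) - 1) / 2.0
        return aff


@dataclass(frozen=True)
class FlashWeighting:
    """One spoiled multi-echo FLASH acquisition."""

    name: str
    flip_angle_deg: float
    tr_ms: float
    te_ms: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 0.0 < self.flip_angle_deg < 90.0:
            raise ValueError(f"{self.name}: flip angle must be in (0, 90) degrees")
        te = np.asarray(self.te_ms, dtype=float)
        if te.size < 1 or np.any(np.diff(te) <= 0):
            raise ValueError(f"{self.name}: echo times must be strictly increasing")
        if np.any(te >= self.tr_ms):
            raise ValueError(f"{self.name}: all echo times must be < TR")

    @property
    def flip_angle_rad(self) -> float:
        return math.radians(self.flip_angle_deg)

    @property
    def tr_s(self) -> float:
        return self.tr_ms / 1000.0

    @property
    def te_s(self) -> np.ndarray:
        return np.asarray(self.te_ms, dtype=float) / 1000.0


@dataclass(frozen=True)
class MtPulse:
    """Metadata of the off-resonance MT preparation pulse (not simulated
    mechanistically; carried for provenance)."""

    duration_ms: float = 4.0
    offset_khz: float = 2.0
    flip_angle_deg: float = 220.0


@dataclass(frozen=True)
class AcquisitionProtocol:
    weightings: dict[str, FlashWeighting]
    mt_pulse: MtPulse = field(default_factory=MtPulse)

    def __post_init__(self) -> None:
        for key, w in self.weightings.items():
            if key != w.name:
                raise ValueError(f"weighting key {key!r} does not match name {w.name!r}")

    def __getitem__(self, name: str) -> FlashWeighting:
        return self.weightings[name]

    def __contains__(self, name: str) -> bool:
        return name in self.weightings


def default_protocol() -> AcquisitionProtocol:
    """Three-weighting multi-echo FLASH protocol.

    T1w at 21 deg, PDw and MTw at 6 deg, common TR of 25.0 ms.  PDw and T1w
    acquire eight echoes, MTw six (the MT pulse occupies part of the TR).
    The echo grid starts at 2.30 ms with a 2.314 ms spacing so that the
    sixth echo falls on 13.87 ms.
    """
    te8 = tuple(round(2.30 + 2.314 * n, 4) for n in range(8))
    te6 = te8[:6]
    return AcquisitionProtocol(
        weightings={
            "T1w": FlashWeighting("T1w", 21.0, 25.0, te8),
            "PDw": FlashWeighting("PDw", 6.0, 25.0, te8),
            "MTw": FlashWeighting("MTw", 6.0, 25.0, te6),
        }
    )


@dataclass
class SubjectTruth:
    """Ground truth for one phantom subject.

    Displacement fields are stored in voxel units on the subject grid with
    the pull-back convention: ``subject(x) = template(x + warp_fwd(x))`` and
    ``template(y) = subject(y + warp_inv(y))`` (the latter is what group-space
    warping uses).  Fields have shape ``(3, *grid_dims)``.
    """

    labels: np.ndarray                      # uint8, 0=background
    tissue_probs: dict[str, np.ndarray]     # per class, values in [0, 1]
    r1: np.ndarray                          # 1/s
    r2s: np.ndarray                         # 1/s
    amplitude: np.ndarray                   # effective amplitude (a.u.)
    pd: np.ndarray                          # p.u.
    mtsat: np.ndarray                       # p.u.
    f_t: np.ndarray                         # transmit fraction, dimensionless
    receive: np.ndarray                     # receive sensitivity, dimensionless
    hab_left: np.ndarray                    # bool
    hab_right: np.ndarray                   # bool
    ac: np.ndarray                          # mm, world space
    pc: np.ndarray                          # mm, world space
    warp_fwd: np.ndarray                    # (3, *dims), voxel units
    warp_inv: np.ndarray                    # (3, *dims), voxel units
    affine: np.ndarray                      # 4x4 voxel-to-world
    meta: dict = field(default_factory=dict)

    @property
    def hab_both(self) -> np.ndarray:
        return self.hab_left | self.hab_right

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class CalibrationPair:
    """Low-resolution receive-calibration scans (array coil and body coil).

    Their voxelwise ratio estimates the net receive sensitivity of the
    array coil on a coarse grid.
    """

    array_vol: np.ndarray
    body_vol: np.ndarray
    affine: np.ndarray


@dataclass
class EchoVolumeSet:
    """Simulated weighted multi-echo stacks plus acquisition side-data."""

    stacks: dict[str, np.ndarray]           # name -> (n_echo, *dims)
    protocol: AcquisitionProtocol
    b1_map: np.ndarray                      # transmit fraction f_T
    calibration: CalibrationPair | None
    affine: np.ndarray
    brain_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name, stack in self.stacks.items():
            n_te = len(self.protocol[name].te_ms)
            if stack.shape[0] != n_te:
                raise ValueError(
                    f"{name}: {stack.shape[0]} echoes but protocol lists {n_te}"
                )


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _ellipsoid_distance(dims, center, semi) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, d) for d in dims)]
    return sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))


def _build_geometry(spec: PhantomSpec, hab_volume_mm3: float):
    """Rasterise the labelled geometry.

    Returns (labels, hab_left, hab_right, ac_world, pc_world).
    """
    dims = np.asarray(spec.grid_dims)
    c = (dims - 1) / 2.0

    brain_semi = (dims - 8) / 2.0
    if np.any(brain_semi < 4):
        raise ValueError("grid too small to contain the brain shell")
    labels = np.zeros(tuple(dims), dtype=np.uint8)
    brain = _ellipsoid_distance(tuple(dims), c, brain_semi) <= 1.0
    labels[brain] = LABEL_WM

    # central region spanned by the thalamic blocks and the ventricle slab
    vent_hw = 1.5                           # voxels, slab half-width (x)
    y_ext = 0.19 * dims[1]
    z_ext = 0.21 * dims[2]
    gm_w = 10.0 * dims[0] / 48.0
    grids = np.ogrid[tuple(slice(0, d) for d in dims)]
    dx = grids[0] - c[0]
    in_yz = (np.abs(grids[1] - c[1]) <= y_ext) & (np.abs(grids[2] - c[2]) <= z_ext)
    gm_block = in_yz & (np.abs(dx) > vent_hw) & (np.abs(dx) <= vent_hw + gm_w) & brain
    vent = in_yz & (np.abs(dx) <= vent_hw) & brain
    if not gm_block.any():
        raise ValueError("grid too small to contain the thalamic grey-matter blocks")
    if not vent.any():
        raise ValueError("grid too small to contain the third-ventricle slab")
    labels[gm_block] = LABEL_GM
    labels[vent] = LABEL_CSF

    # habenulae: ellipsoids abutting the ventricle, posterior and dorsal
    n_vox = int(round(hab_volume_mm3 / spec.voxel_volume))
    if n_vox < 1:
        raise ValueError("habenula volume below one voxel")
    semi = np.array([1.6, 2.8, 2.0])
    semi = semi * (n_vox / (4.0 / 3.0 * np.pi * np.prod(semi))) ** (1.0 / 3.0)
    hab_masks = []
    for side in (-1.0, +1.0):
        center = np.array(
            [c[0] + side * (vent_hw + semi[0]), c[1] - 0.09 * dims[1], c[2] + 0.08 * dims[2]]
        )
        dist = _ellipsoid_distance(tuple(dims), center, semi)
        # candidates restricted to the grey-matter side of the slab
        side_ok = (dx * side) > vent_hw
        dist = np.where(side_ok, dist, np.inf)
        flat = np.argsort(dist, axis=None, kind="stable")[:n_vox]
        mask = np.zeros(tuple(dims), dtype=bool)
        mask.flat[flat] = True
        if not np.all(labels[mask] == LABEL_GM):
            raise ValueError(
                "grid too small: habenula does not fit inside the grey-matter block"
            )
        hab_masks.append(mask)
    hab_left, hab_right = hab_masks
    labels[hab_left | hab_right] = LABEL_HAB

    aff = spec.affine
    ac_vox = np.array([c[0], c[1] + 0.19 * dims[1], c[2]])
    pc_vox = np.array([c[0], c[1] - 0.19 * dims[1], c[2]])
    ac = (aff @ np.append(ac_vox, 1.0))[:3]
    pc = (aff @ np.append(pc_vox, 1.0))[:3]
    return labels, hab_left, hab_right, ac, pc


def _volumes_from_labels(labels: np.ndarray, values: dict[str, dict[str, float]]):
    """Fill parameter volumes from per-tissue scalar values."""
    out = {}
    for param in ("r1", "r2s", "pd", "mtsat"):
        vol = np.zeros(labels.shape, dtype=np.float64)
        for name in TISSUE_NAMES:
            vol[labels == LABEL_OF[name]] = values[name][param]
        out[param] = vol
    out["amplitude"] = AMPLITUDE_GAIN * out["pd"]
    return out


def _one_hot_probs(labels: np.ndarray) -> dict[str, np.ndarray]:
    return {
        name: (labels == LABEL_OF[name]).astype(np.float64) for name in TISSUE_NAMES
    }


def build_template(spec: PhantomSpec) -> SubjectTruth:
    """Deterministic template phantom: tissue means, unit fields, identity warp."""
    labels, hab_l, hab_r, ac, pc = _build_geometry(spec, spec.habenula_volume_mean)
    values = {
        name: {
            "r1": tp.r1_mean,
            "r2s": tp.r2s_mean,
            "pd": tp.pd_mean,
            "mtsat": tp.mtsat_mean,
        }
        for name, tp in spec.tissue_params.items()
    }
    vols = _volumes_from_labels(labels, values)
    dims = tuple(spec.grid_dims)
    zero_warp = np.zeros((3,) + dims, dtype=np.float64)
    return SubjectTruth(
        labels=labels,
        tissue_probs=_one_hot_probs(labels),
        r1=vols["r1"],
        r2s=vols["r2s"],
        amplitude=vols["amplitude"],
        pd=vols["pd"],
        mtsat=vols["mtsat"],
        f_t=np.ones(dims),
        receive=np.ones(dims),
        hab_left=hab_l,
        hab_right=hab_r,
        ac=ac,
        pc=pc,
        warp_fwd=zero_warp,
        warp_inv=zero_warp.copy(),
        affine=spec.affine,
        meta={
            "subject": 0,
            "drawn_volume_mm3": spec.habenula_volume_mean,
            "tissue_values": values,
        },
    )


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

def _smooth_random_field(rng, dims, n_components=3, smooth_vox=4.0):
    """Smooth zero-boundary random field(s), unit-free, roughly unit scale."""
    coarse_dims = [max(4, d // 12) for d in dims]
    field_ = rng.normal(size=(n_components, *coarse_dims))
    zoom = [d / cd for d, cd in zip(dims, coarse_dims)]
    up = np.stack(
        [ndimage.zoom(f, zoom, order=3, mode="nearest", grid_mode=True) for f in field_]
    )
    up = up[:, : dims[0], : dims[1], : dims[2]]
    up = np.stack([ndimage.gaussian_filter(f, smooth_vox) for f in up])
    window = 1.0
    for ax, d in enumerate(dims):
        w = np.sin(np.pi * np.arange(d) / (d - 1)) ** 2
        shape = [1, 1, 1]
        shape[ax] = d
        window = window * w.reshape(shape)
    return up * window[None]


def _sample_displacement(u: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Interpolate a displacement field (3, *dims) at voxel coords (3, ...)."""
    return np.stack(
        [
            ndimage.map_coordinates(u[k], coords, order=1, mode="nearest")
            for k in range(3)
        ]
    )


def _invert_displacement(u: np.ndarray, n_iter: int = 30) -> np.ndarray:
    """Fixed-point inverse of y -> y + u(y)."""
    dims = u.shape[1:]
    grid = np.stack(
        np.meshgrid(*[np.arange(d, dtype=float) for d in dims], indexing="ij")
    )
    v = -u.copy()
    for _ in range(n_iter):
        v = -_sample_displacement(u, grid + v)
    return v


def _roundtrip_error(u: np.ndarray, u_inv: np.ndarray, mask: np.ndarray) -> float:
    dims = u.shape[1:]
    grid = np.stack(
        np.meshgrid(*[np.arange(d, dtype=float) for d in dims], indexing="ij")
    )
    resid = u_inv + _sample_displacement(u, grid + u_inv)
    err = np.sqrt((resid ** 2).sum(axis=0))
    return float(err[mask].max()) if mask.any() else float(err.max())


def _warp_nearest(vol: np.ndarray, u: np.ndarray) -> np.ndarray:
    dims = vol.shape
    grid = np.stack(
        np.meshgrid(*[np.arange(d, dtype=float) for d in dims], indexing="ij")
    )
    coords = grid + u
    order = 0
    return ndimage.map_coordinates(vol.astype(np.float64), coords, order=order,
                                   mode="constant", cval=0.0)


def _coil_field(rng, dims, lo: float, hi: float) -> np.ndarray:
    """Random low-order (linear + gentle quadratic) multiplicative coil
    field spanning exactly [lo, hi] over the grid.

    Coil sensitivities vary over centimetres, so across a small central
    field of view they are close to a linear gradient with mild curvature;
    this also keeps them resolvable by the 8 mm calibration scans.
    """
    axes = [np.linspace(-1.0, 1.0, d) for d in dims]
    x = np.stack(np.meshgrid(*axes, indexing="ij"))
    g = rng.normal(size=3)
    q = rng.normal(size=(3, 3)) * 0.4
    q = (q + q.T) / 2.0
    raw = np.einsum("i,i...->...", g, x) + np.einsum("i...,ij,j...->...", x, q, x)
    lo_r, hi_r = float(raw.min()), float(raw.max())
    if hi_r - lo_r < 1e-12:
        return np.full(dims, (lo + hi) / 2.0)
    return lo + (raw - lo_r) * (hi - lo) / (hi_r - lo_r)


def sample_subject(
    template: SubjectTruth, spec: PhantomSpec, subject_index: int, max_retries: int = 5
) -> SubjectTruth:
    """Draw one cohort subject, reproducible from (master_seed, subject_index).

    The subject is the template with (a) its habenulae rescaled to a drawn
    volume, (b) per-tissue parameter values jittered by the between-subject
    SDs, (c) a smooth random invertible deformation, and (d) smooth transmit
    and receive fields.
    """
    if not 1 <= subject_index <= spec.cohort_size:
        raise ValueError(
            f"subject_index {subject_index} outside [1, {spec.cohort_size}]"
        )
    rng = np.random.default_rng([spec.master_seed, subject_index])

    vol_draw = float(
        rng.normal(spec.habenula_volume_mean, spec.habenula_volume_sd)
    )
    vol_draw = max(vol_draw, 0.25 * spec.habenula_volume_mean)
    values = {}
    for name in TISSUE_NAMES:
        tp = spec.tissue_params[name]
        values[name] = {
            "r1": max(float(rng.normal(tp.r1_mean, tp.r1_sd)), 1e-3),
            "r2s": max(float(rng.normal(tp.r2s_mean, tp.r2s_sd)), 1e-3),
            "pd": float(np.clip(rng.normal(tp.pd_mean, tp.pd_sd), 1.0, 100.0)),
            "mtsat": max(float(rng.normal(tp.mtsat_mean, tp.mtsat_sd)), 0.0),
        }

    labels_t, hab_l_t, hab_r_t, ac, pc = _build_geometry(spec, vol_draw)
    dims = tuple(spec.grid_dims)
    amp_vox = spec.deformation_amplitude / spec.voxel_size

    if amp_vox > 0:
        brain_t = labels_t > 0
        for attempt in range(max_retries):
            u = _smooth_random_field(rng, dims)
            peak = np.sqrt((u ** 2).sum(axis=0)).max()
            if peak > 0:
                u *= amp_vox / peak
            u_inv = _invert_displacement(u)
            if _roundtrip_error(u, u_inv, brain_t) < 0.1:
                break
        else:
            raise RuntimeError(
                f"subject {subject_index}: no invertible deformation after "
                f"{max_retries} attempts"
            )
        labels = _warp_nearest(labels_t, u).astype(np.uint8)
        hab_l = _warp_nearest(hab_l_t, u) > 0.5
        hab_r = _warp_nearest(hab_r_t, u) > 0.5
        inv_affine = np.linalg.inv(spec.affine)
        out = []
        for p_world in (ac, pc):
            p_vox = (inv_affine @ np.append(p_world, 1.0))[:3]
            shift = _sample_displacement(u_inv, p_vox.reshape(3, 1)).ravel()
            out.append((spec.affine @ np.append(p_vox + shift, 1.0))[:3])
        ac, pc = out
    else:
        u = np.zeros((3,) + dims)
        u_inv = np.zeros((3,) + dims)
        labels, hab_l, hab_r = labels_t, hab_l_t, hab_r_t

    vols = _volumes_from_labels(labels, values)
    f_t = _coil_field(rng, dims, 0.9, 1.1)
    receive = _coil_field(rng, dims, 0.7, 1.3)

    return SubjectTruth(
        labels=labels,
        tissue_probs=_one_hot_probs(labels),
        r1=vols["r1"],
        r2s=vols["r2s"],
        amplitude=vols["amplitude"],
        pd=vols["pd"],
        mtsat=vols["mtsat"],
        f_t=f_t,
        receive=receive,
        hab_left=hab_l,
        hab_right=hab_r,
        ac=np.asarray(ac, dtype=float),
        pc=np.asarray(pc, dtype=float),
        warp_fwd=u,
        warp_inv=u_inv,
        affine=spec.affine,
        meta={
            "subject": subject_index,
            "drawn_volume_mm3": vol_draw,
            "tissue_values": values,
        },
    )


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

def flash_signal(amplitude, r1, alpha_rad, tr_s, f_t=1.0, saturation=0.0,
                 r2s=0.0, te_s=0.0):
    """Steady-state spoiled gradient-echo signal.

    ``S = A sin(a) (1-d) (1-E1) / (1 - (1-d) cos(a) E1) * exp(-TE R2*)``
    with ``a = f_T * alpha`` and ``E1 = exp(-TR R1)``.  ``saturation`` is the
    per-TR fractional loss of longitudinal magnetisation (MT weighting).
    """
    a = f_t * alpha_rad
    e1 = np.exp(-tr_s * r1)
    keep = 1.0 - saturation
    return (
        amplitude
        * np.sin(a)
        * keep
        * (1.0 - e1)
        / (1.0 - keep * np.cos(a) * e1)
        * np.exp(-np.asarray(te_s) * r2s)
    )


def simulate_flash(
    subject: SubjectTruth, protocol: AcquisitionProtocol
) -> EchoVolumeSet:
    """Forward-simulate the weighted multi-echo stacks, noise-free.

    Also emits the transmit-field map and the coarse receive-calibration
    pair (the true receive field sampled at 8 mm plus a unit body-coil
    companion; noise is added separately).
    """
    brain = subject.brain_mask
    for pname in ("r1", "r2s", "amplitude"):
        vol = getattr(subject, pname)
        bad = ~np.isfinite(vol[brain])
        if bad.any():
            idx = np.argwhere(brain)[np.nonzero(bad)[0][0]]
            raise ValueError(f"non-finite {pname} at voxel {tuple(idx)}")
        if pname in ("r1", "amplitude") and np.any(vol[brain] <= 0):
            idx = np.argwhere(brain)[np.nonzero(vol[brain] <= 0)[0][0]]
            raise ValueError(f"non-positive {pname} at voxel {tuple(idx)}")

    delta = subject.mtsat / 100.0
    # realised saturation varies with the local transmit field following the
    # empirical law the estimator's correction inverts
    sat_mtw = delta * (1.0 - MTSAT_B1_SLOPE * subject.f_t) / (1.0 - MTSAT_B1_SLOPE)

    stacks = {}
    for name, w in protocol.weightings.items():
        sat = sat_mtw if name == "MTw" else 0.0
        base = flash_signal(
            subject.amplitude, subject.r1, w.flip_angle_rad, w.tr_s,
            f_t=subject.f_t, saturation=sat,
        )
        base = base * subject.receive
        stack = np.zeros((len(w.te_ms),) + subject.labels.shape)
        decay_rate = subject.r2s
        for i, te in enumerate(w.te_s):
            vol = base * np.exp(-te * decay_rate)
            vol[~brain] = 0.0
            stack[i] = vol
        stacks[name] = stack

    calib = _sample_calibration(subject)
    return EchoVolumeSet(
        stacks=stacks,
        protocol=protocol,
        b1_map=subject.f_t.copy(),
        calibration=calib,
        affine=subject.affine.copy(),
        brain_mask=brain.copy(),
    )


CALIB_RESOLUTION_MM = 8.0


def _sample_calibration(subject: SubjectTruth) -> CalibrationPair:
    dims = np.asarray(subject.labels.shape)
    voxel = float(subject.affine[0, 0])
    factor = max(int(round(CALIB_RESOLUTION_MM / voxel)), 1)
    coarse_dims = np.maximum(-(-dims // factor), 2)
    centers = [
        (np.arange(cd) + 0.5) * (d / cd) - 0.5
        for cd, d in zip(coarse_dims, dims)
    ]
    coords = np.stack(np.meshgrid(*centers, indexing="ij"))
    array_vol = ndimage.map_coordinates(
        subject.receive, coords, order=1, mode="nearest"
    )
    body_vol = np.ones_like(array_vol)
    scale = np.diag([d / cd for d, cd in zip(dims, coarse_dims)])
    caffine = np.eye(4)
    caffine[:3, :3] = subject.affine[:3, :3] @ scale
    shift = (np.asarray([d / cd for d, cd in zip(dims, coarse_dims)]) - 1.0) / 2.0
    caffine[:3, 3] = (subject.affine @ np.append(shift, 1.0))[:3]
    return CalibrationPair(array_vol=array_vol, body_vol=body_vol, affine=caffine)


def add_noise(volumes: EchoVolumeSet, spec: PhantomSpec, seed: int) -> EchoVolumeSet:
    """Add magnitude (Rician) noise to every echo volume, reproducibly.

    The noise SD is ``spec.noise_sigma`` if given, otherwise the mean
    noise-free brain signal of the first PDw echo divided by
    ``spec.target_snr``.  The calibration pair receives small Gaussian
    noise (0.5% of its mean).  With zero noise the input is returned
    unchanged (same object contents, new container).
    """
    if spec.noise_sigma is not None:
        sigma = spec.noise_sigma
    else:
        ref = volumes.stacks["PDw"][0]
        mask = volumes.brain_mask
        if mask is None:
            mask = ref > 0
        sigma = float(ref[mask].mean()) / spec.target_snr
    if sigma == 0:
        return EchoVolumeSet(
            stacks={k: v.copy() for k, v in volumes.stacks.items()},
            protocol=volumes.protocol,
            b1_map=volumes.b1_map.copy(),
            calibration=volumes.calibration,
            affine=volumes.affine.copy(),
            brain_mask=None if volumes.brain_mask is None else volumes.brain_mask.copy(),
        )
    rng = np.random.default_rng(seed)
    stacks = {}
    for name in volumes.stacks:
        s = volumes.stacks[name]
        if spec.noise_model == "rician":
            noisy = np.abs(
                s + rng.normal(0, sigma, s.shape) + 1j * rng.normal(0, sigma, s.shape)
            )
        else:
            noisy = s + rng.normal(0, sigma, s.shape)
        stacks[name] = noisy
    calib = volumes.calibration
    if calib is not None:
        rel = 0.005
        calib = CalibrationPair(
            array_vol=calib.array_vol
            + rng.normal(0, rel * abs(float(calib.array_vol.mean())), calib.array_vol.shape),
            body_vol=calib.body_vol
            + rng.normal(0, rel * abs(float(calib.body_vol.mean())), calib.body_vol.shape),
            affine=calib.affine.copy(),
        )
    return EchoVolumeSet(
        stacks=stacks,
        protocol=volumes.protocol,
        b1_map=volumes.b1_map.copy(),
        calibration=calib,
        affine=volumes.affine.copy(),
        brain_mask=None if volumes.brain_mask is None else volumes.brain_mask.copy(),
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _save_nifti(path: Path, data: np.ndarray, affine: np.ndarray) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_subject(
    subject: SubjectTruth, volumes: EchoVolumeSet, directory: str | Path
) -> dict:
    """Write one subject to disk: weighted stacks with JSON sidecars, the
    transmit map, the calibration pair and a ``truth/`` subtree; returns the
    manifest (also written as ``manifest.json``)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    truth_dir = directory / "truth"
    truth_dir.mkdir(exist_ok=True)
    entries: list[dict] = []

    def record(path: Path, role: str) -> None:
        entries.append(
            {"path": str(path.relative_to(directory)), "role": role, "sha256": _sha256(path)}
        )

    for name, stack in volumes.stacks.items():
        w = volumes.protocol[name]
        p = directory / f"{name}.nii.gz"
        _save_nifti(p, np.moveaxis(stack, 0, -1), volumes.affine)
        record(p, f"echo-stack:{name}")
        sidecar = {
            "Weighting": name,
            "FlipAngle": w.flip_angle_deg,
            "RepetitionTime": w.tr_ms,
            "EchoTimes": list(w.te_ms),
        }
        if name == "MTw":
            mt = volumes.protocol.mt_pulse
            sidecar["MTPulse"] = {
                "DurationMs": mt.duration_ms,
                "OffsetKHz": mt.offset_khz,
                "FlipAngle": mt.flip_angle_deg,
            }
        sp = directory / f"{name}.json"
        sp.write_text(json.dumps(sidecar, indent=1))
        record(sp, f"sidecar:{name}")

    p = directory / "B1map.nii.gz"
    _save_nifti(p, volumes.b1_map, volumes.affine)
    record(p, "b1-map")
    if volumes.calibration is not None:
        for tag, vol in (
            ("calib_array", volumes.calibration.array_vol),
            ("calib_body", volumes.calibration.body_vol),
        ):
            p = directory / f"{tag}.nii.gz"
            _save_nifti(p, vol, volumes.calibration.affine)
            record(p, f"receive-calibration:{tag}")

    truth_vols = {
        "labels": subject.labels,
        "R1": subject.r1,
        "R2s": subject.r2s,
        "A": subject.amplitude,
        "PD": subject.pd,
        "MTsat": subject.mtsat,
        "f_T": subject.f_t,
        "receive": subject.receive,
        "hab_left": subject.hab_left,
        "hab_right": subject.hab_right,
    }
    for name, prob in subject.tissue_probs.items():
        truth_vols[f"prob_{name}"] = prob
    for name, vol in truth_vols.items():
        p = truth_dir / f"{name}.nii.gz"
        _save_nifti(p, vol, subject.affine)
        record(p, f"truth:{name}")
    for name, warp in (("warp_fwd", subject.warp_fwd), ("warp_inv", subject.warp_inv)):
        p = truth_dir / f"{name}.nii.gz"
        _save_nifti(p, np.moveaxis(warp, 0, -1), subject.affine)
        record(p, f"truth:{name}")
    meta = {
        "ac_mm": subject.ac.tolist(),
        "pc_mm": subject.pc.tolist(),
        **{
            k: v
            for k, v in subject.meta.items()
        },
    }
    p = truth_dir / "meta.json"
    p.write_text(json.dumps(meta, indent=1))
    record(p, "truth:meta")

    manifest = {"n_files": len(entries), "files": entries}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_subject(directory: str | Path) -> tuple[SubjectTruth, EchoVolumeSet]:
    """Load a subject written by :func:`write_subject`."""
    directory = Path(directory)

    def load(p: Path) -> tuple[np.ndarray, np.ndarray]:
        img = nib.load(str(p))
        return np.asarray(img.get_fdata(), dtype=np.float64), np.asarray(img.affine)

    stacks = {}
    weightings = {}
    affine = None
    for name in ("T1w", "PDw", "MTw"):
        vp, sp = directory / f"{name}.nii.gz", directory / f"{name}.json"
        if not vp.exists():
            continue
        data, affine = load(vp)
        stacks[name] = np.moveaxis(data, -1, 0)
        sc = json.loads(sp.read_text())
        weightings[name] = FlashWeighting(
            name, float(sc["FlipAngle"]), float(sc["RepetitionTime"]),
            tuple(float(t) for t in sc["EchoTimes"]),
        )
    if not stacks:
        raise FileNotFoundError(f"no weighted stacks found in {directory}")
    protocol = AcquisitionProtocol(weightings=weightings)
    b1_map, _ = load(directory / "B1map.nii.gz")

    calibration = None
    ap, bp = directory / "calib_array.nii.gz", directory / "calib_body.nii.gz"
    if ap.exists() and bp.exists():
        arr, caff = load(ap)
        body, _ = load(bp)
        calibration = CalibrationPair(arr, body, caff)

    t = directory / "truth"
    labels, _ = load(t / "labels.nii.gz")
    labels = labels.astype(np.uint8)
    probs = {name: load(t / f"prob_{name}.nii.gz")[0] for name in TISSUE_NAMES}
    meta = json.loads((t / "meta.json").read_text())
    subject = SubjectTruth(
        labels=labels,
        tissue_probs=probs,
        r1=load(t / "R1.nii.gz")[0],
        r2s=load(t / "R2s.nii.gz")[0],
        amplitude=load(t / "A.nii.gz")[0],
        pd=load(t / "PD.nii.gz")[0],
        mtsat=load(t / "MTsat.nii.gz")[0],
        f_t=load(t / "f_T.nii.gz")[0],
        receive=load(t / "receive.nii.gz")[0],
        hab_left=load(t / "hab_left.nii.gz")[0] > 0.5,
        hab_right=load(t / "hab_right.nii.gz")[0] > 0.5,
        ac=np.asarray(meta["ac_mm"], dtype=float),
        pc=np.asarray(meta["pc_mm"], dtype=float),
        warp_fwd=np.moveaxis(load(t / "warp_fwd.nii.gz")[0], -1, 0),
        warp_inv=np.moveaxis(load(t / "warp_inv.nii.gz")[0], -1, 0),
        affine=affine,
        meta={k: v for k, v in meta.items() if k not in ("ac_mm", "pc_mm")},
    )
    volumes = EchoVolumeSet(
        stacks=stacks,
        protocol=protocol,
        b1_map=b1_map,
        calibration=calibration,
        affine=affine,
        brain_mask=labels > 0,
    )
    return subject, volumes
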