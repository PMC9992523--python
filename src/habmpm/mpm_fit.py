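"""Quantitative map estimation from weighted multi-echo FLASH stacks.

The chain mirrors the standard multi-parameter-mapping recipe:

1. joint log-linear fit of all echo trains with one shared R2* decay and
   one TE=0 intercept per weighting (the ESTATICS model);
2. dual-flip-angle rational approximation for R1 and the effective
   amplitude A from the T1w and PDw intercepts, with transmit-field (B1+)
   corrected flip angles;
3. proton density from A divided by an upsampled receive-sensitivity
   estimate, globally calibrated so that mean white-matter PD is 69 p.u.;
4. MT saturation from the MTw intercept, A and R1, with an empirical
   transmit-bias correction.

All equations take TR/TE in seconds internally; public metadata carries
milliseconds, as scanner sidecars do.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .phantom import AcquisitionProtocol, EchoVolumeSet, CalibrationPair, read_subject

__all__ = [
    "EstaticsResult",
    "QuantMaps",
    "estatics_fit",
    "compute_r1",
    "compute_amplitude",
    "compute_pd",
    "compute_mtsat",
    "fit_maps",
    "run_mpm",
]

logger = logging.getLogger(__name__)

#: default white-matter proton-density calibration value, percent units
WM_PD_REFERENCE = 69.0

#: slope of the empirical MTsat transmit-bias correction
MTSAT_B1_SLOPE = 0.4


@dataclass
class EstaticsResult:
    """Joint-decay fit: per-weighting TE=0 intercepts and one shared R2*."""

    intercepts: dict[str, np.ndarray]   # signal units
    r2s: np.ndarray                     # 1/s
    residual_sum: np.ndarray            # sum of squared log-residuals
    mask: np.ndarray                    # voxels with a valid fit
    n_excluded: int = 0                 # non-positive-signal voxels dropped


@dataclass
class QuantMaps:
    """Estimated quantitative maps with a shared validity mask."""

    r1: np.ndarray                      # 1/s
    r2s: np.ndarray                     # 1/s
    pd: np.ndarray | None               # p.u.
    mtsat: np.ndarray | None            # p.u.
    mask: np.ndarray
    affine: np.ndarray
    provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, np.ndarray]:
        out = {"R1": self.r1, "R2s": self.r2s}
        if self.pd is not None:
            out["PD"] = self.pd
        if self.mtsat is not None:
            out["MTsat"] = self.mtsat
        return out


def estatics_fit(
    volumes: EchoVolumeSet, mask: np.ndarray | None = None
) -> EstaticsResult:
    """Ordinary least squares on ``ln S_w(TE) = ln S_w(0) - R2* TE`` jointly
    over all weightings with a single shared slope.

    Because every voxel shares the same design matrix, the fit is a single
    pinv-matrix product over all voxels.  Voxels with any non-positive
    signal are excluded from the valid mask.  R2* is clamped at zero.
    """
    names = list(volumes.stacks)
    n_w = len(names)
    te_all, rows = [], []
    for i, name in enumerate(names):
        w = volumes.protocol[name]
        if len(w.te_ms) < 2:
            raise ValueError(f"{name}: at least two echoes required")
        if len(set(w.te_ms)) < 2:
            raise ValueError(f"{name}: degenerate design, all echo times equal")
        for te in w.te_s:
            row = np.zeros(n_w + 1)
            row[i] = 1.0
            row[n_w] = -te
            rows.append(row)
            te_all.append(te)
    design = np.asarray(rows)

    dims = next(iter(volumes.stacks.values())).shape[1:]
    if mask is None:
        mask = volumes.brain_mask
    if mask is None:
        mask = np.ones(dims, dtype=bool)
    mask = mask.copy()

    signals = np.concatenate([volumes.stacks[n] for n in names], axis=0)
    flat = signals.reshape(signals.shape[0], -1)[:, mask.ravel()]
    positive = np.all(flat > 0, axis=0)
    n_excluded = int((~positive).sum())
    if n_excluded:
        logger.info("estatics_fit: excluded %d non-positive-signal voxels", n_excluded)
        idx = np.flatnonzero(mask.ravel())
        mask.ravel()[idx[~positive]] = False
        flat = flat[:, positive]

    log_s = np.log(flat)
    coef = np.linalg.pinv(design) @ log_s
    fitted = design @ coef
    resid = ((log_s - fitted) ** 2).sum(axis=0)

    r2s = np.zeros(dims)
    r2s[mask] = np.maximum(coef[n_w], 0.0)
    residual_sum = np.zeros(dims)
    residual_sum[mask] = resid
    intercepts = {}
    for i, name in enumerate(names):
        vol = np.zeros(dims)
        vol[mask] = np.exp(coef[i])
        intercepts[name] = vol
    return EstaticsResult(
        intercepts=intercepts, r2s=r2s, residual_sum=residual_sum,
        mask=mask, n_excluded=n_excluded,
    )


def _corrected_angles(protocol: AcquisitionProtocol, f_t, t1w="T1w", pdw="PDw"):
    a_t1 = f_t * protocol[t1w].flip_angle_rad
    a_pd = f_t * protocol[pdw].flip_angle_rad
    tr = protocol[t1w].tr_s
    if protocol[pdw].tr_s != tr:
        raise ValueError("rational approximation assumes a common TR")
    return a_t1, a_pd, tr


def compute_r1(
    s_t1: np.ndarray,
    s_pd: np.ndarray,
    protocol: AcquisitionProtocol,
    f_t: np.ndarray | float,
    mask: np.ndarray | None = None,
    denom_rtol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Dual-flip-angle rational approximation of R1 (1/s).

    ``R1 = 1/2 (S_T1 a_T1/TR - S_PD a_PD/TR) / (S_PD/a_PD - S_T1/a_T1)``
    with B1-corrected flip angles ``a_w = f_T alpha_w``.  Returns the map and
    the mask of valid voxels (finite, positive, non-degenerate denominator).
    """
    a_t1, a_pd, tr = _corrected_angles(protocol, f_t)
    if mask is None:
        mask = (s_t1 > 0) & (s_pd > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = s_t1 * a_t1 / tr - s_pd * a_pd / tr
        den = s_pd / a_pd - s_t1 / a_t1
        r1 = 0.5 * num / den
    scale = np.abs(s_pd / np.maximum(a_pd, 1e-12)) + np.abs(
        s_t1 / np.maximum(a_t1, 1e-12)
    )
    ok = mask & np.isfinite(r1) & (np.abs(den) > denom_rtol * scale) & (r1 > 0)
    r1 = np.where(ok, r1, 0.0)
    return r1, ok


def compute_amplitude(
    s_t1: np.ndarray,
    s_pd: np.ndarray,
    protocol: AcquisitionProtocol,
    f_t: np.ndarray | float,
    mask: np.ndarray | None = None,
    denom_rtol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Companion rational approximation of the effective amplitude A.

    ``A = S_PD S_T1 (TR a_T1/a_PD - TR a_PD/a_T1) /
    (S_T1 TR a_T1 - S_PD TR a_PD)``; A still carries the receive field,
    removed later by the proton-density calibration.
    """
    a_t1, a_pd, tr = _corrected_angles(protocol, f_t)
    if mask is None:
        mask = (s_t1 > 0) & (s_pd > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = s_pd * s_t1 * (tr * a_t1 / a_pd - tr * a_pd / a_t1)
        den = s_t1 * tr * a_t1 - s_pd * tr * a_pd
        amp = num / den
    scale = tr * (np.abs(s_t1 * a_t1) + np.abs(s_pd * a_pd))
    ok = mask & np.isfinite(amp) & (np.abs(den) > denom_rtol * scale) & (amp > 0)
    return np.where(ok, amp, 0.0), ok


def upsample_receive_field(
    calibration: CalibrationPair,
    target_shape: tuple[int, int, int],
    target_affine: np.ndarray,
) -> np.ndarray:
    """Ratio of the calibration pair, tricubically upsampled to the map grid
    and clamped to be positive."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = calibration.array_vol / calibration.body_vol
    ratio = np.where(np.isfinite(ratio), ratio, 1.0)
    # voxel coords of the target grid expressed in coarse-grid voxel coords
    xform = np.linalg.inv(calibration.affine) @ target_affine
    grid = np.stack(
        np.meshgrid(*[np.arange(d, dtype=float) for d in target_shape], indexing="ij")
    )
    coords = np.einsum("ij,j...->i...", xform[:3, :3], grid) + xform[:3, 3].reshape(
        3, 1, 1, 1
    )
    up = ndimage.map_coordinates(ratio, coords, order=3, mode="nearest")
    floor = 1e-3 * float(np.abs(ratio).max() or 1.0)
    return np.maximum(up, floor)


def compute_pd(
    amplitude: np.ndarray,
    calibration: CalibrationPair,
    wm_mask: np.ndarray,
    affine: np.ndarray,
    mask: np.ndarray | None = None,
    wm_pd: float = WM_PD_REFERENCE,
) -> tuple[np.ndarray, np.ndarray]:
    """Receive-corrected, white-matter-calibrated proton density (p.u.)."""
    if not wm_mask.any():
        raise ValueError("empty white-matter mask: PD calibration impossible")
    if mask is None:
        mask = amplitude > 0
    receive = upsample_receive_field(calibration, amplitude.shape, affine)
    bad = receive <= 0
    n_bad = int((bad & mask).sum())
    if n_bad:
        logger.info("compute_pd: masked %d voxels with non-positive receive", n_bad)
    ok = mask & ~bad
    pd_uncal = np.where(ok, amplitude / receive, 0.0)
    wm_ok = wm_mask & ok
    if not wm_ok.any():
        raise ValueError("white-matter mask is empty after receive masking")
    scale = wm_pd / float(pd_uncal[wm_ok].mean())
    return pd_uncal * scale, ok


def compute_mtsat(
    s_mt: np.ndarray,
    amplitude: np.ndarray,
    r1: np.ndarray,
    protocol: AcquisitionProtocol,
    f_t: np.ndarray | float,
    mask: np.ndarray | None = None,
    b1_correction: bool = True,
    b1_slope: float = MTSAT_B1_SLOPE,
    clamp: tuple[float, float] = (-0.5, 10.0),
) -> tuple[np.ndarray, np.ndarray]:
    """MT saturation in percent units.

    ``delta = (A a_MT / S_MT - 1) R1 TR - a_MT^2 / 2`` with
    ``a_MT = f_T alpha_MT``, followed (optionally) by the empirical
    transmit-bias correction ``delta (1 - C) / (1 - C f_T)`` with C = 0.4.
    Voxels outside ``clamp`` (in p.u.) are masked.
    """
    w = protocol["MTw"]
    a_mt = f_t * w.flip_angle_rad
    tr = w.tr_s
    if mask is None:
        mask = (s_mt > 0) & (amplitude > 0)
    ok = mask & (s_mt > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = (amplitude * a_mt / s_mt - 1.0) * r1 * tr - a_mt ** 2 / 2.0
        if b1_correction:
            delta = delta * (1.0 - b1_slope) / (1.0 - b1_slope * f_t)
    delta_pu = delta * 100.0
    inside = (delta_pu >= clamp[0]) & (delta_pu <= clamp[1])
    n_clamped = int((ok & ~inside & np.isfinite(delta_pu)).sum())
    if n_clamped:
        logger.info("compute_mtsat: masked %d out-of-range voxels", n_clamped)
    ok = ok & np.isfinite(delta_pu) & inside
    return np.where(ok, delta_pu, 0.0), ok


def fit_maps(
    volumes: EchoVolumeSet,
    wm_mask: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    wm_pd: float = WM_PD_REFERENCE,
    b1_correction: bool = True,
) -> QuantMaps:
    """Full estimation chain on an in-memory echo set.

    PD requires both a calibration pair and a white-matter mask; MTsat
    requires the MTw stack (a missing stack degrades gracefully with a
    warning, mirroring discarded MT acquisitions in practice).
    """
    for required in ("T1w", "PDw"):
        if required not in volumes.stacks:
            raise ValueError(f"missing required weighting: {required}")
    est = estatics_fit(volumes, mask=mask)
    f_t = volumes.b1_map
    r1, ok_r1 = compute_r1(
        est.intercepts["T1w"], est.intercepts["PDw"], volumes.protocol, f_t,
        mask=est.mask,
    )
    amp, ok_a = compute_amplitude(
        est.intercepts["T1w"], est.intercepts["PDw"], volumes.protocol, f_t,
        mask=est.mask,
    )
    valid = est.mask & ok_r1 & ok_a

    pd = None
    if volumes.calibration is not None and wm_mask is not None:
        pd, ok_pd = compute_pd(
            amp, volumes.calibration, wm_mask, volumes.affine, mask=valid, wm_pd=wm_pd
        )
        valid = valid & ok_pd

    mtsat = None
    if "MTw" in volumes.stacks:
        mtsat, ok_mt = compute_mtsat(
            est.intercepts["MTw"], amp, r1, volumes.protocol, f_t,
            mask=valid, b1_correction=b1_correction,
        )
        valid = valid & ok_mt
    else:
        warnings.warn("MTw stack absent: MTsat map not produced", stacklevel=2)

    prov = {
        "weightings": {
            n: {
                "flip_angle_deg": w.flip_angle_deg,
                "tr_ms": w.tr_ms,
                "te_ms": list(w.te_ms),
            }
            for n, w in volumes.protocol.weightings.items()
        },
        "wm_pd_reference": wm_pd,
        "mtsat_b1_correction": b1_correction,
        "mtsat_b1_slope": MTSAT_B1_SLOPE,
        "n_excluded_nonpositive": est.n_excluded,
    }
    return QuantMaps(
        r1=np.where(valid, r1, 0.0),
        r2s=np.where(est.mask, est.r2s, 0.0),
        pd=pd if pd is None else np.where(valid, pd, 0.0),
        mtsat=mtsat if mtsat is None else np.where(valid, mtsat, 0.0),
        mask=valid,
        affine=volumes.affine,
        provenance=prov,
    )


def run_mpm(
    subject_dir: str | Path,
    out_dir: str | Path | None = None,
    wm_pd: float = WM_PD_REFERENCE,
    b1_correction: bool = True,
) -> QuantMaps:
    """File-based pipeline stage: read a written subject, fit all maps and
    (optionally) write R1/R2s/PD/MTsat NIfTI volumes plus provenance JSON."""
    subject, volumes = read_subject(subject_dir)
    wm_mask = subject.tissue_probs["wm"] > 0.5
    maps = fit_maps(
        volumes, wm_mask=wm_mask, mask=subject.brain_mask,
        wm_pd=wm_pd, b1_correction=b1_correction,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, vol in maps.as_dict().items():
            nib.save(
                nib.Nifti1Image(np.asarray(vol, dtype=np.float32), maps.affine),
                str(out_dir / f"{name}.nii.gz"),
            )
        nib.save(
            nib.Nifti1Image(maps.mask.astype(np.uint8), maps.affine),
            str(out_dir / "mask.nii.gz"),
        )
        (out_dir / "provenance.json").write_text(json.dumps(maps.provenance, indent=1))
    return maps
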