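"""Contrast-to-noise ratio between the habenula and its surrounding grey
matter.

The GM reference region is a one-voxel shell around the habenula ROI
restricted to high-probability grey matter; the CNR is
``(mean(habenula) - mean(GM)) / std(habenula)``, signed, so that a
hypointense habenula (as on proton-density maps) yields a negative value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "CnrResult",
    "surround_gm_mask",
    "compute_cnr",
    "native_cnr_report",
]


@dataclass(frozen=True)
class CnrResult:
    subject: int | str
    map_name: str
    hab_mean: float
    gm_mean: float
    hab_sd: float
    cnr: float


def _structuring_element(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        # discrete unit ball: face neighbours only
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6 or 26")


def surround_gm_mask(
    habenula_mask: np.ndarray,
    gm_prob: np.ndarray,
    threshold: float = 0.9,
    connectivity: int = 6,
) -> np.ndarray:
    """One-voxel GM shell around the habenula.

    Dilate the habenula mask by one voxel (6-connected by default), remove
    the habenula itself, and intersect with ``gm_prob > threshold``.
    """
    if not habenula_mask.any():
        raise ValueError("empty habenula mask")
    struct = _structuring_element(connectivity)
    dilated = ndimage.binary_dilation(habenula_mask, structure=struct)
    shell = dilated & ~habenula_mask
    out = shell & (gm_prob > threshold)
    if not out.any():
        raise ValueError(
            "surrounding grey-matter mask is empty; review the GM probability "
            "threshold"
        )
    return out


def compute_cnr(
    map_volume: np.ndarray,
    habenula_mask: np.ndarray,
    gm_mask: np.ndarray,
    subject: int | str = "",
    map_name: str = "",
    ddof: int = 0,
) -> CnrResult:
    """``CNR = (mean(habenula) - mean(GM)) / std(habenula)``, sign preserved."""
    if not habenula_mask.any() or not gm_mask.any():
        raise ValueError("both ROI masks must be nonempty")
    hab = map_volume[habenula_mask]
    gm = map_volume[gm_mask]
    sd = float(hab.std(ddof=ddof))
    if sd == 0:
        raise ValueError("habenula SD is zero: CNR undefined")
    return CnrResult(
        subject=subject,
        map_name=map_name,
        hab_mean=float(hab.mean()),
        gm_mean=float(gm.mean()),
        hab_sd=sd,
        cnr=(float(hab.mean()) - float(gm.mean())) / sd,
    )


def native_cnr_report(
    results: list[CnrResult],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject CNR table plus a cohort summary.

    Returns ``(rows, summary)``; the summary holds mean, SD (population) and
    the ranking of maps by cohort-mean CNR.
    """
    if not results:
        raise ValueError("no CNR results supplied")
    rows = pd.DataFrame(
        [
            {
                "subject": r.subject,
                "map": r.map_name,
                "hab_mean": r.hab_mean,
                "gm_mean": r.gm_mean,
                "hab_sd": r.hab_sd,
                "cnr": r.cnr,
            }
            for r in results
        ]
    )
    summary = (
        rows.groupby("map")["cnr"]
        .agg(cnr_mean="mean", cnr_sd=lambda x: float(np.std(x)))
        .reset_index()
        .sort_values("cnr_mean", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    summary["rank"] = np.arange(1, len(summary) + 1)
    return rows, summary
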