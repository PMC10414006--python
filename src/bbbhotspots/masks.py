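"""White-matter analysis masks and volume metrics.

The PS analysis is restricted to white matter (NAWM plus WMH), excluding the
brainstem, after a one-voxel-kernel erosion that strips the tissue boundary
where partial-volume contamination from cortex, CSF and superficial vessels
is worst.  Cerebellar white matter is included by default (configurable).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import phantom as ph


class UndefinedLogError(ValueError):
    """log10(WMH volume) requested but the WMH volume is zero."""


@dataclass
class AnalysisMasks:
    """Boolean analysis masks: full WM, eroded WM, NAWM and WMH partitions."""

    wm_all: np.ndarray
    wm_eroded: np.ndarray
    nawm: np.ndarray
    wmh: np.ndarray
    #: erosion of the cavity-filled WM mask; lesion interiors count as WM
    #: here, so a deep lesion's centroid lands inside it
    wm_eroded_filled: np.ndarray | None = None


@dataclass
class VolumeMetrics:
    """Intracranial and WMH volumes (mL) plus the normalized WMH burden."""

    icv_ml: float
    wmh_ml: float

    @property
    def wmh_normalized(self) -> float:
        return self.wmh_ml / self.icv_ml

    @property
    def log10_wmh_normalized(self) -> float:
        if self.wmh_ml <= 0:
            raise UndefinedLogError("log10 of normalized WMH volume undefined: WMH volume is zero")
        return float(np.log10(self.wmh_normalized))


def _structure(kernel: str) -> np.ndarray:
    if kernel == "cube":  # full 3x3x3, 26-neighbourhood
        return np.ones((3, 3, 3), dtype=bool)
    if kernel == "cross":  # 6-neighbourhood
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError(f"unknown erosion kernel {kernel!r}; expected 'cube' or 'cross'")


def erode_one_voxel(mask: np.ndarray, kernel: str = "cube") -> np.ndarray:
    """One-voxel morphological erosion.

    With the default cubic kernel a voxel survives iff its entire 3x3x3
    neighbourhood lies in the mask; voxels beyond the volume edge count as
    background.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    return ndimage.binary_erosion(mask, structure=_structure(kernel), border_value=0)


def build_analysis_masks(
    labels: np.ndarray,
    kernel: str = "cube",
    include_cerebellum: bool = True,
) -> AnalysisMasks:
    """Build the eroded white-matter analysis mask from a label volume.

    ``wm_all`` is NAWM plus WMH (optionally including cerebellar WM) with the
    brainstem excluded; ``wm_eroded`` is its one-voxel erosion; ``nawm`` is
    ``wm_all`` minus WMH.

    Lacune and microbleed interiors are excluded from the mask but treated
    as filled during the erosion: the erosion strips the outer tissue
    boundary (against cortex, CSF, background), not a halo around each
    internal cavity, so white matter in direct contact with a lesion stays
    analysable — a prerequisite for edge colocalization.
    """
    labels = np.asarray(labels)
    wm_codes = [ph.WM, ph.WMH]
    if include_cerebellum:
        wm_codes.append(ph.CEREBELLUM)
    wm_all = np.isin(labels, wm_codes) & (labels != ph.BRAINSTEM)
    if not wm_all.any():
        raise ValueError("label volume contains no white matter voxels")
    filled = wm_all | np.isin(labels, (ph.LACUNE, ph.CMB))
    wmh = labels == ph.WMH
    eroded_filled = erode_one_voxel(filled, kernel=kernel)
    return AnalysisMasks(
        wm_all=wm_all,
        wm_eroded=eroded_filled & wm_all,
        nawm=wm_all & ~wmh,
        wmh=wmh & wm_all,
        wm_eroded_filled=eroded_filled,
    )


def volume_metrics(labels: np.ndarray, voxel_mm: tuple[float, float, float]) -> VolumeMetrics:
    """ICV and WMH volumes in mL.

    ICV counts every non-background intracranial label (CSF included);
    volume = voxel count * voxel volume (mm^3) / 1000.
    """
    voxel_mm = tuple(float(v) for v in voxel_mm)
    if any(v <= 0 for v in voxel_mm):
        raise ValueError("voxel_mm must be positive on all axes")
    vox_ml = float(np.prod(voxel_mm)) / 1000.0
    labels = np.asarray(labels)
    icv_ml = float((labels != ph.BACKGROUND).sum()) * vox_ml
    wmh_ml = float((labels == ph.WMH).sum()) * vox_ml
    if icv_ml <= 0:
        raise ValueError("label volume contains no intracranial voxels")
    return VolumeMetrics(icv_ml=icv_ml, wmh_ml=wmh_ml)
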