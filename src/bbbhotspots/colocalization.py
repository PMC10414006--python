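"""Spatial relation of hotspots to lacunes, WMH and microbleeds.

A hotspot is "at a lesion edge" when it overlaps the lesion or its one-voxel
outer boundary band (26-neighbourhood contact).  A hotspot is "within WMH"
when every one of its voxels is a WMH voxel; any partial overlap with the
WMH border region counts as "at WMH edge" instead, so the two WMH
categories are mutually exclusive per hotspot.  A hotspot may carry flags
for several lesion classes at once (e.g. at a lacune edge and within WMH).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .hotspots import HotspotSet
from .masks import AnalysisMasks
from .phantom import PhantomTruth

CATEGORIES = ("at_lacune_edge", "within_wmh", "at_wmh_edge", "at_cmb_edge")


@dataclass
class LesionSet:
    """Labeled lesion maps consumed by the colocalization rules."""

    lacunes: np.ndarray  # labeled (0 = none, else lesion id)
    wmh: np.ndarray  # boolean
    cmbs: np.ndarray  # labeled

    @classmethod
    def from_phantom(cls, phantom: PhantomTruth) -> "LesionSet":
        from . import phantom as ph

        return cls(
            lacunes=phantom.lesion_label_map("lacune"),
            wmh=phantom.labels == ph.WMH,
            cmbs=phantom.lesion_label_map("cmb"),
        )


@dataclass
class HotspotFlags:
    """Colocalization flags and touched lesion ids for one hotspot."""

    hotspot_id: int
    at_lacune_edge: bool
    within_wmh: bool
    at_wmh_edge: bool
    at_cmb_edge: bool
    lacune_ids: tuple[int, ...] = ()
    cmb_ids: tuple[int, ...] = ()


@dataclass
class ColocalizationTable:
    """Per-hotspot flags plus per-lesion and per-patient summaries."""

    flags: list[HotspotFlags]
    lacunes_with_hotspot: set[int] = field(default_factory=set)
    cmbs_with_hotspot: set[int] = field(default_factory=set)

    def count(self, category: str) -> int:
        return sum(getattr(f, category) for f in self.flags)

    def presence(self, category: str) -> bool:
        return self.count(category) > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "hotspot_id": f.hotspot_id,
                    **{c: getattr(f, c) for c in CATEGORIES},
                    "lacune_ids": ";".join(map(str, f.lacune_ids)),
                    "cmb_ids": ";".join(map(str, f.cmb_ids)),
                }
                for f in self.flags
            ],
            columns=["hotspot_id", *CATEGORIES, "lacune_ids", "cmb_ids"],
        )


def outer_band(lesion_mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """One-voxel (by default) outer boundary band: dilation minus the mask."""
    if radius < 1:
        raise ValueError("band radius must be >= 1")
    mask = np.asarray(lesion_mask, dtype=bool)
    dil = ndimage.binary_dilation(mask, structure=np.ones((3, 3, 3)), iterations=radius)
    return dil & ~mask


def _touch_mask(voxels: np.ndarray, shape: tuple[int, ...], radius: int) -> np.ndarray:
    """Hotspot voxels dilated by the contact radius (26-neighbourhood)."""
    m = np.zeros(shape, dtype=bool)
    m[tuple(np.asarray(voxels).T)] = True
    return ndimage.binary_dilation(m, structure=np.ones((3, 3, 3)), iterations=radius)


def classify_hotspot(
    voxels: np.ndarray,
    lesions: LesionSet,
    hotspot_id: int = 0,
    band_radius: int = 1,
    wmh_containment: str = "full",
) -> HotspotFlags:
    """Apply the edge/within rules to one hotspot voxel set.

    ``wmh_containment='full'`` demands every voxel inside WMH for the
    "within" flag; ``'majority'`` demands more than half.
    """
    voxels = np.asarray(voxels)
    touch = _touch_mask(voxels, lesions.wmh.shape, band_radius)

    lacune_ids = tuple(int(i) for i in np.unique(lesions.lacunes[touch]) if i > 0)
    cmb_ids = tuple(int(i) for i in np.unique(lesions.cmbs[touch]) if i > 0)

    in_wmh = lesions.wmh[tuple(voxels.T)]
    if wmh_containment == "full":
        within = bool(in_wmh.all())
    elif wmh_containment == "majority":
        within = bool(in_wmh.mean() > 0.5)
    else:
        raise ValueError(f"unknown wmh_containment {wmh_containment!r}")
    touches_wmh = bool(lesions.wmh[touch].any())
    at_wmh_edge = (not within) and touches_wmh

    return HotspotFlags(
        hotspot_id=hotspot_id,
        at_lacune_edge=len(lacune_ids) > 0,
        within_wmh=within,
        at_wmh_edge=at_wmh_edge,
        at_cmb_edge=len(cmb_ids) > 0,
        lacune_ids=lacune_ids,
        cmb_ids=cmb_ids,
    )


def classify_hotspot_set(
    hotspot_set: HotspotSet,
    lesions: LesionSet,
    band_radius: int = 1,
    wmh_containment: str = "full",
) -> ColocalizationTable:
    """Classify every hotspot of a patient and collect touched lesions."""
    flags = [
        classify_hotspot(h.voxels, lesions, hotspot_id=h.id, band_radius=band_radius, wmh_containment=wmh_containment)
        for h in hotspot_set.hotspots
    ]
    table = ColocalizationTable(flags=flags)
    for f in flags:
        table.lacunes_with_hotspot.update(f.lacune_ids)
        table.cmbs_with_hotspot.update(f.cmb_ids)
    return table


def _deep_wm_lesion_ids(labeled: np.ndarray, wm_eroded: np.ndarray) -> list[int]:
    """Lesions whose (rounded) centroid lies inside the eroded WM mask."""
    ids = []
    for i in np.unique(labeled):
        if i == 0:
            continue
        vox = np.argwhere(labeled == i)
        c = tuple(np.round(vox.mean(axis=0)).astype(int))
        if wm_eroded[c]:
            ids.append(int(i))
    return ids


def subgroup_eligibility(
    lesions: LesionSet,
    analysis_masks: AnalysisMasks,
    fazekas_dwmh: int,
    fazekas_pvh: int,
    nawm_fraction_threshold: float = 0.10,
) -> dict[str, bool]:
    """Per-patient eligibility for the lacune, WMH and CMB subgroup analyses.

    Lacune/CMB subgroups require at least one lesion with centroid in the
    eroded WM mask.  The WMH subgroup requires more than minimal WMH load
    (deep Fazekas > 0 or periventricular Fazekas > 1) and enough remaining
    NAWM (NAWM at least ``nawm_fraction_threshold`` of the WM mask).
    """
    for name, grade in (("fazekas_dwmh", fazekas_dwmh), ("fazekas_pvh", fazekas_pvh)):
        if grade not in (0, 1, 2, 3):
            raise ValueError(f"{name} must be in 0..3, got {grade}")
    nawm_fraction = analysis_masks.nawm.sum() / max(analysis_masks.wm_all.sum(), 1)
    deep_ref = (
        analysis_masks.wm_eroded_filled
        if analysis_masks.wm_eroded_filled is not None
        else analysis_masks.wm_eroded
    )
    return {
        "lacune_subgroup": len(_deep_wm_lesion_ids(lesions.lacunes, deep_ref)) > 0,
        "wmh_subgroup": bool(
            (fazekas_dwmh > 0 or fazekas_pvh > 1) and nawm_fraction >= nawm_fraction_threshold
        ),
        "cmb_subgroup": len(_deep_wm_lesion_ids(lesions.cmbs, deep_ref)) > 0,
    }


def summarize_colocalization(
    patient_tables: dict[str, ColocalizationTable],
    eligibility: dict[str, dict[str, bool]],
    lesion_counts: dict[str, dict[str, int]] | None = None,
) -> pd.DataFrame:
    """Cohort summary: eligible-patient presence fractions per category.

    ``patient_tables`` maps patient id -> ColocalizationTable; ``eligibility``
    maps patient id -> subgroup flags; ``lesion_counts`` (optional) maps
    patient id -> {"lacunes": n, "cmbs": n} of deep-WM lesions, enabling the
    per-lesion touched fractions.
    """
    subgroup_for = {
        "at_lacune_edge": "lacune_subgroup",
        "within_wmh": "wmh_subgroup",
        "at_wmh_edge": "wmh_subgroup",
        "at_cmb_edge": "cmb_subgroup",
    }
    rows = []
    for category, subgroup in subgroup_for.items():
        eligible = [pid for pid in patient_tables if eligibility[pid][subgroup]]
        n_eligible = len(eligible)
        n_present = sum(patient_tables[pid].presence(category) for pid in eligible)
        row = {
            "category": category,
            "n_eligible": n_eligible,
            "n_with_hotspot": n_present,
            "presence_fraction": (n_present / n_eligible) if n_eligible else float("nan"),
            "no_eligible_patients": n_eligible == 0,
        }
        if lesion_counts is not None and category in ("at_lacune_edge", "at_cmb_edge"):
            key = "lacunes" if category == "at_lacune_edge" else "cmbs"
            touched_attr = "lacunes_with_hotspot" if key == "lacunes" else "cmbs_with_hotspot"
            n_lesions = sum(lesion_counts[pid][key] for pid in eligible)
            n_touched = sum(len(getattr(patient_tables[pid], touched_attr)) for pid in eligible)
            row["n_lesions"] = n_lesions
            row["n_lesions_with_hotspot"] = n_touched
            row["lesion_fraction"] = (n_touched / n_lesions) if n_lesions else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
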