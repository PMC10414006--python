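"""Per-patient BBB-leakage hotspot extraction and regional load scoring.

A hotspot is a connected cluster of at least ``min_size`` voxels whose PS
values fall in the top decile of the patient's eroded white-matter mask.
The decile threshold is relative (per patient): the k-th largest in-mask PS
value with k = round(0.10 * N), ties at the threshold included.  Contiguity
defaults to 26-connectivity.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .phantom import REGION_NAMES, SIDE_NAMES, decode_atlas

UNASSIGNED = 0  # region code when a hotspot sits entirely on unlabeled atlas voxels

#: ordinal load per side from hotspot count: absence / low / medium / high.
#: The count boundaries are a package convention, surfaced in output metadata.
DEFAULT_LOAD_CUTOFFS = (1, 3, 6)  # count >= cutoff -> load >= 1, 2, 3


@dataclass
class Hotspot:
    """One connected top-decile PS cluster."""

    id: int
    voxels: np.ndarray  # (n, 3) int
    size: int
    centroid_mm: tuple[float, float, float]
    region: int  # region code (1..6) or UNASSIGNED
    side: int  # 0 left / 1 right
    mean_ps: float

    @property
    def region_name(self) -> str:
        return REGION_NAMES.get(self.region, "unassigned")

    @property
    def side_name(self) -> str:
        return SIDE_NAMES.get(self.side, "unassigned")


@dataclass
class HotspotSet:
    """All hotspots of one patient plus the thresholding bookkeeping."""

    hotspots: list[Hotspot]
    threshold_value: float
    n_mask_voxels: int
    n_selected_voxels: int

    @property
    def count(self) -> int:
        return len(self.hotspots)


@dataclass
class RegionalLoad:
    """Ordinal hotspot load per (region, side) and summed left+right (0-6)."""

    per_side: dict[tuple[int, int], int] = field(default_factory=dict)

    def summed(self, region: int) -> int:
        return self.per_side.get((region, 0), 0) + self.per_side.get((region, 1), 0)

    def as_dict(self) -> dict[str, int]:
        out = {}
        for region, name in REGION_NAMES.items():
            out[f"load_{name}_left"] = self.per_side.get((region, 0), 0)
            out[f"load_{name}_right"] = self.per_side.get((region, 1), 0)
            out[f"load_{name}"] = self.summed(region)
        return out


def decile_threshold(
    ps_map: np.ndarray, mask: np.ndarray, fraction: float = 0.10
) -> tuple[float, np.ndarray]:
    """Top-decile selection: threshold at the k-th largest in-mask value.

    k = round(fraction * N), at least 1; every voxel with PS >= threshold is
    selected, so ties at the threshold can push the selected count above k.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty hotspot analysis mask")
    values = np.asarray(ps_map, dtype=float)[mask]
    n = values.size
    k = max(int(round(fraction * n)), 1)
    threshold = float(np.partition(values, n - k)[n - k])
    selected = np.zeros(mask.shape, dtype=bool)
    selected[mask] = values >= threshold
    return threshold, selected


def connected_components(selected: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Label maximal connected sets; labels are deterministic (scan order)."""
    conn = {6: 1, 18: 2, 26: 3}.get(connectivity)
    if conn is None:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    return measure.label(np.asarray(selected, dtype=bool), connectivity=conn)


def assign_region(voxels: np.ndarray, atlas: np.ndarray) -> tuple[int, int]:
    """Majority-vote (region, side) over a hotspot's atlas codes.

    Unlabeled voxels (code 0) never outvote labeled ones; an all-unlabeled
    hotspot gets the UNASSIGNED code.  Exact ties break to the lowest region
    code, then to the left side.
    """
    codes = atlas[tuple(np.asarray(voxels).T)]
    codes = codes[codes > 0]
    if codes.size == 0:
        return UNASSIGNED, 0
    counts = np.bincount(codes)
    best = counts.max()
    tied = np.flatnonzero(counts == best)
    pairs = sorted(decode_atlas(int(c)) for c in tied)
    return pairs[0]


def filter_min_size(
    components: np.ndarray,
    ps_map: np.ndarray,
    atlas: np.ndarray,
    voxel_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    min_size: int = 5,
    threshold_value: float = float("nan"),
    n_mask_voxels: int = 0,
) -> HotspotSet:
    """Keep components of at least ``min_size`` voxels and score them.

    The per-patient hotspot count is the number of retained components.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    components = np.asarray(components)
    n_selected = int((components > 0).sum())
    hotspots: list[Hotspot] = []
    next_id = 1
    for lab in range(1, components.max() + 1):
        vox = np.argwhere(components == lab)
        if len(vox) < min_size:
            continue
        region, side = assign_region(vox, atlas)
        centroid = tuple(float(c) for c in vox.mean(axis=0) * np.asarray(voxel_mm))
        hotspots.append(
            Hotspot(
                id=next_id,
                voxels=vox,
                size=len(vox),
                centroid_mm=centroid,
                region=region,
                side=side,
                mean_ps=float(np.asarray(ps_map, dtype=float)[tuple(vox.T)].mean()),
            )
        )
        next_id += 1
    return HotspotSet(
        hotspots=hotspots,
        threshold_value=float(threshold_value),
        n_mask_voxels=int(n_mask_voxels),
        n_selected_voxels=n_selected,
    )


def detect_hotspots(
    ps_map: np.ndarray,
    mask: np.ndarray,
    atlas: np.ndarray,
    voxel_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    fraction: float = 0.10,
    min_size: int = 5,
    connectivity: int = 26,
) -> HotspotSet:
    """Full hotspot extraction: decile threshold, contiguity, size filter."""
    threshold, selected = decile_threshold(ps_map, mask, fraction=fraction)
    comps = connected_components(selected, connectivity=connectivity)
    return filter_min_size(
        comps,
        ps_map,
        atlas,
        voxel_mm=voxel_mm,
        min_size=min_size,
        threshold_value=threshold,
        n_mask_voxels=int(np.asarray(mask, bool).sum()),
    )


def _load_level(count: int, cutoffs: tuple[int, int, int] = DEFAULT_LOAD_CUTOFFS) -> int:
    if count < 0:
        raise ValueError("hotspot count must be >= 0")
    low, medium, high = cutoffs
    if count >= high:
        return 3
    if count >= medium:
        return 2
    if count >= low:
        return 1
    return 0


def regional_load(
    counts_per_region_side: dict[tuple[int, int], int],
    cutoffs: tuple[int, int, int] = DEFAULT_LOAD_CUTOFFS,
) -> RegionalLoad:
    """Map per-(region, side) hotspot counts to the 0-3 ordinal load scale.

    Default scale: 0 hotspots -> absence (0), 1-2 -> low (1), 3-5 -> medium
    (2), >= 6 -> high (3); left+right sums span 0-6 per region.
    """
    per_side = {}
    for region in REGION_NAMES:
        for side in (0, 1):
            per_side[(region, side)] = _load_level(
                counts_per_region_side.get((region, side), 0), cutoffs
            )
    return RegionalLoad(per_side=per_side)


def hotspot_region_counts(hotspot_set: HotspotSet) -> dict[tuple[int, int], int]:
    """Count hotspots per (region, side), skipping unassigned ones."""
    counts: dict[tuple[int, int], int] = {}
    for h in hotspot_set.hotspots:
        if h.region == UNASSIGNED:
            continue
        counts[(h.region, h.side)] = counts.get((h.region, h.side), 0) + 1
    return counts
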