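"""Synthetic brain phantoms with small-vessel-disease lesion geometry.

The phantom is a co-registered stack of integer label volumes emulating the
tissue classes a structural MRI segmentation would provide: grey matter,
white matter, white matter hyperintensities (WMH), lacunes (CSF-filled
cavities inside white matter), cerebral microbleeds (CMB), ventricles,
brainstem and cerebellum.  A companion atlas volume partitions the brain into
the anatomical regions used for regional hotspot scoring (cerebellum,
internal capsule, temporal lobes, anterior/posterior ventricle-horn white
matter, centrum semiovale), each split into a left and right side.

Everything is generated from a seeded :class:`numpy.random.Generator`, so a
given ``(shape, voxel_mm, lesion_spec, seed)`` tuple is bit-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# ---------------------------------------------------------------------------
# label vocabulary

BACKGROUND = 0
GM = 1
WM = 2
WMH = 3
LACUNE = 4
CMB = 5
CSF = 6
BRAINSTEM = 7
CEREBELLUM = 8

LABEL_NAMES = {
    BACKGROUND: "background",
    GM: "gm",
    WM: "wm",
    WMH: "wmh",
    LACUNE: "lacune",
    CMB: "cmb",
    CSF: "csf",
    BRAINSTEM: "brainstem",
    CEREBELLUM: "cerebellum",
}

LESION_CLASSES = ("lacune", "wmh", "cmb")

# atlas vocabulary: regions 1..6, sides left (0) / right (1) packed into a
# single code: left = 1..6, right = 7..12; 0 means "outside the atlas".
REGION_CEREBELLUM = 1
REGION_INTERNAL_CAPSULE = 2
REGION_TEMPORAL = 3
REGION_ANTERIOR_HORN = 4
REGION_POSTERIOR_HORN = 5
REGION_CENTRUM_SEMIOVALE = 6

REGION_NAMES = {
    REGION_CEREBELLUM: "cerebellum",
    REGION_INTERNAL_CAPSULE: "internal_capsule",
    REGION_TEMPORAL: "temporal",
    REGION_ANTERIOR_HORN: "anterior_horn_wm",
    REGION_POSTERIOR_HORN: "posterior_horn_wm",
    REGION_CENTRUM_SEMIOVALE: "centrum_semiovale",
}
SIDE_LEFT = 0
SIDE_RIGHT = 1
SIDE_NAMES = {SIDE_LEFT: "left", SIDE_RIGHT: "right"}


def atlas_code(region: int, side: int) -> int:
    """Pack a (region, side) pair into a single positive atlas code."""
    if region not in REGION_NAMES or side not in SIDE_NAMES:
        raise ValueError(f"invalid region/side pair ({region}, {side})")
    return region + 6 * side


def decode_atlas(code: int) -> tuple[int, int]:
    """Inverse of :func:`atlas_code`; returns ``(region, side)``."""
    if not 1 <= code <= 12:
        raise ValueError(f"invalid atlas code {code}")
    return (code - 1) % 6 + 1, (code - 1) // 6


# ---------------------------------------------------------------------------
# specs and containers


@dataclass(frozen=True)
class LesionClassSpec:
    """Count and voxel-radius range for one lesion class."""

    count: int = 0
    radius_range: tuple[float, float] = (2.0, 3.0)

    def validate(self, name: str) -> None:
        if self.count < 0:
            raise ValueError(f"{name}: negative lesion count")
        lo, hi = self.radius_range
        if not (0 < lo <= hi):
            raise ValueError(f"{name}: invalid radius range {self.radius_range}")


@dataclass(frozen=True)
class LesionSpec:
    """Per-class lesion counts and sizes for a phantom."""

    lacunes: LesionClassSpec = LesionClassSpec(0, (2.0, 3.0))
    wmh_blobs: LesionClassSpec = LesionClassSpec(0, (3.0, 5.0))
    cmbs: LesionClassSpec = LesionClassSpec(0, (1.0, 2.0))

    def validate(self) -> None:
        self.lacunes.validate("lacunes")
        self.wmh_blobs.validate("wmh_blobs")
        self.cmbs.validate("cmbs")


@dataclass
class Lesion:
    """One enumerated lesion: id, class name and its voxel coordinates."""

    id: int
    lesion_class: str
    voxels: np.ndarray  # (n, 3) int array


@dataclass
class PhantomTruth:
    """Ground-truth label and atlas volumes for one synthetic patient."""

    labels: np.ndarray
    atlas: np.ndarray
    voxel_mm: tuple[float, float, float]
    lesion_index: dict[int, Lesion] = field(default_factory=dict)

    def lesion_label_map(self, lesion_class: str) -> np.ndarray:
        """Labeled volume (0 = none, else lesion id) for one lesion class."""
        out = np.zeros(self.labels.shape, dtype=np.int32)
        for lesion in self.lesion_index.values():
            if lesion.lesion_class == lesion_class and len(lesion.voxels):
                out[tuple(lesion.voxels.T)] = lesion.id
        return out

    def lesion_ids(self, lesion_class: str) -> list[int]:
        return [l.id for l in self.lesion_index.values() if l.lesion_class == lesion_class]


# ---------------------------------------------------------------------------
# generation


def _ball_offsets(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    grid = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1].reshape(3, -1).T
    return grid[np.sum(grid**2, axis=1) <= radius**2 + 1e-9]


def _place_spheres(
    rng: np.random.Generator,
    allowed: np.ndarray,
    n: int,
    radius_range: tuple[float, float],
    min_center_sep: float,
    what: str,
    max_tries_per_lesion: int = 400,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Sample ``n`` non-touching balls whose voxels all lie in ``allowed``.

    Returns a list of (center, voxel-array) pairs; raises a sizing error when
    the requested lesions do not fit.
    """
    coords = np.argwhere(allowed)
    placed: list[tuple[np.ndarray, np.ndarray]] = []
    centers: list[np.ndarray] = []
    radii: list[float] = []
    shape = allowed.shape
    for _ in range(n):
        ok = False
        for _try in range(max_tries_per_lesion):
            if len(coords) == 0:
                break
            c = coords[rng.integers(len(coords))]
            r = float(rng.uniform(*radius_range))
            if centers:
                d = np.linalg.norm(np.asarray(centers) - c, axis=1)
                if np.any(d < np.asarray(radii) + r + min_center_sep):
                    continue
            vox = c + _ball_offsets(r)
            if np.any(vox < 0) or np.any(vox >= np.asarray(shape)):
                continue
            if not np.all(allowed[tuple(vox.T)]):
                continue
            placed.append((c, vox))
            centers.append(c)
            radii.append(r)
            ok = True
            break
        if not ok:
            raise ValueError(
                f"phantom too small to place {n} {what} lesions "
                f"(placed {len(placed)}); increase shape or reduce counts/radii"
            )
    return placed


def generate_phantom(
    shape: tuple[int, int, int],
    voxel_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    lesion_spec: LesionSpec | None = None,
    seed: int = 0,
) -> PhantomTruth:
    """Generate one co-registered synthetic brain with SVD lesions.

    Axes follow radiological array convention: axis 0 = left-right,
    axis 1 = posterior-anterior, axis 2 = inferior-superior.

    Parameters
    ----------
    shape
        Grid size per axis; each axis must be at least 32 voxels.
    voxel_mm
        Voxel edge length per axis in millimetres (all positive).
    lesion_spec
        Counts and radius ranges per lesion class; defaults to no lesions.
    seed
        Seed for all stochastic placement; the output is bit-reproducible.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 32 for s in shape):
        raise ValueError(f"shape must be 3D with every axis >= 32, got {shape}")
    if any(v <= 0 for v in voxel_mm):
        raise ValueError(f"voxel_mm must be positive, got {voxel_mm}")
    spec = lesion_spec or LesionSpec()
    spec.validate()
    rng = np.random.default_rng(seed)

    # normalised coordinates in [-1, 1] per axis
    x, y, z = np.meshgrid(*(np.linspace(-1.0, 1.0, s) for s in shape), indexing="ij")

    brain = (x / 0.92) ** 2 + (y / 0.95) ** 2 + (z / 0.88) ** 2 <= 1.0
    inner = (x / 0.76) ** 2 + (y / 0.80) ** 2 + (z / 0.72) ** 2 <= 1.0

    labels = np.zeros(shape, dtype=np.int16)
    labels[brain] = GM
    labels[brain & inner] = WM

    # lateral ventricles: two elongated ellipsoids flanking the midline
    for sx in (-1.0, 1.0):
        vent = ((x - 0.17 * sx) / 0.10) ** 2 + (y / 0.42) ** 2 + ((z - 0.05) / 0.16) ** 2 <= 1.0
        labels[vent & brain] = CSF

    # brainstem: central inferior column; cerebellum: posterior-inferior lobe
    stem = (x / 0.12) ** 2 + ((y + 0.12) / 0.14) ** 2 <= 1.0
    labels[stem & (z < -0.30) & brain] = BRAINSTEM
    cereb = (x / 0.55) ** 2 + ((y + 0.60) / 0.40) ** 2 + ((z + 0.60) / 0.34) ** 2 <= 1.0
    labels[cereb & brain & (labels != BRAINSTEM)] = CEREBELLUM

    atlas = _build_atlas(labels, x, y, z, brain)

    lesion_index: dict[int, Lesion] = {}
    next_id = 1

    # WMH: periventricular, possibly confluent blobs grown from the
    # ventricle surface into white matter.
    if spec.wmh_blobs.count:
        from scipy import ndimage

        peri = ndimage.binary_dilation(labels == CSF, np.ones((3, 3, 3)), iterations=2)
        seeds_allowed = peri & (labels == WM)
        seed_coords = np.argwhere(seeds_allowed)
        if len(seed_coords) == 0:
            raise ValueError("phantom has no periventricular white matter for WMH")
        for _ in range(spec.wmh_blobs.count):
            c = seed_coords[rng.integers(len(seed_coords))]
            r = float(rng.uniform(*spec.wmh_blobs.radius_range))
            vox = c + _ball_offsets(r)
            inb = np.all((vox >= 0) & (vox < np.asarray(shape)), axis=1)
            vox = vox[inb]
            keep = np.isin(labels[tuple(vox.T)], (WM, WMH))
            vox = vox[keep]
            labels[tuple(vox.T)] = WMH
            lesion_index[next_id] = Lesion(next_id, "wmh", vox)
            next_id += 1

    # lacunes: CSF-filled cavities strictly inside white matter, mutually
    # separated so each remains its own connected component.
    if spec.lacunes.count:
        placed = _place_spheres(
            rng, labels == WM, spec.lacunes.count, spec.lacunes.radius_range, 2.0, "lacune"
        )
        for _, vox in placed:
            labels[tuple(vox.T)] = LACUNE
            lesion_index[next_id] = Lesion(next_id, "lacune", vox)
            next_id += 1

    # microbleeds: 1-2 voxel-radius spheres in white matter
    if spec.cmbs.count:
        placed = _place_spheres(
            rng, labels == WM, spec.cmbs.count, spec.cmbs.radius_range, 2.0, "microbleed"
        )
        for _, vox in placed:
            labels[tuple(vox.T)] = CMB
            lesion_index[next_id] = Lesion(next_id, "cmb", vox)
            next_id += 1

    return PhantomTruth(labels=labels, atlas=atlas, voxel_mm=tuple(float(v) for v in voxel_mm), lesion_index=lesion_index)


def _build_atlas(labels, x, y, z, brain) -> np.ndarray:
    """Geometric region atlas over every brain voxel (lesions included)."""
    region = np.full(labels.shape, REGION_CENTRUM_SEMIOVALE, dtype=np.int16)
    region[y > 0.28] = REGION_ANTERIOR_HORN
    region[y < -0.28] = REGION_POSTERIOR_HORN
    region[(z < -0.05) & (np.abs(x) > 0.42)] = REGION_TEMPORAL
    capsule = (np.abs(x) < 0.32) & (np.abs(y) < 0.30) & (z > -0.35) & (z < 0.15)
    region[capsule] = REGION_INTERNAL_CAPSULE
    region[labels == CEREBELLUM] = REGION_CEREBELLUM
    region[labels == BRAINSTEM] = REGION_INTERNAL_CAPSULE

    side = (x > 0).astype(np.int16)  # midline and left half -> left
    atlas = np.zeros(labels.shape, dtype=np.int16)
    atlas[brain] = (region + 6 * side)[brain]
    return atlas
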