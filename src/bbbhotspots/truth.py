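"""Ground-truth permeability maps and Patlak-consistent DCE synthesis.

PS (permeability surface area product, 1/min) and vP (fractional plasma
volume) truth maps are piecewise constant over tissue classes, with planted
high-PS foci: small balls of elevated PS attached to lesion rims, inside
WMH, or at random white-matter locations.  The DCE series is the exact
Patlak forward model C_t(t) = vP*C_p(t) + PS*int_0^t C_p dtau plus optional
i.i.d. Gaussian noise in concentration space.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import phantom as ph
from .vif import VascularInputFunction, cumulative_plasma_integral

ATTACHMENTS = ("lacune_rim", "within_wmh", "wmh_rim", "cmb_rim", "random_wm")

#: default tissue base values in internal units: PS in 1/min,
#: vP dimensionless.  NAWM PS ~0.4e-4 /min and vP ~41e-4 match typical
#: sporadic-SVD white matter; WMH runs slightly leakier.
DEFAULT_BASE_PS = {"nawm": 0.43e-4, "wmh": 0.91e-4, "gm": 1.5e-4, "csf": 0.0, "other": 0.0}
DEFAULT_BASE_VP = {"nawm": 41e-4, "wmh": 62e-4, "gm": 150e-4, "csf": 0.0, "other": 0.0}
#: default planted focus amplitude (1/min): an order of magnitude above the
#: NAWM base so foci land in the top PS decile under realistic noise.
DEFAULT_FOCUS_AMPLITUDE = 5.0e-4


@dataclass(frozen=True)
class FocusSpec:
    """A batch of planted high-PS foci sharing amplitude/radius/attachment."""

    count: int
    amplitude: float = DEFAULT_FOCUS_AMPLITUDE
    radius: float = 2.0
    attach: str = "random_wm"

    def validate(self) -> None:
        if self.count < 0:
            raise ValueError("focus count must be >= 0")
        if self.radius <= 0:
            raise ValueError("focus radius must be > 0")
        if self.attach not in ATTACHMENTS:
            raise ValueError(f"unknown attachment {self.attach!r}; expected one of {ATTACHMENTS}")


@dataclass
class Focus:
    """Ground-truth record of one planted focus."""

    seed_voxel: tuple[int, int, int]
    radius: float
    amplitude: float
    attach: str
    lesion_id: int | None


@dataclass
class TruthMaps:
    """Voxelwise ground-truth PS/vP and the planted-focus index."""

    ps_true: np.ndarray
    vp_true: np.ndarray
    focus_index: list[Focus] = field(default_factory=list)


@dataclass
class DceSeries:
    """4D tissue concentration series, shape (*spatial, n_times), in mM."""

    times: np.ndarray
    conc: np.ndarray
    noise_sd: float


def _tissue_value_map(labels: np.ndarray, base: dict[str, float]) -> np.ndarray:
    for key in ("nawm", "wmh"):
        if key not in base:
            raise ValueError(f"base values must include {key!r}")
    gm = base.get("gm", base["nawm"])
    csf = base.get("csf", 0.0)
    other = base.get("other", 0.0)
    out = np.full(labels.shape, other, dtype=float)
    out[np.isin(labels, (ph.WM, ph.CEREBELLUM, ph.BRAINSTEM, ph.CMB))] = base["nawm"]
    out[labels == ph.WMH] = base["wmh"]
    out[labels == ph.GM] = gm
    out[np.isin(labels, (ph.CSF, ph.LACUNE))] = csf
    return out


def _outer_band(mask: np.ndarray) -> np.ndarray:
    return ndimage.binary_dilation(mask, np.ones((3, 3, 3))) & ~mask


def generate_truth_maps(
    phantom: ph.PhantomTruth,
    base_ps_by_tissue: dict[str, float] | None = None,
    base_vp_by_tissue: dict[str, float] | None = None,
    focus_spec: tuple[FocusSpec, ...] = (),
    seed: int = 0,
    texture_log_sd: float = 0.0,
    texture_scale_vox: float = 1.5,
) -> TruthMaps:
    """Build tissue-wise PS/vP truth maps and plant high-PS foci.

    With ``texture_log_sd = 0`` (default) the maps are piecewise constant
    over tissue classes.  A positive ``texture_log_sd`` multiplies the
    white-matter PS base by a smooth log-normal random field (Gaussian field
    of correlation scale ``texture_scale_vox`` voxels, log-scale SD
    ``texture_log_sd``), emulating the spatially structured permeability of
    real maps while keeping the truth strictly non-negative; without it, a
    per-patient relative decile on near-constant truth is decided by fit
    noise alone, which percolates into implausibly fragmented clusters.

    Each focus then raises PS by ``amplitude`` inside a ball clipped to the
    white-matter-class mask (WM plus WMH); the focus index records the
    ground-truth attachment so downstream recovery can be scored.
    """
    base_ps = dict(DEFAULT_BASE_PS, **(base_ps_by_tissue or {}))
    base_vp = dict(DEFAULT_BASE_VP, **(base_vp_by_tissue or {}))
    labels = phantom.labels
    ps = _tissue_value_map(labels, base_ps)
    vp = _tissue_value_map(labels, base_vp)
    if np.any(vp < 0) or np.any(vp > 1):
        raise ValueError("vp base values must lie in [0, 1]")

    wm_class = np.isin(labels, (ph.WM, ph.WMH))
    rng = np.random.default_rng(seed)
    if texture_log_sd > 0:
        field = ndimage.gaussian_filter(rng.standard_normal(labels.shape), texture_scale_vox)
        sd = field[wm_class].std()
        field = (field - field[wm_class].mean()) / sd * texture_log_sd
        ps = np.where(wm_class, ps * np.exp(field), ps)
    focus_index: list[Focus] = []
    shape = np.asarray(labels.shape)

    for spec in focus_spec:
        spec.validate()
        for _ in range(spec.count):
            lesion_id: int | None = None
            if spec.attach == "random_wm":
                allowed = labels == ph.WM
            elif spec.attach == "within_wmh":
                allowed = labels == ph.WMH
                if not allowed.any():
                    raise ValueError("within_wmh focus requested but phantom has no WMH")
            elif spec.attach == "wmh_rim":
                wmh = labels == ph.WMH
                if not wmh.any():
                    raise ValueError("wmh_rim focus requested but phantom has no WMH")
                allowed = _outer_band(wmh) & (labels == ph.WM)
            elif spec.attach in ("lacune_rim", "cmb_rim"):
                cls = "lacune" if spec.attach == "lacune_rim" else "cmb"
                ids = phantom.lesion_ids(cls)
                if not ids:
                    raise ValueError(f"{spec.attach} focus requested but phantom has no {cls}s")
                lesion_id = int(ids[rng.integers(len(ids))])
                lesion = phantom.lesion_index[lesion_id]
                lmask = np.zeros(labels.shape, dtype=bool)
                lmask[tuple(lesion.voxels.T)] = True
                allowed = _outer_band(lmask) & wm_class
            coords = np.argwhere(allowed)
            if len(coords) == 0:
                raise ValueError(f"no admissible seed voxels for focus attachment {spec.attach!r}")
            c = coords[rng.integers(len(coords))]
            vox = c + ph._ball_offsets(spec.radius)
            inb = np.all((vox >= 0) & (vox < shape), axis=1)
            vox = vox[inb]
            vox = vox[wm_class[tuple(vox.T)]]
            ps[tuple(vox.T)] += spec.amplitude
            focus_index.append(
                Focus(tuple(int(v) for v in c), spec.radius, spec.amplitude, spec.attach, lesion_id)
            )

    if not np.all(np.isfinite(ps)):
        raise ValueError("ps_true contains non-finite values")
    return TruthMaps(ps_true=ps, vp_true=vp, focus_index=focus_index)


def synthesize_dce(
    truth: TruthMaps,
    vif: VascularInputFunction,
    times: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DceSeries:
    """Exact Patlak forward synthesis plus seeded Gaussian noise.

    ``conc[..., k] = vp_true*cp(t_k) + ps_true*int_0^{t_k} cp dtau + eps``
    with ``eps ~ N(0, noise_sd)`` i.i.d. per voxel and frame.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if times is None:
        times = vif.times
    times = np.asarray(times, dtype=float)
    if times.shape != vif.times.shape or not np.allclose(times, vif.times):
        raise ValueError("DCE time axis must match the VIF time axis")
    integral = cumulative_plasma_integral(vif)  # mM*min
    conc = (
        truth.vp_true[..., None] * vif.cp[None, None, None, :]
        + truth.ps_true[..., None] * integral[None, None, None, :]
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        conc = conc + rng.normal(0.0, noise_sd, size=conc.shape)
    return DceSeries(times=times, conc=conc, noise_sd=float(noise_sd))
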