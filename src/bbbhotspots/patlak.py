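"""Voxelwise Patlak estimation of PS and vP from DCE series.

The Patlak graphical model treats each voxel's concentration curve as a
linear combination of the plasma concentration and its running integral:

    C_t(t) = vP * C_p(t) + PS * int_0^t C_p dtau

with no intercept and no backflux term.  PS (1/min) and vP (fraction) are
the ordinary-least-squares coefficients.  Negative estimates are a real
outcome of noise around near-zero truth and are reported unmodified; no
clamping is applied anywhere.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .truth import DceSeries
from .vif import VascularInputFunction, cumulative_plasma_integral

__all__ = [
    "PermeabilityMaps",
    "RoiMetrics",
    "SingularFitError",
    "cumulative_vif_integral",
    "fit_patlak_voxel",
    "map_patlak",
    "roi_means",
]


class SingularFitError(ValueError):
    """The Patlak design matrix is rank-deficient (e.g. all-zero plasma curve)."""


@dataclass
class PermeabilityMaps:
    """Voxelwise PS/vP estimates over the fitted mask.

    ``ps`` and ``vp`` are NaN outside ``fit_mask``; inside, values are raw
    OLS estimates (possibly negative PS, vP outside [0, 1] under noise).
    """

    ps: np.ndarray
    vp: np.ndarray
    fit_mask: np.ndarray
    n_frames_used: int


@dataclass
class RoiMetrics:
    """Mean PS/vP over NAWM and WMH regions of interest (internal units)."""

    ps_mean_nawm: float
    ps_mean_wmh: float
    vp_mean_nawm: float
    vp_mean_wmh: float
    n_nawm: int
    n_wmh: int

    def display_row(self) -> dict[str, float]:
        """Table-style reporting scale: PS and vP multiplied by 1e4."""
        return {
            "ps_mean_nawm_x1e4": self.ps_mean_nawm * 1e4,
            "ps_mean_wmh_x1e4": self.ps_mean_wmh * 1e4,
            "vp_mean_nawm_x1e4": self.vp_mean_nawm * 1e4,
            "vp_mean_wmh_x1e4": self.vp_mean_wmh * 1e4,
            "n_nawm": self.n_nawm,
            "n_wmh": self.n_wmh,
        }


def cumulative_vif_integral(vif: VascularInputFunction) -> np.ndarray:
    """Running integral of the plasma curve, trapezoidal, in mM*min.

    First element is 0 and the sequence is non-decreasing because cp >= 0.
    """
    return cumulative_plasma_integral(vif)


def _frame_window(vif: VascularInputFunction, frame_window: np.ndarray | None) -> np.ndarray:
    if frame_window is None:
        w = vif.times >= vif.arrival_time  # all post-arrival frames
    else:
        frame_window = np.asarray(frame_window)
        if frame_window.dtype == bool:
            w = frame_window
        else:
            w = np.zeros(vif.times.shape, dtype=bool)
            w[frame_window] = True
    if w.sum() < 3:
        raise ValueError("frame window must contain at least 3 frames")
    return w


def _design(vif: VascularInputFunction, window: np.ndarray) -> np.ndarray:
    integral = cumulative_plasma_integral(vif)
    X = np.column_stack([vif.cp[window], integral[window]])
    if np.linalg.matrix_rank(X) < 2:
        raise SingularFitError("Patlak design is singular (plasma curve degenerate in window)")
    return X


def fit_patlak_voxel(
    ct_curve: np.ndarray,
    vif: VascularInputFunction,
    integral: np.ndarray | None = None,
    frame_window: np.ndarray | None = None,
) -> tuple[float, float]:
    """OLS Patlak fit for one voxel; returns ``(ps, vp)`` unmodified.

    The design has two columns, ``[cp(t), int cp]``, and no intercept; vp is
    the cp coefficient, ps the integral coefficient.
    """
    ct_curve = np.asarray(ct_curve, dtype=float)
    if ct_curve.shape != vif.times.shape:
        raise ValueError("ct_curve length must match the VIF time axis")
    w = _frame_window(vif, frame_window)
    X = _design(vif, w)
    beta, *_ = np.linalg.lstsq(X, ct_curve[w], rcond=None)
    vp, ps = beta
    return float(ps), float(vp)


def map_patlak(
    dce: DceSeries,
    vif: VascularInputFunction,
    analysis_mask: np.ndarray,
    frame_window: np.ndarray | None = None,
) -> PermeabilityMaps:
    """Fit the Patlak model at every voxel of ``analysis_mask``.

    Voxels with non-finite curves are dropped from ``fit_mask`` (QC) rather
    than imputed.  The fit is a single shared-design least squares solve, so
    the result is deterministic.
    """
    analysis_mask = np.asarray(analysis_mask, dtype=bool)
    if analysis_mask.shape != dce.conc.shape[:-1]:
        raise ValueError("analysis_mask shape must match the DCE spatial grid")
    if not analysis_mask.any():
        raise ValueError("empty analysis mask")
    if dce.times.shape != vif.times.shape or not np.allclose(dce.times, vif.times):
        raise ValueError("DCE time axis must match the VIF time axis")

    w = _frame_window(vif, frame_window)
    X = _design(vif, w)

    curves = dce.conc[analysis_mask][:, w]  # (n_vox, n_frames)
    finite = np.all(np.isfinite(curves), axis=1)
    beta = np.full((curves.shape[0], 2), np.nan)
    if finite.any():
        sol, *_ = np.linalg.lstsq(X, curves[finite].T, rcond=None)
        beta[finite] = sol.T

    ps = np.full(analysis_mask.shape, np.nan)
    vp = np.full(analysis_mask.shape, np.nan)
    fit_mask = np.zeros(analysis_mask.shape, dtype=bool)
    idx = np.argwhere(analysis_mask)
    ps[tuple(idx.T)] = beta[:, 1]
    vp[tuple(idx.T)] = beta[:, 0]
    fit_mask[tuple(idx[finite].T)] = True
    return PermeabilityMaps(ps=ps, vp=vp, fit_mask=fit_mask, n_frames_used=int(w.sum()))


def roi_means(maps: PermeabilityMaps, nawm_mask: np.ndarray, wmh_mask: np.ndarray) -> RoiMetrics:
    """Arithmetic PS/vP means over ``fit_mask`` intersected with each ROI."""
    out = {}
    counts = {}
    for name, roi in (("nawm", np.asarray(nawm_mask, bool)), ("wmh", np.asarray(wmh_mask, bool))):
        if roi.shape != maps.fit_mask.shape:
            raise ValueError(f"{name} mask shape mismatch")
        sel = roi & maps.fit_mask
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"empty ROI: {name.upper() if name == 'wmh' else 'NAWM'}")
        out[f"ps_mean_{name}"] = float(maps.ps[sel].mean())
        out[f"vp_mean_{name}"] = float(maps.vp[sel].mean())
        counts[name] = n
    return RoiMetrics(
        ps_mean_nawm=out["ps_mean_nawm"],
        ps_mean_wmh=out["ps_mean_wmh"],
        vp_mean_nawm=out["vp_mean_nawm"],
        vp_mean_wmh=out["vp_mean_wmh"],
        n_nawm=counts["nawm"],
        n_wmh=counts["wmh"],
    )
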