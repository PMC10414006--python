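"""Two-arm synthetic cohorts (sporadic SVD vs CADASIL) with known effects.

The generator emulates the structure of a sporadic-SVD / CADASIL DCE-MRI
cohort: arm-dependent age, sex and risk-factor distributions, heavier lesion
burden in the CADASIL arm, and a planted effect linking lower WMH
cerebrovascular reactivity (CVR) to more high-PS foci at lacune rims.  Each
patient bundles a phantom, truth maps, an optional DCE series and a
covariate row; everything derives from one seed.

For regression-recovery experiments that do not need images,
``simulate_regression_records`` draws covariates and hotspot outcomes
directly from the planted logistic / count models.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .phantom import LesionClassSpec, LesionSpec, PhantomTruth, generate_phantom
from .truth import (
    DEFAULT_FOCUS_AMPLITUDE,
    DceSeries,
    FocusSpec,
    TruthMaps,
    generate_truth_maps,
    synthesize_dce,
)
from .vif import VascularInputFunction, generate_vif


@dataclass(frozen=True)
class ArmDistributions:
    """Covariate and lesion-burden distributions for one study arm."""

    age_mean: float
    age_sd: float
    female_p: float
    hypertension_p: float
    diabetes_p: float
    hyperlipidaemia_p: float
    ihd_p: float
    smoking_p: float
    alcohol_p: float
    antiplatelet_p: float
    lacune_mean: float  # Poisson mean
    cmb_mean: float
    wmh_blob_mean: float
    cvr_nawm_mean: float  # on the x1e2 display scale
    cvr_nawm_sd: float
    cvr_wmh_mean: float
    cvr_wmh_sd: float


#: defaults emulate a 69-patient sporadic/CADASIL DCE cohort: CADASIL
#: patients are younger, carry fewer vascular risk factors but a heavier
#: lesion burden and lower WMH CVR.
SPORADIC = ArmDistributions(
    age_mean=63.9, age_sd=10.7, female_p=0.43,
    hypertension_p=0.81, diabetes_p=0.21, hyperlipidaemia_p=0.74, ihd_p=0.17,
    smoking_p=0.50, alcohol_p=0.69, antiplatelet_p=0.95,
    lacune_mean=2.2, cmb_mean=1.0, wmh_blob_mean=3.0,
    cvr_nawm_mean=3.6, cvr_nawm_sd=3.2, cvr_wmh_mean=7.5, cvr_wmh_sd=6.3,
)
CADASIL = ArmDistributions(
    age_mean=52.9, age_sd=11.4, female_p=0.48,
    hypertension_p=0.37, diabetes_p=0.04, hyperlipidaemia_p=0.37, ihd_p=0.04,
    smoking_p=0.52, alcohol_p=0.74, antiplatelet_p=0.59,
    lacune_mean=5.5, cmb_mean=2.2, wmh_blob_mean=6.0,
    cvr_nawm_mean=3.6, cvr_nawm_sd=3.6, cvr_wmh_mean=3.6, cvr_wmh_sd=6.5,
)


@dataclass(frozen=True)
class CohortDesign:
    """Sampling plan for one synthetic cohort."""

    n_patients: int = 69
    proportion_cadasil: float = 27 / 69
    sporadic: ArmDistributions = SPORADIC
    cadasil: ArmDistributions = CADASIL
    image_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    noise_sd: float = 0.01  # mM, concentration-space Gaussian noise
    generate_images: bool = True
    generate_dce: bool = True
    missing_cvr_p: float = 0.09  # ~6/69 patients lack CVR
    #: planted effect: log-odds that a given lacune carries a rim focus,
    #: per 1-unit drop of (display-scale) WMH CVR below its cohort mean
    lacune_focus_base_logodds: float = 0.0
    lacune_focus_cvr_logodds: float = -0.25
    random_foci_mean: float = 6.0
    wmh_foci_mean: float = 1.5
    focus_amplitude: float = DEFAULT_FOCUS_AMPLITUDE
    focus_radius: float = 2.0
    #: smooth log-normal spatial texture on the white-matter PS truth,
    #: emulating the spatial structure of real permeability maps
    ps_texture_log_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        for name, p in (("proportion_cadasil", self.proportion_cadasil), ("missing_cvr_p", self.missing_cvr_p)):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class PatientBundle:
    """One synthetic patient: truth volumes plus the covariate row."""

    patient_id: str
    covariates: dict
    phantom: PhantomTruth | None
    truth: TruthMaps | None
    dce: DceSeries | None
    vif: VascularInputFunction | None


def _fazekas_from_wmh(n_blobs: int) -> tuple[int, int]:
    """Monotone map from WMH burden to (deep, periventricular) Fazekas."""
    dwmh = int(np.clip(n_blobs // 2, 0, 3)) if n_blobs else 0
    pvh = int(np.clip((n_blobs + 1) // 2, 0, 3)) if n_blobs else 0
    return dwmh, pvh


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def sample_cohort(design: CohortDesign) -> list[PatientBundle]:
    """Draw a full cohort; bit-reproducible for a fixed design seed."""
    design.validate()
    rng = np.random.default_rng(design.seed)
    vif = generate_vif() if design.generate_dce else None
    bundles: list[PatientBundle] = []
    cvr_wmh_cohort_mean = (
        design.sporadic.cvr_wmh_mean * (1 - design.proportion_cadasil)
        + design.cadasil.cvr_wmh_mean * design.proportion_cadasil
    )
    for i in range(design.n_patients):
        pseed = int(rng.integers(2**31))
        prng = np.random.default_rng(pseed)
        is_cadasil = bool(prng.random() < design.proportion_cadasil)
        arm = design.cadasil if is_cadasil else design.sporadic

        n_lacunes = int(prng.poisson(arm.lacune_mean))
        n_cmbs = int(prng.poisson(arm.cmb_mean))
        n_wmh = int(prng.poisson(arm.wmh_blob_mean))
        cvr_missing = bool(prng.random() < design.missing_cvr_p)
        cvr_nawm = float(prng.normal(arm.cvr_nawm_mean, arm.cvr_nawm_sd))
        cvr_wmh = float(prng.normal(arm.cvr_wmh_mean, arm.cvr_wmh_sd))
        dwmh, pvh = _fazekas_from_wmh(n_wmh)
        pvs_bg = int(np.clip(prng.integers(1, 4) + is_cadasil, 0, 4))
        pvs_cso = int(np.clip(prng.integers(1, 4) + is_cadasil, 0, 4))

        covariates = {
            "patient_id": f"P{i:03d}",
            "svd_type": "cadasil" if is_cadasil else "sporadic",
            "svd_type_cadasil": int(is_cadasil),
            "age": float(prng.normal(arm.age_mean, arm.age_sd)),
            "female": int(prng.random() < arm.female_p),
            "hypertension": int(prng.random() < arm.hypertension_p),
            "diabetes": int(prng.random() < arm.diabetes_p),
            "hyperlipidaemia": int(prng.random() < arm.hyperlipidaemia_p),
            "ihd": int(prng.random() < arm.ihd_p),
            "smoking": int(prng.random() < arm.smoking_p),
            "alcohol": int(prng.random() < arm.alcohol_p),
            "antiplatelet": int(prng.random() < arm.antiplatelet_p),
            "lacune_count": n_lacunes,
            "cmb_count": n_cmbs,
            "n_wmh_blobs": n_wmh,
            "fazekas_dwmh": dwmh,
            "fazekas_pvh": pvh,
            "pvs_bg": pvs_bg,
            "pvs_cso": pvs_cso,
            "cvr_nawm_x1e2": float("nan") if cvr_missing else cvr_nawm,
            "cvr_wmh_x1e2": float("nan") if cvr_missing else cvr_wmh,
            "seed": pseed,
        }

        phantom = truth = dce = None
        if design.generate_images:
            spec = LesionSpec(
                lacunes=LesionClassSpec(n_lacunes, (1.6, 2.6)),
                wmh_blobs=LesionClassSpec(n_wmh, (2.5, 4.5)),
                cmbs=LesionClassSpec(n_cmbs, (1.0, 2.0)),
            )
            phantom = generate_phantom(design.image_shape, design.voxel_mm, spec, seed=pseed)
            # planted effect: each lacune gets a rim focus with probability
            # driven by the (true, pre-missingness) WMH CVR
            p_rim = _sigmoid(
                design.lacune_focus_base_logodds
                + design.lacune_focus_cvr_logodds * (cvr_wmh - cvr_wmh_cohort_mean)
            )
            n_rim = int(prng.binomial(n_lacunes, p_rim)) if n_lacunes else 0
            focus_spec = []
            if n_rim:
                focus_spec.append(FocusSpec(n_rim, design.focus_amplitude, design.focus_radius, "lacune_rim"))
            n_random = int(prng.poisson(design.random_foci_mean))
            if n_random:
                focus_spec.append(FocusSpec(n_random, design.focus_amplitude, design.focus_radius, "random_wm"))
            n_wmh_foci = int(prng.poisson(design.wmh_foci_mean)) if n_wmh else 0
            if n_wmh_foci:
                focus_spec.append(FocusSpec(n_wmh_foci, design.focus_amplitude, design.focus_radius, "within_wmh"))
            truth = generate_truth_maps(
                phantom,
                focus_spec=tuple(focus_spec),
                seed=pseed + 1,
                texture_log_sd=design.ps_texture_log_sd,
            )
            if design.generate_dce:
                dce = synthesize_dce(truth, vif, noise_sd=design.noise_sd, seed=pseed + 2)
            covariates["n_rim_foci_true"] = n_rim
            covariates["n_random_foci_true"] = n_random

        bundles.append(PatientBundle(covariates["patient_id"], covariates, phantom, truth, dce, vif))
    return bundles


def covariate_table(bundles: list[PatientBundle]) -> pd.DataFrame:
    """Stack per-patient covariate dicts into the cohort CSV frame."""
    if not bundles:
        return pd.DataFrame()
    return pd.DataFrame([b.covariates for b in bundles]).set_index("patient_id")


def simulate_regression_records(
    n: int,
    effect_logodds: float = 0.8,
    base_logodds: float = -0.5,
    count_effect: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Record-level simulation for regression recovery experiments.

    A standardized exposure ``x`` (think: centred WMH CVR) drives hotspot
    presence through a logistic model with the planted log-odds and the
    hotspot count through a Poisson log-linear model; the model-1 adjustment
    covariates are drawn independently so their true effects are null.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n)
    age = rng.normal(60, 12, n)
    log10_wmh_norm = rng.normal(-2.5, 0.5, n)
    lacunes = rng.poisson(3, n)
    cmbs = rng.poisson(1, n)
    cadasil = rng.binomial(1, 0.4, n)
    logit = base_logodds + effect_logodds * x
    presence = rng.binomial(1, 1 / (1 + np.exp(-logit)))
    counts = rng.poisson(np.exp(0.5 + count_effect * x))
    return pd.DataFrame(
        {
            "exposure": x,
            "age": age,
            "log10_wmh_norm": log10_wmh_norm,
            "lacune_count": lacunes,
            "cmb_count": cmbs,
            "svd_type_cadasil": cadasil,
            "hotspot_presence": presence,
            "hotspot_count": counts,
        }
    )
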