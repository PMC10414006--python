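"""End-to-end pipeline: synth -> Patlak -> masks -> hotspots -> colocalization -> stats.

Stages run in dependency order against a single output directory; a stage
whose outputs already exist is skipped, so partial runs resume from disk.
Every run writes its resolved configuration and a manifest listing each
artifact with a content hash, per-stage counters and aggregated warnings.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .cohort import CohortDesign, PatientBundle, covariate_table, sample_cohort
from .colocalization import (
    LesionSet,
    classify_hotspot_set,
    subgroup_eligibility,
    summarize_colocalization,
    _deep_wm_lesion_ids,
)
from .hotspots import detect_hotspots, hotspot_region_counts, regional_load, DEFAULT_LOAD_CUTOFFS
from .masks import build_analysis_masks, volume_metrics
from .patlak import map_patlak, roi_means
from .truth import DceSeries
from .stats import compare_groups, cohort_table as make_cohort_table, total_svd_score

STAGES = ("synth", "patlak", "hotspots", "colocalize", "stats")


@dataclass
class PipelineConfig:
    """Resolved pipeline parameters; defaults reproduce the published rule
    constants (top decile, 5-voxel minimum, one-voxel erosion)."""

    outdir: str = "bbbhotspots_run"
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    n_patients: int = 5
    image_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    noise_sd: float = 0.01
    fraction: float = 0.10
    min_size: int = 5
    connectivity: int = 26
    erosion_kernel: str = "cube"
    include_cerebellum: bool = True
    band_radius: int = 1
    wmh_containment: str = "full"
    nawm_fraction_threshold: float = 0.10
    load_cutoffs: tuple[int, int, int] = DEFAULT_LOAD_CUTOFFS


class ConfigError(ValueError):
    """Invalid configuration; ``errors`` lists every problem found."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


def validate_config(raw: dict) -> PipelineConfig:
    """Build a PipelineConfig from a raw mapping, reporting all problems at once."""
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    errors = [f"unknown config key: {k}" for k in raw if k not in known]
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})
    cfg = dataclasses.replace(
        cfg,
        stages=tuple(cfg.stages),
        image_shape=tuple(cfg.image_shape),
        voxel_mm=tuple(cfg.voxel_mm),
        load_cutoffs=tuple(cfg.load_cutoffs),
    )
    if not 0 < cfg.fraction < 1:
        errors.append(f"fraction must be in (0, 1), got {cfg.fraction}")
    if cfg.min_size < 1:
        errors.append(f"min_size must be >= 1, got {cfg.min_size}")
    if cfg.connectivity not in (6, 18, 26):
        errors.append(f"connectivity must be 6, 18 or 26, got {cfg.connectivity}")
    if cfg.erosion_kernel not in ("cube", "cross"):
        errors.append(f"erosion_kernel must be 'cube' or 'cross', got {cfg.erosion_kernel!r}")
    if cfg.band_radius < 1:
        errors.append(f"band_radius must be >= 1, got {cfg.band_radius}")
    if not 0 <= cfg.nawm_fraction_threshold <= 1:
        errors.append(f"nawm_fraction_threshold must be in [0, 1], got {cfg.nawm_fraction_threshold}")
    if cfg.n_patients < 0:
        errors.append(f"n_patients must be >= 0, got {cfg.n_patients}")
    if any(s < 32 for s in cfg.image_shape):
        errors.append(f"image_shape axes must be >= 32, got {cfg.image_shape}")
    if cfg.noise_sd < 0:
        errors.append(f"noise_sd must be >= 0, got {cfg.noise_sd}")
    unknown_stages = [s for s in cfg.stages if s not in STAGES]
    if unknown_stages:
        errors.append(f"unknown stages: {unknown_stages}")
    if errors:
        raise ConfigError(errors)
    return cfg


def run_pipeline(config: PipelineConfig | dict) -> dict:
    """Execute the configured stages; returns the run manifest."""
    if isinstance(config, dict):
        config = validate_config(config)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(dataclasses.asdict(config)))

    manifest: dict = {"stages": {}, "warnings": [], "artifacts": {}}
    patient_ids = [f"P{i:03d}" for i in range(config.n_patients)]

    if "synth" in config.stages:
        _stage_synth(config, out, manifest)
    if "patlak" in config.stages:
        _stage_patlak(config, out, patient_ids, manifest)
    if "hotspots" in config.stages:
        _stage_hotspots(config, out, patient_ids, manifest)
    if "colocalize" in config.stages:
        _stage_colocalize(config, out, patient_ids, manifest)
    if "stats" in config.stages:
        _stage_stats(config, out, patient_ids, manifest)

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["artifacts"][str(p.relative_to(out))] = pio.sha256_file(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _pdir(out: Path, pid: str) -> Path:
    d = out / pid
    d.mkdir(exist_ok=True)
    return d


def _stage_synth(config: PipelineConfig, out: Path, manifest: dict) -> None:
    cov_path = out / "covariates.csv"
    if cov_path.exists():
        manifest["stages"]["synth"] = {"skipped": True}
        return
    design = CohortDesign(
        n_patients=config.n_patients,
        image_shape=config.image_shape,
        voxel_mm=config.voxel_mm,
        noise_sd=config.noise_sd,
        seed=config.seed,
    )
    bundles = sample_cohort(design)
    for b in bundles:
        d = _pdir(out, b.patient_id)
        pio.save_nifti(d / "labels.nii.gz", b.phantom.labels, config.voxel_mm)
        pio.save_nifti(d / "atlas.nii.gz", b.phantom.atlas, config.voxel_mm)
        pio.save_nifti(d / "ps_true.nii.gz", b.truth.ps_true, config.voxel_mm)
        pio.save_nifti(d / "vp_true.nii.gz", b.truth.vp_true, config.voxel_mm)
        pio.save_nifti(d / "dce.nii.gz", b.dce.conc.astype(np.float32), config.voxel_mm)
        lesions = [
            {"id": l.id, "class": l.lesion_class, "voxels": l.voxels.tolist()}
            for l in b.phantom.lesion_index.values()
        ]
        (d / "lesions.json").write_text(json.dumps(lesions))
    if bundles:
        pio.save_vif(out / "vif.csv", bundles[0].vif)
    covariate_table(bundles).to_csv(cov_path)
    (out / "truth_manifest.json").write_text(
        json.dumps({"seed": config.seed, "n_patients": config.n_patients,
                    "foci": {b.patient_id: [dataclasses.asdict(f) for f in b.truth.focus_index]
                             for b in bundles}}, default=str)
    )
    manifest["stages"]["synth"] = {"n_patients": len(bundles)}


def _load_phantom_lesions(d: Path, shape) -> tuple[np.ndarray, np.ndarray]:
    lesions = json.loads((d / "lesions.json").read_text())
    lacunes = np.zeros(shape, np.int32)
    cmbs = np.zeros(shape, np.int32)
    for l in lesions:
        vox = np.asarray(l["voxels"], dtype=int)
        if not len(vox):
            continue
        if l["class"] == "lacune":
            lacunes[tuple(vox.T)] = l["id"]
        elif l["class"] == "cmb":
            cmbs[tuple(vox.T)] = l["id"]
    return lacunes, cmbs


def _stage_patlak(config, out: Path, patient_ids, manifest) -> None:
    vif = pio.load_vif(out / "vif.csv")
    n_done = 0
    n_singular = 0
    for pid in patient_ids:
        d = _pdir(out, pid)
        if (d / "ps.nii.gz").exists():
            continue
        if not (d / "dce.nii.gz").exists():
            raise FileNotFoundError(f"patlak stage: missing input {d / 'dce.nii.gz'}")
        labels, voxel_mm = pio.load_nifti(d / "labels.nii.gz")
        am = build_analysis_masks(labels, kernel=config.erosion_kernel,
                                  include_cerebellum=config.include_cerebellum)
        conc, _ = pio.load_nifti(d / "dce.nii.gz")
        dce = DceSeries(times=vif.times, conc=np.asarray(conc, dtype=float), noise_sd=config.noise_sd)
        maps = map_patlak(dce, vif, am.wm_eroded)
        n_singular += int(am.wm_eroded.sum() - maps.fit_mask.sum())
        pio.save_nifti(d / "ps.nii.gz", maps.ps.astype(np.float64), voxel_mm)
        pio.save_nifti(d / "vp.nii.gz", maps.vp.astype(np.float64), voxel_mm)
        pio.save_nifti(d / "fit_mask.nii.gz", maps.fit_mask.astype(np.uint8), voxel_mm)
        wmh_fit = am.wmh & am.wm_eroded & maps.fit_mask
        if wmh_fit.any():
            metrics_row = roi_means(maps, am.nawm & am.wm_eroded, wmh_fit).display_row()
        else:  # no analysable WMH in this patient
            nawm_fit = am.nawm & am.wm_eroded & maps.fit_mask
            metrics_row = {
                "ps_mean_nawm_x1e4": float(maps.ps[nawm_fit].mean()) * 1e4,
                "ps_mean_wmh_x1e4": np.nan,
                "vp_mean_nawm_x1e4": float(maps.vp[nawm_fit].mean()) * 1e4,
                "vp_mean_wmh_x1e4": np.nan,
                "n_nawm": int(nawm_fit.sum()),
                "n_wmh": 0,
            }
            manifest["warnings"].append(f"patlak: {pid} has no WMH voxels in the analysis mask")
        vols = volume_metrics(labels, voxel_mm)
        row = {"patient_id": pid, **metrics_row, "icv_ml": vols.icv_ml, "wmh_ml": vols.wmh_ml,
               "wmh_normalized": vols.wmh_normalized,
               "log10_wmh_norm": vols.log10_wmh_normalized if vols.wmh_ml > 0 else np.nan,
               "volume_note": "" if vols.wmh_ml > 0 else "log10 WMH volume undefined (zero WMH)"}
        pd.DataFrame([row]).to_csv(d / "roi_metrics.csv", index=False)
        n_done += 1
    if n_singular:
        manifest["warnings"].append(f"patlak: {n_singular} voxels dropped from fit masks")
    manifest["stages"]["patlak"] = {"n_patients": n_done}


def _stage_hotspots(config, out: Path, patient_ids, manifest) -> None:
    n_done = 0
    for pid in patient_ids:
        d = _pdir(out, pid)
        if (d / "hotspots.csv").exists():
            continue
        if not (d / "ps.nii.gz").exists():
            raise FileNotFoundError(f"hotspots stage: missing input {d / 'ps.nii.gz'}")
        ps, voxel_mm = pio.load_nifti(d / "ps.nii.gz")
        fit_mask, _ = pio.load_nifti(d / "fit_mask.nii.gz")
        atlas, _ = pio.load_nifti(d / "atlas.nii.gz")
        hs = detect_hotspots(np.asarray(ps, float), np.asarray(fit_mask, bool), np.asarray(atlas),
                             voxel_mm=voxel_mm, fraction=config.fraction,
                             min_size=config.min_size, connectivity=config.connectivity)
        label_map = np.zeros(np.asarray(ps).shape, np.int32)
        rows = []
        for h in hs.hotspots:
            label_map[tuple(h.voxels.T)] = h.id
            rows.append({"hotspot_id": h.id, "size": h.size,
                         "centroid_x_mm": h.centroid_mm[0], "centroid_y_mm": h.centroid_mm[1],
                         "centroid_z_mm": h.centroid_mm[2], "region": h.region_name,
                         "side": h.side_name, "mean_ps": h.mean_ps})
        pio.save_nifti(d / "hotspot_labels.nii.gz", label_map, voxel_mm)
        pd.DataFrame(rows, columns=["hotspot_id", "size", "centroid_x_mm", "centroid_y_mm",
                                    "centroid_z_mm", "region", "side", "mean_ps"]).to_csv(
            d / "hotspots.csv", index=False)
        load = regional_load(hotspot_region_counts(hs), cutoffs=config.load_cutoffs)
        summary = {"patient_id": pid, "n_hotspots": hs.count, "threshold_value": hs.threshold_value,
                   "n_mask_voxels": hs.n_mask_voxels, "n_selected_voxels": hs.n_selected_voxels,
                   "load_cutoffs": "/".join(map(str, config.load_cutoffs)), **load.as_dict()}
        pd.DataFrame([summary]).to_csv(d / "hotspot_summary.csv", index=False)
        n_done += 1
    manifest["stages"]["hotspots"] = {"n_patients": n_done}


def _stage_colocalize(config, out: Path, patient_ids, manifest) -> None:
    cov = pd.read_csv(out / "covariates.csv").set_index("patient_id")
    tables, eligibility, lesion_counts = {}, {}, {}
    for pid in patient_ids:
        d = _pdir(out, pid)
        if not (d / "hotspot_labels.nii.gz").exists():
            raise FileNotFoundError(f"colocalize stage: missing input {d / 'hotspot_labels.nii.gz'}")
        labels, _ = pio.load_nifti(d / "labels.nii.gz")
        hot_labels, _ = pio.load_nifti(d / "hotspot_labels.nii.gz")
        lacunes, cmbs = _load_phantom_lesions(d, labels.shape)
        from . import phantom as ph

        lesions = LesionSet(lacunes=lacunes, wmh=np.asarray(labels) == ph.WMH, cmbs=cmbs)
        am = build_analysis_masks(labels, kernel=config.erosion_kernel,
                                  include_cerebellum=config.include_cerebellum)
        # rebuild hotspot voxel sets from the label map
        from .hotspots import Hotspot, HotspotSet

        hs_list = []
        for lab in np.unique(hot_labels):
            if lab == 0:
                continue
            vox = np.argwhere(hot_labels == lab)
            hs_list.append(Hotspot(int(lab), vox, len(vox), (0, 0, 0), 0, 0, float("nan")))
        hs = HotspotSet(hs_list, float("nan"), 0, 0)
        table = classify_hotspot_set(hs, lesions, band_radius=config.band_radius,
                                     wmh_containment=config.wmh_containment)
        table.to_frame().to_csv(d / "colocalization.csv", index=False)
        row = cov.loc[pid]
        elig = subgroup_eligibility(lesions, am, int(row["fazekas_dwmh"]), int(row["fazekas_pvh"]),
                                    nawm_fraction_threshold=config.nawm_fraction_threshold)
        tables[pid] = table
        eligibility[pid] = elig
        lesion_counts[pid] = {
            "lacunes": len(_deep_wm_lesion_ids(lacunes, am.wm_eroded_filled)),
            "cmbs": len(_deep_wm_lesion_ids(cmbs, am.wm_eroded_filled)),
        }
        per_patient = {"patient_id": pid, **elig,
                       **{f"n_{c}": table.count(c) for c in
                          ("at_lacune_edge", "within_wmh", "at_wmh_edge", "at_cmb_edge")},
                       **{f"has_{c}": int(table.presence(c)) for c in
                          ("at_lacune_edge", "within_wmh", "at_wmh_edge", "at_cmb_edge")}}
        pd.DataFrame([per_patient]).to_csv(d / "colocalization_summary.csv", index=False)
    summary = summarize_colocalization(tables, eligibility, lesion_counts)
    summary.to_csv(out / "colocalization_cohort.csv", index=False)
    manifest["stages"]["colocalize"] = {"n_patients": len(tables)}


def _stage_stats(config, out: Path, patient_ids, manifest) -> None:
    cov = pd.read_csv(out / "covariates.csv").set_index("patient_id")
    rows = []
    for pid in patient_ids:
        d = out / pid
        row = cov.loc[pid].to_dict()
        row["patient_id"] = pid
        for name in ("roi_metrics", "hotspot_summary", "colocalization_summary"):
            p = d / f"{name}.csv"
            if p.exists():
                row.update(pd.read_csv(p).iloc[0].to_dict())
        row["total_svd_score"] = total_svd_score(
            int(row["lacune_count"]), int(row["cmb_count"]),
            int(row["fazekas_dwmh"]), int(row["fazekas_pvh"]), int(row["pvs_bg"]))
        rows.append(row)
    records = pd.DataFrame(rows).set_index("patient_id")
    records.to_csv(out / "patient_records.csv")

    variables = {"age": "continuous", "female": "binary", "hypertension": "binary",
                 "lacune_count": "ordinal", "cmb_count": "ordinal",
                 "fazekas_dwmh": "ordinal", "total_svd_score": "ordinal",
                 "n_hotspots": "continuous"}
    variables = {k: v for k, v in variables.items() if k in records.columns}
    table1 = make_cohort_table(records, variables, group="svd_type")
    table1.to_csv(out / "table1.csv")
    comparisons = []
    if records["svd_type"].nunique() > 1:
        for var, kind in variables.items():
            try:
                c = compare_groups(records, var, "svd_type", kind=kind)
                comparisons.append({"variable": var, "test": c.test, "statistic": c.statistic, "p": c.p})
            except ValueError as exc:
                manifest["warnings"].append(f"stats: {var}: {exc}")
    pd.DataFrame(comparisons).to_csv(out / "group_comparisons.csv", index=False)
    manifest["stages"]["stats"] = {"n_patients": len(records)}
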