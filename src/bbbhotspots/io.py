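"""NIfTI / CSV / JSON I/O helpers shared by the pipeline stages."""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .vif import VascularInputFunction


def save_nifti(path: Path, array: np.ndarray, voxel_mm: tuple[float, float, float]) -> None:
    affine = np.diag([*voxel_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(array), affine)
    nib.save(img, str(path))


def load_nifti(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    voxel_mm = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), voxel_mm


def save_vif(path: Path, vif: VascularInputFunction) -> None:
    pd.DataFrame({"time_s": vif.times, "cp_mM": vif.cp}).to_csv(path, index=False)
    meta = Path(path).with_suffix(".json")
    meta.write_text(json.dumps({"arrival_time_s": vif.arrival_time}))


def load_vif(path: Path) -> VascularInputFunction:
    df = pd.read_csv(path)
    meta = json.loads(Path(path).with_suffix(".json").read_text())
    return VascularInputFunction(
        times=df["time_s"].to_numpy(),
        cp=df["cp_mM"].to_numpy(),
        arrival_time=float(meta["arrival_time_s"]),
    )


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
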