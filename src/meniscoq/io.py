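"""Format adapters: NIfTI-1 images, JSON landmarks/sidecars, CSV tables.

All image I/O goes through nibabel with affines preserved; JSON landmark
files store world millimetres (never voxel indices); tables are plain
comma-separated UTF-8 with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import GeometryError, SchemaError
from .phantom import LandmarkSet
from .relaxometry import MultiEchoVolume, ParameterMaps

_LANDMARK_FIELDS = (
    "anterior_horn_mm",
    "posterior_horn_mm",
    "tibial_plateau_margin_mm",
    "meniscal_body_peripheral_mm",
    "coronal_reference_index",
    "medial_direction",
)


def _voxel_size_from_affine(affine: np.ndarray) -> tuple[float, float, float]:
    return tuple(np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0)))


def check_same_geometry(affine_a: np.ndarray, affine_b: np.ndarray,
                        what: str = "images") -> None:
    if not np.allclose(affine_a, affine_b, atol=1e-6):
        raise GeometryError(
            f"{what} have mismatched affines:\n{np.asarray(affine_a)}\nvs\n{np.asarray(affine_b)}"
        )


def write_multiecho(vol: MultiEchoVolume, nifti_path: str | Path,
                    sidecar_path: str | Path | None = None,
                    seed: int | None = None) -> None:
    """Write the 4-D (x, y, z, echo) volume plus a JSON echo-time sidecar."""
    nifti_path = Path(nifti_path)
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), vol.affine), nifti_path)
    sidecar = Path(sidecar_path) if sidecar_path else nifti_path.with_name(
        nifti_path.name.split(".")[0] + "_te.json")
    payload = {"te_ms": list(map(float, vol.te_ms)),
               "voxel_size_mm": list(map(float, vol.voxel_size_mm))}
    if seed is not None:
        payload["seed"] = int(seed)
    sidecar.write_text(json.dumps(payload, indent=2))


def read_multiecho(nifti_path: str | Path, te_path: str | Path) -> MultiEchoVolume:
    img = nib.load(str(nifti_path))
    meta = json.loads(Path(te_path).read_text())
    if "te_ms" not in meta:
        raise SchemaError("echo-time sidecar is missing field 'te_ms'")
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 4:
        raise GeometryError(f"{nifti_path}: expected a 4-D multi-echo volume")
    return MultiEchoVolume(
        data=data,
        te_ms=np.asarray(meta["te_ms"], dtype=float),
        voxel_size_mm=_voxel_size_from_affine(img.affine),
        affine=np.asarray(img.affine),
    )


def write_labels(labels: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(labels).astype(np.int16), affine), Path(path))


def read_mask(path: str | Path, reference_affine: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Load a label/mask image; optionally enforce geometry agreement."""
    img = nib.load(str(path))
    if reference_affine is not None:
        check_same_geometry(img.affine, reference_affine, what=f"{path} and reference volume")
    return np.asanyarray(img.dataobj), np.asarray(img.affine)


_MAP_FILES = {"t2star_ms": "t2star.nii.gz", "s0": "s0.nii.gz",
              "nrmse": "nrmse.nii.gz", "converged": "converged.nii.gz"}


def write_maps(maps: ParameterMaps, out_dir: str | Path) -> dict:
    """Write S0/T2*/NRMSE/converged maps plus a JSON fit report; returns the report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for attr, fname in _MAP_FILES.items():
        arr = getattr(maps, attr)
        dtype = np.uint8 if attr == "converged" else np.float32
        nib.save(nib.Nifti1Image(arr.astype(dtype), maps.affine), out / fname)
    fitted = int(maps.converged.sum())
    report = {
        "voxels_fitted": fitted,
        "voxels_failed": int(maps.n_failed),
        "median_nrmse": float(np.median(maps.nrmse[maps.converged])) if fitted else None,
    }
    (out / "fit_report.json").write_text(json.dumps(report, indent=2))
    return report


def read_maps(map_dir: str | Path) -> ParameterMaps:
    d = Path(map_dir)
    arrays, affine = {}, None
    for attr, fname in _MAP_FILES.items():
        img = nib.load(str(d / fname))
        if affine is None:
            affine = np.asarray(img.affine)
        else:
            check_same_geometry(img.affine, affine, what=f"{fname} and other maps")
        arrays[attr] = np.asanyarray(img.dataobj).astype(
            bool if attr == "converged" else float)
    return ParameterMaps(
        t2star_ms=arrays["t2star_ms"], s0=arrays["s0"], nrmse=arrays["nrmse"],
        converged=arrays["converged"],
        voxel_size_mm=_voxel_size_from_affine(affine), affine=affine,
    )


def write_landmarks(lm: LandmarkSet, path: str | Path) -> None:
    payload = {
        "anterior_horn_mm": {s: list(map(float, v)) for s, v in lm.anterior_horn_mm.items()},
        "posterior_horn_mm": {s: list(map(float, v)) for s, v in lm.posterior_horn_mm.items()},
        "tibial_plateau_margin_mm": list(map(float, lm.tibial_plateau_margin_mm)),
        "meniscal_body_peripheral_mm": list(map(float, lm.meniscal_body_peripheral_mm)),
        "coronal_reference_index": int(lm.coronal_reference_index),
        "medial_direction": list(map(float, lm.medial_direction)),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_landmarks(path: str | Path) -> LandmarkSet:
    data = json.loads(Path(path).read_text())
    for f in _LANDMARK_FIELDS:
        if f not in data:
            raise SchemaError(f"landmark file {path} is missing field {f!r}")
    for horn in ("anterior_horn_mm", "posterior_horn_mm"):
        for side in ("medial", "lateral"):
            if side not in data[horn]:
                raise SchemaError(f"landmark file {path}: {horn} is missing side {side!r}")
    return LandmarkSet(
        anterior_horn_mm={s: np.asarray(v, float) for s, v in data["anterior_horn_mm"].items()},
        posterior_horn_mm={s: np.asarray(v, float) for s, v in data["posterior_horn_mm"].items()},
        tibial_plateau_margin_mm=np.asarray(data["tibial_plateau_margin_mm"], float),
        meniscal_body_peripheral_mm=np.asarray(data["meniscal_body_peripheral_mm"], float),
        coronal_reference_index=int(data["coronal_reference_index"]),
        medial_direction=np.asarray(data["medial_direction"], float),
    )


def write_region_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(Path(path), index=False)


def read_region_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
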