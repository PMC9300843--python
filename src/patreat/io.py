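"""Readers and writers for volumes, masks and cohort tables.

Scenes are stored as paired single/multi-page TIFF (or NIfTI) volumes
named ``<scene>_<wavelength>nm.<ext>`` plus a YAML metadata sidecar
``<scene>.yaml`` holding wavelengths (nm), voxel spacing (mm), the
identity of the depth axis, the generator seed and a spec echo.  ROI
masks and truth maps are same-shaped volumes with a suffix.  Cohort and
feature tables are plain CSV (comma-separated, UTF-8, header row,
missing values empty).
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile
import yaml

from .errors import AlignmentError, ValidationError
from .volumes import PAVolumePair

__all__ = [
    "write_volume",
    "read_volume",
    "write_volume_pair",
    "read_volume_pair",
    "write_scene",
    "write_sidecar",
    "read_sidecar",
]


def _ext(fmt: str) -> str:
    if fmt == "tiff":
        return ".tif"
    if fmt == "nifti":
        return ".nii"
    raise ValidationError("format must be 'tiff' or 'nifti'")


def write_volume(array: np.ndarray, path: str | Path) -> None:
    """Write a 3D array as multi-page TIFF (.tif) or NIfTI (.nii/.nii.gz)."""
    path = Path(path)
    arr = np.asarray(array)
    if path.suffix == ".tif":
        tifffile.imwrite(path, arr.astype(np.float32))
    elif path.suffix in (".nii", ".gz"):
        nib.save(nib.Nifti1Image(arr.astype(np.float32), affine=np.eye(4)), path)
    else:
        raise ValidationError(f"unsupported volume extension {path.suffix!r}")


def read_volume(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".tif":
        return np.asarray(tifffile.imread(path), dtype=float)
    if path.suffix in (".nii", ".gz"):
        return np.asarray(nib.load(path).get_fdata(), dtype=float)
    raise ValidationError(f"unsupported volume extension {path.suffix!r}")


def write_sidecar(path: str | Path, meta: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_sidecar(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ValidationError(
            f"metadata sidecar {path} is required but missing"
        )
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def write_volume_pair(
    pair: PAVolumePair, directory: str | Path, name: str, fmt: str = "tiff"
) -> dict[str, Path]:
    """Write both amplitude volumes and the sidecar; returns written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ext = _ext(fmt)
    wl_lo, wl_hi = pair.wavelengths
    p_lo = directory / f"{name}_{int(wl_lo)}nm{ext}"
    p_hi = directory / f"{name}_{int(wl_hi)}nm{ext}"
    write_volume(pair.vol_lo, p_lo)
    write_volume(pair.vol_hi, p_hi)
    sidecar = directory / f"{name}.yaml"
    write_sidecar(
        sidecar,
        {
            "wavelengths_nm": [float(wl_lo), float(wl_hi)],
            "voxel_spacing_mm": [float(s) for s in pair.voxel_spacing],
            "depth_axis": int(pair.depth_axis),
            "shape": [int(n) for n in pair.shape],
            "format": fmt,
            "meta": _yaml_safe(pair.meta),
        },
    )
    return {"lo": p_lo, "hi": p_hi, "sidecar": sidecar}


def read_volume_pair(
    path_lo: str | Path, path_hi: str | Path, sidecar: str | Path
) -> PAVolumePair:
    """Load a co-registered pair; shapes and declared wavelengths are checked."""
    meta = read_sidecar(sidecar)
    for key in ("wavelengths_nm", "voxel_spacing_mm", "depth_axis"):
        if key not in meta:
            raise ValidationError(f"sidecar missing required key {key!r}")
    lo = read_volume(path_lo)
    hi = read_volume(path_hi)
    if lo.shape != hi.shape:
        raise AlignmentError(f"volume shapes differ: {lo.shape} vs {hi.shape}")
    if "shape" in meta and tuple(meta["shape"]) != lo.shape:
        raise AlignmentError("sidecar shape does not match the volumes")
    return PAVolumePair(
        lo,
        hi,
        wavelengths=tuple(float(w) for w in meta["wavelengths_nm"]),
        voxel_spacing=tuple(float(s) for s in meta["voxel_spacing_mm"]),
        depth_axis=int(meta["depth_axis"]),
        meta=dict(meta.get("meta") or {}),
    )


def write_scene(scene, directory: str | Path, name: str, fmt: str = "tiff") -> dict:
    """Write a synthetic scene: amplitude pair, ROI mask and truth maps."""
    paths = write_volume_pair(scene.volumes, directory, name, fmt=fmt)
    directory = Path(directory)
    ext = _ext(fmt)
    extra = {
        "roi": (f"{name}_roi{ext}", scene.roi_mask.astype(np.uint8)),
        "truth_chbo2": (f"{name}_truth_chbo2{ext}", scene.truth_chbo2),
        "truth_chb": (f"{name}_truth_chb{ext}", scene.truth_chb),
        "truth_sto2": (f"{name}_truth_sto2{ext}", scene.truth_sto2),
    }
    for key, (fname, arr) in extra.items():
        p = directory / fname
        write_volume(arr, p)
        paths[key] = p
    return paths


def _yaml_safe(obj):
    """Coerce numpy scalars/containers into plain YAML-serializable types."""
    if isinstance(obj, dict):
        return {str(k): _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
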