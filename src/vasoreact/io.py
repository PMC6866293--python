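"""File formats and configuration.

NIfTI-1 is the on-disk container for volumes (RAS+ affine, TR stored in the
standard time-step header slot); cohort tables are UTF-8 comma-separated CSV
with a mandatory header row; nested reports are JSON. All writes are atomic
(temp file in the target directory, then rename).
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .core import StimulusParadigm, Volume4D

__all__ = [
    "read_volume4d",
    "write_volume4d",
    "read_map3d",
    "write_map3d",
    "paradigm_to_config",
    "paradigm_from_config",
    "read_yaml",
    "atomic_write_text",
    "write_json",
]

_PARADIGM_KEYS = {
    "n_blocks": "n_blocks",
    "stim_duration_s": "stim_duration",
    "rest_duration_s": "rest_duration",
    "tr_s": "tr",
    "flicker_hz": "flicker_rate",
}


def _ras_affine(voxel_size: float = 3.0) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size
    return aff


def write_volume4d(vol: Volume4D, path: str | Path, mask_path: str | Path | None = None) -> None:
    """Write a 4-D run (and optionally its mask) as NIfTI-1, TR in pixdim[4]."""
    img = nib.Nifti1Image(vol.data.astype(np.float64), _ras_affine())
    img.header.set_xyzt_units("mm", "sec")
    zooms = list(img.header.get_zooms())
    zooms[3] = vol.tr
    img.header.set_zooms(zooms)
    _atomic_nifti_save(img, path)
    if mask_path is not None:
        write_map3d(vol.mask.astype(np.uint8), mask_path)


def read_volume4d(path: str | Path, mask_path: str | Path | None = None) -> Volume4D:
    """Read a 4-D NIfTI run; TR comes from the time-step header field."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D image, got {data.ndim}-D")
    tr = float(img.header.get_zooms()[3])
    if tr <= 0:
        raise ValueError(f"{path}: non-positive TR in header")
    if mask_path is not None:
        mask = read_map3d(mask_path).astype(bool)
    else:
        mask = np.ones(data.shape[:3], dtype=bool)
    return Volume4D(data=data, mask=mask, tr=tr)


def write_map3d(values: np.ndarray, path: str | Path) -> None:
    values = np.asarray(values)
    if values.ndim != 3:
        raise ValueError("expected a 3-D map")
    img = nib.Nifti1Image(values.astype(np.float64), _ras_affine())
    _atomic_nifti_save(img, path)


def read_map3d(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image, got {data.ndim}-D")
    return data


def _atomic_nifti_save(img: nib.Nifti1Image, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix="".join(path.suffixes))
    os.close(fd)
    try:
        nib.save(img, tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def paradigm_to_config(paradigm: StimulusParadigm) -> dict:
    """Flat config mapping with the canonical key names."""
    return {
        "n_blocks": paradigm.n_blocks,
        "stim_duration_s": paradigm.stim_duration,
        "rest_duration_s": paradigm.rest_duration,
        "tr_s": paradigm.tr,
        "flicker_hz": paradigm.flicker_rate,
    }


def paradigm_from_config(cfg: dict) -> StimulusParadigm:
    kwargs = {}
    for key, attr in _PARADIGM_KEYS.items():
        if key in cfg:
            kwargs[attr] = cfg[key]
    unknown = set(cfg) - set(_PARADIGM_KEYS)
    if unknown:
        raise ValueError(f"unknown paradigm keys: {sorted(unknown)}")
    return StimulusParadigm(**kwargs)


def read_yaml(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


def atomic_write_text(text: str, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent)
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_json(obj, path: str | Path) -> None:
    atomic_write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", path)
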