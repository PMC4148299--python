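"""Thin NIfTI/TSV/JSON I/O helpers shared by the pipeline stages."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np


def save_nifti(data: np.ndarray, affine: np.ndarray, path) -> None:
    img = nib.Nifti1Image(np.asarray(data), affine)
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")


def write_json(payload: dict, path) -> None:
    Path(path).write_text(
        json.dumps(payload, indent=1, sort_keys=True, default=_jsonable)
    )


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def read_motion(path, n_volumes: int | None = None) -> np.ndarray:
    motion = np.loadtxt(str(path))
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion file {path} must have 6 columns")
    if n_volumes is not None and motion.shape[0] != n_volumes:
        raise ValueError(
            f"motion file {path} has {motion.shape[0]} rows, expected {n_volumes}"
        )
    return motion
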