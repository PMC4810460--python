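"""NIfTI / TSV / YAML input-output for runs, masks, maps and tables."""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .ica import BOLDRun, GroupSpatialMaps

logger = logging.getLogger(__name__)


def read_mask(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 3D mask; non-binary values are binarized with a warning."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"mask must be 3D, got {data.ndim}D: {path}")
    uniq = np.unique(data)
    if not np.all(np.isin(uniq, (0, 1))):
        warnings.warn(f"mask {path} is not binary; binarizing at > 0")
    return data > 0, img.affine


def read_run(path, mask: np.ndarray, tr: float | None = None,
             subject: str | None = None, affine: np.ndarray | None = None
             ) -> BOLDRun:
    """Load a 4D run and apply the mask, yielding a time x voxel matrix."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"run must be 4D, got {data.ndim}D: {path}")
    if data.shape[:3] != mask.shape:
        raise ValueError(f"run grid {data.shape[:3]} does not match mask {mask.shape}")
    if tr is None:
        tr = float(img.header.get_zooms()[3]) or 2.0
    flat = data.reshape(-1, data.shape[3])[mask.ravel()]
    return BOLDRun(data=flat.T, tr=tr, subject=subject or Path(path).stem,
                   mask_index=np.flatnonzero(mask.ravel()),
                   shape3d=mask.shape, affine=img.affine)


def write_run(path, run: BOLDRun, mask: np.ndarray,
              affine: np.ndarray | None = None) -> None:
    """Write a masked run back to a 4D NIfTI (zeros outside the mask)."""
    vol = np.zeros((mask.size, run.n_volumes))
    vol[mask.ravel()] = run.data.T
    img = nib.Nifti1Image(vol.reshape(*mask.shape, run.n_volumes),
                          affine if affine is not None else np.eye(4))
    img.header.set_zooms((*img.header.get_zooms()[:3], run.tr))
    nib.save(img, str(path))


def write_mask(path, mask: np.ndarray, affine: np.ndarray | None = None) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8),
                             affine if affine is not None else np.eye(4)), str(path))


def write_maps(path, maps: np.ndarray, mask: np.ndarray,
               affine: np.ndarray | None = None) -> None:
    """Write (C, V) maps as a 4D NIfTI with component as the 4th axis."""
    vol = np.zeros((mask.size, maps.shape[0]))
    vol[mask.ravel()] = maps.T
    nib.save(nib.Nifti1Image(vol.reshape(*mask.shape, maps.shape[0]),
                             affine if affine is not None else np.eye(4)), str(path))


def read_maps(path, mask: np.ndarray) -> GroupSpatialMaps:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("maps file must be 4D (component as 4th axis)")
    flat = data.reshape(-1, data.shape[3])[mask.ravel()]
    return GroupSpatialMaps(maps=flat.T)


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(str(path), sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t")


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_manifest(path, entries: dict) -> None:
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True, default=str)
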