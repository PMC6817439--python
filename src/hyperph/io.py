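"""Disk formats: NIfTI scalar maps, FidGrid containers, CSV tables.

Scalar per-voxel maps travel as NIfTI-1 with a JSON sidecar carrying the
quantities NIfTI cannot (noise level, thresholds, QC counts).  Raw CSI
data is a ``.npy`` complex array plus a JSON sidecar of the acquisition
parameters — a documented, portable container for spatio-spectral data
that has no standard interchange format.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .cohort import AcquisitionParams, FidGrid

__all__ = [
    "save_map_nifti",
    "load_map_nifti",
    "save_fid_grid",
    "load_fid_grid",
]


def _affine(spacing_mm) -> np.ndarray:
    aff = np.eye(4)
    for i, s in enumerate(np.atleast_1d(spacing_mm)[:3]):
        aff[i, i] = s
    return aff


def save_map_nifti(values: np.ndarray, path: str | Path,
                   spacing_mm=(1.0, 1.0, 1.0),
                   sidecar: dict | None = None) -> Path:
    """Write a scalar map to NIfTI (float64) with an optional JSON sidecar."""
    path = Path(path)
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[..., None]
    nib.save(nib.Nifti1Image(arr, _affine(spacing_mm)), str(path))
    if sidecar is not None:
        with open(path.with_suffix("").with_suffix(".json"), "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return path


def load_map_nifti(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a scalar map and its JSON sidecar (empty dict if absent)."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.squeeze(np.asarray(img.dataobj, dtype=np.float64))
    sidecar_path = path.with_suffix("").with_suffix(".json")
    sidecar = {}
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            sidecar = json.load(fh)
    return data, sidecar


def save_fid_grid(fid: FidGrid, stem: str | Path) -> Path:
    """Write raw CSI data as ``<stem>.npy`` + ``<stem>.json`` sidecar."""
    stem = Path(stem)
    np.save(stem.with_suffix(".npy"), fid.data)
    params = dataclasses.asdict(fid.params)
    sidecar = {"params": params,
               "reference_frequencies": fid.reference_frequencies}
    with open(stem.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return stem.with_suffix(".npy")


def load_fid_grid(stem: str | Path) -> FidGrid:
    """Read a FidGrid written by :func:`save_fid_grid`."""
    stem = Path(stem)
    data = np.load(stem.with_suffix(".npy"))
    with open(stem.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    raw = sidecar["params"]
    for key in ("csi_matrix", "grase_matrix", "dwi_matrix", "b_values",
                "volume_fov_mm"):
        raw[key] = tuple(raw[key])
    params = AcquisitionParams(**raw)
    return FidGrid(data=data, params=params,
                   reference_frequencies=sidecar["reference_frequencies"])
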