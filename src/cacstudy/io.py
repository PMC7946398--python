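"""Volume and sidecar I/O: NIfTI images with JSON metadata."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from cacstudy.phantom_forge import PhantomVolume


def _affine(spacing) -> np.ndarray:
    dx, dy, dz = spacing
    return np.diag([dx, dy, dz, 1.0])


def save_volume(path: Path, volume: np.ndarray, spacing, meta: dict | None = None, dtype=np.float32) -> None:
    """Write a (nz, ny, nx) volume as NIfTI (x, y, z order) plus sidecar."""
    path = Path(path)
    data = np.ascontiguousarray(np.transpose(volume, (2, 1, 0)).astype(dtype))
    nib.save(nib.Nifti1Image(data, _affine(spacing)), str(path))
    if meta is not None:
        sidecar = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" else path.with_suffix(".json")
        sidecar.write_text(json.dumps(meta, indent=2, default=_jsonable))


def load_volume(path: Path) -> tuple[np.ndarray, tuple]:
    """Read a NIfTI volume back into (nz, ny, nx) order with spacing."""
    img = nib.load(str(path))
    data = np.transpose(np.asarray(img.dataobj), (2, 1, 0))
    dx, dy, dz = img.header.get_zooms()[:3]
    return data, (float(dx), float(dy), float(dz))


def save_phantom(path: Path, phantom: PhantomVolume) -> None:
    """mu + labels volumes with an insert-table sidecar."""
    path = Path(path)
    spacing = phantom.grid.spacing
    save_volume(path.with_name(path.stem + "_mu.nii"), phantom.mu, spacing)
    save_volume(path.with_name(path.stem + "_labels.nii"), phantom.labels, spacing, dtype=np.int16)
    meta = {
        "grid": dataclasses.asdict(phantom.grid),
        "rod_radius": phantom.rod_radius,
        "inserts": [dataclasses.asdict(i) for i in phantom.inserts],
        "gap": dataclasses.asdict(phantom.gap) if phantom.gap else None,
    }
    path.with_name(path.stem + ".json").write_text(json.dumps(meta, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    return str(obj)
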