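"""NIfTI volume I/O with sidecar JSON metadata.

Volumes travel as NIfTI-1 with an isotropic-scaled affine; series and map
metadata (axis values, units, provenance) live in a JSON sidecar next to
the image so no information is lost through a write/read round trip.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .relaxometry import EchoSeries, ParameterMap

__all__ = [
    "read_volume",
    "write_volume",
    "read_series",
    "write_series",
    "read_parameter_map",
    "write_parameter_map",
]


def _sidecar(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def write_volume(volume: np.ndarray, path, voxel_size: float = 1.0, meta: dict | None = None) -> None:
    """Write a 3-D/4-D array as NIfTI; optional metadata to a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine)
    nib.save(img, str(path))
    if meta is not None:
        _sidecar(path).write_text(json.dumps(meta, indent=2, default=float))


def read_volume(path) -> tuple[np.ndarray, float, dict]:
    """Read a NIfTI volume; returns (data, voxel_size, metadata)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0]):
        raise ValueError(f"{path}: anisotropic voxels {zooms} are not supported")
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    return np.asarray(img.dataobj, dtype=np.float64), float(zooms[0]), meta


def check_same_geometry(a_path, b_path, a, b) -> None:
    if a.shape != b.shape:
        raise ValueError(
            f"geometry mismatch between {a_path} {a.shape} and {b_path} {b.shape}"
        )


def write_series(series: EchoSeries, path) -> None:
    """EchoSeries -> NIfTI (x, y, z, points) + sidecar with the axis."""
    vol = np.moveaxis(series.volumes, 0, -1)
    write_volume(
        vol,
        path,
        voxel_size=series.voxel_size,
        meta={
            "axis_kind": series.axis_kind,
            "axis_values": list(map(float, series.axis_values)),
        },
    )


def read_series(path) -> EchoSeries:
    data, voxel_size, meta = read_volume(path)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D series")
    if "axis_values" not in meta or "axis_kind" not in meta:
        raise ValueError(f"{path}: missing axis_kind/axis_values sidecar metadata")
    return EchoSeries(
        np.moveaxis(data, -1, 0), np.asarray(meta["axis_values"]), meta["axis_kind"], voxel_size
    )


def write_parameter_map(pmap: ParameterMap, path, voxel_size: float = 1.0) -> None:
    write_volume(
        pmap.values,
        path,
        voxel_size=voxel_size,
        meta={"units": pmap.units, "provenance": pmap.provenance},
    )
    mask_path = Path(str(path).replace(".nii", "_mask.nii", 1))
    write_volume(pmap.valid_mask.astype(np.float64), mask_path, voxel_size=voxel_size)


def read_parameter_map(path) -> ParameterMap:
    data, _, meta = read_volume(path)
    mask_path = Path(str(path).replace(".nii", "_mask.nii", 1))
    if mask_path.exists():
        mask = read_volume(mask_path)[0] > 0.5
    else:
        mask = np.ones_like(data, dtype=bool)
    return ParameterMap(
        data, meta.get("units", ""), mask, meta.get("provenance", {})
    )
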