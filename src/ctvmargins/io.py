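"""Reading and writing masks and planar contours.

Volumes go through SimpleITK, whose physical-space model (LPS patient
coordinates, direction matrix with index-axis columns) matches this package's
:class:`~ctvmargins.geometry.BinaryVolume` exactly. Supported containers are
NIfTI (``.nii``/``.nii.gz``) and NRRD (``.nrrd``); any non-zero voxel reads as
foreground, and masks are written as unsigned 8-bit 0/1.

Planar contours use a small JSON format that any RT-STRUCT converter can emit::

    {"slices": [{"z": -12.5, "polygons": [[[x0, y0], [x1, y1], ...], ...]},
                ...]}

with all coordinates in patient (LPS) mm; ``z`` is the axial plane position.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .geometry import BinaryVolume

__all__ = [
    "read_mask",
    "write_mask",
    "write_probability_map",
    "read_contours",
    "write_contours",
]


def _volume_from_image(img: sitk.Image) -> BinaryVolume:
    arr = sitk.GetArrayFromImage(img)  # indexed [k, j, i]
    occ = np.ascontiguousarray(arr.transpose(2, 1, 0)) != 0
    directions = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    return BinaryVolume(
        occupancy=occ,
        spacing=np.asarray(img.GetSpacing(), dtype=float),
        origin=np.asarray(img.GetOrigin(), dtype=float),
        axis_directions=directions,
    )


def _image_from_array(arr: np.ndarray, vol: BinaryVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    img.SetDirection(tuple(float(d) for d in vol.axis_directions.ravel()))
    return img


def read_mask(path: str | Path) -> BinaryVolume:
    """Read a binary mask from a NIfTI or NRRD file (non-zero = foreground)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    return _volume_from_image(sitk.ReadImage(str(path)))


def write_mask(vol: BinaryVolume, path: str | Path) -> None:
    """Write a mask as unsigned 8-bit 0/1 (format chosen by file extension)."""
    sitk.WriteImage(_image_from_array(vol.occupancy.astype(np.uint8), vol), str(path))


def write_probability_map(
    probabilities: np.ndarray, grid: BinaryVolume, path: str | Path
) -> None:
    """Write a voxel-wise probability map (e.g. a STAPLE posterior) as float32."""
    sitk.WriteImage(_image_from_array(probabilities.astype(np.float32), grid), str(path))


def read_contours(path: str | Path) -> list[tuple[float, list[np.ndarray]]]:
    """Read planar contours from the JSON format documented in this module."""
    with open(path) as fh:
        data = json.load(fh)
    slices = []
    for rec in data["slices"]:
        polygons = [np.asarray(p, dtype=float) for p in rec["polygons"]]
        slices.append((float(rec["z"]), polygons))
    return slices


def write_contours(
    slices: list[tuple[float, list[np.ndarray]]], path: str | Path
) -> None:
    """Write planar contours to the JSON format documented in this module."""
    data = {
        "slices": [
            {"z": float(z), "polygons": [np.asarray(p, float).tolist() for p in polys]}
            for z, polys in slices
        ]
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)
        fh.write("\n")
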