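"""Voxel-grid geometry: binary masks with physical coordinates.

Coordinate conventions
----------------------
Patient coordinates are **LPS** (+x Left, +y Posterior, +z Superior), in
millimetres — the dominant convention in radiotherapy imaging and the native
convention of ITK/SimpleITK, which this package uses for file I/O.

A :class:`BinaryVolume` stores a boolean occupancy value per voxel index
``(i, j, k)`` together with the affine index→physical mapping

    physical = origin + axis_directions @ (spacing * index)

where ``axis_directions`` is orthonormal (its columns are the patient-space
unit vectors of the three index axes) and ``origin`` is the physical position
of the *center* of voxel ``(0, 0, 0)``.

Sub-voxel occupancy is defined by trilinear interpolation of the 0/1 voxel
values; a point is *inside* when its interpolated occupancy is >= 0.5, and
points beyond the outermost voxel centers interpolate against background 0.
This gives the caster sub-voxel boundary localisation: on an axis-aligned
face the 0.5 level sits exactly midway between the last foreground and first
background voxel centers, i.e. on the physical face of the voxelised solid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import binary_erosion, generate_binary_structure, map_coordinates

from .errors import (
    DegenerateContourError,
    EmptyVolumeError,
    GeometryMismatchError,
    LabelParseError,
)

__all__ = [
    "BinaryVolume",
    "DirectionSpec",
    "SurfacePointSet",
    "OccupancySampler",
    "direction_from_label",
    "extract_surface",
    "occupancy_at",
    "rasterize_contours",
]

#: Tolerance (mm) within which two grids are considered identical.
GRID_TOL_MM = 1e-6

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class BinaryVolume:
    """A 3D binary mask on a regular grid with physical geometry.

    Parameters
    ----------
    occupancy
        Boolean array indexed ``[i, j, k]``.
    spacing
        Voxel size in mm along each index axis; all components > 0.
    origin
        Physical (LPS, mm) position of the center of voxel ``(0, 0, 0)``.
    axis_directions
        3x3 orthonormal matrix whose *columns* map index axes to patient
        axes. Defaults to the identity (index axes aligned with LPS).
    """

    occupancy: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    axis_directions: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.ndim != 3:
            raise ValueError(f"occupancy must be 3D, got ndim={occ.ndim}")
        if occ.dtype != bool:
            occ = occ.astype(bool)
        spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        directions = np.asarray(self.axis_directions, dtype=float).reshape(3, 3)
        if not np.all(spacing > 0):
            raise ValueError(f"spacing must be positive, got {spacing}")
        if not np.allclose(directions.T @ directions, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("axis_directions must be orthonormal")
        object.__setattr__(self, "occupancy", occ)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axis_directions", directions)

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape  # type: ignore[return-value]

    @property
    def n_foreground(self) -> int:
        return int(self.occupancy.sum())

    @property
    def physical_diagonal_mm(self) -> float:
        """Length of the grid's physical diagonal (ray-marching cap)."""
        return float(np.linalg.norm(self.spacing * np.asarray(self.shape)))

    def index_to_physical(self, index: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) index coordinates to physical mm."""
        idx = np.asarray(index, dtype=float)
        return self.origin + (idx * self.spacing) @ self.axis_directions.T

    def physical_to_index(self, point: np.ndarray) -> np.ndarray:
        """Map physical mm coordinates to fractional index coordinates."""
        p = np.asarray(point, dtype=float)
        return ((p - self.origin) @ self.axis_directions) / self.spacing

    def voxel_centers(self) -> np.ndarray:
        """Physical centers of all voxels, shape ``(*shape, 3)``."""
        idx = np.stack(
            np.meshgrid(*(np.arange(n) for n in self.shape), indexing="ij"), axis=-1
        )
        return self.index_to_physical(idx)

    # -- compatibility ------------------------------------------------------

    def is_compatible(self, other: "BinaryVolume", tol: float = GRID_TOL_MM) -> bool:
        """True when both volumes live on the same physical grid."""
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.axis_directions, other.axis_directions, atol=tol)
        )

    def with_occupancy(self, occupancy: np.ndarray) -> "BinaryVolume":
        """A new volume on the same grid with different voxel values."""
        return BinaryVolume(occupancy, self.spacing, self.origin, self.axis_directions)


def require_compatible(*volumes: BinaryVolume, names: Sequence[str] | None = None) -> None:
    """Raise :class:`GeometryMismatchError` unless all volumes share a grid."""
    if len(volumes) < 2:
        return
    ref = volumes[0]
    labels = list(names) if names else [f"volume[{i}]" for i in range(len(volumes))]
    for vol, label in zip(volumes[1:], labels[1:]):
        if not ref.is_compatible(vol):
            raise GeometryMismatchError(
                f"{labels[0]} and {label} are not on the same grid "
                f"(shape {ref.shape} vs {vol.shape}, spacing {ref.spacing} vs "
                f"{vol.spacing}, origin {ref.origin} vs {vol.origin})"
            )


@dataclass(frozen=True)
class DirectionSpec:
    """A labeled unit direction in patient (LPS) coordinates.

    ``route_class`` tags the clinical route of spread the direction probes
    (e.g. ``"intraosseous"`` or ``"extraosseous"``); any string is accepted.
    """

    label: str
    vector: np.ndarray
    route_class: str = "unspecified"

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("direction label must be non-empty")
        v = np.asarray(self.vector, dtype=float).reshape(3)
        norm = float(np.linalg.norm(v))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"direction vector must be unit length, |v|={norm}")
        object.__setattr__(self, "vector", v)

    @classmethod
    def from_vector(
        cls, vector: Iterable[float], label: str = "custom", route_class: str = "unspecified"
    ) -> "DirectionSpec":
        """Build a spec from an arbitrary non-zero vector (normalised here)."""
        v = np.asarray(list(vector), dtype=float).reshape(3)
        norm = float(np.linalg.norm(v))
        if norm == 0.0:
            raise ValueError("direction vector must be non-zero")
        return cls(label, v / norm, route_class)

    @classmethod
    def from_label(cls, label: str, route_class: str = "unspecified") -> "DirectionSpec":
        """Build a spec from an anatomical label such as ``"SA"``."""
        return cls(label, direction_from_label(label), route_class)


# Anatomical axis tokens in LPS: +x Left, +y Posterior, +z Superior.
_TOKEN_VECTORS = {
    "R": np.array([-1.0, 0.0, 0.0]),
    "L": np.array([1.0, 0.0, 0.0]),
    "A": np.array([0.0, -1.0, 0.0]),
    "P": np.array([0.0, 1.0, 0.0]),
    "S": np.array([0.0, 0.0, 1.0]),
    "I": np.array([0.0, 0.0, -1.0]),
}
_OPPOSITES = {("R", "L"), ("A", "P"), ("S", "I")}


def direction_from_label(label: str) -> np.ndarray:
    """Unit vector for an anatomical direction label.

    Labels are concatenations or hyphenations of the tokens R, L, A, P, S, I
    (e.g. ``"L"``, ``"SA"``, ``"superior-anterior"`` is *not* accepted — use
    the initials). Compound labels are the normalised sum of their axes:
    ``"SA"`` -> (0, -1, 1)/sqrt(2) in LPS.
    """
    tokens = [t for part in label.split("-") for t in part.strip().upper()]
    if not tokens:
        raise LabelParseError(f"empty direction label {label!r}")
    for t in tokens:
        if t not in _TOKEN_VECTORS:
            raise LabelParseError(f"unknown anatomical token {t!r} in label {label!r}")
    present = set(tokens)
    for a, b in _OPPOSITES:
        if a in present and b in present:
            raise LabelParseError(f"label {label!r} combines opposing tokens {a} and {b}")
    v = np.sum([_TOKEN_VECTORS[t] for t in tokens], axis=0)
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class SurfacePointSet:
    """Boundary voxels of a mask: physical centers plus their indices.

    A voxel is a surface voxel when it is foreground and at least one of its
    six face neighbours is background or lies outside the grid.
    """

    points: np.ndarray  # (n, 3) physical mm
    source_indices: np.ndarray  # (n, 3) integer voxel indices

    def __len__(self) -> int:
        return len(self.points)


_FACE_STRUCTURE = generate_binary_structure(3, 1)


def extract_surface(vol: BinaryVolume) -> SurfacePointSet:
    """Surface voxels of ``vol`` under 6-connectivity.

    Raises :class:`EmptyVolumeError` for an all-background mask.
    """
    occ = vol.occupancy
    if not occ.any():
        raise EmptyVolumeError("cannot extract the surface of an empty mask")
    interior = binary_erosion(occ, _FACE_STRUCTURE, border_value=0)
    surface = occ & ~interior
    indices = np.argwhere(surface)
    return SurfacePointSet(points=vol.index_to_physical(indices), source_indices=indices)


class OccupancySampler:
    """Trilinear occupancy interpolator for one volume.

    Precomputes the float view of the mask once so repeated queries (the ray
    caster issues thousands) stay cheap. Outside the outermost voxel centers
    the interpolation blends toward background 0.
    """

    def __init__(self, vol: BinaryVolume):
        self._vol = vol
        self._values = vol.occupancy.astype(np.float64)

    def at_index(self, index_pts: np.ndarray) -> np.ndarray:
        """Occupancy at fractional index coordinates, shape ``(n, 3)`` -> ``(n,)``."""
        pts = np.asarray(index_pts, dtype=float)
        return map_coordinates(
            self._values, pts.T, order=1, mode="grid-constant", cval=0.0, prefilter=False
        )

    def at_physical(self, points: np.ndarray) -> np.ndarray:
        return self.at_index(self._vol.physical_to_index(points))


def occupancy_at(vol: BinaryVolume, point: np.ndarray) -> float | np.ndarray:
    """Trilinear occupancy of ``vol`` at physical point(s), in [0, 1].

    ``point`` may be a single (3,) coordinate or an ``(n, 3)`` array. A point
    is *inside* when the returned value is >= 0.5.
    """
    p = np.asarray(point, dtype=float)
    single = p.ndim == 1
    values = OccupancySampler(vol).at_physical(p.reshape(-1, 3))
    return float(values[0]) if single else values


# -- planar-contour rasterization ------------------------------------------


def _points_in_polygon(px: np.ndarray, py: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Even–odd (crossing-number) containment test, vectorised over points.

    Points exactly on an edge follow the half-open crossing rule, which is
    deterministic; callers needing strict-interior semantics should avoid
    placing query points on polygon edges.
    """
    inside = np.zeros(px.shape, dtype=bool)
    x0, y0 = poly[:, 0], poly[:, 1]
    x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
    for ex0, ey0, ex1, ey1 in zip(x0, y0, x1, y1):
        if ey0 == ey1:
            continue  # horizontal edges never cross a horizontal ray
        crosses = (ey0 > py) != (ey1 > py)
        with np.errstate(invalid="ignore"):
            x_at = ex0 + (py - ey0) * (ex1 - ex0) / (ey1 - ey0)
        inside ^= crosses & (px < x_at)
    return inside


def rasterize_contours(
    slices: Sequence[tuple[float, Sequence[np.ndarray]]],
    grid: BinaryVolume,
) -> BinaryVolume:
    """Rasterize closed planar polygons onto the grid of ``grid``.

    ``slices`` is a sequence of ``(plane_position_mm, polygons)`` records.
    Contours are axial: each polygon is an ``(m, 2)`` array of patient
    ``(x, y)`` mm vertices lying at patient ``z = plane_position_mm``, and
    each plane must map onto exactly one slice index of the grid (within half
    a slice thickness). A voxel becomes foreground when its center lies
    inside an odd number of that slice's polygons (even–odd rule), so a hole
    is expressed as a second polygon inside the first.
    """
    occ = np.zeros(grid.shape, dtype=bool)
    nz = grid.shape[2]
    per_slice: dict[int, list[np.ndarray]] = {}
    for plane_pos, polygons in slices:
        for poly in polygons:
            arr = np.asarray(poly, dtype=float)
            if arr.ndim != 2 or arr.shape[0] < 3 or arr.shape[1] != 2:
                raise DegenerateContourError(
                    f"polygon on plane {plane_pos} mm must be (m>=3, 2), got {arr.shape}"
                )
        if not len(polygons):
            continue
        # map every vertex into index space; the slice index must be unique
        verts3 = np.concatenate(
            [
                np.column_stack([np.asarray(p, float), np.full(len(p), plane_pos)])
                for p in polygons
            ]
        )
        idx = grid.physical_to_index(verts3)
        k = int(np.round(np.mean(idx[:, 2])))
        if k < 0 or k >= nz or np.any(np.abs(idx[:, 2] - k) > 0.5 + 1e-9):
            raise GeometryMismatchError(
                f"plane position {plane_pos} mm does not match a single slice "
                f"of the grid (nearest index {k})"
            )
        offset = 0
        for poly in polygons:
            m = len(poly)
            per_slice.setdefault(k, []).append(idx[offset : offset + m, :2])
            offset += m
    ii, jj = np.meshgrid(
        np.arange(grid.shape[0], dtype=float),
        np.arange(grid.shape[1], dtype=float),
        indexing="ij",
    )
    for k, polys in per_slice.items():
        inside = np.zeros(ii.shape, dtype=bool)
        for poly_idx in polys:
            inside ^= _points_in_polygon(ii, jj, poly_idx)
        occ[:, :, k] = inside
    return grid.with_occupancy(occ)
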