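"""Phantoms with known ground truth for the margin pipeline.

The generators build a GTV analytically (a distance-function test at voxel
centers), derive the CTV from a direction-dependent analytic expansion of the
same function — never from morphological dilation, so the true geometry is
exact in mm and independent of grid resolution — and record, per requested
direction, the *expected directional margin*: the analytic prediction of the
median expansion-vector length under the casting algorithm.

For curved surfaces that prediction is **not** the applied expansion: rays
from obliquely oriented surface patches are longer than the face-on gap, so
the ensemble median of a sphere of radius r expanded isotropically by m is

    M = sqrt((r + m)^2 - 0.75 r^2) - r / 2     (> m),

the length at median obliquity |cos theta| = 1/2. Flat-faced phantoms (slabs,
boxes with per-face offsets probed along their face normals) have all vector
lengths equal, so there the expected margin *is* the applied offset. Both
kinds of truth are recorded so recovery tests have exact references.

Expert ensembles perturb a true margin with truncated-normal noise (the
simplest noise model that keeps margins non-negative) and expand the GTV by
each drawn margin using the exact Euclidean distance transform.

What these phantoms do not emulate: imaging appearance, realistic bone
anatomy, spatially correlated expert disagreement, or contour smoothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.stats import truncnorm

from .errors import ClearanceError, InsufficientExpertsError
from .geometry import BinaryVolume, DirectionSpec

__all__ = [
    "PhantomSpec",
    "Phantom",
    "make_phantom",
    "make_expert_ensemble",
    "example_specs",
    "expected_sphere_margin",
    "expected_ellipsoid_axis_margin",
]

_AXIS_LABELS = {  # LPS axis directions used as default probes
    0: ("L", "R"),
    1: ("P", "A"),
    2: ("S", "I"),
}


def expected_sphere_margin(radius_mm: float, expansion_mm: float) -> float:
    """Analytic median vector length for an isotropically expanded sphere."""
    r, m = float(radius_mm), float(expansion_mm)
    return math.sqrt((r + m) ** 2 - 0.75 * r**2) - 0.5 * r


def expected_ellipsoid_axis_margin(
    radius_mm: float,
    semi_axes_mm: tuple[float, float, float],
    axis: int,
    n_polar: int = 720,
    n_azimuth: int = 360,
) -> float:
    """Continuum median vector length along a principal axis.

    GTV: sphere of radius r; CTV: co-centered ellipsoid with the given
    semi-axes. Surface points are integrated on a uniform area measure
    (uniform in cos(theta) x phi); each ray parallel to the axis runs from
    the sphere to its first ellipsoid exit.
    """
    r = float(radius_mm)
    semi = np.asarray(semi_axes_mm, dtype=float)
    o = [i for i in range(3) if i != axis]
    u = np.linspace(-1.0, 1.0, n_polar, endpoint=False) + 1.0 / n_polar
    phi = np.linspace(0.0, 2.0 * np.pi, n_azimuth, endpoint=False)
    uu, pp = np.meshgrid(u, phi, indexing="ij")
    rho = r * np.sqrt(1.0 - uu**2)
    y = rho * np.cos(pp)
    z = rho * np.sin(pp)
    q = 1.0 - (y / semi[o[0]]) ** 2 - (z / semi[o[1]]) ** 2
    ok = q > 0.0
    lengths = semi[axis] * np.sqrt(q[ok]) - np.sqrt(
        np.maximum(r**2 - rho[ok] ** 2, 0.0)
    )
    return float(np.median(lengths))


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one phantom.

    gtv_shape
        ``"sphere"`` (size = radius), ``"slab"`` (size = thickness along x,
        spanning the grid laterally), ``"box"`` (size = edge lengths) or
        ``"u_shape"`` (size = outer box edges; a slot opening toward +y is
        carved out, leaving two prongs joined at a base).
    expansion
        ``{"isotropic": m}``, ``{"per_axis": (a, b, c)}`` (sphere only:
        CTV is the co-centered ellipsoid with semi-axes r+a, r+b, r+c) or
        ``{"per_face": {"+x": ..., "-x": ..., ...}}`` (box/slab/u_shape:
        each face plane is offset outward by its own amount).
    barrier
        Optional ``{"halfspace": {"normal": (nx, ny, nz), "offset_mm": c}}``;
        the barrier mask occupies ``n . p >= c``.
    directions
        Probe directions recorded in the truth table. Defaults to the six
        axis directions.
    """

    gtv_shape: str
    size_mm: tuple[float, ...]
    expansion: dict
    spacing_mm: tuple[float, float, float] = (0.5, 0.5, 0.5)
    padding_mm: float = 3.0
    barrier: Optional[dict] = None
    directions: tuple[DirectionSpec, ...] = ()
    seed: int = 0


@dataclass(frozen=True)
class Phantom:
    """A generated phantom plus its analytic truth.

    ``truth`` maps each probe direction's label to the expected directional
    margin in mm, or ``None`` when the direction is expected to be barrier-
    affected (its accepted ensemble is not analytically clean).
    ``expected_interior_rejections`` lists labels whose casts must reject
    some rays for GTV-interior crossing (concave phantoms).
    """

    gtv: BinaryVolume
    ctv: BinaryVolume
    truth: dict[str, Optional[float]]
    directions: tuple[DirectionSpec, ...]
    barrier: Optional[BinaryVolume] = None
    expected_interior_rejections: tuple[str, ...] = ()
    spec: Optional[PhantomSpec] = field(default=None, repr=False)


def _axis_directions() -> tuple[DirectionSpec, ...]:
    labels = [lab for pair in _AXIS_LABELS.values() for lab in pair]
    return tuple(DirectionSpec.from_label(lab) for lab in labels)


def _grid(lo: np.ndarray, hi: np.ndarray, spacing: np.ndarray):
    """Voxel centers covering [lo, hi] with half-voxel crossings on lo/hi.

    The grid start is snapped to a multiple of the spacing so that flat
    phantom faces placed at multiples of the spacing fall exactly midway
    between voxel centers (the trilinear 0.5 level).
    """
    start = np.floor(lo / spacing) * spacing
    n = np.ceil((hi - start) / spacing).astype(int) + 1
    origin = start + 0.5 * spacing
    centers = [origin[a] + spacing[a] * np.arange(n[a]) for a in range(3)]
    X, Y, Z = np.meshgrid(*centers, indexing="ij")
    return tuple(int(v) for v in n), origin, (X, Y, Z)


def _check_clearance(ctv: BinaryVolume, spanning_axes: tuple[int, ...] = ()) -> None:
    occ = ctv.occupancy
    for a in range(3):
        if a in spanning_axes:
            continue
        first = [slice(None)] * 3
        last = [slice(None)] * 3
        first[a] = 0
        last[a] = occ.shape[a] - 1
        if occ[tuple(first)].any() or occ[tuple(last)].any():
            raise ClearanceError(
                f"expanded CTV reaches the grid boundary along axis {a}; "
                "increase padding or grid size"
            )


def _per_face(expansion: dict) -> dict[str, float]:
    faces = {"+x": 0.0, "-x": 0.0, "+y": 0.0, "-y": 0.0, "+z": 0.0, "-z": 0.0}
    if "isotropic" in expansion:
        m = float(expansion["isotropic"])
        return {k: m for k in faces}
    faces.update({k: float(v) for k, v in expansion["per_face"].items()})
    return faces


def _face_margin_for(direction: DirectionSpec, faces: dict[str, float]) -> Optional[float]:
    """Expected margin along an axis-aligned probe of a per-face box."""
    v = direction.vector
    axis = int(np.argmax(np.abs(v)))
    if abs(abs(v[axis]) - 1.0) > 1e-12:
        return None  # oblique probes of a box have no single-face truth
    sign = "+" if v[axis] > 0 else "-"
    return faces[sign + "xyz"[axis]]


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Build the GTV/CTV pair (and barrier) described by ``spec``."""
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    pad = float(spec.padding_mm)
    directions = spec.directions or _axis_directions()
    builder = {
        "sphere": _build_sphere,
        "slab": _build_box,
        "box": _build_box,
        "u_shape": _build_u_shape,
    }.get(spec.gtv_shape)
    if builder is None:
        raise ValueError(f"unknown phantom shape {spec.gtv_shape!r}")
    phantom = builder(spec, spacing, pad, directions)
    if spec.barrier is not None:
        half = spec.barrier["halfspace"]
        n_vec = np.asarray(half["normal"], dtype=float)
        n_vec = n_vec / np.linalg.norm(n_vec)
        offset = float(half["offset_mm"])
        X, Y, Z = _centers_of(phantom.gtv)
        barrier_occ = (X * n_vec[0] + Y * n_vec[1] + Z * n_vec[2]) >= offset
        barrier = phantom.gtv.with_occupancy(barrier_occ)
        truth = dict(phantom.truth)
        for d in directions:
            if float(d.vector @ n_vec) > 1e-9:
                truth[d.label] = None  # rays head into the barrier half-space
        phantom = Phantom(
            gtv=phantom.gtv,
            ctv=phantom.ctv,
            truth=truth,
            directions=phantom.directions,
            barrier=barrier,
            expected_interior_rejections=phantom.expected_interior_rejections,
            spec=spec,
        )
    return phantom


def _centers_of(vol: BinaryVolume):
    centers = [
        vol.origin[a] + vol.spacing[a] * np.arange(vol.shape[a]) for a in range(3)
    ]
    return np.meshgrid(*centers, indexing="ij")


def _build_sphere(spec, spacing, pad, directions) -> Phantom:
    (r,) = spec.size_mm
    if "per_axis" in spec.expansion:
        exc = np.asarray(spec.expansion["per_axis"], dtype=float)
    else:
        exc = np.full(3, float(spec.expansion["isotropic"]))
    semi = r + exc
    ext = semi.max() + pad
    _, origin, (X, Y, Z) = _grid(np.full(3, -ext), np.full(3, ext), spacing)
    gtv_occ = X**2 + Y**2 + Z**2 <= r**2
    ctv_occ = (X / semi[0]) ** 2 + (Y / semi[1]) ** 2 + (Z / semi[2]) ** 2 <= 1.0
    gtv = BinaryVolume(gtv_occ, spacing, origin)
    ctv = gtv.with_occupancy(ctv_occ)
    _check_clearance(ctv)
    isotropic = bool(np.all(exc == exc[0]))
    truth: dict[str, Optional[float]] = {}
    for d in directions:
        if isotropic:
            truth[d.label] = expected_sphere_margin(r, float(exc[0]))
        else:
            axis = int(np.argmax(np.abs(d.vector)))
            if abs(abs(d.vector[axis]) - 1.0) <= 1e-12:
                truth[d.label] = expected_ellipsoid_axis_margin(r, tuple(semi), axis)
            else:
                truth[d.label] = None
    return Phantom(gtv=gtv, ctv=ctv, truth=truth, directions=directions, spec=spec)


def _build_box(spec, spacing, pad, directions) -> Phantom:
    if spec.gtv_shape == "slab":
        (thickness,) = spec.size_mm
        half = np.array([thickness / 2.0, np.inf, np.inf])
    else:
        half = np.asarray(spec.size_mm, dtype=float) / 2.0
    faces = _per_face(spec.expansion)
    plus = np.array([faces["+x"], faces["+y"], faces["+z"]])
    minus = np.array([faces["-x"], faces["-y"], faces["-z"]])
    finite = np.isfinite(half)
    lo = np.where(finite, -half - minus - pad, -pad)
    hi = np.where(finite, half + plus + pad, pad)
    # lateral extent of a slab: a few voxels is enough, the geometry is uniform
    lateral = 8.0 * spacing
    lo = np.where(finite, lo, -lateral)
    hi = np.where(finite, hi, lateral)
    _, origin, (X, Y, Z) = _grid(lo, hi, spacing)
    coords = (X, Y, Z)
    gtv_occ = np.ones(X.shape, dtype=bool)
    ctv_occ = np.ones(X.shape, dtype=bool)
    spanning = tuple(a for a in range(3) if not finite[a])
    for a in range(3):
        if not finite[a]:
            continue
        gtv_occ &= (coords[a] >= -half[a]) & (coords[a] <= half[a])
        ctv_occ &= (coords[a] >= -half[a] - minus[a]) & (coords[a] <= half[a] + plus[a])
    gtv = BinaryVolume(gtv_occ, spacing, origin)
    ctv = gtv.with_occupancy(ctv_occ)
    _check_clearance(ctv, spanning_axes=spanning)
    truth = {d.label: _face_margin_for(d, faces) for d in directions}
    for a in spanning:
        for lab in _AXIS_LABELS[a]:
            if lab in truth:
                truth[lab] = None  # slab spans the grid here; no face to probe
    return Phantom(gtv=gtv, ctv=ctv, truth=truth, directions=directions, spec=spec)


def _build_u_shape(spec, spacing, pad, directions) -> Phantom:
    outer = np.asarray(spec.size_mm[:3], dtype=float)
    slot_width, slot_depth = float(spec.size_mm[3]), float(spec.size_mm[4])
    half = outer / 2.0
    faces = _per_face(spec.expansion)
    plus = np.array([faces["+x"], faces["+y"], faces["+z"]])
    minus = np.array([faces["-x"], faces["-y"], faces["-z"]])
    lo = -half - minus - pad
    hi = half + plus + pad
    _, origin, (X, Y, Z) = _grid(lo, hi, spacing)
    outer_occ = (
        (np.abs(X) <= half[0]) & (np.abs(Y) <= half[1]) & (np.abs(Z) <= half[2])
    )
    # slot opening toward +y, centered in x, cutting slot_depth into the box
    slot = (
        (np.abs(X) < slot_width / 2.0)
        & (Y > half[1] - slot_depth)
        & (np.abs(Z) <= half[2] + 1.0)
    )
    gtv_occ = outer_occ & ~slot
    ctv_occ = (
        (X >= -half[0] - minus[0])
        & (X <= half[0] + plus[0])
        & (Y >= -half[1] - minus[1])
        & (Y <= half[1] + plus[1])
        & (Z >= -half[2] - minus[2])
        & (Z <= half[2] + plus[2])
    )
    gtv = BinaryVolume(gtv_occ, spacing, origin)
    ctv = gtv.with_occupancy(ctv_occ)
    _check_clearance(ctv)
    truth: dict[str, Optional[float]] = {}
    for d in directions:
        margin = _face_margin_for(d, faces)
        axis = int(np.argmax(np.abs(d.vector)))
        if axis == 0:
            # rays across the slot re-enter the opposite prong: no clean truth
            truth[d.label] = None
        elif axis == 1 and d.vector[1] > 0:
            # toward the slot opening: slot-bottom rays are offset + slot_depth
            truth[d.label] = None
        else:
            truth[d.label] = margin
    rejections = tuple(
        d.label for d in directions if int(np.argmax(np.abs(d.vector))) == 0
    )
    return Phantom(
        gtv=gtv,
        ctv=ctv,
        truth=truth,
        directions=directions,
        expected_interior_rejections=rejections,
        spec=spec,
    )


def make_expert_ensemble(
    gtv: BinaryVolume,
    true_margin_mm: float,
    margin_sd_mm: float,
    K: int,
    seed: int,
) -> list[BinaryVolume]:
    """Simulate K expert CTVs around a true margin.

    Expert j's CTV is the exact Euclidean-distance expansion of the GTV by
    m_j, with m_j drawn from a normal distribution of mean
    ``true_margin_mm`` and SD ``margin_sd_mm`` truncated at zero. Draws are
    reproducible from ``seed``.
    """
    if K < 2:
        raise InsufficientExpertsError(f"an ensemble needs K >= 2 experts, got {K}")
    if true_margin_mm <= 0:
        raise ValueError("true_margin_mm must be positive")
    if margin_sd_mm < 0:
        raise ValueError("margin_sd_mm must be non-negative")
    rng = np.random.default_rng(seed)
    if margin_sd_mm == 0.0:
        draws = np.full(K, float(true_margin_mm))
    else:
        a = (0.0 - true_margin_mm) / margin_sd_mm
        draws = truncnorm.rvs(
            a, np.inf, loc=true_margin_mm, scale=margin_sd_mm, size=K, random_state=rng
        )
    distance = distance_transform_edt(~gtv.occupancy, sampling=gtv.spacing)
    return [gtv.with_occupancy(distance <= m_j) for m_j in draws]


def write_example_study(out_dir, seed: int = 0) -> "Path":
    """Write a small two-case phantom study to disk; returns the config path.

    Case ``slab``: the asymmetric slab with its analytic consensus CTV and
    three simulated experts (true margin 7 mm, SD 1 mm), probed left/right
    (intraosseous). Case ``sphere``: a 10 mm sphere with a 5 mm isotropic
    expansion, consensus left to STAPLE over four simulated experts, an
    anatomical-barrier half-space at z >= 11 mm, and three probes
    (extraosseous); the superior probe is fully blocked by the barrier and
    exercises the per-direction failure reporting.
    """
    from pathlib import Path

    import yaml

    from .io import write_mask

    out = Path(out_dir)
    masks = out / "masks"
    masks.mkdir(parents=True, exist_ok=True)

    slab = make_phantom(
        PhantomSpec(
            gtv_shape="slab",
            size_mm=(10.0,),
            expansion={"per_face": {"+x": 7.0, "-x": 2.0}},
            spacing_mm=(1.0, 1.0, 1.0),
            # generous padding: the simulated experts expand ~7 mm on *both*
            # faces and must not touch the grid boundary
            padding_mm=12.0,
        )
    )
    write_mask(slab.gtv, masks / "slab_gtv.nii.gz")
    write_mask(slab.ctv, masks / "slab_consensus.nii.gz")
    slab_experts = make_expert_ensemble(slab.gtv, 7.0, 1.0, 3, seed=seed)
    for j, e in enumerate(slab_experts):
        write_mask(e, masks / f"slab_expert_{j}.nii.gz")

    sphere = make_phantom(
        PhantomSpec(
            gtv_shape="sphere",
            size_mm=(10.0,),
            expansion={"isotropic": 5.0},
            spacing_mm=(1.0, 1.0, 1.0),
            padding_mm=6.0,
        )
    )
    write_mask(sphere.gtv, masks / "sphere_gtv.nii.gz")
    for j, e in enumerate(make_expert_ensemble(sphere.gtv, 5.0, 1.0, 4, seed=seed + 1)):
        write_mask(e, masks / f"sphere_expert_{j}.nii.gz")
    zc = sphere.gtv.origin[2] + sphere.gtv.spacing[2] * np.arange(sphere.gtv.shape[2])
    barrier_occ = np.zeros(sphere.gtv.shape, dtype=bool)
    barrier_occ[:, :, zc >= 11.0] = True
    write_mask(sphere.gtv.with_occupancy(barrier_occ), masks / "sphere_barrier.nii.gz")

    config = {
        "cases": [
            {
                "case_id": "slab",
                "gtv": "masks/slab_gtv.nii.gz",
                "consensus_ctv": "masks/slab_consensus.nii.gz",
                "experts": [f"masks/slab_expert_{j}.nii.gz" for j in range(3)],
                "directions": [
                    {"label": "L", "route_class": "intraosseous"},
                    {"label": "R", "route_class": "intraosseous"},
                ],
            },
            {
                "case_id": "sphere",
                "gtv": "masks/sphere_gtv.nii.gz",
                "experts": [f"masks/sphere_expert_{j}.nii.gz" for j in range(4)],
                "barrier": "masks/sphere_barrier.nii.gz",
                "directions": [
                    {"label": "L", "route_class": "extraosseous"},
                    {"label": "I", "route_class": "extraosseous"},
                    {"label": "S", "route_class": "extraosseous"},
                ],
            },
        ]
    }
    config_path = out / "study.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return config_path


def example_specs() -> dict[str, PhantomSpec]:
    """The phantom suite shipped with the package."""
    return {
        "isotropic_sphere": PhantomSpec(
            gtv_shape="sphere", size_mm=(10.0,), expansion={"isotropic": 5.0}
        ),
        "anisotropic_ellipsoid": PhantomSpec(
            gtv_shape="sphere",
            size_mm=(10.0,),
            expansion={"per_axis": (3.0, 5.0, 7.0)},
        ),
        "asymmetric_slab": PhantomSpec(
            gtv_shape="slab",
            size_mm=(10.0,),
            expansion={"per_face": {"+x": 7.0, "-x": 2.0}},
            spacing_mm=(1.0, 1.0, 1.0),
        ),
        "u_shape": PhantomSpec(
            gtv_shape="u_shape",
            size_mm=(20.0, 16.0, 8.0, 6.0, 10.0),
            expansion={"isotropic": 4.0},
        ),
        "barrier_hemisphere": PhantomSpec(
            gtv_shape="sphere",
            size_mm=(10.0,),
            expansion={"isotropic": 5.0},
            barrier={"halfspace": {"normal": (0.0, 0.0, 1.0), "offset_mm": 12.0}},
        ),
    }
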