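"""Directional CTV margins from expansion-vector ray casting.

The directional margin M(d) of a CTV with respect to its GTV is the median
length of the *expansion vectors* in direction d: segments parallel to the
unit vector d that run from the GTV surface to the CTV surface without
passing through the GTV interior. Casting one ray per GTV surface voxel
yields the vector ensemble; the per-direction interobserver *margin
deviation* CV(d) is the coefficient of variation of the margins measured
against each expert's CTV individually.

Ray resolution. Each ray starts at a surface-voxel center and marches in
steps of ``step_factor * min(spacing)``. The sub-voxel crossing where the
trilinear occupancy of a mask falls below 0.5 is bracketed by the march and
refined by bisection to ``bisect_tol_mm``; the GTV crossing anchors the
vector start (so lengths are boundary-to-boundary, not voxel-center-based)
and the CTV crossing anchors its end. A ray whose path re-enters the GTV
more than ``reentry_grace_mm`` past its start before reaching the CTV
boundary is rejected (it would cross the GTV interior — e.g. across a
concavity); a ray passing through an optional barrier mask between start and
end is likewise rejected. A surface point already outside the CTV yields a
zero-length vector ("clamped"): a tighter-than-GTV expert contour means *no
expansion there*, not a missing observation, which keeps the per-expert
sample complete for CV(d).

Note that on curved surfaces the ensemble median exceeds the face-on
expansion: rays from obliquely oriented surface regions are longer than the
perpendicular gap between the surfaces. See ``docs/methods.md``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import (
    CastError,
    EmptyVolumeError,
    FewVectorsWarning,
    InsufficientExpertsError,
    NoVectorError,
)
from .geometry import (
    BinaryVolume,
    DirectionSpec,
    OccupancySampler,
    extract_surface,
    require_compatible,
)

__all__ = [
    "CastParams",
    "CastOutcome",
    "ExpansionVectorSet",
    "DirectionalMarginResult",
    "MarginDeviationResult",
    "cast_expansion_vector",
    "directional_margin",
    "margin_deviation",
]


@dataclass(frozen=True)
class CastParams:
    """Resolution parameters of the ray caster.

    step_factor
        Marching step as a fraction of the smallest voxel spacing.
    bisect_tol_mm
        Absolute tolerance to which each boundary crossing is refined.
    reentry_grace_mm
        Distance past the vector start within which GTV occupancy >= 0.5 is
        ignored (interpolation jitter at the departure point, not a true
        interior crossing).
    few_vector_threshold
        Emit :class:`FewVectorsWarning` when fewer vectors are accepted;
        medians over very few rays are unstable.
    """

    step_factor: float = 0.1
    bisect_tol_mm: float = 0.01
    reentry_grace_mm: float = 0.05
    few_vector_threshold: int = 10

    def scaled(self, s: float) -> "CastParams":
        """Parameters for a grid whose physical scale is multiplied by ``s``."""
        return CastParams(
            step_factor=self.step_factor,
            bisect_tol_mm=self.bisect_tol_mm * s,
            reentry_grace_mm=self.reentry_grace_mm * s,
            few_vector_threshold=self.few_vector_threshold,
        )


@dataclass(frozen=True)
class ExpansionVectorSet:
    """The accepted expansion vectors for one (GTV, CTV, direction) triple.

    ``starts``/``ends`` are (n, 3) physical mm endpoints on the GTV and CTV
    boundaries; ``lengths`` are their separations along the direction.
    Zero-length (clamped) vectors are included in the arrays and counted in
    ``n_clamped``. ``n_candidates`` is the number of surface points examined.
    """

    direction: DirectionSpec
    starts: np.ndarray
    ends: np.ndarray
    lengths: np.ndarray
    n_candidates: int
    n_rejected_interior: int
    n_rejected_barrier: int
    n_clamped: int
    n_cast_failed: int = 0

    @property
    def vectors(self) -> list[tuple[np.ndarray, np.ndarray, float]]:
        return [
            (self.starts[i], self.ends[i], float(self.lengths[i]))
            for i in range(len(self.lengths))
        ]

    def counters(self) -> dict[str, int]:
        return {
            "n_vectors": len(self.lengths),
            "n_candidates": self.n_candidates,
            "n_rejected_interior": self.n_rejected_interior,
            "n_rejected_barrier": self.n_rejected_barrier,
            "n_clamped": self.n_clamped,
            "n_cast_failed": self.n_cast_failed,
        }


@dataclass(frozen=True)
class DirectionalMarginResult:
    """Directional margin M(d): the median accepted vector length (mm)."""

    direction: DirectionSpec
    margin_mm: float
    vector_set: ExpansionVectorSet
    n_used: int


@dataclass(frozen=True)
class MarginDeviationResult:
    """Margin deviation CV(d): spread of per-expert margins in direction d.

    ``cv`` is the sample standard deviation (K-1 denominator) of the
    per-expert directional margins divided by their mean; 0 by convention
    when every expert margin is 0.
    """

    direction: DirectionSpec
    per_expert_margins_mm: np.ndarray
    cv: float
    per_expert_results: tuple[DirectionalMarginResult, ...] = field(
        default=(), repr=False, compare=False
    )


# ray status codes used by the vectorised caster
_PENDING, _ACCEPTED, _CLAMPED, _REJ_INTERIOR, _REJ_BARRIER, _FAILED = range(6)


def _bisect_crossing(
    sampler: OccupancySampler,
    base_idx: np.ndarray,
    d_idx: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    tol_mm: float,
) -> np.ndarray:
    """Refine per-ray occupancy crossings: occ(lo) >= 0.5 > occ(hi).

    ``lo``/``hi`` are physical arc lengths along the (unit, patient-space)
    direction; ``d_idx`` is the direction expressed per mm in index space.
    """
    lo = lo.copy()
    hi = hi.copy()
    while len(lo) and float(np.max(hi - lo)) > tol_mm:
        mid = 0.5 * (lo + hi)
        occ = sampler.at_index(base_idx + mid[:, None] * d_idx)
        inside = occ >= 0.5
        lo = np.where(inside, mid, lo)
        hi = np.where(inside, hi, mid)
    if not len(lo):
        return lo
    # linear polish inside the converged bracket: the trilinear occupancy is
    # near-linear (exactly linear for axis-aligned rays) over a sub-voxel
    # interval, so one regula-falsi step pins the 0.5 crossing far below the
    # bisection tolerance
    f_lo = sampler.at_index(base_idx + lo[:, None] * d_idx)
    f_hi = sampler.at_index(base_idx + hi[:, None] * d_idx)
    df = f_hi - f_lo
    safe = np.abs(df) > 1e-12
    t = np.where(safe, lo + (0.5 - f_lo) * (hi - lo) / np.where(safe, df, 1.0), 0.5 * (lo + hi))
    return np.clip(t, lo, hi)


def _cast_rays(
    base_indices: np.ndarray,
    direction: DirectionSpec,
    gtv: BinaryVolume,
    ctv: BinaryVolume,
    barrier: Optional[BinaryVolume],
    params: CastParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cast one ray per row of ``base_indices`` (integer voxel indices).

    Returns ``(status, t_start, t_end)`` with physical arc lengths measured
    from each voxel center along the direction.
    """
    n = len(base_indices)
    base = base_indices.astype(np.float64)
    d = direction.vector
    d_idx = (gtv.axis_directions.T @ d) / gtv.spacing
    step = params.step_factor * float(gtv.spacing.min())
    cap = gtv.physical_diagonal_mm
    gs = OccupancySampler(gtv)
    cs = OccupancySampler(ctv)
    bs = OccupancySampler(barrier) if barrier is not None else None

    status = np.full(n, _PENDING, dtype=np.int8)
    t_start = np.full(n, np.nan)
    t_end = np.full(n, np.nan)
    lo = np.full(n, np.nan)
    hi = np.full(n, np.nan)

    # ---- phase A: bracket the GTV exit crossing along d ------------------
    t = np.zeros(n)
    act = np.arange(n)
    while act.size:
        over = t[act] + step > cap
        if over.any():
            status[act[over]] = _FAILED  # pathological: ray never leaves the GTV
            act = act[~over]
            if not act.size:
                break
        occ = gs.at_index(base[act] + (t[act] + step)[:, None] * d_idx)
        out = occ < 0.5
        done = act[out]
        lo[done] = t[done]
        hi[done] = t[done] + step
        t[act] += step
        act = act[~out]
    pend = np.flatnonzero(status == _PENDING)
    t_start[pend] = _bisect_crossing(
        gs, base[pend], d_idx, lo[pend], hi[pend], params.bisect_tol_mm
    )

    # ---- clamp: the start already lies outside the CTV -------------------
    c0 = cs.at_index(base[pend] + t_start[pend, None] * d_idx)
    clamped = pend[c0 < 0.5]
    status[clamped] = _CLAMPED
    t_end[clamped] = t_start[clamped]
    act = pend[c0 >= 0.5]

    # barrier check at the start sample itself
    if bs is not None and act.size:
        b0 = bs.at_index(base[act] + t_start[act, None] * d_idx)
        hit = b0 >= 0.5
        status[act[hit]] = _REJ_BARRIER
        act = act[~hit]

    # ---- phase B: march to the CTV exit, watching for GTV re-entry -------
    lo[:] = np.nan
    hi[:] = np.nan
    t = t_start.copy()
    grace = params.reentry_grace_mm
    while act.size:
        over = t[act] + step > cap
        if over.any():
            status[act[over]] = _FAILED  # ray never leaves the CTV
            act = act[~over]
            if not act.size:
                break
        t_next = t[act] + step
        p = base[act] + t_next[:, None] * d_idx
        cocc = cs.at_index(p)
        gocc = gs.at_index(p)
        exited = cocc < 0.5
        reenter = ~exited & (gocc >= 0.5) & (t_next > t_start[act] + grace)
        stop = exited | reenter
        if bs is not None:
            bocc = bs.at_index(p)
            bhit = ~stop & (bocc >= 0.5)
            status[act[bhit]] = _REJ_BARRIER
            stop = stop | bhit
        done = act[exited]
        lo[done] = t[done]
        hi[done] = t[done] + step
        status[act[reenter]] = _REJ_INTERIOR
        t[act] += step
        act = act[~stop]
    ex = np.flatnonzero((status == _PENDING) & np.isfinite(lo))
    t_end[ex] = _bisect_crossing(cs, base[ex], d_idx, lo[ex], hi[ex], params.bisect_tol_mm)
    status[ex] = _ACCEPTED
    return status, t_start, t_end


def _build_vector_set(
    surf_points: np.ndarray,
    direction: DirectionSpec,
    status: np.ndarray,
    t_start: np.ndarray,
    t_end: np.ndarray,
) -> ExpansionVectorSet:
    keep = (status == _ACCEPTED) | (status == _CLAMPED)
    d = direction.vector
    starts = surf_points[keep] + t_start[keep, None] * d
    lengths = t_end[keep] - t_start[keep]
    ends = starts + lengths[:, None] * d
    return ExpansionVectorSet(
        direction=direction,
        starts=starts,
        ends=ends,
        lengths=lengths,
        n_candidates=len(status),
        n_rejected_interior=int(np.sum(status == _REJ_INTERIOR)),
        n_rejected_barrier=int(np.sum(status == _REJ_BARRIER)),
        n_clamped=int(np.sum(status == _CLAMPED)),
        n_cast_failed=int(np.sum(status == _FAILED)),
    )


@dataclass(frozen=True)
class CastOutcome:
    """Result of casting a single expansion vector.

    ``status`` is one of ``"accepted"``, ``"clamped"``,
    ``"rejected_interior"`` or ``"rejected_barrier"``; endpoints and length
    are present for accepted and clamped rays only.
    """

    status: str
    start: Optional[np.ndarray] = None
    end: Optional[np.ndarray] = None
    length_mm: Optional[float] = None


def cast_expansion_vector(
    surface_point: np.ndarray,
    direction: DirectionSpec,
    gtv: BinaryVolume,
    ctv: BinaryVolume,
    barrier: Optional[BinaryVolume] = None,
    params: CastParams = CastParams(),
) -> CastOutcome:
    """Cast one expansion vector from a GTV surface voxel center.

    ``surface_point`` must be the physical center of a foreground GTV voxel.
    Raises :class:`CastError` when the ray cannot be resolved within the
    grid's physical diagonal.
    """
    require_compatible(gtv, ctv, names=["gtv", "ctv"])
    if barrier is not None:
        require_compatible(gtv, barrier, names=["gtv", "barrier"])
    idx = np.round(gtv.physical_to_index(np.asarray(surface_point, float))).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(gtv.shape)):
        raise ValueError(f"surface point {surface_point} lies outside the grid")
    if not gtv.occupancy[tuple(idx)]:
        raise ValueError(f"surface point {surface_point} is not a GTV foreground voxel")
    status, t_start, t_end = _cast_rays(
        idx[None, :], direction, gtv, ctv, barrier, params
    )
    s = int(status[0])
    if s == _FAILED:
        raise CastError(
            f"ray from {np.asarray(surface_point)} along {direction.label} could not "
            "be resolved within the grid diagonal"
        )
    if s == _REJ_INTERIOR:
        return CastOutcome(status="rejected_interior")
    if s == _REJ_BARRIER:
        return CastOutcome(status="rejected_barrier")
    d = direction.vector
    start = np.asarray(surface_point, float) + t_start[0] * d
    length = float(t_end[0] - t_start[0])
    return CastOutcome(
        status="clamped" if s == _CLAMPED else "accepted",
        start=start,
        end=start + length * d,
        length_mm=length,
    )


def directional_margin(
    gtv: BinaryVolume,
    ctv: BinaryVolume,
    direction: DirectionSpec,
    barrier: Optional[BinaryVolume] = None,
    params: CastParams = CastParams(),
) -> DirectionalMarginResult:
    """Directional margin M(d): median expansion-vector length in mm.

    Casts one ray per GTV surface voxel, drops rays that would cross the GTV
    interior (or the barrier, when given), clamps surface points the CTV does
    not cover to zero length, and takes the median of the remaining lengths
    (an even count averages the two central order statistics, per
    ``numpy.median``).

    Raises
    ------
    EmptyVolumeError
        When the GTV has no foreground voxels.
    NoVectorError
        When no vector is accepted — the caller decides whether the
        direction is simply inapplicable for the case.
    """
    if not gtv.occupancy.any():
        raise EmptyVolumeError("GTV mask is empty")
    require_compatible(gtv, ctv, names=["gtv", "ctv"])
    if barrier is not None:
        require_compatible(gtv, barrier, names=["gtv", "barrier"])
    surf = extract_surface(gtv)
    status, t_start, t_end = _cast_rays(
        surf.source_indices, direction, gtv, ctv, barrier, params
    )
    vset = _build_vector_set(surf.points, direction, status, t_start, t_end)
    n_used = len(vset.lengths)
    if n_used == 0:
        raise NoVectorError(
            f"no expansion vector accepted in direction {direction.label!r} "
            f"({vset.n_rejected_interior} interior rejections, "
            f"{vset.n_rejected_barrier} barrier rejections)"
        )
    if n_used < params.few_vector_threshold:
        warnings.warn(
            f"direction {direction.label!r}: margin based on only {n_used} "
            "accepted vectors",
            FewVectorsWarning,
            stacklevel=2,
        )
    return DirectionalMarginResult(
        direction=direction,
        margin_mm=float(np.median(vset.lengths)),
        vector_set=vset,
        n_used=n_used,
    )


def margin_deviation(
    gtv: BinaryVolume,
    expert_ctvs: Sequence[BinaryVolume],
    direction: DirectionSpec,
    barrier: Optional[BinaryVolume] = None,
    params: CastParams = CastParams(),
) -> MarginDeviationResult:
    """Margin deviation CV(d) across K >= 2 expert CTVs.

    Computes M(d) against each expert independently, then
    ``cv = std(margins, ddof=1) / mean(margins)``; all-zero margins give
    ``cv = 0`` by convention. A zero-vector failure against any expert
    propagates as :class:`NoVectorError` naming the expert.
    """
    if len(expert_ctvs) < 2:
        raise InsufficientExpertsError(
            f"margin deviation needs at least 2 expert CTVs, got {len(expert_ctvs)}"
        )
    results = []
    for j, ctv in enumerate(expert_ctvs):
        try:
            results.append(directional_margin(gtv, ctv, direction, barrier, params))
        except NoVectorError as exc:
            raise NoVectorError(f"expert {j}: {exc}") from exc
    margins = np.array([r.margin_mm for r in results])
    mean = float(margins.mean())
    cv = 0.0 if mean == 0.0 else float(margins.std(ddof=1) / mean)
    return MarginDeviationResult(
        direction=direction,
        per_expert_margins_mm=margins,
        cv=cv,
        per_expert_results=tuple(results),
    )
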