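"""Independent reference implementations used only as test oracles.

Everything here is deliberately written along a different code path than the
package: explicit per-point / per-ray / per-voxel loops, fixed-step marching
instead of bracketing + bisection, and a loop-based STAPLE EM. Slow, simple,
and only run on tiny inputs.
"""

from __future__ import annotations

import numpy as np

from ctvmargins import BinaryVolume, DirectionSpec, occupancy_at


def point_in_polygon_evenodd(x: float, y: float, poly: np.ndarray) -> bool:
    """Classic scalar crossing-number (even–odd) containment test."""
    inside = False
    m = len(poly)
    j = m - 1
    for i in range(m):
        xi, yi = poly[i]
        xj, yj = poly[j]
        if (yi > y) != (yj > y):
            x_cross = xi + (y - yi) * (xj - xi) / (yj - yi)
            if x < x_cross:
                inside = not inside
        j = i
    return inside


def surface_voxels_bruteforce(occ: np.ndarray) -> set[tuple[int, int, int]]:
    """All foreground voxels with a background / out-of-grid 6-neighbour."""
    out = set()
    nx, ny, nz = occ.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not occ[i, j, k]:
                    continue
                for di, dj, dk in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
                    a, b, c = i + di, j + dj, k + dk
                    if not (0 <= a < nx and 0 <= b < ny and 0 <= c < nz) or not occ[a, b, c]:
                        out.add((i, j, k))
                        break
    return out


def dense_cast(
    gtv: BinaryVolume,
    ctv: BinaryVolume,
    direction: DirectionSpec,
    start_point: np.ndarray,
    barrier: BinaryVolume | None = None,
    step_factor: float = 0.005,
    grace_mm: float = 0.05,
):
    """Fixed-step ray marcher (no bisection): the caster's reference.

    Returns ``(status, length)`` with status in {"accepted", "clamped",
    "rejected_interior", "rejected_barrier"}; the crossing positions are
    taken as the midpoints of the fixed-step samples, so lengths carry an
    uncertainty of about one step.
    """
    d = direction.vector
    step = step_factor * float(min(gtv.spacing))
    cap = gtv.physical_diagonal_mm
    ts = np.arange(0.0, cap, step)
    pts = np.asarray(start_point, float) + ts[:, None] * d
    g = np.asarray(occupancy_at(gtv, pts))
    c = np.asarray(occupancy_at(ctv, pts))
    in_g = g >= 0.5
    assert in_g[0], "ray must start inside the GTV"
    exits = np.flatnonzero(~in_g)
    if exits.size == 0:
        return "failed", None
    i_exit = exits[0]
    t_start = 0.5 * (ts[i_exit - 1] + ts[i_exit])
    c_at_start = float(occupancy_at(ctv, np.asarray(start_point) + t_start * d))
    if c_at_start < 0.5:
        return "clamped", 0.0
    after = np.arange(len(ts)) >= i_exit  # samples from the GTV exit onward
    ctv_exits = np.flatnonzero(after & (c < 0.5))
    if ctv_exits.size == 0:
        return "failed", None
    j_exit = ctv_exits[0]
    t_end = 0.5 * (ts[j_exit - 1] + ts[j_exit])
    between = (ts > t_start + grace_mm) & (ts < t_end)
    if np.any(between & in_g):
        return "rejected_interior", None
    if barrier is not None:
        b = np.asarray(occupancy_at(barrier, pts))
        span = (ts >= t_start) & (ts <= t_end)
        if np.any(span & (b >= 0.5)):
            return "rejected_barrier", None
    return "accepted", float(t_end - t_start)


def staple_em_loops(
    masks: list[np.ndarray],
    max_iter: int = 100,
    tol: float = 1e-6,
):
    """Loop-based binary STAPLE EM with the package's conventions.

    Scalar prior = mean foreground fraction across raters over the working
    region; init p = q = 0.99999; computation over the one-voxel-dilated
    bounding box of the union; convergence on mean absolute posterior change.
    Returns (posterior array over the full grid, p, q).
    """
    union = np.zeros(masks[0].shape, dtype=bool)
    for m in masks:
        union |= m
    nz = np.argwhere(union)
    lo = np.maximum(nz.min(axis=0) - 1, 0)
    hi = np.minimum(nz.max(axis=0) + 2, union.shape)
    voxels = [
        (i, j, k)
        for i in range(lo[0], hi[0])
        for j in range(lo[1], hi[1])
        for k in range(lo[2], hi[2])
    ]
    K = len(masks)
    D = [[1.0 if m[v] else 0.0 for v in voxels] for m in masks]
    n_vox = len(voxels)
    f = sum(sum(row) for row in D) / (K * n_vox)
    p = [0.99999] * K
    q = [0.99999] * K
    W = None
    for _ in range(max_iter):
        W_new = []
        for i in range(n_vox):
            a = f
            b = 1.0 - f
            for j in range(K):
                if D[j][i] == 1.0:
                    a *= p[j]
                    b *= 1.0 - q[j]
                else:
                    a *= 1.0 - p[j]
                    b *= q[j]
            W_new.append(a / (a + b) if (a + b) > 0 else f)
        if W is not None and sum(abs(x - y) for x, y in zip(W_new, W)) / n_vox < tol:
            W = W_new
            break
        W = W_new
        sw = sum(W)
        swc = n_vox - sw
        for j in range(K):
            pj = sum(w for w, d in zip(W, D[j]) if d == 1.0) / max(sw, 1e-7)
            qj = sum((1.0 - w) for w, d in zip(W, D[j]) if d == 0.0) / max(swc, 1e-7)
            p[j] = min(max(pj, 1e-7), 1.0 - 1e-7)
            q[j] = min(max(qj, 1e-7), 1.0 - 1e-7)
    posterior = np.zeros(union.shape)
    for v, w in zip(voxels, W):
        posterior[v] = w
    return posterior, np.array(p), np.array(q)
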