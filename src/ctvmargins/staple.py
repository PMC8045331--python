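"""STAPLE consensus segmentation (binary, EM).

Simultaneous Truth And Performance Level Estimation treats the unknown true
segmentation as a latent binary field and each rater j as a noisy channel
with sensitivity p_j = P(D_j = 1 | T = 1) and specificity
q_j = P(D_j = 0 | T = 0). The EM iteration alternates:

* E-step — voxel posterior of foreground given the rater decisions,
  ``W_i = a_i / (a_i + b_i)`` with
  ``a_i = f * prod_j p_j^{D_ij} (1 - p_j)^{1 - D_ij}`` and
  ``b_i = (1 - f) * prod_j q_j^{1 - D_ij} (1 - q_j)^{D_ij}``;
* M-step — re-estimate each rater's p_j, q_j from the posteriors.

The foreground prior ``f`` is a scalar, fixed across iterations at the mean
foreground fraction of the raters (computed over the working region), and
both performance parameters start at 0.99999 — the conventional near-perfect
initialisation that avoids the label-swapped fixed point. Computation is
restricted to the bounding box of the union of the rater masks dilated by
one voxel; everything outside has posterior 0. Without that restriction the
unbounded background would dominate the specificity estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateInputError, NoRatersError
from .geometry import BinaryVolume, require_compatible

__all__ = ["StapleResult", "staple_consensus"]

_INIT_PERFORMANCE = 0.99999
_PARAM_FLOOR = 1e-7  # keep p, q away from exact 0/1 so products stay finite


@dataclass(frozen=True)
class StapleResult:
    """Output of :func:`staple_consensus`.

    ``probability_map`` is the voxel-wise posterior probability of foreground
    on the full grid; ``consensus_mask`` thresholds it at the requested
    level. ``sensitivities``/``specificities`` are the per-rater performance
    estimates at convergence.
    """

    probability_map: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    consensus_mask: BinaryVolume
    n_iterations: int
    converged: bool
    threshold: float


def staple_consensus(
    expert_masks: Sequence[BinaryVolume],
    threshold: float = 0.5,
    max_iter: int = 100,
    tol: float = 1e-6,
    prior: Optional[float] = None,
) -> StapleResult:
    """Estimate the consensus mask of K rater masks by binary STAPLE.

    Parameters
    ----------
    expert_masks
        K >= 1 grid-compatible binary volumes.
    threshold
        Posterior level defining the consensus mask (foreground iff
        posterior >= threshold). 0.5 is the conventional cut.
    max_iter, tol
        EM stops when the mean absolute posterior change drops below
        ``tol`` or after ``max_iter`` iterations.
    prior
        Optional scalar foreground prior overriding the default (mean
        foreground fraction across raters in the working region).
    """
    K = len(expert_masks)
    if K == 0:
        raise NoRatersError("STAPLE needs at least one rater mask")
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    require_compatible(*expert_masks, names=[f"rater[{j}]" for j in range(K)])
    grid = expert_masks[0]
    union = np.zeros(grid.shape, dtype=bool)
    for m in expert_masks:
        union |= m.occupancy
    if not union.any():
        raise DegenerateInputError("all rater masks are background")

    # working region: union bounding box dilated by one voxel, clipped to grid
    nz = np.argwhere(union)
    lo = np.maximum(nz.min(axis=0) - 1, 0)
    hi = np.minimum(nz.max(axis=0) + 2, grid.shape)
    box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    D = np.stack([m.occupancy[box].ravel() for m in expert_masks]).astype(np.float64)

    f = float(D.mean()) if prior is None else float(prior)
    p = np.full(K, _INIT_PERFORMANCE)
    q = np.full(K, _INIT_PERFORMANCE)

    W = None
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step; per-rater terms are sorted before summing so the posterior
        # is exactly invariant under rater permutation (float addition is not
        # associative, but the sorted sequence is canonical)
        terms_a = np.where(D == 1.0, np.log(p)[:, None], np.log1p(-p)[:, None])
        terms_b = np.where(D == 0.0, np.log(q)[:, None], np.log1p(-q)[:, None])
        log_a = np.sort(terms_a, axis=0).sum(axis=0)
        log_b = np.sort(terms_b, axis=0).sum(axis=0)
        a = f * np.exp(log_a)
        b = (1.0 - f) * np.exp(log_b)
        denom = a + b
        W_new = np.where(denom > 0.0, a / np.where(denom > 0.0, denom, 1.0), f)
        if W is not None and float(np.mean(np.abs(W_new - W))) < tol:
            W = W_new
            converged = True
            break
        W = W_new
        # M-step
        sw = W.sum()
        swc = (1.0 - W).sum()
        p = np.clip((D * W).sum(axis=1) / max(sw, _PARAM_FLOOR), _PARAM_FLOOR, 1.0 - _PARAM_FLOOR)
        q = np.clip(((1.0 - D) * (1.0 - W)).sum(axis=1) / max(swc, _PARAM_FLOOR), _PARAM_FLOOR, 1.0 - _PARAM_FLOOR)

    probability = np.zeros(grid.shape, dtype=np.float64)
    probability[box] = W.reshape(tuple(int(b - a) for a, b in zip(lo, hi)))
    consensus = grid.with_occupancy(probability >= threshold)
    return StapleResult(
        probability_map=probability,
        sensitivities=p,
        specificities=q,
        consensus_mask=consensus,
        n_iterations=n_iter,
        converged=converged,
        threshold=threshold,
    )
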