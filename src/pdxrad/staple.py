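"""STAPLE: consensus segmentation by expectation-maximization.

Given binary delineations D_ij of the same volume by several raters j, the
algorithm treats the true segmentation T_i as a hidden voxelwise label and
alternates between

* E-step: posterior weight W_i = P(T_i = 1 | D, p, q) proportional to
  ``prior * prod_j p_j^D_ij (1-p_j)^(1-D_ij)`` against
  ``(1-prior) * prod_j q_j^(1-D_ij) (1-q_j)^D_ij``;
* M-step: per-rater sensitivity ``p_j = sum_i W_i D_ij / sum_i W_i`` and
  specificity ``q_j = sum_i (1-W_i)(1-D_ij) / sum_i (1-W_i)``.

The scalar prior is held fixed during EM, so the observed-data
log-likelihood is non-decreasing at every iteration.  By default the
computation is restricted to a bounding box around the union of rater
masks (dilated by a margin) to keep the background from saturating the
specificity estimates; voxels outside the box get weight 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import BinaryMask3D, ProbabilityMap3D, RaterSet

__all__ = ["ConsensusResult", "run_staple", "binarize_consensus"]


@dataclass
class ConsensusResult:
    weight_map: ProbabilityMap3D
    sensitivities: np.ndarray  # p_j per rater
    specificities: np.ndarray  # q_j per rater
    prior: float
    iterations: int
    converged: bool
    log_likelihoods: np.ndarray  # per iteration, non-decreasing
    consensus_mask: BinaryMask3D


def _bounding_box(union: np.ndarray, margin: int) -> tuple[slice, ...]:
    idx = np.nonzero(union)
    return tuple(
        slice(max(0, int(a.min()) - margin), min(n, int(a.max()) + 1 + margin))
        for a, n in zip(idx, union.shape)
    )


def run_staple(
    raters: RaterSet,
    prior: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
    crop_margin: int | None = 10,
    init_p: float = 0.99,
    init_q: float = 0.99,
) -> ConsensusResult:
    """Estimate the consensus map and per-rater performance parameters.

    ``prior=None`` uses the mean foreground fraction across raters (within
    the analysis region).  ``crop_margin=None`` disables the bounding-box
    restriction and runs EM on the full grid.
    """
    if len(raters) < 2:
        raise ValueError("STAPLE needs at least 2 raters")
    spacing = raters.masks[0].voxel_spacing
    full = raters.as_array().astype(np.float64)  # (R, Z, Y, X)
    union = full.max(axis=0)
    if union.sum() == 0:
        raise ValueError("degenerate input: all rater masks are empty")
    if full.min(axis=0).sum() == union.size:
        raise ValueError("degenerate input: all rater masks are full")

    if crop_margin is not None:
        box = _bounding_box(union.astype(bool), crop_margin)
        d = full[(slice(None),) + box].reshape(len(raters), -1)
    else:
        box = None
        d = full.reshape(len(raters), -1)

    if prior is None:
        pi = float(d.mean())
    else:
        if not 0.0 < prior < 1.0:
            raise ValueError("scalar prior must lie in (0, 1)")
        pi = float(prior)

    p = np.full(len(raters), init_p)
    q = np.full(len(raters), init_q)
    eps = 1e-12
    log_liks = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step (log space for numerical stability)
        log_a = d.T @ np.log(p + eps) + (1 - d).T @ np.log(1 - p + eps)
        log_b = (1 - d).T @ np.log(q + eps) + d.T @ np.log(1 - q + eps)
        fa = np.log(pi + eps) + log_a
        fb = np.log(1 - pi + eps) + log_b
        m = np.maximum(fa, fb)
        log_norm = m + np.log(np.exp(fa - m) + np.exp(fb - m))
        w = np.exp(fa - log_norm)
        log_liks.append(float(log_norm.sum()))
        # M-step
        sw = w.sum()
        swc = (1.0 - w).sum()
        p_new = (d @ w) / max(sw, eps)
        q_new = ((1 - d) @ (1 - w)) / max(swc, eps)
        delta = max(np.abs(p_new - p).max(), np.abs(q_new - q).max())
        p, q = p_new, q_new
        if delta < tol:
            converged = True
            break

    # final E-step with converged parameters
    log_a = d.T @ np.log(p + eps) + (1 - d).T @ np.log(1 - p + eps)
    log_b = (1 - d).T @ np.log(q + eps) + d.T @ np.log(1 - q + eps)
    fa = np.log(pi + eps) + log_a
    fb = np.log(1 - pi + eps) + log_b
    m = np.maximum(fa, fb)
    w = np.exp(fa - (m + np.log(np.exp(fa - m) + np.exp(fb - m))))

    weights = np.zeros(raters.masks[0].voxels.shape)
    if box is None:
        weights = w.reshape(weights.shape)
    else:
        weights[box] = w.reshape(tuple(s.stop - s.start for s in box))
    wmap = ProbabilityMap3D(weights, spacing)
    return ConsensusResult(
        weight_map=wmap,
        sensitivities=p,
        specificities=q,
        prior=pi,
        iterations=it,
        converged=converged,
        log_likelihoods=np.asarray(log_liks),
        consensus_mask=wmap.binarize(0.5),
    )


def binarize_consensus(result: ConsensusResult, level: float = 0.5) -> BinaryMask3D:
    """Threshold the posterior weight map (MAP rule at the default 0.5)."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    return result.weight_map.binarize(level)
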