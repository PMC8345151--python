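"""Grey-level quantization: fixed-bin and Lloyd-Max.

Fixed-bin quantization splits the ROI intensity range into equal-width
bins.  The Lloyd-Max quantizer minimizes quantization mean squared error by
alternating two updates until the MSE stops changing: each boundary moves
to the midpoint of its neighbouring representatives, and each
representative moves to the conditional mean of the samples in its cell.
Both map intensities to integer levels 1..levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["QuantizerModel", "fixed_bin_quantize", "lloyd_max_quantize"]


@dataclass
class QuantizerModel:
    method: str  # "fixed_bin" or "lloyd_max"
    levels: int
    boundaries: np.ndarray  # ascending, len == levels - 1
    representatives: np.ndarray  # len == levels

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=np.float64)
        self.representatives = np.asarray(self.representatives, dtype=np.float64)
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if len(self.boundaries) != self.levels - 1:
            raise ValueError("len(boundaries) must equal levels - 1")
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly ascending")

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Map values to integer levels 1..levels."""
        return np.searchsorted(self.boundaries, np.asarray(values), side="right") + 1

    def mse(self, values: np.ndarray) -> float:
        q = self.representatives[self.assign(values) - 1]
        return float(np.mean((np.asarray(values, dtype=np.float64) - q) ** 2))


def fixed_bin_quantize(
    values: np.ndarray, levels: int = 64
) -> tuple[np.ndarray, QuantizerModel | None]:
    """Equal-width binning over [min, max]; topmost edge inclusive.

    A constant input maps every sample to level 1 (and no quantizer model
    can be formed).  Level assignment is invariant to positive affine
    rescaling of the input.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return np.ones(values.shape, dtype=np.int64), None
    width = (hi - lo) / levels
    q = np.minimum(np.floor((values - lo) / width).astype(np.int64) + 1, levels)
    boundaries = lo + width * np.arange(1, levels)
    reps = lo + width * (np.arange(levels) + 0.5)
    return q, QuantizerModel("fixed_bin", levels, boundaries, reps)


def lloyd_max_quantize(
    values: np.ndarray,
    levels: int = 64,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[QuantizerModel, np.ndarray]:
    """MSE-optimal scalar quantizer fitted to the sample distribution.

    Initialized from fixed-bin representatives; cells that become empty are
    re-seeded at the midpoint of their boundaries.  Falls back to fixed-bin
    (with a warning) when the sample has fewer distinct values than levels.
    Deterministic for a fixed input.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    distinct = np.unique(values)
    if distinct.size < levels:
        warnings.warn(
            f"only {distinct.size} distinct values for {levels} levels; "
            "falling back to fixed-bin quantization"
        )
        if distinct.size < 2:
            reps = np.full(levels, values[0] if values.size else 0.0)
            boundaries = np.arange(1, levels, dtype=np.float64)  # placeholder grid
            model = QuantizerModel("fixed_bin", levels, boundaries, reps)
            return model, np.ones(values.shape, dtype=np.int64)
        q, model = fixed_bin_quantize(values, levels)
        return model, q

    lo, hi = float(values.min()), float(values.max())
    reps = lo + (hi - lo) * (np.arange(levels) + 0.5) / levels
    prev_mse = np.inf
    scale = max(values.var(), 1e-30)
    for _ in range(max_iter):
        boundaries = 0.5 * (reps[:-1] + reps[1:])
        q = np.searchsorted(boundaries, values, side="right")
        sums = np.bincount(q, weights=values, minlength=levels)
        counts = np.bincount(q, minlength=levels)
        edges = np.concatenate(([lo], boundaries, [hi]))
        new_reps = np.where(
            counts > 0,
            sums / np.maximum(counts, 1),
            0.5 * (edges[:-1] + edges[1:]),  # re-seed empty cells
        )
        reps = np.sort(new_reps)
        mse = float(np.mean((values - reps[np.searchsorted(
            0.5 * (reps[:-1] + reps[1:]), values, side="right")]) ** 2))
        if abs(prev_mse - mse) < tol * scale:
            break
        prev_mse = mse

    boundaries = 0.5 * (reps[:-1] + reps[1:])
    # enforce strict ascent (duplicate representatives can collapse cells)
    eps = 1e-12 * max(1.0, abs(hi))
    for i in range(1, len(boundaries)):
        if boundaries[i] <= boundaries[i - 1]:
            boundaries[i] = boundaries[i - 1] + eps
    model = QuantizerModel("lloyd_max", levels, boundaries, reps)
    return model, model.assign(values)
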