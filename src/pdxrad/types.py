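"""Core in-memory containers shared by every stage of the pipeline.

Conventions used throughout the package:

* all 3-D arrays are indexed ``(slice, row, col)``, 0-based;
* a multi-contrast volume adds a trailing channel axis, ordered (T1w, T2w);
* ``voxel_spacing`` is millimetres per axis, in the same ``(slice, row, col)``
  order as the arrays;
* binary masks share the voxel grid of the volume they delineate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MultiContrastVolume",
    "BinaryMask3D",
    "ProbabilityMap3D",
    "RaterSet",
    "RoiVolume",
]


@dataclass
class MultiContrastVolume:
    """Co-registered multi-contrast MR volume.

    Parameters
    ----------
    voxels:
        4-D float array ``(slice, row, col, channel)``.
    channel_names:
        Ordered channel labels, e.g. ``("T1w", "T2w")``.
    voxel_spacing:
        mm per axis, ``(slice, row, col)``.
    subject_id:
        Free-form identifier carried through the pipeline.
    """

    voxels: np.ndarray
    channel_names: tuple[str, ...]
    voxel_spacing: tuple[float, float, float]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 4:
            raise ValueError("voxels must be 4-D (slice, row, col, channel)")
        if self.voxels.shape[-1] != len(self.channel_names):
            raise ValueError("channel axis does not match channel_names")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]

    def channel(self, name: str) -> np.ndarray:
        """Return the 3-D array for one named contrast."""
        return self.voxels[..., self.channel_names.index(name)]


@dataclass
class BinaryMask3D:
    """A 3-D binary segmentation mask on a voxel grid."""

    voxels: np.ndarray
    voxel_spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim != 3:
            raise ValueError("mask must be 3-D (slice, row, col)")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be 0/1")
        self.voxels = arr.astype(np.uint8)
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_spacing))

    def volume_mm3(self) -> float:
        """Tumor volume as foreground voxel count times voxel volume."""
        return float(self.voxels.sum()) * self.voxel_volume_mm3


@dataclass
class ProbabilityMap3D:
    """Per-voxel foreground probabilities in [0, 1]."""

    voxels: np.ndarray
    voxel_spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("probability map must be 3-D")
        if self.voxels.min() < -1e-9 or self.voxels.max() > 1 + 1e-9:
            raise ValueError("probabilities must lie in [0, 1]")
        self.voxels = np.clip(self.voxels, 0.0, 1.0)

    def binarize(self, threshold: float = 0.5) -> BinaryMask3D:
        return BinaryMask3D(
            (self.voxels >= threshold).astype(np.uint8), self.voxel_spacing
        )


@dataclass
class RaterSet:
    """Binary delineations of one volume by several raters."""

    masks: list[BinaryMask3D]
    rater_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.masks) < 1:
            raise ValueError("at least one rater mask required")
        shape = self.masks[0].voxels.shape
        for m in self.masks:
            if m.voxels.shape != shape:
                raise ValueError("all rater masks must share one grid")
        if not self.rater_ids:
            self.rater_ids = [f"rater{i + 1}" for i in range(len(self.masks))]
        if len(self.rater_ids) != len(self.masks):
            raise ValueError("rater_ids length must match masks")

    def __len__(self) -> int:
        return len(self.masks)

    def as_array(self) -> np.ndarray:
        """Stack decisions into a ``(n_raters, slice, row, col)`` array."""
        return np.stack([m.voxels for m in self.masks], axis=0)


@dataclass
class RoiVolume:
    """Single-contrast intensities restricted to a segmented region."""

    intensities: np.ndarray
    mask: BinaryMask3D
    voxel_spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.shape != self.mask.voxels.shape:
            raise ValueError("intensities and mask shapes must match")
        if self.mask.voxels.sum() == 0:
            raise ValueError("ROI mask is empty")

    def roi_values(self) -> np.ndarray:
        """1-D array of intensities inside the mask."""
        return self.intensities[self.mask.voxels.astype(bool)]
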