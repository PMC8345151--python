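"""Assembly of the default 144-feature radiomic bank.

Family cardinalities: morphological 12, statistical 18, histogram 23,
GLCM 24, GLRLM 16, GLSZM 16, GLDZM 16, NGLDM 14, NGTDM 5.  The candidate
bank additionally computes Compactness 1, Compactness 2, Spherical
Disproportion (redundant with sphericity) and GLCM Sum Average (redundant
with joint average); these four are removed by :func:`apply_exclusions`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..types import BinaryMask3D, MultiContrastVolume, RoiVolume
from . import texture
from .intensity import histogram_features, intensity_features
from .morphology import morphological_features
from .quantize import fixed_bin_quantize, lloyd_max_quantize

__all__ = ["FeatureVector", "CANDIDATE_EXCLUSIONS", "extract_all", "apply_exclusions"]

CANDIDATE_EXCLUSIONS = (
    "morph_compactness1",
    "morph_compactness2",
    "morph_spherical_disproportion",
    "glcm_sum_average",
)

EXPECTED_FAMILY_SIZES = {
    "morphological": 12,
    "statistical": 18,
    "histogram": 23,
    "GLCM": 24,
    "GLRLM": 16,
    "GLSZM": 16,
    "GLDZM": 16,
    "NGLDM": 14,
    "NGTDM": 5,
}


@dataclass
class FeatureVector:
    """Named radiomic features with family tags and extraction provenance."""

    values: dict[str, float]
    families: dict[str, str]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.values)

    def family(self, name: str) -> dict[str, float]:
        return {k: v for k, v in self.values.items() if self.families[k] == name}

    def as_series(self):
        import pandas as pd

        return pd.Series(self.values)


def _tagged(prefix: str, family: str, feats: dict[str, float]) -> tuple[dict, dict]:
    values = {f"{prefix}_{k}": float(v) for k, v in feats.items()}
    return values, {k: family for k in values}


def extract_all(
    volume: MultiContrastVolume | np.ndarray,
    mask: BinaryMask3D,
    contrast_label: str = "",
    n_levels: int = 64,
    exclude_redundant: bool = True,
) -> FeatureVector:
    """Extract the radiomic bank from one contrast of a segmented volume.

    Morphological features come from the mask alone; statistical features
    from the raw ROI intensities; histogram features from 64-level
    fixed-bin quantization; the six texture families from 64-level
    Lloyd-Max quantization with 26-voxel connectivity.  With
    ``exclude_redundant`` (default) the four redundant candidates are
    removed, leaving exactly 144 features.
    """
    if isinstance(volume, MultiContrastVolume):
        if not contrast_label:
            raise ValueError("contrast_label required for a multi-contrast volume")
        intensities = volume.channel(contrast_label)
    else:
        intensities = np.asarray(volume, dtype=np.float64)
    roi = RoiVolume(intensities, mask, mask.voxel_spacing)
    vals = roi.roi_values()
    n_voxels = int(mask.voxels.sum())

    values: dict[str, float] = {}
    families: dict[str, str] = {}

    v, f = _tagged("morph", "morphological", morphological_features(mask, include_candidates=True))
    values.update(v)
    families.update(f)
    v, f = _tagged("stat", "statistical", intensity_features(vals))
    values.update(v)
    families.update(f)

    fb_levels, _ = fixed_bin_quantize(vals, n_levels)
    v, f = _tagged("hist", "histogram", histogram_features(fb_levels, n_levels))
    values.update(v)
    families.update(f)

    lm_model, lm_levels = lloyd_max_quantize(vals, n_levels)
    lvol = np.zeros(mask.voxels.shape, dtype=np.int64)
    lvol[mask.voxels.astype(bool)] = lm_levels

    glcm = texture.glcm_matrix(lvol, n_levels)
    v, f = _tagged("glcm", "GLCM", texture.glcm_features(glcm))
    values.update(v)
    families.update(f)
    v, f = _tagged("glrlm", "GLRLM", texture.glrlm_features(texture.glrlm_matrix(lvol, n_levels), n_voxels))
    values.update(v)
    families.update(f)
    v, f = _tagged("glszm", "GLSZM", texture.glszm_features(texture.glszm_matrix(lvol, n_levels), n_voxels))
    values.update(v)
    families.update(f)
    v, f = _tagged("gldzm", "GLDZM", texture.gldzm_features(texture.gldzm_matrix(lvol, n_levels), n_voxels))
    values.update(v)
    families.update(f)
    v, f = _tagged("ngldm", "NGLDM", texture.ngldm_features(texture.ngldm_matrix(lvol, n_levels)))
    values.update(v)
    families.update(f)
    n_t, s_t = texture.ngtdm_table(lvol, n_levels)
    v, f = _tagged("ngtdm", "NGTDM", texture.ngtdm_features(n_t, s_t))
    values.update(v)
    families.update(f)

    candidate = FeatureVector(
        values=values,
        families=families,
        provenance={
            "contrast": contrast_label,
            "n_levels": n_levels,
            "texture_quantizer": lm_model.method,
            "histogram_quantizer": "fixed_bin",
            "connectivity": 26,
            "n_voxels": n_voxels,
        },
    )
    return apply_exclusions(candidate)[0] if exclude_redundant else candidate


def apply_exclusions(candidate: FeatureVector) -> tuple[FeatureVector, list[str]]:
    """Drop the redundant candidate features; idempotent.

    Returns the default bank and the list of names actually removed.
    """
    removed = [n for n in CANDIDATE_EXCLUSIONS if n in candidate.values]
    values = {k: v for k, v in candidate.values.items() if k not in CANDIDATE_EXCLUSIONS}
    families = {k: candidate.families[k] for k in values}
    prov = dict(candidate.provenance)
    prov["excluded"] = list(CANDIDATE_EXCLUSIONS)
    return FeatureVector(values, families, prov), removed
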