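"""Load phantom/real cohorts written in the on-disk layout of ``generate_cohort``."""

from __future__ import annotations

import json
from pathlib import Path

from . import imgio
from .types import BinaryMask3D, MultiContrastVolume, RaterSet

__all__ = ["load_manifest", "load_subject_volume", "load_subject_raters", "load_subject_mask"]


def load_manifest(cohort_dir: str | Path) -> dict:
    path = Path(cohort_dir) / "manifest.json"
    if not path.exists():
        raise FileNotFoundError(
            f"no manifest.json in {cohort_dir}; run the simulate stage first"
        )
    with open(path) as fh:
        return json.load(fh)


def load_subject_volume(
    cohort_dir: str | Path, subject: dict, channel_mode: str = "t1t2"
) -> MultiContrastVolume:
    """Assemble the (T1w, T2w) or T2w-only input volume for one subject."""
    cohort_dir = Path(cohort_dir)
    t2w, spacing = imgio.read_dicom_series(cohort_dir / subject["paths"]["T2w"])
    if channel_mode == "t2only":
        return imgio.stack_channels(None, t2w, spacing, subject["subject_id"])
    if channel_mode != "t1t2":
        raise ValueError("channel_mode must be 't1t2' or 't2only'")
    t1w, _ = imgio.read_dicom_series(cohort_dir / subject["paths"]["T1w"])
    return imgio.stack_channels(t1w, t2w, spacing, subject["subject_id"])


def load_subject_raters(cohort_dir: str | Path, subject: dict) -> RaterSet:
    cohort_dir = Path(cohort_dir)
    masks = [imgio.read_nifti_mask(cohort_dir / p) for p in subject["rater_masks"]]
    return RaterSet(masks)


def load_subject_mask(cohort_dir: str | Path, rel_path: str) -> BinaryMask3D:
    return imgio.read_nifti_mask(Path(cohort_dir) / rel_path)
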