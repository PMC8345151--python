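"""Imaging I/O and intensity preparation.

DICOM is used for multi-slice MR acquisitions (one series per contrast),
NIfTI for masks and derived maps.  Slice order is always recovered from the
DICOM position headers, never from file names.  Intensities are returned as
stored (no modality rescale is applied).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, MRImageStorage, generate_uid

from .types import BinaryMask3D, MultiContrastVolume, ProbabilityMap3D

__all__ = [
    "FormatError",
    "read_dicom_series",
    "write_dicom_series",
    "read_nifti",
    "write_nifti",
    "read_nifti_mask",
    "write_nifti_mask",
    "normalize",
    "stack_channels",
]


class FormatError(ValueError):
    """Raised for incoherent or unreadable imaging data."""


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

def read_dicom_series(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read one DICOM series from a directory into a 3-D array.

    Returns ``(voxels, spacing)`` with voxels shaped ``(slice, row, col)``
    and spacing in mm ``(slice, row, col)``.  Slices are ordered by their
    position along the slice normal; stored pixel values are returned
    without rescaling.
    """
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise FormatError(f"no DICOM files found in {path}")
    datasets = [pydicom.dcmread(f) for f in files]

    uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(uids) != 1:
        raise FormatError(f"directory {path} mixes {len(uids)} series")
    for ds in datasets:
        if "ImagePositionPatient" not in ds:
            raise FormatError("missing ImagePositionPatient tag")

    # project position onto the slice normal (cross product of row/col axes)
    first = datasets[0]
    orient = np.array(first.ImageOrientationPatient, dtype=float)
    normal = np.cross(orient[:3], orient[3:])
    zpos = [float(np.dot(normal, np.array(ds.ImagePositionPatient, float))) for ds in datasets]
    order = np.argsort(zpos)
    datasets = [datasets[i] for i in order]
    zpos = [zpos[i] for i in order]

    arr = np.stack([ds.pixel_array.astype(np.float64) for ds in datasets], axis=0)
    row_sp, col_sp = (float(v) for v in first.PixelSpacing)
    if len(zpos) > 1:
        slice_sp = float(np.median(np.diff(zpos)))
    else:
        slice_sp = float(getattr(first, "SpacingBetweenSlices", getattr(first, "SliceThickness", 1.0)))
    return arr, (slice_sp, row_sp, col_sp)


def write_dicom_series(
    voxels: np.ndarray,
    spacing: tuple[float, float, float],
    out_dir: str | Path,
    *,
    subject_id: str = "subject",
    series_description: str = "MR",
    shuffle_names_rng: np.random.Generator | None = None,
) -> Path:
    """Write a 3-D volume as one DICOM MR series (one file per slice).

    Intensities must be non-negative integers representable as uint16 (the
    phantom generator emits integer-valued arrays for exactly this reason).
    File naming is arbitrary by design; readers must rely on position tags.
    """
    voxels = np.asarray(voxels)
    if np.any(voxels < 0) or np.any(voxels > 65535) or not np.allclose(voxels, np.round(voxels)):
        raise FormatError("DICOM writer requires integer intensities in [0, 65535]")
    voxels = np.round(voxels).astype(np.uint16)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    slice_sp, row_sp, col_sp = spacing
    series_uid = generate_uid(entropy_srcs=[subject_id, series_description, "series"])
    n = voxels.shape[0]
    indices = list(range(n))
    names = [f"slice_{i:03d}.dcm" for i in range(n)]
    if shuffle_names_rng is not None:
        shuffle_names_rng.shuffle(names)

    for i in indices:
        sop_uid = generate_uid(entropy_srcs=[subject_id, series_description, f"sop{i}"])
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = MRImageStorage
        meta.MediaStorageSOPInstanceUID = sop_uid
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = MRImageStorage
        ds.SOPInstanceUID = sop_uid
        ds.Modality = "MR"
        ds.PatientID = subject_id
        ds.PatientName = subject_id
        ds.StudyInstanceUID = generate_uid(entropy_srcs=[subject_id, "study"])
        ds.SeriesInstanceUID = series_uid
        ds.SeriesDescription = series_description
        ds.InstanceNumber = i + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [0.0, 0.0, float(i) * slice_sp]
        ds.PixelSpacing = [row_sp, col_sp]
        ds.SliceThickness = slice_sp
        ds.SpacingBetweenSlices = slice_sp
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.Rows, ds.Columns = voxels.shape[1:3]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = voxels[i].tobytes()
        ds.save_as(out_dir / names[i], enforce_file_format=True)
    return out_dir


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    # data stored as (col, row, slice) on disk; internal order is (slice, row, col)
    return np.diag([spacing[2], spacing[1], spacing[0], 1.0])


def write_nifti(voxels: np.ndarray, spacing: tuple[float, float, float], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(voxels, dtype=np.float64).T, _affine(spacing))
    nib.save(img, path)
    return path


def read_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64).T
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return data, spacing


def write_nifti_mask(mask: BinaryMask3D, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8).T, _affine(mask.voxel_spacing))
    nib.save(img, path)
    return path


def read_nifti_mask(path: str | Path) -> BinaryMask3D:
    data, spacing = read_nifti(path)
    return BinaryMask3D((data > 0.5).astype(np.uint8), spacing)


# ---------------------------------------------------------------------------
# Intensity preparation
# ---------------------------------------------------------------------------

def normalize(volume: MultiContrastVolume, mode: str = "volume") -> MultiContrastVolume:
    """Z-score each contrast channel to zero mean, unit SD.

    ``mode="volume"`` (default) pools statistics over the whole 3-D channel;
    ``mode="slice"`` standardizes each slice independently.
    """
    if mode not in ("volume", "slice"):
        raise ValueError("mode must be 'volume' or 'slice'")
    out = volume.voxels.astype(np.float64).copy()
    for c in range(out.shape[-1]):
        chan = out[..., c]
        if mode == "volume":
            sd = chan.std()
            if sd == 0:
                raise ValueError(f"channel {volume.channel_names[c]} is constant")
            out[..., c] = (chan - chan.mean()) / sd
        else:
            for s in range(chan.shape[0]):
                sd = chan[s].std()
                if sd == 0:
                    raise ValueError(
                        f"channel {volume.channel_names[c]} slice {s} is constant"
                    )
                out[s, ..., c] = (chan[s] - chan[s].mean()) / sd
    return MultiContrastVolume(out, volume.channel_names, volume.voxel_spacing, volume.subject_id)


def stack_channels(
    t1w: np.ndarray | None,
    t2w: np.ndarray,
    spacing: tuple[float, float, float],
    subject_id: str = "",
) -> MultiContrastVolume:
    """Assemble network input channels in the fixed order (T1w, T2w).

    Passing ``t1w=None`` builds a single-channel (T2w-only) volume for the
    single-contrast experiments.
    """
    t2w = np.asarray(t2w, dtype=np.float64)
    if t1w is None:
        return MultiContrastVolume(t2w[..., None], ("T2w",), spacing, subject_id)
    t1w = np.asarray(t1w, dtype=np.float64)
    if t1w.shape != t2w.shape:
        raise ValueError(f"channel shapes differ: {t1w.shape} vs {t2w.shape}")
    return MultiContrastVolume(
        np.stack([t1w, t2w], axis=-1), ("T1w", "T2w"), spacing, subject_id
    )
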