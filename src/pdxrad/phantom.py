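"""Synthetic multi-contrast MR phantoms with simulated expert raters.

The generator emulates the kind of data the pipeline is built for: a
co-registered T1w/T2w axial multi-slice acquisition of a single subcutaneous
tumor, bright against background on T2w and texturally more heterogeneous on
T2w than on T1w.  Ground truth is a lumpy ellipsoid; simulated raters
perturb it with a smooth boundary displacement followed by independent
voxel flips at rates ``1 - sensitivity`` (inside) and ``1 - specificity``
(outside), so that the flip rates are the asymptotic per-rater performance
parameters a consensus algorithm should recover.

Intensities are emitted as non-negative integers so that DICOM round trips
are bit-exact.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.special import sph_harm_y

from . import imgio
from .types import BinaryMask3D, MultiContrastVolume, RaterSet

__all__ = [
    "ContrastParams",
    "PhantomSpec",
    "RaterModel",
    "generate_volume",
    "simulate_raters",
    "generate_cohort",
]


@dataclass(frozen=True)
class ContrastParams:
    """Mean intensities and texture scale of one MR contrast."""

    tumor_mean: float
    background_mean: float
    heterogeneity: float  # SD of the intra-tumor texture field, as a fraction of tumor_mean


def _default_contrasts() -> dict[str, ContrastParams]:
    # T2w: brighter tumor and more texture variability than T1w.
    return {
        "T1w": ContrastParams(tumor_mean=260.0, background_mean=140.0, heterogeneity=0.04),
        "T2w": ContrastParams(tumor_mean=520.0, background_mean=110.0, heterogeneity=0.12),
    }


@dataclass
class PhantomSpec:
    """Geometry, contrast and noise of one synthetic acquisition.

    Defaults mirror a small-animal axial protocol: 128 x 128 in-plane over
    14 slices at 0.25 x 0.25 mm in-plane resolution and 1 mm slices with a
    0.1 mm gap (slice pitch 1.1 mm).  Axis order everywhere is
    ``(slice, row, col)``.
    """

    grid_shape: tuple[int, int, int] = (14, 128, 128)
    voxel_spacing: tuple[float, float, float] = (1.1, 0.25, 0.25)
    tumor_center: tuple[float, float, float] | None = None  # mm; None = grid centre
    tumor_radii: tuple[float, float, float] = (3.5, 4.5, 4.5)  # mm
    boundary_lumpiness: float = 0.15
    contrast_params: dict[str, ContrastParams] = field(default_factory=_default_contrasts)
    noise_sigma: float = 8.0
    noise_model: str = "gaussian"  # or "rician"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")
        if self.tumor_center is None:
            self.tumor_center = tuple(
                n * s / 2.0 for n, s in zip(self.grid_shape, self.voxel_spacing)
            )
        extent = [n * s for n, s in zip(self.grid_shape, self.voxel_spacing)]
        for c, r, e in zip(self.tumor_center, self.tumor_radii, extent):
            if r <= 0:
                raise ValueError("tumor radii must be positive")
            if c - r < 0 or c + r > e:
                raise ValueError("tumor does not fit inside the grid")


@dataclass(frozen=True)
class RaterModel:
    """Per-rater delineation behaviour.

    ``sensitivity``/``specificity`` are the asymptotic voxelwise agreement
    rates with the (jittered) reference inside and outside the tumor;
    ``boundary_jitter_mm`` is the RMS amplitude of a smooth random boundary
    displacement applied before the voxel flips.
    """

    sensitivity: float = 0.95
    specificity: float = 0.995
    boundary_jitter_mm: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.sensitivity <= 1.0) or not (0.0 < self.specificity <= 1.0):
            raise ValueError("sensitivity and specificity must lie in (0, 1]")
        if self.boundary_jitter_mm < 0:
            raise ValueError("boundary_jitter_mm must be >= 0")


def _voxel_centres_mm(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [
        (np.arange(n) + 0.5) * s
        for n, s in zip(spec.grid_shape, spec.voxel_spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _lumpy_indicator(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Rasterize the (optionally lumpy) ellipsoid onto the voxel grid."""
    zz, yy, xx = _voxel_centres_mm(spec)
    dz = (zz - spec.tumor_center[0]) / spec.tumor_radii[0]
    dy = (yy - spec.tumor_center[1]) / spec.tumor_radii[1]
    dx = (xx - spec.tumor_center[2]) / spec.tumor_radii[2]
    rho = np.sqrt(dz**2 + dy**2 + dx**2)
    if spec.boundary_lumpiness == 0:
        return (rho <= 1.0).astype(np.uint8)

    # low-order spherical-harmonic radial perturbation: smooth, lumpy, seeded
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(np.where(rho > 0, dz / np.maximum(rho, 1e-12), 1.0), -1, 1))
    phi = np.arctan2(dy, dx)
    pert = np.zeros_like(rho)
    for ell in (2, 3):
        for m in range(0, ell + 1):
            a = rng.standard_normal()
            b = rng.standard_normal()
            ylm = sph_harm_y(ell, m, theta, phi)
            pert += a * ylm.real + (b * ylm.imag if m > 0 else 0.0)
    pert /= max(pert.std(), 1e-12)
    return (rho <= 1.0 + spec.boundary_lumpiness * pert).astype(np.uint8)


def generate_volume(spec: PhantomSpec) -> tuple[MultiContrastVolume, BinaryMask3D]:
    """Generate one two-contrast phantom volume and its ground-truth mask.

    Deterministic for a fixed ``spec.seed``.  Intensities are integer-valued.
    """
    rng = np.random.default_rng(spec.seed)
    indicator = _lumpy_indicator(spec, rng)

    channels = []
    names = tuple(spec.contrast_params.keys())
    for name in names:
        cp = spec.contrast_params[name]
        img = np.full(spec.grid_shape, cp.background_mean, dtype=np.float64)
        img[indicator == 1] = cp.tumor_mean
        if cp.heterogeneity > 0:
            texture = ndimage.gaussian_filter(
                rng.standard_normal(spec.grid_shape), sigma=(0.8, 2.0, 2.0)
            )
            texture /= max(texture.std(), 1e-12)
            img += indicator * cp.heterogeneity * cp.tumor_mean * texture
        if spec.noise_sigma > 0:
            if spec.noise_model == "gaussian":
                img += spec.noise_sigma * rng.standard_normal(spec.grid_shape)
            else:  # Rician: magnitude of a complex signal with Gaussian noise
                n1 = spec.noise_sigma * rng.standard_normal(spec.grid_shape)
                n2 = spec.noise_sigma * rng.standard_normal(spec.grid_shape)
                img = np.sqrt((img + n1) ** 2 + n2**2)
        channels.append(np.clip(np.round(img), 0, 65535))

    voxels = np.stack(channels, axis=-1)
    volume = MultiContrastVolume(voxels, names, spec.voxel_spacing)
    mask = BinaryMask3D(indicator, spec.voxel_spacing)
    return volume, mask


def simulate_raters(ground_truth: BinaryMask3D, models: list[RaterModel]) -> RaterSet:
    """Simulate expert delineations of one ground-truth mask.

    Each rater mask is the ground truth displaced by a smooth random
    boundary field (RMS ``boundary_jitter_mm``) and then corrupted by
    independent voxel flips: foreground voxels are dropped with probability
    ``1 - sensitivity`` and background voxels added with probability
    ``1 - specificity``.  Deterministic per ``RaterModel.seed``.
    """
    if not models:
        raise ValueError("at least one rater model required")
    gt = ground_truth.voxels
    if gt.sum() == 0:
        raise ValueError("ground truth mask is empty")
    spacing = ground_truth.voxel_spacing

    masks = []
    for model in models:
        rng = np.random.default_rng(model.seed)
        mask = gt.copy()
        if model.boundary_jitter_mm > 0:
            inside = ndimage.distance_transform_edt(gt, sampling=spacing)
            outside = ndimage.distance_transform_edt(1 - gt, sampling=spacing)
            sdt = inside - outside  # mm, positive inside
            fld = ndimage.gaussian_filter(
                rng.standard_normal(gt.shape), sigma=(1.0, 3.0, 3.0)
            )
            fld /= max(fld.std(), 1e-12)
            mask = (sdt + model.boundary_jitter_mm * fld > 0).astype(np.uint8)
        u = rng.random(gt.shape)
        flipped = mask.copy()
        flipped[(mask == 1) & (u < 1.0 - model.sensitivity)] = 0
        flipped[(mask == 0) & (u < 1.0 - model.specificity)] = 1
        masks.append(BinaryMask3D(flipped, spacing))
    return RaterSet(masks)


def generate_cohort(
    n_subjects: int,
    spec_template: PhantomSpec,
    rater_models: list[RaterModel],
    seed: int,
    out_dir: str | Path,
    n_test: int | None = None,
) -> dict:
    """Write a cohort of phantom subjects to disk and return its manifest.

    Per subject: one DICOM series per contrast, a ground-truth NIfTI mask
    and one NIfTI mask per simulated rater.  Tumor size and position vary
    between subjects.  The train/test split (by default about 8 test per 49
    subjects, the cohort design the pipeline targets) is recorded in
    ``manifest.json``.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if n_test is None:
        n_test = max(1, round(n_subjects * 8 / 49))
    if not 0 < n_test < n_subjects:
        raise ValueError("n_test must be in (0, n_subjects)")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    root_ss = np.random.SeedSequence(seed)
    subject_seeds = root_ss.spawn(n_subjects)
    split_rng = np.random.default_rng(root_ss.spawn(1)[0])
    order = split_rng.permutation(n_subjects)
    test_ids = set(order[:n_test].tolist())

    extent = [n * s for n, s in zip(spec_template.grid_shape, spec_template.voxel_spacing)]
    subjects = []
    for i in range(n_subjects):
        srng = np.random.default_rng(subject_seeds[i])
        sid = f"sub{i + 1:03d}"
        radii = tuple(r * srng.uniform(0.8, 1.2) for r in spec_template.tumor_radii)
        center = tuple(
            float(np.clip(e / 2 + srng.uniform(-d, d), r + 0.5, e - r - 0.5))
            for e, r, d in zip(extent, radii, (0.5, 2.0, 2.0))
        )
        spec = dataclasses.replace(
            spec_template,
            tumor_center=center,
            tumor_radii=radii,
            seed=int(srng.integers(2**31 - 1)),
        )
        volume, gt = generate_volume(spec)
        models = [
            dataclasses.replace(m, seed=int(srng.integers(2**31 - 1)))
            for m in rater_models
        ]
        raters = simulate_raters(gt, models)

        sub_dir = out_dir / sid
        paths: dict[str, str] = {}
        for name in volume.channel_names:
            series_dir = sub_dir / name
            imgio.write_dicom_series(
                volume.channel(name),
                spec.voxel_spacing,
                series_dir,
                subject_id=sid,
                series_description=name,
            )
            paths[name] = str(series_dir.relative_to(out_dir))
        gt_path = sub_dir / "ground_truth.nii.gz"
        imgio.write_nifti_mask(gt, gt_path)
        paths["ground_truth"] = str(gt_path.relative_to(out_dir))
        rater_paths = []
        for j, m in enumerate(raters.masks):
            rp = sub_dir / f"rater{j + 1}.nii.gz"
            imgio.write_nifti_mask(m, rp)
            rater_paths.append(str(rp.relative_to(out_dir)))
        subjects.append(
            {
                "subject_id": sid,
                "split": "test" if i in test_ids else "train",
                "paths": paths,
                "rater_masks": rater_paths,
                "true_volume_mm3": gt.volume_mm3(),
            }
        )

    manifest = {
        "seed": seed,
        "n_subjects": n_subjects,
        "n_train": n_subjects - n_test,
        "n_test": n_test,
        "channels": list(spec_template.contrast_params.keys()),
        "voxel_spacing": list(spec_template.voxel_spacing),
        "subjects": subjects,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
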