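"""Segmentation networks: build, train, threshold, predict, post-process.

Five 2-D encoder-decoder architectures share one I/O contract (NHWC in,
per-pixel foreground probability out): a plain U-Net, a dense U-Net
(concatenating skip connections inside each block), a residual U-Net, a
recurrent-residual U-Net (R2U-Net, recurrent convolutions with a fixed
number of time steps inside residual units) and the dense recurrent
residual U-Net (D-R2UNet) combining all three mechanisms.  Segmentation is
per slice; predictions are stacked back into a 3-D volume.

Training uses the soft Dice loss with Adam, Xavier-initialized weights and
geometric augmentation (right-angle rotations, flips, small shifts and
shears).  The binarization threshold is chosen where the precision and
recall curves of pooled training predictions cross.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure

from . import imgio, nn
from .nn.autodiff import Tensor
from .types import BinaryMask3D, MultiContrastVolume, ProbabilityMap3D

__all__ = [
    "NetConfig",
    "TrainConfig",
    "ThresholdResult",
    "SegmentationModel",
    "build_network",
    "dice_loss",
    "augment_pair",
    "augment",
    "train",
    "cross_validate",
    "optimize_threshold",
    "predict",
    "postprocess_largest_component",
]

ARCHS = ("unet", "dense_unet", "res_unet", "r2unet", "dr2unet")


@dataclass
class NetConfig:
    arch: str = "dr2unet"
    depth: int = 4
    base_filters: int = 32
    rcl_timesteps: int = 2
    dropout_rate: float = 0.2
    input_channels: int = 2
    input_size: int = 128
    # initial output bias = logit(head_bias_prior); starting predictions near
    # the expected foreground fraction keeps early Dice training away from
    # the all-background local optimum
    head_bias_prior: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.head_bias_prior < 1.0:
            raise ValueError("head_bias_prior must lie in (0, 1)")
        if self.arch not in ARCHS:
            raise ValueError(f"arch must be one of {ARCHS}")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.rcl_timesteps < 1:
            raise ValueError("rcl_timesteps must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.input_channels not in (1, 2):
            raise ValueError("input_channels must be 1 or 2")


@dataclass
class TrainConfig:
    epochs: int = 250
    learning_rate: float = 1e-5  # configurable; see docs on the printed value
    batch_size: int = 8
    folds: int = 5
    augment: bool = True
    shift_fraction: float = 0.05
    shear: float = 0.05
    seed: int = 0
    final: str = "retrain_all"  # or "best_fold"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.final not in ("retrain_all", "best_fold"):
            raise ValueError("final must be 'retrain_all' or 'best_fold'")


@dataclass
class ThresholdResult:
    threshold: float
    thresholds: np.ndarray
    precision_curve: np.ndarray
    recall_curve: np.ndarray


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


class SegmentationModel:
    """One of the five U-Net variants, parameterized by :class:`NetConfig`."""

    def __init__(self, config: NetConfig, seed: int = 0):
        if config.input_size % 2**config.depth != 0:
            raise ValueError(
                f"input_size {config.input_size} not divisible by 2^depth"
            )
        self.config = config
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(seed)
        f = [config.base_filters * 2**level for level in range(config.depth + 1)]
        cin = config.input_channels
        for level in range(config.depth):
            self._register_block(f"enc{level}", cin, f[level], rng)
            cin = f[level]
        self._register_block("bottom", cin, f[config.depth], rng)
        cin = f[config.depth]
        for level in reversed(range(config.depth)):
            self._conv(f"up{level}", 3, cin, f[level], rng)
            self._register_block(f"dec{level}", 2 * f[level], f[level], rng)
            cin = f[level]
        self._conv("head", 1, cin, 1, rng)
        prior = config.head_bias_prior
        self.params["head_b"].data[:] = np.log(prior / (1.0 - prior))

    # -- parameter registration -------------------------------------------
    def _conv(self, name: str, k: int, cin: int, cout: int, rng) -> None:
        self.params[f"{name}_W"] = nn.xavier_init((k, k, cin, cout), rng)
        self.params[f"{name}_b"] = Tensor(np.zeros(cout), requires_grad=True)

    def _register_block(self, name: str, cin: int, cout: int, rng) -> None:
        arch = self.config.arch
        dense = arch in ("dense_unet", "dr2unet")
        recurrent = arch in ("r2unet", "dr2unet")
        residual = arch in ("res_unet", "r2unet", "dr2unet")
        if dense:
            self._conv(f"{name}_d", 3, cin, cout, rng)
            cin_eff = cin + cout
        else:
            cin_eff = cin
        if recurrent or residual:
            self._conv(f"{name}_proj", 1, cin_eff, cout, rng)
        if recurrent:
            for u in (1, 2):
                self._conv(f"{name}_rcl{u}_f", 3, cout, cout, rng)
                self._conv(f"{name}_rcl{u}_r", 3, cout, cout, rng)
        else:
            self._conv(f"{name}_c1", 3, cin_eff, cout, rng)
            self._conv(f"{name}_c2", 3, cout, cout, rng)

    # -- forward ------------------------------------------------------------
    def _apply_conv(self, name: str, x: Tensor) -> Tensor:
        return nn.conv2d(x, self.params[f"{name}_W"], self.params[f"{name}_b"])

    def _spatial_dropout(self, x: Tensor, train: bool, rng) -> Tensor:
        rate = self.config.dropout_rate
        if not train or rate == 0.0 or rng is None:
            return x
        n, _, _, c = x.data.shape
        keep = (rng.random((n, 1, 1, c)) >= rate) / (1.0 - rate)
        return nn.mul_const(x, keep)

    def _rcl_unit(self, name: str, x: Tensor) -> Tensor:
        """Recurrent convolution: feedforward conv then t recurrent additions."""
        y0 = self._apply_conv(f"{name}_f", x)
        h = nn.relu(y0)
        for _ in range(self.config.rcl_timesteps):
            h = nn.relu(nn.add(self._apply_conv(f"{name}_r", h), y0))
        return h

    def _block(self, name: str, x: Tensor, train: bool, rng) -> Tensor:
        arch = self.config.arch
        dense = arch in ("dense_unet", "dr2unet")
        recurrent = arch in ("r2unet", "dr2unet")
        residual = arch in ("res_unet", "r2unet", "dr2unet")
        if dense:
            x = nn.concat([x, nn.relu(self._apply_conv(f"{name}_d", x))])
        if recurrent:
            base = self._apply_conv(f"{name}_proj", x)
            h = self._rcl_unit(f"{name}_rcl1", base)
            h = self._spatial_dropout(h, train, rng)  # between RCL blocks
            h = self._rcl_unit(f"{name}_rcl2", h)
            return nn.add(base, h)
        h = nn.relu(self._apply_conv(f"{name}_c1", x))
        h = self._apply_conv(f"{name}_c2", h)
        if residual:
            return nn.relu(nn.add(h, self._apply_conv(f"{name}_proj", x)))
        return nn.relu(h)

    def forward(
        self,
        x: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Forward pass on a batch ``(n, H, W, C)``; returns probabilities."""
        depth = self.config.depth
        h = Tensor(np.asarray(x, dtype=np.float64))
        skips = []
        for level in range(depth):
            h = self._block(f"enc{level}", h, train, rng)
            skips.append(h)
            if level >= depth // 2:  # dropout before pooling in deeper levels
                h = self._spatial_dropout(h, train, rng)
            h = nn.maxpool2(h)
        h = self._block("bottom", h, train, rng)
        for level in reversed(range(depth)):
            h = nn.relu(self._apply_conv(f"up{level}", nn.upsample2(h)))
            h = nn.concat([h, skips[level]])
            h = self._block(f"dec{level}", h, train, rng)
        return nn.sigmoid(self._apply_conv("head", h))

    def predict_proba(self, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Inference-mode probabilities for a stack of slices (n, H, W, C)."""
        out = []
        for i in range(0, x.shape[0], batch_size):
            res = self.forward(x[i : i + batch_size])
            out.append(res.data[..., 0])
            nn.release(res)  # free the forward graph promptly
        return np.concatenate(out, axis=0)

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path, threshold: float | None = None) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, **{k: v.data for k, v in self.params.items()})
        sidecar = {"net_config": self.config.__dict__, "threshold": threshold}
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path: str | Path) -> tuple["SegmentationModel", float | None]:
        path = Path(path)
        with open(path.with_suffix(".json")) as fh:
            sidecar = json.load(fh)
        model = cls(NetConfig(**sidecar["net_config"]))
        with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as npz:
            for k in model.params:
                model.params[k].data = npz[k]
        return model, sidecar.get("threshold")


def build_network(config: NetConfig, seed: int = 0) -> SegmentationModel:
    """Construct one of the five architectures with Xavier-initialized weights."""
    return SegmentationModel(config, seed=seed)


# ---------------------------------------------------------------------------
# Loss and augmentation
# ---------------------------------------------------------------------------


def dice_loss(pred: np.ndarray, target: np.ndarray, eps: float = 1.0) -> float:
    """Soft Dice loss ``1 - (2|P.T| + eps) / (|P| + |T| + eps)``."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError("pred and target shapes differ")
    num = 2.0 * (pred * target).sum() + eps
    den = pred.sum() + target.sum() + eps
    return float(1.0 - num / den)


def augment_pair(
    image: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator,
    shift_fraction: float = 0.05,
    shear: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """One random geometric augmentation applied identically to image and mask.

    Rotations are restricted to {90, 180, 270} degrees plus horizontal and
    vertical flips; shifts and shears are small and continuous.  The image
    is linearly interpolated, the mask nearest-neighbour so it stays binary.
    """
    img = np.asarray(image, dtype=np.float64)
    msk = np.asarray(mask)
    k = int(rng.integers(0, 4))
    if k:
        img = np.rot90(img, k, axes=(0, 1))
        msk = np.rot90(msk, k, axes=(0, 1))
    if rng.random() < 0.5:
        img = img[:, ::-1]
        msk = msk[:, ::-1]
    if rng.random() < 0.5:
        img = img[::-1]
        msk = msk[::-1]
    h, w = msk.shape
    dy = rng.uniform(-shift_fraction, shift_fraction) * h
    dx = rng.uniform(-shift_fraction, shift_fraction) * w
    s = rng.uniform(-shear, shear)
    matrix = np.array([[1.0, s], [0.0, 1.0]])
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = center - matrix @ center - np.array([dy, dx])
    out_img = np.empty_like(img)
    for c in range(img.shape[2]):
        out_img[..., c] = ndimage.affine_transform(
            img[..., c], matrix, offset=offset, order=1, mode="constant"
        )
    out_msk = ndimage.affine_transform(
        msk.astype(np.float64), matrix, offset=offset, order=0, mode="constant"
    )
    return out_img, (out_msk > 0.5).astype(np.uint8)


def augment(
    image: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator,
    n: int = 8,
    shift_fraction: float = 0.05,
    shear: float = 0.05,
):
    """Yield ``n`` augmented (image, mask) pairs."""
    for _ in range(n):
        yield augment_pair(image, mask, rng, shift_fraction, shear)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _subject_slices(
    subjects: list[tuple[MultiContrastVolume, BinaryMask3D]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalize each volume and unstack into 2-D slices with subject ids."""
    xs, ys, sid = [], [], []
    for i, (vol, msk) in enumerate(subjects):
        norm = imgio.normalize(vol)
        xs.append(norm.voxels)
        ys.append(msk.voxels)
        sid.extend([i] * vol.voxels.shape[0])
    return np.concatenate(xs), np.concatenate(ys), np.asarray(sid)


@dataclass
class TrainedModel:
    model: SegmentationModel
    history: list[dict] = field(default_factory=list)
    threshold: float = 0.5


def train(
    net_config: NetConfig,
    subjects: list[tuple[MultiContrastVolume, BinaryMask3D]],
    train_config: TrainConfig,
    val_subjects: list[tuple[MultiContrastVolume, BinaryMask3D]] | None = None,
) -> TrainedModel:
    """Train one model on whole subjects (the split is never by slice)."""
    model = build_network(net_config, seed=train_config.seed)
    x, y, _ = _subject_slices(subjects)
    if val_subjects:
        xv, yv, _ = _subject_slices(val_subjects)
    opt = nn.Adam(model.parameters(), lr=train_config.learning_rate)
    rng = np.random.default_rng(train_config.seed)
    history = []
    n = x.shape[0]
    for epoch in range(train_config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, train_config.batch_size):
            idx = order[start : start + train_config.batch_size]
            xb = x[idx]
            yb = y[idx]
            if train_config.augment:
                xb = xb.copy()
                yb = yb.copy()
                for j in range(len(idx)):
                    xb[j], yb[j] = augment_pair(
                        xb[j], yb[j], rng,
                        train_config.shift_fraction, train_config.shear,
                    )
            probs = model.forward(xb, train=True, rng=rng)
            loss = nn.dice_loss_op(probs, yb[..., None].astype(np.float64))
            opt.zero_grad()
            nn.backward(loss)
            opt.step()
            losses.append(float(loss.data))
        rec = {"epoch": epoch, "loss": float(np.mean(losses))}
        if val_subjects:
            pv = model.predict_proba(xv)
            rec["val_loss"] = dice_loss(pv, yv.astype(np.float64))
            rec["val_f1"] = 1.0 - dice_loss((pv >= 0.5).astype(float), yv.astype(float), eps=1e-9)
        history.append(rec)
    return TrainedModel(model=model, history=history)


def cross_validate(
    net_config: NetConfig,
    subjects: list[tuple[MultiContrastVolume, BinaryMask3D]],
    train_config: TrainConfig,
) -> list[list[dict]]:
    """K-fold cross-validation with folds assigned by subject (seeded)."""
    k = train_config.folds
    if len(subjects) < k:
        raise ValueError(f"need at least {k} subjects for {k}-fold CV")
    rng = np.random.default_rng(train_config.seed)
    order = rng.permutation(len(subjects))
    folds = np.array_split(order, k)
    histories = []
    for fold in folds:
        val = [subjects[i] for i in fold]
        trn = [s for i, s in enumerate(subjects) if i not in set(fold.tolist())]
        tm = train(net_config, trn, train_config, val_subjects=val)
        histories.append(tm.history)
    return histories


def fold_assignments(n_subjects: int, folds: int, seed: int) -> list[np.ndarray]:
    """Seeded subject-level fold assignment (exposed for reproducibility)."""
    rng = np.random.default_rng(seed)
    return np.array_split(rng.permutation(n_subjects), folds)


# ---------------------------------------------------------------------------
# Threshold optimization
# ---------------------------------------------------------------------------


def optimize_threshold(
    probs: list[np.ndarray] | np.ndarray,
    refs: list[np.ndarray] | np.ndarray,
    grid: np.ndarray | None = None,
) -> ThresholdResult:
    """Pick the binarization threshold where precision and recall curves cross.

    Precision(t) and recall(t) are computed over a threshold grid on pooled
    predictions; the crossing is linearly interpolated between grid points.
    Ties (multiple or no crossings) resolve toward 0.5; degenerate
    predictions fall back to 0.5 with a warning.
    """
    if grid is None:
        grid = np.linspace(0.02, 0.98, 49)
    p = np.concatenate([np.asarray(a, dtype=float).ravel() for a in np.atleast_1d(probs)]) \
        if isinstance(probs, list) else np.asarray(probs, dtype=float).ravel()
    r = np.concatenate([np.asarray(a).ravel() for a in refs]) \
        if isinstance(refs, list) else np.asarray(refs).ravel()
    pos = r > 0.5
    n_pos = int(pos.sum())
    if n_pos == 0 or n_pos == r.size:
        warnings.warn("degenerate reference (single class); threshold falls back to 0.5")
        return ThresholdResult(0.5, grid, np.full_like(grid, np.nan), np.full_like(grid, np.nan))

    precision = np.empty_like(grid)
    recall = np.empty_like(grid)
    for i, t in enumerate(grid):
        pred = p >= t
        tp = float(np.sum(pred & pos))
        npred = float(pred.sum())
        precision[i] = tp / npred if npred > 0 else np.nan
        recall[i] = tp / n_pos

    diff = precision - recall
    valid = ~np.isnan(diff)
    if not valid.any() or np.nanmax(np.abs(diff)) < 1e-12:
        return ThresholdResult(0.5, grid, precision, recall)

    crossings = []
    vi = np.flatnonzero(valid)
    for a, b in zip(vi[:-1], vi[1:]):
        da, db = diff[a], diff[b]
        if da == 0.0:
            crossings.append(grid[a])
        elif da * db < 0:
            frac = da / (da - db)
            crossings.append(grid[a] + frac * (grid[b] - grid[a]))
    if diff[vi[-1]] == 0.0:
        crossings.append(grid[vi[-1]])
    if not crossings:
        warnings.warn("precision and recall curves do not cross; threshold falls back to 0.5")
        return ThresholdResult(0.5, grid, precision, recall)
    best = min(crossings, key=lambda t: (abs(t - 0.5), t))
    return ThresholdResult(float(best), grid, precision, recall)


# ---------------------------------------------------------------------------
# Prediction and post-processing
# ---------------------------------------------------------------------------


def predict(
    model: SegmentationModel,
    volume: MultiContrastVolume,
    threshold: float = 0.5,
) -> tuple[ProbabilityMap3D, BinaryMask3D]:
    """Slice-wise 2-D inference stacked back into a 3-D volume.

    Expects an intensity-normalized volume with the channel count the model
    was built for; the mask is ``probability >= threshold``.
    """
    if volume.voxels.shape[-1] != model.config.input_channels:
        raise ValueError(
            f"model expects {model.config.input_channels} channels, "
            f"volume has {volume.voxels.shape[-1]}"
        )
    prob = model.predict_proba(volume.voxels)
    pmap = ProbabilityMap3D(prob, volume.voxel_spacing)
    return pmap, BinaryMask3D((prob >= threshold).astype(np.uint8), volume.voxel_spacing)


def postprocess_largest_component(mask: BinaryMask3D) -> BinaryMask3D:
    """Keep only the largest 8-connected foreground component per 2-D slice.

    Equal-size ties keep the component containing the smallest (row, col)
    index in row-major order, making the operation deterministic.
    """
    out = np.zeros_like(mask.voxels)
    for s in range(mask.voxels.shape[0]):
        sl = mask.voxels[s]
        if sl.sum() == 0:
            continue
        labels = measure.label(sl, connectivity=2)
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        max_size = sizes.max()
        tied = np.flatnonzero(sizes == max_size)
        if len(tied) == 1:
            keep = tied[0]
        else:
            first_idx = {
                lab: np.flatnonzero(labels.ravel() == lab)[0] for lab in tied
            }
            keep = min(tied, key=lambda lab: first_idx[lab])
        out[s] = (labels == keep).astype(np.uint8)
    return BinaryMask3D(out, mask.voxel_spacing)
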