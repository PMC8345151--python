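"""Voxelwise segmentation scoring against a reference mask.

F1 (Dice), precision, recall and accuracy are computed from the voxel
confusion counts; AUC is the area under the ROC curve of voxel
probabilities against reference labels.  Metrics with an empty denominator
are reported as missing (never coerced to 0 or 1) so cohort means stay
unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .types import BinaryMask3D, ProbabilityMap3D

__all__ = [
    "UndefinedMetricError",
    "ConfusionCounts",
    "confusion",
    "f1_score",
    "precision_recall_accuracy",
    "auc",
    "score_cohort",
]


class UndefinedMetricError(ValueError):
    """A metric's denominator is zero; the value is undefined, not 0."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(pred: BinaryMask3D | np.ndarray, ref: BinaryMask3D | np.ndarray) -> ConfusionCounts:
    p = pred.voxels if isinstance(pred, BinaryMask3D) else np.asarray(pred)
    r = ref.voxels if isinstance(ref, BinaryMask3D) else np.asarray(ref)
    if p.shape != r.shape:
        raise ValueError(f"grid mismatch: {p.shape} vs {r.shape}")
    p = p.astype(bool)
    r = r.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(p & r)),
        tn=int(np.sum(~p & ~r)),
        fp=int(np.sum(p & ~r)),
        fn=int(np.sum(~p & r)),
    )


def f1_score(c: ConfusionCounts) -> float:
    """Dice overlap 2TP / (2TP + FP + FN)."""
    den = 2 * c.tp + c.fp + c.fn
    if den == 0:
        raise UndefinedMetricError("F1 undefined: both masks empty")
    return 2.0 * c.tp / den


def precision_recall_accuracy(c: ConfusionCounts) -> tuple[float, float, float]:
    """TP/(TP+FP), TP/(TP+FN), (TP+TN)/total."""
    if c.tp + c.fp == 0:
        raise UndefinedMetricError("precision undefined: empty prediction")
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("recall undefined: empty reference")
    precision = c.tp / (c.tp + c.fp)
    recall = c.tp / (c.tp + c.fn)
    accuracy = (c.tp + c.tn) / c.total
    return precision, recall, accuracy


def auc(prob: ProbabilityMap3D | np.ndarray, ref: BinaryMask3D | np.ndarray) -> float:
    """Area under the voxelwise ROC curve (midrank tie handling)."""
    p = prob.voxels if isinstance(prob, ProbabilityMap3D) else np.asarray(prob)
    r = ref.voxels if isinstance(ref, BinaryMask3D) else np.asarray(ref)
    if p.shape != r.shape:
        raise ValueError("grid mismatch")
    labels = r.ravel().astype(int)
    if labels.min() == labels.max():
        raise UndefinedMetricError("AUC undefined: reference has a single class")
    return float(roc_auc_score(labels, p.ravel().astype(float)))


def _subject_scores(prob, pred, ref) -> dict[str, float]:
    c = confusion(pred, ref)
    out: dict[str, float] = {}
    try:
        out["f1"] = f1_score(c)
    except UndefinedMetricError:
        out["f1"] = np.nan
    try:
        pr, rc, ac = precision_recall_accuracy(c)
        out["precision"], out["recall"], out["accuracy"] = pr, rc, ac
    except UndefinedMetricError:
        out.setdefault("precision", np.nan)
        out.setdefault("recall", np.nan)
        out["accuracy"] = c.total and (c.tp + c.tn) / c.total
    if prob is not None:
        try:
            out["auc"] = auc(prob, ref)
        except UndefinedMetricError:
            out["auc"] = np.nan
    return out


def score_cohort(
    predictions: dict[str, BinaryMask3D],
    references: dict[str, BinaryMask3D],
    probabilities: dict[str, ProbabilityMap3D] | None = None,
    mode: str = "volume",
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject scores plus mean, SD and bootstrap 95% CI per metric.

    ``mode="volume"`` pools 3-D counts per subject (default);
    ``mode="slice"`` scores each 2-D slice as one observation.
    """
    if set(predictions) != set(references):
        raise ValueError("unmatched subject IDs between predictions and references")
    if mode not in ("volume", "slice"):
        raise ValueError("mode must be 'volume' or 'slice'")
    rows = []
    for sid in sorted(predictions):
        pred, ref = predictions[sid], references[sid]
        prob = probabilities.get(sid) if probabilities else None
        if mode == "volume":
            rows.append({"subject_id": sid, **_subject_scores(prob, pred, ref)})
        else:
            for s in range(pred.voxels.shape[0]):
                pr = prob.voxels[s] if prob is not None else None
                rows.append(
                    {
                        "subject_id": f"{sid}/slice{s:03d}",
                        **_subject_scores(pr, pred.voxels[s][None], ref.voxels[s][None]),
                    }
                )
    table = pd.DataFrame(rows).set_index("subject_id")

    rng = np.random.default_rng(seed)
    summary_rows = []
    for col in table.columns:
        vals = table[col].dropna().to_numpy()
        if len(vals) == 0:
            summary_rows.append({"metric": col, "mean": np.nan, "sd": np.nan,
                                 "ci_low": np.nan, "ci_high": np.nan, "n": 0})
            continue
        boots = np.array([
            rng.choice(vals, size=len(vals), replace=True).mean()
            for _ in range(n_bootstrap)
        ])
        summary_rows.append(
            {
                "metric": col,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "ci_low": float(np.percentile(boots, 2.5)),
                "ci_high": float(np.percentile(boots, 97.5)),
                "n": int(len(vals)),
            }
        )
    return table, pd.DataFrame(summary_rows).set_index("metric")
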