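"""First-order intensity statistics and intensity-histogram features.

The statistical family operates on the raw ROI intensities; the histogram
family on the 64-level fixed-bin quantized levels, adding discretization-
specific features (mode, entropy, uniformity and histogram gradients).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "intensity_features",
    "histogram_features",
    "STAT_FEATURES",
    "HIST_FEATURES",
]

STAT_FEATURES = (
    "mean", "variance", "skewness", "kurtosis", "median", "minimum", "p10",
    "p90", "maximum", "iqr", "range", "mad", "robust_mad", "median_ad",
    "cov", "qcod", "energy", "rms",
)

HIST_FEATURES = (
    "mean", "variance", "skewness", "kurtosis", "median", "minimum", "p10",
    "p90", "maximum", "mode", "iqr", "range", "mad", "robust_mad",
    "median_ad", "cov", "qcod", "entropy", "uniformity",
    "max_gradient", "max_gradient_level", "min_gradient", "min_gradient_level",
)


def _moments(x: np.ndarray) -> dict[str, float]:
    mu = float(x.mean())
    m2 = float(((x - mu) ** 2).mean())
    out = {"mean": mu, "variance": m2}
    if m2 > 0:
        m3 = float(((x - mu) ** 3).mean())
        m4 = float(((x - mu) ** 4).mean())
        out["skewness"] = m3 / m2**1.5
        out["kurtosis"] = m4 / m2**2 - 3.0  # excess kurtosis
    else:
        out["skewness"] = 0.0
        out["kurtosis"] = 0.0
    return out


def _common(x: np.ndarray) -> dict[str, float]:
    out = _moments(x)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    out["median"] = float(p50)
    out["minimum"] = float(x.min())
    out["p10"] = float(p10)
    out["p90"] = float(p90)
    out["maximum"] = float(x.max())
    out["iqr"] = float(p75 - p25)
    out["range"] = float(x.max() - x.min())
    out["mad"] = float(np.abs(x - out["mean"]).mean())
    sub = x[(x >= p10) & (x <= p90)]
    out["robust_mad"] = float(np.abs(sub - sub.mean()).mean()) if sub.size else 0.0
    out["median_ad"] = float(np.abs(x - p50).mean())
    out["cov"] = float(np.sqrt(out["variance"]) / out["mean"]) if out["mean"] != 0 else np.nan
    out["qcod"] = float((p75 - p25) / (p75 + p25)) if (p75 + p25) != 0 else np.nan
    return out


def intensity_features(values: np.ndarray) -> dict[str, float]:
    """The 18 first-order statistics of the raw ROI intensities."""
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    out = _common(x)
    out["energy"] = float((x**2).sum())
    out["rms"] = float(np.sqrt((x**2).mean()))
    return {k: out[k] for k in STAT_FEATURES}


def histogram_features(levels: np.ndarray, n_levels: int = 64) -> dict[str, float]:
    """The 23 intensity-histogram features of quantized levels 1..n_levels."""
    g = np.asarray(levels, dtype=np.int64).ravel()
    if g.size == 0:
        raise ValueError("empty ROI")
    if g.min() < 1 or g.max() > n_levels:
        raise ValueError("levels must lie in 1..n_levels")
    out = _common(g.astype(np.float64))

    counts = np.bincount(g, minlength=n_levels + 1)[1:]
    p = counts / g.size
    nz = p > 0
    out["mode"] = float(np.argmax(counts) + 1)  # smallest level on ties
    out["entropy"] = float(-(p[nz] * np.log2(p[nz])).sum())
    out["uniformity"] = float((p**2).sum())

    grad = np.empty(n_levels, dtype=np.float64)
    if n_levels >= 2:
        grad[0] = counts[1] - counts[0]
        grad[-1] = counts[-1] - counts[-2]
        if n_levels > 2:
            grad[1:-1] = (counts[2:] - counts[:-2]) / 2.0
    else:
        grad[:] = 0.0
    out["max_gradient"] = float(grad.max())
    out["max_gradient_level"] = float(np.argmax(grad) + 1)
    out["min_gradient"] = float(grad.min())
    out["min_gradient_level"] = float(np.argmin(grad) + 1)
    return {k: out[k] for k in HIST_FEATURES}
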