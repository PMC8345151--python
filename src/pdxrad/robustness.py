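"""Statistical comparison of radiomic feature sets across segmentations.

Four analyses quantify how features respond to segmentation provenance:

* Spearman correlation between feature tables from two sources (consensus
  vs network), with exact permutation p-values at small n;
* test-retest reproducibility via Lin's concordance correlation
  coefficient (CCC);
* Bland-Altman agreement of tumor volumes (bias and limits of agreement on
  percent differences relative to the reference);
* boundary-sensitivity: the Spearman correlation of per-subject feature
  changes against volume changes, with features flagged robust when
  ``-0.4 <= rho <= 0.4``, plus hierarchical clustering of the feature
  change profiles (complete linkage on correlation distance).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "spearman_rho_p",
    "spearman_table",
    "ccc",
    "ccc_table",
    "bland_altman_volumes",
    "sensitivity_to_boundary",
    "ClusterReport",
    "cluster_features",
    "consensus_feature_report",
]

HIGH_CORR_RHO = 0.9
HIGH_CORR_P = 0.05
REPRODUCIBLE_CCC = 0.9
ROBUST_BAND = 0.4
EXACT_P_MAX_N = 8


@lru_cache(maxsize=8)
def _exact_null_rhos(n: int) -> np.ndarray:
    """Null distribution of Spearman's rho over all n! rank permutations."""
    base = np.arange(1, n + 1, dtype=np.float64)
    perms = np.array(list(permutations(base)))
    bc = base - base.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    denom = np.sqrt((bc**2).sum() * (pc**2).sum(axis=1))
    return (pc @ bc) / denom


def spearman_rho_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The p-value comes from the exact permutation null when ``n <= 8`` and
    neither vector has ties, otherwise from the t-approximation.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return np.nan, np.nan
    rho = float(stats.spearmanr(x, y).statistic)
    ties = np.unique(x).size < n or np.unique(y).size < n
    if n <= EXACT_P_MAX_N and not ties:
        null = _exact_null_rhos(n)
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def spearman_table(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Per-feature Spearman rho and p between two matched feature tables.

    Rows are subjects, columns features; tables must share subjects and
    features.  Adds the high-correlation flag (rho >= 0.9 and p <= 0.05).
    """
    a, b = a.align(b, join="inner")
    if a.shape[0] < 4:
        raise ValueError("need at least 4 matched subjects")
    rows = []
    for feat in a.columns:
        rho, p = spearman_rho_p(a[feat].to_numpy(), b[feat].to_numpy())
        rows.append(
            {
                "feature": feat,
                "rho": rho,
                "p": p,
                "high_corr": bool(rho >= HIGH_CORR_RHO and p <= HIGH_CORR_P)
                if np.isfinite(rho)
                else False,
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def ccc(x: np.ndarray, y: np.ndarray, convention: str = "population") -> float:
    """Lin's concordance correlation coefficient.

    ``2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)`` with population
    (1/n) moments by default; ``convention="sample"`` uses 1/(n-1).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 matched pairs")
    ddof = 0 if convention == "population" else 1
    sx = x.var(ddof=ddof)
    sy = y.var(ddof=ddof)
    sxy = ((x - x.mean()) * (y - y.mean())).sum() / (len(x) - ddof)
    den = sx + sy + (x.mean() - y.mean()) ** 2
    if den == 0:
        return np.nan
    return float(2.0 * sxy / den)


def ccc_table(a: pd.DataFrame, b: pd.DataFrame, convention: str = "population") -> pd.DataFrame:
    """Per-feature CCC between two matched tables, with reproducibility flag."""
    a, b = a.align(b, join="inner")
    rows = []
    for feat in a.columns:
        v = ccc(a[feat].to_numpy(), b[feat].to_numpy(), convention)
        rows.append(
            {
                "feature": feat,
                "ccc": v,
                "reproducible": bool(v >= REPRODUCIBLE_CCC) if np.isfinite(v) else False,
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def bland_altman_volumes(v_ref: np.ndarray, v_test: np.ndarray) -> dict[str, float]:
    """Bland-Altman agreement of volumes, in percent of the reference.

    Per-subject difference is ``(ref - test) / ref * 100`` so a method that
    underestimates the reference yields a positive bias.  Limits of
    agreement are ``bias +/- 1.96 SD``; the bias-vs-mean-volume Pearson
    correlation is reported alongside.
    """
    v_ref = np.asarray(v_ref, dtype=np.float64)
    v_test = np.asarray(v_test, dtype=np.float64)
    if len(v_ref) != len(v_test) or len(v_ref) < 3:
        raise ValueError("need at least 3 matched volumes")
    if np.any(v_ref == 0):
        raise ValueError("zero reference volume")
    diff = (v_ref - v_test) / v_ref * 100.0
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    mean_vol = (v_ref + v_test) / 2.0
    if np.unique(diff).size > 1 and np.unique(mean_vol).size > 1:
        corr = float(stats.pearsonr(mean_vol, diff).statistic)
    else:
        corr = np.nan
    return {
        "bias_percent": bias,
        "sd_percent": sd,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "bias_volume_corr": corr,
    }


def sensitivity_to_boundary(
    staple_table: pd.DataFrame,
    net_table: pd.DataFrame,
    volumes_staple: pd.Series,
    volumes_net: pd.Series,
) -> pd.DataFrame:
    """Per-feature sensitivity to boundary change.

    For each feature f the per-subject change ``delta_f = staple - net`` is
    correlated (Spearman) with the volume change ``delta_v``; features with
    ``-0.4 <= rho <= 0.4`` are flagged robust.  Features whose changes are
    constant across subjects have no defined correlation and are flagged
    ``degenerate`` (reported separately, not silently classed robust).
    """
    staple_table, net_table = staple_table.align(net_table, join="inner")
    if staple_table.shape[0] < 4:
        raise ValueError("need at least 4 matched subjects")
    dv = (volumes_staple - volumes_net).loc[staple_table.index].to_numpy()
    rows = []
    for feat in staple_table.columns:
        df = staple_table[feat].to_numpy() - net_table[feat].to_numpy()
        if np.unique(df).size == 1 or np.unique(dv).size == 1:
            rows.append(
                {"feature": feat, "rho": np.nan, "p": np.nan,
                 "robust": False, "degenerate": True}
            )
            continue
        rho, p = spearman_rho_p(df, dv)
        rows.append(
            {
                "feature": feat,
                "rho": rho,
                "p": p,
                "robust": bool(-ROBUST_BAND <= rho <= ROBUST_BAND),
                "degenerate": False,
            }
        )
    return pd.DataFrame(rows).set_index("feature")


@dataclass
class ClusterReport:
    linkage_matrix: np.ndarray  # scipy linkage format
    merge_heights: np.ndarray
    cut_height: float
    cluster_assignments: dict[str, int]
    n_clusters: int
    cophenetic_coefficients: dict[str, float]  # per linkage method
    feature_names: list[str]


def correlation_distance_matrix(delta_table: pd.DataFrame, min_pairs: int = 3) -> tuple[np.ndarray, list[str]]:
    """Pairwise Spearman correlation distance ``d = 1 - rho`` between features.

    Correlations use pairwise-complete observations; pairs with fewer than
    ``min_pairs`` complete rows (or a constant profile) get the maximum
    distance 2.0.
    """
    feats = list(delta_table.columns)
    k = len(feats)
    d = np.zeros((k, k))
    cols = [delta_table[f].to_numpy(dtype=np.float64) for f in feats]
    for i in range(k):
        for j in range(i + 1, k):
            ok = np.isfinite(cols[i]) & np.isfinite(cols[j])
            if ok.sum() < min_pairs or np.unique(cols[i][ok]).size == 1 or np.unique(cols[j][ok]).size == 1:
                dist = 2.0
            else:
                rho = float(stats.spearmanr(cols[i][ok], cols[j][ok]).statistic)
                dist = 1.0 - rho
            d[i, j] = d[j, i] = dist
    return d, feats


def cluster_features(
    delta_table: pd.DataFrame,
    cut_height: float,
    method: str = "complete",
    min_pairs: int = 3,
) -> ClusterReport:
    """Hierarchical clustering of feature change profiles.

    Distance is ``1 - Spearman rho`` between per-subject change profiles;
    agglomeration uses complete linkage by default.  The cut height is an
    explicit required parameter (correlation distances live in [0, 2]).
    Cophenetic correlation coefficients are reported for single, average
    and complete linkage so the choice of linkage can be justified.
    """
    if delta_table.shape[1] < 3:
        raise ValueError("need at least 3 features to cluster")
    d, feats = correlation_distance_matrix(delta_table, min_pairs)
    condensed = squareform(d, checks=False)
    z = linkage(condensed, method=method)
    coph = {}
    for m in ("single", "average", "complete"):
        zc = z if m == method else linkage(condensed, method=m)
        c, _ = cophenet(zc, condensed)
        coph[m] = float(c)
    labels = fcluster(z, t=cut_height, criterion="distance")
    return ClusterReport(
        linkage_matrix=z,
        merge_heights=z[:, 2].copy(),
        cut_height=float(cut_height),
        cluster_assignments=dict(zip(feats, (int(v) for v in labels))),
        n_clusters=int(labels.max()),
        cophenetic_coefficients=coph,
        feature_names=feats,
    )


def consensus_feature_report(
    scc: pd.DataFrame,
    reproducibility: pd.DataFrame,
    sensitivity: pd.DataFrame,
    denominator: int | None = None,
) -> dict:
    """Intersection of high-correlation, reproducible and robust features.

    Returns counts and percentages (two decimals) over the configured
    denominator (defaults to the number of features present).
    """
    feats = scc.index.intersection(reproducibility.index).intersection(sensitivity.index)
    high = set(scc.loc[feats].index[scc.loc[feats, "high_corr"]])
    rep = set(reproducibility.loc[feats].index[reproducibility.loc[feats, "reproducible"]])
    rob = set(sensitivity.loc[feats].index[sensitivity.loc[feats, "robust"]])
    consensus = sorted(high & rep & rob)
    den = denominator if denominator is not None else len(feats)
    pct = lambda k: round(100.0 * k / den, 2)  # noqa: E731
    return {
        "n_features": len(feats),
        "denominator": den,
        "n_high_corr": len(high),
        "pct_high_corr": pct(len(high)),
        "n_reproducible": len(rep),
        "pct_reproducible": pct(len(rep)),
        "n_robust": len(rob),
        "pct_robust": pct(len(rob)),
        "n_consensus": len(consensus),
        "pct_consensus": pct(len(consensus)),
        "consensus_features": consensus,
    }
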