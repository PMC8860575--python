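"""Stage-module clustering and cross-dataset integration statistics.

Time-course profiles (nascent RNA, total mRNA, SUMO sites, ChIP occupancy)
are row Z-scored and clustered with k-means into modules; each module gets
a differentiation-stage label — PA (pre-adipocyte), CE (clonal expansion)
or MA (mature adipocyte) — from where its centroid peaks.  Per-feature
Pearson correlation links profiles across datasets, and hypergeometric
over-representation with Benjamini-Hochberg correction tests set overlaps.
Also hosts the negative-binomial likelihood-ratio test used as the
documented stand-in for differential time-course testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from ._errors import ConfigurationError, ParameterError, ValidationError

logger = logging.getLogger(__name__)

STAGES = ("PA", "CE", "MA")
DEFAULT_STAGE_MAP = {"d-2": "PA", "d1": "CE", "d3": "CE", "d7": "MA"}


@dataclass
class TimecourseMatrix:
    """Feature x time-point values with an assay tag and transform state."""

    values: pd.DataFrame
    assay: str = ""
    transform: str = "raw"
    constant_rows: tuple[str, ...] = ()


def zscore_rows(matrix: pd.DataFrame | TimecourseMatrix) -> TimecourseMatrix:
    """Row Z-score with the sample SD; constant rows become zero and are flagged."""
    df = matrix.values if isinstance(matrix, TimecourseMatrix) else matrix
    assay = matrix.assay if isinstance(matrix, TimecourseMatrix) else ""
    if df.shape[1] < 2:
        raise ParameterError("need >= 2 columns to Z-score")
    sd = df.std(axis=1, ddof=1)
    constant = sd == 0
    z = df.sub(df.mean(axis=1), axis=0).div(sd.replace(0.0, np.nan), axis=0)
    z[constant] = 0.0
    return TimecourseMatrix(
        z, assay=assay, transform="zscore", constant_rows=tuple(df.index[constant])
    )


@dataclass
class ModuleAssignment:
    """k-means module membership with per-module stage labels and centroids."""

    labels: pd.Series  # feature_id -> module id
    centroids: pd.DataFrame  # module id x time point
    stages: dict[int, str] = field(default_factory=dict)

    def stage_of(self, feature_id: str) -> str:
        return self.stages[int(self.labels.loc[feature_id])]


def cluster_modules(
    z: pd.DataFrame | TimecourseMatrix, k: int, seed: int = 0, n_init: int = 10
) -> ModuleAssignment:
    """k-means (Euclidean, k-means++, >= 10 restarts, fixed seed) on Z rows."""
    df = z.values if isinstance(z, TimecourseMatrix) else z
    if k < 2:
        raise ParameterError("k must be >= 2")
    if k > df.shape[0]:
        raise ParameterError(f"k={k} exceeds the {df.shape[0]} rows available")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    labels = km.fit_predict(df.to_numpy())
    centroids = pd.DataFrame(km.cluster_centers_, columns=df.columns)
    centroids.index.name = "module"
    return ModuleAssignment(pd.Series(labels, index=df.index, name="module"), centroids)


def choose_k(
    z: pd.DataFrame | TimecourseMatrix,
    k_range: Sequence[int] = range(4, 16),
    seed: int = 0,
) -> int:
    """Silhouette scan over candidate k; returns the best-scoring k."""
    df = z.values if isinstance(z, TimecourseMatrix) else z
    best_k, best_score = None, -np.inf
    for k in k_range:
        if k >= df.shape[0]:
            continue
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(
            df.to_numpy()
        )
        score = silhouette_score(df.to_numpy(), labels)
        if score > best_score:
            best_k, best_score = k, score
    if best_k is None:
        raise ParameterError("no candidate k fits the data")
    return best_k


def assign_stage(
    centroid: pd.Series, stage_map: Mapping[str, str] = DEFAULT_STAGE_MAP
) -> str:
    """Stage whose time points have the highest mean centroid value.

    Ties break in PA > CE > MA order with a logged warning.
    """
    unmapped = [tp for tp in centroid.index if tp not in stage_map]
    if unmapped:
        raise ConfigurationError(f"time points without a stage mapping: {unmapped}")
    means = {}
    for stage in STAGES:
        tps = [tp for tp in centroid.index if stage_map[tp] == stage]
        if tps:
            means[stage] = float(centroid.loc[tps].mean())
    best = max(means.values())
    winners = [s for s in STAGES if means.get(s) == best]
    if len(winners) > 1:
        logger.warning("stage tie %s broken to %s", winners, winners[0])
    return winners[0]


def assign_stages(
    assignment: ModuleAssignment, stage_map: Mapping[str, str] = DEFAULT_STAGE_MAP
) -> ModuleAssignment:
    """Fill ``assignment.stages`` from the module centroids."""
    assignment.stages = {
        int(m): assign_stage(assignment.centroids.loc[m], stage_map)
        for m in assignment.centroids.index
    }
    return assignment


def profile_correlation(
    dataset_a: pd.DataFrame, dataset_b: pd.DataFrame, min_points: int = 3
) -> pd.DataFrame:
    """Per-feature Pearson r between matched time-course profiles.

    Features are matched by index, time points by column intersection
    (>= ``min_points`` required).  Zero-variance profiles give undefined r
    (NaN, excluded from binning but counted).  Returns a frame with columns
    feature_id, r, defined.
    """
    common_cols = [c for c in dataset_a.columns if c in set(dataset_b.columns)]
    if len(common_cols) < min_points:
        raise ParameterError(
            f"only {len(common_cols)} matched time points; need >= {min_points}"
        )
    features = dataset_a.index.intersection(dataset_b.index)
    a = dataset_a.loc[features, common_cols].to_numpy(dtype=float)
    b = dataset_b.loc[features, common_cols].to_numpy(dtype=float)
    a_c = a - a.mean(axis=1, keepdims=True)
    b_c = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((a_c**2).sum(axis=1) * (b_c**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (a_c * b_c).sum(axis=1) / denom, np.nan)
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame({"feature_id": features, "r": r, "defined": ~np.isnan(r)})


def correlation_bins(r: Sequence[float], n_bins: int = 10) -> np.ndarray:
    """Right-closed equal-width histogram of r over [-1, 1]; r=-1 in the lowest bin.

    Undefined (NaN) values are excluded; counts sum to the number of defined r.
    """
    arr = np.asarray(r, dtype=float)
    arr = arr[~np.isnan(arr)]
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    idx = np.digitize(arr, edges[1:-1], right=True)
    return np.bincount(idx, minlength=n_bins)


def hypergeom_overrep(k: int, n: int, m: int, universe: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(universe, n, m)."""
    if not (0 <= k <= min(n, m) <= universe) or max(n, m) > universe:
        raise ValidationError(
            f"inconsistent counts k={k}, n={n}, m={m}, N={universe}"
        )
    return float(stats.hypergeom.sf(k - 1, universe, n, m))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, order-stable)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def nb_lrt(counts: Sequence[float], group_indices: Sequence[np.ndarray]) -> float:
    """Negative-binomial likelihood-ratio p-value for a group-means vs grand-mean fit.

    A shared dispersion is estimated by method of moments from the
    full-model residuals; the likelihood ratio is referred to chi-square
    with (groups - 1) degrees of freedom.  All-zero features return p = 1.
    This is a transparent stand-in for a full GLM-based count LRT, not a
    re-implementation of one.
    """
    y = np.asarray(counts, dtype=float)
    if len(group_indices) < 2:
        raise ParameterError("need >= 2 groups")
    if any(len(idx) < 2 for idx in group_indices):
        raise ParameterError("need >= 2 replicates per group")
    if not np.any(y > 0):
        return 1.0
    n = y.size
    g = len(group_indices)
    mu_full = np.empty(n)
    for idx in group_indices:
        mu_full[idx] = y[idx].mean()
    mu_red = np.full(n, y.mean())

    resid_ss = float(((y - mu_full) ** 2).sum()) * n / max(n - g, 1)
    denom = float((mu_full**2).sum())
    alpha = max((resid_ss - mu_full.sum()) / denom, 0.0) if denom > 0 else 0.0

    def loglik(mu: np.ndarray) -> float:
        mu = np.maximum(mu, 1e-8)
        if alpha < 1e-8:
            return float(stats.poisson.logpmf(y, mu).sum())
        r = 1.0 / alpha
        return float(stats.nbinom.logpmf(y, r, r / (r + mu)).sum())

    stat = max(2.0 * (loglik(mu_full) - loglik(mu_red)), 0.0)
    return float(stats.chi2.sf(stat, df=g - 1))


def overlap_report(sets: Mapping[str, set]) -> dict[tuple[str, ...], int]:
    """Exact Venn-partition counts over named identifier sets.

    Keys are sorted tuples of set names; the value counts elements belonging
    to exactly those sets (and no others).
    """
    names = sorted(sets)
    report: dict[tuple[str, ...], int] = {}
    for size in range(1, len(names) + 1):
        for combo in combinations(names, size):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(set(), *(sets[n] for n in names if n not in combo))
            report[combo] = len(inside - outside)
    return report


__all__ = [
    "TimecourseMatrix",
    "ModuleAssignment",
    "zscore_rows",
    "cluster_modules",
    "choose_k",
    "assign_stage",
    "assign_stages",
    "profile_correlation",
    "correlation_bins",
    "hypergeom_overrep",
    "bh_adjust",
    "nb_lrt",
    "overlap_report",
    "STAGES",
    "DEFAULT_STAGE_MAP",
]
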