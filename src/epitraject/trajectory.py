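"""Developmental trajectory calling, age profiles and k-means clustering.

The central contrast compares the prenatal samples with the samples
older than one year (infants are held out of the test but retained in
profiles).  A region is a "down" call when its prenatal mean density
clears the floor, exceeds the older-group mean at least two-fold, the
two-sided Welch t-test is significant, and the region is at least 1 kb
long; "up" calls use the reciprocal criteria.  Max-normalized age
profiles of all sufficiently dense regions are additionally clustered
with k-means (default k = 5) and each cluster centroid labeled
up/down/flat by its Spearman rank correlation with age.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .quantify import DensityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "assign_age_groups",
    "TrajectoryCallConfig",
    "classify_up_down",
    "mean_profile",
    "filter_and_normalize_for_clustering",
    "ClusterResult",
    "kmeans_profiles",
    "label_cluster_trend",
    "geneset_mean_expression",
]


def assign_age_groups(ages) -> np.ndarray:
    """prenatal (age <= 0, i.e. at or before term), infant (<1 yr), older (>=1 yr)."""
    ages = np.asarray(ages, dtype=float)
    out = np.where(ages <= 0, "prenatal", np.where(ages < 1, "infant", "older"))
    return out.astype(object)


@dataclass(frozen=True)
class TrajectoryCallConfig:
    density_floor: float = 0.01
    min_fold: float = 2.0
    max_p: float = 0.05
    min_length: int = 1000
    equal_var: bool = False  # Welch by default; pooled-variance optional

    def __post_init__(self):
        if min(self.density_floor, self.min_fold, self.max_p, self.min_length) <= 0:
            raise ValueError("all thresholds must be positive")
        if not (0 < self.max_p < 1):
            raise ValueError("max_p must be in (0, 1)")


def classify_up_down(
    matrix: DensityMatrix,
    ages,
    cfg: TrajectoryCallConfig = TrajectoryCallConfig(),
) -> "pandas.DataFrame":
    """Call each region up / down / none between prenatal and >1 yr groups.

    down: prenatal mean >= floor, prenatal/older fold >= min_fold,
    t-test p <= max_p, length >= min_length.  up: the reciprocal (older
    mean >= floor, older/prenatal >= min_fold).  The density floor is
    applied to the higher group.  Infant samples never enter the test.
    Returns a DataFrame with region coordinates, class, group means,
    older-relative fold and p.
    """
    import pandas as pd

    groups = assign_age_groups(ages)
    pren = groups == "prenatal"
    older = groups == "older"
    if pren.sum() < 2 or older.sum() < 2:
        raise ValueError("need >= 2 prenatal and >= 2 older samples")
    X = matrix.values
    A = X[:, pren]
    B = X[:, older]
    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)
    with np.errstate(invalid="ignore"):
        t, p = stats.ttest_ind(A, B, axis=1, equal_var=cfg.equal_var)
    # zero variance in both groups: the test statistic is undefined even
    # when the means differ
    degenerate = ~np.isfinite(p) | (
        (A.var(axis=1) == 0) & (B.var(axis=1) == 0)
    )
    p = np.where(degenerate, np.nan, p)
    if np.any(degenerate):
        logger.info("%d regions with undefined t-test (zero variance): class none",
                    int(degenerate.sum()))
    lengths = matrix.region_lengths
    with np.errstate(divide="ignore", invalid="ignore"):
        fold_down = np.where(mean_b > 0, mean_a / mean_b, np.inf)
        fold_up = np.where(mean_a > 0, mean_b / mean_a, np.inf)
    ok = (~degenerate) & (p <= cfg.max_p) & (lengths >= cfg.min_length)
    down = ok & (mean_a >= cfg.density_floor) & (fold_down >= cfg.min_fold)
    up = ok & (mean_b >= cfg.density_floor) & (fold_up >= cfg.min_fold)
    klass = np.where(down, "down", np.where(up, "up", "none"))
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(mean_a > 0, mean_b / mean_a, np.inf)
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in matrix.regions],
            "start": [r.start for r in matrix.regions],
            "end": [r.end for r in matrix.regions],
            "klass": klass,
            "prenatal_mean": mean_a,
            "older_mean": mean_b,
            "fold_older_vs_prenatal": fold,
            "p_value": p,
        }
    )


def mean_profile(matrix: DensityMatrix, region_indices) -> np.ndarray:
    """Per-sample mean density over a region subset (sample order preserved)."""
    idx = np.asarray(region_indices)
    if idx.size == 0:
        raise ValueError("empty region subset")
    return matrix.values[idx, :].mean(axis=0)


def filter_and_normalize_for_clustering(
    matrix: DensityMatrix,
    ages,
    cfg: TrajectoryCallConfig = TrajectoryCallConfig(),
    exclude_chrY: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Select cluster-worthy regions and max-normalize their profiles.

    Keeps regions at least ``min_length`` long whose prenatal or older
    mean density clears the floor (chrY excluded); divides each region's
    profile by its maximum so values lie in [0, 1] with max exactly 1.
    Returns (normalized profiles, kept region indices).
    """
    groups = assign_age_groups(ages)
    pren = groups == "prenatal"
    older = groups == "older"
    X = matrix.values
    mean_a = X[:, pren].mean(axis=1)
    mean_b = X[:, older].mean(axis=1)
    lengths = matrix.region_lengths
    chroms = np.array([r.chrom for r in matrix.regions])
    keep = (lengths >= cfg.min_length) & (
        (mean_a >= cfg.density_floor) | (mean_b >= cfg.density_floor)
    )
    if exclude_chrY:
        keep &= chroms != "chrY"
    rowmax = X.max(axis=1)
    allzero = keep & (rowmax == 0)
    if np.any(allzero):
        logger.info("dropping %d all-zero profiles", int(allzero.sum()))
        keep &= rowmax > 0
    idx = np.flatnonzero(keep)
    profiles = X[idx] / rowmax[idx, None]
    return profiles, idx


@dataclass
class ClusterResult:
    k: int
    region_indices: np.ndarray
    assignments: np.ndarray
    centroids: np.ndarray  # (k, n_samples), values in [0, 1]
    trends: list[str] = field(default_factory=list)


def kmeans_profiles(
    profiles: np.ndarray,
    region_indices,
    ages,
    k: int = 5,
    seed: int = 0,
    n_init: int = 10,
    trend_rho: float = 0.5,
) -> ClusterResult:
    """Euclidean k-means over max-normalized profiles, best of n_init restarts.

    Centroids are recomputed as plain means of member profiles and each
    is trend-labeled against age.  Deterministic given ``seed``.
    """
    from sklearn.cluster import KMeans

    profiles = np.asarray(profiles, dtype=float)
    if profiles.shape[0] < k:
        raise ValueError(f"need at least k={k} regions, got {profiles.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(profiles)
    centroids = np.vstack([
        profiles[labels == c].mean(axis=0) if np.any(labels == c) else km.cluster_centers_[c]
        for c in range(k)
    ])
    trends = [label_cluster_trend(centroids[c], ages, trend_rho) for c in range(k)]
    return ClusterResult(
        k=k,
        region_indices=np.asarray(region_indices),
        assignments=labels,
        centroids=centroids,
        trends=trends,
    )


def label_cluster_trend(centroid, ages, rho_threshold: float = 0.5) -> str:
    """up / down / flat by Spearman rank correlation of centroid with age."""
    centroid = np.asarray(centroid, dtype=float)
    if centroid.shape[0] != np.asarray(ages).shape[0]:
        raise ValueError("centroid length must equal sample count")
    if np.all(centroid == centroid[0]):
        return "flat"
    rho = stats.spearmanr(centroid, ages).statistic
    if rho >= rho_threshold:
        return "up"
    if rho <= -rho_threshold:
        return "down"
    return "flat"


def geneset_mean_expression(expr, gene_set, ages=None) -> np.ndarray:
    """Per-sample mean log2 expression of a gene set.

    ``expr`` is a gene x sample DataFrame.  Genes absent from the table
    are dropped (count logged); an empty intersection is an error.
    """
    gene_set = list(gene_set)
    present = [g for g in gene_set if g in expr.index]
    if not present:
        raise ValueError(
            f"none of the {len(gene_set)} genes are in the expression table "
            f"({expr.shape[0]} genes)"
        )
    if len(present) < len(gene_set):
        logger.info("dropping %d genes absent from expression table",
                    len(gene_set) - len(present))
    return expr.loc[present].to_numpy(dtype=float).mean(axis=0)
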