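"""Computational phenotyping: k-means clusters over fitted model parameters.

Each user's fitted (alpha, P, C) triple is treated as a mechanistic
behavioral profile.  Parameters are log-transformed and standardized,
clustered with k-means across a range of candidate cluster counts, and
the count is chosen by majority vote over four standard internal indices
(silhouette, Calinski-Harabasz, Davies-Bouldin, gap statistic).  The
solution ships with 2-D principal-component display coordinates, an
optional association measure against a dataset label, and a bootstrap
stability report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import (
    adjusted_rand_score,
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

__all__ = [
    "ClusterSolution",
    "cluster_parameters",
    "cramers_v",
    "stability_report",
    "log_standardize",
]


@dataclass
class ClusterSolution:
    """A chosen k-means partition of users in parameter space."""

    k: int
    assignments: np.ndarray  # cluster ids 1..k per user
    criteria_votes: dict  # criterion name -> k it voted for
    scores: pd.DataFrame  # per-candidate-k value of each criterion
    profiles: pd.DataFrame  # median standardized parameter per cluster
    pca_scores: np.ndarray  # (n_users, 2) display coordinates
    pca_explained: np.ndarray
    centroids: np.ndarray  # canonicalized (sorted on first coordinate)
    X: np.ndarray = field(repr=False)  # standardized feature matrix
    cramers_v_dataset: float | None = None


def log_standardize(param_table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Log-transform and z-score a (users x parameters) table.

    Non-positive values (possible for the initial-policy parameter, which
    is already on a log scale) trigger a documented offset so the log is
    defined; a warning reports the offset used.
    """
    cols = list(param_table.columns)
    X = param_table.to_numpy(dtype=float).copy()
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.any(col <= 0):
            offset = 1e-6 - col.min()
            warnings.warn(
                f"parameter {cols[j]!r} has non-positive values; "
                f"log applied after offset {offset:.3g}",
                RuntimeWarning,
            )
            col = col + offset
        X[:, j] = np.log(col)
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    return X, cols


def _kmeans(X: np.ndarray, k: int, seed: int, n_init: int = 50) -> KMeans:
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    km.fit(X)
    return km


def _gap_statistic(
    X: np.ndarray, k_range: range, seed: int, n_ref: int = 10, n_init: int = 10
) -> int:
    """Gap-statistic vote: smallest k with gap(k) >= gap(k+1) - s(k+1),
    comparing within-cluster dispersion to uniform reference data drawn
    over the feature bounding box."""
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)

    def log_wk(data: np.ndarray, k: int, sd: int) -> float:
        km = _kmeans(data, k, sd, n_init=n_init)
        return float(np.log(km.inertia_ + 1e-300))

    ks = list(k_range)
    gaps, sks = [], []
    for k in ks:
        ref = np.array(
            [log_wk(rng.uniform(lo, hi, size=X.shape), k, seed + b)
             for b in range(n_ref)]
        )
        gaps.append(ref.mean() - log_wk(X, k, seed))
        sks.append(ref.std(ddof=1) * np.sqrt(1 + 1 / n_ref))
    for i in range(len(ks) - 1):
        if gaps[i] >= gaps[i + 1] - sks[i + 1]:
            return ks[i]
    return ks[-1]


def cluster_parameters(
    param_table: pd.DataFrame,
    k_range: range | tuple[int, int] = (2, 10),
    seed: int = 0,
    n_init: int = 50,
    dataset_labels: np.ndarray | None = None,
) -> ClusterSolution:
    """Cluster users on log-standardized parameters, choosing k by vote.

    ``param_table`` holds one row per user and one column per parameter
    (at least alpha, P, C).  Four criteria each vote for a k in
    ``k_range``: silhouette and Calinski-Harabasz vote for their maximum,
    Davies-Bouldin for its minimum, and the gap statistic by the standard
    one-standard-error rule; the majority wins, ties broken by the
    silhouette's choice.  Cluster labels are canonicalized by sorting
    centroids on their first coordinate so the labeling is stable across
    user permutations.
    """
    if param_table.shape[1] < 3:
        raise ValueError("need at least 3 parameters per user")
    if len(param_table) < 10:
        raise ValueError("need at least 10 users to phenotype")
    if isinstance(k_range, tuple):
        k_range = range(k_range[0], k_range[1] + 1)
    X, cols = log_standardize(param_table)

    rows = []
    models: dict[int, KMeans] = {}
    for k in k_range:
        km = _kmeans(X, k, seed, n_init=n_init)
        models[k] = km
        lab = km.labels_
        rows.append(
            {
                "k": k,
                "silhouette": silhouette_score(X, lab) if k > 1 else np.nan,
                "calinski_harabasz": calinski_harabasz_score(X, lab),
                "davies_bouldin": davies_bouldin_score(X, lab),
            }
        )
    scores = pd.DataFrame(rows).set_index("k")
    votes = {
        "silhouette": int(scores["silhouette"].idxmax()),
        "calinski_harabasz": int(scores["calinski_harabasz"].idxmax()),
        "davies_bouldin": int(scores["davies_bouldin"].idxmin()),
        "gap": _gap_statistic(X, k_range, seed),
    }
    counts = pd.Series(list(votes.values())).value_counts()
    top = counts[counts == counts.max()].index
    k_best = votes["silhouette"] if len(top) > 1 else int(top[0])

    km = models[k_best]
    order = np.argsort(km.cluster_centers_[:, 0])
    relabel = np.empty(k_best, dtype=int)
    relabel[order] = np.arange(1, k_best + 1)
    assignments = relabel[km.labels_]
    centroids = km.cluster_centers_[order]

    prof = pd.DataFrame(X, columns=cols).groupby(assignments).median()
    prof.index.name = "cluster"

    pca = PCA(n_components=2, random_state=seed)
    pcs = pca.fit_transform(X)

    v = None
    if dataset_labels is not None:
        v = cramers_v(assignments, np.asarray(dataset_labels))

    return ClusterSolution(
        k=k_best, assignments=assignments, criteria_votes=votes, scores=scores,
        profiles=prof, pca_scores=pcs, pca_explained=pca.explained_variance_ratio_,
        centroids=centroids, X=X, cramers_v_dataset=v,
    )


def cramers_v(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Cramer's V association between two categorical vectors.

    V = sqrt(chi2 / (n * (min(r, c) - 1))) from the contingency table;
    0 for independent labels, 1 for a perfect association.  Degenerate
    single-category input is defined as 0 with a warning.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    table = pd.crosstab(a, b).to_numpy()
    r, c = table.shape
    if min(r, c) < 2:
        warnings.warn("single-category labels: Cramer's V defined as 0",
                      RuntimeWarning)
        return 0.0
    chi2 = scipy.stats.chi2_contingency(table, correction=False).statistic
    n = table.sum()
    return float(np.sqrt(chi2 / (n * (min(r, c) - 1))))


def stability_report(
    param_table: pd.DataFrame,
    solution: ClusterSolution,
    n_boot: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap agreement of the cluster solution.

    Users are resampled with replacement; each replicate is re-clustered
    at the chosen k and the adjusted Rand index between the replicate's
    labels and the original assignments (over the resampled users) is
    recorded.  Returns one row per replicate plus a summary row with the
    mean and a normal-theory 95% interval.  ``n_boot=0`` yields an empty
    report.
    """
    rng = np.random.default_rng(seed)
    X = solution.X
    n = X.shape[0]
    rows = []
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        km = _kmeans(X[idx], solution.k, seed + 1 + b, n_init=10)
        ari = adjusted_rand_score(solution.assignments[idx], km.labels_)
        rows.append({"replicate": b, "ari": ari})
    report = pd.DataFrame(rows, columns=["replicate", "ari"])
    if n_boot > 0:
        m = report["ari"].mean()
        s = report["ari"].std(ddof=1) / np.sqrt(n_boot) if n_boot > 1 else 0.0
        report.attrs["mean_ari"] = float(m)
        report.attrs["ci95"] = (float(m - 1.96 * s), float(m + 1.96 * s))
    return report
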