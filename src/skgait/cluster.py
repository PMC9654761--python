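"""k-means partitioning with replicate restarts and gap-statistic model selection.

The clusterer is a deliberately transparent Lloyd implementation: the
severity scheme downstream depends on exact replicate selection (lowest
total within-cluster sum of squared Euclidean distances over all restarts),
on deterministic seeding, and on a monotone within-SS trace that the test
suite asserts — so the loop is kept in-package rather than delegated.
k-means++ seeding reuses :func:`sklearn.cluster.kmeans_plusplus`.

The number of clusters is chosen with the gap statistic of Tibshirani,
Walther & Hastie: the pooled within-cluster dispersion ``W_k`` (under
squared Euclidean distance this equals the k-means inertia) is compared on
a log scale against B reference data sets drawn uniformly over the observed
per-feature ranges, and the smallest k with
``Gap(k) >= Gap(k+1) - s_{k+1}`` is selected.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import kmeans_plusplus
from sklearn.utils.validation import check_array, check_is_fitted, check_random_state

__all__ = [
    "standardize",
    "ReplicatedKMeans",
    "kmeans_fit",
    "ClusterModel",
    "GapCurve",
    "gap_select_k",
    "medoid_indices",
]


def standardize(X: np.ndarray, mode: str = "zscore") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise z-scoring (or identity). Returns (X', location, scale).

    ``zscore`` uses the column mean and population SD (ddof=0); a
    zero-variance column is an error (use ``mode='none'`` for such data).
    """
    X = np.asarray(X, float)
    if mode == "none":
        d = X.shape[1] if X.ndim == 2 else 1
        return X.copy(), np.zeros(d), np.ones(d)
    if mode != "zscore":
        raise ValueError(f"unknown standardization mode {mode!r}")
    if X.shape[0] < 2:
        raise ValueError("z-scoring needs at least 2 rows")
    loc = X.mean(axis=0)
    scale = X.std(axis=0)
    if np.any(scale == 0):
        bad = np.flatnonzero(scale == 0).tolist()
        raise ValueError(
            f"zero-variance column(s) {bad} cannot be z-scored; use mode='none'"
        )
    return (X - loc) / scale, loc, scale


def _assign(X: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-centroid labels and per-point squared distances."""
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)
    return labels, d2[np.arange(X.shape[0]), labels]


def _lloyd(
    X: np.ndarray,
    centers: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, float, int, list[float]]:
    """One Lloyd run from given initial centers.

    Empty clusters are repaired by promoting the point farthest from its
    assigned centroid to a singleton centroid, so every returned cluster is
    nonempty. Returns (labels, centers, inertia, n_iter, inertia trace).
    """
    k = centers.shape[0]
    prev_labels = None
    trace: list[float] = []
    for it in range(1, max_iter + 1):
        labels, d2 = _assign(X, centers)
        for empty in np.flatnonzero(np.bincount(labels, minlength=k) == 0):
            far = int(np.argmax(d2))
            centers[empty] = X[far]
            labels, d2 = _assign(X, centers)
        trace.append(float(d2.sum()))
        if prev_labels is not None and np.array_equal(labels, prev_labels):
            return labels, centers, trace[-1], it, trace
        new_centers = np.vstack([X[labels == j].mean(axis=0) for j in range(k)])
        shift = float(np.max(np.abs(new_centers - centers)))
        centers = new_centers
        prev_labels = labels
        if shift < tol:
            break
    labels, d2 = _assign(X, centers)
    trace.append(float(d2.sum()))
    return labels, centers, trace[-1], it, trace


class ReplicatedKMeans(ClusterMixin, BaseEstimator):
    """Lloyd k-means restarted ``replicates`` times; best restart kept.

    Parameters
    ----------
    n_clusters : int
        Number of clusters k (k <= n required at fit time).
    replicates : int, default 5
        Independent restarts, each with fresh initial centroids; the
        solution with the lowest total within-cluster sum of squared
        Euclidean distances wins.
    init : {"k-means++", "random"}
        Seeding scheme per replicate.
    max_iter : int, default 300
        Lloyd iteration cap per replicate.
    tol : float, default 1e-6
        Centroid-movement threshold (degrees / feature units) that, with
        unchanged assignments, stops a replicate.
    random_state : int or None
        Seeds all replicates; a fixed value makes ``fit`` bit-reproducible.

    Attributes
    ----------
    cluster_centers_ : (k, d) ndarray — centroids (arithmetic cluster means).
    labels_ : (n,) ndarray — nearest-centroid assignment of each row.
    inertia_ : float — total within-cluster sum of squared distances.
    inertia_trace_ : list of float — within-SS per Lloyd iteration of the
        winning replicate (non-increasing).
    n_iter_ : int — Lloyd iterations of the winning replicate.
    """

    def __init__(
        self,
        n_clusters: int = 5,
        replicates: int = 5,
        init: str = "k-means++",
        max_iter: int = 300,
        tol: float = 1e-6,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.replicates = replicates
        self.init = init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        n = X.shape[0]
        k = self.n_clusters
        if k < 1:
            raise ValueError("n_clusters must be >= 1")
        if k > n:
            raise ValueError(f"n_clusters={k} exceeds the number of rows n={n}")
        rng = check_random_state(self.random_state)
        best = None
        for _ in range(max(1, self.replicates)):
            if self.init == "k-means++":
                seed = rng.randint(np.iinfo(np.int32).max)
                centers, _ = kmeans_plusplus(X, k, random_state=seed)
            elif self.init == "random":
                centers = X[rng.choice(n, size=k, replace=False)].copy()
            else:
                raise ValueError(f"unknown init {self.init!r}")
            result = _lloyd(X, centers.astype(float), self.max_iter, self.tol)
            if best is None or result[2] < best[2]:
                best = result
        labels, centers, inertia, n_iter, trace = best
        self.labels_ = labels
        self.cluster_centers_ = centers
        self.inertia_ = inertia
        self.n_iter_ = n_iter
        self.inertia_trace_ = trace
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        X = check_array(X, dtype=float)
        labels, _ = _assign(X, self.cluster_centers_)
        return labels


@dataclass
class ClusterModel:
    """Serializable result of a clustering run (raw + standardized space)."""

    k: int
    centroids: np.ndarray          # standardized (clustering) space
    centroids_raw: np.ndarray      # raw feature space
    assignments: np.ndarray
    total_within_ss: float
    standardization: str
    location: np.ndarray
    scale: np.ndarray
    seed: int | None = None

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "k": int(self.k),
            "centroids_standardized": self.centroids.tolist(),
            "centroids_raw": self.centroids_raw.tolist(),
            "assignments": self.assignments.tolist(),
            "total_within_ss": self.total_within_ss,
            "standardization": self.standardization,
            "location": self.location.tolist(),
            "scale": self.scale.tolist(),
            "seed": self.seed,
        }
        path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterModel":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            k=d["k"],
            centroids=np.asarray(d["centroids_standardized"], float),
            centroids_raw=np.asarray(d["centroids_raw"], float),
            assignments=np.asarray(d["assignments"], int),
            total_within_ss=d["total_within_ss"],
            standardization=d["standardization"],
            location=np.asarray(d["location"], float),
            scale=np.asarray(d["scale"], float),
            seed=d.get("seed"),
        )


def kmeans_fit(
    X: np.ndarray,
    k: int,
    replicates: int = 5,
    seed: int | None = None,
    standardization: str = "zscore",
) -> ClusterModel:
    """Standardize, run replicated k-means, and package a :class:`ClusterModel`."""
    X = np.asarray(X, float)
    Xs, loc, scale = standardize(X, mode=standardization)
    est = ReplicatedKMeans(n_clusters=k, replicates=replicates, random_state=seed).fit(Xs)
    centroids_raw = est.cluster_centers_ * scale + loc
    return ClusterModel(
        k=k,
        centroids=est.cluster_centers_,
        centroids_raw=centroids_raw,
        assignments=est.labels_,
        total_within_ss=est.inertia_,
        standardization=standardization,
        location=loc,
        scale=scale,
        seed=seed,
    )


@dataclass
class GapCurve:
    """Gap statistic per candidate k, with the selected number of clusters."""

    k_values: np.ndarray
    gap: np.ndarray
    s_k: np.ndarray              # reference SD * sqrt(1 + 1/B)
    log_w_obs: np.ndarray
    log_w_ref_mean: np.ndarray
    selected_k: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.k_values, "gap": self.gap, "s_k": self.s_k,
             "log_W": self.log_w_obs, "log_W_ref": self.log_w_ref_mean}
        )


def _within_dispersion(X: np.ndarray, k: int, replicates: int, rng: np.random.RandomState) -> float:
    if k == 1:
        return float(((X - X.mean(axis=0)) ** 2).sum())
    seed = rng.randint(np.iinfo(np.int32).max)
    est = ReplicatedKMeans(n_clusters=k, replicates=replicates, random_state=seed).fit(X)
    return float(est.inertia_)


def gap_select_k(
    X: np.ndarray,
    kmax: int = 6,
    B: int = 100,
    seed: int | None = None,
    replicates: int = 5,
) -> GapCurve:
    """Gap-statistic selection of k over 1..kmax.

    ``Gap(k) = mean_b log W*_kb - log W_k`` with reference data drawn
    uniformly over the observed per-column ranges, and
    ``s_k = SD_b(log W*_kb) * sqrt(1 + 1/B)``. The selected k is the
    smallest with ``Gap(k) >= Gap(k+1) - s_{k+1}``, else kmax. Degenerate
    data (all rows identical) selects k = 1 directly.
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    if n <= kmax:
        raise ValueError(f"need n > kmax, got n={n}, kmax={kmax}")
    ks = np.arange(1, kmax + 1)
    if np.allclose(X, X[0]):
        zero = np.zeros(kmax)
        return GapCurve(ks, zero, zero, zero, zero, selected_k=1)

    rng = check_random_state(seed)
    tiny = np.finfo(float).tiny
    log_w_obs = np.array([
        np.log(max(_within_dispersion(X, k, replicates, rng), tiny)) for k in ks
    ])
    lo, hi = X.min(axis=0), X.max(axis=0)
    log_w_ref = np.empty((B, kmax))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=X.shape)
        for j, k in enumerate(ks):
            log_w_ref[b, j] = np.log(max(_within_dispersion(ref, k, replicates, rng), tiny))
    log_w_ref_mean = log_w_ref.mean(axis=0)
    gap = log_w_ref_mean - log_w_obs
    s_k = log_w_ref.std(axis=0) * np.sqrt(1.0 + 1.0 / B)

    selected = int(kmax)
    for j in range(kmax - 1):
        if gap[j] >= gap[j + 1] - s_k[j + 1]:
            selected = int(ks[j])
            break
    if selected == 1:
        warnings.warn("gap statistic selected k = 1 (no cluster structure)")
    return GapCurve(ks, gap, s_k, log_w_obs, log_w_ref_mean, selected_k=selected)


def medoid_indices(X: np.ndarray, model: ClusterModel) -> np.ndarray:
    """Index of each cluster's medoid: the row nearest its centroid.

    Presentation helper (e.g. plotting a representative curve per
    cluster) — not a clusterer. Distances are computed in the model's
    standardized space.
    """
    X = np.asarray(X, float)
    Xs = (X - model.location) / model.scale
    out = np.empty(model.k, dtype=int)
    for j in range(model.k):
        members = np.flatnonzero(model.assignments == j)
        d2 = ((Xs[members] - model.centroids[j]) ** 2).sum(axis=1)
        out[j] = members[int(np.argmin(d2))]
    return out
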