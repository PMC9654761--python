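"""Five-level severity labeling of knee-kinematics clusters and classification.

A fitted 5-cluster solution on the (PKF1, KFE, T1, KFM, T2) features is
turned into the named severity scheme:

* ``healthy`` and ``non-SKG`` — the two clusters whose centroid first-bump
  peak knee flexion (PKF1, raw degrees) reaches the stiff-knee cutoff
  (40° by default; stiff-knee gait is diagnosed for swing-phase peak knee
  flexion *strictly below* the cutoff);
* ``UKG`` (unbend-knee gait, mild), ``BKG`` (braked-knee gait, moderate)
  and ``FLG`` (frozen-limb gait, severe) — the three sub-cutoff clusters
  in order of decreasing centroid PKF1.

Prospective subjects are assigned by nearest centroid in the model's
standardized feature space (squared Euclidean), with ties broken toward
the more severe label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .cluster import ClusterModel, ReplicatedKMeans, standardize
from .features import FEATURE_NAMES, ClusteringFeatures

SEVERITY_LEVELS = ("healthy", "non-SKG", "UKG", "BKG", "FLG")
#: rank used for tie-breaking: higher = more severe
SEVERITY_RANK = {name: i for i, name in enumerate(SEVERITY_LEVELS)}

DEFAULT_SKG_CUTOFF = 40.0

__all__ = [
    "SEVERITY_LEVELS",
    "SEVERITY_RANK",
    "DEFAULT_SKG_CUTOFF",
    "SeverityLabelingError",
    "SeverityModel",
    "SeverityClassifier",
    "diagnose_skg",
    "label_clusters",
    "classify_subject",
    "default_reference_model",
]


class SeverityLabelingError(ValueError):
    pass


def diagnose_skg(K5: float, cutoff: float = DEFAULT_SKG_CUTOFF) -> bool:
    """Stiff-knee gait diagnosis: swing-phase peak knee flexion strictly below cutoff."""
    if not np.isfinite(K5):
        raise ValueError("K5 must be finite")
    return bool(K5 < cutoff)


@dataclass
class SeverityModel:
    """Labeled 5-centroid severity model (raw + standardized space).

    ``centroids_raw[i]`` and ``centroids_std[i]`` belong to ``labels[i]``;
    ``location``/``scale`` reproduce the standardization of the training
    features, and ``skg_cutoff`` is the PKF1 boundary (degrees) separating
    stiff from non-stiff clusters.
    """

    labels: tuple[str, ...]
    centroids_raw: np.ndarray
    centroids_std: np.ndarray
    location: np.ndarray
    scale: np.ndarray
    skg_cutoff: float = DEFAULT_SKG_CUTOFF
    standardization: str = "zscore"
    note: str = ""

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise SeverityLabelingError("severity labels must be unique")
        unknown = set(self.labels) - set(SEVERITY_LEVELS)
        if unknown:
            raise SeverityLabelingError(f"unknown severity labels {sorted(unknown)}")
        pkf1 = {lab: self.centroids_raw[i][0] for i, lab in enumerate(self.labels)}
        skg = [lab for lab in ("UKG", "BKG", "FLG") if lab in pkf1]
        vals = [pkf1[lab] for lab in skg]
        if any(a <= b for a, b in zip(vals, vals[1:])):
            raise SeverityLabelingError(
                f"SKG centroid PKF1 must strictly decrease from UKG to FLG, got {vals}"
            )

    def centroid_for(self, label: str) -> np.ndarray:
        return self.centroids_raw[self.labels.index(label)]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "labels": list(self.labels),
            "centroids_raw": self.centroids_raw.tolist(),
            "centroids_standardized": self.centroids_std.tolist(),
            "location": self.location.tolist(),
            "scale": self.scale.tolist(),
            "skg_cutoff": self.skg_cutoff,
            "standardization": self.standardization,
            "feature_order": list(FEATURE_NAMES),
            "note": self.note,
        }
        path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SeverityModel":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            labels=tuple(d["labels"]),
            centroids_raw=np.asarray(d["centroids_raw"], float),
            centroids_std=np.asarray(d["centroids_standardized"], float),
            location=np.asarray(d["location"], float),
            scale=np.asarray(d["scale"], float),
            skg_cutoff=d.get("skg_cutoff", DEFAULT_SKG_CUTOFF),
            standardization=d.get("standardization", "zscore"),
            note=d.get("note", ""),
        )


def label_clusters(
    model: ClusterModel,
    is_healthy: np.ndarray,
    skg_cutoff: float = DEFAULT_SKG_CUTOFF,
) -> SeverityModel:
    """Name the five clusters of a fitted :class:`ClusterModel`.

    Clusters whose centroid PKF1 (raw degrees, feature column 0) reaches
    ``skg_cutoff`` are non-stiff; among those two, the cluster with the
    larger fraction of known-healthy members is ``healthy`` and the other
    ``non-SKG`` (without any healthy flags the higher-KFE cluster is taken
    as healthy). The three sub-cutoff clusters become UKG/BKG/FLG by
    decreasing centroid PKF1.
    """
    if model.k != 5:
        raise SeverityLabelingError(f"severity labeling requires k = 5, got k = {model.k}")
    is_healthy = np.asarray(is_healthy, bool)
    if is_healthy.shape[0] != model.assignments.shape[0]:
        raise SeverityLabelingError("is_healthy must align with the clustered rows")

    pkf1 = model.centroids_raw[:, 0]
    non_stiff = np.flatnonzero(pkf1 >= skg_cutoff)
    stiff = np.flatnonzero(pkf1 < skg_cutoff)
    if non_stiff.size != 2 or stiff.size != 3:
        raise SeverityLabelingError(
            f"expected 2 non-stiff and 3 stiff clusters at cutoff {skg_cutoff}°; "
            f"centroid PKF1 = {np.round(pkf1, 1).tolist()} gives "
            f"{non_stiff.size} non-stiff / {stiff.size} stiff"
        )

    if is_healthy.any():
        frac = []
        for j in non_stiff:
            members = model.assignments == j
            frac.append(is_healthy[members].mean() if members.any() else 0.0)
        healthy_idx = non_stiff[int(np.argmax(frac))]
    else:  # documented heuristic: healthy gait has the larger knee-flexion enhancement
        kfe = model.centroids_raw[non_stiff, 1]
        healthy_idx = non_stiff[int(np.argmax(kfe))]
    nonskg_idx = int(non_stiff[non_stiff != healthy_idx][0])

    order = stiff[np.argsort(pkf1[stiff])[::-1]]  # descending PKF1: UKG, BKG, FLG
    cluster_to_label = {int(healthy_idx): "healthy", nonskg_idx: "non-SKG"}
    for lab, j in zip(("UKG", "BKG", "FLG"), order):
        cluster_to_label[int(j)] = lab

    idx = sorted(cluster_to_label)
    return SeverityModel(
        labels=tuple(cluster_to_label[j] for j in idx),
        centroids_raw=model.centroids_raw[idx],
        centroids_std=model.centroids[idx],
        location=model.location,
        scale=model.scale,
        skg_cutoff=skg_cutoff,
        standardization=model.standardization,
    )


def _nearest_severe(Xs: np.ndarray, model: SeverityModel) -> list[str]:
    d2 = ((Xs[:, None, :] - model.centroids_std[None, :, :]) ** 2).sum(axis=2)
    out = []
    for row in d2:
        best = row.min()
        ties = np.flatnonzero(row <= best * (1 + 1e-12) + 1e-12)
        lab = max((model.labels[j] for j in ties), key=SEVERITY_RANK.__getitem__)
        out.append(lab)
    return out


def classify_subject(features: ClusteringFeatures | np.ndarray, model: SeverityModel) -> str:
    """Severity label of one feature vector via nearest labeled centroid."""
    vec = features.as_array() if isinstance(features, ClusteringFeatures) else np.asarray(features, float)
    if vec.shape != (5,):
        raise ValueError(f"expected a 5-feature vector, got shape {vec.shape}")
    if not np.all(np.isfinite(vec)):
        raise ValueError("features must be finite")
    Xs = ((vec - model.location) / model.scale)[None, :]
    return _nearest_severe(Xs, model)[0]


class SeverityClassifier(ClassifierMixin, BaseEstimator):
    """Discover and apply the five-level stiff-knee-gait severity scheme.

    ``fit(X, is_healthy)`` standardizes the n x 5 feature matrix
    (PKF1, KFE, T1, KFM, T2), partitions it with replicated k-means
    (k = 5), and names the clusters; ``predict`` assigns severity labels
    by nearest centroid with ties broken toward the more severe level.

    Parameters
    ----------
    replicates : int, default 5
        k-means restarts.
    standardization : {"zscore", "none"}
        Feature scaling before clustering.
    skg_cutoff : float, default 40.0
        PKF1 boundary (degrees) between stiff and non-stiff clusters.
    random_state : int or None
        Seeds the k-means restarts.

    Attributes
    ----------
    model_ : SeverityModel — labeled centroids and scaling.
    cluster_model_ : ClusterModel — the underlying unlabeled solution.
    labels_ : ndarray of str — severity label of each training row.
    classes_ : ndarray of str — the label alphabet actually assigned.
    """

    def __init__(
        self,
        replicates: int = 5,
        standardization: str = "zscore",
        skg_cutoff: float = DEFAULT_SKG_CUTOFF,
        random_state: int | None = None,
    ):
        self.replicates = replicates
        self.standardization = standardization
        self.skg_cutoff = skg_cutoff
        self.random_state = random_state

    def fit(self, X, y=None):
        """Fit on features X; ``y`` is the per-row known-healthy flag (bool)."""
        from .cluster import kmeans_fit

        X = check_array(X, dtype=float)
        if X.shape[1] != 5:
            raise ValueError(f"expected 5 feature columns {FEATURE_NAMES}, got {X.shape[1]}")
        is_healthy = (np.zeros(X.shape[0], bool) if y is None
                      else np.asarray(y, bool))
        self.cluster_model_ = kmeans_fit(
            X, k=5, replicates=self.replicates, seed=self.random_state,
            standardization=self.standardization,
        )
        self.model_ = label_clusters(self.cluster_model_, is_healthy, skg_cutoff=self.skg_cutoff)
        # map raw cluster ids to label strings via centroid identity
        order = {tuple(np.round(c, 9)): lab
                 for c, lab in zip(self.model_.centroids_std, self.model_.labels)}
        self.labels_ = np.array([
            order[tuple(np.round(self.cluster_model_.centroids[j], 9))]
            for j in self.cluster_model_.assignments
        ])
        self.classes_ = np.unique(self.labels_)
        return self

    @classmethod
    def from_model(cls, model: SeverityModel) -> "SeverityClassifier":
        """Wrap an existing (e.g. deserialized or reference) severity model."""
        est = cls(skg_cutoff=model.skg_cutoff, standardization=model.standardization)
        est.model_ = model
        est.labels_ = np.array(model.labels)
        est.classes_ = np.unique(est.labels_)
        return est

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X, dtype=float)
        Xs = (X - self.model_.location) / self.model_.scale
        return np.array(_nearest_severe(Xs, self.model_))


# Reconstructed reference model ---------------------------------------------
#
# The three stiff centroids pin PKF1 at the published cluster means (36, 21,
# 10 degrees for mild/moderate/severe); every other coordinate — and both
# non-stiff centroids — comes from this package's calibrated synthetic
# archetype means and is therefore a reconstruction, not a published value.
_REFERENCE_CENTROIDS_RAW = {
    # label:  PKF1   KFE    T1    KFM    T2
    "healthy": (47.0, 20.0, 12.0, 17.0, 13.0),
    "non-SKG": (43.0, 11.0, 10.0, 15.0, 13.0),
    "UKG":     (36.0, 12.0, 15.0, 10.0,  7.0),
    "BKG":     (21.0,  7.0,  4.5,  2.0, 17.0),
    "FLG":     (10.0,  3.0,  2.5,  2.5, 10.0),
}


def default_reference_model() -> SeverityModel:
    """Packaged severity model for prospective classification.

    PKF1 of the stiff centroids equals the published cluster means
    (36/21/10°); all remaining coordinates are reconstructed from the
    synthetic archetype calibration and flagged as such in the model note.
    Standardization uses the spread of the packaged centroids themselves.
    """
    labels = tuple(_REFERENCE_CENTROIDS_RAW)
    raw = np.array([_REFERENCE_CENTROIDS_RAW[lab] for lab in labels], float)
    loc = raw.mean(axis=0)
    scale = raw.std(axis=0)
    return SeverityModel(
        labels=labels,
        centroids_raw=raw,
        centroids_std=(raw - loc) / scale,
        location=loc,
        scale=scale,
        note=(
            "reconstructed reference model: stiff-cluster PKF1 follows the "
            "published means (36/21/10 deg); all other coordinates are "
            "synthetic-archetype calibrations, not published values"
        ),
    )
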