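"""Goldberg knee-stiffness index, CHGC handling, and cluster cross-tabulation.

The Goldberg index scores four knee kinematic parameters of a gait cycle —
global swing-phase peak knee flexion (PKF), time from toe-off to that peak
(T), knee flexion range from toe-off to the peak (KFE), and total range of
knee flexion over the cycle (RKT) — one point per parameter abnormal in the
stiff direction relative to a healthy reference (below mean - m*SD for
PKF/KFE/RKT, above mean + m*SD for T). Score >= 3 is stiff, exactly 2 is
borderline, <= 1 is not-stiff.

The CHGC (chronic hemiparesis gait classification) groups G0/GIa..GIIIb are
clinician-assigned inputs; this module only cross-tabulates them (and
Goldberg scores) against the severity clusters and computes the two
misclassification statistics used for construct validity. Borderline
(score 2) counts as non-stiff in the misclassification rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gait_data import CHGC_GROUPS, GaitCycle, angle_at

SKG_CLUSTERS = ("k1", "k2", "k3")       # UKG, BKG, FLG
NON_SKG_CLUSTERS = ("k4", "k5")          # healthy, non-SKG
CHGC_NON_SKG = ("G0", "GIa", "GIb")      # healthy / equinus-only groups
CHGC_SKG = ("GIIa", "GIIb", "GIIIa", "GIIIb")

__all__ = [
    "GoldbergParams",
    "GoldbergResult",
    "HealthyReference",
    "compute_goldberg_params",
    "goldberg_score",
    "crosstab",
    "goldberg_misclassification",
    "chgc_misclassification",
    "median_score_by_cluster",
    "load_table3_fixture",
]


@dataclass(frozen=True)
class GoldbergParams:
    """The four knee parameters entering the Goldberg index."""

    PKF: float    # degrees, global swing peak
    T: float      # %GC, toe-off to PKF
    KFE_g: float  # degrees, PKF minus knee angle at toe-off
    RKT: float    # degrees, total knee flexion range over the cycle


@dataclass(frozen=True)
class GoldbergResult:
    score: int
    category: str

    def __post_init__(self):
        expected = "stiff" if self.score >= 3 else ("borderline" if self.score == 2 else "not-stiff")
        if self.category != expected:
            raise ValueError(f"score {self.score} implies {expected!r}, got {self.category!r}")


#: per-parameter healthy mean and SD
HealthyReference = Mapping[str, tuple[float, float]]


def compute_goldberg_params(cycle: GaitCycle) -> GoldbergParams:
    """Goldberg parameters of one cycle.

    PKF is the *global* swing maximum (unlike the first-bump PKF1), its
    time taken at the earliest occurrence; for a knee that never flexes
    above its toe-off value, PKF is the toe-off angle and T = 0.
    """
    knee = cycle.knee_angle
    to = cycle.toe_off
    start = int(np.ceil(to))
    window = knee[start:]
    knee_to = angle_at(knee, to)
    if window.size and float(np.max(window)) > knee_to:
        i = int(np.argmax(window))
        pkf, t_pkf = float(window[i]), float(start + i)
    else:
        pkf, t_pkf = float(knee_to), float(to)
    return GoldbergParams(
        PKF=pkf,
        T=t_pkf - to,
        KFE_g=pkf - knee_to,
        RKT=float(np.max(knee) - np.min(knee)),
    )


def goldberg_score(
    params: GoldbergParams,
    healthy_ref: HealthyReference,
    sd_multiplier: float = 1.0,
) -> GoldbergResult:
    """Score 0-4 against a healthy reference; categorize stiff/borderline/not-stiff.

    One point each for PKF, KFE and RKT below the healthy mean minus
    ``sd_multiplier`` SDs, and for T above the healthy mean plus
    ``sd_multiplier`` SDs.
    """
    if sd_multiplier <= 0:
        raise ValueError("sd_multiplier must be > 0")
    for key in ("PKF", "T", "KFE_g", "RKT"):
        if key not in healthy_ref:
            raise ValueError(f"healthy reference missing {key!r}")
    m = sd_multiplier
    score = 0
    for key, low_is_stiff in (("PKF", True), ("KFE_g", True), ("RKT", True), ("T", False)):
        mean, sd = healthy_ref[key]
        value = getattr(params, key)
        if low_is_stiff:
            score += value < mean - m * sd
        else:
            score += value > mean + m * sd
    category = "stiff" if score >= 3 else ("borderline" if score == 2 else "not-stiff")
    return GoldbergResult(score=int(score), category=category)


# ---------------------------------------------------------------------------
# contingency tables


def crosstab(
    cluster_labels: Sequence[str],
    categories: Sequence,
    cluster_order: Sequence[str] = SKG_CLUSTERS + NON_SKG_CLUSTERS,
    category_order: Sequence | None = None,
) -> pd.DataFrame:
    """Counts per (category, cluster); rows = categories, columns = clusters."""
    if len(cluster_labels) != len(categories):
        raise ValueError(
            f"length mismatch: {len(cluster_labels)} cluster labels vs "
            f"{len(categories)} categories"
        )
    cats = pd.Series(list(categories), name="category")
    clus = pd.Series(list(cluster_labels), name="cluster")
    if cats.isna().any() or clus.isna().any():
        raise ValueError("missing labels are not allowed in a contingency table")
    table = pd.crosstab(cats, clus)
    cols = [c for c in cluster_order if c in table.columns] + [
        c for c in table.columns if c not in cluster_order
    ]
    table = table.reindex(columns=cols, fill_value=0)
    if category_order is not None:
        table = table.reindex(index=list(category_order), fill_value=0)
    return table.astype(int)


def _split_columns(table: pd.DataFrame) -> tuple[list, list]:
    skg = [c for c in table.columns if c in SKG_CLUSTERS]
    non = [c for c in table.columns if c in NON_SKG_CLUSTERS]
    if not skg or not non:
        raise ValueError(
            f"table columns {list(table.columns)} must contain SKG clusters "
            f"{SKG_CLUSTERS} and non-SKG clusters {NON_SKG_CLUSTERS}"
        )
    return skg, non


def goldberg_misclassification(table: pd.DataFrame) -> tuple[int, float]:
    """Disagreements between Goldberg categories and the severity clusters.

    A subject is misclassified when it sits in an SKG cluster (k1-k3) with
    a Goldberg score <= 2 (borderline counts as non-stiff), or in a
    non-SKG cluster (k4-k5) with score >= 3. Returns (count, rate).
    """
    try:
        scores = np.array([int(r) for r in table.index])
    except (TypeError, ValueError) as exc:
        raise ValueError(f"not a Goldberg-score table: rows {list(table.index)}") from exc
    if not np.isin(scores, np.arange(5)).all():
        raise ValueError(f"Goldberg scores must be 0..4, got {scores.tolist()}")
    total = int(table.to_numpy().sum())
    if total == 0:
        raise ValueError("empty table: misclassification rate undefined")
    skg, non = _split_columns(table)
    count = int(table.loc[scores <= 2, skg].to_numpy().sum()
                + table.loc[scores >= 3, non].to_numpy().sum())
    return count, count / total


def chgc_misclassification(table: pd.DataFrame) -> tuple[int, float]:
    """Disagreements between CHGC groups and the severity clusters.

    Misclassified: SKG cluster (k1-k3) but CHGC G0/GI, or non-SKG cluster
    (k4-k5) but CHGC GII/GIII. Returns (count, rate).
    """
    unknown = set(table.index) - set(CHGC_GROUPS)
    if unknown:
        raise ValueError(f"not a CHGC table: unknown rows {sorted(unknown)}")
    total = int(table.to_numpy().sum())
    if total == 0:
        raise ValueError("empty table: misclassification rate undefined")
    skg, non = _split_columns(table)
    in_non_skg_rows = table.index.isin(CHGC_NON_SKG)
    in_skg_rows = table.index.isin(CHGC_SKG)
    count = int(table.loc[in_non_skg_rows, skg].to_numpy().sum()
                + table.loc[in_skg_rows, non].to_numpy().sum())
    return count, count / total


def median_score_by_cluster(table: pd.DataFrame) -> pd.Series:
    """Median Goldberg score per cluster column (NaN for empty columns)."""
    scores = np.array([int(r) for r in table.index])
    out = {}
    for col in table.columns:
        counts = table[col].to_numpy()
        if counts.sum() == 0:
            out[col] = np.nan
            continue
        expanded = np.repeat(scores, counts)
        out[col] = float(np.median(expanded))
    return pd.Series(out, name="median_goldberg_score")


def load_table3_fixture() -> dict[str, pd.DataFrame]:
    """The packaged published cross-tabulation (Goldberg and CHGC blocks)."""
    raw = json.loads(
        resources.files("skgait.data").joinpath("table3_contingency.json").read_text()
    )
    out = {}
    for block in ("goldberg", "chgc"):
        out[block] = pd.DataFrame(
            raw[block]["counts"], index=raw[block]["rows"], columns=raw["clusters"]
        )
    return out
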