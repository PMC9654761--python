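"""Between-cluster statistics and study-similarity (S/G) scores.

Continuous gait parameters are compared across severity clusters with
one-way ANOVA followed by Holm-Sidak step-down pairwise comparisons;
ordinal clinical scores with the Kruskal-Wallis test followed by Dunn's
post hoc z tests on mean ranks (tie-corrected). 99% t-based confidence
intervals support the per-cluster peak-knee-flexion ranges.

The similarity score between two study samples for one variable is
``S = 100 * min/max`` of the two central values, rounded half-up to an
integer percent, with the conventions that one zero value gives 0% and
two zeros give 100%; the generalizability score of a characteristic block
is the rounded mean of its S scores.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "one_way_anova",
    "holm_sidak_pairwise",
    "kruskal_wallis",
    "dunn_pairwise",
    "ci99_mean",
    "s_score",
    "g_score",
    "load_table5_fixture",
    "block_scores",
    "cluster_statistics_report",
]


def _validate_groups(samples: Mapping[str, Sequence[float]], min_n: int = 1) -> dict[str, np.ndarray]:
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    out = {}
    for name, vals in samples.items():
        arr = np.asarray(vals, float)
        if arr.size < min_n:
            raise ValueError(f"group {name!r} needs at least {min_n} values")
        out[name] = arr
    return out


def one_way_anova(samples: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA (F, p). All-identical data returns (0, 1)."""
    groups = _validate_groups(samples, min_n=2)
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    f, p = sps.f_oneway(*groups.values())
    if not np.isfinite(f):  # zero within-group variance: p -> 0
        return float("inf"), 0.0
    return float(f), float(p)


def holm_sidak_pairwise(samples: Mapping[str, Sequence[float]], welch: bool = False) -> pd.DataFrame:
    """All pairwise t tests with step-down Sidak (Holm-Sidak) adjustment.

    Pooled-variance t by default (the classical post hoc after ANOVA);
    ``welch=True`` drops the equal-variance assumption. Degenerate pairs
    (both groups constant and equal) report p = 1; both groups constant
    but different report p = 0 with a flag.
    """
    groups = _validate_groups(samples, min_n=2)
    names = list(groups)
    rows = []
    for a, b in itertools.combinations(names, 2):
        x, y = groups[a], groups[b]
        degenerate = x.std(ddof=1) == 0 and y.std(ddof=1) == 0
        if degenerate:
            p_raw = 1.0 if x.mean() == y.mean() else 0.0
            t_stat = 0.0 if x.mean() == y.mean() else math.inf
        else:
            t_stat, p_raw = sps.ttest_ind(x, y, equal_var=not welch)
        rows.append({"group_a": a, "group_b": b, "t": float(t_stat),
                     "p_raw": float(p_raw), "degenerate": degenerate})
    frame = pd.DataFrame(rows)
    _, p_adj, _, _ = multipletests(frame["p_raw"], method="holm-sidak")
    frame["p_adjusted"] = p_adj
    return frame


def kruskal_wallis(samples: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H and p with tie correction. Constant data returns (0, 1)."""
    groups = _validate_groups(samples)
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*groups.values())
    return float(h), float(p)


def dunn_pairwise(samples: Mapping[str, Sequence[float]], adjust: str | None = None) -> pd.DataFrame:
    """Dunn's post hoc test after Kruskal-Wallis.

    z statistics on mean ranks with tie-corrected variance
    ``sigma^2 = (N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j)`` where
    ``T = sum(t^3 - t)`` over tie groups. Unadjusted two-sided p by
    default; ``adjust='holm'`` applies Holm's step-down correction.
    """
    groups = _validate_groups(samples)
    names = list(groups)
    pooled = np.concatenate([groups[n] for n in names])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes, start = {}, {}, 0
    for name in names:
        n_i = groups[name].size
        mean_ranks[name] = ranks[start:start + n_i].mean()
        sizes[name] = n_i
        start += n_i
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    base_var = n_total * (n_total + 1) / 12.0
    tie_corr = tie_term / (12.0 * (n_total - 1)) if n_total > 1 else 0.0

    rows = []
    for a, b in itertools.combinations(names, 2):
        var = (base_var - tie_corr) * (1.0 / sizes[a] + 1.0 / sizes[b])
        if var <= 0:  # all observations tied
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / math.sqrt(var)
            p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": float(z), "p_raw": float(p)})
    frame = pd.DataFrame(rows)
    if adjust is None:
        frame["p_adjusted"] = frame["p_raw"]
    elif adjust == "holm":
        _, p_adj, _, _ = multipletests(frame["p_raw"], method="holm")
        frame["p_adjusted"] = p_adj
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return frame


def ci99_mean(values: Sequence[float], confidence: float = 0.99) -> tuple[float, float]:
    """Two-sided t-based confidence interval for the mean (99% by default)."""
    arr = np.asarray(values, float)
    if arr.size < 2:
        raise ValueError("confidence interval needs at least 2 values")
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size))
    if sem == 0.0:
        return mean, mean
    low, high = sps.t.interval(confidence, df=arr.size - 1, loc=mean, scale=sem)
    return float(low), float(high)


# ---------------------------------------------------------------------------
# similarity / generalizability scores


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def s_score(present_value: float, target_value: float) -> int:
    """Percent similarity between two study values: 100*min/max, half-up.

    One zero value scores 0%; two zeros score 100%. Negative inputs are
    rejected (the score compares magnitudes of like-signed summaries).
    """
    a, b = float(present_value), float(target_value)
    if not (math.isfinite(a) and math.isfinite(b)):
        raise ValueError("values must be finite")
    if a < 0 or b < 0:
        raise ValueError("values must be nonnegative")
    if a == 0.0 and b == 0.0:
        return 100
    if a == 0.0 or b == 0.0:
        return 0
    return _round_half_up(100.0 * min(a, b) / max(a, b))


def g_score(s_scores: Iterable[float]) -> int:
    """Generalizability score: rounded (half-up) mean of a block's S scores."""
    scores = list(s_scores)
    if not scores:
        raise ValueError("g_score of an empty block is undefined")
    return _round_half_up(float(np.mean(scores)))


def load_table5_fixture() -> dict:
    """The packaged study-comparison table (per-variable central values)."""
    return json.loads(
        resources.files("skgait.data").joinpath("table5_samples.json").read_text()
    )


def block_scores(block: dict) -> tuple[list[int], int]:
    """S scores of every (variable, target) pair in a block, plus the G score."""
    scores = []
    for row in block["rows"]:
        scores.extend(s_score(row["present"], t) for t in row["targets"])
    return scores, g_score(scores)


def cluster_statistics_report(
    features_by_cluster: Mapping[str, pd.DataFrame],
    ordinal_columns: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-parameter between-cluster tests in the conventional layout.

    Continuous columns get ANOVA F/p with Holm-Sidak adjacent-pair flags;
    ``ordinal_columns`` get Kruskal-Wallis H/p with Dunn pairs instead.
    ``features_by_cluster`` maps cluster label -> per-subject parameter
    table; cluster order in the mapping defines adjacency.
    """
    labels = list(features_by_cluster)
    columns = features_by_cluster[labels[0]].columns
    adjacent = list(zip(labels, labels[1:]))
    rows = []
    for col in columns:
        samples = {lab: features_by_cluster[lab][col].dropna().to_numpy()
                   for lab in labels}
        samples = {k: v for k, v in samples.items() if v.size >= 2}
        if len(samples) < 2:
            continue
        if col in ordinal_columns:
            stat, p = kruskal_wallis(samples)
            pairs = dunn_pairwise(samples)
            test = "kruskal-wallis"
        else:
            stat, p = one_way_anova(samples)
            pairs = holm_sidak_pairwise(samples)
            test = "anova"
        sig = []
        for a, b in adjacent:
            hit = pairs[((pairs.group_a == a) & (pairs.group_b == b))
                        | ((pairs.group_a == b) & (pairs.group_b == a))]
            if len(hit) and float(hit["p_adjusted"].iloc[0]) < 0.05:
                sig.append(f"{a}|{b}")
        rows.append({"parameter": col, "test": test, "statistic": stat,
                     "p": p, "significant_adjacent_pairs": ";".join(sig)})
    return pd.DataFrame(rows).set_index("parameter")
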