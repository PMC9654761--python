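"""Goldberg knee-stiffness index, cross-tabulation against clusters, and the
two construct-validity misclassification statistics on the published table."""

import numpy as np
import pandas as pd
import pytest
from scipy.interpolate import PchipInterpolator

from skgait.gait_data import GaitCycle
from skgait.goldberg import (
    GoldbergParams,
    chgc_misclassification,
    compute_goldberg_params,
    crosstab,
    goldberg_misclassification,
    goldberg_score,
    load_table3_fixture,
    median_score_by_cluster,
)

HEALTHY_REF = {"PKF": (60.0, 5.0), "T": (13.0, 2.0),
               "KFE_g": (25.0, 4.0), "RKT": (55.0, 5.0)}


def _cycle(knee, toe_off=60.0):
    return GaitCycle(
        hip_angle=np.full(101, 10.0), knee_angle=np.asarray(knee, float),
        ankle_angle=np.zeros(101), toe_off=toe_off, tibia_vertical=85.0,
        cycle_duration=1.2,
    )


class TestGoldbergParams:
    def test_global_peak_not_first_bump(self):
        knee = PchipInterpolator(
            [0, 40, 60, 68, 76, 85, 100], [5, 4, 12, 22, 15, 25, 5])(np.arange(101))
        p = compute_goldberg_params(_cycle(knee))
        assert p.PKF == pytest.approx(25.0, abs=1e-9)
        assert p.T == pytest.approx(25.0, abs=1e-9)  # peak at 85 %GC

    def test_constant_curve(self):
        p = compute_goldberg_params(_cycle(np.full(101, 8.0)))
        assert (p.PKF, p.T, p.KFE_g, p.RKT) == (8.0, 0.0, 0.0, 0.0)

    def test_matches_brute_force_scan(self, rng):
        from tests.conftest import random_cycle

        grid = np.arange(101)
        for _ in range(30):
            c = random_cycle(rng, n_bumps=int(rng.integers(1, 3)))
            p = compute_goldberg_params(c)
            start = int(np.ceil(c.toe_off))
            knee_to = np.interp(c.toe_off, grid, c.knee_angle)
            expected_pkf = max(float(c.knee_angle[start:].max()), knee_to)
            assert p.PKF == pytest.approx(expected_pkf, abs=1e-9)
            assert p.KFE_g == pytest.approx(expected_pkf - knee_to, abs=1e-9)
            assert p.RKT == pytest.approx(np.ptp(c.knee_angle), abs=1e-9)

    def test_pkf_dominates_pkf1_and_rkt_dominates_kfe(self, rng):
        from skgait.features import compute_clustering_features
        from tests.conftest import random_cycle

        for _ in range(30):
            c = random_cycle(rng, n_bumps=int(rng.integers(1, 4)))
            p = compute_goldberg_params(c)
            f = compute_clustering_features(c)
            assert p.PKF >= f.PKF1 - 1e-9
            assert p.RKT >= p.KFE_g - 1e-9


class TestGoldbergScore:
    def test_healthy_means_score_zero(self):
        p = GoldbergParams(PKF=60.0, T=13.0, KFE_g=25.0, RKT=55.0)
        res = goldberg_score(p, HEALTHY_REF)
        assert (res.score, res.category) == (0, "not-stiff")

    def test_three_abnormal_is_stiff(self):
        p = GoldbergParams(PKF=45.0, T=13.0, KFE_g=13.0, RKT=40.0)  # 3 SD below
        res = goldberg_score(p, HEALTHY_REF)
        assert (res.score, res.category) == (3, "stiff")

    def test_score_two_is_borderline(self):
        p = GoldbergParams(PKF=45.0, T=13.0, KFE_g=13.0, RKT=55.0)
        assert goldberg_score(p, HEALTHY_REF).category == "borderline"

    def test_monotone_in_stiff_direction(self, rng):
        for _ in range(50):
            p = GoldbergParams(
                PKF=float(rng.uniform(30, 70)), T=float(rng.uniform(5, 25)),
                KFE_g=float(rng.uniform(5, 35)), RKT=float(rng.uniform(30, 70)))
            worse = GoldbergParams(
                PKF=p.PKF - float(rng.uniform(0, 10)),
                T=p.T + float(rng.uniform(0, 10)),
                KFE_g=p.KFE_g - float(rng.uniform(0, 10)),
                RKT=p.RKT - float(rng.uniform(0, 10)))
            assert goldberg_score(worse, HEALTHY_REF).score >= \
                goldberg_score(p, HEALTHY_REF).score

    def test_bad_multiplier_rejected(self):
        p = GoldbergParams(PKF=60.0, T=13.0, KFE_g=25.0, RKT=55.0)
        with pytest.raises(ValueError):
            goldberg_score(p, HEALTHY_REF, sd_multiplier=0.0)


def _expand(table):
    """Per-subject (cluster, category) pairs implied by a count table."""
    clusters, cats = [], []
    for cat in table.index:
        for col in table.columns:
            clusters += [col] * int(table.loc[cat, col])
            cats += [cat] * int(table.loc[cat, col])
    return clusters, cats


class TestCrosstab:
    def test_reconstructs_fixture_counts(self):
        fixture = load_table3_fixture()
        for block in ("goldberg", "chgc"):
            table = fixture[block]
            clusters, cats = _expand(table)
            rebuilt = crosstab(clusters, cats, category_order=list(table.index))
            pd.testing.assert_frame_equal(rebuilt, table, check_dtype=False, check_names=False)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            crosstab(["k1", "k2"], [1])

    def test_row_and_column_sums_count_labels(self, rng):
        clusters = [f"k{i}" for i in rng.integers(1, 6, size=100)]
        cats = [int(v) for v in rng.integers(0, 5, size=100)]
        table = crosstab(clusters, cats)
        for col in table.columns:
            assert table[col].sum() == clusters.count(col)
        for cat in table.index:
            assert table.loc[cat].sum() == cats.count(cat)


class TestMisclassification:
    def test_published_goldberg_block(self):
        table = load_table3_fixture()["goldberg"]
        count, rate = goldberg_misclassification(table)
        assert count == 30
        assert round(100 * rate, 1) == 26.1

    def test_published_chgc_block(self):
        table = load_table3_fixture()["chgc"]
        count, rate = chgc_misclassification(table)
        assert count == 7
        assert round(100 * rate, 1) == 6.1

    def test_perfect_table_has_zero_errors(self):
        table = pd.DataFrame(0, index=[0, 1, 2, 3, 4],
                             columns=["k1", "k2", "k3", "k4", "k5"])
        table.loc[4, "k1"] = 10
        table.loc[3, "k2"] = 10
        table.loc[3, "k3"] = 5
        table.loc[0, "k4"] = 10
        table.loc[1, "k5"] = 10
        assert goldberg_misclassification(table)[0] == 0

    def test_matches_cell_loop_oracle(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 8, size=(5, 5))
            table = pd.DataFrame(counts, index=[0, 1, 2, 3, 4],
                                 columns=["k1", "k2", "k3", "k4", "k5"])
            count, rate = goldberg_misclassification(table)
            expected = 0
            for score in range(5):
                for col in table.columns:
                    bad_skg = col in ("k1", "k2", "k3") and score <= 2
                    bad_non = col in ("k4", "k5") and score >= 3
                    if bad_skg or bad_non:
                        expected += table.loc[score, col]
            assert count == expected
            assert rate == pytest.approx(expected / counts.sum())

    def test_empty_table_rejected(self):
        table = pd.DataFrame(0, index=[0, 1, 2, 3, 4],
                             columns=["k1", "k2", "k3", "k4", "k5"])
        with pytest.raises(ValueError, match="undefined"):
            goldberg_misclassification(table)

    def test_non_goldberg_rows_rejected(self):
        table = load_table3_fixture()["chgc"]
        with pytest.raises(ValueError, match="Goldberg"):
            goldberg_misclassification(table)

    def test_invariant_to_permutation_within_blocks(self, rng):
        table = load_table3_fixture()["goldberg"].copy()
        count, _ = goldberg_misclassification(table)
        permuted = table.reindex(index=["1", "0", "2", "4", "3"])  # within <=2 and >=3 blocks
        assert goldberg_misclassification(permuted)[0] == count


class TestMedianScores:
    def test_published_cluster_medians(self):
        medians = median_score_by_cluster(load_table3_fixture()["goldberg"])
        assert medians["k1"] == 2.0
        assert medians["k2"] == 3.0
        assert medians["k3"] == 3.0

    def test_single_count_column(self):
        table = pd.DataFrame({"k1": [1, 0, 0, 0, 0]}, index=[0, 1, 2, 3, 4])
        assert median_score_by_cluster(table)["k1"] == 0.0

    def test_empty_column_reported_missing(self):
        table = pd.DataFrame({"k1": [2, 0, 0, 0, 0], "k2": [0] * 5},
                             index=[0, 1, 2, 3, 4])
        assert np.isnan(median_score_by_cluster(table)["k2"])

    def test_even_count_median_is_mean_of_central_pair(self):
        table = pd.DataFrame({"k1": [1, 1, 0, 0, 0]}, index=[0, 1, 2, 3, 4])
        assert median_score_by_cluster(table)["k1"] == 0.5
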