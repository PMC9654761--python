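"""Event-anchored feature extraction: peak detection, clustering features,
standard parameters, and agreement with an independent straight-line
reference implementation."""

import numpy as np
import pytest
from scipy.interpolate import PchipInterpolator

from skgait.features import (
    FeatureExtractionError,
    PhaseConfig,
    compute_clustering_features,
    compute_standard_parameters,
    detect_pkf1,
    feature_matrix,
)
from skgait.gait_data import GaitCycle, angle_at


def _curve(points):
    xs, ys = zip(*points)
    return PchipInterpolator(np.array(xs, float), np.array(ys, float))(np.arange(101))


def _cycle(knee, toe_off=60.0, tv=82.0, **kw):
    base = dict(
        hip_angle=np.full(101, 10.0), knee_angle=knee, ankle_angle=np.zeros(101),
        toe_off=toe_off, tibia_vertical=tv,
        contralateral_foot_strike=toe_off - 10, cycle_duration=1.2,
    )
    base.update(kw)
    return GaitCycle(**base)


# --- independent straight-line reference, kept free of the library's helpers

def _reference_pkf1(knee, toe_off, prominence=0.5):
    start = int(np.ceil(toe_off))
    peaks = []
    i = start + 1
    while i < 100:
        if knee[i] > knee[i - 1]:
            j = i
            while j + 1 <= 100 and knee[j + 1] == knee[j]:
                j += 1
            if j < 100 and knee[j + 1] < knee[j]:
                # prominence: drop to the highest base on either side
                left = knee[start:i]
                lmin = left.min() if left.size else knee[i]
                k = j + 1
                rmin = knee[j]
                while k <= 100 and knee[k] < knee[i]:
                    rmin = min(rmin, knee[k])
                    k += 1
                base = max(lmin, rmin) if left.size else rmin
                if knee[i] - base >= prominence:
                    peaks.append(i)
                i = j + 1
                continue
        i += 1
    if peaks:
        return float(knee[peaks[0]]), float(peaks[0])
    bval = float(np.interp(toe_off, np.arange(101), knee))
    window = knee[start:]
    if window.size == 0 or bval >= window.max():
        return bval, float(toe_off)
    k = int(np.argmax(window))
    return float(knee[start + k]), float(start + k)


class TestDetectPKF1:
    def test_unique_maximum(self):
        knee = _curve([(0, 5), (15, 18), (45, 5), (60, 25), (73, 36), (85, 20), (100, 5)])
        angle, t = detect_pkf1(knee, 60.0)
        assert t == 73.0
        assert angle == pytest.approx(36.0, abs=1e-9)

    def test_double_bump_returns_first_lower_bump(self):
        knee = _curve([(0, 5), (40, 4), (60, 12), (68, 22), (76, 15),
                       (85, 25), (100, 5)])
        angle, t = detect_pkf1(knee, 60.0)
        assert (angle, t) == (pytest.approx(22.0, abs=1e-9), 68.0)

    def test_plateau_returns_first_sample(self):
        knee = np.zeros(101)
        knee[60:70] = np.linspace(0, 11, 10)
        knee[70:75] = 12.0
        angle, t = detect_pkf1(knee, 55.0)
        assert (angle, t) == (12.0, 70.0)

    def test_non_increasing_window_returns_toe_off(self):
        knee = np.linspace(50.0, 0.0, 101)
        angle, t = detect_pkf1(knee, 60.0)
        assert t == 60.0
        assert angle == pytest.approx(20.0)

    def test_constant_shift_moves_angle_not_time(self, rng):
        from tests.conftest import random_cycle

        for _ in range(20):
            c = random_cycle(rng, n_bumps=int(rng.integers(1, 3)))
            a0, t0 = detect_pkf1(c.knee_angle, c.toe_off)
            shift = float(rng.uniform(-30, 30))
            a1, t1 = detect_pkf1(c.knee_angle + shift, c.toe_off)
            assert t1 == t0
            assert a1 == pytest.approx(a0 + shift, abs=1e-9)

    def test_matches_reference_on_random_cycles(self, rng):
        from tests.conftest import random_cycle

        for _ in range(50):
            c = random_cycle(rng, n_bumps=int(rng.integers(1, 4)))
            got = detect_pkf1(c.knee_angle, c.toe_off)
            want = _reference_pkf1(c.knee_angle, c.toe_off)
            assert got == (pytest.approx(want[0], abs=1e-9), want[1])


class TestClusteringFeatures:
    def test_definitional_arithmetic(self):
        knee = _curve([(0, 5), (40, 5), (60, 25), (73, 36), (82, 30), (100, 5)])
        feats = compute_clustering_features(_cycle(knee, toe_off=60.0, tv=82.0))
        assert feats.PKF1 == pytest.approx(36.0, abs=1e-9)
        assert feats.KFE == pytest.approx(11.0, abs=1e-9)
        assert feats.T1 == pytest.approx(13.0, abs=1e-9)
        assert feats.KFM == pytest.approx(6.0, abs=1e-9)
        assert feats.T2 == pytest.approx(9.0, abs=1e-9)

    def test_constant_series(self):
        feats = compute_clustering_features(_cycle(np.full(101, 8.0)))
        assert (feats.PKF1, feats.KFE, feats.T1, feats.KFM) == (8.0, 0.0, 0.0, 0.0)
        assert feats.T2 == pytest.approx(22.0)  # tibia-vertical minus toe-off

    def test_matches_straight_line_reference(self, rng):
        from tests.conftest import random_cycle

        for _ in range(50):
            c = random_cycle(rng, n_bumps=int(rng.integers(1, 3)))
            feats = compute_clustering_features(c)
            pkf1, tp = _reference_pkf1(c.knee_angle, c.toe_off)
            grid = np.arange(101)
            assert feats.PKF1 == pytest.approx(pkf1, abs=1e-9)
            assert feats.KFE == pytest.approx(
                pkf1 - np.interp(c.toe_off, grid, c.knee_angle), abs=1e-9)
            assert feats.T1 == pytest.approx(tp - c.toe_off, abs=1e-9)
            assert feats.KFM == pytest.approx(
                pkf1 - np.interp(c.tibia_vertical, grid, c.knee_angle), abs=1e-9)
            assert feats.T2 == pytest.approx(c.tibia_vertical - tp, abs=1e-9)

    def test_kfe_and_t1_nonnegative(self, default_cohort, cohort_features):
        assert (cohort_features["KFE"] >= 0).all()
        assert (cohort_features["T1"] >= 0).all()

    def test_missing_tibia_vertical_warns_with_fallback(self):
        knee = _curve([(0, 5), (60, 25), (73, 36), (100, 5)])
        cycle = _cycle(knee, tv=None)
        with pytest.warns(UserWarning, match="tibia_vertical"):
            feats = compute_clustering_features(cycle)
        assert feats.T2 == pytest.approx((60.0 + 100.0) / 2.0 - 73.0)


class TestStandardParameters:
    def test_kfv_slope_of_line(self):
        knee = np.interp(np.arange(101), [0, 50, 60, 100], [20, 20, 30, 30]).astype(float)
        cycle = _cycle(knee, toe_off=60.0, contralateral_foot_strike=50.0,
                       cycle_duration=1.2)
        params = compute_standard_parameters(cycle)
        assert params.KFV == pytest.approx(10.0 / 0.12)

    def test_constant_ankle_mavp_zero(self):
        params = compute_standard_parameters(_cycle(np.full(101, 8.0)))
        assert params.MAVP == 0.0

    def test_k5_matches_brute_force_swing_scan(self, rng):
        from tests.conftest import random_cycle

        for _ in range(20):
            c = random_cycle(rng, n_bumps=2)
            params = compute_standard_parameters(c)
            start = int(np.ceil(c.toe_off))
            expected = max(c.knee_angle[start:].max(),
                           angle_at(c.knee_angle, c.toe_off))
            assert params.K5 == pytest.approx(expected, abs=1e-9)

    def test_range_invariants(self, rng):
        from tests.conftest import random_cycle

        for _ in range(20):
            c = random_cycle(rng, n_bumps=int(rng.integers(1, 3)))
            p = compute_standard_parameters(c)
            assert p.H6 >= 0 and p.K6 >= 0 and p.A6 >= 0
            assert p.K6 >= p.K5 - p.K3 - 1e-9

    def test_pkf1_equals_k5_on_unique_maximum(self):
        # noise-free single-bump cycle: both extraction paths must agree
        from skgait.simulate import default_specs, generate_cycle
        from dataclasses import replace

        spec = replace(default_specs()["healthy"], noise_sd=0.0)
        rng = np.random.default_rng(0)
        for _ in range(10):
            c = generate_cycle(spec, rng)
            feats = compute_clustering_features(c)
            params = compute_standard_parameters(c)
            assert feats.PKF1 == pytest.approx(params.K5, abs=1e-9)

    def test_degenerate_preswing_window_rejected(self):
        cycle = _cycle(np.full(101, 8.0), contralateral_foot_strike=None)
        with pytest.raises(FeatureExtractionError, match="preswing"):
            compute_standard_parameters(cycle, PhaseConfig(preswing_width=0.0))


class TestFeatureMatrix:
    def test_shape_and_order(self, default_cohort, cohort_features):
        assert cohort_features.shape == (len(default_cohort), 5)
        assert list(cohort_features.columns) == ["PKF1", "KFE", "T1", "KFM", "T2"]
        assert list(cohort_features.index) == default_cohort.subject_ids

    def test_permutation_equivariance_and_loop_oracle(self, default_cohort, cohort_features):
        from skgait.gait_data import Cohort, average_cycles

        permuted = Cohort(default_cohort.subjects[::-1])
        feats_p = feature_matrix(permuted)
        assert list(feats_p.index) == default_cohort.subject_ids[::-1]
        np.testing.assert_allclose(
            feats_p.to_numpy(), cohort_features.to_numpy()[::-1], atol=1e-12)
        # loop oracle on a handful of subjects
        for subject in default_cohort.subjects[::25]:
            feats = compute_clustering_features(average_cycles(subject, n_keep=5))
            np.testing.assert_allclose(
                cohort_features.loc[subject.subject_id].to_numpy(),
                feats.as_array(), atol=1e-12)
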