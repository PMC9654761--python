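"""Event-anchored extraction of sagittal kinematic parameters from a gait cycle.

Two families of parameters are produced from the 101-sample, time-normalized
sagittal joint angles:

* the five swing-phase knee parameters fed to the severity clustering —
  first-bump peak knee flexion (PKF1, degrees), knee flexion enhancement
  from toe-off to that peak (KFE), time from toe-off to the peak (T1, %GC),
  knee flexion decrease from the peak to the tibia-vertical instant (KFM),
  and time from the peak to tibia-vertical (T2, %GC);
* the standard per-joint sagittal parameters (H1..H6, K1..K6, KFV,
  A1..A7, MAVP) used for between-cluster construct-validity statistics.

When a stiff knee produces several swing-phase flexion bumps, PKF1 is the
*first* bump, not the global maximum; the global maximum is the separate
Goldberg-style PKF handled in :mod:`skgait.goldberg`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .gait_data import Cohort, GaitCycle, N_SAMPLES, angle_at, average_cycles

FEATURE_NAMES = ("PKF1", "KFE", "T1", "KFM", "T2")

STANDARD_PARAMETER_NAMES = (
    "H1", "H2", "H3", "H4", "H5", "H6",
    "K1", "K2", "K3", "K4", "K5", "K6", "KFV",
    "A1", "A2", "A3", "A4", "A5", "A6", "A7", "MAVP",
)

__all__ = [
    "FEATURE_NAMES",
    "STANDARD_PARAMETER_NAMES",
    "ClusteringFeatures",
    "StandardParameters",
    "PhaseConfig",
    "FeatureExtractionError",
    "detect_pkf1",
    "compute_clustering_features",
    "compute_standard_parameters",
    "feature_matrix",
    "standard_parameter_table",
]


class FeatureExtractionError(ValueError):
    pass


@dataclass(frozen=True)
class ClusteringFeatures:
    """The five swing-phase knee parameters used for severity clustering."""

    PKF1: float
    KFE: float
    T1: float
    KFM: float
    T2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.PKF1, self.KFE, self.T1, self.KFM, self.T2], float)


@dataclass(frozen=True)
class StandardParameters:
    """The 20 + 2 standard sagittal parameters of hip, knee and ankle.

    Angles in degrees (flexion / dorsiflexion positive; plantarflexion and
    hip/knee extension appear as negative values), velocities in deg/s.
    """

    H1: float; H2: float; H3: float; H4: float; H5: float; H6: float
    K1: float; K2: float; K3: float; K4: float; K5: float; K6: float
    KFV: float
    A1: float; A2: float; A3: float; A4: float; A5: float; A6: float; A7: float
    MAVP: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass(frozen=True)
class PhaseConfig:
    """Gait-phase window boundaries in percent of the gait cycle.

    Stance runs from foot-strike to toe-off and swing from toe-off to the
    next foot-strike; the loading phase covers initial double support, and
    preswing runs from contralateral foot-strike to toe-off (falling back
    to a fixed-width window before toe-off when that event is missing).
    """

    loading_end: float = 10.0
    preswing_width: float = 12.0  # fallback when contralateral foot-strike absent
    tibia_vertical_fallback: str = "midswing"  # midpoint of (toe_off, 100)


def _window_series(series: np.ndarray, start: float, stop: float) -> np.ndarray:
    """Series over [start, stop] %GC: interior samples plus interpolated endpoints."""
    if stop < start:
        raise FeatureExtractionError(f"degenerate phase window [{start}, {stop}]")
    lo = int(np.ceil(start))
    hi = int(np.floor(stop))
    parts = [np.array([angle_at(series, start)])]
    if hi >= lo:
        parts.append(series[lo:hi + 1])
    parts.append(np.array([angle_at(series, stop)]))
    return np.concatenate(parts)


def detect_pkf1(
    knee_angle: np.ndarray,
    toe_off: float,
    prominence: float = 0.5,
    smooth: int = 0,
) -> tuple[float, float]:
    """First swing-phase knee-flexion bump: (angle in degrees, time in %GC).

    Searches [toe_off, 100]. A bump is a local maximum with prominence
    >= ``prominence`` degrees (a plateau counts from its first sample).
    Several bumps return the earliest, not the highest. If no bump exists,
    the maximum over the window is returned — for a non-increasing window
    that is the (interpolated) value at toe-off itself.

    ``smooth`` > 0 applies a centred moving average of that width before
    peak detection (off by default); the reported angle is read from the
    raw series at the detected time.
    """
    knee_angle = np.asarray(knee_angle, float)
    if not (0.0 < toe_off < 100.0):
        raise FeatureExtractionError(f"toe_off must lie in (0, 100), got {toe_off}")
    series = knee_angle
    if smooth and smooth > 1:
        kernel = np.ones(int(smooth)) / int(smooth)
        series = np.convolve(knee_angle, kernel, mode="same")

    start = int(np.ceil(toe_off))
    window = series[start:]
    peaks, props = find_peaks(window, prominence=prominence, plateau_size=1)
    if peaks.size:
        first = int(props["left_edges"][0])  # plateau -> first sample
        t = float(start + first)
        return float(knee_angle[start + first]), t

    # No interior bump: fall back to the window maximum (earliest occurrence),
    # including the interpolated toe-off endpoint.
    boundary_val = angle_at(knee_angle, toe_off)
    if window.size == 0 or boundary_val >= float(np.max(window)):
        return float(boundary_val), float(toe_off)
    i = int(np.argmax(window))
    return float(knee_angle[start + i]), float(start + i)


def _resolve_tibia_vertical(cycle: GaitCycle, phases: PhaseConfig) -> float:
    if cycle.tibia_vertical is not None:
        return float(cycle.tibia_vertical)
    if phases.tibia_vertical_fallback == "midswing":
        import warnings

        warnings.warn(
            "tibia_vertical event missing; falling back to the midpoint of "
            "the swing phase", stacklevel=3,
        )
        return float((cycle.toe_off + 100.0) / 2.0)
    raise FeatureExtractionError(
        "tibia_vertical event missing and no fallback configured for this cycle"
    )


def compute_clustering_features(
    cycle: GaitCycle,
    phases: PhaseConfig | None = None,
    prominence: float = 0.5,
    smooth: int = 0,
) -> ClusteringFeatures:
    """The five clustering parameters of one cycle (PKF1, KFE, T1, KFM, T2)."""
    phases = phases or PhaseConfig()
    pkf1, t_p = detect_pkf1(cycle.knee_angle, cycle.toe_off, prominence=prominence, smooth=smooth)
    tv = _resolve_tibia_vertical(cycle, phases)
    knee_to = cycle.knee_at(cycle.toe_off)
    knee_tv = cycle.knee_at(tv)
    return ClusteringFeatures(
        PKF1=pkf1,
        KFE=pkf1 - knee_to,
        T1=t_p - cycle.toe_off,
        KFM=pkf1 - knee_tv,
        T2=tv - t_p,
    )


def compute_standard_parameters(
    cycle: GaitCycle, phases: PhaseConfig | None = None
) -> StandardParameters:
    """The standard sagittal hip/knee/ankle parameters of one cycle.

    Extrema use the phase windows of ``phases``; "maximum extension" and
    "maximum plantarflexion" are reported as the signed minimum of the
    flexion-positive (dorsiflexion-positive) series over the window. KFV
    and MAVP are mean angular velocities over the preswing phase in deg/s
    (MAVP positive when the ankle moves toward plantarflexion), using the
    cycle duration to convert %GC to seconds.
    """
    phases = phases or PhaseConfig()
    to = cycle.toe_off
    hip, knee, ankle = cycle.hip_angle, cycle.knee_angle, cycle.ankle_angle

    loading = (0.0, min(phases.loading_end, to))
    stance = (0.0, to)
    swing = (to, 100.0)
    if cycle.contralateral_foot_strike is not None:
        preswing = (cycle.contralateral_foot_strike, to)
    else:
        preswing = (max(0.0, to - phases.preswing_width), to)
    if preswing[1] <= preswing[0]:
        raise FeatureExtractionError("degenerate (empty) preswing window")

    def vmax(series, win):
        return float(np.max(_window_series(series, *win)))

    def vmin(series, win):
        return float(np.min(_window_series(series, *win)))

    preswing_seconds = (preswing[1] - preswing[0]) / 100.0 * cycle.cycle_duration
    knee_rate = (angle_at(knee, preswing[1]) - angle_at(knee, preswing[0])) / preswing_seconds
    ankle_rate = (angle_at(ankle, preswing[0]) - angle_at(ankle, preswing[1])) / preswing_seconds

    return StandardParameters(
        H1=float(hip[0]),
        H2=vmax(hip, loading),
        H3=vmin(hip, stance),
        H4=angle_at(hip, to),
        H5=vmax(hip, swing),
        H6=float(np.max(hip) - np.min(hip)),
        K1=float(knee[0]),
        K2=vmax(knee, loading),
        K3=vmin(knee, stance),
        K4=angle_at(knee, to),
        K5=vmax(knee, swing),
        K6=float(np.max(knee) - np.min(knee)),
        KFV=float(knee_rate),
        A1=float(ankle[0]),
        A2=vmin(ankle, loading),
        A3=vmax(ankle, stance),
        A4=angle_at(ankle, to),
        A5=vmax(ankle, swing),
        A6=float(np.max(ankle) - np.min(ankle)),
        A7=vmin(ankle, swing),
        MAVP=float(ankle_rate),
    )


def feature_matrix(
    cohort: Cohort,
    n_keep: int = 5,
    phases: PhaseConfig | None = None,
    prominence: float = 0.5,
) -> pd.DataFrame:
    """Per-subject clustering features: one averaged cycle per subject.

    Rows follow cohort order (index = subject_id); columns are exactly
    ``PKF1, KFE, T1, KFM, T2``.
    """
    rows, index = [], []
    for subject in cohort:
        n = min(n_keep, len(subject.cycles)) if n_keep is None else n_keep
        try:
            mean_cycle = average_cycles(subject, n_keep=n)
            feats = compute_clustering_features(mean_cycle, phases=phases, prominence=prominence)
        except (FeatureExtractionError, ValueError) as exc:
            raise FeatureExtractionError(f"subject {subject.subject_id!r}: {exc}") from exc
        rows.append(feats.as_array())
        index.append(subject.subject_id)
    return pd.DataFrame(rows, index=pd.Index(index, name="subject_id"),
                        columns=list(FEATURE_NAMES))


def standard_parameter_table(
    cohort: Cohort, n_keep: int = 5, phases: PhaseConfig | None = None
) -> pd.DataFrame:
    """Per-subject standard sagittal parameters on the averaged cycle."""
    rows, index = [], []
    for subject in cohort:
        mean_cycle = average_cycles(subject, n_keep=n_keep)
        rows.append(compute_standard_parameters(mean_cycle, phases=phases).as_dict())
        index.append(subject.subject_id)
    return pd.DataFrame(rows, index=pd.Index(index, name="subject_id"),
                        columns=list(STANDARD_PARAMETER_NAMES))
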