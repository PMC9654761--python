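"""Synthetic gait-cohort generator for the five knee-kinematics archetypes.

Real sagittal knee curves behind the severity scheme fall into five
morphologies: a normal curve (healthy), a near-normal patient curve
(non-SKG), a lowered and delayed or flattened swing peak (UKG, mild), a
"double bump" — two swing flexion peaks separated by an extension dip —
with a low first peak (BKG, moderate), and a nearly flat, frozen curve
(FLG, severe). The generator reproduces these families with a small set
of interpretable parameters: each knee curve is a shape-preserving
(PCHIP) interpolation through event-anchored control points, the hip is a
sinusoidal flexion-extension wave, the ankle a standard dorsi/plantar
pattern shifted toward plantarflexion (equinus) in the stiff archetypes,
and smooth correlated Gaussian noise is added on top.

Archetype swing-peak targets are calibrated to the published cluster
means of first-bump peak knee flexion: 36 deg (UKG), 21 deg (BKG), 10 deg
(FLG), with healthy subjects inside the published 44-50 deg swing-peak
confidence band; the non-SKG archetype (no published centroid) sits just
above the 40 deg stiff-knee cutoff with a reduced flexion enhancement and
is this package's own construction.

Everything is driven by a single integer seed: the same seed yields a
bit-identical cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

from .gait_data import Cohort, GaitCycle, N_SAMPLES, Subject

ARCHETYPES = ("healthy", "non-SKG", "UKG", "BKG", "FLG")

__all__ = [
    "ARCHETYPES",
    "ArchetypeSpec",
    "CohortConfig",
    "default_specs",
    "default_config",
    "generate_cycle",
    "generate_cohort",
]


@dataclass(frozen=True)
class ArchetypeSpec:
    """Parametric description of one synthetic gait-curve family.

    Angles in degrees, timings in percent gait cycle, durations in
    seconds. ``pkf1_mean``/``pkf1_sd`` set the between-subject
    distribution of the first-bump swing peak; ``kfe_mean`` fixes the knee
    angle at toe-off (``pkf1 - kfe``), and ``kfm_mean`` the descent from
    the peak to the tibia-vertical instant. ``double_bump_prob`` cycles
    get a second, higher swing bump after an extension dip;
    ``flatten_prob`` subjects get a broadened (plateau-like) peak.
    """

    name: str
    # knee swing peak
    pkf1_mean: float
    pkf1_sd: float
    peak_time_mean: float
    peak_time_sd: float = 0.7
    # knee anchors
    kfe_mean: float = 12.0          # peak minus knee at toe-off
    kfe_sd: float = 1.5
    kfm_mean: float = 10.0          # peak minus knee at tibia-vertical
    kfm_sd: float = 1.5
    initial_contact_angle: float = 5.0
    stance_flexion_amplitude: float = 15.0
    stance_flexion_time: float = 15.0
    stance_min_angle: float = 5.0
    # swing-shape variants
    double_bump_prob: float = 0.0
    double_bump_offset: float = 13.0   # second bump this much after the first
    double_bump_dip: float = 5.0       # extension dip between the bumps
    double_bump_gain: float = 3.0      # second bump height above the first
    flatten_prob: float = 0.0
    flatten_width: float = 3.0         # plateau half-width around the peak
    # other joints
    recurvatum_prob: float = 0.0
    recurvatum_depth: float = 5.0
    equinus_shift: float = 0.0
    hip_rom: float = 40.0
    # events and timing
    toe_off_mean: float = 60.0
    toe_off_sd: float = 0.7
    tibia_vertical_mean: float = 85.0
    tibia_vertical_sd: float = 0.7
    preswing_width: float = 10.0       # contralateral foot-strike to toe-off
    cycle_duration_mean: float = 1.1
    cycle_duration_sd: float = 0.1
    # noise
    noise_sd: float = 0.8              # white SD before smoothing
    noise_corr_len: int = 5            # moving-average window, samples
    # metadata distributions
    velocity_mean: float = 0.6
    velocity_sd: float = 0.2
    mas_probs: tuple[float, ...] = (0.5, 0.3, 0.15, 0.05, 0.0)   # mAS 0..4
    mrc_hip_probs: tuple[float, ...] = (0.0, 0.0, 0.1, 0.3, 0.4, 0.2)   # MRC 0..5
    mrc_ankle_probs: tuple[float, ...] = (0.1, 0.25, 0.3, 0.2, 0.1, 0.05)
    chgc_groups: tuple[str, ...] = ("GIIa", "GIIb")


def default_specs() -> dict[str, ArchetypeSpec]:
    """The five archetype families with their calibrated defaults."""
    return {
        "healthy": ArchetypeSpec(
            name="healthy", pkf1_mean=47.0, pkf1_sd=2.5, peak_time_mean=72.0,
            kfe_mean=20.0, kfm_mean=17.0, stance_flexion_amplitude=18.0,
            hip_rom=42.0, toe_off_mean=60.0, cycle_duration_mean=1.05,
            cycle_duration_sd=0.06, velocity_mean=0.59, velocity_sd=0.07,
            mas_probs=(1.0, 0.0, 0.0, 0.0, 0.0),
            mrc_hip_probs=(0, 0, 0, 0, 0.2, 0.8),
            mrc_ankle_probs=(0, 0, 0, 0, 0.2, 0.8),
            chgc_groups=("G0",),
        ),
        "non-SKG": ArchetypeSpec(
            name="non-SKG", pkf1_mean=43.0, pkf1_sd=2.0, peak_time_mean=72.0,
            kfe_mean=11.0, kfe_sd=1.2, kfm_mean=15.0, stance_flexion_amplitude=14.0,
            recurvatum_prob=0.35, equinus_shift=3.0, hip_rom=36.0,
            toe_off_mean=62.0, cycle_duration_mean=1.25, cycle_duration_sd=0.15,
            velocity_mean=0.80, velocity_sd=0.18,
            mas_probs=(0.6, 0.3, 0.1, 0.0, 0.0),
            mrc_hip_probs=(0, 0, 0.05, 0.15, 0.4, 0.4),
            mrc_ankle_probs=(0, 0.1, 0.2, 0.3, 0.3, 0.1),
            chgc_groups=("GIa", "GIb"),
        ),
        "UKG": ArchetypeSpec(
            name="UKG", pkf1_mean=36.0, pkf1_sd=2.0, peak_time_mean=78.0,
            kfe_mean=12.0, kfm_mean=10.0, stance_flexion_amplitude=12.0,
            flatten_prob=0.35, recurvatum_prob=0.35, equinus_shift=4.0,
            hip_rom=34.0, toe_off_mean=63.0, cycle_duration_mean=1.4,
            cycle_duration_sd=0.2, velocity_mean=0.70, velocity_sd=0.22,
            mas_probs=(0.5, 0.3, 0.15, 0.05, 0.0),
            mrc_hip_probs=(0, 0, 0.1, 0.25, 0.45, 0.2),
            mrc_ankle_probs=(0.05, 0.25, 0.3, 0.25, 0.1, 0.05),
            chgc_groups=("GIIa", "GIIb"),
        ),
        "BKG": ArchetypeSpec(
            name="BKG", pkf1_mean=21.0, pkf1_sd=2.0, peak_time_mean=68.0,
            kfe_mean=7.0, kfe_sd=1.0, kfm_mean=2.0, kfm_sd=1.0,
            stance_flexion_amplitude=10.0, double_bump_prob=0.68,
            recurvatum_prob=0.4, equinus_shift=6.0, hip_rom=30.0,
            toe_off_mean=64.0, cycle_duration_mean=1.55, cycle_duration_sd=0.25,
            velocity_mean=0.50, velocity_sd=0.18,
            mas_probs=(0.35, 0.3, 0.2, 0.15, 0.0),
            mrc_hip_probs=(0, 0.05, 0.15, 0.35, 0.35, 0.1),
            mrc_ankle_probs=(0.15, 0.35, 0.3, 0.15, 0.05, 0.0),
            chgc_groups=("GIIa", "GIIb", "GIIIa", "GIIIb"),
        ),
        "FLG": ArchetypeSpec(
            name="FLG", pkf1_mean=10.0, pkf1_sd=2.0, peak_time_mean=67.0,
            peak_time_sd=0.8, kfe_mean=3.0, kfe_sd=0.6, kfm_mean=2.5,
            kfm_sd=0.5, initial_contact_angle=8.0, stance_flexion_amplitude=4.0,
            stance_min_angle=6.0, recurvatum_prob=0.45, equinus_shift=8.0,
            hip_rom=22.0, toe_off_mean=66.0, tibia_vertical_mean=78.0, cycle_duration_mean=1.8,
            cycle_duration_sd=0.3, velocity_mean=0.35, velocity_sd=0.12,
            mas_probs=(0.25, 0.3, 0.25, 0.15, 0.05),
            mrc_hip_probs=(0.05, 0.1, 0.25, 0.35, 0.2, 0.05),
            mrc_ankle_probs=(0.35, 0.35, 0.2, 0.1, 0.0, 0.0),
            chgc_groups=("GIIIa", "GIIIb"),
        ),
    }


@dataclass
class CohortConfig:
    """Composition and seed of a synthetic cohort.

    ``n_per_archetype`` maps archetype name to subject count;
    ``n_healthy_subjects`` of the healthy-archetype subjects are flagged
    as healthy adults (the rest are patients whose gait happens to be in
    the normal band). The default composition follows the study that the
    severity scheme was derived from.
    """

    n_per_archetype: dict[str, int] = field(
        default_factory=lambda: {"UKG": 34, "BKG": 28, "FLG": 9, "healthy": 25, "non-SKG": 14}
    )
    n_healthy_subjects: int = 19
    n_cycles: int = 5
    seed: int = 0
    specs: dict[str, ArchetypeSpec] = field(default_factory=default_specs)

    def to_dict(self) -> dict:
        return {
            "n_per_archetype": dict(self.n_per_archetype),
            "n_healthy_subjects": self.n_healthy_subjects,
            "n_cycles": self.n_cycles,
            "seed": self.seed,
            "specs": {k: asdict(v) for k, v in self.specs.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        specs = {k: ArchetypeSpec(**{**v, "mas_probs": tuple(v.get("mas_probs", ())),
                                     "mrc_hip_probs": tuple(v.get("mrc_hip_probs", ())),
                                     "mrc_ankle_probs": tuple(v.get("mrc_ankle_probs", ())),
                                     "chgc_groups": tuple(v.get("chgc_groups", ()))})
                 for k, v in d.get("specs", {}).items()} or default_specs()
        return cls(
            n_per_archetype=dict(d.get("n_per_archetype", cls().n_per_archetype)),
            n_healthy_subjects=d.get("n_healthy_subjects", 19),
            n_cycles=d.get("n_cycles", 5),
            seed=d.get("seed", 0),
            specs=specs,
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1), encoding="utf-8")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortConfig":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def default_config(seed: int = 0) -> CohortConfig:
    return CohortConfig(seed=seed)


# ---------------------------------------------------------------------------
# curve construction


def _smooth_noise(rng: np.random.Generator, sd: float, corr_len: int) -> np.ndarray:
    white = rng.normal(0.0, sd, N_SAMPLES)
    if corr_len and corr_len > 1:
        kernel = np.ones(corr_len) / corr_len
        pad = corr_len  # reflect-pad so the ends are not attenuated
        padded = np.concatenate([white[pad:0:-1], white, white[-2:-pad - 2:-1]])
        white = np.convolve(padded, kernel, mode="same")[pad:pad + N_SAMPLES]
    return white


def _draw_subject_params(spec: ArchetypeSpec, rng: np.random.Generator) -> dict:
    """Between-subject draw of the curve parameters of one participant."""
    pkf1 = rng.normal(spec.pkf1_mean, spec.pkf1_sd)
    toe_off = float(np.clip(rng.normal(spec.toe_off_mean, spec.toe_off_sd), 45.0, 75.0))
    peak_time = float(np.clip(rng.normal(spec.peak_time_mean, spec.peak_time_sd),
                              toe_off + 2.0, 90.0))
    tv = float(np.clip(rng.normal(spec.tibia_vertical_mean, spec.tibia_vertical_sd),
                       toe_off + 3.0, 97.0))
    return {
        "pkf1": float(pkf1),
        "kfe": float(max(0.5, rng.normal(spec.kfe_mean, spec.kfe_sd))),
        "kfm": float(rng.normal(spec.kfm_mean, spec.kfm_sd)),
        "toe_off": toe_off,
        "peak_time": peak_time,
        "tibia_vertical": tv,
        "double_bump": bool(rng.random() < spec.double_bump_prob),
        "flatten": bool(rng.random() < spec.flatten_prob),
        "recurvatum": bool(rng.random() < spec.recurvatum_prob),
        "cycle_duration": float(max(0.6, rng.normal(spec.cycle_duration_mean,
                                                    spec.cycle_duration_sd))),
        "velocity": float(max(0.1, rng.normal(spec.velocity_mean, spec.velocity_sd))),
    }


def _knee_curve(spec: ArchetypeSpec, p: dict) -> np.ndarray:
    to, tp, tv = p["toe_off"], p["peak_time"], p["tibia_vertical"]
    pkf1, kfe, kfm = p["pkf1"], p["kfe"], p["kfm"]
    k_to = pkf1 - kfe
    k_ic = spec.initial_contact_angle
    stance_min = -p["recurvatum"] * spec.recurvatum_depth + spec.stance_min_angle * (not p["recurvatum"])
    stance_peak = max(spec.initial_contact_angle + spec.stance_flexion_amplitude, k_ic + 1.0)

    pts: list[tuple[float, float]] = [
        (0.0, k_ic),
        (spec.stance_flexion_time, stance_peak),
        (40.0, stance_min),
        (max(41.0, to - 12.0), stance_min + 0.25 * (k_to - stance_min)),
        (to, k_to),
    ]
    if p["double_bump"]:
        t2 = min(tp + spec.double_bump_offset, 94.0)
        t_dip = (tp + t2) / 2.0
        pts += [
            (tp, pkf1),
            (t_dip, pkf1 - spec.double_bump_dip),
            (t2, pkf1 + spec.double_bump_gain),
        ]
        tail_start = t2
        tail_val = pkf1 + spec.double_bump_gain
    elif p["flatten"]:
        w = spec.flatten_width
        pts += [
            (max(to + 1.0, tp - w), pkf1 - 1.0),
            (tp, pkf1),
            (min(tp + w, 97.0), pkf1 - 1.0),
        ]
        tail_start = min(tp + w, 97.0)
        tail_val = pkf1 - 1.0
    else:
        # immediate post-peak descent so slow declines never read as plateaus
        shoulder = min(tp + 3.0, 96.0)
        pts += [(tp, pkf1), (shoulder, pkf1 - 2.0)]
        tail_start = shoulder
        tail_val = pkf1 - 2.0

    # descent anchored at the tibia-vertical instant (sets KFM), then to the
    # next foot-strike
    if tv > tail_start + 1.0:
        pts.append((tv, min(tail_val - 1.0, pkf1 - kfm)))
    pts.append((100.0, k_ic))

    xs = np.array([x for x, _ in pts])
    ys = np.array([y for _, y in pts])
    keep = np.concatenate([[True], np.diff(xs) > 0.5])
    return PchipInterpolator(xs[keep], ys[keep])(np.arange(N_SAMPLES))


def _hip_curve(spec: ArchetypeSpec, p: dict) -> np.ndarray:
    t = np.arange(N_SAMPLES, dtype=float)
    mid = 10.0  # mean hip posture, flexion-biased
    return mid + (spec.hip_rom / 2.0) * np.cos(2.0 * np.pi * (t - 88.0) / 100.0)


def _ankle_curve(spec: ArchetypeSpec, p: dict) -> np.ndarray:
    to = p["toe_off"]
    pts = [
        (0.0, 0.0), (8.0, -5.0), (45.0, 10.0),
        (min(to + 3.0, 80.0), -15.0), (88.0, 2.0), (100.0, 0.0),
    ]
    xs = np.array([x for x, _ in pts])
    ys = np.array([y for _, y in pts])
    keep = np.concatenate([[True], np.diff(xs) > 0.5])
    return PchipInterpolator(xs[keep], ys[keep])(np.arange(N_SAMPLES)) - spec.equinus_shift


def generate_cycle(
    spec: ArchetypeSpec,
    rng: np.random.Generator,
    params: dict | None = None,
    side: str = "affected",
) -> GaitCycle:
    """One synthetic gait cycle of the given archetype.

    ``params`` are the between-subject curve parameters (drawn fresh when
    omitted); repeated calls with the same ``params`` produce within-
    subject cycle-to-cycle variability only.
    """
    p = dict(params) if params is not None else _draw_subject_params(spec, rng)
    # within-subject jitter
    p["pkf1"] += rng.normal(0.0, 0.25)
    p["peak_time"] = float(np.clip(p["peak_time"] + rng.normal(0.0, 0.2),
                                   p["toe_off"] + 2.0, 90.0))
    p["toe_off"] = float(np.clip(p["toe_off"] + rng.normal(0.0, 0.2), 45.0, 75.0))
    p["tibia_vertical"] = float(np.clip(p["tibia_vertical"] + rng.normal(0.0, 0.2),
                                        p["toe_off"] + 3.0, 97.0))
    duration = max(0.5, p["cycle_duration"] + rng.normal(0.0, 0.02))

    knee = _knee_curve(spec, p) + _smooth_noise(rng, spec.noise_sd, spec.noise_corr_len)
    hip = _hip_curve(spec, p) + _smooth_noise(rng, spec.noise_sd, spec.noise_corr_len)
    ankle = _ankle_curve(spec, p) + _smooth_noise(rng, spec.noise_sd, spec.noise_corr_len)

    return GaitCycle(
        hip_angle=hip, knee_angle=knee, ankle_angle=ankle,
        toe_off=p["toe_off"],
        contralateral_foot_strike=max(1.0, p["toe_off"] - spec.preswing_width),
        tibia_vertical=p["tibia_vertical"],
        cycle_duration=duration,
        side=side,
        label=spec.name,
    )


def _draw_ordinal(rng: np.random.Generator, probs: tuple[float, ...]) -> int:
    p = np.asarray(probs, float)
    return int(rng.choice(len(p), p=p / p.sum()))


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Synthetic cohort with per-subject archetype labels in ``subject.label``.

    Each subject carries ``config.n_cycles`` cycles (so the per-subject
    averaging step is exercised), demographic and clinical metadata drawn
    from archetype-specific distributions, and a plausible clinician CHGC
    group (recurvatum subjects get the 'a' subgroup).
    """
    config = config or default_config()
    rng = np.random.default_rng(config.seed)
    subjects: list[Subject] = []
    sid = 0
    for arch in ARCHETYPES:
        n = config.n_per_archetype.get(arch, 0)
        spec = config.specs[arch]
        for i in range(n):
            healthy = arch == "healthy" and i < config.n_healthy_subjects
            params = _draw_subject_params(spec, rng)
            side = "right" if healthy else "affected"
            cycles = [generate_cycle(spec, rng, params=params, side=side)
                      for _ in range(config.n_cycles)]
            if healthy:
                chgc = "G0"
            else:
                choices = [g for g in spec.chgc_groups if g != "G0"] or ["GIa"]
                base = str(rng.choice(choices))
                if base != "G0" and len(base) > 2:
                    chgc = base[:-1] + ("a" if params["recurvatum"] else "b")
                else:
                    chgc = base
            sid += 1
            subjects.append(
                Subject(
                    subject_id=f"S{sid:03d}",
                    group="healthy" if healthy else "patient",
                    cycles=cycles,
                    walking_velocity=params["velocity"],
                    chgc_group=chgc,
                    mAS_4ceps=None if healthy else _draw_ordinal(rng, spec.mas_probs),
                    MRC_hip=None if healthy else _draw_ordinal(rng, spec.mrc_hip_probs),
                    MRC_ankle=None if healthy else _draw_ordinal(rng, spec.mrc_ankle_probs),
                    age=float(np.clip(rng.normal(54.0, 12.0), 20.0, 85.0)),
                    weight=float(np.clip(rng.normal(78.0, 16.0), 45.0, 130.0)),
                    height=float(np.clip(rng.normal(1.70, 0.08), 1.45, 2.0)),
                    sex="w" if rng.random() < 0.4 else "m",
                    label=arch,
                )
            )
    return Cohort(subjects=subjects,
                  provenance=f"synthetic cohort, seed={config.seed}")
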