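"""Data model and I/O for time-normalized gait cycles, subjects and cohorts.

A :class:`GaitCycle` holds the sagittal hip/knee/ankle angle series of one
gait cycle, resampled to 101 points (sample 0 = ipsilateral foot-strike,
sample 100 = the next ipsilateral foot-strike), together with the gait
events used to anchor feature extraction:

* ``toe_off`` — ipsilateral foot-off, the stance/swing boundary;
* ``contralateral_foot_strike`` — start of the preswing (terminal
  double-support) phase;
* ``tibia_vertical`` — end of mid-swing, when the ipsilateral shank is
  vertical.

Events are stored as percent of the gait cycle and may be fractional;
angle values at fractional events are obtained by linear interpolation.

Sign conventions: hip and knee flexion positive, ankle dorsiflexion
positive. Importers must convert into these conventions.

The native exchange format is a long CSV (one row per
subject x cycle x joint x sample, columns
``subject_id,cycle,joint,sample_index,angle_deg``) plus a JSON sidecar
``<stem>.meta.json`` holding per-cycle events and per-subject metadata.
A single-file JSON format is also supported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

N_SAMPLES = 101
JOINTS = ("hip", "knee", "ankle")

__all__ = [
    "N_SAMPLES",
    "GaitCycle",
    "Subject",
    "Cohort",
    "CohortFormatError",
    "read_cohort",
    "write_cohort",
    "average_cycles",
    "cohort_summary",
    "angle_at",
]


class CohortFormatError(ValueError):
    """Raised when a cohort file or in-memory cohort violates the data model."""


def _as_series(values, name: str, context: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (N_SAMPLES,):
        raise CohortFormatError(
            f"{context}: {name} must have exactly {N_SAMPLES} samples, got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise CohortFormatError(f"{context}: {name} contains non-finite values")
    return arr


def angle_at(series: np.ndarray, t_percent: float) -> float:
    """Angle at an arbitrary (possibly fractional) percent of the gait cycle."""
    return float(np.interp(t_percent, np.arange(N_SAMPLES), series))


@dataclass
class GaitCycle:
    """One time-normalized gait cycle of sagittal joint angles (degrees)."""

    hip_angle: np.ndarray
    knee_angle: np.ndarray
    ankle_angle: np.ndarray
    toe_off: float
    cycle_duration: float
    side: str = "affected"
    contralateral_foot_strike: float | None = None
    tibia_vertical: float | None = None
    label: str | None = None  # true archetype for synthetic cycles

    def __post_init__(self) -> None:
        ctx = "GaitCycle"
        self.hip_angle = _as_series(self.hip_angle, "hip_angle", ctx)
        self.knee_angle = _as_series(self.knee_angle, "knee_angle", ctx)
        self.ankle_angle = _as_series(self.ankle_angle, "ankle_angle", ctx)
        if not (0.0 < self.toe_off < 100.0):
            raise CohortFormatError(f"{ctx}: toe_off must lie in (0, 100), got {self.toe_off}")
        if self.cycle_duration <= 0:
            raise CohortFormatError(f"{ctx}: cycle_duration must be > 0")
        if self.side not in ("left", "right", "affected"):
            raise CohortFormatError(f"{ctx}: side must be left/right/affected, got {self.side!r}")
        if self.tibia_vertical is not None:
            if not (self.toe_off < self.tibia_vertical <= 100.0):
                raise CohortFormatError(
                    f"{ctx}: tibia_vertical must lie in (toe_off, 100], got "
                    f"{self.tibia_vertical} with toe_off {self.toe_off}"
                )
        if self.contralateral_foot_strike is not None:
            if not (0.0 < self.contralateral_foot_strike < self.toe_off):
                raise CohortFormatError(
                    f"{ctx}: contralateral_foot_strike must precede toe_off, got "
                    f"{self.contralateral_foot_strike} with toe_off {self.toe_off}"
                )

    def knee_at(self, t_percent: float) -> float:
        return angle_at(self.knee_angle, t_percent)


_ORDINAL_RANGES = {"mAS_4ceps": (0, 4), "MRC_hip": (0, 5), "MRC_ankle": (0, 5)}
CHGC_GROUPS = ("G0", "GIa", "GIb", "GIIa", "GIIb", "GIIIa", "GIIIb")


@dataclass
class Subject:
    """One participant with >= 1 gait cycles and clinical/demographic metadata."""

    subject_id: str
    group: str  # "patient" or "healthy"
    cycles: list[GaitCycle]
    walking_velocity: float | None = None
    chgc_group: str | None = None
    mAS_4ceps: int | None = None
    MRC_hip: int | None = None
    MRC_ankle: int | None = None
    age: float | None = None
    weight: float | None = None
    height: float | None = None
    sex: str | None = None
    label: str | None = None  # true archetype for synthetic subjects

    def __post_init__(self) -> None:
        ctx = f"Subject {self.subject_id!r}"
        if self.group not in ("patient", "healthy"):
            raise CohortFormatError(f"{ctx}: group must be patient/healthy, got {self.group!r}")
        if not self.cycles:
            raise CohortFormatError(f"{ctx}: needs at least one gait cycle")
        if self.chgc_group is not None and self.chgc_group not in CHGC_GROUPS:
            raise CohortFormatError(f"{ctx}: unknown CHGC group {self.chgc_group!r}")
        for name, (lo, hi) in _ORDINAL_RANGES.items():
            val = getattr(self, name)
            if val is not None and not (lo <= val <= hi):
                raise CohortFormatError(f"{ctx}: {name}={val} outside [{lo}, {hi}]")
        # Patients contribute the affected side; healthy adults the right side.
        expected = "affected" if self.group == "patient" else "right"
        for cyc in self.cycles:
            if cyc.side != expected:
                raise CohortFormatError(
                    f"{ctx}: {self.group} subjects must carry the {expected} side, "
                    f"found cycle with side {cyc.side!r}"
                )

    @property
    def is_healthy(self) -> bool:
        return self.group == "healthy"


@dataclass
class Cohort:
    """A collection of subjects with unique ids."""

    subjects: list[Subject]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortFormatError(f"Cohort: duplicate subject_ids {dupes}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]


# ---------------------------------------------------------------------------
# averaging and summaries


def average_cycles(subject: Subject, n_keep: int = 5) -> GaitCycle:
    """Pointwise mean of the subject's first ``n_keep`` cycles.

    Angle series, events and cycle duration are all averaged; an optional
    event enters the average only if present on every kept cycle.
    """
    if len(subject.cycles) < n_keep:
        raise CohortFormatError(
            f"Subject {subject.subject_id!r}: has {len(subject.cycles)} cycles, "
            f"needs {n_keep} for averaging"
        )
    kept = subject.cycles[:n_keep]

    def _mean_opt(values: list[float | None]) -> float | None:
        if any(v is None for v in values):
            return None
        return float(np.mean([float(v) for v in values]))

    return GaitCycle(
        hip_angle=np.mean([c.hip_angle for c in kept], axis=0),
        knee_angle=np.mean([c.knee_angle for c in kept], axis=0),
        ankle_angle=np.mean([c.ankle_angle for c in kept], axis=0),
        toe_off=float(np.mean([c.toe_off for c in kept])),
        contralateral_foot_strike=_mean_opt([c.contralateral_foot_strike for c in kept]),
        tibia_vertical=_mean_opt([c.tibia_vertical for c in kept]),
        cycle_duration=float(np.mean([c.cycle_duration for c in kept])),
        side=kept[0].side,
        label=kept[0].label,
    )


_CONTINUOUS = ("age", "weight", "height", "walking_velocity")
_ORDINAL = ("mAS_4ceps", "MRC_hip", "MRC_ankle")
_CATEGORICAL = ("group", "sex", "chgc_group")


def cohort_summary(cohort: Cohort) -> pd.DataFrame:
    """Demographic/clinical/gait descriptors in the conventional clinical layout.

    Continuous variables as mean +/- SD (ddof=1; SD reported as 0 for a single
    subject), ordinal scores as median [Q1-Q3] with linear-interpolation
    (type-7) quartiles, categorical variables as counts.
    """
    if len(cohort) == 0:
        raise CohortFormatError("cohort_summary: empty cohort")
    rows = []
    for name in _CONTINUOUS:
        vals = np.array([getattr(s, name) for s in cohort if getattr(s, name) is not None], float)
        if vals.size == 0:
            continue
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        rows.append(
            {"variable": name, "kind": "continuous", "n": vals.size,
             "mean": float(np.mean(vals)), "sd": sd,
             "summary": f"{np.mean(vals):.2f} ± {sd:.2f}"}
        )
    for name in _ORDINAL:
        vals = np.array([getattr(s, name) for s in cohort if getattr(s, name) is not None], float)
        if vals.size == 0:
            continue
        med = float(np.median(vals))
        q1, q3 = (float(q) for q in np.quantile(vals, [0.25, 0.75]))  # type-7 default
        rows.append(
            {"variable": name, "kind": "ordinal", "n": vals.size,
             "median": med, "q1": q1, "q3": q3,
             "summary": f"{med:g} [{q1:g}–{q3:g}]"}
        )
    for name in _CATEGORICAL:
        vals = [getattr(s, name) for s in cohort if getattr(s, name) is not None]
        if not vals:
            continue
        counts = pd.Series(vals).value_counts().sort_index()
        rows.append(
            {"variable": name, "kind": "categorical", "n": len(vals),
             "summary": "/".join(f"{k}:{v}" for k, v in counts.items())}
        )
    return pd.DataFrame(rows).set_index("variable")


# ---------------------------------------------------------------------------
# I/O

_EVENT_FIELDS = ("toe_off", "contralateral_foot_strike", "tibia_vertical",
                 "cycle_duration", "side", "label")
_SUBJECT_META = ("group", "walking_velocity", "chgc_group", "mAS_4ceps",
                 "MRC_hip", "MRC_ankle", "age", "weight", "height", "sex", "label")


def _subject_meta_dict(s: Subject) -> dict:
    meta = {k: getattr(s, k) for k in _SUBJECT_META}
    meta["cycles"] = [
        {k: getattr(c, k) for k in _EVENT_FIELDS} for c in s.cycles
    ]
    return meta


def write_cohort(cohort: Cohort, csv_path: str | Path, *, header_comment: str | None = None) -> Path:
    """Write the cohort as long CSV plus ``<stem>.meta.json`` sidecar.

    Returns the CSV path. ``header_comment`` (e.g. a seed/config stamp) is
    written as ``#``-prefixed lines at the top of the CSV.
    """
    csv_path = Path(csv_path)
    records = []
    for s in cohort:
        for ci, cyc in enumerate(s.cycles):
            for joint in JOINTS:
                series = getattr(cyc, f"{joint}_angle")
                records.append(
                    pd.DataFrame(
                        {"subject_id": s.subject_id, "cycle": ci, "joint": joint,
                         "sample_index": np.arange(N_SAMPLES), "angle_deg": series}
                    )
                )
    frame = pd.concat(records, ignore_index=True)
    with open(csv_path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, index=False, float_format="%.10g")
    meta = {
        "provenance": cohort.provenance,
        "subjects": {s.subject_id: _subject_meta_dict(s) for s in cohort},
    }
    sidecar = csv_path.with_suffix(".meta.json")
    sidecar.write_text(json.dumps(meta, indent=1), encoding="utf-8")
    return csv_path


def write_cohort_json(cohort: Cohort, path: str | Path) -> Path:
    """Write the cohort as a single self-contained JSON file."""
    path = Path(path)
    payload = {"provenance": cohort.provenance, "subjects": []}
    for s in cohort:
        meta = _subject_meta_dict(s)
        meta["subject_id"] = s.subject_id
        for cyc_meta, cyc in zip(meta["cycles"], s.cycles):
            cyc_meta["hip_angle"] = cyc.hip_angle.tolist()
            cyc_meta["knee_angle"] = cyc.knee_angle.tolist()
            cyc_meta["ankle_angle"] = cyc.ankle_angle.tolist()
        payload["subjects"].append(meta)
    path.write_text(json.dumps(payload), encoding="utf-8")
    return path


def _build_subject(subject_id: str, meta: dict, angle_blocks: list[dict[str, np.ndarray]]) -> Subject:
    cycles = []
    cycle_metas = meta.get("cycles", [])
    if len(cycle_metas) != len(angle_blocks):
        raise CohortFormatError(
            f"Subject {subject_id!r}: {len(angle_blocks)} cycles in CSV but "
            f"{len(cycle_metas)} cycle entries in metadata"
        )
    for ci, (cmeta, angles) in enumerate(zip(cycle_metas, angle_blocks)):
        for joint in JOINTS:
            if joint not in angles:
                raise CohortFormatError(
                    f"Subject {subject_id!r} cycle {ci}: missing {joint} series"
                )
        try:
            cycles.append(
                GaitCycle(
                    hip_angle=angles["hip"], knee_angle=angles["knee"],
                    ankle_angle=angles["ankle"],
                    toe_off=cmeta["toe_off"],
                    contralateral_foot_strike=cmeta.get("contralateral_foot_strike"),
                    tibia_vertical=cmeta.get("tibia_vertical"),
                    cycle_duration=cmeta["cycle_duration"],
                    side=cmeta.get("side", "affected"),
                    label=cmeta.get("label"),
                )
            )
        except (KeyError, CohortFormatError) as exc:
            raise CohortFormatError(f"Subject {subject_id!r} cycle {ci}: {exc}") from exc
    kwargs = {k: meta.get(k) for k in _SUBJECT_META}
    return Subject(subject_id=subject_id, cycles=cycles, **kwargs)


def read_cohort(path: str | Path, format: str | None = None) -> Cohort:
    """Read a cohort from long CSV (+ ``.meta.json`` sidecar) or single JSON.

    ``format`` is ``"csv"`` or ``"json"``; inferred from the extension when
    omitted. All data-model invariants are validated; violations raise
    :class:`CohortFormatError` naming the offending subject/cycle.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        subjects = []
        for meta in payload["subjects"]:
            blocks = [
                {j: np.asarray(c[f"{j}_angle"], float) for j in JOINTS}
                for c in meta["cycles"]
            ]
            subjects.append(_build_subject(meta["subject_id"], meta, blocks))
        return Cohort(subjects=subjects, provenance=payload.get("provenance", ""))
    if format != "csv":
        raise ValueError(f"unknown cohort format {format!r}")

    frame = pd.read_csv(path, comment="#")
    required = {"subject_id", "cycle", "joint", "sample_index", "angle_deg"}
    missing = required - set(frame.columns)
    if missing:
        raise CohortFormatError(f"{path}: missing columns {sorted(missing)}")
    sidecar = path.with_suffix(".meta.json")
    if not sidecar.exists():
        raise CohortFormatError(f"{path}: metadata sidecar {sidecar.name} not found")
    meta_all = json.loads(sidecar.read_text(encoding="utf-8"))

    subjects = []
    for subject_id, sub_frame in frame.groupby("subject_id", sort=False):
        meta = meta_all["subjects"].get(str(subject_id))
        if meta is None:
            raise CohortFormatError(f"{path}: subject {subject_id!r} absent from sidecar")
        blocks: list[dict[str, np.ndarray]] = []
        for ci in sorted(sub_frame["cycle"].unique()):
            block = {}
            cyc_frame = sub_frame[sub_frame["cycle"] == ci]
            for joint, joint_frame in cyc_frame.groupby("joint"):
                joint_frame = joint_frame.sort_values("sample_index")
                idx = joint_frame["sample_index"].to_numpy()
                if idx.size != N_SAMPLES or not np.array_equal(idx, np.arange(N_SAMPLES)):
                    raise CohortFormatError(
                        f"{path}: subject {subject_id!r} cycle {ci} joint {joint!r} has "
                        f"{idx.size} samples (expected {N_SAMPLES} with indices 0..100)"
                    )
                block[str(joint)] = joint_frame["angle_deg"].to_numpy(dtype=float)
            blocks.append(block)
        subjects.append(_build_subject(str(subject_id), meta, blocks))
    return Cohort(subjects=subjects, provenance=meta_all.get("provenance", ""))
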