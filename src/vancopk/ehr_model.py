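"""Event-timeline data model for encounter-level EHR time series.

One encounter is an ordered sequence of timestamped clinical events
(vancomycin doses, other medication administrations, labs, vitals, measured
vancomycin serum levels, and end-of-day markers).  This module handles CSV
ingestion/serialization, the preprocessing pipeline (forward filling, mean
imputation, z-score standardization fitted on the training split only), and
patient-level train/test/validation splitting.
"""

from __future__ import annotations

import csv
import hashlib
import math
import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from . import pk_core

__all__ = [
    "EVENT_KINDS",
    "ClinicalEvent",
    "EventTimeline",
    "FeatureRegistry",
    "DEFAULT_REGISTRY",
    "FeatureFrame",
    "Standardizer",
    "SplitSpec",
    "read_events",
    "write_events",
    "training_view",
    "insert_end_of_day_events",
    "impute_and_standardize",
    "split_patients",
]

EVENT_KINDS = ("MED_ADMIN", "VANC_DOSE", "LAB", "VITAL", "VANC_LEVEL", "END_OF_DAY")


@dataclass(frozen=True)
class ClinicalEvent:
    t: float                      # hours from encounter start
    kind: str
    code: str = ""                # lab/vital name; empty otherwise
    med_codes: tuple = ()         # medication vocabulary indices
    dose_mg: float = 0.0          # VANC_DOSE only
    value: float = float("nan")   # LAB / VITAL / VANC_LEVEL

    def __post_init__(self):
        if self.t < 0:
            raise ValueError("event time must be >= 0")
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "VANC_DOSE" and not self.dose_mg > 0:
            raise ValueError("VANC_DOSE requires dose_mg > 0")
        if self.kind == "VANC_LEVEL" and not self.value >= 0:
            raise ValueError("VANC_LEVEL requires value >= 0")


@dataclass
class EventTimeline:
    patient_id: str
    encounter_id: str
    start_time: datetime          # wall-clock time of the first record
    events: list                  # time-ordered ClinicalEvent
    static: dict = field(default_factory=dict)  # age, sex, race, height_cm, weight_kg

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda e: e.t)

    @property
    def span(self) -> float:
        return self.events[-1].t if self.events else 0.0

    def doses(self) -> list:
        """(t, dose_mg) pairs for all vancomycin doses."""
        return [(e.t, e.dose_mg) for e in self.events if e.kind == "VANC_DOSE"]

    def levels(self) -> list:
        return [(e.t, e.value) for e in self.events if e.kind == "VANC_LEVEL"]

    def is_trainable(self) -> bool:
        """At least one dose and one level after the first dose."""
        d = self.doses()
        if not d:
            return False
        first = d[0][0]
        return any(t > first for t, _ in self.levels())

    def trimmed(self) -> "EventTimeline":
        """Restrict to the window ending at the last measured level."""
        lv = self.levels()
        if not lv:
            return self
        t_last = max(t for t, _ in lv)
        ev = [e for e in self.events if e.t <= t_last + 1e-9]
        return EventTimeline(self.patient_id, self.encounter_id,
                             self.start_time, ev, dict(self.static))


# ---------------------------------------------------------------------------
# Feature registry

_CORE = ["time_h", "time_diff_h", "vanc_dose_mg", "vanc_level_mg_L"]
_DEMO = ["age_years", "sex_male", "weight_kg", "height_cm"]
_VITALS = ["heart_rate", "systolic_bp", "diastolic_bp", "respiratory_rate",
           "temperature_c"]
_LABS = [
    "serum_creatinine", "blood_urea_nitrogen", "sodium", "potassium",
    "chloride", "bicarbonate", "glucose", "serum_calcium", "phosphorus",
    "serum_magnesium", "total_bilirubin", "total_protein", "albumin",
    "alt", "ast", "alkaline_phosphatase", "wbc", "hemoglobin", "hematocrit",
    "platelets", "nucleated_rbc", "neutrophils_pct", "lymphocytes_pct",
    "lactate", "inr", "anion_gap", "crp",
]


@dataclass(frozen=True)
class FeatureRegistry:
    """Ordered names of the continuous feature vector (default 40) and the
    medication vocabulary size (default 911 codes of 324 medications)."""

    continuous: tuple = tuple(_CORE + _DEMO + _VITALS + _LABS)
    vocab_size: int = 911
    n_medications: int = 324

    @property
    def dim(self) -> int:
        return len(self.continuous)

    def index(self, name: str) -> int:
        return self.continuous.index(name)

    def digest(self) -> str:
        h = hashlib.sha256(("|".join(self.continuous) + f"#{self.vocab_size}").encode())
        return h.hexdigest()[:16]


DEFAULT_REGISTRY = FeatureRegistry()
assert DEFAULT_REGISTRY.dim == 40


@dataclass
class FeatureFrame:
    """Per-encounter model-ready arrays (one row per merged event step)."""

    patient_id: str
    encounter_id: str
    times: np.ndarray           # (n,) hours
    x: np.ndarray               # (n, dim) standardized continuous features
    med_codes: list             # per step: tuple of vocab indices
    kinds: list                 # per step: set of event kinds merged in
    dose_mg: np.ndarray         # (n,) dose given at the step (0 if none)
    level: np.ndarray           # (n,) observed level at the step (nan if none)
    crcl: np.ndarray            # (n,) Cockcroft-Gault CrCL (mL/min), raw
    doses: list                 # (t, mg) for the whole encounter
    registry: FeatureRegistry = DEFAULT_REGISTRY

    @property
    def n_steps(self) -> int:
        return len(self.times)


# ---------------------------------------------------------------------------
# CSV ingestion

_EVENT_COLS = ["patient_id", "encounter_id", "timestamp", "event_type",
               "code", "value", "unit", "dose_mg"]
_STATIC_COLS = ["patient_id", "age", "sex", "race", "height_cm", "weight_kg"]


def read_events(events_csv, static_csv=None) -> list:
    """Assemble EventTimelines from the documented CSV schema.

    Rows are grouped by (patient_id, encounter_id); event times are hours
    from each encounter's earliest record.  Malformed rows are reported with
    their line numbers; unsorted timestamps are auto-sorted with a warning.
    """
    df = pd.read_csv(events_csv, dtype={"patient_id": str, "encounter_id": str,
                                        "code": str, "unit": str},
                     keep_default_na=False, na_values=[""])
    missing = [c for c in _EVENT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"events CSV missing mandatory columns: {missing}")
    if len(df) == 0:
        return []
    static = {}
    if static_csv is not None:
        sdf = pd.read_csv(static_csv, dtype={"patient_id": str})
        miss = [c for c in _STATIC_COLS if c not in sdf.columns]
        if miss:
            raise ValueError(f"static CSV missing mandatory columns: {miss}")
        for _, row in sdf.iterrows():
            static[row["patient_id"]] = {
                "age": float(row["age"]), "sex": str(row["sex"]),
                "race": str(row["race"]), "height_cm": float(row["height_cm"]),
                "weight_kg": float(row["weight_kg"]),
            }
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    timelines, bad_rows = [], []
    for (pid, eid), grp in df.groupby(["patient_id", "encounter_id"], sort=True):
        if not grp["timestamp"].is_monotonic_increasing:
            warnings.warn(f"encounter {eid}: timestamps not sorted; auto-sorting")
        grp = grp.sort_values("timestamp", kind="stable")
        t0 = grp["timestamp"].iloc[0]
        events = []
        for line, (_, row) in zip(grp.index, grp.iterrows()):
            try:
                t = (row["timestamp"] - t0).total_seconds() / 3600.0
                kind = row["event_type"]
                med_codes = ()
                code = "" if pd.isna(row["code"]) else str(row["code"])
                if kind in ("MED_ADMIN", "VANC_DOSE") and code:
                    med_codes = tuple(int(c) for c in code.split(";") if c != "")
                    code = ""
                events.append(ClinicalEvent(
                    t=t, kind=kind, code=code, med_codes=med_codes,
                    dose_mg=0.0 if pd.isna(row["dose_mg"]) else float(row["dose_mg"]),
                    value=float("nan") if pd.isna(row["value"]) else float(row["value"]),
                ))
            except (ValueError, KeyError) as exc:
                bad_rows.append((line + 2, str(exc)))  # +2: header + 0-base
        timelines.append(EventTimeline(pid, eid, t0.to_pydatetime(), events,
                                       static.get(pid, {})))
    if bad_rows:
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in bad_rows[:10])
        warnings.warn(f"{len(bad_rows)} malformed event rows skipped ({detail})")
    return timelines


def _fmt(x: float) -> str:
    if isinstance(x, float) and math.isnan(x):
        return ""
    return f"{x:.10g}"


def write_events(timelines: list, events_csv, static_csv=None) -> None:
    """Serialize timelines back to the canonical CSV schema.

    Canonical form: encounters sorted by (patient_id, encounter_id), events
    by time; floats in shortest round-trip-safe %.10g format; ISO-8601
    timestamps.  read_events(write_events(x)) is the identity on canonical
    input.
    """
    rows = []
    for tl in sorted(timelines, key=lambda t: (t.patient_id, t.encounter_id)):
        for e in tl.events:
            ts = tl.start_time + timedelta(hours=e.t)
            code = ";".join(str(c) for c in e.med_codes) if e.med_codes else e.code
            rows.append({
                "patient_id": tl.patient_id, "encounter_id": tl.encounter_id,
                "timestamp": ts.isoformat(timespec="microseconds"),
                "event_type": e.kind,
                "code": code, "value": _fmt(e.value),
                "unit": _unit_for(e), "dose_mg": _fmt(e.dose_mg) if e.dose_mg else "",
            })
    with open(events_csv, "w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=_EVENT_COLS)
        w.writeheader()
        w.writerows(rows)
    if static_csv is not None:
        seen, srows = set(), []
        for tl in sorted(timelines, key=lambda t: (t.patient_id, t.encounter_id)):
            if tl.patient_id in seen or not tl.static:
                continue
            seen.add(tl.patient_id)
            s = tl.static
            srows.append({"patient_id": tl.patient_id, "age": _fmt(s["age"]),
                          "sex": s["sex"], "race": s["race"],
                          "height_cm": _fmt(s["height_cm"]),
                          "weight_kg": _fmt(s["weight_kg"])})
        with open(static_csv, "w", newline="", encoding="utf-8") as fh:
            w = csv.DictWriter(fh, fieldnames=_STATIC_COLS)
            w.writeheader()
            w.writerows(srows)


def _unit_for(e: ClinicalEvent) -> str:
    if e.kind == "VANC_LEVEL":
        return "mg/L"
    if e.kind == "VANC_DOSE":
        return "mg"
    return ""


def training_view(timelines: list) -> list:
    """Encounters meeting the inclusion rule (>=1 level after the first
    dose), trimmed to end at the last measured level."""
    return [tl.trimmed() for tl in timelines if tl.is_trainable()]


def insert_end_of_day_events(tl: EventTimeline) -> EventTimeline:
    """Add an END_OF_DAY event at every calendar-day boundary in the span."""
    if not tl.events:
        return tl
    existing = {round(e.t, 9) for e in tl.events if e.kind == "END_OF_DAY"}
    t_end = tl.events[-1].t
    day0 = tl.start_time.replace(hour=0, minute=0, second=0, microsecond=0)
    new = []
    boundary = day0 + timedelta(days=1)
    while (boundary - tl.start_time).total_seconds() / 3600.0 < t_end:
        th = (boundary - tl.start_time).total_seconds() / 3600.0
        if th > 0 and round(th, 9) not in existing:
            new.append(ClinicalEvent(t=th, kind="END_OF_DAY"))
        boundary += timedelta(days=1)
    return EventTimeline(tl.patient_id, tl.encounter_id, tl.start_time,
                         tl.events + new, dict(tl.static))


# ---------------------------------------------------------------------------
# Splitting


@dataclass(frozen=True)
class SplitSpec:
    train: float = 0.50
    test: float = 0.30
    validation: float = 0.20
    seed: int = 0

    def __post_init__(self):
        if abs(self.train + self.test + self.validation - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def split_patients(timelines: list, spec: SplitSpec = SplitSpec()):
    """Partition encounters by patient ID into train/test/validation.

    Deterministic for a given seed; no patient appears in two splits.
    """
    pids = sorted({tl.patient_id for tl in timelines})
    if len(pids) < 3:
        raise ValueError("need at least 3 patients to split")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(len(pids))
    n_train = int(round(spec.train * len(pids)))
    n_test = int(round(spec.test * len(pids)))
    train_ids = {pids[i] for i in perm[:n_train]}
    test_ids = {pids[i] for i in perm[n_train:n_train + n_test]}
    val_ids = set(pids) - train_ids - test_ids
    pick = lambda ids: [tl for tl in timelines if tl.patient_id in ids]
    return pick(train_ids), pick(test_ids), pick(val_ids)


# ---------------------------------------------------------------------------
# Preprocessing


@dataclass
class Standardizer:
    """Columnwise z-score parameters fitted on the training split."""

    mean: np.ndarray
    sd: np.ndarray
    registry: FeatureRegistry = DEFAULT_REGISTRY

    def transform(self, x: np.ndarray) -> np.ndarray:
        sd = np.where(self.sd > 0, self.sd, 1.0)
        z = (x - self.mean) / sd
        z[:, self.sd == 0] = 0.0
        return z


def _merge_steps(tl: EventTimeline):
    """Group simultaneous events into single RNN steps."""
    steps = []
    for e in tl.events:
        if steps and abs(e.t - steps[-1][0]) < 1e-9:
            steps[-1][1].append(e)
        else:
            steps.append((e.t, [e]))
    return steps


def _raw_frame(tl: EventTimeline, registry: FeatureRegistry):
    """Unstandardized feature matrix with NaN for unobserved entries, plus
    per-step metadata.  The vancomycin-level feature at a step is the most
    recent level observed STRICTLY BEFORE that step (0 before the first), so
    a measurement never feeds the step that predicts it."""
    steps = _merge_steps(tl)
    n, dim = len(steps), registry.dim
    x = np.full((n, dim), np.nan)
    med_codes, kinds = [], []
    dose = np.zeros(n)
    level = np.full(n, np.nan)
    i_t = registry.index("time_h")
    i_dt = registry.index("time_diff_h")
    i_dose = registry.index("vanc_dose_mg")
    i_lvl = registry.index("vanc_level_mg_L")
    demo = {
        "age_years": tl.static.get("age", np.nan),
        "sex_male": 1.0 if tl.static.get("sex") == "male" else 0.0,
        "weight_kg": tl.static.get("weight_kg", np.nan),
        "height_cm": tl.static.get("height_cm", np.nan),
    }
    last_level = 0.0
    prev_t = 0.0
    for i, (t, evs) in enumerate(steps):
        x[i, i_t] = t
        x[i, i_dt] = t - prev_t
        prev_t = t
        x[i, i_lvl] = last_level
        codes = []
        kset = set()
        d = 0.0
        for e in evs:
            kset.add(e.kind)
            codes.extend(e.med_codes)
            if e.kind == "VANC_DOSE":
                d += e.dose_mg
            elif e.kind == "VANC_LEVEL":
                level[i] = e.value
            elif e.kind in ("LAB", "VITAL") and e.code in registry.continuous:
                x[i, registry.index(e.code)] = e.value
        dose[i] = d
        x[i, i_dose] = d
        for name, val in demo.items():
            x[i, registry.index(name)] = val
        med_codes.append(tuple(codes))
        kinds.append(kset)
        if not math.isnan(level[i]):
            last_level = level[i]
    return steps, x, med_codes, kinds, dose, level


def _forward_fill(x: np.ndarray) -> np.ndarray:
    df = pd.DataFrame(x)
    return df.ffill().to_numpy()


def _crcl_series(tl: EventTimeline, x_filled: np.ndarray,
                 registry: FeatureRegistry, default_cr: float) -> np.ndarray:
    i_cr = registry.index("serum_creatinine")
    cr = x_filled[:, i_cr].copy()
    cr[np.isnan(cr)] = default_cr
    cr = np.maximum(cr, 0.1)
    age = tl.static.get("age", 60.0)
    weight = tl.static.get("weight_kg", 80.0)
    sex = tl.static.get("sex", "male")
    cov = [pk_core.RenalCovariates(age=min(age, 139.0), weight=weight,
                                   serum_cr=c, sex=sex) for c in cr]
    return np.array([pk_core.cockcroft_gault(c) for c in cov])


def impute_and_standardize(timelines: list, fit_on: list,
                           registry: FeatureRegistry = DEFAULT_REGISTRY):
    """Build model-ready FeatureFrames.

    Within each encounter, last observation carried forward; remaining gaps
    take the training-split mean; continuous features are then z-scored with
    training-split statistics (zero-variance features map to 0).  Returns
    (frames: dict encounter_id -> FeatureFrame, standardizer).
    """
    if not fit_on:
        raise ValueError("training split must be non-empty")
    raw = {}
    for tl in timelines:
        steps, x, med, kinds, dose, level = _raw_frame(tl, registry)
        raw[tl.encounter_id] = (tl, steps, _forward_fill(x), med, kinds, dose, level)
    train_rows = np.vstack([raw[tl.encounter_id][2] for tl in fit_on])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(train_rows, axis=0)
    all_nan = np.isnan(col_mean)
    if all_nan.any():
        names = [registry.continuous[i] for i in np.where(all_nan)[0]]
        warnings.warn(f"features never observed in training split, set to 0: {names}")
        col_mean[all_nan] = 0.0
    filled_train = np.where(np.isnan(train_rows), col_mean, train_rows)
    mean = filled_train.mean(axis=0)
    sd = filled_train.std(axis=0)
    std = Standardizer(mean=mean, sd=sd, registry=registry)
    i_cr = registry.index("serum_creatinine")
    default_cr = col_mean[i_cr] if col_mean[i_cr] > 0 else 0.9
    frames = {}
    for eid, (tl, steps, xf, med, kinds, dose, level) in raw.items():
        xi = np.where(np.isnan(xf), col_mean, xf)
        crcl = _crcl_series(tl, xf, registry, default_cr)
        frames[eid] = FeatureFrame(
            patient_id=tl.patient_id, encounter_id=eid,
            times=np.array([t for t, _ in steps]), x=std.transform(xi),
            med_codes=med, kinds=kinds, dose_mg=dose, level=level,
            crcl=crcl, doses=tl.doses(), registry=registry)
    return frames, std
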