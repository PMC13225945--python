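"""Synthetic EHR cohort generator.

Emulates the structure of a hospital vancomycin-TDM cohort so the full
pipeline (ingestion, preprocessing, model training, simulation) is testable
without any protected data: demographics matched to published cohort
summaries (age median 61, IQR 48-73; weight median 82.9 kg, IQR 65.5-101.6;
height median 172 cm; 55% male), an AR(1) log-creatinine process, renal
function dependent dosing at 750-2000 mg every 8/12/24 h infused at 1 g/h,
sparse trough-dominant vancomycin levels, lab/vital noise around typical
values with realistic missingness, and Zipf-weighted medication codes.

True concentration trajectories come from the deterministic two-compartment
core under per-encounter random effects drawn from the published prior;
observed levels add Gaussian noise.  Ground truth (eta, noiseless curves)
is kept in a sidecar separate from the observable event stream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np

from . import pk_core
from .ehr_model import (DEFAULT_REGISTRY, ClinicalEvent, EventTimeline,
                        FeatureRegistry, insert_end_of_day_events)

__all__ = ["CohortSpec", "GroundTruth", "generate_cohort", "generate_recovery_suite"]

# Typical values and relative noise scales for the lab/vital registry.
_TYPICAL = {
    "heart_rate": (85.0, 12.0), "systolic_bp": (120.0, 15.0),
    "diastolic_bp": (72.0, 10.0), "respiratory_rate": (18.0, 3.0),
    "temperature_c": (37.0, 0.5), "serum_creatinine": (0.9, 0.0),
    "blood_urea_nitrogen": (18.0, 7.0), "sodium": (138.0, 3.0),
    "potassium": (4.1, 0.4), "chloride": (102.0, 4.0),
    "bicarbonate": (24.0, 3.0), "glucose": (120.0, 30.0),
    "serum_calcium": (9.0, 0.6), "phosphorus": (3.4, 0.8),
    "serum_magnesium": (2.0, 0.3), "total_bilirubin": (0.8, 0.5),
    "total_protein": (6.6, 0.8), "albumin": (3.4, 0.6),
    "alt": (35.0, 20.0), "ast": (32.0, 18.0),
    "alkaline_phosphatase": (95.0, 35.0), "wbc": (11.0, 4.0),
    "hemoglobin": (11.5, 2.0), "hematocrit": (34.0, 5.0),
    "platelets": (240.0, 80.0), "nucleated_rbc": (0.1, 0.2),
    "neutrophils_pct": (72.0, 10.0), "lymphocytes_pct": (18.0, 8.0),
    "lactate": (1.6, 0.8), "inr": (1.2, 0.3), "anion_gap": (10.0, 3.0),
    "crp": (8.0, 6.0),
}


@dataclass(frozen=True)
class CohortSpec:
    n_patients: int = 100
    max_encounters_per_patient: int = 2   # geometric-ish: most have 1
    # demographic targets (medians / IQRs of the emulated cohort)
    age_median: float = 61.0
    age_iqr: tuple = (48.0, 73.0)
    weight_median: float = 82.9
    weight_iqr: tuple = (65.5, 101.6)
    height_median: float = 172.0
    height_iqr: tuple = (165.1, 181.1)
    male_fraction: float = 0.55
    # creatinine AR(1) log-process
    cr_log_sd: float = 0.35
    cr_ar1_rho: float = 0.9
    cr_ar1_innovation_sd: float = 0.08
    # dosing
    doses_min: int = 6
    doses_max: int = 20
    dose_choices: tuple = (750.0, 1000.0, 1250.0, 1500.0, 1750.0, 2000.0)
    infusion_policy: str = "uniform"
    # measured levels (trough-dominant, sparse)
    levels_min: int = 1
    levels_max: int = 4
    peak_level_fraction: float = 0.15
    noise_sd: float = 1.0            # mg/L additive measurement noise
    # misc structure
    vocab_size: int = 911
    n_medications: int = 324
    med_poisson_lambda: float = 2.0
    lab_missing_prob: float = 0.3
    eta_prior: pk_core.EtaPrior = pk_core.DEFAULT_PRIOR
    registry: FeatureRegistry = DEFAULT_REGISTRY
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0 <= self.male_fraction <= 1:
            raise ValueError("male_fraction must be in [0, 1]")
        if self.doses_min < 1 or self.doses_max < self.doses_min:
            raise ValueError("invalid dose-count range")


@dataclass
class GroundTruth:
    """Per-encounter generating truth, stored apart from the observables."""

    eta: dict            # encounter_id -> 4-list
    noise_sd: float
    curves: dict         # encounter_id -> ConcentrationCurve JSON string
    crcl_series: dict    # encounter_id -> [(t, crcl), ...]

    def to_json(self) -> str:
        return json.dumps({"noise_sd": self.noise_sd, "eta": self.eta,
                           "curves": self.curves, "crcl_series": self.crcl_series})

    @staticmethod
    def from_json(s: str) -> "GroundTruth":
        d = json.loads(s)
        return GroundTruth(d["eta"], d["noise_sd"], d["curves"], d["crcl_series"])

    def curve(self, encounter_id: str) -> pk_core.ConcentrationCurve:
        return pk_core.ConcentrationCurve.from_json(self.curves[encounter_id])


def _iqr_normal(rng, median, iqr, n, lo=None, hi=None):
    """Normal draws with the requested median and IQR, clipped to [lo, hi]."""
    sd = (iqr[1] - iqr[0]) / 1.349
    x = rng.normal(median, sd, size=n)
    return np.clip(x, lo, hi)


def _iqr_lognormal(rng, median, iqr, n, lo=None, hi=None):
    mu = math.log(median)
    sigma = (math.log(iqr[1]) - math.log(iqr[0])) / 1.349
    x = np.exp(rng.normal(mu, sigma, size=n))
    return np.clip(x, lo, hi)


def _dose_interval(crcl: float, rng) -> float:
    """Dosing interval (h) by renal function band."""
    if crcl >= 60:
        return float(rng.choice([8.0, 12.0]))
    if crcl >= 30:
        return float(rng.choice([12.0, 24.0]))
    return 24.0


def _zipf_codes(rng, lam: float, vocab: int) -> tuple:
    n = rng.poisson(lam)
    if n == 0:
        return ()
    ranks = np.arange(1, vocab + 1, dtype=float)
    p = 1.0 / ranks
    p /= p.sum()
    return tuple(int(c) for c in rng.choice(vocab, size=n, replace=False, p=p))


def _pick_dose(weight: float, choices: tuple, rng) -> float:
    """~15 mg/kg rounded to the nearest available dose strength."""
    target = 15.0 * weight
    arr = np.asarray(choices)
    return float(arr[np.argmin(np.abs(arr - target))])


def generate_cohort(spec: CohortSpec):
    """Generate (timelines, ground_truth); deterministic per spec.seed.

    Every encounter has >= 1 dose and >= 1 level after the first dose, so
    the whole cohort passes the training inclusion rules.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    ages = _iqr_normal(rng, spec.age_median, spec.age_iqr, n, 18.0, 100.0)
    weights = _iqr_lognormal(rng, spec.weight_median, spec.weight_iqr, n, 35.0, 250.0)
    heights = _iqr_normal(rng, spec.height_median, spec.height_iqr, n, 140.0, 210.0)
    sexes = np.where(rng.random(n) < spec.male_fraction, "male", "female")
    races = rng.choice(["white", "african_american", "hispanic", "asian", "other"],
                       size=n, p=[0.36, 0.20, 0.14, 0.02, 0.28])
    base_date = datetime(2024, 1, 1)
    timelines = []
    gt_eta, gt_curves, gt_crcl = {}, {}, {}
    for i in range(n):
        pid = f"P{i:05d}"
        static = {"age": float(round(ages[i], 1)), "sex": str(sexes[i]),
                  "race": str(races[i]), "height_cm": float(round(heights[i], 1)),
                  "weight_kg": float(round(weights[i], 1))}
        n_enc = 1 + rng.integers(0, spec.max_encounters_per_patient)
        for j in range(n_enc):
            eid = f"{pid}E{j}"
            start = base_date + timedelta(days=int(rng.integers(0, 365)),
                                          hours=float(rng.uniform(0, 24)))
            tl, eta, curve_json, crcl_series = _generate_encounter(
                pid, eid, start, static, spec, rng)
            timelines.append(tl)
            gt_eta[eid] = eta
            gt_curves[eid] = curve_json
            gt_crcl[eid] = crcl_series
    gt = GroundTruth(gt_eta, spec.noise_sd, gt_curves, gt_crcl)
    return timelines, gt


def _generate_encounter(pid, eid, start, static, spec: CohortSpec, rng):
    var = np.asarray(spec.eta_prior.variances)
    eta_arr = rng.normal(0.0, np.sqrt(var))
    eta = pk_core.EtaVector.from_array(eta_arr)
    # creatinine AR(1) log-process, one value per day
    cr_mu = math.log(0.9) + rng.normal(0.0, spec.cr_log_sd)
    n_doses = int(rng.integers(spec.doses_min, spec.doses_max + 1))
    cov0 = pk_core.RenalCovariates(age=min(static["age"], 139.0),
                                   weight=static["weight_kg"],
                                   serum_cr=max(math.exp(cr_mu), 0.2),
                                   sex=static["sex"])
    interval = _dose_interval(pk_core.cockcroft_gault(cov0), rng)
    dose_mg = _pick_dose(static["weight_kg"], spec.dose_choices, rng)
    dose_times = [2.0 + k * interval for k in range(n_doses)]
    span_guess = dose_times[-1] + interval

    # daily creatinine (and CrCL) trajectory
    n_days = int(span_guess // 24) + 2
    log_cr = [cr_mu + rng.normal(0.0, spec.cr_ar1_innovation_sd)]
    for _ in range(n_days - 1):
        log_cr.append(cr_mu + spec.cr_ar1_rho * (log_cr[-1] - cr_mu)
                      + rng.normal(0.0, spec.cr_ar1_innovation_sd))
    cr_vals = np.maximum(np.exp(log_cr), 0.2)
    crcl_series = []
    for d, cr in enumerate(cr_vals):
        cov = pk_core.RenalCovariates(age=min(static["age"], 139.0),
                                      weight=static["weight_kg"],
                                      serum_cr=float(cr), sex=static["sex"])
        crcl_series.append((d * 24.0 + (0.5 if d else 0.0),
                            pk_core.cockcroft_gault(cov)))
    crcl_series[0] = (0.0, crcl_series[0][1])

    # measured levels: trough-dominant, all after the first dose
    n_levels = int(rng.integers(spec.levels_min, spec.levels_max + 1))
    dur = pk_core.infusion_duration(dose_mg, spec.infusion_policy)
    candidate_doses = list(range(1, n_doses))
    level_times = []
    if candidate_doses:
        picks = rng.choice(candidate_doses,
                           size=min(n_levels, len(candidate_doses)), replace=False)
        for kd in np.sort(picks):
            if rng.random() < spec.peak_level_fraction:
                level_times.append(dose_times[kd - 1] + dur
                                   + (2.0 if dose_mg <= 1000 else 3.0) - dur)
            else:
                level_times.append(dose_times[kd] - 1.0)
    if not level_times:
        level_times = [dose_times[0] + interval - 1.0]
    t_end = max(level_times)
    span = max(t_end, dose_times[-1] + dur) + 0.5

    doses = [(t, dose_mg) for t in dose_times]
    curve = pk_core.build_curve_2c(eta, doses, span, crcl_series,
                                   spec.infusion_policy)
    events = [ClinicalEvent(t=0.0, kind="VITAL", code="heart_rate",
                            value=float(rng.normal(*_TYPICAL["heart_rate"])))]
    for t in dose_times:
        codes = _zipf_codes(rng, spec.med_poisson_lambda, spec.vocab_size)
        events.append(ClinicalEvent(t=t, kind="VANC_DOSE", med_codes=codes,
                                    dose_mg=dose_mg))
    for t in level_times:
        val = curve.evaluate(t) + rng.normal(0.0, spec.noise_sd)
        events.append(ClinicalEvent(t=t, kind="VANC_LEVEL", value=max(val, 0.0)))
    # daily labs with missingness; creatinine drawn from the AR(1) path
    for d in range(n_days):
        t_lab = d * 24.0 + (0.5 if d else 0.25)
        if t_lab > t_end:
            break
        events.append(ClinicalEvent(t=t_lab, kind="LAB", code="serum_creatinine",
                                    value=float(cr_vals[d])))
        for name, (mu, sd) in _TYPICAL.items():
            if name == "serum_creatinine" or name in ("heart_rate",):
                continue
            if rng.random() < spec.lab_missing_prob:
                continue
            kind = "VITAL" if name in ("heart_rate", "systolic_bp", "diastolic_bp",
                                       "respiratory_rate", "temperature_c") else "LAB"
            events.append(ClinicalEvent(t=t_lab, kind=kind, code=name,
                                        value=float(max(rng.normal(mu, sd), 0.01))))
    # occasional non-vancomycin medication administrations
    for _ in range(int(rng.integers(0, 4))):
        codes = _zipf_codes(rng, spec.med_poisson_lambda, spec.vocab_size)
        if codes:
            events.append(ClinicalEvent(t=float(rng.uniform(0.0, t_end)),
                                        kind="MED_ADMIN", med_codes=codes))
    events = [e for e in events if e.t <= t_end + 1e-9]
    tl = EventTimeline(pid, eid, start, events, static)
    tl = insert_end_of_day_events(tl)
    return tl, [float(v) for v in eta_arr], curve.to_json(), \
        [(float(t), float(c)) for t, c in crcl_series]


def generate_recovery_suite(n: int, sampling: str = "peak_trough",
                            noise_sd: float = 0.0, seed: int = 0,
                            spec: CohortSpec = None):
    """Cohort with known static eta and dense level sampling.

    `sampling`: 'peak_trough' places a peak (2/3 h post-infusion-start by
    dose) and a trough (1 h pre-next-dose) for EVERY dose; 'trough' places
    troughs only.  Intended for MAP and recurrent-model recovery
    experiments; with noise_sd 0 the observed levels equal the true curve.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = spec if spec is not None else CohortSpec()
    dense = replace(base, n_patients=n, seed=seed, noise_sd=noise_sd,
                    max_encounters_per_patient=1)
    timelines, gt = generate_cohort(dense)
    out = []
    rng = np.random.default_rng(seed + 7)
    for tl in timelines:
        eid = tl.encounter_id
        doses = tl.doses()
        keep = [e for e in tl.events if e.kind != "VANC_LEVEL"]
        # source encounters truncated at an early sparse level can carry too
        # few doses to identify eta; extend short courses to >= 6 doses
        if len(doses) < 6:
            interval = (doses[1][0] - doses[0][0]) if len(doses) > 1 else 12.0
            mg = doses[-1][1]
            while len(doses) < 6:
                t_new = doses[-1][0] + interval
                doses.append((t_new, mg))
                keep.append(ClinicalEvent(t=t_new, kind="VANC_DOSE", dose_mg=mg))
        level_times = []
        for i, (t0, mg) in enumerate(doses):
            if sampling == "peak_trough":
                level_times.append(t0 + (2.0 if mg <= 1000 else 3.0))
            if i + 1 < len(doses):
                level_times.append(doses[i + 1][0] - 1.0)
        level_times = sorted({round(t, 6) for t in level_times if t > doses[0][0]})
        # the stored curve ends at the source encounter's last sparse level;
        # rebuild the truth over the full dosing span of the dense design
        span = max(level_times) + 0.5
        eta = pk_core.EtaVector.from_array(gt.eta[eid])
        curve = pk_core.build_curve_2c(eta, doses, span, gt.crcl_series[eid],
                                       dense.infusion_policy)
        gt.curves[eid] = curve.to_json()
        for t in level_times:
            val = curve.evaluate(t)
            if noise_sd > 0:
                val += rng.normal(0.0, noise_sd)
            keep.append(ClinicalEvent(t=t, kind="VANC_LEVEL", value=max(val, 0.0)))
        out.append(insert_end_of_day_events(
            EventTimeline(tl.patient_id, eid, tl.start_time, keep, dict(tl.static))))
    return out, gt
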