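"""Deterministic pharmacokinetic core for vancomycin compartment models.

Typical-value parameter maps, the closed-form one- and two-compartment
infusion solvers, exact AUC computation, Cockcroft-Gault renal function,
and a MAP-Bayesian individualization baseline.

Parameterization
----------------
Individual PK parameters are exponential perturbations of population
typical values by a vector of random effects eta = (eta1..eta4) with a
diagonal multivariate-normal prior:

    V1 = 33.1 * exp(eta1)   [L]     central volume
    CL = 0.0396 * CrCL * exp(eta2)  [L/h]  central clearance
    Q  = 6.99 * exp(eta3)   [L/h]   intercompartmental clearance
    V2 = 48.3 * exp(eta4)   [L]     peripheral volume

CrCL is the Cockcroft-Gault creatinine clearance in mL/min.  The published
prior gives variances for only three of the four effects
(0.120, 0.149, 0.416); the fourth (peripheral volume) defaults to the
volume-scale value 0.120 and is configurable.
"""

from __future__ import annotations

import bisect
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from ._linode import step_1c, step_2c

__all__ = [
    "TV_V1",
    "TV_V2",
    "TV_Q",
    "CL_CRCL_COEF",
    "DEFAULT_PRIOR",
    "EtaVector",
    "EtaPrior",
    "PKParams2C",
    "PKParams1C",
    "RenalCovariates",
    "CompartmentState",
    "OneCompState",
    "InfusionSegment",
    "CurvePiece",
    "ConcentrationCurve",
    "AucMicConfig",
    "MapResult",
    "cockcroft_gault",
    "eta_to_pk2c",
    "solve_segment_2c",
    "solve_segment_1c",
    "solve_schedule_2c",
    "solve_schedule_1c",
    "evaluate_curve",
    "segment_auc",
    "time_avg_dose_norm_auc_mic",
    "infusion_rate_segments",
    "build_curve_2c",
    "map_bayes_update",
]

# Population typical values (vancomycin two-compartment model).
TV_V1 = 33.1      # L
TV_V2 = 48.3      # L
TV_Q = 6.99       # L/h
CL_CRCL_COEF = 0.0396  # (L/h) per (mL/min) of CrCL


@dataclass(frozen=True)
class EtaVector:
    """Dimensionless individual random effects."""

    eta1: float = 0.0
    eta2: float = 0.0
    eta3: float = 0.0
    eta4: float = 0.0

    def __post_init__(self):
        if not all(math.isfinite(v) for v in self.as_array()):
            raise ValueError("eta components must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.eta1, self.eta2, self.eta3, self.eta4])

    @staticmethod
    def from_array(a) -> "EtaVector":
        a = np.asarray(a, dtype=float)
        return EtaVector(*a.tolist())


@dataclass(frozen=True)
class EtaPrior:
    """Diagonal MVN prior on eta; mean is zero."""

    variances: tuple = (0.120, 0.149, 0.416, 0.120)

    def __post_init__(self):
        if len(self.variances) != 4 or any(v <= 0 for v in self.variances):
            raise ValueError("prior needs 4 positive variances")

    def quad(self, eta: np.ndarray) -> float:
        """eta' Sigma^-1 eta."""
        return float(np.sum(np.asarray(eta) ** 2 / np.asarray(self.variances)))


DEFAULT_PRIOR = EtaPrior()


@dataclass(frozen=True)
class PKParams2C:
    v1: float  # L
    v2: float  # L
    q: float   # L/h
    cl: float  # L/h

    def __post_init__(self):
        if self.v1 <= 0 or self.v2 <= 0 or self.cl <= 0:
            raise ValueError("V1, V2, CL must be strictly positive")
        if self.q < 0:
            raise ValueError("Q must be non-negative")


@dataclass(frozen=True)
class PKParams1C:
    k: float  # 1/h
    v: float  # L

    def __post_init__(self):
        if self.k <= 0 or self.v <= 0:
            raise ValueError("k and V must be strictly positive")


@dataclass(frozen=True)
class RenalCovariates:
    age: float        # years
    weight: float     # kg
    serum_cr: float   # mg/dL
    sex: str          # 'male' | 'female'

    def __post_init__(self):
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.weight <= 0 or self.serum_cr <= 0:
            raise ValueError("weight and serum creatinine must be positive")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")


@dataclass(frozen=True)
class CompartmentState:
    c_a: float  # mg/L central
    c_b: float  # mg/L peripheral
    t: float    # h


@dataclass(frozen=True)
class OneCompState:
    mass: float  # mg
    t: float     # h


@dataclass(frozen=True)
class InfusionSegment:
    t_start: float
    t_end: float
    rate: float  # mg/h, constant over the segment (0 between doses)
    params: object  # PKParams2C or PKParams1C

    def __post_init__(self):
        if self.t_end < self.t_start:
            raise ValueError("t_end must be >= t_start")
        if self.rate < 0:
            raise ValueError("infusion rate must be non-negative")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class AucMicConfig:
    mic: float = 1.0                 # mg/L
    normalization_dose: float = None  # mg; filled from max(doses) when None

    def __post_init__(self):
        if self.mic <= 0:
            raise ValueError("MIC must be positive")
        if self.normalization_dose is not None and self.normalization_dose <= 0:
            raise ValueError("normalization dose must be positive")


def cockcroft_gault(cov: RenalCovariates) -> float:
    """Cockcroft-Gault creatinine clearance in mL/min.

    CrCL = (140 - age) * weight / (72 * serum_cr), times 0.85 for women.
    """
    if cov.age >= 140:
        raise ValueError("age >= 140 years is outside the Cockcroft-Gault domain")
    crcl = (140.0 - cov.age) * cov.weight / (72.0 * cov.serum_cr)
    if cov.sex == "female":
        crcl *= 0.85
    return crcl


def eta_to_pk2c(eta: EtaVector, crcl: float) -> PKParams2C:
    """Map random effects and renal function to individual 2C parameters."""
    if crcl <= 0:
        raise ValueError("CrCL must be positive")
    return PKParams2C(
        v1=TV_V1 * math.exp(eta.eta1),
        v2=TV_V2 * math.exp(eta.eta4),
        q=TV_Q * math.exp(eta.eta3),
        cl=CL_CRCL_COEF * crcl * math.exp(eta.eta2),
    )


# ---------------------------------------------------------------------------
# Closed-form segment solvers


def _phi1(lam: float, dt: float) -> float:
    x = lam * dt
    if abs(x) < 1e-8:
        return dt * (1.0 + x / 2.0 + x * x / 6.0)
    return math.expm1(x) / lam


def _phi2(lam: float, dt: float) -> float:
    x = lam * dt
    if abs(x) < 1e-6:
        return dt * dt * (0.5 + x / 6.0 + x * x / 24.0)
    return (math.expm1(x) - x) / (lam * lam)


def _advance_2c(ca, cb, p: PKParams2C, rate, dt, want_auc=False):
    """State (and optional central AUC) after `dt` hours; handles edges."""
    if dt == 0.0:
        return (ca, cb, 0.0) if want_auc else (ca, cb)
    a11 = -(p.cl + p.q) / p.v1
    a12 = p.q / p.v1
    a21 = p.q / p.v2
    a22 = -p.q / p.v2
    tr = a11 + a22
    disc2 = (a11 - a22) ** 2 + 4.0 * a12 * a21
    disc = math.sqrt(max(disc2, 0.0))
    lam1 = 0.5 * (tr + disc)
    lam2 = 0.5 * (tr - disc)

    if disc > 1e-9 * abs(lam2):
        # distinct eigenvalues (generic case) — Lagrange form
        if p.q > 0.0 and lam1 < 0.0 and abs(lam1) * dt > 1e-300:
            # strictly positive parameters: shared fast path
            return step_2c(ca, cb, p.v1, p.v2, p.q, p.cl, rate, dt, want_auc=want_auc)
        inv = 1.0 / disc
        f1, f2 = math.exp(lam1 * dt), math.exp(lam2 * dt)
        p1_1, p1_2 = _phi1(lam1, dt), _phi1(lam2, dt)
        e11 = (f1 * (a11 - lam2) - f2 * (a11 - lam1)) * inv
        e12 = (f1 - f2) * a12 * inv
        e21 = (f1 - f2) * a21 * inv
        e22 = (f1 * (a22 - lam2) - f2 * (a22 - lam1)) * inv
        g11 = (p1_1 * (a11 - lam2) - p1_2 * (a11 - lam1)) * inv
        g21 = (p1_1 - p1_2) * a21 * inv
        u = rate / p.v1
        ca_end = e11 * ca + e12 * cb + g11 * u
        cb_end = e21 * ca + e22 * cb + g21 * u
        if not want_auc:
            return ca_end, cb_end
        g12 = (p1_1 - p1_2) * a12 * inv
        h11 = (_phi2(lam1, dt) * (a11 - lam2) - _phi2(lam2, dt) * (a11 - lam1)) * inv
        return ca_end, cb_end, g11 * ca + g12 * cb + h11 * u

    # (near-)repeated eigenvalues: e^{A dt} = e^{lam dt} (I + N dt), N = A - lam I
    lam = 0.5 * tr
    n11, n12, n21, n22 = a11 - lam, a12, a21, a22 - lam
    f = math.exp(lam * dt)
    e11, e12 = f * (1.0 + n11 * dt), f * n12 * dt
    e21, e22 = f * n21 * dt, f * (1.0 + n22 * dt)
    ph1 = _phi1(lam, dt)
    x = lam * dt
    if abs(x) < 1e-6:
        psi = dt * dt * (0.5 + x / 3.0 + x * x / 8.0)
    else:
        psi = (dt * f - ph1) / lam
    g11 = ph1 + n11 * psi
    g21 = n21 * psi
    u = rate / p.v1
    ca_end = e11 * ca + e12 * cb + g11 * u
    cb_end = e21 * ca + e22 * cb + g21 * u
    if not want_auc:
        return ca_end, cb_end
    ph2 = _phi2(lam, dt)
    if abs(x) < 1e-6:
        rho = dt ** 3 * (1.0 / 6.0 + x / 8.0)
    else:
        j2 = (dt * dt * f - 2.0 * psi) / lam
        rho = dt * psi - j2
    g12 = n12 * psi
    h11 = ph2 + n11 * rho
    return ca_end, cb_end, g11 * ca + g12 * cb + h11 * u


@dataclass(frozen=True)
class CurvePiece:
    """One constant-rate, constant-parameter span of a concentration curve."""

    t0: float
    t1: float
    rate: float
    params: object        # PKParams2C or PKParams1C
    state0: tuple         # (c_a, c_b) for 2C, (mass,) for 1C
    model: str            # '2c' | '1c'

    @property
    def duration(self) -> float:
        return self.t1 - self.t0

    def evaluate(self, t: float) -> float:
        """Central concentration at absolute time t within [t0, t1]."""
        if t < self.t0 - 1e-9 or t > self.t1 + 1e-9:
            raise ValueError(f"t={t} outside piece span [{self.t0}, {self.t1}]")
        dt = min(max(t - self.t0, 0.0), self.duration)
        if self.model == "2c":
            ca, _ = _advance_2c(self.state0[0], self.state0[1], self.params, self.rate, dt)
            return ca
        mass = step_1c(self.state0[0], self.params.k, self.rate, dt)
        return mass / self.params.v

    def end_state(self) -> tuple:
        if self.model == "2c":
            return _advance_2c(self.state0[0], self.state0[1], self.params, self.rate, self.duration)
        return (step_1c(self.state0[0], self.params.k, self.rate, self.duration),)

    def auc(self) -> float:
        """Exact integral of central concentration over the piece (mg*h/L)."""
        if self.duration == 0.0:
            return 0.0
        if self.model == "2c":
            return _advance_2c(*self.state0, self.params, self.rate, self.duration, want_auc=True)[2]
        _, auc_mass = step_1c(self.state0[0], self.params.k, self.rate, self.duration, want_auc_mass=True)
        return auc_mass / self.params.v


class ConcentrationCurve:
    """Piecewise-analytic concentration trajectory.

    Central concentration is continuous across 2C piece boundaries by
    construction (the end state of one piece is the initial state of the
    next).  For the 1C model the carried state is mass, so concentration may
    jump at boundaries where V changes.
    """

    def __init__(self, pieces: list):
        self.pieces = list(pieces)
        self._starts = [p.t0 for p in self.pieces]

    @property
    def t_start(self) -> float:
        return self.pieces[0].t0

    @property
    def t_end(self) -> float:
        return self.pieces[-1].t1

    def evaluate(self, t: float) -> float:
        if t < self.t_start - 1e-9 or t > self.t_end + 1e-9:
            raise ValueError(f"t={t} outside curve span [{self.t_start}, {self.t_end}]")
        i = bisect.bisect_right(self._starts, t) - 1
        i = max(i, 0)
        return self.pieces[i].evaluate(t)

    def auc(self) -> float:
        return sum(p.auc() for p in self.pieces)

    def end_state(self) -> tuple:
        return self.pieces[-1].end_state()

    def to_json(self) -> str:
        """Serialize to a documented JSON structure (hours, mg, mg/L)."""
        out = []
        for p in self.pieces:
            d = {"t0": p.t0, "t1": p.t1, "rate_mg_per_h": p.rate, "model": p.model,
                 "state0": list(p.state0)}
            if p.model == "2c":
                d["params"] = {"v1": p.params.v1, "v2": p.params.v2,
                               "q": p.params.q, "cl": p.params.cl}
            else:
                d["params"] = {"k": p.params.k, "v": p.params.v}
            out.append(d)
        return json.dumps(out)

    @staticmethod
    def from_json(s: str) -> "ConcentrationCurve":
        pieces = []
        for d in json.loads(s):
            params = (PKParams2C(**d["params"]) if d["model"] == "2c"
                      else PKParams1C(**d["params"]))
            pieces.append(CurvePiece(d["t0"], d["t1"], d["rate_mg_per_h"],
                                     params, tuple(d["state0"]), d["model"]))
        return ConcentrationCurve(pieces)


def solve_segment_2c(state0: CompartmentState, seg: InfusionSegment):
    """Exact solution over one constant-rate segment.

    Returns (CurvePiece, CompartmentState at seg.t_end).
    """
    if abs(state0.t - seg.t_start) > 1e-9:
        raise ValueError("state time must equal segment start")
    if not (math.isfinite(state0.c_a) and math.isfinite(state0.c_b)):
        raise ValueError("non-finite initial state")
    piece = CurvePiece(seg.t_start, seg.t_end, seg.rate, seg.params,
                       (state0.c_a, state0.c_b), "2c")
    ca, cb = piece.end_state()
    return piece, CompartmentState(ca, cb, seg.t_end)


def solve_segment_1c(state0: OneCompState, seg: InfusionSegment):
    if abs(state0.t - seg.t_start) > 1e-9:
        raise ValueError("state time must equal segment start")
    piece = CurvePiece(seg.t_start, seg.t_end, seg.rate, seg.params,
                       (state0.mass,), "1c")
    (mass,) = piece.end_state()
    return piece, OneCompState(mass, seg.t_end)


def solve_schedule_2c(state0: CompartmentState, segments: list) -> ConcentrationCurve:
    pieces, state = [], state0
    for seg in segments:
        piece, state = solve_segment_2c(state, seg)
        pieces.append(piece)
    return ConcentrationCurve(pieces)


def solve_schedule_1c(state0: OneCompState, segments: list) -> ConcentrationCurve:
    pieces, state = [], state0
    for seg in segments:
        piece, state = solve_segment_1c(state, seg)
        pieces.append(piece)
    return ConcentrationCurve(pieces)


def evaluate_curve(curve: ConcentrationCurve, t: float) -> float:
    """Central concentration (mg/L) at time t (hours from encounter start)."""
    return curve.evaluate(t)


def segment_auc(piece: CurvePiece) -> float:
    return piece.auc()


def time_avg_dose_norm_auc_mic(curve: ConcentrationCurve, doses: list,
                               cfg: AucMicConfig = AucMicConfig()) -> float:
    """Time-averaged, dose-normalized AUC/MIC over the curve span.

    (total AUC / span duration) / MIC / normalization dose, with the
    normalization dose defaulting to the encounter's maximum dose (mg).
    The result is in 1/mg.
    """
    if not doses:
        raise ValueError("dose list must be non-empty")
    span = curve.t_end - curve.t_start
    if span <= 0:
        raise ValueError("curve has zero span")
    norm = cfg.normalization_dose if cfg.normalization_dose is not None else max(doses)
    return curve.auc() / span / cfg.mic / norm


# ---------------------------------------------------------------------------
# Schedule construction

# Dose-dependent infusion durations (h) used by the source health system.
_MHHS_DURATIONS = ((1000.0, 1.0), (1500.0, 1.5), (2000.0, 2.0), (float("inf"), 2.5))


def infusion_duration(dose_mg: float, policy: str = "uniform") -> float:
    """Infusion duration in hours for a dose.

    'uniform': constant 1 g/h rate, so duration = dose/1000 h.
    'mhhs': the dose-banded duration table (1.0/1.5/2.0/2.5 h).
    """
    if dose_mg <= 0:
        raise ValueError("dose must be positive")
    if policy == "uniform":
        return dose_mg / 1000.0
    if policy == "mhhs":
        for upper, dur in _MHHS_DURATIONS:
            if dose_mg <= upper:
                return dur
        raise AssertionError("unreachable")
    raise ValueError(f"unknown infusion policy {policy!r}")


def infusion_rate_segments(doses: list, t_end: float, policy: str = "uniform",
                           extra_breaks: list = ()) -> list:
    """Piecewise-constant infusion rate over [0, t_end].

    `doses` is a list of (t_start_h, dose_mg).  Returns a list of
    (t0, t1, rate_mg_per_h) covering [0, t_end]; overlapping infusions sum.
    `extra_breaks` forces additional segment boundaries (e.g. CrCL changes,
    observation times).
    """
    events = []
    for t0, mg in doses:
        dur = infusion_duration(mg, policy)
        events.append((t0, mg / dur))
        events.append((t0 + dur, -mg / dur))
    breaks = {0.0, t_end}
    breaks.update(t for t, _ in events if 0.0 <= t <= t_end)
    breaks.update(b for b in extra_breaks if 0.0 <= b <= t_end)
    times = sorted(breaks)
    segs = []
    for a, b in zip(times[:-1], times[1:]):
        rate = sum(r for t, r in events if t <= a + 1e-12)
        segs.append((a, b, max(rate, 0.0)))
    return segs


def _crcl_at(crcl_series: list, t: float) -> float:
    """Step-function lookup: most recent (t_i, crcl_i) with t_i <= t."""
    val = crcl_series[0][1]
    for ti, ci in crcl_series:
        if ti <= t + 1e-12:
            val = ci
        else:
            break
    return val


def build_curve_2c(eta: EtaVector, doses: list, t_end: float,
                   crcl_series: list, policy: str = "uniform",
                   state0: CompartmentState = None) -> ConcentrationCurve:
    """Two-compartment curve for one individual over [0, t_end].

    `doses`: list of (t_start_h, dose_mg); `crcl_series`: list of
    (t_h, crcl_mL_min) step changes (first entry applies from time 0).
    Parameters are re-derived from eta whenever CrCL changes.
    """
    breaks = [t for t, _ in crcl_series]
    rate_segs = infusion_rate_segments(doses, t_end, policy, extra_breaks=breaks)
    state = state0 if state0 is not None else CompartmentState(0.0, 0.0, 0.0)
    segments = []
    for a, b, rate in rate_segs:
        params = eta_to_pk2c(eta, _crcl_at(crcl_series, a))
        segments.append(InfusionSegment(a, b, rate, params))
    return solve_schedule_2c(state, segments)


# ---------------------------------------------------------------------------
# MAP-Bayesian baseline


@dataclass
class MapResult:
    eta: EtaVector
    converged: bool
    grad_norm: float
    n_obs: int
    message: str = ""
    nll: float = float("nan")


def map_bayes_update(doses: list, observations: list, crcl_series: list,
                     t_end: float = None, prior: EtaPrior = DEFAULT_PRIOR,
                     noise_sd: float = 1.0, policy: str = "uniform") -> MapResult:
    """Posterior-mode eta given observed levels under the 2C model.

    `observations`: list of (t_h, level_mg_L); the likelihood is Gaussian
    with the supplied measurement noise sd.  With no observations the prior
    mode (eta = 0) is returned.
    """
    observations = list(observations)
    if not observations:
        return MapResult(EtaVector(), True, 0.0, 0, "prior mode (no observations)", 0.0)
    if t_end is None:
        t_end = max(max(t for t, _ in observations),
                    max(t + infusion_duration(mg, policy) for t, mg in doses))
    var = np.asarray(prior.variances)
    obs_t = np.array([t for t, _ in observations])
    obs_y = np.array([y for _, y in observations])

    def objective(x: np.ndarray) -> float:
        prior_term = 0.5 * float(np.sum(x * x / var))
        try:
            eta = EtaVector.from_array(x)
            curve = build_curve_2c(eta, doses, t_end, crcl_series, policy)
            pred = np.array([curve.evaluate(t) for t in obs_t])
        except (ValueError, OverflowError, FloatingPointError):
            return 1e12 + prior_term  # extreme eta overflowed the curve
        if not np.all(np.isfinite(pred)):
            return 1e12 + prior_term
        return prior_term + 0.5 * float(np.sum((pred - obs_y) ** 2)) / (noise_sd ** 2)

    res = optimize.minimize(objective, np.zeros(4), method="L-BFGS-B",
                            options={"ftol": 1e-14, "gtol": 1e-9, "maxiter": 500})
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else float("nan")
    converged = bool(res.success)
    msg = "" if converged else f"optimizer did not converge: {res.message}"
    return MapResult(EtaVector.from_array(res.x), converged, grad_norm,
                     len(observations), msg, float(res.fun))
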