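"""Sampling-design simulation framework.

A trained "derived" model serves as ground truth: its prospective
concentration curves, evaluated at protocol-defined sampling times, replace
the measured vancomycin levels of a source cohort, while every other event
(doses, labs, vitals, medications, demographics) is kept verbatim.
"Estimated" models (one- or two-compartment) are then trained from scratch
on the simulated measurements and compared by RMSE on a common test split,
and by the error of their time-averaged dose-normalized AUC/MIC against the
derived model's.

Sampling designs combine a location (peak: 2 h post infusion start for
doses <= 1000 mg, 3 h for larger; trough: 1 h before the next infusion;
both) with a coverage (all doses, or a random half of them).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from . import pk_core, pkrnn
from .ehr_model import (DEFAULT_REGISTRY, ClinicalEvent, EventTimeline,
                        SplitSpec, impute_and_standardize, split_patients,
                        training_view)

__all__ = [
    "SimulationDesign",
    "SimulatedDataset",
    "peak_time",
    "trough_time",
    "simulate_dataset",
    "run_comparison",
    "auc_mic_comparison",
]


@dataclass(frozen=True)
class SimulationDesign:
    location: str = "both"      # 'peak' | 'trough' | 'both'
    coverage: str = "all"       # 'all' | 'half'
    noise_sd: float = 0.0       # mg/L added to simulated measurements
    half_policy: str = "random"  # 'random' | 'every_other'
    seed: int = 0

    def __post_init__(self):
        if self.location not in ("peak", "trough", "both"):
            raise ValueError("location must be peak, trough or both")
        if self.coverage not in ("all", "half"):
            raise ValueError("coverage must be all or half")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def name(self) -> str:
        return f"{self.location}_{self.coverage}"


@dataclass
class SimulatedDataset:
    timelines: list
    design: SimulationDesign
    derived_digest: str          # provenance hash of the derived model
    n_clipped: int = 0           # design times outside the encounter span
    n_dropped: int = 0           # collisions (inside an infusion / before prev sample)


def peak_time(dose_mg: float, infusion_start: float) -> float:
    """Peak sampling time: 2 h after infusion start for doses <= 1000 mg,
    3 h for doses > 1000 mg."""
    if dose_mg <= 0:
        raise ValueError("dose must be positive")
    return infusion_start + (2.0 if dose_mg <= 1000.0 else 3.0)


def trough_time(next_infusion_start: float) -> float:
    """Trough sampling time: 1 h before the next infusion."""
    return next_infusion_start - 1.0


def _design_times(doses: list, span: float, design: SimulationDesign,
                  rng, policy: str = "uniform"):
    """Sampling times for one encounter; returns (times, n_clipped, n_dropped)."""
    if not doses:
        return [], 0, 0
    if design.coverage == "half":
        if design.half_policy == "every_other":
            idx = list(range(0, len(doses), 2))
        else:
            k = max(1, len(doses) // 2)
            idx = sorted(rng.choice(len(doses), size=k, replace=False))
    else:
        idx = list(range(len(doses)))
    chosen = set(idx)
    raw = []
    for i, (t0, mg) in enumerate(doses):
        if i not in chosen:
            continue
        if design.location in ("peak", "both"):
            raw.append(peak_time(mg, t0))
        if design.location in ("trough", "both") and i + 1 < len(doses):
            raw.append(trough_time(doses[i + 1][0]))
    raw = sorted(set(raw))
    times, clipped, dropped, prev = [], 0, 0, -math.inf
    infusions = [(t0, t0 + pk_core.infusion_duration(mg, policy)) for t0, mg in doses]
    for t in raw:
        # collision rule: a sample inside a running infusion or not after
        # the previous sample is dropped, not moved
        if any(a <= t < b for a, b in infusions) or t <= prev:
            dropped += 1
        elif not 0.0 < t <= span:
            clipped += 1
        else:
            times.append(t)
            prev = t
    return times, clipped, dropped


def simulate_dataset(derived_model: "pkrnn.PKRNNModel", timelines: list,
                     frames: dict, design: SimulationDesign) -> SimulatedDataset:
    """Replace measured levels with derived-model values at design times.

    `frames` must be the preprocessed FeatureFrames of `timelines` (the
    derived model's prospective curve is computed from them).  Everything
    except VANC_LEVEL events is carried over unchanged.
    """
    rng = np.random.default_rng(design.seed)
    policy = derived_model.config.infusion_policy
    out, n_clip, n_drop = [], 0, 0
    for tl in timelines:
        frame = frames[tl.encounter_id]
        _, curve = pkrnn.predict_prospective(derived_model, frame)
        doses = tl.doses()
        times, c, d = _design_times(doses, tl.span, design, rng, policy)
        n_clip += c
        n_drop += d
        keep = [e for e in tl.events if e.kind != "VANC_LEVEL"]
        for t in times:
            t_eval = min(max(t, curve.t_start), curve.t_end)
            val = max(curve.evaluate(t_eval), 0.0)
            if design.noise_sd > 0:
                val = max(val + rng.normal(0.0, design.noise_sd), 0.0)
            keep.append(ClinicalEvent(t=t, kind="VANC_LEVEL", value=val))
        out.append(EventTimeline(tl.patient_id, tl.encounter_id, tl.start_time,
                                 keep, dict(tl.static)))
    return SimulatedDataset(out, design, pkrnn.checkpoint_digest(derived_model),
                            n_clip, n_drop)


def _rmse_on(model, frames_list, config):
    batches = [pkrnn.prepare_batch(frames_list[i:i + config.batch_size], config)
               for i in range(0, len(frames_list), config.batch_size)]
    return math.sqrt(pkrnn.evaluate_mse(model, batches))


def _frames_for(timelines, split, frames):
    return [frames[tl.encounter_id] for tl in split]


def run_comparison(derived_model, source_timelines: list, frames: dict,
                   designs: list, estimators=("1cm", "2cm"), repeats: int = 5,
                   split: SplitSpec = SplitSpec(), base_config=None,
                   base_seed: int = 0) -> dict:
    """Train estimated models on simulated data and compare test RMSE.

    For each (design, estimator) the model is retrained `repeats` times with
    different seeds on the simulated training split; the report gives mean
    RMSE +/- SD on the common test split and the pairwise two-sample t-test
    between estimators, mirroring a sampling-strategy comparison table.
    """
    from .evalcli import two_sample_t_test
    report = {"designs": {}, "derived_digest": pkrnn.checkpoint_digest(derived_model),
              "repeats": repeats}
    for design in designs:
        sim = simulate_dataset(derived_model, source_timelines, frames, design)
        view = training_view(sim.timelines)
        tr, te, va = split_patients(view, split)
        sim_frames, _ = impute_and_standardize(view, tr)
        entry = {"n_train": len(tr), "n_test": len(te), "n_val": len(va),
                 "clipped": sim.n_clipped, "dropped": sim.n_dropped,
                 "estimators": {}, "trained": {}}
        for kind in estimators:
            rmses, failures, models = [], [], []
            for r in range(repeats):
                cfg = _estimator_config(base_config, kind, base_seed + r)
                try:
                    model, _ = pkrnn.train(_frames_for(sim.timelines, tr, sim_frames),
                                           _frames_for(sim.timelines, va, sim_frames),
                                           cfg)
                    rmses.append(_rmse_on(model, _frames_for(sim.timelines, te, sim_frames), cfg))
                    models.append(model)
                except FloatingPointError as exc:
                    failures.append(str(exc))
            entry["estimators"][kind] = {
                "rmse": rmses, "mean": float(np.mean(rmses)) if rmses else math.nan,
                "sd": float(np.std(rmses, ddof=1)) if len(rmses) > 1 else math.nan,
                "failures": failures,
            }
            entry["trained"][kind] = models
        if len(entry["estimators"]) == 2:
            a, b = (entry["estimators"][k]["rmse"] for k in estimators)
            if len(a) >= 2 and len(b) >= 2:
                t, p = two_sample_t_test(a, b)
                entry["t_test"] = {"t": t, "p": p,
                                   "groups": list(estimators)}
        entry["test_ids"] = [tl.encounter_id for tl in te]
        entry["sim_frames"] = sim_frames
        report["designs"][design.name] = entry
    return report


def _estimator_config(base_config, kind: str, seed: int):
    if base_config is None:
        return pkrnn.ModelConfig(head=kind, seed=seed)
    from dataclasses import replace
    return replace(base_config, head=kind, seed=seed)


def auc_mic_comparison(derived_model, report: dict, source_timelines: list,
                       frames: dict, cfg: pk_core.AucMicConfig = pk_core.AucMicConfig()) -> dict:
    """Per-design RMSE of each estimated model's time-averaged
    dose-normalized AUC/MIC against the derived model's (the ground truth).

    Uses the trained models stored in a `run_comparison` report; the metric
    is computed per test encounter from each model's prospective curve.
    """
    by_enc = {tl.encounter_id: tl for tl in source_timelines}
    out = {}
    for design_name, entry in report["designs"].items():
        truth = {}
        for eid in entry["test_ids"]:
            _, curve = pkrnn.predict_prospective(derived_model, frames[eid])
            doses = [mg for _, mg in by_enc[eid].doses()]
            if not doses or curve.t_end <= curve.t_start:
                continue
            truth[eid] = pk_core.time_avg_dose_norm_auc_mic(curve, doses, cfg)
        res = {}
        for kind, models in entry["trained"].items():
            errs = []
            for model in models:
                diffs = []
                for eid, gt_val in truth.items():
                    _, curve = pkrnn.predict_prospective(model, entry["sim_frames"][eid])
                    doses = [mg for _, mg in by_enc[eid].doses()]
                    val = pk_core.time_avg_dose_norm_auc_mic(curve, doses, cfg)
                    diffs.append(val - gt_val)
                errs.append(float(np.sqrt(np.mean(np.square(diffs)))))
            res[kind] = {"rmse": errs, "mean": float(np.mean(errs)) if errs else math.nan,
                         "sd": float(np.std(errs, ddof=1)) if len(errs) > 1 else math.nan}
        out[design_name] = res
    return out


def render_table(report: dict) -> str:
    """Plain-text table of the comparison report (design x estimator)."""
    lines = [f"{'design':<14}" + "".join(f"{k:>22}" for k in
                                         next(iter(report['designs'].values()))['estimators'])]
    for name, entry in report["designs"].items():
        cells = []
        for k, st in entry["estimators"].items():
            cells.append(f"{st['mean']:.2f} ({st['sd']:.2f})".rjust(22)
                         if st["rmse"] else "failed".rjust(22))
        p = entry.get("t_test", {}).get("p")
        lines.append(f"{name:<14}" + "".join(cells) +
                     (f"   p={p:.3g}" if p is not None else ""))
    return "\n".join(lines)
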