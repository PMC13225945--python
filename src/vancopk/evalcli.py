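"""Evaluation metrics, statistical comparison, and the command-line surface.

Subcommands: gen-data, train, simulate, evaluate, compare, auc-mic.  Each
reads an optional YAML config overridable by flags, logs to stderr, and
writes machine-readable JSON to --out.
"""

from __future__ import annotations

import json
import math
import sys
from dataclasses import asdict, replace

import click
import numpy as np
from scipy import stats

__all__ = ["rmse", "two_sample_t_test", "cli"]


def rmse(pairs) -> float:
    """Root mean square error over (predicted, observed) pairs, in mg/L."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("rmse requires at least one pair")
    arr = np.asarray(pairs, dtype=float)
    return float(np.sqrt(np.mean((arr[:, 0] - arr[:, 1]) ** 2)))


def two_sample_t_test(a, b, welch: bool = False):
    """Two-sample two-tailed t-test; Student's pooled-variance by default.

    Returns (t, p).  Two zero-variance groups with equal means give
    (0, 1) by convention.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return math.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def _log(msg: str) -> None:
    click.echo(msg, err=True)


def _load_config(path):
    import yaml
    if path is None:
        return {}
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _write_out(obj, out):
    if out:
        with open(out, "w") as fh:
            json.dump(obj, fh, indent=2)
        _log(f"wrote {out}")
    else:
        click.echo(json.dumps(obj, indent=2))


@click.group()
def cli():
    """Recurrent-network two-compartment vancomycin PK modelling."""


@cli.command("gen-data")
@click.option("--config", type=click.Path(exists=True), default=None)
@click.option("--n", type=int, default=100, help="number of patients")
@click.option("--seed", type=int, default=0)
@click.option("--events-out", type=click.Path(), default="events.csv")
@click.option("--static-out", type=click.Path(), default="static.csv")
@click.option("--truth-out", type=click.Path(), default=None)
@click.option("--out", type=click.Path(), default=None)
def gen_data(config, n, seed, events_out, static_out, truth_out, out):
    """Generate a synthetic vancomycin-TDM cohort in the events-CSV schema."""
    from . import ehr_model, synthgen
    cfgd = _load_config(config).get("cohort", {})
    cfgd.update({"n_patients": n, "seed": seed})
    spec = synthgen.CohortSpec(**cfgd)
    timelines, gt = synthgen.generate_cohort(spec)
    ehr_model.write_events(timelines, events_out, static_out)
    if truth_out:
        with open(truth_out, "w") as fh:
            fh.write(gt.to_json())
    _log(f"generated {len(timelines)} encounters for {n} patients")
    _write_out({"n_patients": n, "n_encounters": len(timelines),
                "events_csv": events_out, "static_csv": static_out}, out)


def _prepare(events, static, split_seed):
    from . import ehr_model
    timelines = ehr_model.read_events(events, static)
    view = ehr_model.training_view(timelines)
    tr, te, va = ehr_model.split_patients(view, ehr_model.SplitSpec(seed=split_seed))
    frames, std = ehr_model.impute_and_standardize(view, tr)
    return view, tr, te, va, frames


@cli.command("train")
@click.option("--config", type=click.Path(exists=True), default=None)
@click.option("--events", type=click.Path(exists=True), required=True)
@click.option("--static", type=click.Path(exists=True), default=None)
@click.option("--model", "head", type=click.Choice(["1cm", "2cm"]), default="2cm")
@click.option("--seed", type=int, default=0)
@click.option("--checkpoint-out", type=click.Path(), default="model.json")
@click.option("--out", type=click.Path(), default=None)
def train_cmd(config, events, static, head, seed, checkpoint_out, out):
    """Train a PK-RNN model on an events CSV and save a checkpoint."""
    from . import pkrnn
    cfgd = _load_config(config).get("model", {})
    cfgd.update({"head": head, "seed": seed})
    cfg = pkrnn.ModelConfig(**cfgd)
    view, tr, te, va, frames = _prepare(events, static, seed)
    model, history = pkrnn.train([frames[t.encounter_id] for t in tr],
                                 [frames[t.encounter_id] for t in va], cfg)
    pkrnn.save_checkpoint(model, checkpoint_out)
    test_frames = [frames[t.encounter_id] for t in te]
    batches = [pkrnn.prepare_batch(test_frames[i:i + cfg.batch_size], cfg)
               for i in range(0, len(test_frames), cfg.batch_size)]
    test_rmse = math.sqrt(pkrnn.evaluate_mse(model, batches))
    _log(f"trained {head} for {len(history)} epochs; test RMSE {test_rmse:.3f} mg/L")
    _write_out({"model": head, "epochs": len(history), "test_rmse": test_rmse,
                "checkpoint": checkpoint_out, "history": history}, out)


@cli.command("evaluate")
@click.option("--events", type=click.Path(exists=True), required=True)
@click.option("--static", type=click.Path(exists=True), default=None)
@click.option("--checkpoint", type=click.Path(exists=True), required=True)
@click.option("--seed", type=int, default=0)
@click.option("--out", type=click.Path(), default=None)
def evaluate_cmd(events, static, checkpoint, seed, out):
    """Prospective test-set RMSE of a saved model."""
    from . import pkrnn
    model = pkrnn.load_checkpoint(checkpoint)
    view, tr, te, va, frames = _prepare(events, static, seed)
    cfg = model.config
    test_frames = [frames[t.encounter_id] for t in te]
    batches = [pkrnn.prepare_batch(test_frames[i:i + cfg.batch_size], cfg)
               for i in range(0, len(test_frames), cfg.batch_size)]
    test_rmse = math.sqrt(pkrnn.evaluate_mse(model, batches))
    _log(f"test RMSE {test_rmse:.3f} mg/L over {len(test_frames)} encounters")
    _write_out({"test_rmse": test_rmse, "n_test": len(test_frames)}, out)


@cli.command("simulate")
@click.option("--events", type=click.Path(exists=True), required=True)
@click.option("--static", type=click.Path(exists=True), default=None)
@click.option("--checkpoint", type=click.Path(exists=True), required=True)
@click.option("--design", type=str, default="both_all",
              help="location_coverage, e.g. peak_all, trough_half, both_all")
@click.option("--noise-sd", type=float, default=0.0)
@click.option("--seed", type=int, default=0)
@click.option("--events-out", type=click.Path(), default="simulated_events.csv")
@click.option("--out", type=click.Path(), default=None)
def simulate_cmd(events, static, checkpoint, design, noise_sd, seed,
                 events_out, out):
    """Replace measured levels with derived-model samples under a design."""
    from . import ehr_model, pkrnn, simkit
    model = pkrnn.load_checkpoint(checkpoint)
    loc, cov = design.rsplit("_", 1)
    dsn = simkit.SimulationDesign(location=loc, coverage=cov,
                                  noise_sd=noise_sd, seed=seed)
    timelines = ehr_model.read_events(events, static)
    view = ehr_model.training_view(timelines)
    tr, te, va = ehr_model.split_patients(view, ehr_model.SplitSpec(seed=seed))
    frames, _ = ehr_model.impute_and_standardize(view, tr)
    sim = simkit.simulate_dataset(model, view, frames, dsn)
    ehr_model.write_events(sim.timelines, events_out)
    sidecar = {"derived_model": sim.derived_digest, "design": asdict(dsn),
               "clipped": sim.n_clipped, "dropped": sim.n_dropped}
    with open(str(events_out) + ".provenance.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    _log(f"simulated {len(sim.timelines)} encounters under {dsn.name}")
    _write_out(sidecar, out)


@cli.command("compare")
@click.option("--config", type=click.Path(exists=True), default=None)
@click.option("--events", type=click.Path(exists=True), required=True)
@click.option("--static", type=click.Path(exists=True), default=None)
@click.option("--checkpoint", type=click.Path(exists=True), required=True)
@click.option("--design", "designs", type=str, multiple=True, default=("both_all",))
@click.option("--repeats", type=int, default=5)
@click.option("--seed", type=int, default=0)
@click.option("--out", type=click.Path(), default=None)
def compare_cmd(config, events, static, checkpoint, designs, repeats, seed, out):
    """Retrain 1CM/2CM estimators on simulated data and compare RMSE."""
    from . import ehr_model, pkrnn, simkit
    model = pkrnn.load_checkpoint(checkpoint)
    cfgd = _load_config(config).get("model", {})
    base = replace(pkrnn.ModelConfig(**cfgd)) if cfgd else None
    view, tr, te, va, frames = _prepare(events, static, seed)
    dsns = []
    for d in designs:
        loc, cov = d.rsplit("_", 1)
        dsns.append(simkit.SimulationDesign(location=loc, coverage=cov, seed=seed))
    report = simkit.run_comparison(model, view, frames, dsns, repeats=repeats,
                                   base_config=base, base_seed=seed)
    _log(simkit.render_table(report))
    _write_out(_strip_models(report), out)


@cli.command("auc-mic")
@click.option("--events", type=click.Path(exists=True), required=True)
@click.option("--static", type=click.Path(exists=True), default=None)
@click.option("--checkpoint", type=click.Path(exists=True), required=True)
@click.option("--design", "designs", type=str, multiple=True, default=("both_all",))
@click.option("--repeats", type=int, default=5)
@click.option("--mic", type=float, default=1.0)
@click.option("--seed", type=int, default=0)
@click.option("--out", type=click.Path(), default=None)
def auc_mic_cmd(events, static, checkpoint, designs, repeats, mic, seed, out):
    """AUC/MIC recovery of estimated models against the derived model."""
    from . import ehr_model, pk_core, pkrnn, simkit
    model = pkrnn.load_checkpoint(checkpoint)
    view, tr, te, va, frames = _prepare(events, static, seed)
    dsns = []
    for d in designs:
        loc, cov = d.rsplit("_", 1)
        dsns.append(simkit.SimulationDesign(location=loc, coverage=cov, seed=seed))
    report = simkit.run_comparison(model, view, frames, dsns, repeats=repeats,
                                   base_seed=seed)
    auc = simkit.auc_mic_comparison(model, report, view, frames,
                                    pk_core.AucMicConfig(mic=mic))
    _log(json.dumps(auc, indent=2))
    _write_out(auc, out)


def _strip_models(report: dict) -> dict:
    """Drop non-serializable entries (trained models, frames) from a report."""
    out = {"repeats": report["repeats"], "derived_digest": report["derived_digest"],
           "designs": {}}
    for name, entry in report["designs"].items():
        e = {k: v for k, v in entry.items()
             if k not in ("trained", "sim_frames")}
        out["designs"][name] = e
    return out


def main(argv=None) -> int:
    try:
        cli.main(args=argv, standalone_mode=False)
        return 0
    except click.UsageError as exc:
        _log(f"config error: {exc}")
        return 2
    except click.exceptions.Exit as exc:
        return exc.exit_code
    except Exception as exc:  # runtime failure
        _log(f"error: {exc}")
        return 1


if __name__ == "__main__":
    sys.exit(main())
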