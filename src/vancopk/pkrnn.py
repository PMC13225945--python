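"""Recurrent individualized PK parameter estimation for vancomycin.

Architecture: medication codes are embedded (8-d, averaged per step) and
concatenated with 40 standardized continuous features into a 48-d input to a
single-layer GRU (hidden 64).  A linear head maps each hidden state to the
random-effect vector eta (4-d for the two-compartment head, 2-d log-scale
multipliers for the one-compartment head).  A closed-form PK layer advances
the compartment state over each inter-event interval using the parameters
implied by eta, and the predicted central concentration at every measured
level is compared with the observation.

The two-compartment head carries compartment CONCENTRATIONS across
parameter changes (concentration continuity); the one-compartment head
carries MASS (mass conservation), so its concentration may jump when the
estimated volume changes.

Training: Adamax (lr 1e-2, weight decay 0.2), minibatches of 50 encounters,
early stopping with patience 10 on validation MSE.  The loss is the MSE
over observed levels plus a Gaussian-prior penalty on eta and an L2
first-difference smoothness penalty on the eta trajectory.

Gradients flow through the analytic closed form of the PK layer (no
discretized ODE stepping), via the package's reverse-mode autodiff engine.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from ._linode import step_1c, step_2c
from .ehr_model import DEFAULT_REGISTRY, FeatureFrame, FeatureRegistry
from .pk_core import (CL_CRCL_COEF, DEFAULT_PRIOR, TV_Q, TV_V1, TV_V2,
                      ConcentrationCurve, CurvePiece, EtaPrior, PKParams1C,
                      PKParams2C, infusion_rate_segments)

__all__ = [
    "ModelConfig",
    "PKRNNModel",
    "PredictionRecord",
    "prepare_batch",
    "loss_components",
    "train",
    "predict_prospective",
    "save_checkpoint",
    "load_checkpoint",
]

# Penalty variances for the 1C head's (log k, log V) deviations: the
# clearance-like and volume-like scales of the 4-d prior.
_PRIOR_1C = (0.149, 0.120)


@dataclass
class ModelConfig:
    head: str = "2cm"                  # '2cm' | '1cm'
    embedding_dim: int = 8
    continuous_dim: int = 40
    hidden_dim: int = 64
    vocab_size: int = 911
    learning_rate: float = 1e-2
    weight_decay: float = 0.2
    batch_size: int = 50
    patience: int = 10
    max_epochs: int = 50
    prior_penalty_weight: float = 1e-3
    smoothness_penalty_weight: float = 1e-3
    infusion_policy: str = "uniform"
    seed: int = 0

    def __post_init__(self):
        if self.head not in ("2cm", "1cm"):
            raise ValueError("head must be '2cm' or '1cm'")
        if self.patience < 1 or self.max_epochs < 1:
            raise ValueError("patience and max_epochs must be >= 1")
        if min(self.embedding_dim, self.continuous_dim, self.hidden_dim,
               self.vocab_size, self.batch_size) <= 0:
            raise ValueError("dimensions must be positive")

    @property
    def input_dim(self) -> int:
        return self.embedding_dim + self.continuous_dim

    @property
    def head_out(self) -> int:
        return 4 if self.head == "2cm" else 2


@dataclass(frozen=True)
class PredictionRecord:
    t: float                 # hours from encounter start
    predicted: float         # central concentration, mg/L
    observed: float | None   # measured level when the event is one, else None
    eta: tuple               # head output at that step


class PKRNNModel:
    """Parameter container + forward pass."""

    def __init__(self, config: ModelConfig,
                 registry: FeatureRegistry = DEFAULT_REGISTRY,
                 prior: EtaPrior = DEFAULT_PRIOR):
        self.config = config
        self.registry = registry
        self.prior = prior
        rng = np.random.default_rng(config.seed)
        H, D, V, O = (config.hidden_dim, config.input_dim,
                      config.vocab_size, config.head_out)
        s = 1.0 / math.sqrt(H)
        self.params = {
            "emb": ad.Tensor(rng.normal(0.0, 0.1, size=(V, config.embedding_dim)),
                             requires_grad=True),
            "w_x": ad.Tensor(rng.uniform(-s, s, size=(D, 3 * H)), requires_grad=True),
            "w_h": ad.Tensor(rng.uniform(-s, s, size=(H, 3 * H)), requires_grad=True),
            "b_x": ad.Tensor(rng.uniform(-s, s, size=(3 * H,)), requires_grad=True),
            "b_h": ad.Tensor(rng.uniform(-s, s, size=(3 * H,)), requires_grad=True),
            # head starts near the prior mode (eta ~ 0)
            "w_head": ad.Tensor(rng.normal(0.0, 0.01, size=(H, O)), requires_grad=True),
            "b_head": ad.Tensor(np.zeros(O), requires_grad=True),
        }

    def zero_head(self) -> None:
        """Zero the output head: eta == 0 at every step (population model)."""
        self.params["w_head"].data[:] = 0.0
        self.params["b_head"].data[:] = 0.0

    def parameters(self):
        return self.params.values()

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, sd: dict) -> None:
        for k, v in self.params.items():
            v.data = sd[k].copy()

    # -- forward ----------------------------------------------------------

    def embed_step(self, med_codes, continuous) -> np.ndarray:
        """48-d input vector for one event step (mean of code embeddings,
        zero when there are no codes, concatenated with the continuous
        features)."""
        E = self.params["emb"].data
        for c in med_codes:
            if not 0 <= c < self.config.vocab_size:
                raise ValueError(f"medication code {c} outside vocabulary")
        emb = (E[list(med_codes)].mean(axis=0) if med_codes
               else np.zeros(self.config.embedding_dim))
        out = np.concatenate([emb, np.asarray(continuous, dtype=float)])
        if out.shape != (self.config.input_dim,):
            raise ValueError("continuous feature vector has wrong length")
        return out

    def forward(self, batch: "PreparedBatch"):
        """Run the GRU + PK layer over a prepared batch.

        Returns (preds, etas) where preds is a (T, B) Tensor of predicted
        central concentrations at each step's arrival time and etas a
        (T, B, head_out) Tensor of head outputs.
        """
        cfg = self.config
        P = self.params
        T, B = batch.x.shape[:2]
        H = cfg.hidden_dim
        h = ad.Tensor(np.zeros((B, H)))
        two_c = cfg.head == "2cm"
        if two_c:
            ca = ad.Tensor(np.zeros(B))
            cb = ad.Tensor(np.zeros(B))
        else:
            mass = ad.Tensor(np.zeros(B))
        preds = [ad.Tensor(np.zeros(B))]   # arrival concentration at step 0
        etas = []
        for t in range(T):
            emb = ad.embedding_mean(P["emb"], batch.code_idx[t], batch.code_w[t])
            x = ad.concatenate([emb, ad.Tensor(batch.x[t])], axis=1)
            gx = x @ P["w_x"] + P["b_x"]
            gh = h @ P["w_h"] + P["b_h"]
            r = ad.sigmoid(gx[:, 0:H] + gh[:, 0:H])
            z = ad.sigmoid(gx[:, H:2 * H] + gh[:, H:2 * H])
            n = ad.tanh(gx[:, 2 * H:] + r * gh[:, 2 * H:])
            h = (1.0 - z) * n + z * h
            eta = h @ P["w_head"] + P["b_head"]
            etas.append(eta)
            if not np.all(np.isfinite(eta.data)):
                raise FloatingPointError(f"non-finite activations at step {t}")
            if t == T - 1:
                break
            crcl = batch.crcl[t]
            if two_c:
                v1 = TV_V1 * ad.exp(eta[:, 0])
                cl = (CL_CRCL_COEF * crcl) * ad.exp(eta[:, 1])
                q = TV_Q * ad.exp(eta[:, 2])
                v2 = TV_V2 * ad.exp(eta[:, 3])
                for k in range(batch.seg_dur.shape[2]):
                    ca, cb = step_2c(ca, cb, v1, v2, q, cl,
                                     batch.seg_rate[t, :, k], batch.seg_dur[t, :, k])
                preds.append(ca)
            else:
                k_el = (CL_CRCL_COEF * crcl / TV_V1) * ad.exp(eta[:, 0])
                v = TV_V1 * ad.exp(eta[:, 1])
                for k in range(batch.seg_dur.shape[2]):
                    mass = step_1c(mass, k_el, batch.seg_rate[t, :, k],
                                   batch.seg_dur[t, :, k])
                preds.append(mass / v)
        return ad.stack(preds, axis=0), ad.stack(etas, axis=0)


@dataclass
class PreparedBatch:
    encounter_ids: list
    x: np.ndarray           # (T, B, continuous_dim)
    code_idx: list          # per step: (B, K_t) int
    code_w: list            # per step: (B, K_t) float, rows sum to 1 or 0
    crcl: np.ndarray        # (T, B), padded with 100
    seq_mask: np.ndarray    # (T, B)
    level: np.ndarray       # (T, B), 0 where no observation
    level_mask: np.ndarray  # (T, B)
    seg_dur: np.ndarray     # (T, B, K) inter-event sub-segment durations (h)
    seg_rate: np.ndarray    # (T, B, K) constant infusion rate per sub-segment
    times: list             # per encounter: (n_i,) step times

    @property
    def n_obs(self) -> int:
        return int(self.level_mask.sum())


def _interval_subsegments(frame: FeatureFrame, policy: str):
    """Constant-rate pieces of each inter-event interval.

    Returns a list of length n_steps-1; element t is a list of
    (duration_h, rate_mg_per_h) covering [times[t], times[t+1]].
    """
    span = float(frame.times[-1]) if frame.n_steps else 0.0
    if frame.doses and span > 0:
        rate_segs = infusion_rate_segments(frame.doses, max(span, max(
            t + 0.0 for t, _ in frame.doses) + 5.0), policy)
    else:
        rate_segs = [(0.0, max(span, 1.0), 0.0)]
    out = []
    for t0, t1 in zip(frame.times[:-1], frame.times[1:]):
        pieces = []
        for a, b, r in rate_segs:
            lo, hi = max(a, t0), min(b, t1)
            if hi > lo + 1e-12:
                pieces.append((hi - lo, r))
        if not pieces:
            pieces = [(max(t1 - t0, 0.0), 0.0)]
        out.append(pieces)
    return out


def prepare_batch(frames: list, config: ModelConfig) -> PreparedBatch:
    """Pad a list of FeatureFrames into step-major arrays."""
    B = len(frames)
    T = max(f.n_steps for f in frames)
    dim = frames[0].x.shape[1]
    x = np.zeros((T, B, dim))
    crcl = np.full((T, B), 100.0)
    seq_mask = np.zeros((T, B))
    level = np.zeros((T, B))
    level_mask = np.zeros((T, B))
    subsegs = [_interval_subsegments(f, config.infusion_policy) for f in frames]
    K = max((len(p) for s in subsegs for p in s), default=1)
    seg_dur = np.zeros((T, B, K))
    seg_rate = np.zeros((T, B, K))
    code_idx = [np.zeros((B, 1), dtype=int) for _ in range(T)]
    code_w = [np.zeros((B, 1)) for _ in range(T)]
    step_codes = [[() for _ in range(B)] for _ in range(T)]
    for b, f in enumerate(frames):
        n = f.n_steps
        x[:n, b] = f.x
        crcl[:n, b] = f.crcl
        seq_mask[:n, b] = 1.0
        obs = ~np.isnan(f.level)
        level[:n, b][obs] = f.level[obs]
        level_mask[:n, b] = obs
        for t, pieces in enumerate(subsegs[b]):
            for k, (d, r) in enumerate(pieces):
                seg_dur[t, b, k] = d
                seg_rate[t, b, k] = r
        for t in range(n):
            step_codes[t][b] = f.med_codes[t]
    for t in range(T):
        kmax = max((len(c) for c in step_codes[t]), default=0)
        if kmax == 0:
            continue
        idx = np.zeros((B, kmax), dtype=int)
        w = np.zeros((B, kmax))
        for b, codes in enumerate(step_codes[t]):
            if codes:
                idx[b, :len(codes)] = codes
                w[b, :len(codes)] = 1.0 / len(codes)
        code_idx[t], code_w[t] = idx, w
    return PreparedBatch([f.encounter_id for f in frames], x, code_idx, code_w,
                         crcl, seq_mask, level, level_mask, seg_dur, seg_rate,
                         [f.times for f in frames])


def loss_components(preds: "ad.Tensor", etas: "ad.Tensor", batch: PreparedBatch,
                    config: ModelConfig, prior: EtaPrior = DEFAULT_PRIOR):
    """Composite loss: (total, mse, prior_penalty, smoothness_penalty).

    mse: mean squared error over observed levels.
    prior: mean over valid steps of eta' Sigma^-1 eta.
    smoothness: mean over valid consecutive step pairs of ||eta_t - eta_{t-1}||^2.
    total = mse + w1 * prior + w2 * smoothness (exact decomposition).
    """
    n_obs = batch.n_obs
    if n_obs == 0:
        raise ValueError("batch contains no observed levels")
    mask = ad.Tensor(batch.level_mask)
    mse = (mask * (preds - ad.Tensor(batch.level)) ** 2).sum() * (1.0 / n_obs)
    var = (np.asarray(prior.variances[:etas.shape[2]]) if config.head == "2cm"
           else np.asarray(_PRIOR_1C))
    quad = ((etas * etas) * (1.0 / var)).sum(axis=2)          # (T, B)
    n_steps = batch.seq_mask.sum()
    prior_pen = (ad.Tensor(batch.seq_mask) * quad).sum() * (1.0 / n_steps)
    diff = etas[1:] - etas[:-1]
    pair_mask = batch.seq_mask[1:] * batch.seq_mask[:-1]
    n_pairs = max(pair_mask.sum(), 1.0)
    smooth = (ad.Tensor(pair_mask) * (diff * diff).sum(axis=2)).sum() * (1.0 / n_pairs)
    total = (mse + config.prior_penalty_weight * prior_pen
             + config.smoothness_penalty_weight * smooth)
    return total, mse, prior_pen, smooth


class Adamax:
    """Adamax with decoupled-from-nothing (classic additive) weight decay."""

    def __init__(self, params, lr=1e-2, weight_decay=0.0,
                 betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.u = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        bias = 1.0 - self.b1 ** self.t
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.wd:
                g = g + self.wd * p.data
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.u[i] = np.maximum(self.b2 * self.u[i], np.abs(g))
            p.data = p.data - (self.lr / bias) * self.m[i] / (self.u[i] + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def _make_batches(frames: list, batch_size: int) -> list:
    return [frames[i:i + batch_size] for i in range(0, len(frames), batch_size)]


def train(train_frames: list, val_frames: list, config: ModelConfig,
          registry: FeatureRegistry = DEFAULT_REGISTRY,
          prior: EtaPrior = DEFAULT_PRIOR, log_path=None):
    """Fit a model with early stopping; returns (model, history).

    Stops when validation MSE has not improved for `patience` consecutive
    epochs (or at max_epochs); the best-validation weights are restored.
    Fully deterministic for a given config.seed.
    """
    if not train_frames or not val_frames:
        raise ValueError("training and validation sets must be non-empty")
    model = PKRNNModel(config, registry, prior)
    rng = np.random.default_rng(config.seed + 1)
    order = rng.permutation(len(train_frames))
    batches = [prepare_batch(b, config) for b in
               _make_batches([train_frames[i] for i in order], config.batch_size)]
    val_batches = [prepare_batch(b, config)
                   for b in _make_batches(val_frames, config.batch_size)]
    opt = Adamax(model.parameters(), lr=config.learning_rate,
                 weight_decay=config.weight_decay)
    best_val, best_state, bad = math.inf, model.state_dict(), 0
    history = []
    log_fh = open(log_path, "w") if log_path else None
    try:
        for epoch in range(1, config.max_epochs + 1):
            tr_tot = tr_mse = tr_pri = tr_smo = 0.0
            for batch in batches:
                opt.zero_grad()
                preds, etas = model.forward(batch)
                total, mse, pri, smo = loss_components(preds, etas, batch, config, prior)
                if not math.isfinite(total.item()):
                    raise FloatingPointError(
                        f"training diverged at epoch {epoch} (loss={total.item()})")
                total.backward()
                opt.step()
                tr_tot += total.item(); tr_mse += mse.item()
                tr_pri += pri.item(); tr_smo += smo.item()
            nb = len(batches)
            val_mse = evaluate_mse(model, val_batches)
            rec = {"epoch": epoch, "train_total": tr_tot / nb,
                   "train_mse": tr_mse / nb, "train_prior": tr_pri / nb,
                   "train_smooth": tr_smo / nb, "val_mse": val_mse}
            history.append(rec)
            if log_fh:
                log_fh.write(json.dumps(rec) + "\n")
            if val_mse < best_val:
                best_val, best_state, bad = val_mse, model.state_dict(), 0
            else:
                bad += 1
                if bad >= config.patience:
                    break
    finally:
        if log_fh:
            log_fh.close()
    model.load_state_dict(best_state)
    return model, history


def evaluate_mse(model: PKRNNModel, batches: list) -> float:
    """Mean squared prediction error over all observed levels in `batches`."""
    se = n = 0.0
    for b in batches:
        preds, _ = model.forward(b)
        se += float((b.level_mask * (preds.data - b.level) ** 2).sum())
        n += b.n_obs
    return se / n if n else math.nan


def predict_prospective(model: PKRNNModel, frame: FeatureFrame):
    """Full prospective trajectory for one encounter.

    Returns (records, curve): PredictionRecords at every event step and the
    piecewise-analytic ConcentrationCurve with the per-step parameters.
    Every prediction uses only information from strictly earlier events.
    """
    cfg = model.config
    batch = prepare_batch([frame], cfg)
    preds, etas = model.forward(batch)
    pred = preds.data[:, 0]
    eta = etas.data[:, 0, :]
    records = []
    for i in range(frame.n_steps):
        obs = None if math.isnan(frame.level[i]) else float(frame.level[i])
        records.append(PredictionRecord(float(frame.times[i]),
                                        max(float(pred[i]), 0.0), obs,
                                        tuple(eta[i])))
    pieces = []
    two_c = cfg.head == "2cm"
    state = (0.0, 0.0) if two_c else (0.0,)
    subsegs = _interval_subsegments(frame, cfg.infusion_policy)
    for t in range(frame.n_steps - 1):
        crcl = frame.crcl[t]
        if two_c:
            params = PKParams2C(v1=TV_V1 * math.exp(eta[t, 0]),
                                v2=TV_V2 * math.exp(eta[t, 3]),
                                q=TV_Q * math.exp(eta[t, 2]),
                                cl=CL_CRCL_COEF * crcl * math.exp(eta[t, 1]))
        else:
            params = PKParams1C(k=CL_CRCL_COEF * crcl / TV_V1 * math.exp(eta[t, 0]),
                                v=TV_V1 * math.exp(eta[t, 1]))
        t0 = float(frame.times[t])
        for dur, rate in subsegs[t]:
            piece = CurvePiece(t0, t0 + dur, rate, params, state,
                               "2c" if two_c else "1c")
            pieces.append(piece)
            state = piece.end_state()
            t0 += dur
    if not pieces:  # single-event encounter: degenerate flat curve
        params = (PKParams2C(TV_V1, TV_V2, TV_Q, CL_CRCL_COEF * frame.crcl[0])
                  if two_c else PKParams1C(CL_CRCL_COEF * frame.crcl[0] / TV_V1, TV_V1))
        pieces = [CurvePiece(float(frame.times[0]), float(frame.times[0]),
                             0.0, params, state, "2c" if two_c else "1c")]
    return records, ConcentrationCurve(pieces)


# ---------------------------------------------------------------------------
# Checkpoints


def save_checkpoint(model: PKRNNModel, path) -> None:
    payload = {
        "config": asdict(model.config),
        "registry_digest": model.registry.digest(),
        "prior_variances": list(model.prior.variances),
        "weights": {k: v.data.tolist() for k, v in model.params.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path, registry: FeatureRegistry = DEFAULT_REGISTRY) -> PKRNNModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload["registry_digest"] != registry.digest():
        raise ValueError("checkpoint was trained with a different feature registry")
    cfg = ModelConfig(**payload["config"])
    model = PKRNNModel(cfg, registry, EtaPrior(tuple(payload["prior_variances"])))
    model.load_state_dict({k: np.asarray(v) for k, v in payload["weights"].items()})
    return model


def checkpoint_digest(model: PKRNNModel) -> str:
    """Provenance hash of the model weights."""
    import hashlib
    h = hashlib.sha256()
    for k in sorted(model.params):
        h.update(k.encode())
        h.update(model.params[k].data.tobytes())
    return h.hexdigest()[:16]
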