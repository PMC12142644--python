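"""Gradient-manipulated training loop with validation model selection.

Each parameter update is judged by its global L2 gradient norm G against
two thresholds delta_max < delta_err: updates with G <= delta_max pass
unchanged, those with delta_max < G <= delta_err are rescaled so their
norm equals delta_max (direction preserved), and those above delta_err
are skipped outright — large-norm updates on small heterogeneous data
tend to be catastrophic rather than informative. Thresholds are either
fixed (defaults 0.3 / 0.75) or calibrated from one update-free pass over
the data as (mean norm, 3 x max norm).

Model selection: after every epoch the current network generates one
seeded follow-up per longitudinal validation patient and the mean
per-patient Euclidean distance to the real follow-up is the selection
score; the best-scoring parameters are kept and training stops after
``patience`` epochs without improvement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Cohort, SplitCohorts
from .diffusion import NoiseSchedule, forward_noise_batch, sample_batch
from .network import DenoiserConfig, UNet1D
from .selfcond import TrainingSample, build_training_set

__all__ = [
    "GradientPolicy",
    "TrainConfig",
    "TrainHistory",
    "grad_norm",
    "manipulate_gradient",
    "calibrate_thresholds",
    "policy_from_norms",
    "train",
]


@dataclass(frozen=True)
class GradientPolicy:
    """Thresholds governing pass / clip / skip of each update."""

    mode: str = "fixed"           # "fixed" or "calibrated"
    delta_max: float = 0.3
    delta_err: float = 0.75
    err_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "calibrated"):
            raise ValueError(f"unknown policy mode {self.mode!r}")
        if not (self.delta_max > 0 and self.delta_err > 0):
            raise ValueError("thresholds must be positive")
        if not self.delta_max < self.delta_err:
            raise ValueError("delta_max must be < delta_err")


@dataclass
class TrainConfig:
    epochs: int = 1000
    patience: int = 50
    learning_rate: float = 0.001
    batch_size: int = 128
    seed: int = 0
    selection_metric: str = "mean_euclidean"
    self_conditioning: bool = True
    gradient_manipulation: bool = True
    k_perturb: int = 5
    val_subsample: int = 400

    def __post_init__(self) -> None:
        if self.patience > self.epochs:
            raise ValueError("patience must be <= epochs")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.selection_metric != "mean_euclidean":
            raise ValueError(f"unknown selection metric {self.selection_metric!r}")


@dataclass
class TrainHistory:
    """Per-epoch training diagnostics."""

    train_loss: list[float] = field(default_factory=list)
    val_score: list[float] = field(default_factory=list)
    n_clipped: list[int] = field(default_factory=list)
    n_skipped: list[int] = field(default_factory=list)
    grad_norm_mean: list[float] = field(default_factory=list)
    grad_norm_max: list[float] = field(default_factory=list)
    n_samples: list[int] = field(default_factory=list)
    n_self_conditioned: list[int] = field(default_factory=list)
    best_epoch: int = -1
    best_score: float = math.inf
    effective_policy: "GradientPolicy | None" = None

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(1, self.n_epochs + 1),
            "train_loss": self.train_loss,
            "val_score": self.val_score,
            "n_clipped": self.n_clipped,
            "n_skipped": self.n_skipped,
            "grad_norm_mean": self.grad_norm_mean,
            "grad_norm_max": self.grad_norm_max,
            "n_samples": self.n_samples,
            "n_self_conditioned": self.n_self_conditioned,
        })


def grad_norm(gradients) -> float:
    """Global L2 norm over all parameter gradients (dict or sequence)."""
    arrays = gradients.values() if hasattr(gradients, "values") else gradients
    total = 0.0
    for g in arrays:
        g = np.asarray(g, dtype=float)
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite gradient component")
        total += float(np.sum(g * g))
    return math.sqrt(total)


def _action(G: float, policy: GradientPolicy) -> str:
    if G <= policy.delta_max:
        return "pass"
    if G <= policy.delta_err:
        return "clip"
    return "skip"


def manipulate_gradient(gradients, policy: GradientPolicy):
    """Pass, rescale-to-delta_max, or zero the whole gradient set by its
    global norm. Returns the same container type as given."""
    is_dict = hasattr(gradients, "items")
    G = grad_norm(gradients)
    action = _action(G, policy)
    if action == "pass":
        return gradients
    scale = policy.delta_max / G if action == "clip" else 0.0
    if is_dict:
        return {k: np.asarray(v, dtype=float) * scale for k, v in gradients.items()}
    return [np.asarray(v, dtype=float) * scale for v in gradients]


def policy_from_norms(norms, err_multiplier: float = 3.0) -> GradientPolicy:
    """Thresholds from observed batch norms: (mean, err_multiplier * max)."""
    norms = np.asarray(list(norms), dtype=float)
    if norms.size == 0:
        raise ValueError("no gradient norms observed")
    return GradientPolicy(mode="calibrated",
                          delta_max=float(norms.mean()),
                          delta_err=float(err_multiplier * norms.max()),
                          err_multiplier=err_multiplier)


def _batch_gradients(net: UNet1D, batch: list[TrainingSample],
                     schedule: NoiseSchedule, rng: np.random.Generator):
    """Forward/backward over one batch; returns (loss, gradients)."""
    targets = np.stack([s.target for s in batch])
    conds = np.stack([np.concatenate([s.cond_features, s.labels]) for s in batch])
    B, d = targets.shape
    ts = rng.integers(1, schedule.T + 1, size=B)
    Xt, eps = forward_noise_batch(targets, ts, schedule, rng)
    net.T = schedule.T
    eps_pred, cache = net.forward(Xt, ts, conds)
    diff = eps_pred - eps
    loss = float(np.mean(diff ** 2))
    grads = net.backward(2.0 * diff / diff.size, cache)
    return loss, grads


def calibrate_thresholds(net: UNet1D, data: list[TrainingSample],
                         schedule: NoiseSchedule, policy: GradientPolicy,
                         batch_size: int = 128,
                         seed: int = 0) -> GradientPolicy:
    """One full update-free pass recording per-batch gradient norms, then
    delta_max = mean norm, delta_err = err_multiplier * max norm."""
    if policy.mode != "calibrated":
        raise ValueError("calibration requires policy mode 'calibrated'")
    if not data:
        raise ValueError("no training samples to calibrate on")
    rng = np.random.default_rng(seed)
    norms = []
    for start in range(0, len(data), batch_size):
        batch = data[start:start + batch_size]
        _, grads = _batch_gradients(net, batch, schedule, rng)
        norms.append(grad_norm(grads))
    return policy_from_norms(norms, policy.err_multiplier)


class Adam:
    """Adaptive-moment optimizer over a flat parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            params[k] -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


def _validation_records(val: Cohort, config: TrainConfig,
                        rng: np.random.Generator):
    recs = [r for r in val if r.has_real_followup]
    if not recs:
        raise ValueError("validation cohort has no longitudinal records")
    if len(recs) > config.val_subsample:
        idx = rng.choice(len(recs), size=config.val_subsample, replace=False)
        recs = [recs[i] for i in sorted(idx)]
    return recs


def validation_score(net: UNet1D, val_records, schedule: NoiseSchedule,
                     seeds) -> float:
    """Mean per-patient Euclidean distance between one seeded generation
    and the real follow-up."""
    I1 = np.stack([r.i1 for r in val_records])
    L = np.stack([r.labels for r in val_records])
    I2 = np.stack([r.i2 for r in val_records])
    gen = sample_batch(net.predictor(schedule.T), I1, L, schedule, seeds,
                       clamp=True)
    return float(np.mean(np.linalg.norm(gen - I2, axis=1)))


def train(splits: SplitCohorts,
          denoiser_config: DenoiserConfig,
          train_config: TrainConfig | None = None,
          policy: GradientPolicy | None = None,
          schedule: NoiseSchedule | None = None,
          progress: bool = False):
    """Fit the denoiser; returns (best UNet1D, TrainHistory).

    Per epoch the training set is rebuilt (fresh self-conditioning draws),
    each batch gets one uniformly drawn step t per sample, targets are
    noised in closed form, the network predicts the noise, and the MSE
    gradient is manipulated before an Adam step. Skipped updates bypass
    the optimizer entirely.
    """
    from .diffusion import make_schedule

    cfg = train_config or TrainConfig()
    policy = policy or GradientPolicy()
    schedule = schedule or make_schedule()

    rng = np.random.default_rng(cfg.seed)
    net = UNet1D(denoiser_config, seed=int(rng.integers(2**31)))
    net.T = schedule.T

    train_cohort = splits.train if cfg.self_conditioning else splits.train.paired()
    if len(train_cohort) == 0:
        raise ValueError("no training records (paired subset empty?)")

    val_records = _validation_records(splits.validation, cfg, rng)
    val_seed_base = int(rng.integers(2**31))
    val_seeds = [(val_seed_base + i) % (2**31) for i in range(len(val_records))]

    if policy.mode == "calibrated" and cfg.gradient_manipulation:
        calib_samples = build_training_set(
            train_cohort, schedule, cfg.k_perturb,
            np.random.default_rng(int(rng.integers(2**31))))
        policy = calibrate_thresholds(
            net, calib_samples, schedule, policy, cfg.batch_size,
            seed=int(rng.integers(2**31)))

    opt = Adam(net.params, cfg.learning_rate)
    history = TrainHistory()
    history.effective_policy = policy
    best_params = net.copy_params()
    epochs_since_best = 0

    epoch_iter = range(cfg.epochs)
    if progress:
        epoch_iter = _progress(epoch_iter)
    for epoch in epoch_iter:
        samples = build_training_set(train_cohort, schedule, cfg.k_perturb, rng)
        order = rng.permutation(len(samples))
        losses, norms = [], []
        n_clip = n_skip = 0
        for start in range(0, len(samples), cfg.batch_size):
            batch = [samples[i] for i in order[start:start + cfg.batch_size]]
            loss, grads = _batch_gradients(net, batch, schedule, rng)
            losses.append(loss)
            if cfg.gradient_manipulation:
                G = grad_norm(grads)
                norms.append(G)
                action = _action(G, policy)
                if action == "skip":
                    n_skip += 1
                    continue
                if action == "clip":
                    n_clip += 1
                    scale = policy.delta_max / G
                    grads = {k: v * scale for k, v in grads.items()}
            else:
                norms.append(grad_norm(grads))
            opt.step(net.params, grads)

        score = validation_score(net, val_records, schedule, val_seeds)
        history.train_loss.append(float(np.mean(losses)))
        history.val_score.append(score)
        history.n_clipped.append(n_clip)
        history.n_skipped.append(n_skip)
        history.grad_norm_mean.append(float(np.mean(norms)) if norms else 0.0)
        history.grad_norm_max.append(float(np.max(norms)) if norms else 0.0)
        history.n_samples.append(len(samples))
        history.n_self_conditioned.append(
            sum(1 for s in samples if s.is_self_conditioned))

        if score < history.best_score:
            history.best_score = score
            history.best_epoch = epoch
            best_params = net.copy_params()
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= cfg.patience:
                break

    net.set_params(best_params)
    return net, history


def _progress(it):
    try:
        from tqdm import tqdm
        return tqdm(it)
    except ImportError:  # pragma: no cover
        return it
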