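"""Discrete denoising-diffusion primitives.

The forward process adds Gaussian noise over T discrete steps with a
linear variance schedule beta_1 < ... < beta_T. Writing alpha_t = 1 -
beta_t and alpha_bar_t for the cumulative product of the first t alphas,
the closed-form marginal is

    x_t = sqrt(alpha_bar_t) * x_0 + sqrt(1 - alpha_bar_t) * eps,
    eps ~ N(0, I).

The reverse (ancestral) update uses the predicted noise eps_hat:

    x_{t-1} = (x_t - beta_t / sqrt(1 - alpha_bar_t) * eps_hat) / sqrt(alpha_t)
              + sigma_t * z,   z ~ N(0, I)  (no noise at t = 1),

with the posterior variance sigma_t^2 = beta_t * (1 - alpha_bar_{t-1}) /
(1 - alpha_bar_t) — the lower-variance of the two standard choices, which
injects markedly less noise in the late (small-t) steps where it can no
longer be contracted away. Step indices are 1-based, t in {1..T}.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "NoiseSchedule",
    "NoisedSample",
    "make_schedule",
    "forward_noise",
    "forward_noise_batch",
    "denoising_loss",
    "reverse_step",
    "sample",
    "sample_batch",
]


@dataclass(frozen=True)
class NoiseSchedule:
    """Per-step noising rates beta with derived alpha and alpha_bar."""

    beta: np.ndarray        # (T,)
    alpha: np.ndarray       # (T,) = 1 - beta
    alpha_bar: np.ndarray   # (T,) cumulative product of alpha

    @property
    def T(self) -> int:
        return len(self.beta)

    def at(self, t: int | np.ndarray):
        """(beta_t, alpha_t, alpha_bar_t) for 1-based step index t."""
        idx = np.asarray(t) - 1
        if np.any(idx < 0) or np.any(idx >= self.T):
            raise ValueError(f"step index {t} out of range 1..{self.T}")
        return self.beta[idx], self.alpha[idx], self.alpha_bar[idx]

    def posterior_variance(self, t: int | np.ndarray) -> np.ndarray:
        """sigma_t^2 = beta_t (1 - alpha_bar_{t-1}) / (1 - alpha_bar_t),
        with alpha_bar_0 = 1 so sigma_1 = 0."""
        idx = np.asarray(t) - 1
        beta, _, ab = self.at(t)
        ab_prev = np.where(idx > 0, self.alpha_bar[np.maximum(idx - 1, 0)], 1.0)
        return beta * (1.0 - ab_prev) / (1.0 - ab)

    def to_dict(self) -> dict:
        return {
            "T": int(self.T),
            "beta_start": float(self.beta[0]),
            "beta_end": float(self.beta[-1]),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseSchedule":
        return make_schedule(d["T"], d["beta_start"], d["beta_end"])


@dataclass(frozen=True)
class NoisedSample:
    x_t: np.ndarray
    t: int
    epsilon: np.ndarray


def make_schedule(T: int = 100, beta_start: float = 0.0015,
                  beta_end: float = 0.02) -> NoiseSchedule:
    """Linear beta schedule inclusive of both endpoints."""
    if not (0.0 < beta_start < beta_end < 1.0):
        raise ValueError(
            f"need 0 < beta_start < beta_end < 1, got ({beta_start}, {beta_end})"
        )
    if T < 2:
        raise ValueError("T must be at least 2")
    beta = np.linspace(beta_start, beta_end, T)
    alpha = 1.0 - beta
    alpha_bar = np.cumprod(alpha)
    return NoiseSchedule(beta=beta, alpha=alpha, alpha_bar=alpha_bar)


def forward_noise(x0: np.ndarray, t: int, schedule: NoiseSchedule,
                  rng: np.random.Generator) -> NoisedSample:
    """Draw eps ~ N(0, I) and return the step-t noised vector with its eps."""
    x0 = np.asarray(x0, dtype=float)
    if not np.all(np.isfinite(x0)):
        raise ValueError("x0 must be finite")
    _, _, ab = schedule.at(int(t))
    eps = rng.standard_normal(x0.shape)
    x_t = np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps
    return NoisedSample(x_t=x_t, t=int(t), epsilon=eps)


def forward_noise_batch(X0: np.ndarray, ts: np.ndarray,
                        schedule: NoiseSchedule,
                        rng: np.random.Generator):
    """Vectorized forward noising: one (possibly different) t per row."""
    X0 = np.asarray(X0, dtype=float)
    _, _, ab = schedule.at(np.asarray(ts, dtype=int))
    eps = rng.standard_normal(X0.shape)
    Xt = np.sqrt(ab)[:, None] * X0 + np.sqrt(1.0 - ab)[:, None] * eps
    return Xt, eps


def denoising_loss(eps_true: np.ndarray, eps_pred: np.ndarray) -> float:
    """Mean squared error between true and predicted noise."""
    eps_true = np.asarray(eps_true, dtype=float)
    eps_pred = np.asarray(eps_pred, dtype=float)
    if eps_true.shape != eps_pred.shape:
        raise ValueError(
            f"shape mismatch: {eps_true.shape} vs {eps_pred.shape}"
        )
    return float(np.mean((eps_pred - eps_true) ** 2))


def reverse_step(x_t: np.ndarray, t: int, eps_pred: np.ndarray,
                 schedule: NoiseSchedule,
                 rng: np.random.Generator | None = None,
                 clip_denoised: bool = False) -> np.ndarray:
    """One ancestral denoising step from x_t to x_{t-1}.

    Injects posterior-variance noise for t > 1 and none at the final step
    t = 1. Passing ``rng=None`` suppresses the injected noise at every
    step (useful for deterministic algebra checks).

    With ``clip_denoised`` the implied clean signal x0-hat is clipped to
    the data range [-1, 1] before the posterior mean is formed. The data
    are defined on [-1, 1], and without this restoring force the chain
    can diverge: a layer-normalized denoiser cannot scale its noise
    prediction with the state magnitude, so off-distribution states grow
    unchecked. The unclipped update is the plain algebraic form
    (x_t - beta_t / sqrt(1 - alpha_bar_t) * eps_hat) / sqrt(alpha_t).
    """
    x_t = np.asarray(x_t, dtype=float)
    eps_pred = np.asarray(eps_pred, dtype=float)
    beta, alpha, ab = schedule.at(int(t))
    if clip_denoised:
        x0_hat = np.clip((x_t - np.sqrt(1.0 - ab) * eps_pred) / np.sqrt(ab),
                         -1.0, 1.0)
        ab_prev = schedule.alpha_bar[t - 2] if t > 1 else 1.0
        mean = (np.sqrt(ab_prev) * beta / (1.0 - ab)) * x0_hat \
            + ((1.0 - ab_prev) * np.sqrt(alpha) / (1.0 - ab)) * x_t
    else:
        mean = (x_t - beta / np.sqrt(1.0 - ab) * eps_pred) / np.sqrt(alpha)
    if t > 1 and rng is not None:
        sigma = np.sqrt(schedule.posterior_variance(int(t)))
        mean = mean + sigma * rng.standard_normal(x_t.shape)
    return mean


def sample(denoiser: Callable[[np.ndarray, int, np.ndarray, np.ndarray], np.ndarray],
           conditioning: tuple[np.ndarray, np.ndarray],
           schedule: NoiseSchedule, seed: int,
           clamp: bool = True, inject_noise: bool = True,
           clip_denoised: bool = True) -> np.ndarray:
    """Generate one feature vector by ancestral sampling.

    ``denoiser(x_t, t, i_s, l)`` predicts the noise at step t. Sampling
    starts from a standard Gaussian draw and runs t = T..1; the implied
    clean signal is clipped to the data range at each step (see
    :func:`reverse_step`; disable with ``clip_denoised=False`` for pure
    algebraic chains), and the final output is clipped to [-1, 1] when
    ``clamp``. Pure function of (denoiser weights, conditioning, seed).
    """
    i_s, l = (np.asarray(c, dtype=float) for c in conditioning)
    d = i_s.shape[-1]
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(d)
    for t in range(schedule.T, 0, -1):
        eps = np.asarray(denoiser(x, t, i_s, l), dtype=float)
        if eps.shape != x.shape:
            raise ValueError(
                f"denoiser returned shape {eps.shape}, expected {x.shape}"
            )
        x = reverse_step(x, t, eps, schedule, rng if inject_noise else None,
                         clip_denoised=clip_denoised)
    if clamp:
        x = np.clip(x, -1.0, 1.0)
    return x


def sample_batch(predictor: Callable[[np.ndarray, np.ndarray, np.ndarray, np.ndarray], np.ndarray],
                 I_s: np.ndarray, L: np.ndarray,
                 schedule: NoiseSchedule, seeds: Sequence[int],
                 clamp: bool = True, clip_denoised: bool = True) -> np.ndarray:
    """Vectorized ancestral sampling with an independent noise stream per
    record, so each row is bit-identical to :func:`sample` with its seed.

    ``predictor(X_t, ts, I_s, L)`` maps a batch to predicted noise.
    """
    I_s = np.asarray(I_s, dtype=float)
    L = np.asarray(L, dtype=float)
    B, d = I_s.shape
    if len(seeds) != B:
        raise ValueError("one seed per record required")
    T = schedule.T
    # pre-draw each record's noise exactly in the order sample() would
    X = np.empty((B, d))
    Z = np.zeros((B, T + 1, d))  # Z[:, t] is the noise injected at step t (t>1)
    for i, s in enumerate(seeds):
        rng = np.random.default_rng(int(s))
        X[i] = rng.standard_normal(d)
        for t in range(T, 1, -1):
            Z[i, t] = rng.standard_normal(d)
    for t in range(T, 0, -1):
        ts = np.full(B, t, dtype=int)
        eps = predictor(X, ts, I_s, L)
        beta, alpha, ab = schedule.at(t)
        if clip_denoised:
            x0_hat = np.clip((X - np.sqrt(1.0 - ab) * eps) / np.sqrt(ab),
                             -1.0, 1.0)
            ab_prev = schedule.alpha_bar[t - 2] if t > 1 else 1.0
            X = (np.sqrt(ab_prev) * beta / (1.0 - ab)) * x0_hat \
                + ((1.0 - ab_prev) * np.sqrt(alpha) / (1.0 - ab)) * X
        else:
            X = (X - beta / np.sqrt(1.0 - ab) * eps) / np.sqrt(alpha)
        if t > 1:
            X = X + np.sqrt(schedule.posterior_variance(t)) * Z[:, t]
    if clamp:
        X = np.clip(X, -1.0, 1.0)
    return X
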