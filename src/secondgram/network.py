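"""1D UNet-style noise-prediction network, in pure numpy.

The network maps a noised feature vector x_t, the diffusion step t, and
the conditioning pair (i_s, l) to a prediction of the injected noise.
Time is embedded with sinusoids of the normalized step t/T; the
conditioning vector [i_s; l] is affinely embedded to the same width and
the two embeddings are summed into one composite steering embedding fed
to every encoder/decoder block.

Encoder blocks: LayerNorm -> affine(representation) + affine(embedding)
-> sum -> SiLU -> affine enrichment. Decoder blocks mirror them but first
concatenate the skip activation from the matching encoder depth. Between
the two sit residual blocks (pairs of SiLU linear layers at the
bottleneck width, added back to their input) and, optionally, a single
self-attention head over the bottleneck representation (off by default).

Forward and backward passes are written out explicitly; parameters live
in a flat ``{name: array}`` dict so the training loop can compute a
global gradient norm and apply clipping/skipping across all of them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "DenoiserConfig",
    "UNet1D",
    "time_embed",
    "condition_embed",
    "predict_noise",
]

_LN_EPS = 1e-5


@dataclass(frozen=True)
class DenoiserConfig:
    """Architecture hyperparameters.

    ``down_sizes`` are the encoder output widths; the decoder mirrors
    them, ending at the data dimensionality d. ``embed_dim`` is the width
    of the composite (time + conditioning) embedding.
    """

    d: int
    n_labels: int
    down_sizes: tuple[int, ...] = (512, 256, 128)
    n_residual: int = 2
    embed_dim: int = 128
    attention: bool = False
    attn_tokens: int = 16

    def __post_init__(self) -> None:
        if self.embed_dim % 2 != 0:
            raise ValueError("embed_dim must be even (paired sin/cos)")
        if self.n_residual < 0:
            raise ValueError("n_residual must be >= 0")
        if self.attention and self.down_sizes[-1] % self.attn_tokens != 0:
            raise ValueError("bottleneck width must divide into attn_tokens")

    @property
    def cond_dim(self) -> int:
        return self.d + self.n_labels

    @property
    def up_sizes(self) -> tuple[int, ...]:
        return tuple(reversed(self.down_sizes))[1:] + (self.d,)

    def to_dict(self) -> dict:
        return {
            "d": self.d, "n_labels": self.n_labels,
            "down_sizes": list(self.down_sizes),
            "n_residual": self.n_residual, "embed_dim": self.embed_dim,
            "attention": self.attention, "attn_tokens": self.attn_tokens,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DenoiserConfig":
        d = dict(d)
        d["down_sizes"] = tuple(d["down_sizes"])
        return cls(**d)


def time_embed(t: int | np.ndarray, T: int, embed_dim: int) -> np.ndarray:
    """Sinusoidal positional encoding of the normalized step t/T.

    Alternating sine/cosine over ``embed_dim/2`` geometric frequencies
    spanning 1..2T, so the finest sinusoid still resolves adjacent steps
    without aliasing. Accepts a scalar step (returns ``(embed_dim,)``) or
    an array of steps (returns ``(n, embed_dim)``).
    """
    if embed_dim % 2 != 0:
        raise ValueError("embed_dim must be even (paired sin/cos)")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 1) or np.any(t_arr > T):
        raise ValueError(f"step index {t} out of range 1..{T}")
    s = t_arr / T
    half = embed_dim // 2
    freqs = np.exp(np.linspace(0.0, np.log(2.0 * T), half)) if half > 1 else np.ones(1)
    angles = s[..., None] * freqs
    out = np.empty(angles.shape[:-1] + (embed_dim,))
    out[..., 0::2] = np.sin(angles)
    out[..., 1::2] = np.cos(angles)
    return out


def condition_embed(i_s: np.ndarray, l: np.ndarray, W: np.ndarray,
                    b: np.ndarray) -> np.ndarray:
    """Affine map of the concatenated conditioning [i_s; l] to embed_dim."""
    c = np.concatenate([np.atleast_2d(i_s), np.atleast_2d(l)], axis=-1)
    if c.shape[-1] != W.shape[0]:
        raise ValueError(
            f"conditioning length {c.shape[-1]} != weight rows {W.shape[0]}"
        )
    out = c @ W + b
    return out[0] if np.ndim(i_s) == 1 else out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _silu(x: np.ndarray) -> np.ndarray:
    return x * _sigmoid(x)


def _silu_grad(x: np.ndarray) -> np.ndarray:
    sig = _sigmoid(x)
    return sig * (1.0 + x * (1.0 - sig))


def _ln_forward(x: np.ndarray, g: np.ndarray, b: np.ndarray):
    mu = x.mean(axis=1, keepdims=True)
    var = x.var(axis=1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv, g)


def _ln_backward(dy: np.ndarray, cache):
    xhat, inv, g = cache
    m = xhat.shape[1]
    dg = (dy * xhat).sum(axis=0)
    db = dy.sum(axis=0)
    dxhat = dy * g
    dx = inv * (dxhat - dxhat.mean(axis=1, keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=1, keepdims=True))
    return dx, dg, db


class UNet1D:
    """Noise-prediction network with explicit forward/backward passes."""

    def __init__(self, config: DenoiserConfig, seed: int = 0,
                 params: Mapping[str, np.ndarray] | None = None):
        self.config = config
        if params is not None:
            self.params = {k: np.array(v, dtype=float) for k, v in params.items()}
            self._check_shapes()
        else:
            self.params = self._init_params(seed)

    # -- construction ----------------------------------------------------
    def _block_dims(self):
        cfg = self.config
        down_in = (cfg.d,) + cfg.down_sizes[:-1]
        skip_dims = (cfg.d,) + cfg.down_sizes[:-1]  # skips saved before each block
        # decoder block i consumes (previous width + mirrored skip width)
        up_skip = tuple(reversed(skip_dims))[:len(cfg.up_sizes)]
        up_prev = (cfg.down_sizes[-1],) + cfg.up_sizes[:-1]
        up_in = tuple(p + s for p, s in zip(up_prev, up_skip))
        return down_in, up_in, up_skip

    def _init_params(self, seed: int) -> dict[str, np.ndarray]:
        cfg = self.config
        rng = np.random.default_rng(seed)
        p: dict[str, np.ndarray] = {}

        def lin(name: str, m: int, n: int):
            p[f"{name}.W"] = rng.standard_normal((m, n)) / np.sqrt(m)
            p[f"{name}.b"] = np.zeros(n)

        lin("cond", cfg.cond_dim, cfg.embed_dim)
        down_in, up_in, _ = self._block_dims()
        for i, (m, h) in enumerate(zip(down_in, cfg.down_sizes)):
            p[f"down{i}.ln_g"] = np.ones(m)
            p[f"down{i}.ln_b"] = np.zeros(m)
            lin(f"down{i}.x", m, h)
            lin(f"down{i}.e", cfg.embed_dim, h)
            lin(f"down{i}.f", h, h)
        w = cfg.down_sizes[-1]
        for j in range(cfg.n_residual):
            lin(f"res{j}.l1", w, w)
            lin(f"res{j}.l2", w, w)
        if cfg.attention:
            dt = w // cfg.attn_tokens
            for nm in ("q", "k", "v", "o"):
                p[f"attn.{nm}"] = rng.standard_normal((dt, dt)) / np.sqrt(dt)
        for i, (m, h) in enumerate(zip(up_in, cfg.up_sizes)):
            p[f"up{i}.ln_g"] = np.ones(m)
            p[f"up{i}.ln_b"] = np.zeros(m)
            lin(f"up{i}.x", m, h)
            lin(f"up{i}.e", cfg.embed_dim, h)
            lin(f"up{i}.f", h, h)
        return p

    def _check_shapes(self) -> None:
        ref = UNet1D(self.config, seed=0)
        if set(ref.params) != set(self.params):
            raise ValueError("parameter keys do not match the configuration")
        for k, v in ref.params.items():
            if self.params[k].shape != v.shape:
                raise ValueError(
                    f"parameter {k!r} has shape {self.params[k].shape}, "
                    f"expected {v.shape}"
                )

    @property
    def n_params(self) -> int:
        return sum(v.size for v in self.params.values())

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: Mapping[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.array(params[k], dtype=float)

    # -- forward ---------------------------------------------------------
    def forward(self, X: np.ndarray, ts: np.ndarray, C: np.ndarray):
        """Batch forward pass.

        X: (B, d) noised vectors; ts: (B,) 1-based steps; C: (B, cond_dim)
        conditioning [i_s; l]. Returns (eps_pred (B, d), cache).
        """
        cfg = self.config
        p = self.params
        X = np.atleast_2d(np.asarray(X, dtype=float))
        C = np.atleast_2d(np.asarray(C, dtype=float))
        ts = np.asarray(ts, dtype=int)
        te = time_embed(ts, self._T_hint(ts), cfg.embed_dim)
        e = te + C @ p["cond.W"] + p["cond.b"]

        cache: dict = {"C": C, "e": e, "blocks": []}
        h = X
        skips = []
        for i in range(len(cfg.down_sizes)):
            skips.append(h)
            h, blk = self._block_forward(f"down{i}", h, e)
            cache["blocks"].append(blk)
        cache["skips"] = skips

        res_caches = []
        for j in range(cfg.n_residual):
            r1 = h @ p[f"res{j}.l1.W"] + p[f"res{j}.l1.b"]
            a1 = _silu(r1)
            r2 = a1 @ p[f"res{j}.l2.W"] + p[f"res{j}.l2.b"]
            a2 = _silu(r2)
            res_caches.append((h, r1, a1, r2))
            h = h + a2
        cache["res"] = res_caches

        if cfg.attention:
            h, attn_cache = self._attn_forward(h)
            cache["attn"] = attn_cache

        up_caches = []
        for i in range(len(cfg.up_sizes)):
            skip = skips[len(skips) - 1 - i]
            cat = np.concatenate([h, skip], axis=1)
            h, blk = self._block_forward(f"up{i}", cat, e)
            up_caches.append((blk, skip.shape[1]))
        cache["ups"] = up_caches
        if not np.all(np.isfinite(h)):
            raise FloatingPointError("non-finite values in network output")
        cache["out"] = h
        return h, cache

    def _T_hint(self, ts: np.ndarray) -> int:
        # time_embed needs T; the trainer stores it on the instance
        return getattr(self, "T", int(max(np.max(ts), 1)))

    def _block_forward(self, name: str, x: np.ndarray, e: np.ndarray):
        p = self.params
        ln, ln_cache = _ln_forward(x, p[f"{name}.ln_g"], p[f"{name}.ln_b"])
        a = ln @ p[f"{name}.x.W"] + p[f"{name}.x.b"]
        c = e @ p[f"{name}.e.W"] + p[f"{name}.e.b"]
        s = a + c
        u = _silu(s)
        out = u @ p[f"{name}.f.W"] + p[f"{name}.f.b"]
        return out, (name, ln, ln_cache, s, u)

    def _attn_forward(self, x: np.ndarray):
        cfg = self.config
        p = self.params
        B, w = x.shape
        n, dt = cfg.attn_tokens, w // cfg.attn_tokens
        Xt = x.reshape(B, n, dt)
        Q, K, V = Xt @ p["attn.q"], Xt @ p["attn.k"], Xt @ p["attn.v"]
        S = Q @ K.transpose(0, 2, 1) / np.sqrt(dt)
        S = S - S.max(axis=-1, keepdims=True)
        A = np.exp(S)
        A = A / A.sum(axis=-1, keepdims=True)
        O = A @ V
        Y = O @ p["attn.o"]
        return x + Y.reshape(B, w), (Xt, Q, K, V, A, O)

    # -- backward --------------------------------------------------------
    def backward(self, d_out: np.ndarray, cache) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss w.r.t. every parameter, given the
        loss gradient w.r.t. the network output."""
        cfg = self.config
        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        e = cache["e"]
        de = np.zeros_like(e)
        skip_grads: dict[int, np.ndarray] = {}

        dh = np.atleast_2d(np.asarray(d_out, dtype=float))
        n_skips = len(cache["skips"])
        for i in reversed(range(len(cfg.up_sizes))):
            blk, skip_w = cache["ups"][i]
            d_cat, d_e_blk = self._block_backward(blk, dh, grads, e)
            de += d_e_blk
            dh = d_cat[:, :-skip_w]
            idx = n_skips - 1 - i
            ds = d_cat[:, -skip_w:]
            skip_grads[idx] = skip_grads.get(idx, 0) + ds

        if cfg.attention:
            dh = self._attn_backward(dh, cache["attn"], grads)

        for j in reversed(range(cfg.n_residual)):
            h_in, r1, a1, r2 = cache["res"][j]
            da2 = dh
            dr2 = da2 * _silu_grad(r2)
            grads[f"res{j}.l2.W"] += a1.T @ dr2
            grads[f"res{j}.l2.b"] += dr2.sum(axis=0)
            da1 = dr2 @ p[f"res{j}.l2.W"].T
            dr1 = da1 * _silu_grad(r1)
            grads[f"res{j}.l1.W"] += h_in.T @ dr1
            grads[f"res{j}.l1.b"] += dr1.sum(axis=0)
            dh = dh + dr1 @ p[f"res{j}.l1.W"].T

        for i in reversed(range(len(cfg.down_sizes))):
            d_in, d_e_blk = self._block_backward(cache["blocks"][i], dh, grads, e)
            de += d_e_blk
            dh = d_in
            if i in skip_grads:
                dh = dh + skip_grads[i]
        # skip index 0 is the network input X; its gradient is discarded

        grads["cond.W"] += cache["C"].T @ de
        grads["cond.b"] += de.sum(axis=0)
        return grads

    def _block_backward(self, blk, d_out: np.ndarray, grads, e: np.ndarray):
        p = self.params
        name, ln, ln_cache, s, u = blk
        grads[f"{name}.f.W"] += u.T @ d_out
        grads[f"{name}.f.b"] += d_out.sum(axis=0)
        du = d_out @ p[f"{name}.f.W"].T
        ds = du * _silu_grad(s)
        grads[f"{name}.x.W"] += ln.T @ ds
        grads[f"{name}.x.b"] += ds.sum(axis=0)
        grads[f"{name}.e.W"] += e.T @ ds
        grads[f"{name}.e.b"] += ds.sum(axis=0)
        d_e = ds @ p[f"{name}.e.W"].T
        dln = ds @ p[f"{name}.x.W"].T
        dx, dg, db = _ln_backward(dln, ln_cache)
        grads[f"{name}.ln_g"] += dg
        grads[f"{name}.ln_b"] += db
        return dx, d_e

    def _attn_backward(self, d_out: np.ndarray, attn_cache, grads):
        cfg = self.config
        p = self.params
        Xt, Q, K, V, A, O = attn_cache
        B, n, dt = Xt.shape
        dY = d_out.reshape(B, n, dt)
        grads["attn.o"] += np.einsum("bnd,bne->de", O, dY)
        dO = dY @ p["attn.o"].T
        dA = dO @ V.transpose(0, 2, 1)
        dV = A.transpose(0, 2, 1) @ dO
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dS = dS / np.sqrt(dt)
        dQ = dS @ K
        dK = dS.transpose(0, 2, 1) @ Q
        grads["attn.q"] += np.einsum("bnd,bne->de", Xt, dQ)
        grads["attn.k"] += np.einsum("bnd,bne->de", Xt, dK)
        grads["attn.v"] += np.einsum("bnd,bne->de", Xt, dV)
        dXt = dQ @ p["attn.q"].T + dK @ p["attn.k"].T + dV @ p["attn.v"].T
        return d_out + dXt.reshape(B, n * dt)

    # -- convenience -----------------------------------------------------
    def predictor(self, T: int):
        """Batched noise predictor ``(X_t, ts, I_s, L) -> eps`` bound to a
        schedule length (used by sampling)."""
        def f(Xt, ts, I_s, L):
            self.T = T
            C = np.concatenate([I_s, L], axis=1)
            out, _ = self.forward(Xt, ts, C)
            return out
        return f

    def predict(self, x_t: np.ndarray, t: int, i_s: np.ndarray,
                l: np.ndarray, T: int | None = None) -> np.ndarray:
        """Single-vector noise prediction."""
        if T is not None:
            self.T = T
        C = np.concatenate([np.atleast_1d(i_s), np.atleast_1d(l)])
        out, _ = self.forward(x_t[None, :], np.array([t]), C[None, :])
        return out[0]


def predict_noise(x_t: np.ndarray, t: int, i_s: np.ndarray, l: np.ndarray,
                  net: UNet1D, T: int | None = None) -> np.ndarray:
    """Functional wrapper over :meth:`UNet1D.predict`."""
    return net.predict(np.asarray(x_t, dtype=float), t,
                       np.asarray(i_s, dtype=float),
                       np.asarray(l, dtype=float), T=T)
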