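"""Hybrid 3D vision-transformer/CNN for Patterson-to-density completion.

The network takes two channel-stacked volumes — a Patterson map and one
partial-structure template density, both normalised to [-1, 1] — and
regresses the ground-truth electron density of the same shape.  Stages, in
order: a 3D convolutional stem (optionally a scale-equivariant shared-
weight multi-scale variant), patchification into tokens, a stack of
pre-norm transformer blocks with Nyström-approximated self-attention,
strided-convolution downsampling of the token grid after selected blocks
and transposed-convolution upsampling after later ones, and a linear
de-patchification head cropped back to the input shape.

The loss is MSE plus a negative-Pearson-correlation term.  Training uses
decoupled-weight-decay Adam under a one-cycle learning-rate schedule with
gradient accumulation every two batches.

Default hyperparameters follow the published training configuration
(10 conv channels, patch 4, embed 512, 12 heads of dim 64, MLP 2048,
12 layers, downsample after layers 2 and 4, upsample after 8 and 10);
the "toy" preset shrinks every dimension to something a single CPU core
can overfit in minutes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .scatter import MapGrid

__all__ = ["ModelConfig", "TrainConfig", "CompletionModel", "toy_config",
           "loss", "train_toy", "one_cycle_lr", "exact_attention",
           "nystrom_attention", "TrainHistory"]


@dataclass
class ModelConfig:
    conv_channels: int = 10
    patch: int = 4
    embed_dim: int = 512
    head_dim: int = 64
    n_heads: int = 12
    mlp_dim: int = 2048
    n_layers: int = 12
    landmarks: int = 64
    pinv_iterations: int = 6
    downsample_after: tuple[int, ...] = (2, 4)
    upsample_after: tuple[int, ...] = (8, 10)
    scale_equivariant: bool = False
    pc_loss_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.patch < 1:
            raise ValueError("patch must be >= 1")
        if self.upsample_after and self.n_layers < max(self.upsample_after):
            raise ValueError("n_layers must cover every upsample position")
        if len(self.downsample_after) != len(self.upsample_after):
            raise ValueError("down/upsample lists must pair up")

    @property
    def divisor(self) -> int:
        """Input axes are padded to a multiple of this."""
        return self.patch * self.patch ** len(self.downsample_after)


def toy_config(**overrides) -> ModelConfig:
    """A configuration small enough to overfit a handful of examples on CPU."""
    cfg = ModelConfig(conv_channels=6, patch=2, embed_dim=64, head_dim=16,
                      n_heads=4, mlp_dim=128, n_layers=4, landmarks=32,
                      downsample_after=(2,), upsample_after=(3,))
    return replace(cfg, **overrides)


@dataclass
class TrainConfig:
    lr_initial: float = 4.5e-4
    lr_max: float = 2.85e-3
    lr_final: float = 8.57e-4
    weight_decay: float = 3e-2
    grad_accumulation: int = 2
    epochs: int = 50
    warmup_fraction: float = 0.3
    betas: tuple[float, float] = (0.9, 0.999)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lr_initial, self.lr_max, self.lr_final) <= 0:
            raise ValueError("learning rates must be positive")


def one_cycle_lr(step: int, total_steps: int, cfg: TrainConfig) -> float:
    """Cosine one-cycle schedule: initial -> max over the warmup fraction,
    then max -> final over the remainder."""
    warm = max(1, int(round(cfg.warmup_fraction * total_steps)))
    if step <= 0:
        return cfg.lr_initial
    if step >= total_steps - 1:
        return cfg.lr_final
    if step < warm:
        t = step / warm
        return cfg.lr_initial + (cfg.lr_max - cfg.lr_initial) * 0.5 * (1 - np.cos(np.pi * t))
    t = (step - warm) / max(1, total_steps - 1 - warm)
    return cfg.lr_final + (cfg.lr_max - cfg.lr_final) * 0.5 * (1 + np.cos(np.pi * t))


# ---------------------------------------------------------------------------
# attention

def exact_attention(q: Tensor, k: Tensor, v: Tensor) -> Tensor:
    """Plain softmax attention; the oracle the Nyström path is tested against.
    q, k, v: (..., n, d)."""
    scale = 1.0 / np.sqrt(q.shape[-1])
    attn = ag.softmax((q @ k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)) * scale, axis=-1)
    return attn @ v


def _landmark_matrix(n: int, m: int) -> np.ndarray:
    """(m, n) segment-averaging matrix: landmark i is the mean of its
    contiguous token segment."""
    bounds = np.linspace(0, n, m + 1).astype(int)
    S = np.zeros((m, n), dtype=np.float32)
    for i in range(m):
        lo, hi = bounds[i], max(bounds[i + 1], bounds[i] + 1)
        S[i, lo:hi] = 1.0 / (hi - lo)
    return S


def _iterative_pinv(A: Tensor, iters: int) -> Tensor:
    """Newton–Schulz iteration for the Moore–Penrose pseudo-inverse of a
    (..., m, m) matrix of non-negative entries (a softmax kernel)."""
    axes = (*range(A.ndim - 2), A.ndim - 1, A.ndim - 2)
    At = A.transpose(*axes)
    # scale so the spectral radius of (I - Z A) is < 1
    row = np.abs(A.data).sum(axis=-1).max(axis=-1)
    col = np.abs(A.data).sum(axis=-2).max(axis=-1)
    z0 = (1.0 / (row * col)).astype(np.float32)
    Z = At * Tensor(z0[..., None, None])
    eye = Tensor(np.broadcast_to(np.eye(A.shape[-1], dtype=np.float32), A.shape).copy())
    for _ in range(iters):
        AZ = A @ Z
        Z = Z @ (eye * 13.0 - AZ @ (eye * 15.0 - AZ @ (eye * 7.0 - AZ))) * 0.25
    return Z


def nystrom_attention(q: Tensor, k: Tensor, v: Tensor, landmarks: int = 64,
                      pinv_iterations: int = 6) -> Tensor:
    """Nyström approximation of softmax attention.

    Landmarks are segment means of the queries/keys; the full attention
    matrix is approximated as softmax(QK̃ᵀ) pinv(softmax(Q̃K̃ᵀ)) softmax(Q̃Kᵀ).
    Falls back to exact attention when the sequence is no longer than the
    landmark count.
    """
    n = q.shape[-2]
    if n <= landmarks:
        return exact_attention(q, k, v)
    scale = 1.0 / np.sqrt(q.shape[-1])
    S = Tensor(_landmark_matrix(n, landmarks))
    q_l = S @ q
    k_l = S @ k
    tr = lambda t: t.transpose(*range(t.ndim - 2), t.ndim - 1, t.ndim - 2)
    F1 = ag.softmax((q @ tr(k_l)) * scale, axis=-1)        # (..., n, m)
    A = ag.softmax((q_l @ tr(k_l)) * scale, axis=-1)       # (..., m, m)
    B = ag.softmax((q_l @ tr(k)) * scale, axis=-1)         # (..., m, n)
    return F1 @ (_iterative_pinv(A, pinv_iterations) @ (B @ v))


# ---------------------------------------------------------------------------
# parameterised layers

class _Param(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class _Linear:
    def __init__(self, rng, d_in: int, d_out: int):
        self.w = _Param(rng.normal(0.0, np.sqrt(1.0 / d_in), (d_in, d_out)))
        self.b = _Param(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    def params(self):
        return [self.w, self.b]


class _LayerNorm:
    def __init__(self, dim: int, eps: float = 1e-5):
        self.g = _Param(np.ones(dim))
        self.b = _Param(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.g + self.b

    def params(self):
        return [self.g, self.b]


class _Block:
    """Pre-norm transformer block: Nyström MHSA + GELU MLP, both residual."""

    def __init__(self, rng, cfg: ModelConfig):
        d = cfg.embed_dim
        inner = cfg.n_heads * cfg.head_dim
        self.cfg = cfg
        self.ln1 = _LayerNorm(d)
        self.qkv = _Linear(rng, d, 3 * inner)
        self.proj = _Linear(rng, inner, d)
        self.ln2 = _LayerNorm(d)
        self.fc1 = _Linear(rng, d, cfg.mlp_dim)
        self.fc2 = _Linear(rng, cfg.mlp_dim, d)

    def __call__(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        B, n, _ = x.shape
        h, hd = cfg.n_heads, cfg.head_dim
        qkv = self.qkv(self.ln1(x)).reshape(B, n, 3, h, hd).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]
        att = nystrom_attention(q, k, v, cfg.landmarks, cfg.pinv_iterations)
        att = att.transpose(0, 2, 1, 3).reshape(B, n, h * hd)
        x = x + self.proj(att)
        x = x + self.fc2(ag.gelu(self.fc1(self.ln2(x))))
        return x

    def params(self):
        return (self.ln1.params() + self.qkv.params() + self.proj.params()
                + self.ln2.params() + self.fc1.params() + self.fc2.params())


def _posenc_3d(grid: tuple[int, int, int], dim: int) -> np.ndarray:
    """Fixed sinusoidal positional encoding over a 3D token grid, flattened
    in the same order as the tokens.  Sized per-grid so variable input
    shapes need no learned table."""
    per = dim // 6
    out = np.zeros((*grid, dim), dtype=np.float32)
    offset = 0
    for axis, n in enumerate(grid):
        pos = np.arange(n, dtype=np.float32)
        freq = np.exp(-np.log(100.0) * np.arange(per) / max(per - 1, 1))
        ang = pos[:, None] * freq[None, :]
        sl = [None, None, None]
        sl[axis] = slice(None)
        shape = [1, 1, 1, per]
        shape[axis] = n
        out[..., offset:offset + per] += np.sin(ang).reshape(shape)
        out[..., offset + per:offset + 2 * per] += np.cos(ang).reshape(shape)
        offset += 2 * per
    return out.reshape(-1, dim)


class CompletionModel:
    """The full volumetric completion network."""

    N_SCALES = 2  # dilations used by the scale-equivariant stem

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        k = 3
        self.stem_w = _Param(rng.normal(0.0, np.sqrt(2.0 / (2 * k**3)),
                                        (cfg.conv_channels, 2, k, k, k)))
        self.stem_b = _Param(np.zeros(cfg.conv_channels))
        p3 = cfg.patch ** 3
        self.embed = _Linear(rng, cfg.conv_channels * p3, cfg.embed_dim)
        self.blocks = [_Block(rng, cfg) for _ in range(cfg.n_layers)]
        self.downs = {i: _Linear(rng, cfg.embed_dim * p3, cfg.embed_dim)
                      for i in cfg.downsample_after}
        self.ups = {i: _Linear(rng, cfg.embed_dim, cfg.embed_dim * p3)
                    for i in cfg.upsample_after}
        self.ln_out = _LayerNorm(cfg.embed_dim)
        self.head = _Linear(rng, cfg.embed_dim, p3)

    def params(self) -> list[Tensor]:
        out = [self.stem_w, self.stem_b] + self.embed.params()
        for b in self.blocks:
            out += b.params()
        for lin in list(self.downs.values()) + list(self.ups.values()):
            out += lin.params()
        out += self.ln_out.params() + self.head.params()
        return out

    # -- token-grid reshapes ----------------------------------------------
    @staticmethod
    def _to_blocks(x: Tensor, grid, f: int) -> Tensor:
        """(B, g1*g2*g3, d) tokens -> (B, (g/f)^3 tokens, d*f^3)."""
        B, _, d = x.shape
        g1, g2, g3 = grid
        x = x.reshape(B, g1 // f, f, g2 // f, f, g3 // f, f, d)
        x = x.transpose(0, 1, 3, 5, 2, 4, 6, 7)
        return x.reshape(B, (g1 // f) * (g2 // f) * (g3 // f), f * f * f * d)

    @staticmethod
    def _from_blocks(x: Tensor, grid, f: int, d_out: int) -> Tensor:
        """Inverse of _to_blocks: (B, G^3, d_out*f^3) -> (B, (G*f)^3, d_out)."""
        B = x.shape[0]
        g1, g2, g3 = grid
        x = x.reshape(B, g1, g2, g3, f, f, f, d_out)
        x = x.transpose(0, 1, 4, 2, 5, 3, 6, 7)
        return x.reshape(B, g1 * f * g2 * f * g3 * f, d_out)

    def _stem(self, x: Tensor) -> Tensor:
        y = ag.conv3d(x, self.stem_w, self.stem_b)
        if self.cfg.scale_equivariant:
            # shared weights applied at a coarser scale; max over scales
            for dil in range(2, self.N_SCALES + 1):
                y = ag.maximum(y, ag.conv3d(x, self.stem_w, self.stem_b, dilation=dil))
        return y

    def forward(self, patterson: np.ndarray | MapGrid,
                partial: np.ndarray | MapGrid) -> Tensor:
        """Predict a density volume from a (patterson, template) pair.

        Accepts single volumes (D, H, W) or batches (B, D, H, W); returns a
        Tensor of the same shape as the input.
        """
        pv = patterson.values if isinstance(patterson, MapGrid) else np.asarray(patterson)
        tv = partial.values if isinstance(partial, MapGrid) else np.asarray(partial)
        if pv.shape != tv.shape:
            raise ValueError("patterson/template shapes differ")
        squeeze = pv.ndim == 3
        if squeeze:
            pv, tv = pv[None], tv[None]
        B, D, H, W = pv.shape
        cfg = self.cfg
        m = cfg.divisor
        pads = []
        for n in (D, H, W):
            total = (-n) % m
            pads.append((total // 2, total - total // 2))  # centered reflection pad
        x = Tensor(np.stack([pv, tv], axis=1).astype(np.float32))
        x = ag.pad_reflect3d(x, tuple(pads))
        x = self._stem(x)
        _, C, Dp, Hp, Wp = x.shape
        f = cfg.patch
        grid = (Dp // f, Hp // f, Wp // f)
        # patchify: channels-last blocks -> tokens
        x = x.transpose(0, 2, 3, 4, 1).reshape(B, Dp * Hp * Wp, C)
        x = self._to_blocks(x, (Dp, Hp, Wp), f)
        x = self.embed(x)
        x = x + Tensor(_posenc_3d(grid, cfg.embed_dim))
        for i, block in enumerate(self.blocks, start=1):
            x = block(x)
            if i in self.downs:
                x = self.downs[i](self._to_blocks(x, grid, f))
                grid = tuple(g // f for g in grid)
            if i in self.ups:
                coarse = grid
                x = self._from_blocks(self.ups[i](x), coarse, f, cfg.embed_dim)
                grid = tuple(g * f for g in grid)
        x = self.head(self.ln_out(x))  # (B, tokens, patch^3)
        x = self._from_blocks(x, grid, f, 1).reshape(B, Dp, Hp, Wp)
        out = x[:, pads[0][0]:pads[0][0] + D, pads[1][0]:pads[1][0] + H,
                pads[2][0]:pads[2][0] + W]
        if squeeze:
            out = out.reshape(D, H, W)
        return out


# ---------------------------------------------------------------------------
# loss

def loss(pred: Tensor, truth: np.ndarray | MapGrid, pc_weight: float = 1.0) -> Tensor:
    """MSE plus ``pc_weight`` times the negative Pearson correlation."""
    tv = truth.values if isinstance(truth, MapGrid) else np.asarray(truth)
    if pred.shape != tv.shape:
        raise ValueError("prediction/truth shapes differ")
    t = Tensor(tv.astype(np.float32))
    diff = pred - t
    mse = (diff * diff).mean()
    if pc_weight == 0.0:
        return mse
    if tv.std() == 0:
        warnings.warn("zero-variance truth: Pearson loss term skipped")
        return mse
    pc = pred.mean()
    pcen = pred - pc
    tcen = t - t.mean()
    r = (pcen * tcen).sum() / (((pcen * pcen).sum() * (tcen * tcen).sum()).sqrt() + 1e-12)
    return mse + pc_weight * (-r)


# ---------------------------------------------------------------------------
# optimiser and training

class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params: list[Tensor], cfg: TrainConfig):
        self.params = params
        self.cfg = cfg
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        b1, b2 = self.cfg.betas
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mh = m / (1 - b1**self.t)
            vh = v / (1 - b2**self.t)
            p.data -= lr * (mh / (np.sqrt(vh) + 1e-8) + self.cfg.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


@dataclass
class TrainHistory:
    steps: list[int] = field(default_factory=list)
    lrs: list[float] = field(default_factory=list)
    losses: list[float] = field(default_factory=list)


def train_toy(batches: list[list[tuple[np.ndarray, np.ndarray, np.ndarray]]],
              model: CompletionModel, cfg: TrainConfig,
              max_steps: int | None = None,
              stop_fn=None) -> TrainHistory:
    """Train on a toy dataset.

    ``batches`` is a list of same-shape batches; each entry is a tuple of
    (patterson, template, truth) volumes.  One optimiser step is taken per
    ``cfg.grad_accumulation`` batches.  ``stop_fn(model, step)`` may end
    training early (used by overfitting-capacity checks).
    """
    if not batches:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(model.params(), cfg)
    steps_per_epoch = max(1, len(batches) // cfg.grad_accumulation)
    total_steps = max_steps if max_steps is not None else cfg.epochs * steps_per_epoch
    hist = TrainHistory()
    step = 0
    opt.zero_grad()
    n_accum = 0
    acc_loss = 0.0
    while step < total_steps:
        for batch in (batches[i] for i in rng.permutation(len(batches))):
            pat = np.stack([b[0] for b in batch])
            tpl = np.stack([b[1] for b in batch])
            tru = np.stack([b[2] for b in batch])
            pred = model.forward(pat, tpl)
            l = loss(pred, tru, model.cfg.pc_loss_weight) * (1.0 / cfg.grad_accumulation)
            l.backward()
            acc_loss += float(l.data)
            n_accum += 1
            if n_accum == cfg.grad_accumulation:
                lr = one_cycle_lr(step, total_steps, cfg)
                opt.step(lr)
                opt.zero_grad()
                hist.steps.append(step)
                hist.lrs.append(lr)
                hist.losses.append(acc_loss)
                acc_loss = 0.0
                n_accum = 0
                step += 1
                if stop_fn is not None and stop_fn(model, step):
                    return hist
                if step >= total_steps:
                    break
    return hist
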