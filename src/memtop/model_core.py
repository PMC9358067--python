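"""Scoring network and smoothing filter.

The network maps an L x D per-residue feature matrix to L x 5 class scores
with four convolutional layers:

1. pointwise (kernel 1) convolution D -> 64, layer normalization over the
   whole sequence x feature block of the protein, ReLU;
2. + 3. two parallel depthwise convolutions over the 64 channels with kernels
   9 and 21 (roughly the average transmembrane strand and helix lengths),
   each followed by the same normalization and ReLU;
4. the three 64-dim outputs are concatenated into 192 features per residue
   and a pointwise convolution maps them to the 5 class scores (B, H, S, i, o).

A fixed Gaussian filter (sigma 1, 7 taps, i.e. +-3 sigma) then smooths each
score column along the sequence to suppress single-residue peaks, and a
row-wise softmax turns the smoothed scores into class probabilities.

The network is small enough that it is implemented directly in numpy with
analytic gradients (see :func:`loss_and_gradients`); the gradients are
checked against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from scipy.ndimage import convolve1d

from memtop.io_formats import CLASS_ORDER

__all__ = [
    "ModelConfig",
    "ModelParams",
    "init_model",
    "cnn_forward",
    "gaussian_kernel",
    "gaussian_smooth",
    "class_probabilities",
    "predict_probabilities",
    "loss_and_gradients",
    "save_checkpoint",
    "load_checkpoint",
]

_LN_EPS = 1e-5


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; defaults give the full-size model."""

    input_dim: int = 1024
    reduced_dim: int = 64
    kernel_small: int = 9
    kernel_large: int = 21
    n_classes: int = 5
    gaussian_sigma: float = 1.0
    gaussian_size: int = 7
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.input_dim < 1 or self.reduced_dim < 1:
            raise ValueError("input_dim and reduced_dim must be positive")
        if self.kernel_small % 2 == 0 or self.kernel_large % 2 == 0:
            raise ValueError("depthwise kernel sizes must be odd")
        if self.gaussian_size % 2 == 0:
            raise ValueError("gaussian kernel size must be odd")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_classes != len(CLASS_ORDER):
            raise ValueError(f"n_classes must be {len(CLASS_ORDER)} (class order {CLASS_ORDER})")

    @property
    def concat_dim(self) -> int:
        """Width after concatenating the three 64-dim branches."""
        return 3 * self.reduced_dim


@dataclass
class ModelParams:
    """All trainable tensors plus the config and init seed."""

    config: ModelConfig
    seed: int
    tensors: dict[str, np.ndarray] = field(default_factory=dict)

    def items(self) -> Iterator[tuple[str, np.ndarray]]:
        return iter(self.tensors.items())

    def __getitem__(self, key: str) -> np.ndarray:
        return self.tensors[key]

    def copy(self) -> "ModelParams":
        return ModelParams(self.config, self.seed, {k: v.copy() for k, v in self.tensors.items()})


def init_model(config: ModelConfig, seed: int) -> ModelParams:
    """He-style fan-in init for weights, zeros for biases, identity norms."""
    rng = np.random.default_rng(seed)
    C, D = config.reduced_dim, config.input_dim

    def he(shape: tuple[int, ...], fan_in: int) -> np.ndarray:
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

    t = {
        "W1": he((D, C), D),
        "b1": np.zeros(C),
        "g1": np.ones(C),
        "beta1": np.zeros(C),
        "W2": he((C, config.kernel_small), config.kernel_small),
        "b2": np.zeros(C),
        "g2": np.ones(C),
        "beta2": np.zeros(C),
        "W3": he((C, config.kernel_large), config.kernel_large),
        "b3": np.zeros(C),
        "g3": np.ones(C),
        "beta3": np.zeros(C),
        "W4": he((3 * C, config.n_classes), 3 * C),
        "b4": np.zeros(config.n_classes),
    }
    return ModelParams(config, seed, t)


# ---------------------------------------------------------------------------
# primitive layers (each returns a cache for the backward pass)

def _layer_norm(x: np.ndarray, g: np.ndarray, beta: np.ndarray):
    """Normalize jointly over all positions x channels of one protein.

    Per-channel affine scale/shift; statistics over the full L x C block so
    that the normalization sees both the sequence and the feature dimension.
    """
    mu = x.mean()
    var = x.var()
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return xhat * g + beta, (xhat, inv, g)


def _layer_norm_backward(dy: np.ndarray, cache) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=0)
    dbeta = dy.sum(axis=0)
    dxhat = dy * g
    dx = inv * (dxhat - dxhat.mean() - xhat * (dxhat * xhat).mean())
    return dx, dg, dbeta


def _depthwise(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Per-channel 1-D convolution, zero-padded to preserve length.

    ``W`` has shape (C, K): one length-K kernel per channel.
    """
    L, C = x.shape
    K = W.shape[1]
    pad = (K - 1) // 2
    xp = np.zeros((L + 2 * pad, C))
    xp[pad : pad + L] = x
    out = np.empty((L, C))
    out[:] = b
    for j in range(K):
        out += W[:, j] * xp[j : j + L]
    return out, (xp, W, K, pad, L)


def _depthwise_backward(dy: np.ndarray, cache):
    xp, W, K, pad, L = cache
    C = xp.shape[1]
    dW = np.empty((C, K))
    dxp = np.zeros_like(xp)
    for j in range(K):
        dW[:, j] = (dy * xp[j : j + L]).sum(axis=0)
        dxp[j : j + L] += W[:, j] * dy
    return dxp[pad : pad + L], dW, dy.sum(axis=0)


def cnn_forward(
    params: ModelParams,
    x: np.ndarray,
    training: bool = False,
    dropout_seed: int | None = None,
    _cache: dict | None = None,
) -> np.ndarray:
    """Run the four-layer CNN, returning L x 5 class scores.

    With ``training=True`` a single Bernoulli(dropout_rate) channel mask of
    width 192 is drawn per call (seeded by ``dropout_seed``), broadcast over
    all positions, and surviving channels are rescaled (inverted dropout).
    """
    cfg = params.config
    if x.ndim != 2 or x.shape[1] != cfg.input_dim:
        raise ValueError(f"expected L x {cfg.input_dim} input, got shape {x.shape}")
    t = params.tensors

    z1 = x @ t["W1"] + t["b1"]
    n1, ln1 = _layer_norm(z1, t["g1"], t["beta1"])
    a1 = np.maximum(n1, 0.0)

    z2, dw2 = _depthwise(a1, t["W2"], t["b2"])
    n2, ln2 = _layer_norm(z2, t["g2"], t["beta2"])
    a2 = np.maximum(n2, 0.0)

    z3, dw3 = _depthwise(a1, t["W3"], t["b3"])
    n3, ln3 = _layer_norm(z3, t["g3"], t["beta3"])
    a3 = np.maximum(n3, 0.0)

    h = np.concatenate([a1, a2, a3], axis=1)
    mask = None
    if training and cfg.dropout_rate > 0.0:
        drng = np.random.default_rng(dropout_seed)
        keep = 1.0 - cfg.dropout_rate
        mask = (drng.random(cfg.concat_dim) < keep) / keep
        h = h * mask

    scores = h @ t["W4"] + t["b4"]
    if _cache is not None:
        _cache.update(
            x=x, ln1=ln1, n1=n1, dw2=dw2, ln2=ln2, n2=n2,
            dw3=dw3, ln3=ln3, n3=n3, h=h, mask=mask,
        )
    return scores


def _cnn_backward(params: ModelParams, dscores: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
    t = params.tensors
    C = params.config.reduced_dim
    g = {}
    h = cache["h"]
    g["W4"] = h.T @ dscores
    g["b4"] = dscores.sum(axis=0)
    dh = dscores @ t["W4"].T
    if cache["mask"] is not None:
        dh = dh * cache["mask"]
    da1 = dh[:, :C].copy()
    da2 = dh[:, C : 2 * C]
    da3 = dh[:, 2 * C :]

    dn3 = da3 * (cache["n3"] > 0)
    dz3, g["g3"], g["beta3"] = _layer_norm_backward(dn3, cache["ln3"])
    da1_3, g["W3"], g["b3"] = _depthwise_backward(dz3, cache["dw3"])

    dn2 = da2 * (cache["n2"] > 0)
    dz2, g["g2"], g["beta2"] = _layer_norm_backward(dn2, cache["ln2"])
    da1_2, g["W2"], g["b2"] = _depthwise_backward(dz2, cache["dw2"])

    da1 += da1_2 + da1_3
    dn1 = da1 * (cache["n1"] > 0)
    dz1, g["g1"], g["beta1"] = _layer_norm_backward(dn1, cache["ln1"])
    g["W1"] = cache["x"].T @ dz1
    g["b1"] = dz1.sum(axis=0)
    return g


# ---------------------------------------------------------------------------
# Gaussian filter and softmax

def gaussian_kernel(sigma: float = 1.0, size: int = 7) -> np.ndarray:
    """Normalized Gaussian taps w_k ~ exp(-k^2 / 2 sigma^2), k = -h..h."""
    if size % 2 == 0:
        raise ValueError("kernel size must be odd")
    half = (size - 1) // 2
    k = np.arange(-half, half + 1, dtype=float)
    w = np.exp(-(k**2) / (2.0 * sigma**2))
    return w / w.sum()


def gaussian_smooth(scores: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Convolve each class column with the kernel; zero padding at the ends."""
    return convolve1d(scores, kernel, axis=0, mode="constant", cval=0.0)


def class_probabilities(scores: np.ndarray) -> np.ndarray:
    """Row-wise softmax, stabilized by max subtraction."""
    z = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def predict_probabilities(params: ModelParams, x: np.ndarray) -> np.ndarray:
    """CNN (inference mode) -> Gaussian filter -> softmax."""
    cfg = params.config
    kernel = gaussian_kernel(cfg.gaussian_sigma, cfg.gaussian_size)
    return class_probabilities(gaussian_smooth(cnn_forward(params, x), kernel))


# ---------------------------------------------------------------------------
# training loss

def loss_and_gradients(
    params: ModelParams,
    x: np.ndarray,
    targets: np.ndarray,
    dropout_seed: int | None = None,
    training: bool = True,
) -> tuple[float, dict[str, np.ndarray]]:
    """Summed per-residue cross-entropy and its gradients for one protein.

    The Gaussian filter sits inside the trained graph: loss is the
    cross-entropy of softmax(smooth(scores)) against the 5 observable classes
    (orientation case collapsed).  Returns the *sum* over residues so a batch
    can be averaged by total residue count.
    """
    cfg = params.config
    kernel = gaussian_kernel(cfg.gaussian_sigma, cfg.gaussian_size)
    cache: dict = {}
    scores = cnn_forward(params, x, training=training, dropout_seed=dropout_seed, _cache=cache)
    smoothed = gaussian_smooth(scores, kernel)
    probs = class_probabilities(smoothed)
    L = x.shape[0]
    p_true = probs[np.arange(L), targets]
    loss = float(-np.log(np.maximum(p_true, 1e-300)).sum())

    dsmoothed = probs.copy()
    dsmoothed[np.arange(L), targets] -= 1.0
    # adjoint of the smoothing: correlation == convolution for a symmetric kernel
    dscores = gaussian_smooth(dsmoothed, kernel)
    grads = _cnn_backward(params, dscores, cache)
    return loss, grads


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(path: str | Path, params: ModelParams) -> None:
    """Single-file .npz checkpoint: config fields, seed and all tensors."""
    cfg = params.config
    meta = np.array(
        [cfg.input_dim, cfg.reduced_dim, cfg.kernel_small, cfg.kernel_large,
         cfg.n_classes, cfg.gaussian_size, params.seed],
        dtype=np.int64,
    )
    fmeta = np.array([cfg.gaussian_sigma, cfg.dropout_rate])
    np.savez(path, __meta__=meta, __fmeta__=fmeta, **params.tensors)


def load_checkpoint(path: str | Path) -> ModelParams:
    with np.load(path) as data:
        meta = data["__meta__"]
        fmeta = data["__fmeta__"]
        cfg = ModelConfig(
            input_dim=int(meta[0]), reduced_dim=int(meta[1]),
            kernel_small=int(meta[2]), kernel_large=int(meta[3]),
            n_classes=int(meta[4]), gaussian_size=int(meta[5]),
            gaussian_sigma=float(fmeta[0]), dropout_rate=float(fmeta[1]),
        )
        tensors = {k: np.asarray(data[k], dtype=np.float64)
                   for k in data.files if not k.startswith("__")}
    return ModelParams(cfg, int(meta[6]), tensors)
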