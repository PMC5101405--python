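"""Probabilistic max-pooling convolutional restricted Boltzmann machine.

A CRBM is an energy-based generative model of image patches. Real-valued
visible units ``v`` (a small image, possibly multi-channel) connect to
``K`` groups of binary hidden units through shared convolution filters
``W^k``; each group has a scalar bias ``b_k`` and the visible layer a
shared bias ``c``. The energy of a joint configuration is

    E(v, h) = 1/2 sum v_ij^2
              - sum_k sum_ij h_ij^k (Wtilde^k *_v v)_ij
              - sum_k b_k sum_ij h_ij^k
              - c sum_ij v_ij

subject to *probabilistic max-pooling*: within every C x C block of each
hidden group at most one unit may be on, and a pooling unit p_a^k is on
iff some unit in its block is on. Conditioned on the visible layer this
constraint turns each block into a (C^2 + 1)-way softmax over "which unit
fires (or none)", which is what makes exact block-wise Gibbs sampling and
deterministic probability propagation possible.

Training is contrastive divergence with one Gibbs reconstruction (CD-1)
plus a sparsity penalty that pushes each group's mean activation toward a
small target, preventing the overcomplete filter bank from learning
trivial copies of the input.

Conventions: a visible patch is an ``(n_v, n_v, C)`` float array
(single-channel inputs may be passed as ``(n_v, n_v)``); a batch stacks
patches along a leading axis. Filters are ``(K, n_w, n_w, C)``. The hidden
grid side is ``n_h = n_v - n_w + 1`` and must be divisible by the pooling
block size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "CRBMLayer",
    "HiddenState",
    "TrainingTrace",
    "CRBMGradients",
    "TrainingDivergedError",
    "init_layer",
    "standardize_patch",
    "energy",
    "hidden_conditionals",
    "sample_hidden",
    "visible_conditionals",
    "pooled_representation",
    "cd1_gradient",
    "train_layer",
    "ConvRBM",
]


class TrainingDivergedError(RuntimeError):
    """CD training produced non-finite parameters."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite parameters at epoch {epoch}")


@dataclass
class CRBMLayer:
    """Parameters of one filter-bank + pooling stage.

    Attributes
    ----------
    weights : (K, n_w, n_w, C) array
        Convolution filters W^k.
    hidden_bias : (K,) array
        Per-group hidden biases b_k.
    visible_bias : float
        Shared visible bias c.
    pool_size : int
        Side C of the pooling blocks.
    sparsity_target : float
        Desired mean hidden activation, in (0, 1).
    """

    weights: np.ndarray
    hidden_bias: np.ndarray
    visible_bias: float
    pool_size: int = 2
    sparsity_target: float = 0.003

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.hidden_bias = np.asarray(self.hidden_bias, dtype=np.float64)
        if self.weights.ndim == 3:  # single channel without axis
            self.weights = self.weights[..., None]
        if self.weights.ndim != 4:
            raise ValueError("weights must be (K, n_w, n_w, C)")
        if self.weights.shape[1] != self.weights.shape[2]:
            raise ValueError("filters must be square")
        if self.hidden_bias.shape != (self.weights.shape[0],):
            raise ValueError("hidden_bias must have one entry per filter")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if not (0.0 < self.sparsity_target < 1.0):
            raise ValueError("sparsity_target must lie in (0, 1)")

    @property
    def n_filters(self) -> int:
        return self.weights.shape[0]

    @property
    def filter_size(self) -> int:
        return self.weights.shape[1]

    @property
    def in_channels(self) -> int:
        return self.weights.shape[3]

    def hidden_side(self, n_v: int) -> int:
        """Hidden grid side for an n_v x n_v input; checks pooling divisibility."""
        n_h = n_v - self.filter_size + 1
        if n_h < 1:
            raise ValueError(
                f"input side {n_v} smaller than filter size {self.filter_size}"
            )
        if n_h % self.pool_size:
            raise ValueError(
                f"hidden side {n_h} (= {n_v} - {self.filter_size} + 1) "
                f"not divisible by pool_size {self.pool_size}"
            )
        return n_h

    def output_side(self, n_v: int) -> int:
        return self.hidden_side(n_v) // self.pool_size

    def copy(self) -> "CRBMLayer":
        return CRBMLayer(
            self.weights.copy(),
            self.hidden_bias.copy(),
            float(self.visible_bias),
            self.pool_size,
            self.sparsity_target,
        )

    def to_single_channel(self) -> "CRBMLayer":
        """Average filters over input channels (RGB-pretrained -> grayscale)."""
        out = self.copy()
        out.weights = self.weights.mean(axis=3, keepdims=True)
        return out


@dataclass
class HiddenState:
    """A joint configuration of hidden and pooling units.

    ``hidden`` is binary (n_h, n_h, K); ``pooling`` is binary
    (n_h/C, n_h/C, K) with p_a^k = 1 iff some unit in block a fires.
    """

    hidden: np.ndarray
    pooling: np.ndarray
    pool_size: int

    def validate(self) -> None:
        C = self.pool_size
        h = np.asarray(self.hidden)
        blocks = _block_view(h[None], C)[0]  # (nP, nP, K, C*C)
        counts = blocks.sum(axis=-1)
        if np.any(counts > 1):
            raise ValueError("block constraint violated: >1 active unit in a block")
        if not np.array_equal(counts > 0, np.asarray(self.pooling).astype(bool)):
            raise ValueError("pooling units inconsistent with hidden units")


@dataclass
class TrainingTrace:
    """Per-epoch CD training diagnostics."""

    reconstruction_error: list = field(default_factory=list)
    mean_activation: list = field(default_factory=list)  # (K,) per epoch
    hyperparameters: dict = field(default_factory=dict)


@dataclass
class CRBMGradients:
    """Ascent increments for one CD-1 minibatch."""

    weights: np.ndarray
    hidden_bias: np.ndarray
    visible_bias: float
    reconstruction_error: float
    mean_activation: np.ndarray  # per-group mean P(h=1|v) on the data


# ---------------------------------------------------------------------------
# shape helpers

def _as_batch(v: np.ndarray) -> tuple[np.ndarray, bool]:
    v = np.asarray(v, dtype=np.float64)
    if v.ndim == 2:
        v = v[:, :, None]
    if v.ndim == 3:
        return v[None], True
    if v.ndim == 4:
        return v, False
    raise ValueError("patch must be (H, W), (H, W, C) or (N, H, W, C)")


def _block_view(a: np.ndarray, C: int) -> np.ndarray:
    """(N, n_h, n_h, K) -> (N, nP, nP, K, C*C) without copying rows of blocks."""
    N, nh, _, K = a.shape
    nP = nh // C
    b = a.reshape(N, nP, C, nP, C, K)
    return b.transpose(0, 1, 3, 5, 2, 4).reshape(N, nP, nP, K, C * C)


def _unblock(b: np.ndarray, C: int) -> np.ndarray:
    """Inverse of :func:`_block_view`."""
    N, nP, _, K, _ = b.shape
    a = b.reshape(N, nP, nP, K, C, C).transpose(0, 1, 4, 2, 5, 3)
    return a.reshape(N, nP * C, nP * C, K)


def _windows(V: np.ndarray, n_w: int) -> np.ndarray:
    """im2col: (N, n_v, n_v, C) -> (N, n_h, n_h, n_w*n_w*C)."""
    w = sliding_window_view(V, (n_w, n_w), axis=(1, 2))  # (N, nh, nh, C, nw, nw)
    w = w.transpose(0, 1, 2, 4, 5, 3)  # (N, nh, nh, nw, nw, C)
    N, nh = w.shape[0], w.shape[1]
    return w.reshape(N, nh, nh, -1)


def bottom_up_input(V: np.ndarray, layer: CRBMLayer) -> np.ndarray:
    """Pre-softmax hidden input I(h^k) = (Wtilde^k *_v v) + b_k, batched.

    The valid convolution with the 180-degree-flipped filter equals the
    valid cross-correlation with the filter itself, which is what the
    im2col product computes.
    """
    V, _ = _as_batch(V)
    if V.shape[3] != layer.in_channels:
        raise ValueError(
            f"patch has {V.shape[3]} channels, layer expects {layer.in_channels}"
        )
    layer.hidden_side(V.shape[1])
    cols = _windows(V, layer.filter_size)
    Wmat = layer.weights.reshape(layer.n_filters, -1).T  # (nw*nw*C, K)
    return cols @ Wmat + layer.hidden_bias


def standardize_patch(patch: np.ndarray, eps: float = 1e-8):
    """Zero-mean unit-variance normalization of one patch (all channels jointly).

    Returns ``(standardized, mean, std)``; a constant patch maps to zeros.
    """
    p = np.asarray(patch, dtype=np.float64)
    if p.ndim == 2:
        p = p[:, :, None]
    mu = float(p.mean())
    sd = float(p.std())
    if sd < eps:
        return np.zeros_like(p), mu, sd
    return (p - mu) / sd, mu, sd


# ---------------------------------------------------------------------------
# core operations

def energy(v: np.ndarray, h: HiddenState | np.ndarray, layer: CRBMLayer) -> float:
    """Energy E(v, h) of a joint configuration; channels are summed over."""
    V, _ = _as_batch(v)
    hid = h.hidden if isinstance(h, HiddenState) else np.asarray(h, dtype=np.float64)
    if isinstance(h, HiddenState):
        h.validate()
    else:
        HiddenState(
            hid,
            _block_view(hid[None], layer.pool_size)[0].sum(-1) > 0,
            layer.pool_size,
        ).validate()
    I0 = bottom_up_input(V, layer)[0] - layer.hidden_bias  # interaction only
    if hid.shape != I0.shape:
        raise ValueError(f"hidden shape {hid.shape} incompatible with {I0.shape}")
    quad = 0.5 * float((V**2).sum())
    inter = float((hid * I0).sum())
    hbias = float((layer.hidden_bias * hid.sum(axis=(0, 1))).sum())
    vbias = layer.visible_bias * float(V.sum())
    return quad - inter - hbias - vbias


def hidden_conditionals(v: np.ndarray, layer: CRBMLayer):
    """Exact block-softmax conditionals P(h|v) and P(p=0|v).

    Returns ``(unit_probs, pool_off_probs)`` with shapes (n_h, n_h, K) and
    (n_h/C, n_h/C, K). Within every block the probabilities of the C^2
    unit-on outcomes and the all-off outcome sum to one. Computed with a
    per-block log-sum-exp shift, so any constant added to a block's inputs
    leaves the result unchanged.
    """
    V, single = _as_batch(v)
    up, off = _conditionals_from_input(bottom_up_input(V, layer), layer.pool_size)
    return (up[0], off[0]) if single else (up, off)


def _conditionals_from_input(I: np.ndarray, C: int):
    Ib = _block_view(I, C)  # (N, nP, nP, K, C*C)
    m = np.maximum(Ib.max(axis=-1, keepdims=True), 0.0)
    e = np.exp(Ib - m)
    off = np.exp(-m)  # the implicit 0 logit of "no unit fires"
    denom = off + e.sum(axis=-1, keepdims=True)
    up = _unblock(e / denom, C)
    return up, (off / denom)[..., 0]


def sample_hidden(unit_probs: np.ndarray, pool_off_probs: np.ndarray,
                  rng: np.random.Generator, pool_size: int | None = None) -> HiddenState:
    """Draw a joint hidden/pooling configuration, one categorical per block."""
    up = np.asarray(unit_probs, dtype=np.float64)
    off = np.asarray(pool_off_probs, dtype=np.float64)
    if pool_size is None:
        pool_size = up.shape[0] // off.shape[0]
    C = pool_size
    blocks = _block_view(up[None], C)[0]  # (nP, nP, K, C*C)
    probs = np.concatenate([blocks, off[..., None]], axis=-1)
    cum = np.cumsum(probs, axis=-1)
    u = rng.random(off.shape)
    idx = (u[..., None] < cum).argmax(axis=-1)  # winning outcome per block
    onehot = np.eye(C * C + 1)[idx][..., : C * C]
    hidden = _unblock(onehot[None], C)[0]
    pooling = (idx < C * C).astype(np.float64)
    return HiddenState(hidden=hidden, pooling=pooling, pool_size=C)


def visible_conditionals(h: HiddenState | np.ndarray, layer: CRBMLayer) -> np.ndarray:
    """Gaussian mean of P(v|h): sum_k (W^k *_f h^k) + c (unit variance)."""
    hid = h.hidden if isinstance(h, HiddenState) else np.asarray(h, dtype=np.float64)
    single = hid.ndim == 3
    H = hid[None] if single else hid
    mean = _top_down(H, layer) + layer.visible_bias
    return mean[0] if single else mean


def _top_down(H: np.ndarray, layer: CRBMLayer) -> np.ndarray:
    """Full convolution sum_k W^k *_f h^k, batched: (N,nh,nh,K)->(N,nv,nv,C)."""
    N, nh = H.shape[0], H.shape[1]
    nw, C = layer.filter_size, layer.in_channels
    nv = nh + nw - 1
    out = np.zeros((N, nv, nv, C))
    W = layer.weights  # (K, nw, nw, C)
    for r in range(nw):
        for s in range(nw):
            out[:, r : r + nh, s : s + nh, :] += H @ W[:, r, s, :]
    return out


def pooled_representation(v: np.ndarray, layer: CRBMLayer) -> np.ndarray:
    """Deterministic pooling-unit activations P(p_a^k = 1 | v) = 1 - P(p=0|v).

    This is what feeds the next stage: a (n_h/C, n_h/C, K) grid of values
    in (0, 1).
    """
    V, single = _as_batch(v)
    _, off = _conditionals_from_input(bottom_up_input(V, layer), layer.pool_size)
    pon = 1.0 - off
    return pon[0] if single else pon


def cd1_gradient(batch, layer: CRBMLayer, sparsity_weight: float,
                 rng: np.random.Generator) -> CRBMGradients:
    """CD-1 ascent increments for W^k, b_k, c on one minibatch.

    Positive phase: exact conditionals on the data. Negative phase: sample
    the hidden layer, take the Gaussian reconstruction mean, recompute
    conditionals. Gradients are averaged per hidden position so the
    learning rate is independent of patch size. The sparsity term is the
    descent direction of lambda * (target - mean_activation)^2 applied to
    b_k and, through the mean receptive field, to W^k.
    """
    if isinstance(batch, (list, tuple)):
        if len(batch) == 0:
            raise ValueError("empty batch")
        V = np.stack([np.atleast_3d(np.asarray(p, dtype=np.float64)) for p in batch])
    else:
        V = _as_batch(batch)[0]
    if V.shape[0] == 0:
        raise ValueError("empty batch")
    N = V.shape[0]
    nw = layer.filter_size
    nh = layer.hidden_side(V.shape[1])
    n_pos = nh * nh
    C = layer.pool_size

    cols = _windows(V, nw)  # (N, nh, nh, nw*nw*Cc)
    Wmat = layer.weights.reshape(layer.n_filters, -1).T
    I = cols @ Wmat + layer.hidden_bias
    up_pos, off_pos = _conditionals_from_input(I, C)

    # one Gibbs step: sample h | v, reconstruct mean v' | h, infer h | v'
    blocks = _block_view(up_pos, C)
    probs = np.concatenate([blocks, off_pos[..., None]], axis=-1)
    cum = np.cumsum(probs, axis=-1)
    u = rng.random(off_pos.shape)
    idx = (u[..., None] < cum).argmax(axis=-1)
    onehot = np.eye(C * C + 1)[idx][..., : C * C]
    Hs = _unblock(onehot, C)
    Vneg = _top_down(Hs, layer) + layer.visible_bias
    cols_neg = _windows(Vneg, nw)
    up_neg, _ = _conditionals_from_input(cols_neg @ Wmat + layer.hidden_bias, C)

    up_pos_f = up_pos.reshape(N * n_pos, -1)
    up_neg_f = up_neg.reshape(N * n_pos, -1)
    cols_f = cols.reshape(N * n_pos, -1)
    cols_neg_f = cols_neg.reshape(N * n_pos, -1)
    scale = 1.0 / (N * n_pos)
    gW = (up_pos_f.T @ cols_f - up_neg_f.T @ cols_neg_f) * scale
    gW = gW.reshape(layer.weights.shape)
    gb = (up_pos_f.sum(0) - up_neg_f.sum(0)) * scale
    gc = float((V - Vneg).mean())

    q = up_pos_f.mean(axis=0)  # per-group mean activation on the data
    mean_rf = cols_f.mean(axis=0).reshape(1, nw, nw, layer.in_channels)
    gap = layer.sparsity_target - q
    gb = gb + sparsity_weight * gap
    gW = gW + sparsity_weight * gap[:, None, None, None] * mean_rf

    rerr = float(((V - Vneg) ** 2).mean())
    return CRBMGradients(gW, gb, gc, rerr, q)


def train_layer(data, layer: CRBMLayer, *, n_epochs: int = 50,
                learning_rate: float = 0.05, momentum: float = 0.5,
                batch_size: int = 64, sparsity_weight: float = 50.0,
                rng: np.random.Generator | None = None,
                shuffle: bool = True) -> tuple[CRBMLayer, TrainingTrace]:
    """Minibatch CD-1 with momentum; returns a trained copy and its trace."""
    rng = np.random.default_rng() if rng is None else rng
    V, _ = _as_batch(np.stack([np.atleast_3d(np.asarray(p)) for p in data])
                     if isinstance(data, (list, tuple)) else data)
    layer = layer.copy()
    trace = TrainingTrace(hyperparameters=dict(
        n_epochs=n_epochs, learning_rate=learning_rate, momentum=momentum,
        batch_size=batch_size, sparsity_weight=sparsity_weight,
        sparsity_target=layer.sparsity_target,
    ))
    vel_W = np.zeros_like(layer.weights)
    vel_b = np.zeros_like(layer.hidden_bias)
    vel_c = 0.0
    N = V.shape[0]
    for epoch in range(n_epochs):
        order = rng.permutation(N) if shuffle else np.arange(N)
        errs, acts = [], []
        for start in range(0, N, batch_size):
            mb = V[order[start : start + batch_size]]
            g = cd1_gradient(mb, layer, sparsity_weight, rng)
            vel_W = momentum * vel_W + g.weights
            vel_b = momentum * vel_b + g.hidden_bias
            vel_c = momentum * vel_c + g.visible_bias
            layer.weights += learning_rate * vel_W
            layer.hidden_bias += learning_rate * vel_b
            layer.visible_bias += learning_rate * vel_c
            errs.append(g.reconstruction_error)
            acts.append(g.mean_activation)
        if not (np.isfinite(layer.weights).all()
                and np.isfinite(layer.hidden_bias).all()
                and np.isfinite(layer.visible_bias)):
            raise TrainingDivergedError(epoch)
        trace.reconstruction_error.append(float(np.mean(errs)))
        trace.mean_activation.append(np.mean(acts, axis=0))
    return layer, trace


def init_layer(n_filters: int, filter_size: int, in_channels: int = 1,
               pool_size: int = 2, sparsity_target: float = 0.003,
               weight_scale: float = 0.01,
               rng: np.random.Generator | None = None) -> CRBMLayer:
    """Gaussian(0, weight_scale) filters, zero biases."""
    rng = np.random.default_rng() if rng is None else rng
    W = rng.normal(0.0, weight_scale, size=(n_filters, filter_size, filter_size, in_channels))
    return CRBMLayer(W, np.zeros(n_filters), 0.0, pool_size, sparsity_target)


# ---------------------------------------------------------------------------
# sklearn-style estimator

class ConvRBM(TransformerMixin, BaseEstimator):
    """Probabilistic max-pooling CRBM as a scikit-learn transformer.

    ``fit`` trains the filter bank with sparsity-regularized CD-1;
    ``transform`` maps patches to their deterministic pooled activations
    P(p=1|v), the representation consumed by a stacked next layer.

    Parameters
    ----------
    n_filters : number of filter groups K.
    filter_size : side of the square filters.
    pool_size : pooling block side C.
    sparsity_target : desired mean hidden activation.
    sparsity_weight : strength of the sparsity penalty.
    learning_rate, momentum, n_epochs, batch_size : SGD settings.
    weight_scale : std of the Gaussian filter initialization.
    random_state : int seed or Generator.
    """

    def __init__(self, n_filters=8, filter_size=5, pool_size=2,
                 sparsity_target=0.003, sparsity_weight=50.0,
                 learning_rate=0.05, momentum=0.5, n_epochs=50,
                 batch_size=64, weight_scale=0.01, random_state=None):
        self.n_filters = n_filters
        self.filter_size = filter_size
        self.pool_size = pool_size
        self.sparsity_target = sparsity_target
        self.sparsity_weight = sparsity_weight
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.weight_scale = weight_scale
        self.random_state = random_state

    def _rng(self):
        rs = self.random_state
        return rs if isinstance(rs, np.random.Generator) else np.random.default_rng(rs)

    def fit(self, X, y=None):
        V, _ = _as_batch(X)
        rng = self._rng()
        layer = init_layer(self.n_filters, self.filter_size, V.shape[3],
                           self.pool_size, self.sparsity_target,
                           self.weight_scale, rng)
        self.layer_, self.trace_ = train_layer(
            V, layer, n_epochs=self.n_epochs, learning_rate=self.learning_rate,
            momentum=self.momentum, batch_size=self.batch_size,
            sparsity_weight=self.sparsity_weight, rng=rng)
        return self

    def transform(self, X):
        V, _ = _as_batch(X)
        return pooled_representation(V, self.layer_)


# ---------------------------------------------------------------------------
# serialization (shared with the CDBN container)

def layer_to_arrays(layer: CRBMLayer, prefix: str) -> tuple[dict, dict]:
    arrays = {
        f"{prefix}weights": layer.weights,
        f"{prefix}hidden_bias": layer.hidden_bias,
    }
    header = {
        "visible_bias": layer.visible_bias,
        "pool_size": layer.pool_size,
        "sparsity_target": layer.sparsity_target,
    }
    return arrays, header


def layer_from_arrays(arrays, header: dict, prefix: str) -> CRBMLayer:
    return CRBMLayer(
        np.asarray(arrays[f"{prefix}weights"]),
        np.asarray(arrays[f"{prefix}hidden_bias"]),
        float(header["visible_bias"]),
        int(header["pool_size"]),
        float(header["sparsity_target"]),
    )


def save_layer(layer: CRBMLayer, path) -> None:
    """Single-file container: named arrays + JSON architecture header."""
    arrays, header = layer_to_arrays(layer, "layer0_")
    np.savez(path, __header__=np.frombuffer(
        json.dumps({"kind": "crbm_layer", "layer0": header}).encode(), dtype=np.uint8),
        **arrays)


def load_layer(path) -> CRBMLayer:
    with np.load(path) as z:
        header = json.loads(bytes(z["__header__"]).decode())
        return layer_from_arrays(z, header["layer0"], "layer0_")
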