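"""Convolutional deep belief network with a discriminative head.

Stacked probabilistic max-pooling CRBMs, greedily pretrained layer by
layer, feed a fully connected logistic layer (FC3) and an output layer.
The default architecture mirrors the tracker's appearance model: 32x32
input -> CRBM1 (12 filters, 5x5, pool 2) -> CRBM2 (288 filters, 7x7,
pool 2) -> FC3 with 192 logistic units -> 10-way softmax output, i.e. the
spatial chain 32 -> 28 -> 14 -> 8 -> 4. For transfer to a tracking task
the 10-unit output is removed and replaced by a single logistic unit that
scores a patch as target-vs-background; every other parameter is kept
bit-exactly and the whole stack is then fine-tuned on tracking samples.

The discriminative forward pass propagates the exact block-softmax
pooling probabilities P(p=1|v) as deterministic differentiable
activations (no sampling), which makes end-to-end gradient fine-tuning
possible; the backward pass uses the closed form
d P(p=1)/d I_ij = P(h_ij=1) * P(p=0).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .crbm import (
    CRBMLayer,
    _as_batch,
    _block_view,
    _conditionals_from_input,
    _unblock,
    _windows,
    init_layer,
    layer_from_arrays,
    layer_to_arrays,
    standardize_patch,
    train_layer,
)

__all__ = ["ARCHITECTURES", "CDBNClassifier", "build_architecture",
           "save_model", "load_model"]

# Named presets. "full" is the reference architecture; "reduced" keeps the
# same topology at a size suitable for desk-scale experiments; "tiny" is
# for fast unit tests.
ARCHITECTURES = {
    "full": dict(
        layers=[
            dict(n_filters=12, filter_size=5, pool_size=2, sparsity_target=0.003),
            dict(n_filters=288, filter_size=7, pool_size=2, sparsity_target=0.005),
        ],
        fc_units=192,
        n_out=10,
    ),
    "reduced": dict(
        layers=[
            dict(n_filters=8, filter_size=5, pool_size=2, sparsity_target=0.003),
            dict(n_filters=32, filter_size=7, pool_size=2, sparsity_target=0.005),
        ],
        fc_units=64,
        n_out=10,
    ),
    "tiny": dict(
        layers=[
            dict(n_filters=4, filter_size=5, pool_size=2, sparsity_target=0.02),
            dict(n_filters=8, filter_size=7, pool_size=2, sparsity_target=0.02),
        ],
        fc_units=16,
        n_out=10,
    ),
}


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z):
    m = z.max(axis=1, keepdims=True)
    e = np.exp(z - m)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class _TrainLog:
    loss: list = field(default_factory=list)
    accuracy: list = field(default_factory=list)


class CDBNClassifier(ClassifierMixin, BaseEstimator):
    """CDBN appearance/classification model, scikit-learn style.

    ``fit(X, y)`` performs greedy layer-wise CRBM pretraining followed by
    supervised training of the fully connected head; ``predict_proba``
    runs the deterministic forward pass. Beyond the sklearn surface the
    model exposes ``transfer_output`` (swap the class head for a one-unit
    confidence head, preserving all features), ``finetune`` (end-to-end
    supervised gradient descent) and ``confidence`` (the scalar logistic
    score used as a tracking likelihood).

    Parameters
    ----------
    architecture : str or dict
        A preset name from :data:`ARCHITECTURES` or an explicit dict with
        keys ``layers`` (list of CRBM layer specs), ``fc_units``, ``n_out``.
    input_size, channels : input patch geometry (default 32x32, 1 channel).
    crbm_epochs, crbm_learning_rate, sparsity_weight : greedy stage.
    head_epochs : supervised epochs for the FC head during pretraining.
    learning_rate, momentum, batch_size : supervised SGD settings
        (defaults 0.1 / 0.5 / 64, shared by head training and finetuning).
    random_state : int seed or Generator.
    """

    def __init__(self, architecture="full", input_size=32, channels=1,
                 crbm_epochs=30, crbm_learning_rate=0.05, sparsity_weight=50.0,
                 head_epochs=500, learning_rate=0.1, momentum=0.5,
                 batch_size=64, weight_scale=0.01, random_state=None):
        self.architecture = architecture
        self.input_size = input_size
        self.channels = channels
        self.crbm_epochs = crbm_epochs
        self.crbm_learning_rate = crbm_learning_rate
        self.sparsity_weight = sparsity_weight
        self.head_epochs = head_epochs
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.batch_size = batch_size
        self.weight_scale = weight_scale
        self.random_state = random_state

    # -- construction ------------------------------------------------------

    def _arch_spec(self) -> dict:
        if isinstance(self.architecture, str):
            try:
                return ARCHITECTURES[self.architecture]
            except KeyError:
                raise ValueError(
                    f"unknown architecture {self.architecture!r}; "
                    f"known presets: {sorted(ARCHITECTURES)}") from None
        return dict(self.architecture)

    def _rng(self):
        rs = self.random_state
        return rs if isinstance(rs, np.random.Generator) else np.random.default_rng(rs)

    def build(self, rng: np.random.Generator | None = None) -> "CDBNClassifier":
        """Initialize all parameters randomly without training.

        Validates the dimensional chain (every hidden grid must divide the
        pooling block size) and sets the fitted attributes, so the forward
        pass is usable immediately.
        """
        rng = self._rng() if rng is None else rng
        spec = self._arch_spec()
        layers: list[CRBMLayer] = []
        side = self.input_size
        ch = self.channels
        self.sides_ = [side]
        for i, ls in enumerate(spec["layers"]):
            layer = init_layer(ls["n_filters"], ls["filter_size"], ch,
                               ls.get("pool_size", 2),
                               ls.get("sparsity_target", 0.003),
                               self.weight_scale, rng)
            try:
                nh = layer.hidden_side(side)
            except ValueError as e:
                raise ValueError(f"layer {i + 1}: {e}") from None
            side = nh // layer.pool_size
            self.sides_.extend([nh, side])
            ch = layer.n_filters
            layers.append(layer)
        self.layers_ = layers
        n_feat = side * side * ch
        fc = int(spec["fc_units"])
        n_out = int(spec["n_out"])
        self.fc_w_ = rng.normal(0.0, self.weight_scale, size=(n_feat, fc))
        self.fc_b_ = np.zeros(fc)
        self.out_w_ = rng.normal(0.0, self.weight_scale, size=(fc, n_out))
        self.out_b_ = np.zeros(n_out)
        self.n_out_ = n_out
        self.n_features_ = n_feat
        # per-layer affine rescaling of the pooled output, frozen during
        # pretraining so every CRBM (and the FC head) sees roughly
        # zero-mean unit-variance input, as the Gaussian-visible energy
        # assumes; identity until fit
        self.feature_scale_ = [(0.0, 1.0) for _ in layers]
        return self

    @property
    def n_parameters_(self) -> int:
        n = 0
        for l in self.layers_:
            n += l.weights.size + l.hidden_bias.size + 1
        return n + self.fc_w_.size + self.fc_b_.size + self.out_w_.size + self.out_b_.size

    # -- forward -----------------------------------------------------------

    def _prepare(self, X) -> np.ndarray:
        V, _ = _as_batch(X)
        if V.shape[1] != self.input_size or V.shape[2] != self.input_size:
            raise ValueError(
                f"expected {self.input_size}x{self.input_size} patches, "
                f"got {V.shape[1]}x{V.shape[2]}")
        if V.shape[3] != self.channels:
            raise ValueError(
                f"expected {self.channels} channel(s), got {V.shape[3]}")
        out = np.empty_like(V)
        for i in range(V.shape[0]):
            out[i] = standardize_patch(V[i])[0]
        return out

    def _forward(self, V: np.ndarray, cache: bool = False):
        """Deterministic forward pass on standardized batch V."""
        caches = []
        X = V
        for layer, (mu, sd) in zip(self.layers_, self.feature_scale_):
            cols = _windows(X, layer.filter_size)
            Wmat = layer.weights.reshape(layer.n_filters, -1).T
            I = cols @ Wmat + layer.hidden_bias
            up, off = _conditionals_from_input(I, layer.pool_size)
            pon = 1.0 - off
            if cache:
                caches.append(dict(cols=cols, up=up, off=off, in_shape=X.shape))
            X = (pon - mu) / sd
        feats = X.reshape(X.shape[0], -1)
        z1 = feats @ self.fc_w_ + self.fc_b_
        a1 = _sigmoid(z1)
        z2 = a1 @ self.out_w_ + self.out_b_
        if cache:
            return feats, a1, z2, caches, X.shape
        return feats, a1, z2

    def forward(self, patch):
        """Full activation record for one patch (or a batch).

        Returns a dict with per-layer pooled maps, the FC3 vector and the
        output vector (softmax probabilities if the head is multi-class,
        logistic activations otherwise).
        """
        V = self._prepare(patch)
        single = np.asarray(patch).ndim < 4
        pooled = []
        X = V
        for layer, (mu, sd) in zip(self.layers_, self.feature_scale_):
            cols = _windows(X, layer.filter_size)
            Wmat = layer.weights.reshape(layer.n_filters, -1).T
            _, off = _conditionals_from_input(cols @ Wmat + layer.hidden_bias,
                                              layer.pool_size)
            pooled.append(1.0 - off[0] if single else 1.0 - off)
            X = (1.0 - off - mu) / sd
        feats = X.reshape(X.shape[0], -1)
        a1 = _sigmoid(feats @ self.fc_w_ + self.fc_b_)
        z2 = a1 @ self.out_w_ + self.out_b_
        out = _softmax(z2) if self.n_out_ > 1 else _sigmoid(z2)
        if single:
            a1, out = a1[0], out[0]
        return dict(pooled=pooled, fc3=a1, output=out)

    def predict_proba(self, X):
        V = self._prepare(X)
        _, _, z2 = self._forward(V)
        if self.n_out_ > 1:
            return _softmax(z2)
        p = _sigmoid(z2)
        return np.hstack([1.0 - p, p])

    def predict(self, X):
        p = self.predict_proba(X)
        idx = p.argmax(axis=1)
        return self.classes_[idx] if hasattr(self, "classes_") else idx

    def confidence(self, patch) -> float:
        """Logistic score of the one-unit output head, strictly in (0, 1)."""
        if self.n_out_ != 1:
            raise ValueError(
                "confidence requires a transferred model with a one-unit "
                f"output head (n_out={self.n_out_})")
        V = self._prepare(patch)
        _, _, z2 = self._forward(V)
        p = float(_sigmoid(z2)[0, 0])
        eps = 1e-12
        return min(max(p, eps), 1.0 - eps)

    def confidences(self, patches) -> np.ndarray:
        """Vectorized :meth:`confidence` over a batch."""
        if self.n_out_ != 1:
            raise ValueError("confidences requires n_out=1")
        V = self._prepare(patches)
        _, _, z2 = self._forward(V)
        return np.clip(_sigmoid(z2)[:, 0], 1e-12, 1.0 - 1e-12)

    # -- losses and gradients ---------------------------------------------

    def _loss(self, z2, y, sample_weight):
        n = z2.shape[0]
        if self.n_out_ > 1:
            m = z2.max(axis=1, keepdims=True)
            logp = z2 - m - np.log(np.exp(z2 - m).sum(axis=1, keepdims=True))
            ll = logp[np.arange(n), y]
            dz = _softmax(z2)
            dz[np.arange(n), y] -= 1.0
        else:
            yv = y.astype(np.float64).reshape(-1, 1)
            # stable BCE: log(1+e^z) - y z
            ll = -(np.logaddexp(0.0, z2) - yv * z2)[:, 0]
            dz = _sigmoid(z2) - yv
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
        loss = float(-(w * ll).sum() / n)
        dz = dz * (w / n)[:, None]
        return loss, dz

    def _backward(self, feats, a1, dz2, caches, top_shape, freeze_features):
        grads = {
            "out_w": a1.T @ dz2,
            "out_b": dz2.sum(axis=0),
        }
        da1 = dz2 @ self.out_w_.T
        dz1 = da1 * a1 * (1.0 - a1)
        grads["fc_w"] = feats.T @ dz1
        grads["fc_b"] = dz1.sum(axis=0)
        if freeze_features:
            for i in range(len(self.layers_)):
                grads[f"layer{i}_w"] = np.zeros_like(self.layers_[i].weights)
                grads[f"layer{i}_b"] = np.zeros_like(self.layers_[i].hidden_bias)
            return grads
        dP = (dz1 @ self.fc_w_.T).reshape(top_shape)
        for i in range(len(self.layers_) - 1, -1, -1):
            layer, c = self.layers_[i], caches[i]
            dP = dP / self.feature_scale_[i][1]  # undo the output rescaling
            C = layer.pool_size
            # dI = dP_block * P(h=1) * P(p=0)
            dI_blocks = _block_view(c["up"], C) * (dP * c["off"])[..., None]
            dI = _unblock(dI_blocks, C)
            N, nh = dI.shape[0], dI.shape[1]
            dI_f = dI.reshape(N * nh * nh, -1)
            cols_f = c["cols"].reshape(N * nh * nh, -1)
            grads[f"layer{i}_w"] = (dI_f.T @ cols_f).reshape(layer.weights.shape)
            grads[f"layer{i}_b"] = dI_f.sum(axis=0)
            if i > 0:
                nw = layer.filter_size
                dX = np.zeros(c["in_shape"])
                W = layer.weights  # (K, nw, nw, Cin)
                for r in range(nw):
                    for s in range(nw):
                        dX[:, r : r + nh, s : s + nh, :] += dI @ W[:, r, s, :]
                dP = dX
        return grads

    def loss_and_gradients(self, X, y, sample_weight=None, freeze_features=False):
        """Supervised loss and exact analytic gradients (for checking/SGD)."""
        V = self._prepare(X)
        y = np.asarray(y)
        feats, a1, z2, caches, top_shape = self._forward(V, cache=True)
        loss, dz2 = self._loss(z2, y, sample_weight)
        grads = self._backward(feats, a1, dz2, caches, top_shape, freeze_features)
        return loss, grads

    def _param_refs(self):
        refs = {}
        for i, l in enumerate(self.layers_):
            refs[f"layer{i}_w"] = l.weights
            refs[f"layer{i}_b"] = l.hidden_bias
        refs["fc_w"] = self.fc_w_
        refs["fc_b"] = self.fc_b_
        refs["out_w"] = self.out_w_
        refs["out_b"] = self.out_b_
        return refs

    # -- training ----------------------------------------------------------

    def fit(self, X, y):
        """Greedy layer-wise CRBM pretraining + supervised head training."""
        rng = self._rng()
        V = self._prepare(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("pretraining requires at least two classes")
        self.build(rng)
        yi = np.searchsorted(self.classes_, y)

        # greedy stage: each CRBM trained on the previous pooled output
        data = V
        self.crbm_traces_ = []
        for i, layer in enumerate(self.layers_):
            trained, trace = train_layer(
                data, layer, n_epochs=self.crbm_epochs,
                learning_rate=self.crbm_learning_rate, momentum=self.momentum,
                batch_size=self.batch_size, sparsity_weight=self.sparsity_weight,
                rng=rng)
            self.layers_[i] = trained
            self.crbm_traces_.append(trace)
            cols = _windows(data, trained.filter_size)
            Wmat = trained.weights.reshape(trained.n_filters, -1).T
            _, off = _conditionals_from_input(cols @ Wmat + trained.hidden_bias,
                                              trained.pool_size)
            pon = 1.0 - off
            mu, sd = float(pon.mean()), float(max(pon.std(), 1e-8))
            self.feature_scale_[i] = (mu, sd)
            data = (pon - mu) / sd

        # supervised stage: FC3 + output on frozen features
        feats = data.reshape(data.shape[0], -1)
        self.head_log_ = self._train_head(feats, yi, rng)
        self.loss_history_ = self.head_log_.loss
        return self

    def _train_head(self, feats, yi, rng):
        log = _TrainLog()
        n = feats.shape[0]
        vel = {k: np.zeros_like(v) for k, v in
               (("fc_w", self.fc_w_), ("fc_b", self.fc_b_),
                ("out_w", self.out_w_), ("out_b", self.out_b_))}
        for _ in range(self.head_epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                a1 = _sigmoid(feats[idx] @ self.fc_w_ + self.fc_b_)
                z2 = a1 @ self.out_w_ + self.out_b_
                _, dz2 = self._loss(z2, yi[idx], None)
                da1 = dz2 @ self.out_w_.T
                dz1 = da1 * a1 * (1.0 - a1)
                g = {"out_w": a1.T @ dz2, "out_b": dz2.sum(0),
                     "fc_w": feats[idx].T @ dz1, "fc_b": dz1.sum(0)}
                for k in vel:
                    vel[k] = self.momentum * vel[k] - g[k]
                self.fc_w_ += self.learning_rate * vel["fc_w"]
                self.fc_b_ += self.learning_rate * vel["fc_b"]
                self.out_w_ += self.learning_rate * vel["out_w"]
                self.out_b_ += self.learning_rate * vel["out_b"]
            a1 = _sigmoid(feats @ self.fc_w_ + self.fc_b_)
            z2 = a1 @ self.out_w_ + self.out_b_
            loss, _ = self._loss(z2, yi, None)
            log.loss.append(loss)
            pred = z2.argmax(1) if self.n_out_ > 1 else (z2[:, 0] > 0).astype(int)
            log.accuracy.append(float((pred == yi).mean()))
        return log

    def transfer_output(self, n_out: int = 1,
                        rng: np.random.Generator | None = None) -> "CDBNClassifier":
        """Swap the output layer for a freshly initialized one with n_out units.

        Every CRBM and FC3 parameter is carried over bit-exactly; only the
        output weights/biases are re-drawn. Returns a new model.
        """
        if n_out < 1:
            raise ValueError("n_out must be >= 1")
        rng = self._rng() if rng is None else rng
        other = copy.deepcopy(self)
        other.out_w_ = rng.normal(0.0, self.weight_scale,
                                  size=(self.fc_w_.shape[1], n_out))
        other.out_b_ = np.zeros(n_out)
        other.n_out_ = n_out
        if n_out == 1:
            other.classes_ = np.array([0, 1])
        return other

    def to_single_channel(self) -> "CDBNClassifier":
        """Average first-layer filters over channels for grayscale input."""
        if self.channels == 1:
            return self
        other = copy.deepcopy(self)
        other.layers_[0] = self.layers_[0].to_single_channel()
        other.channels = 1
        return other

    def finetune(self, X, y, *, n_epochs=500, learning_rate=None, momentum=None,
                 batch_size=None, sample_weight=None, class_weight="balanced",
                 freeze_features=False, rng=None):
        """End-to-end supervised gradient descent through the whole stack.

        Defaults follow the tracking configuration: learning rate 0.1,
        momentum 0.5, 500 epochs. With ``class_weight='balanced'`` each
        class contributes equally to the loss regardless of buffer sizes.
        Records the full-data loss before training and after every epoch
        in ``finetune_log_``.
        """
        lr = self.learning_rate if learning_rate is None else learning_rate
        mom = self.momentum if momentum is None else momentum
        bs = self.batch_size if batch_size is None else batch_size
        rng = self._rng() if rng is None else rng
        V = self._prepare(X)
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ValueError("fine-tuning requires both classes present")
        if self.n_out_ > 1:
            yi = np.searchsorted(self.classes_, y) if hasattr(self, "classes_") else y
        else:
            yi = y.astype(int)
        if sample_weight is None and class_weight == "balanced":
            counts = np.bincount(yi, minlength=int(yi.max()) + 1).astype(float)
            cw = yi.size / (np.count_nonzero(counts) * np.maximum(counts, 1))
            sample_weight = cw[yi]
        sw = None if sample_weight is None else np.asarray(sample_weight, float)

        refs = self._param_refs()
        vel = {k: np.zeros_like(v) for k, v in refs.items()}
        log = _TrainLog()

        def full_loss():
            _, _, z2 = self._forward(V)
            return self._loss(z2, yi, sw)[0]

        log.loss.append(full_loss())
        n = V.shape[0]
        for _ in range(n_epochs):
            order = rng.permutation(n)
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                feats, a1, z2, caches, top_shape = self._forward(V[idx], cache=True)
                _, dz2 = self._loss(z2, yi[idx], None if sw is None else sw[idx])
                grads = self._backward(feats, a1, dz2, caches, top_shape,
                                       freeze_features)
                for k, p in refs.items():
                    vel[k] = mom * vel[k] - grads[k]
                    p += lr * vel[k]
            log.loss.append(full_loss())
        self.finetune_log_ = log
        return self


def build_architecture(config="full", *, input_size=32, channels=1,
                       random_state=None, **kwargs) -> CDBNClassifier:
    """Construct and randomly initialize a CDBN (no training).

    ``config`` is a preset name or an explicit architecture dict; raises
    ``ValueError`` naming the offending dimension if any pooled grid is
    not an integer.
    """
    model = CDBNClassifier(architecture=config, input_size=input_size,
                           channels=channels, random_state=random_state, **kwargs)
    return model.build()


# ---------------------------------------------------------------------------
# model container

def save_model(model: CDBNClassifier, path, provenance: dict | None = None) -> None:
    """Single-file npz container with a JSON header; bit-exact round trip."""
    arrays = {}
    header = dict(
        kind="cdbn",
        architecture=model.architecture if isinstance(model.architecture, str)
        else "custom",
        arch_spec=model._arch_spec(),
        input_size=model.input_size,
        channels=model.channels,
        n_out=model.n_out_,
        provenance=provenance or {},
        feature_scale=[list(s) for s in model.feature_scale_],
        layers=[],
    )
    for i, layer in enumerate(model.layers_):
        arrs, h = layer_to_arrays(layer, f"layer{i}_")
        arrays.update(arrs)
        header["layers"].append(h)
    arrays.update(fc_w=model.fc_w_, fc_b=model.fc_b_,
                  out_w=model.out_w_, out_b=model.out_b_)
    np.savez(path, __header__=np.frombuffer(json.dumps(header).encode(),
                                            dtype=np.uint8), **arrays)


def load_model(path) -> CDBNClassifier:
    with np.load(path) as z:
        header = json.loads(bytes(z["__header__"]).decode())
        spec = header["arch_spec"]
        model = CDBNClassifier(
            architecture=header["architecture"] if header["architecture"] != "custom"
            else spec,
            input_size=int(header["input_size"]), channels=int(header["channels"]))
        model.layers_ = [layer_from_arrays(z, h, f"layer{i}_")
                         for i, h in enumerate(header["layers"])]
        model.fc_w_ = np.asarray(z["fc_w"])
        model.fc_b_ = np.asarray(z["fc_b"])
        model.out_w_ = np.asarray(z["out_w"])
        model.out_b_ = np.asarray(z["out_b"])
        model.n_out_ = int(header["n_out"])
        model.n_features_ = model.fc_w_.shape[0]
        model.feature_scale_ = [tuple(s) for s in header["feature_scale"]]
        if model.n_out_ == 1:
            model.classes_ = np.array([0, 1])
        return model
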