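"""Small 3-layer CNN for breathprint classification, in pure numpy.

The network maps a 14x16x16 breathprint image to a lung-cancer probability:
three 'same'-padded convolutions with ReLU, each followed by 2x2 max-pooling
and dropout, then a single sigmoid unit on the flattened deep features. At the
default widths (16, 32, 64) this is ~26k parameters — deliberately
small for the few-hundred-sample cohorts it is trained on, and fast enough
to train on one CPU core in seconds.

Forward and backward passes are written out explicitly (im2col
convolutions, Adam updates); everything is driven by seeded numpy
generators so that training, fine-tuning and prediction are exactly
reproducible. Samples are canonically ordered by sample_id before training,
making the result invariant to the order the caller supplies them in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import InvalidArgumentError, LeakageError
from .preprocess import BreathprintImage
from .synthetic import N_CHANNELS

_CONV_LAYERS = ("conv1", "conv2", "conv3")


@dataclass(frozen=True)
class FinetuneConfig:
    """Few-shot target-site adaptation settings.

    The whole network is updated by default, but gently: full-batch Adam at
    a learning rate an order of magnitude below training for a few dozen
    steps. Under a strong site shift the convolutional features themselves
    are miscalibrated (activations drift toward dead zones), so head-only
    updates cannot recover; slow whole-network adaptation can, while the
    tiny step budget guards against forgetting the source-site solution.
    ``frozen_layers`` still accepts any subset of conv layers to pin.
    """

    n_samples: int = 10
    learning_rate: float = 1e-4
    epochs: int = 30
    frozen_layers: frozenset = frozenset()

    def __post_init__(self):
        if self.n_samples <= 0 or self.epochs < 0 or self.learning_rate <= 0:
            raise InvalidArgumentError("invalid fine-tune config")
        if not set(self.frozen_layers) <= set(_CONV_LAYERS):
            raise InvalidArgumentError(f"frozen_layers must be a subset of {_CONV_LAYERS}")


@dataclass(frozen=True)
class ModelConfig:
    conv_channels: tuple = (16, 32, 64)
    kernel_size: int = 3
    pooling: str = "max"
    dropout_rate: float = 0.25
    learning_rate: float = 1e-3
    epochs: int = 150
    batch_size: int = 32
    patience: int = 20          # early stopping on validation AUC
    seed: int = 0
    finetune: FinetuneConfig = field(default_factory=FinetuneConfig)

    def __post_init__(self):
        if len(self.conv_channels) != 3 or any(c <= 0 for c in self.conv_channels):
            raise InvalidArgumentError("conv_channels must be three positive integers")
        if self.kernel_size <= 0 or self.kernel_size % 2 == 0:
            raise InvalidArgumentError("kernel_size must be a positive odd integer")
        if not (0 <= self.dropout_rate < 1):
            raise InvalidArgumentError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0 or self.epochs < 0 or self.batch_size <= 0:
            raise InvalidArgumentError("invalid optimizer settings")
        # Feature maps shrink 16 -> 8 -> 4 under the two first pools.
        if self.kernel_size > 4:
            raise InvalidArgumentError("kernel_size exceeds the deepest 4x4 feature map")


@dataclass
class TrainedModel:
    """Weights + training history + provenance fingerprints."""

    params: dict
    config: ModelConfig
    history: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def copy_params(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}


def _fingerprint(images) -> frozenset:
    return frozenset(img.sample_id for img in images)


def build_model(config: ModelConfig) -> TrainedModel:
    """He-initialized conv stack with a zero-initialized sigmoid head.

    Zero head weights put every initial prediction at exactly 0.5; the head
    receives gradient on the first update and the convolutions thereafter.
    """
    rng = np.random.default_rng(config.seed)
    k = config.kernel_size
    c1, c2, c3 = config.conv_channels
    shapes = {"conv1": (c1, N_CHANNELS, k, k), "conv2": (c2, c1, k, k), "conv3": (c3, c2, k, k)}
    params = {}
    for name, shp in shapes.items():
        fan_in = shp[1] * k * k
        params[f"{name}_W"] = rng.standard_normal(shp) * np.sqrt(2.0 / fan_in)
        params[f"{name}_b"] = np.zeros(shp[0])
    # Head acts on the flattened 2x2 deep feature map rather than a global
    # average: the pooling stack is already coarsely translation-tolerant,
    # and keeping the residual spatial layout leaves the head sensitive to
    # response timing, where the adsorption/desorption kinetics live.
    params["head_W"] = np.zeros((c3 * 4, 1))
    params["head_b"] = np.zeros(1)
    return TrainedModel(params=params, config=config, provenance={"seed": config.seed})


# ---------------------------------------------------------------------------
# layers

def _im2col(x, k):
    """(N,C,H,W) -> (N, C*k*k, H*W) with 'same' zero padding."""
    N, C, H, W = x.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((N, C, k * k, H * W))
    for i in range(k):
        for j in range(k):
            cols[:, :, i * k + j, :] = xp[:, :, i:i + H, j:j + W].reshape(N, C, H * W)
    return cols.reshape(N, C * k * k, H * W)


def _col2im(dcols, x_shape, k):
    N, C, H, W = x_shape
    pad = k // 2
    dxp = np.zeros((N, C, H + 2 * pad, W + 2 * pad))
    d = dcols.reshape(N, C, k * k, H * W)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + H, j:j + W] += d[:, :, i * k + j, :].reshape(N, C, H, W)
    return dxp[:, :, pad:pad + H, pad:pad + W]


def _conv_forward(x, W, b, k):
    cols = _im2col(x, k)
    F = W.shape[0]
    out = np.matmul(W.reshape(F, -1), cols) + b[:, None]
    N, _, H, Wd = x.shape
    return out.reshape(N, F, H, Wd), cols


def _conv_backward(dout, cols, W, x_shape, k):
    N, F, H, Wd = dout.shape
    d2 = dout.reshape(N, F, H * Wd)
    dW = np.einsum("nfp,nqp->fq", d2, cols).reshape(W.shape)
    db = d2.sum(axis=(0, 2))
    dcols = np.matmul(W.reshape(F, -1).T, d2)
    return _col2im(dcols, x_shape, k), dW, db


def _pool_forward(x):
    N, C, H, W = x.shape
    xr = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H // 2, W // 2, 4)
    idx = xr.argmax(axis=4)
    out = np.take_along_axis(xr, idx[..., None], axis=4)[..., 0]
    return out, idx


def _pool_backward(dout, idx, x_shape):
    N, C, H, W = x_shape
    d = np.zeros((N, C, H // 2, W // 2, 4))
    np.put_along_axis(d, idx[..., None], dout[..., None], axis=4)
    return d.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H, W)


def _sigmoid(z):
    return np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)), np.exp(z) / (1.0 + np.exp(z)))


def _forward(params, x, config, rng=None):
    """Full forward pass; dropout active only when an rng is supplied."""
    k = config.kernel_size
    cache = {"x": x}
    h = x
    for li, name in enumerate(_CONV_LAYERS):
        out, cols = _conv_forward(h, params[f"{name}_W"], params[f"{name}_b"], k)
        relu_mask = out > 0
        out = out * relu_mask
        pooled, pidx = _pool_forward(out)
        if rng is not None and config.dropout_rate > 0:
            keep = (rng.random(pooled.shape) >= config.dropout_rate) / (1.0 - config.dropout_rate)
            pooled = pooled * keep
        else:
            keep = None
        cache[name] = (h.shape, cols, relu_mask, out.shape, pidx, keep)
        h = pooled
    feat = h.reshape(h.shape[0], -1)  # flatten -> (N, c3*2*2)
    cache["feat_shape"] = h.shape
    cache["feat"] = feat
    logits = feat @ params["head_W"][:, 0] + params["head_b"][0]
    return logits, cache


def _backward(params, cache, dlogits, config):
    k = config.kernel_size
    grads = {}
    feat = cache["feat"]
    grads["head_W"] = (feat.T @ dlogits)[:, None]
    grads["head_b"] = np.array([dlogits.sum()])
    dfeat = np.outer(dlogits, params["head_W"][:, 0])
    dh = dfeat.reshape(cache["feat_shape"])
    for name in reversed(_CONV_LAYERS):
        x_shape, cols, relu_mask, out_shape, pidx, keep = cache[name]
        if keep is not None:
            dh = dh * keep
        dout = _pool_backward(dh, pidx, out_shape)
        dout = dout * relu_mask
        dh, dW, db = _conv_backward(dout, cols, params[f"{name}_W"], x_shape, k)
        grads[f"{name}_W"] = dW
        grads[f"{name}_b"] = db
    return grads


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads, trainable):
        self.t += 1
        for k in trainable:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# public operations

def _stack(images) -> tuple[np.ndarray, np.ndarray]:
    order = sorted(range(len(images)), key=lambda i: images[i].sample_id)
    X = np.stack([images[i].tensor for i in order])
    y = np.array([1.0 if images[i].is_cancer else 0.0 for i in order])
    return X, y


def _check_input(x):
    if x.ndim != 4 or x.shape[1:] != (N_CHANNELS, 16, 16):
        raise InvalidArgumentError(f"input must be (N, {N_CHANNELS}, 16, 16), got {x.shape}")


def _auc(y, s):
    # Mann-Whitney AUC, used internally for early stopping.
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(len(s))
    sorted_s = s[order]
    ranks[order] = np.arange(1, len(s) + 1)
    # midranks for ties
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j + 2) / 2.0
        i = j + 1
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        return float("nan")
    return (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def train(
    model: TrainedModel,
    images: list[BreathprintImage],
    config: ModelConfig | None = None,
    validation: list[BreathprintImage] | None = None,
) -> TrainedModel:
    """Minimize binary cross-entropy with Adam on mini-batches.

    If a validation list is given, training early-stops on validation AUC
    (patience ``config.patience``) and the best-epoch weights are restored.
    Only validation *scores* are used for stopping; validation samples never
    enter a gradient step. Deterministic given the config seed.
    """
    config = config or model.config
    X, y = _stack(images)
    _check_input(X)
    if len(np.unique(y)) < 2:
        raise InvalidArgumentError("training data must contain both classes")
    params = model.copy_params()
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    opt = _Adam(params, config.learning_rate)
    trainable = list(params)
    history = []

    Xv = yv = None
    if validation:
        Xv, yv = _stack(validation)
    best = {"auc": -np.inf, "params": None, "epoch": -1}
    since_best = 0

    n = len(X)
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        total = 0.0
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            logits, cache = _forward(params, X[idx], config, rng=rng)
            p = _sigmoid(logits)
            eps = 1e-12
            total += -np.sum(y[idx] * np.log(p + eps) + (1 - y[idx]) * np.log(1 - p + eps))
            dlogits = (p - y[idx]) / len(idx)
            grads = _backward(params, cache, dlogits, config)
            opt.step(params, grads, trainable)
        rec = {"epoch": epoch, "train_loss": total / n}
        if Xv is not None:
            val_scores = _sigmoid(_forward(params, Xv, config)[0])
            rec["val_auc"] = _auc(yv, val_scores)
            if rec["val_auc"] > best["auc"] + 1e-6:
                best = {"auc": rec["val_auc"], "params": {k: v.copy() for k, v in params.items()},
                        "epoch": epoch}
                since_best = 0
            else:
                since_best += 1
        history.append(rec)
        if Xv is not None and since_best >= config.patience:
            break
    if best["params"] is not None:
        params = best["params"]

    prov = dict(model.provenance)
    prov.update(
        train_ids=_fingerprint(images),
        validation_ids=_fingerprint(validation) if validation else frozenset(),
        seed=config.seed,
    )
    return TrainedModel(params=params, config=config, history=model.history + history, provenance=prov)


def predict_proba(model: TrainedModel, images: list[BreathprintImage]) -> np.ndarray:
    """Lung-cancer probability for each image, in input order."""
    X = np.stack([img.tensor for img in images])
    _check_input(X)
    logits, _ = _forward(model.params, X, model.config)
    return _sigmoid(logits)


def fine_tune(
    model: TrainedModel,
    finetune_images: list[BreathprintImage],
    config: ModelConfig | None = None,
) -> TrainedModel:
    """Adapt a trained model with a few target-site samples.

    Layers named in ``finetune.frozen_layers`` keep bit-identical weights;
    the rest (by default only the head) are updated with full-batch Adam.
    The fine-tune ids are recorded in provenance, and any overlap with the
    model's validation fingerprint is rejected as leakage.
    """
    config = config or model.config
    ft = config.finetune
    if len(finetune_images) != ft.n_samples:
        raise InvalidArgumentError(
            f"expected {ft.n_samples} fine-tune samples, got {len(finetune_images)}"
        )
    overlap = _fingerprint(finetune_images) & model.provenance.get("validation_ids", frozenset())
    if overlap:
        raise LeakageError(f"fine-tune samples overlap an evaluation set: {sorted(overlap)}")

    params = model.copy_params()
    frozen = set(ft.frozen_layers)
    trainable = [k for k in params if not any(k.startswith(layer) for layer in frozen)]
    X, y = _stack(finetune_images)
    _check_input(X)
    opt = _Adam(params, ft.learning_rate)
    history = []
    # Dropout stays off: ten samples and a 65-parameter head need the
    # stable full-batch gradient, not stochastic regularization.
    for epoch in range(ft.epochs):
        logits, cache = _forward(params, X, config)
        p = _sigmoid(logits)
        eps = 1e-12
        loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
        dlogits = (p - y) / len(y)
        grads = _backward(params, cache, dlogits, config)
        opt.step(params, grads, trainable)
        history.append({"epoch": epoch, "finetune_loss": float(loss)})

    prov = dict(model.provenance)
    prov["finetune_ids"] = _fingerprint(finetune_images)
    return TrainedModel(params=params, config=config, history=model.history + history, provenance=prov)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist weights as .npz next to a JSON manifest of config/provenance."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.params)
    manifest = {
        "config": {
            "conv_channels": list(model.config.conv_channels),
            "kernel_size": model.config.kernel_size,
            "dropout_rate": model.config.dropout_rate,
            "seed": model.config.seed,
        },
        "provenance": {
            k: sorted(v) if isinstance(v, frozenset) else v
            for k, v in model.provenance.items()
        },
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_model(path: str | Path, config: ModelConfig | None = None) -> TrainedModel:
    path = Path(path)
    data = np.load(path.with_suffix(".npz"))
    manifest = json.loads(path.with_suffix(".json").read_text())
    cfg = config or ModelConfig(
        conv_channels=tuple(manifest["config"]["conv_channels"]),
        kernel_size=manifest["config"]["kernel_size"],
        dropout_rate=manifest["config"]["dropout_rate"],
        seed=manifest["config"]["seed"],
    )
    prov = {
        k: frozenset(v) if isinstance(v, list) else v
        for k, v in manifest["provenance"].items()
    }
    return TrainedModel(params={k: data[k] for k in data.files}, config=cfg, provenance=prov)
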