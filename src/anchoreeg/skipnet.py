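"""Skip-Net: a shallow convolutional classifier for anchored-STFT images.

The network is deliberately small — the point of the architecture is that a
shallow CNN with a skip connection decodes motor imagery at least as well
as much deeper baselines while remaining trainable on small EEG datasets:

    input (N_h x N_t)
      -> conv1: F kernels of N_h x 1, stride 1       (output 1 x N_t x F)
      -> batch norm -> ReLU                           [branch a]
      -> conv2: F kernels of 1 x 3, same padding
      -> batch norm -> ReLU                           [branch b]
      -> add(a, b)  (the skip connection)
      -> flatten -> dense 128 -> ReLU -> dropout 0.5
      -> dense n_classes -> softmax

The first convolution spans the full image height, so each of its F filters
collapses the stacked (channel x band) frequency rows into one temporal
profile; the second convolution smooths along time only.

Training uses Adam (first-moment decay 0.9), initial learning rate 0.01
halved every 5 epochs, L2 weight penalty 0.01 on convolution and dense
weights, dropout 0.5, mini-batches of 200, up to 200 epochs.  All of it is
implemented directly on numpy arrays, including the backward pass; the
model also exposes ``cost_gradient(x, label)`` — the gradient of the
cross-entropy data term with respect to the *input*, evaluated in inference
mode — which is the contract the adversarial-augmentation module builds on.
Everything is reproducible from the integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyInputError, InputShapeError, SpecError

__all__ = [
    "SkipNetSpec",
    "TrainConfig",
    "SkipNet",
    "build_skipnet",
    "count_parameters",
    "train",
    "examples_from_feature_sets",
    "save_checkpoint",
    "load_checkpoint",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass(frozen=True)
class SkipNetSpec:
    """Architecture description.

    ``input_h`` and ``input_w`` are the feature-image dimensions
    (N_h x N_t); defaults follow the reference architecture: 16 filters,
    1 x 3 second kernel, 128 dense units, 50% dropout.
    """

    input_h: int
    input_w: int
    n_classes: int
    conv_filters: int = 16
    conv2_width: int = 3
    fc_units: int = 128
    dropout: float = 0.5

    def __post_init__(self) -> None:
        if self.input_h < 1 or self.input_w < 1:
            raise SpecError("input dimensions must be positive")
        if self.n_classes < 2:
            raise SpecError("need at least two classes")
        if self.conv_filters < 1 or self.fc_units < 1:
            raise SpecError("layer widths must be positive")
        if self.conv2_width < 1 or self.conv2_width % 2 == 0:
            raise SpecError("conv2_width must be odd for same padding")
        if not 0 <= self.dropout < 1:
            raise SpecError("dropout must lie in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (reference values as defaults)."""

    beta1: float = 0.9
    beta2: float = 0.999
    initial_lr: float = 0.01
    lr_drop_factor: float = 0.5
    lr_drop_period: int = 5
    l2: float = 0.01
    max_epochs: int = 200
    batch_size: int = 200
    seed: int = 0

    def lr_at(self, epoch: int) -> float:
        """Stepped schedule: initial_lr * drop_factor ** (epoch // period)."""
        return self.initial_lr * self.lr_drop_factor ** (epoch // self.lr_drop_period)


def _he_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


class SkipNet:
    """The network: parameters, forward/backward, and the gradient contract.

    Parameters live in ``self.params`` (trainable) and ``self.stats``
    (batch-norm running statistics); both are plain dicts of numpy arrays.
    """

    def __init__(self, spec: SkipNetSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        H, W, F = spec.input_h, spec.input_w, spec.conv_filters
        k2, FC, C = spec.conv2_width, spec.fc_units, spec.n_classes
        self.params = {
            "W1": _he_uniform(rng, (F, H), H),
            "b1": np.zeros(F),
            "g1": np.ones(F),
            "be1": np.zeros(F),
            "W2": _he_uniform(rng, (F, F, k2), F * k2),
            "b2": np.zeros(F),
            "g2": np.ones(F),
            "be2": np.zeros(F),
            "Wf": _he_uniform(rng, (F * W, FC), F * W),
            "bf": np.zeros(FC),
            "Wo": _he_uniform(rng, (FC, C), FC),
            "bo": np.zeros(C),
        }
        self.stats = {
            "mean1": np.zeros(F),
            "var1": np.ones(F),
            "mean2": np.zeros(F),
            "var2": np.ones(F),
        }
        self.history: dict[str, list[float]] = {"loss": [], "accuracy": []}
        self.train_config: TrainConfig | None = None

    # -- forward -----------------------------------------------------------

    def _check_input(self, x: np.ndarray) -> tuple[np.ndarray, bool]:
        x = np.asarray(x, dtype=np.float64)
        single = x.ndim == 2
        if single:
            x = x[None]
        if x.ndim != 3 or x.shape[1:] != (self.spec.input_h, self.spec.input_w):
            raise InputShapeError(
                f"expected images of shape "
                f"({self.spec.input_h}, {self.spec.input_w}), got {x.shape}"
            )
        return x, single

    def _bn_forward(self, z, which: str, training: bool, cache: dict):
        g = self.params[f"g{which}"][None, :, None]
        be = self.params[f"be{which}"][None, :, None]
        if training:
            mu = z.mean(axis=(0, 2))
            var = z.var(axis=(0, 2))
            m = f"mean{which}"
            v = f"var{which}"
            self.stats[m] = (1 - _BN_MOMENTUM) * self.stats[m] + _BN_MOMENTUM * mu
            self.stats[v] = (1 - _BN_MOMENTUM) * self.stats[v] + _BN_MOMENTUM * var
        else:
            mu = self.stats[f"mean{which}"]
            var = self.stats[f"var{which}"]
        invstd = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (z - mu[None, :, None]) * invstd[None, :, None]
        cache[f"xhat{which}"] = xhat
        cache[f"invstd{which}"] = invstd
        return g * xhat + be

    def _forward(self, x, training: bool, drop_rng=None):
        p, s = self.params, self.spec
        cache: dict = {"x": x, "training": training}
        B, W, F = x.shape[0], s.input_w, s.conv_filters
        half = s.conv2_width // 2

        z1 = np.einsum("fh,bhw->bfw", p["W1"], x) + p["b1"][None, :, None]
        y1 = self._bn_forward(z1, "1", training, cache)
        a1 = np.maximum(y1, 0.0)
        cache["y1"], cache["a1"] = y1, a1

        ap = np.pad(a1, ((0, 0), (0, 0), (half, half)))
        z2 = np.zeros_like(a1)
        for k in range(s.conv2_width):
            z2 += np.einsum("oi,biw->bow", p["W2"][:, :, k], ap[:, :, k : k + W])
        z2 += p["b2"][None, :, None]
        y2 = self._bn_forward(z2, "2", training, cache)
        a2 = np.maximum(y2, 0.0)
        cache["ap"], cache["y2"], cache["a2"] = ap, y2, a2

        flat = (a1 + a2).reshape(B, F * W)
        u = flat @ p["Wf"] + p["bf"]
        h = np.maximum(u, 0.0)
        if training and s.dropout > 0:
            mask = (drop_rng.random(h.shape) >= s.dropout) / (1.0 - s.dropout)
        else:
            mask = np.ones_like(h)
        hd = h * mask
        logits = hd @ p["Wo"] + p["bo"]
        cache.update(flat=flat, u=u, h=h, mask=mask, hd=hd)

        logits = logits - logits.max(axis=1, keepdims=True)
        ex = np.exp(logits)
        probs = ex / ex.sum(axis=1, keepdims=True)
        cache["probs"] = probs
        return probs, cache

    def _bn_backward(self, dy, which: str, cache: dict):
        g = self.params[f"g{which}"]
        xhat = cache[f"xhat{which}"]
        invstd = cache[f"invstd{which}"]
        dg = (dy * xhat).sum(axis=(0, 2))
        dbe = dy.sum(axis=(0, 2))
        dxhat = dy * g[None, :, None]
        if cache["training"]:
            M = dy.shape[0] * dy.shape[2]
            s1 = dxhat.sum(axis=(0, 2), keepdims=True)
            s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
            dz = (invstd[None, :, None] / M) * (M * dxhat - s1 - xhat * s2)
        else:
            dz = dxhat * invstd[None, :, None]
        return dz, dg, dbe

    def _backward(self, cache: dict, dlogits: np.ndarray):
        """Gradients of the (already weighted) loss w.r.t. params and input."""
        p, s = self.params, self.spec
        B = dlogits.shape[0]
        W, F = s.input_w, s.conv_filters
        half = s.conv2_width // 2
        grads: dict[str, np.ndarray] = {}

        grads["Wo"] = cache["hd"].T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dhd = dlogits @ p["Wo"].T
        dh = dhd * cache["mask"]
        du = dh * (cache["u"] > 0)
        grads["Wf"] = cache["flat"].T @ du
        grads["bf"] = du.sum(axis=0)
        dflat = du @ p["Wf"].T
        ds = dflat.reshape(B, F, W)

        da2 = ds
        dy2 = da2 * (cache["y2"] > 0)
        dz2, grads["g2"], grads["be2"] = self._bn_backward(dy2, "2", cache)

        grads["W2"] = np.zeros_like(p["W2"])
        dap = np.zeros_like(cache["ap"])
        for k in range(s.conv2_width):
            grads["W2"][:, :, k] = np.einsum(
                "bow,biw->oi", dz2, cache["ap"][:, :, k : k + W]
            )
            dap[:, :, k : k + W] += np.einsum("oi,bow->biw", p["W2"][:, :, k], dz2)
        grads["b2"] = dz2.sum(axis=(0, 2))

        da1 = ds + dap[:, :, half : half + W]
        dy1 = da1 * (cache["y1"] > 0)
        dz1, grads["g1"], grads["be1"] = self._bn_backward(dy1, "1", cache)
        grads["W1"] = np.einsum("bfw,bhw->fh", dz1, cache["x"])
        grads["b1"] = dz1.sum(axis=(0, 2))
        dx = np.einsum("fh,bfw->bhw", p["W1"], dz1)
        return grads, dx

    # -- public API --------------------------------------------------------

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities in inference mode (dropout off, BN eval)."""
        xb, single = self._check_input(x)
        probs, _ = self._forward(xb, training=False)
        return probs[0] if single else probs

    def predict_label(self, x: np.ndarray):
        probs = self.predict(x)
        return int(np.argmax(probs)) if probs.ndim == 1 else np.argmax(probs, axis=1)

    def cost_gradient(self, x: np.ndarray, label) -> np.ndarray:
        """d(cross-entropy)/d(input), inference mode, data term only.

        ``x`` may be a single image or a batch; with a batch, each row's
        gradient is that of its own example's cross-entropy (examples are
        independent in inference mode, so the batch call equals the loop).
        """
        xb, single = self._check_input(x)
        labels = np.atleast_1d(np.asarray(label, dtype=np.int64))
        if labels.shape[0] != xb.shape[0]:
            raise InputShapeError("one label per input image required")
        probs, cache = self._forward(xb, training=False)
        dlogits = probs.copy()
        dlogits[np.arange(len(labels)), labels] -= 1.0
        _, dx = self._backward(cache, dlogits)
        return dx[0] if single else dx

    def activation_shapes(self) -> dict[str, tuple[int, int, int]]:
        """Spatial shapes (height x width x filters) of the conv outputs."""
        s = self.spec
        shape = (1, s.input_w, s.conv_filters)
        return {"conv1": shape, "conv2": shape, "add": shape}


def build_skipnet(spec: SkipNetSpec, seed: int = 0) -> SkipNet:
    """Construct an untrained Skip-Net with seeded He-uniform weights."""
    return SkipNet(spec, seed)


def count_parameters(model: SkipNet) -> int:
    """Total count of trainable scalars (conv, batch-norm, dense)."""
    return int(sum(v.size for v in model.params.values()))


def examples_from_feature_sets(feature_sets) -> tuple[np.ndarray, np.ndarray]:
    """Flatten FeatureSets into (images, labels): every anchor image is an
    independent training example carrying its trial's label."""
    xs, ys = [], []
    for fs in feature_sets:
        for im in fs.images:
            xs.append(im.values)
            ys.append(fs.label)
    if not xs:
        raise EmptyInputError("no training examples")
    return np.stack(xs), np.array(ys, dtype=np.int64)


def train(model: SkipNet, features, cfg: TrainConfig = TrainConfig()) -> SkipNet:
    """Train in place with Adam, the stepped lr schedule and L2 penalty.

    ``features`` is a list of FeatureSets (each anchor image becomes one
    example) or a pre-flattened ``(images, labels)`` pair.  History records
    per-epoch mean training loss and accuracy.  Two runs with the same
    data, config and seed produce identical weights.
    """
    if isinstance(features, tuple):
        X, y = features
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
    else:
        X, y = examples_from_feature_sets(features)
    if X.shape[0] == 0:
        raise EmptyInputError("empty training set")
    if X.shape[1:] != (model.spec.input_h, model.spec.input_w):
        raise InputShapeError(
            f"feature images {X.shape[1:]} do not match the model spec "
            f"({model.spec.input_h}, {model.spec.input_w})"
        )
    if y.max() >= model.spec.n_classes:
        raise InputShapeError("label exceeds the model's class count")

    rng = np.random.default_rng(cfg.seed)
    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(p) for k, p in model.params.items()}
    t = 0
    n = X.shape[0]
    penalized = ("W1", "W2", "Wf", "Wo")

    for epoch in range(cfg.max_epochs):
        lr = cfg.lr_at(epoch)
        order = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            probs, cache = model._forward(xb, training=True, drop_rng=rng)
            B = len(idx)
            ce = -np.log(probs[np.arange(B), yb] + 1e-30).mean()
            ep_loss += ce * B
            ep_correct += int((np.argmax(probs, axis=1) == yb).sum())

            dlogits = probs.copy()
            dlogits[np.arange(B), yb] -= 1.0
            dlogits /= B
            grads, _ = model._backward(cache, dlogits)
            for key in penalized:
                grads[key] = grads[key] + 2.0 * cfg.l2 * model.params[key]

            t += 1
            for key, g in grads.items():
                m[key] = cfg.beta1 * m[key] + (1 - cfg.beta1) * g
                v[key] = cfg.beta2 * v[key] + (1 - cfg.beta2) * g**2
                mhat = m[key] / (1 - cfg.beta1**t)
                vhat = v[key] / (1 - cfg.beta2**t)
                model.params[key] -= lr * mhat / (np.sqrt(vhat) + 1e-8)

        model.history["loss"].append(ep_loss / n)
        model.history["accuracy"].append(ep_correct / n)
    model.train_config = cfg
    return model


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: SkipNet, path) -> None:
    """Serialize weights (npz) plus a JSON sidecar with spec and config."""
    arrays = {f"param_{k}": v for k, v in model.params.items()}
    arrays.update({f"stat_{k}": v for k, v in model.stats.items()})
    np.savez(path, **arrays)
    sidecar = {
        "spec": vars(model.spec),
        "train_config": vars(model.train_config) if model.train_config else None,
        "history": model.history,
    }
    with open(str(path) + ".json", "w") as f:
        json.dump(sidecar, f, indent=1)


def load_checkpoint(path) -> SkipNet:
    with open(str(path) + ".json") as f:
        sidecar = json.load(f)
    model = SkipNet(SkipNetSpec(**sidecar["spec"]))
    npz_path = str(path) if str(path).endswith(".npz") else str(path) + ".npz"
    import os

    if not os.path.exists(npz_path):
        npz_path = str(path)
    with np.load(npz_path) as data:
        for k in model.params:
            model.params[k] = data[f"param_{k}"]
        for k in model.stats:
            model.stats[k] = data[f"stat_{k}"]
    model.history = sidecar.get("history", {"loss": [], "accuracy": []})
    if sidecar.get("train_config"):
        model.train_config = TrainConfig(**sidecar["train_config"])
    return model
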