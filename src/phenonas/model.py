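"""Executable multi-task network: build, train, predict.

A compact NumPy engine executes :class:`~phenonas.arch.ArchitectureSpec`
DAGs.  Convolutions are im2col matrix products, the three heads share the
trunk, and training minimizes

    w_cls * CE(genotype) + w_count * MSE(count) + w_area * MSE(area)
                                                + lambda * ||theta||^2

with Adam.  Everything is float32 and deterministic given the seeds, so two
builds or two training runs with the same configuration are bit-identical
on one device.

Activations follow the generating framework's defaults: ReLU after every
convolution, softmax on the classification head, identity on the regression
heads.  Dropout (inverted scaling) is active only during training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .arch import ArchitectureSpec, count_parameters, _conv_defaults

__all__ = [
    "PredictionTriple",
    "TrainConfig",
    "Network",
    "build",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
    "history_to_csv",
]

N_CLASSES = 5


@dataclass(frozen=True)
class PredictionTriple:
    """One plant's three task outputs."""

    genotype_probabilities: np.ndarray  # 5-vector, sums to 1
    leaf_count_pred: float
    leaf_area_pred: float  # normalized units (foreground fraction)

    @property
    def genotype_index(self) -> int:
        return int(np.argmax(self.genotype_probabilities))

    @property
    def leaf_count_rounded(self) -> int:
        return int(round(self.leaf_count_pred))


@dataclass
class TrainConfig:
    epochs: int = 300
    batch_size: int = 32
    learning_rate: float = 1e-3
    loss_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (cls, count, area)
    weight_decay: float = 0.0  # lambda in the L2 penalty
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if any(w < 0 for w in self.loss_weights):
            raise ValueError("loss weights must be nonnegative")
        if not (0 < self.validation_fraction < 1):
            raise ValueError("validation_fraction must be in (0, 1)")


# ---------------------------------------------------------------------------
# layer math
# ---------------------------------------------------------------------------

def _conv_forward(x, W, b, padding):
    k = W.shape[0]
    if padding == "same":
        pad = k // 2
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    n, h, w, c = x.shape
    oh, ow = h - k + 1, w - k + 1
    win = sliding_window_view(x, (k, k), axis=(1, 2))  # (n, oh, ow, c, k, k)
    cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(n, oh, ow, k * k * c)
    z = cols.reshape(-1, k * k * c) @ W.reshape(k * k * c, -1) + b
    return z.reshape(n, oh, ow, -1), cols


def _conv_backward(dz, cols, W, x_shape, padding):
    k = W.shape[0]
    n, oh, ow, f = dz.shape
    c = W.shape[2]
    dz2 = dz.reshape(-1, f)
    dW = (cols.reshape(-1, k * k * c).T @ dz2).reshape(W.shape)
    db = dz2.sum(axis=0)
    dcols = (dz2 @ W.reshape(k * k * c, f).T).reshape(n, oh, ow, k, k, c)
    if padding == "same":
        pad = k // 2
        h, w = x_shape[1] + 2 * pad, x_shape[2] + 2 * pad
    else:
        pad = 0
        h, w = x_shape[1], x_shape[2]
    dx = np.zeros((n, h, w, c), dtype=dz.dtype)
    for i in range(k):
        for j in range(k):
            dx[:, i : i + oh, j : j + ow, :] += dcols[:, :, :, i, j, :]
    if pad:
        dx = dx[:, pad:-pad, pad:-pad, :]
    return dx, dW, db


def _softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class Network:
    """An :class:`ArchitectureSpec` bound to concrete float32 weights."""

    def __init__(self, arch: ArchitectureSpec, seed: int = 0):
        self.arch = arch
        self.shapes = arch.output_shapes()
        self.params: dict[str, dict[str, np.ndarray]] = {}
        rng = np.random.default_rng(seed)
        for layer in arch.layers:
            if layer.kind == "conv":
                p = _conv_defaults(layer.p)
                (src,) = [self.shapes[s] for s in layer.inbound]
                k, cin, cout = p["kernel"], src[-1], p["filters"]
                std = np.sqrt(2.0 / (k * k * cin))
                self.params[layer.name] = {
                    "W": rng.normal(0.0, std, (k, k, cin, cout)).astype(np.float32),
                    "b": np.zeros(cout, dtype=np.float32),
                }
            elif layer.kind in ("dense", "regression_head"):
                (src,) = [self.shapes[s] for s in layer.inbound]
                din, dout = src[0], layer.p.get("units", 1)
                lim = np.sqrt(6.0 / (din + dout))
                self.params[layer.name] = {
                    "W": rng.uniform(-lim, lim, (din, dout)).astype(np.float32),
                    "b": np.zeros(dout, dtype=np.float32),
                }

    # -- bookkeeping -------------------------------------------------------

    def n_parameters(self) -> int:
        return sum(int(a.size) for d in self.params.values() for a in d.values())

    def copy(self) -> "Network":
        clone = Network.__new__(Network)
        clone.arch = self.arch
        clone.shapes = dict(self.shapes)
        clone.params = {k: {n: a.copy() for n, a in d.items()} for k, d in self.params.items()}
        return clone

    # -- forward -----------------------------------------------------------

    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[dict[str, np.ndarray], dict]:
        """Run the DAG; returns (per-layer outputs, backward cache)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        outs: dict[str, np.ndarray] = {}
        cache: dict[str, dict] = {}
        for layer in self.arch.layers:
            ins = [outs[s] for s in layer.inbound]
            if layer.kind == "input":
                out = x
            elif layer.kind == "cast":
                out = ins[0].astype(np.float32)
            elif layer.kind == "conv":
                p = _conv_defaults(layer.p)
                W, b = self.params[layer.name]["W"], self.params[layer.name]["b"]
                z, cols = _conv_forward(ins[0], W, b, p["padding"])
                out = np.maximum(z, 0.0) if p["activation"] == "relu" else z
                cache[layer.name] = {"cols": cols, "z": z, "x_shape": ins[0].shape}
            elif layer.kind == "flatten":
                out = ins[0].reshape(ins[0].shape[0], -1)
                cache[layer.name] = {"shape": ins[0].shape}
            elif layer.kind == "dropout":
                rate = float(layer.p.get("rate", 0.25))
                if training and rate > 0:
                    if rng is None:
                        raise ValueError("training forward pass needs an rng for dropout")
                    mask = (rng.random(ins[0].shape) >= rate).astype(np.float32) / (1.0 - rate)
                    out = ins[0] * mask
                    cache[layer.name] = {"mask": mask}
                else:
                    out = ins[0]
                    cache[layer.name] = {"mask": None}
            elif layer.kind in ("dense", "regression_head"):
                W, b = self.params[layer.name]["W"], self.params[layer.name]["b"]
                out = ins[0] @ W + b
                cache[layer.name] = {"x": ins[0]}
            elif layer.kind == "softmax_head":
                out = _softmax(ins[0])
            elif layer.kind == "add":
                out = ins[0] + ins[1]
            elif layer.kind == "concat":
                out = np.concatenate(ins, axis=-1)
                cache[layer.name] = {"split": ins[0].shape[-1]}
            else:  # pragma: no cover
                raise AssertionError(layer.kind)
            outs[layer.name] = out
        return outs, cache

    def __call__(self, x: np.ndarray) -> list[PredictionTriple]:
        cls, reg1, reg2 = self.arch.heads()
        outs, _ = self.forward(x, training=False)
        probs, counts, areas = outs[cls], outs[reg1], outs[reg2]
        return [
            PredictionTriple(probs[i], float(counts[i, 0]), float(areas[i, 0]))
            for i in range(probs.shape[0])
        ]

    # -- loss & gradients --------------------------------------------------

    def loss_and_grads(
        self,
        x: np.ndarray,
        y_cls: np.ndarray,
        y_count: np.ndarray,
        y_area: np.ndarray,
        loss_weights: tuple[float, float, float],
        weight_decay: float,
        training: bool = True,
        rng: np.random.Generator | None = None,
    ) -> tuple[dict[str, float], dict[str, dict[str, np.ndarray]] | None]:
        """Total and per-task losses, plus parameter gradients when training."""
        w_cls, w_cnt, w_area = loss_weights
        cls_head, reg1, reg2 = self.arch.heads()
        logits_layer = self.arch.layer(cls_head).inbound[0]
        outs, cache = self.forward(x, training=training, rng=rng)
        n = x.shape[0] if x.ndim == 4 else 1

        probs = outs[cls_head]
        eps = 1e-12
        ce = float(-np.mean(np.log(probs[np.arange(n), y_cls] + eps)))
        mse_cnt = float(np.mean((outs[reg1][:, 0] - y_count) ** 2))
        mse_area = float(np.mean((outs[reg2][:, 0] - y_area) ** 2))
        l2 = sum(float((p["W"] ** 2).sum() + (p["b"] ** 2).sum()) for p in self.params.values())
        total = w_cls * ce + w_cnt * mse_cnt + w_area * mse_area + weight_decay * l2
        losses = {
            "loss": total,
            "cls_loss": ce,
            "count_loss": mse_cnt,
            "area_loss": mse_area,
        }
        if not np.isfinite(total):
            raise FloatingPointError(
                f"non-finite loss (cls={ce}, count={mse_cnt}, area={mse_area}); "
                "reduce the learning rate or check the inputs"
            )
        if not training:
            return losses, None

        # seed gradients at the head inputs / outputs
        grads_out: dict[str, np.ndarray] = {}
        onehot = np.zeros_like(probs)
        onehot[np.arange(n), y_cls] = 1.0
        grads_out[logits_layer] = (w_cls / n) * (probs - onehot)
        grads_out[reg1] = (2.0 * w_cnt / n) * (outs[reg1] - y_count[:, None])
        grads_out[reg2] = (2.0 * w_area / n) * (outs[reg2] - y_area[:, None])

        pgrads: dict[str, dict[str, np.ndarray]] = {}
        for layer in reversed(self.arch.layers):
            if layer.name not in grads_out:
                continue
            g = grads_out.pop(layer.name).astype(np.float32)

            def send(src: str, grad: np.ndarray) -> None:
                if src in grads_out:
                    grads_out[src] = grads_out[src] + grad
                else:
                    grads_out[src] = grad

            if layer.kind in ("input", "softmax_head"):
                continue
            if layer.kind == "cast":
                send(layer.inbound[0], g)
            elif layer.kind == "conv":
                p = _conv_defaults(layer.p)
                c = cache[layer.name]
                if p["activation"] == "relu":
                    g = g * (c["z"] > 0)
                dx, dW, db = _conv_backward(g, c["cols"], self.params[layer.name]["W"], c["x_shape"], p["padding"])
                pgrads[layer.name] = {"W": dW, "b": db}
                send(layer.inbound[0], dx)
            elif layer.kind == "flatten":
                send(layer.inbound[0], g.reshape(cache[layer.name]["shape"]))
            elif layer.kind == "dropout":
                mask = cache[layer.name]["mask"]
                send(layer.inbound[0], g if mask is None else g * mask)
            elif layer.kind in ("dense", "regression_head"):
                xin = cache[layer.name]["x"]
                pgrads[layer.name] = {"W": xin.T @ g, "b": g.sum(axis=0)}
                send(layer.inbound[0], g @ self.params[layer.name]["W"].T)
            elif layer.kind == "add":
                send(layer.inbound[0], g)
                send(layer.inbound[1], g)
            elif layer.kind == "concat":
                split = cache[layer.name]["split"]
                send(layer.inbound[0], g[..., :split])
                send(layer.inbound[1], g[..., split:])

        if weight_decay > 0:
            for name, p in self.params.items():
                pg = pgrads.setdefault(name, {"W": np.zeros_like(p["W"]), "b": np.zeros_like(p["b"])})
                pg["W"] = pg["W"] + 2.0 * weight_decay * p["W"]
                pg["b"] = pg["b"] + 2.0 * weight_decay * p["b"]
        return losses, pgrads


def build(arch: ArchitectureSpec, seed: int = 0) -> Network:
    """Instantiate an architecture with deterministic weight initialization.

    The trainable parameter count of the result equals
    :func:`~phenonas.arch.count_parameters` on the same spec.
    """
    net = Network(arch, seed)
    _, expected = count_parameters(arch)
    actual = net.n_parameters()
    if actual != expected:  # pragma: no cover - internal consistency
        raise AssertionError(f"parameter mismatch: built {actual}, counted {expected}")
    return net


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: {n: np.zeros_like(a) for n, a in d.items()} for k, d in params.items()}
        self.v = {k: {n: np.zeros_like(a) for n, a in d.items()} for k, d in params.items()}

    def step(self, params, grads):
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for k, d in grads.items():
            for n, g in d.items():
                g = g.astype(np.float32)
                m = self.m[k][n] = self.b1 * self.m[k][n] + (1 - self.b1) * g
                v = self.v[k][n] = self.b2 * self.v[k][n] + (1 - self.b2) * g * g
                params[k][n] -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


def _split(n: int, fraction: float, rng: np.random.Generator):
    order = rng.permutation(n)
    n_val = max(1, int(round(n * fraction)))
    return order[n_val:], order[:n_val]


def train(
    model: Network,
    arrays: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    config: TrainConfig,
    patience: int | None = None,
) -> tuple[Network, list[dict]]:
    """Minimize the weighted multi-task loss with Adam.

    ``arrays`` is ``(images, genotype_indices, leaf_counts, areas)`` as
    produced by :func:`phenonas.dataprep.build_training_arrays`.  The
    history records total and per-task training losses and the validation
    total loss per epoch.  With ``patience`` set, training stops once the
    validation loss has not improved for that many consecutive epochs.
    Deterministic given ``config.seed``.
    """
    x, y_cls, y_cnt, y_area = arrays
    if len(x) < 2:
        raise ValueError("need at least 2 samples to split off a validation set")
    rng = np.random.default_rng(config.seed)
    tr, va = _split(len(x), config.validation_fraction, rng)

    # Regression targets are standardized (training-split statistics) so the
    # three loss terms share a scale; the inverse transform is folded back
    # into the head weights on exit, so predictions and checkpoints stay in
    # raw units.  A warm-started model is unfolded first, which exactly
    # restores its trained standardized heads when the statistics match.
    stats = {}
    _, reg1, reg2 = model.arch.heads()
    for head, y in ((reg1, y_cnt), (reg2, y_area)):
        mu = float(np.mean(y[tr]))
        sigma = max(float(np.std(y[tr])), 1e-8)
        stats[head] = (mu, sigma)
        p = model.params[head]
        p["W"] /= sigma
        p["b"] = (p["b"] - mu) / sigma
    y_cnt = ((y_cnt - stats[reg1][0]) / stats[reg1][1]).astype(np.float32)
    y_area = ((y_area - stats[reg2][0]) / stats[reg2][1]).astype(np.float32)

    opt = _Adam(model.params, config.learning_rate)
    history: list[dict] = []
    best_val = np.inf
    since_improve = 0

    for epoch in range(config.epochs):
        order = tr[rng.permutation(len(tr))]
        sums = {"loss": 0.0, "cls_loss": 0.0, "count_loss": 0.0, "area_loss": 0.0}
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            losses, grads = model.loss_and_grads(
                x[idx], y_cls[idx], y_cnt[idx], y_area[idx],
                config.loss_weights, config.weight_decay, training=True, rng=rng,
            )
            opt.step(model.params, grads)
            for k in sums:
                sums[k] += losses[k]
            n_batches += 1
        val_losses, _ = model.loss_and_grads(
            x[va], y_cls[va], y_cnt[va], y_area[va],
            config.loss_weights, config.weight_decay, training=False,
        )
        record = {"epoch": epoch, **{k: v / n_batches for k, v in sums.items()},
                  "val_loss": val_losses["loss"]}
        history.append(record)

        if record["val_loss"] < best_val - 1e-12:
            best_val = record["val_loss"]
            since_improve = 0
        else:
            since_improve += 1
        if patience is not None and since_improve >= patience:
            break

    for head, (mu, sigma) in stats.items():
        p = model.params[head]
        p["W"] *= sigma
        p["b"] = p["b"] * sigma + mu
    return model, history


def predict(model: Network, image: np.ndarray) -> PredictionTriple:
    """Inference on one image (28x28x3 or reshapable to it); dropout off."""
    image = np.asarray(image, dtype=np.float32)
    h, w, c = model.arch.input_shape
    if image.shape != (h, w, c):
        if image.size != h * w * c:
            raise ValueError(f"cannot reshape image of shape {image.shape} to {(h, w, c)}")
        image = image.reshape(h, w, c)
    return model(image[None])[0]


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_checkpoint(model: Network, prefix: str | Path) -> None:
    """Write ``<prefix>.arch.json`` plus ``<prefix>.weights.npz``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    model.arch.save(prefix.with_suffix(".arch.json"))
    flat = {f"{layer}/{n}": a for layer, d in model.params.items() for n, a in d.items()}
    np.savez(prefix.with_suffix(".weights.npz"), **flat)


def load_checkpoint(prefix: str | Path) -> Network:
    prefix = Path(prefix)
    arch = ArchitectureSpec.load(prefix.with_suffix(".arch.json"))
    net = Network(arch, seed=0)
    with np.load(prefix.with_suffix(".weights.npz")) as data:
        for key in data.files:
            layer, n = key.split("/")
            net.params[layer][n] = data[key]
    return net


def history_to_csv(history: list[dict], path: str | Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(history[0].keys()))
        writer.writeheader()
        writer.writerows(history)
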