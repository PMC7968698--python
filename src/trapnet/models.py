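"""The three trap-image classifiers and their training harness.

Three architectures emit a probability vector over the five computed
categories from a 60x60 grayscale tile:

* **CNN-2** — a 2-convolution baseline: 3x3 kernels with strides 1 and 2,
  batch normalization on both layers, ReLU, 2x2 max pooling, 25% dropout
  on the second layer, a hidden dense layer and a softmax head.
* **CNN-13** — a 13-convolution network in homogeneous groups of 3x3
  layers with 2x2 pooling between groups and batch normalization + 25%
  dropout on every layer, closing with a single dense softmax head.
* **CapsNet** — a capsule network with dynamic routing: a 9x9 stride-1
  convolution (valid padding, 60 -> 52), a 9x9 stride-2 primary-capsule
  convolution (52 -> 22) reshaped to a 22x22 grid of 32 capsule types of
  dimension 8, squashed and routed into five 16-dimensional class
  capsules.  Class-capsule lengths, normalized to sum to one, are the
  class probabilities, and a dense decoder reconstructs the input from the
  correct class capsule (the reconstruction error regularizes training).

Training follows the statsmodels convention: :class:`TrapClassifier`
couples an architecture spec with a dataset, ``fit`` returns a
:class:`TrainingResult` holding the learned network, per-epoch history,
validation accuracy, ``predict`` and ``summary``.  CNNs train with
categorical cross-entropy; CapsNet with margin loss (m+ = 0.9, m- = 0.1,
lambda = 0.5) plus the reconstruction error down-weighted by 0.0005 per
pixel-sum.  The optimizer is Adam throughout.  Everything is seeded and
deterministic on a fixed backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .augment import AugmentationConfig, augment_dataset, apply_feature_norm, fit_feature_stats
from .data import TILE, TrapDataset, onehot
from .labels import CATEGORIES_5
from .nnet import (
    Adam,
    BatchNorm,
    Conv2d,
    Dense,
    Dropout,
    Flatten,
    MaxPool,
    ReLU,
    Sequential,
    Tensor,
    cross_entropy,
    softmax,
)
from .nnet.autodiff import einsum as einsum_op

ARCHITECTURES = ("cnn2", "cnn13", "capsnet")

# CapsNet shape chain on a 60x60 input (valid convolutions):
# 9x9 stride 1 -> 52x52 feature maps; 9x9 stride 2 -> 22x22 primary grid.
CONV1_SIDE = (TILE - 9) // 1 + 1
PRIMARY_GRID_SIDE = (CONV1_SIDE - 9) // 2 + 1


@dataclass(frozen=True)
class ModelSpec:
    """Architecture identifier plus the layer hyperparameters that matter."""

    architecture_id: str
    # CNN widths
    cnn2_channels: tuple[int, int] = (32, 64)
    cnn2_dense: int = 128
    # SimpleNet-style group widths, scaled to the 60x60 input
    cnn13_channels: tuple[int, ...] = (
        64, 128, 128, 128, 128, 128, 256, 256, 256, 256, 512, 256, 256
    )
    dropout: float = 0.25
    # CapsNet widths
    conv1_channels: int = 256
    primary_capsule_types: int = 32
    primary_capsule_dim: int = 8
    class_capsule_dim: int = 16
    decoder_widths: tuple[int, int] = (512, 1024)

    def __post_init__(self):
        if self.architecture_id not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture_id!r}")
        if self.architecture_id == "cnn13" and len(self.cnn13_channels) != 13:
            raise ValueError("cnn13 requires exactly 13 convolution widths")

    @property
    def shape_chain(self) -> dict[str, int]:
        """Derived CapsNet geometry on the 60x60 input contract."""
        n_caps = PRIMARY_GRID_SIDE ** 2 * self.primary_capsule_types
        return {
            "conv1_side": CONV1_SIDE,
            "primary_grid_side": PRIMARY_GRID_SIDE,
            "primary_capsule_types": self.primary_capsule_types,
            "primary_capsule_dim": self.primary_capsule_dim,
            "n_primary_capsules": n_caps,
            "n_class_capsules": len(CATEGORIES_5),
            "class_capsule_dim": self.class_capsule_dim,
        }


def build_cnn2(channels: tuple[int, int] = (32, 64), dense: int = 128) -> ModelSpec:
    """The 2-convolution baseline architecture."""
    return ModelSpec("cnn2", cnn2_channels=tuple(channels), cnn2_dense=dense)


def build_cnn13(channels: tuple[int, ...] | None = None) -> ModelSpec:
    """The 13-convolution architecture (homogeneous 3x3 groups)."""
    spec = ModelSpec("cnn13")
    if channels is not None:
        spec = ModelSpec("cnn13", cnn13_channels=tuple(channels))
    return spec


def build_capsnet(conv1_channels: int = 256, primary_capsule_types: int = 32,
                  decoder_widths: tuple[int, int] = (512, 1024)) -> ModelSpec:
    """The capsule network with dynamic routing."""
    return ModelSpec(
        "capsnet",
        conv1_channels=conv1_channels,
        primary_capsule_types=primary_capsule_types,
        decoder_widths=tuple(decoder_widths),
    )


@dataclass(frozen=True)
class HyperParams:
    """Training hyperparameters (the six grid-searched axes plus the seed)."""

    routing_iterations: int = 3      # capsnet only; ignored by the CNNs
    learning_rate: float = 1e-3
    batch_size: int = 32
    add_noise: bool = False          # additive Gaussian noise on training batches
    epochs: int = 5
    augmentation: bool = False
    augmentation_config: AugmentationConfig | None = None
    label_smoothing: float = 0.1     # CNN cross-entropy target smoothing
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size <= 0:
            raise ValueError("learning_rate and batch_size must be positive")
        if self.epochs < 1 or self.routing_iterations < 1:
            raise ValueError("epochs and routing_iterations must be >= 1")


# -- network implementations --------------------------------------------------

def _squash_t(s: Tensor, eps: float = 1e-12) -> Tensor:
    sq = (s ** 2.0).sum(axis=-1, keepdims=True)
    return s * (sq / (1.0 + sq)) * ((sq + eps) ** -0.5)


class _CNN:
    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        self.spec = spec
        p = spec.dropout
        if spec.architecture_id == "cnn2":
            c1, c2 = spec.cnn2_channels
            side = TILE // 2 // 2  # stride-2 conv then 2x2 pool
            self.net = Sequential(
                Conv2d(1, c1, 3, stride=1, pad=1, rng=rng), BatchNorm(c1), ReLU(),
                Conv2d(c1, c2, 3, stride=2, pad=1, rng=rng), BatchNorm(c2), ReLU(),
                Dropout(p, rng),
                MaxPool(2), Flatten(),
                Dense(c2 * side * side, spec.cnn2_dense, rng=rng), ReLU(),
                Dense(spec.cnn2_dense, 5, rng=rng),
            )
        else:
            layers = []
            c_in = 1
            pool_after = {3, 6, 9, 11}  # 0-based layer indices; 60->30->15->7->3
            side = TILE
            for i, c_out in enumerate(spec.cnn13_channels):
                layers += [Conv2d(c_in, c_out, 3, stride=1, pad=1, rng=rng),
                           BatchNorm(c_out), ReLU(), Dropout(p, rng)]
                if i in pool_after:
                    layers.append(MaxPool(2))
                    side //= 2
                c_in = c_out
            layers += [MaxPool(2), Flatten(),
                       Dense(c_in * (side // 2) ** 2, 5, rng=rng)]
            self.net = Sequential(*layers)

    def parameters(self):
        return self.net.parameters()

    def forward(self, x: Tensor, train: bool, hp: HyperParams) -> Tensor:
        return softmax(self.net(x, train=train), axis=-1)

    def loss(self, x: Tensor, y: np.ndarray, hp: HyperParams) -> tuple[Tensor, Tensor]:
        probs = self.forward(x, True, hp)
        return cross_entropy(probs, y, smoothing=hp.label_smoothing), probs


class _CapsNet:
    RECON_WEIGHT = 0.0005  # reconstruction error scaled per pixel-sum
    M_POS, M_NEG, LAMBDA = 0.9, 0.1, 0.5

    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        self.spec = spec
        t, d, dc = spec.primary_capsule_types, spec.primary_capsule_dim, spec.class_capsule_dim
        self.conv1 = Conv2d(1, spec.conv1_channels, 9, stride=1, pad=0, rng=rng)
        self.conv2 = Conv2d(spec.conv1_channels, t * d, 9, stride=2, pad=0, rng=rng)
        self.n_caps = PRIMARY_GRID_SIDE ** 2 * t
        self.w = Tensor(rng.normal(0.0, 0.1, (self.n_caps, d, 5 * dc)),
                        requires_grad=True)
        d1, d2 = spec.decoder_widths
        self.dec = Sequential(
            Dense(dc, d1, rng=rng), ReLU(),
            Dense(d1, d2, rng=rng), ReLU(),
            Dense(d2, TILE * TILE, rng=rng),
        )

    def parameters(self):
        return (self.conv1.parameters() + self.conv2.parameters() + [self.w]
                + self.dec.parameters())

    def class_capsules(self, x: Tensor, hp: HyperParams) -> Tensor:
        """Forward pass to the five class-capsule output vectors (N, 5, dc)."""
        n = x.shape[0]
        d, dc = self.spec.primary_capsule_dim, self.spec.class_capsule_dim
        h = self.conv1(x).relu()
        h = self.conv2(h)                                  # (N, t*d, 22, 22)
        t = self.spec.primary_capsule_types
        u = (h.reshape(n, t, d, PRIMARY_GRID_SIDE ** 2)
              .transpose(0, 1, 3, 2)
              .reshape(n, self.n_caps, d))
        u = _squash_t(u)
        # prediction vectors u_hat[j|i] = W_ij u_i, capsule-major so every
        # capsule contributes one (N, d) @ (d, 5*dc) product
        u_hat = (u.transpose(1, 0, 2) @ self.w).reshape(self.n_caps, n, 5, dc)
        u_hat = u_hat.transpose(1, 0, 2, 3)                # (N, caps, 5, dc)
        b = Tensor(np.zeros((n, self.n_caps, 5), dtype=np.float32))
        for it in range(hp.routing_iterations):
            c = softmax(b, axis=-1)
            s = einsum_op("nij,nijk->njk", c, u_hat)
            v = _squash_t(s)                               # (N, 5, dc)
            if it < hp.routing_iterations - 1:
                b = b + einsum_op("nijk,njk->nij", u_hat, v)
        return v

    def forward(self, x: Tensor, train: bool, hp: HyperParams) -> Tensor:
        v = self.class_capsules(x, hp)
        lengths = ((v ** 2.0).sum(axis=-1) + 1e-12) ** 0.5
        return lengths / lengths.sum(axis=-1, keepdims=True)

    def loss(self, x: Tensor, y: np.ndarray, hp: HyperParams) -> tuple[Tensor, Tensor]:
        n = x.shape[0]
        v = self.class_capsules(x, hp)
        lengths = ((v ** 2.0).sum(axis=-1) + 1e-12) ** 0.5
        t = Tensor(y)
        margin = (
            t * ((self.M_POS - lengths).relu() ** 2.0)
            + self.LAMBDA * (1.0 - t) * ((lengths - self.M_NEG).relu() ** 2.0)
        ).sum() * (1.0 / n)
        # decoder sees the correct class capsule only (masked by the label)
        masked = (v * Tensor(y[:, :, None])).sum(axis=1)
        recon = self.dec(masked, train=True).sigmoid()
        recon_err = ((recon - x.reshape(n, -1)) ** 2.0).sum() * (self.RECON_WEIGHT / n)
        probs = lengths / lengths.sum(axis=-1, keepdims=True)
        return margin + recon_err, probs

    def reconstruct(self, x: Tensor, labels_onehot: np.ndarray, hp: HyperParams) -> np.ndarray:
        v = self.class_capsules(x, hp)
        masked = (v * Tensor(labels_onehot[:, :, None])).sum(axis=1)
        out = self.dec(masked, train=False).sigmoid()
        return out.data.reshape(-1, TILE, TILE)


def _build_network(spec: ModelSpec, rng: np.random.Generator):
    return _CapsNet(spec, rng) if spec.architecture_id == "capsnet" else _CNN(spec, rng)


# -- Model / Results ----------------------------------------------------------

class TrapClassifier:
    """A classifier architecture bound to a dataset with train/val splits.

    ``fit`` trains on the train split only (optionally augmented), measures
    accuracy on the untouched validation split, and returns a
    :class:`TrainingResult`.
    """

    def __init__(self, spec: ModelSpec, dataset: TrapDataset):
        self.spec = spec
        self.dataset = dataset

    @staticmethod
    def from_architecture(name: str, dataset: TrapDataset, **kw) -> "TrapClassifier":
        builder = {"cnn2": build_cnn2, "cnn13": build_cnn13,
                   "capsnet": build_capsnet}[name]
        return TrapClassifier(builder(**kw), dataset)

    def fit(self, hp: HyperParams | None = None, verbose: bool = False) -> "TrainingResult":
        hp = hp or HyperParams()
        train = self.dataset.split("train")
        val = self.dataset.split("val")
        if len(train) == 0:
            raise ValueError("training split is empty")
        if len(val) == 0:
            raise ValueError("validation split is empty")
        if hp.augmentation:
            cfg = hp.augmentation_config or AugmentationConfig(multiplier=2)
            train = augment_dataset(train, cfg, seed=hp.seed)
            stats = None
            if cfg.featurewise_center or cfg.featurewise_std_normalization:
                stats = fit_feature_stats(train)
        else:
            cfg, stats = None, None

        rng = np.random.default_rng(hp.seed)
        net = _build_network(self.spec, rng)
        opt = Adam(net.parameters(), lr=hp.learning_rate)
        x_train = train.images
        if stats is not None:
            x_train = apply_feature_norm(x_train, stats)
        x_train = x_train.astype(np.float32)
        y_train = onehot(train.labels, CATEGORIES_5)
        noise_rng = np.random.default_rng(hp.seed + 1)
        history = []
        best = {"val_acc": -1.0, "state": None}
        for epoch in range(hp.epochs):
            # brief warmup: the first epoch runs at a fifth of the target
            # rate, which keeps deep stacks from diverging at the start
            opt.lr = hp.learning_rate * (0.2 if epoch == 0 and hp.epochs > 1 else 1.0)
            order = rng.permutation(len(x_train))
            losses, correct = [], 0
            for start in range(0, len(order), hp.batch_size):
                idx = order[start : start + hp.batch_size]
                xb = x_train[idx][:, None, :, :]
                if hp.add_noise:
                    xb = np.clip(
                        xb + noise_rng.normal(0, 0.02, xb.shape), 0, 1
                    ).astype(np.float32)
                loss, probs = net.loss(Tensor(xb), y_train[idx], hp)
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data) * len(idx))
                correct += int(
                    (np.argmax(probs.data, axis=1) == np.argmax(y_train[idx], axis=1)).sum()
                )
            _calibrate_batchnorm(net, x_train, hp)
            val_acc, val_loss = _accuracy(net, val, hp, stats)
            if val_acc > best["val_acc"]:
                best.update(val_acc=val_acc, state=_snapshot_state(net))
            history.append({
                "epoch": epoch + 1,
                "loss": sum(losses) / len(x_train),
                "acc": correct / len(x_train),
                "val_loss": val_loss,
                "val_acc": val_acc,
            })
            if verbose:
                print(f"[{self.spec.architecture_id}] epoch {epoch + 1}: "
                      f"loss {history[-1]['loss']:.4f} acc {history[-1]['acc']:.4f} "
                      f"val_acc {val_acc:.4f}")
        # keep the epoch with the best validation accuracy (selection on
        # the validation split only; the test split is never consulted)
        _restore_state(net, best["state"])
        return TrainingResult(
            spec=self.spec,
            hyperparams=hp,
            network=net,
            history=pd.DataFrame(history),
            validation_accuracy=best["val_acc"],
            feature_stats=stats,
        )


from contextlib import contextmanager


@contextmanager
def _no_grad(net):
    """Temporarily drop requires_grad so forward passes skip the tape."""
    params = net.parameters()
    flags = [p.requires_grad for p in params]
    for p in params:
        p.requires_grad = False
    try:
        yield
    finally:
        for p, f in zip(params, flags):
            p.requires_grad = f


def _network_layers(net):
    if isinstance(net, _CNN):
        return net.net.layers
    return net.dec.layers


def _snapshot_state(net):
    params = [p.data.copy() for p in net.parameters()]
    bn = [(l.running_mean.copy(), l.running_var.copy())
          for l in _network_layers(net) if isinstance(l, BatchNorm)]
    return params, bn


def _restore_state(net, state):
    if state is None:
        return
    params, bn = state
    for p, d in zip(net.parameters(), params):
        p.data = d
    bns = [l for l in _network_layers(net) if isinstance(l, BatchNorm)]
    for l, (m, v) in zip(bns, bn):
        l.running_mean, l.running_var = m, v


def _calibrate_batchnorm(net, x_train: np.ndarray, hp: HyperParams,
                         chunk: int = 256, max_images: int = 512) -> None:
    """Replace batch-norm running averages with population statistics of
    (up to ``max_images`` of) the training set under the current weights,
    dropout disabled.  A few hundred images pin the per-channel moments
    tightly; using more only costs forward passes."""
    layers = list(_network_layers(net))
    bns = [l for l in layers if isinstance(l, BatchNorm)]
    if not bns:
        return
    if len(x_train) > max_images:  # strided subset keeps class coverage
        x_train = x_train[:: len(x_train) // max_images + 1]
    drops = [l for l in layers if isinstance(l, Dropout)]
    for d in drops:
        d.enabled = False
    for l in bns:
        l.start_accumulate()
    with _no_grad(net):
        for start in range(0, len(x_train), chunk):
            xb = x_train[start : start + chunk][:, None, :, :]
            net.forward(Tensor(xb), True, hp)
    for l in bns:
        l.finish_accumulate()
    for d in drops:
        d.enabled = True


def _predict_probs(net, images: np.ndarray, hp: HyperParams,
                   stats=None, chunk: int = 128) -> np.ndarray:
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 2:
        images = images[None]
    if images.shape[1:] != (TILE, TILE):
        raise ValueError(f"images must be (n, {TILE}, {TILE}), got {images.shape}")
    if stats is not None:
        images = apply_feature_norm(images, stats)
    out = []
    with _no_grad(net):
        for start in range(0, len(images), chunk):
            xb = images[start : start + chunk][:, None, :, :]
            out.append(net.forward(Tensor(xb), False, hp).data)
    return np.concatenate(out) if out else np.zeros((0, 5))


def _accuracy(net, ds: TrapDataset, hp: HyperParams, stats=None) -> tuple[float, float]:
    """(accuracy, mean negative log-likelihood) on a split."""
    probs = _predict_probs(net, ds.images, hp, stats)
    pred = np.argmax(probs, axis=1)
    true = np.array([CATEGORIES_5.index(l) for l in ds.labels])
    nll = float(-np.mean(np.log(probs[np.arange(len(true)), true] + 1e-12)))
    return float((pred == true).mean()), nll


@dataclass
class TrainingResult:
    """A fitted classifier: learned parameters, history and diagnostics."""

    spec: ModelSpec
    hyperparams: HyperParams
    network: object = field(repr=False)
    history: pd.DataFrame = field(repr=False)
    validation_accuracy: float = 0.0
    feature_stats: object = field(default=None, repr=False)

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Probability vectors over the five computed categories, (n, 5)."""
        return _predict_probs(self.network, images, self.hyperparams,
                              self.feature_stats)

    def predict_labels(self, images: np.ndarray, space: int = 5) -> list[str]:
        from .labels import merge_probs, categories
        probs = self.predict(images)
        if space == 4:
            probs = merge_probs(probs)
        cats = categories(space)
        return [cats[i] for i in np.argmax(probs, axis=1)]

    def summary(self) -> str:
        n_par = sum(p.data.size for p in self.network.parameters())
        lines = [
            f"TrapClassifier fit: {self.spec.architecture_id}",
            f"  parameters: {n_par:,}",
            f"  epochs: {self.hyperparams.epochs}  "
            f"lr: {self.hyperparams.learning_rate}  "
            f"batch: {self.hyperparams.batch_size}  "
            f"augmentation: {self.hyperparams.augmentation}",
            f"  final train loss {self.history['loss'].iloc[-1]:.4f}, "
            f"train acc {self.history['acc'].iloc[-1]:.4f}",
            f"  validation accuracy: {self.validation_accuracy:.4f}",
        ]
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        """Single-file archive: spec + hyperparams + weights + history."""
        path = Path(path)
        arrays = {f"p{i}": p.data for i, p in enumerate(self.network.parameters())}
        bn = _bn_buffers(self.network)
        for i, (m, v) in enumerate(bn):
            arrays[f"bn_mean{i}"], arrays[f"bn_var{i}"] = m, v
        hp = asdict(self.hyperparams)
        hp["augmentation_config"] = (
            asdict(self.hyperparams.augmentation_config)
            if self.hyperparams.augmentation_config else None
        )
        meta = {
            "spec": asdict(self.spec),
            "hyperparams": hp,
            "validation_accuracy": self.validation_accuracy,
            "history": self.history.to_dict(orient="list"),
        }
        np.savez_compressed(path, meta=yaml.safe_dump(meta), **arrays)

    @staticmethod
    def load(path: str | Path) -> "TrainingResult":
        with np.load(path, allow_pickle=False) as z:
            meta = yaml.safe_load(str(z["meta"]))
            spec_kw = meta["spec"]
            for k, v in spec_kw.items():
                if isinstance(v, list):
                    spec_kw[k] = tuple(v)
            spec = ModelSpec(**spec_kw)
            hp_kw = meta["hyperparams"]
            aug = hp_kw.pop("augmentation_config", None)
            if aug:
                if isinstance(aug.get("brightness_range"), list):
                    aug["brightness_range"] = tuple(aug["brightness_range"])
                hp_kw["augmentation_config"] = AugmentationConfig(**aug)
            hp = HyperParams(**hp_kw)
            net = _build_network(spec, np.random.default_rng(0))
            for i, p in enumerate(net.parameters()):
                p.data = z[f"p{i}"]
            for i, (m, v) in enumerate(_bn_buffers(net)):
                m[...] = z[f"bn_mean{i}"]
                v[...] = z[f"bn_var{i}"]
        return TrainingResult(
            spec=spec, hyperparams=hp, network=net,
            history=pd.DataFrame(meta["history"]),
            validation_accuracy=meta["validation_accuracy"],
        )


def _bn_buffers(net):
    out = []
    layers = net.net.layers if isinstance(net, _CNN) else []
    for l in layers:
        if isinstance(l, BatchNorm):
            out.append((l.running_mean, l.running_var))
    return out


def n_parameters(spec: ModelSpec) -> int:
    """Total learnable parameter count of an architecture spec."""
    net = _build_network(spec, np.random.default_rng(0))
    return sum(p.data.size for p in net.parameters())


# -- spec-level functional surface -------------------------------------------

def train(spec: ModelSpec, dataset: TrapDataset,
          hp: HyperParams | None = None, verbose: bool = False) -> TrainingResult:
    """Train ``spec`` on the dataset's train split; validate on ``val``."""
    return TrapClassifier(spec, dataset).fit(hp, verbose=verbose)


def predict(model: TrainingResult, images: np.ndarray) -> np.ndarray:
    """Per-image probability vectors over the five computed categories."""
    return model.predict(images)
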