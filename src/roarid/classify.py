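"""Image classifiers over time-frequency images.

The study fine-tunes ImageNet-pretrained CNNs (AlexNet, VGG16, ResNet50)
with the final fully connected layer replaced by a fresh n-way head.
Here those backbones are runtime plug-ins resolved through torch /
torchvision when available; the package's built-in, always-available
backbone is ``tiny-scratch``: two deterministic random convolutional
blocks (conv -> ReLU -> 2x2 max pool) whose fixed features feed a
trainable softmax head optimised by minibatch SGD with momentum.  Fixed
random convolutional features plus a trained linear head is a standard
small-data construction (extreme-learning-machine style) and keeps the
whole pipeline runnable on one CPU with no pretrained weights.

Head replacement therefore holds trivially for the built-ins: the
backbone weights are a pure function of the backbone seed and are never
touched by training.
"""

from __future__ import annotations

import importlib.util
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import BackboneUnavailableError, DegenerateFoldError

__all__ = [
    "BackboneSpec",
    "TrainConfig",
    "ScoreMatrix",
    "build_classifier",
    "train_classifier",
    "predict_scores",
    "fold_seed",
    "BUILTIN_BACKBONES",
    "PLUGIN_BACKBONES",
]

BUILTIN_BACKBONES = ("tiny-scratch",)
PLUGIN_BACKBONES = ("alexnet-class", "vgg16-class", "resnet50-class")


@dataclass(frozen=True)
class BackboneSpec:
    """Identifies a feature backbone and how it is initialised."""

    name: str = "tiny-scratch"
    input_height: int = 64
    input_width: int = 64
    weights_origin: str = "random_init"  # or "pretrained_imagenet"
    trainable_scope: str = "head_only"   # or "all_layers" (plug-ins only)
    backbone_seed: int = 2023


@dataclass(frozen=True)
class TrainConfig:
    """Softmax-head optimisation hyperparameters (none are reported by the
    study; all are config)."""

    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 0.05
    optimizer: str = "sgd"
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class ScoreMatrix:
    """Per-sample posterior scores over classes; rows sum to 1."""

    values: np.ndarray
    sample_ids: list[str]
    class_labels: list[str]
    true_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.sample_ids), len(self.class_labels)):
            raise ValueError("score matrix shape does not match ids/labels")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        if len(self.class_labels) < 2:
            raise ValueError("need at least 2 classes")

    def predictions(self) -> list[str]:
        """Argmax class per row; ties break toward the lowest class index."""
        return [self.class_labels[i] for i in np.argmax(self.values, axis=1)]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=self.class_labels)
        df.insert(0, "sample_id", self.sample_ids)
        df.insert(1, "true_label",
                  self.true_labels if self.true_labels is not None else "")
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ScoreMatrix":
        df = pd.read_csv(path)
        class_labels = [c for c in df.columns if c not in ("sample_id", "true_label")]
        true = None
        if "true_label" in df.columns and df["true_label"].notna().all():
            true = df["true_label"].astype(str).tolist()
        return cls(df[class_labels].to_numpy(dtype=float),
                   df["sample_id"].astype(str).tolist(),
                   class_labels, true)


def fold_seed(master_seed: int, fold_index: int) -> int:
    """Deterministic per-fold seed fan-out from one master seed."""
    return zlib.crc32(f"fold:{master_seed}:{fold_index}".encode()) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# tiny-scratch backbone: fixed random conv features
# ---------------------------------------------------------------------------

def _conv_valid(x: np.ndarray, filters: np.ndarray) -> np.ndarray:
    """x: (N, H, W, Cin); filters: (Cout, kh, kw, Cin) -> (N, H', W', Cout)."""
    kh, kw = filters.shape[1], filters.shape[2]
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    # win: (N, H', W', Cin, kh, kw)
    return np.einsum("nijckl,oklc->nijo", win, filters, optimize=True)


def _max_pool2(x: np.ndarray) -> np.ndarray:
    n, h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    x = x[:, : h2 * 2, : w2 * 2]
    return x.reshape(n, h2, 2, w2, 2, c).max(axis=(2, 4))


class TinyConvBackbone:
    """Two fixed random conv blocks; features are deterministic in the seed."""

    def __init__(self, spec: BackboneSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.backbone_seed)
        self.filters1 = rng.standard_normal((8, 5, 5, 1)) / 5.0
        self.filters2 = rng.standard_normal((16, 3, 3, 8)) / 8.0

    def weights(self) -> tuple[np.ndarray, np.ndarray]:
        return self.filters1, self.filters2

    def features(self, images: np.ndarray) -> np.ndarray:
        """images: (N, H, W, 3) in [0, 255] -> (N, F) feature matrix."""
        x = images.mean(axis=3, keepdims=True) / 255.0 - 0.5
        x = np.maximum(_conv_valid(x, self.filters1), 0.0)
        x = _max_pool2(x)
        x = np.maximum(_conv_valid(x, self.filters2), 0.0)
        x = _max_pool2(x)
        x = _max_pool2(x)  # coarse spatial grid keeps the head small
        return x.reshape(len(x), -1)


class _SoftmaxHead:
    """Multinomial logistic head trained with minibatch SGD + momentum."""

    def __init__(self, n_features: int, n_classes: int, seed: int):
        rng = np.random.default_rng(seed)
        self.W = 0.01 * rng.standard_normal((n_features, n_classes))
        self.b = np.zeros(n_classes)
        self.mu = np.zeros(n_features)
        self.sd = np.ones(n_features)
        self.loss_history: list[float] = []
        self._rng = rng

    @staticmethod
    def _softmax(z: np.ndarray) -> np.ndarray:
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def fit(self, feats: np.ndarray, y: np.ndarray, cfg: TrainConfig) -> None:
        self.mu = feats.mean(axis=0)
        self.sd = feats.std(axis=0)
        self.sd[self.sd < 1e-8] = 1.0
        x = (feats - self.mu) / self.sd
        n = len(x)
        vel_w = np.zeros_like(self.W)
        vel_b = np.zeros_like(self.b)
        onehot = np.eye(self.W.shape[1])[y]
        for _ in range(cfg.epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                p = self._softmax(x[idx] @ self.W + self.b)
                epoch_loss -= float(
                    np.sum(np.log(np.maximum(p[np.arange(len(idx)), y[idx]], 1e-12)))
                )
                grad = (p - onehot[idx]) / len(idx)
                gw = x[idx].T @ grad + 1e-4 * self.W
                gb = grad.sum(axis=0)
                vel_w = cfg.momentum * vel_w - cfg.learning_rate * gw
                vel_b = cfg.momentum * vel_b - cfg.learning_rate * gb
                self.W += vel_w
                self.b += vel_b
            self.loss_history.append(epoch_loss / n)

    def predict_proba(self, feats: np.ndarray) -> np.ndarray:
        x = (feats - self.mu) / self.sd
        return self._softmax(x @ self.W + self.b)


# ---------------------------------------------------------------------------
# plug-in backbones (torch/torchvision, resolved at runtime)
# ---------------------------------------------------------------------------

def _resolve_plugin(spec: BackboneSpec):
    if importlib.util.find_spec("torch") is None or \
            importlib.util.find_spec("torchvision") is None:
        raise BackboneUnavailableError(
            f"backbone {spec.name!r} needs torch/torchvision with pretrained "
            "weights, which are not available here; use the built-in "
            "'tiny-scratch' backbone or weights_origin='random_init' with a "
            "plug-in environment that provides them"
        )
    # Imported lazily so the package has no hard torch dependency.
    raise BackboneUnavailableError(  # pragma: no cover - torch absent in CI
        f"plug-in adapter for {spec.name!r} must be registered by the caller"
    )


# ---------------------------------------------------------------------------
# public classifier handle
# ---------------------------------------------------------------------------

class ImageClassifier:
    """A backbone plus a replaceable softmax head."""

    def __init__(self, spec: BackboneSpec, n_classes: int):
        self.spec = spec
        self.n_classes = n_classes
        self.backbone = TinyConvBackbone(spec)
        self.head: _SoftmaxHead | None = None
        self.class_labels: list[str] | None = None

    # -- feature caching hook used by evaluation.cross_validate ----------
    def feature_map(self, images) -> np.ndarray:
        return self.backbone.features(np.asarray(images, dtype=np.float64))

    def fit_head(self, feats: np.ndarray, labels, cfg: TrainConfig) -> None:
        classes = sorted(set(labels))
        if len(classes) < self.n_classes:
            missing = self.n_classes - len(classes)
            raise DegenerateFoldError(
                f"{missing} of {self.n_classes} classes absent from training "
                f"labels (got {classes}); reject this fold upstream"
            )
        self.class_labels = classes
        y = np.array([classes.index(l) for l in labels])
        self.head = _SoftmaxHead(feats.shape[1], self.n_classes, cfg.seed)
        self.head.fit(feats, y, cfg)

    @property
    def loss_history(self) -> list[float]:
        return self.head.loss_history if self.head else []


def build_classifier(spec: BackboneSpec, n_classes: int) -> ImageClassifier:
    """Construct a classifier with a fresh n-way head.

    The backbone is loaded per ``weights_origin``; plug-in names raise an
    explicit resolvable error when no pretrained runtime is available.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if spec.name in PLUGIN_BACKBONES:
        _resolve_plugin(spec)
    if spec.name not in BUILTIN_BACKBONES:
        raise ValueError(
            f"unknown backbone {spec.name!r}; builtins: {BUILTIN_BACKBONES}, "
            f"plug-ins: {PLUGIN_BACKBONES}"
        )
    if spec.trainable_scope == "all_layers":
        raise ValueError(
            "built-in backbones train head_only (fixed random conv features); "
            "all_layers fine-tuning applies to pretrained plug-ins"
        )
    return ImageClassifier(spec, n_classes)


def train_classifier(handle: ImageClassifier, images, labels,
                     cfg: TrainConfig) -> ImageClassifier:
    """Fit the softmax head on (images, labels); returns the same handle.

    Deterministic given ``cfg.seed`` and fixed inputs; every class must be
    present in ``labels``.
    """
    images = np.asarray(images, dtype=np.float64)
    if len(images) != len(labels):
        raise ValueError("images and labels must align")
    if len(images) < handle.n_classes:
        raise ValueError("need at least one image per class")
    handle.fit_head(handle.feature_map(images), list(labels), cfg)
    return handle


def predict_scores(handle: ImageClassifier, images, sample_ids) -> ScoreMatrix:
    """Softmax-normalised scores in input order."""
    if handle.head is None or handle.class_labels is None:
        raise ValueError("classifier is not trained")
    images = np.asarray(images, dtype=np.float64)
    if len(images) == 0 or len(images) != len(sample_ids):
        raise ValueError("images and sample_ids must align and be nonempty")
    probs = handle.head.predict_proba(handle.feature_map(images))
    return ScoreMatrix(probs, list(sample_ids), handle.class_labels)
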