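"""The classification function: CNN backbone + modified global-pooling head.

The classifier maps a normalized RGB image ``x`` to five class probabilities.
A convolutional backbone produces a spatial feature map at 1/r of the input
resolution (r = 16 for the default backbone); the modified representation
head then applies

    1x1 convolution (C_f -> 5 channels)  ->  batch normalization
    ->  global average pooling           ->  log-softmax,

so the network emits log probabilities directly, with no fully connected
layer.  The decision rule is ``c = argmax_j p_j(F(x))`` where ``p`` is the
softmax of the pooled responses.  Because pooling is the last spatial
operation, the per-class pre-pooling maps are class activation maps: their
spatial mean equals the class logit exactly.

The default ``tiny`` backbone is a four-stage strided ConvNet sized for CPU
work (64 x 64 inputs train in minutes); the full high-resolution network
(HRNet-W18) the design targets at clinical scale is an optional plug-in that
requires external weights.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from ._nn import BatchNorm2d, Conv2d, Network, Param, ReLU

__all__ = [
    "ClassScores",
    "Prediction",
    "softmax",
    "log_softmax",
    "head_forward",
    "predict",
    "make_backbone",
    "BackboneUnavailableError",
    "OralClassifier",
    "N_CLASSES",
]

N_CLASSES = 5


@dataclass(frozen=True)
class ClassScores:
    """Per-image class log-probabilities and probabilities."""

    log_probs: np.ndarray  # (5,)

    @property
    def probs(self) -> np.ndarray:
        return np.exp(self.log_probs)


@dataclass(frozen=True)
class Prediction:
    """The decision-rule output: argmax class and its probability."""

    class_index: int
    confidence: float


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax (max-subtracted) along the last axis."""
    z = np.asarray(logits, dtype=np.float64)
    if not np.all(np.isfinite(z)):
        raise ValueError("softmax requires finite logits")
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def log_softmax(logits: np.ndarray) -> np.ndarray:
    z = np.asarray(logits, dtype=np.float64)
    if not np.all(np.isfinite(z)):
        raise ValueError("log_softmax requires finite logits")
    z = z - z.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


def predict(scores: ClassScores) -> Prediction:
    """Argmax decision rule; exact ties resolve to the lowest class index."""
    probs = scores.probs
    idx = int(np.argmax(probs))
    return Prediction(class_index=idx, confidence=float(probs[idx]))


class BackboneUnavailableError(RuntimeError):
    """Requested backbone (or its pretrained weights) is not available."""


class TinyBackbone(Network):
    """Four-stage strided ConvNet: 3 -> 8 -> 16 -> 32 -> 64 channels, r = 16.

    Each stage is Conv3x3(stride 2) -> BN -> ReLU, so a 512 x 512 input
    yields a 32 x 32 x 64 feature map and a 64 x 64 input a 4 x 4 map.
    """

    reduction = 16
    out_channels = 64
    name = "tiny"

    def __init__(self, rng_seed: int = 0):
        rng = np.random.default_rng(rng_seed)
        layers = []
        channels = [3, 8, 16, 32, 64]
        for cin, cout in zip(channels[:-1], channels[1:]):
            layers += [
                Conv2d(cin, cout, 3, stride=2, padding=1, rng=rng),
                BatchNorm2d(cout),
                ReLU(),
            ]
        super().__init__(layers)


def make_backbone(name: str, pretrained: bool = False, rng_seed: int = 0):
    """Instantiate a feature backbone by name.

    ``tiny`` is the built-in CPU-scale backbone (random init only).
    ``hrnet_w18`` is the full high-resolution network; it needs the optional
    PyTorch implementation plus an ImageNet checkpoint, neither of which
    ships with this package, so requesting it raises
    :class:`BackboneUnavailableError` rather than silently substituting a
    randomly initialized network.
    """
    if name == "tiny":
        if pretrained:
            raise BackboneUnavailableError(
                "no pretrained weights exist for the 'tiny' backbone; "
                "construct it with pretrained=False and train it"
            )
        return TinyBackbone(rng_seed=rng_seed)
    if name == "hrnet_w18":
        raise BackboneUnavailableError(
            "the 'hrnet_w18' backbone requires the optional PyTorch "
            "implementation and an ImageNet-pretrained checkpoint; install "
            "torch, obtain the weights, and register the backbone — it is "
            "never substituted by a randomly initialized network"
        )
    raise ValueError(f"unknown backbone {name!r}; supported: 'tiny', 'hrnet_w18'")


class _Head:
    """Modified representation head: 1x1 conv to 5 channels + BN."""

    def __init__(self, in_channels: int, n_classes: int, rng: np.random.Generator):
        self.conv = Conv2d(in_channels, n_classes, 1, rng=rng)
        # small-scale init of the output layer: an untrained network predicts
        # near-uniform probabilities (cross-entropy ~ ln C on balanced data);
        # batch norm makes the training dynamics invariant to this scale
        self.conv.weight.value *= 0.01
        self.bn = BatchNorm2d(n_classes)

    @property
    def params(self) -> list[Param]:
        return self.conv.params + self.bn.params

    def forward(self, features: np.ndarray, train: bool) -> np.ndarray:
        return self.bn.forward(self.conv.forward(features, train), train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.bn.backward(dout))


class OralClassifier:
    """Backbone + modified head, operating on (N, 3, H, W) float32 input."""

    def __init__(self, backbone=None, rng_seed: int = 0, n_classes: int = N_CLASSES):
        self.backbone = backbone if backbone is not None else TinyBackbone(rng_seed)
        self.head = _Head(
            self.backbone.out_channels, n_classes, np.random.default_rng(rng_seed + 1)
        )
        self.n_classes = n_classes

    # -- forward ------------------------------------------------------------

    @property
    def params(self) -> list[Param]:
        return self.backbone.params + self.head.params

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def forward_prepool(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """The 5-channel pre-pooling map (the class activation maps)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if not np.all(np.isfinite(x)):
            raise ValueError("model input must be finite")
        features = self.backbone.forward(x, train)
        return self.head.forward(features, train)

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Global-average-pooled pre-softmax class responses, (N, 5)."""
        prepool = self.forward_prepool(x, train)
        out = prepool.mean(axis=(2, 3))
        if train:
            self._prepool_shape = prepool.shape
        return out

    def backward_from_logits(self, dlogits: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the pooled logits."""
        n, c, h, w = self._prepool_shape
        dprepool = np.broadcast_to(
            dlogits[:, :, None, None].astype(np.float32), (n, c, h, w)
        ) / (h * w)
        dfeat = self.head.backward(np.ascontiguousarray(dprepool))
        self.backbone.backward(dfeat)

    # -- inference ----------------------------------------------------------

    def predict_log_proba(self, x: np.ndarray) -> np.ndarray:
        return log_softmax(self.logits(x, train=False))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.logits(x, train=False))

    def scores(self, image: np.ndarray) -> ClassScores:
        """Single-image :class:`ClassScores` (one deterministic forward pass)."""
        return ClassScores(log_probs=self.predict_log_proba(image)[0])

    # -- serialization ------------------------------------------------------

    def _stateful_layers(self) -> list:
        return list(self.backbone.layers) + [self.head.conv, self.head.bn]

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {"backbone_name": np.array(self.backbone.name)}
        for i, layer in enumerate(self._stateful_layers()):
            for j, p in enumerate(layer.params):
                state[f"layer{i}.param{j}"] = p.value
            if isinstance(layer, BatchNorm2d):
                state[f"layer{i}.running_mean"] = layer.running_mean
                state[f"layer{i}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self._stateful_layers()):
            for j, p in enumerate(layer.params):
                p.value = np.asarray(state[f"layer{i}.param{j}"], dtype=np.float32)
                p.grad = np.zeros_like(p.value)
            if isinstance(layer, BatchNorm2d):
                layer.running_mean = np.asarray(
                    state[f"layer{i}.running_mean"], dtype=np.float32
                )
                layer.running_var = np.asarray(
                    state[f"layer{i}.running_var"], dtype=np.float32
                )

    def save(self, path: str) -> None:
        np.savez(path, **self.state_dict())

    @classmethod
    def load(cls, path: str) -> "OralClassifier":
        state = dict(np.load(path, allow_pickle=False))
        name = str(state.pop("backbone_name"))
        model = cls(backbone=make_backbone(name))
        model.load_state_dict(state)
        return model

    def clone(self) -> "OralClassifier":
        return copy.deepcopy(self)


def head_forward(features: np.ndarray, head: _Head | OralClassifier) -> ClassScores:
    """Run the modified head on one backbone feature map (C_f, h, w).

    1x1 conv -> BN (eval statistics) -> global average pooling ->
    log-softmax.  Returns the per-class scores.
    """
    h = head.head if isinstance(head, OralClassifier) else head
    feats = np.asarray(features, dtype=np.float32)
    if feats.ndim == 3:
        feats = feats[None]
    if not np.all(np.isfinite(feats)):
        raise ValueError("head_forward requires finite features")
    prepool = h.forward(feats, train=False)
    logits = prepool.mean(axis=(2, 3))
    return ClassScores(log_probs=log_softmax(logits)[0])
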