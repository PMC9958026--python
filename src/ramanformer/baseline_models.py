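"""1D-convolutional baseline classifiers: AlexNet-1D and ResNet-18-1D.

The classic image architectures with every k×k convolution replaced by a
length-k 1D convolution over the wavenumber axis.  Both expose the same
``params`` / ``logits`` / ``check_axis`` surface as the transformer, so
:func:`ramanformer.transformer_model.train_model` and ``predict`` work
unchanged, and checkpoints share one format (the architecture tag is stored
inside).

A ``width_multiplier`` scales all channel counts; the default 1.0 matches
the published layouts and the 0.25 "scaled" setting trains in minutes on a
CPU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np

from ._autograd import Tensor

__all__ = ["ConvNetConfig", "conv1d", "build_classifier",
           "AlexNet1D", "ResNet1D"]


def conv1d(x, kernel, stride: int = 1, padding: int = 0) -> np.ndarray:
    """Single-channel 1D cross-correlation of a vector with a kernel.

    y[i] = Σ_j x[i·stride + j − padding] · kernel[j], zero outside the input;
    output length ⌊(L + 2·padding − k)/stride⌋ + 1.
    """
    x = np.asarray(x, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if stride < 1:
        raise ValueError("stride must be >= 1")
    xt = Tensor(x.reshape(1, 1, -1))
    wt = Tensor(kernel.reshape(1, 1, -1))
    return xt.conv1d(wt, stride=stride, padding=padding).data[0, 0]


@dataclass(frozen=True)
class ConvNetConfig:
    """Baseline architecture choice and scaling."""

    architecture: str = "alexnet1d"
    n_classes: int = 8
    input_length: int = 2801
    width_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.architecture not in ("alexnet1d", "resnet1d"):
            raise ValueError("architecture must be 'alexnet1d' or 'resnet1d'")
        if self.n_classes < 2 or self.width_multiplier <= 0:
            raise ValueError("invalid config")


def _conv_out(length: int, k: int, stride: int, padding: int) -> int:
    return (length + 2 * padding - k) // stride + 1


class _ParamFactory:
    """He-initialised weights keyed by name, collected into a ModelParams."""

    def __init__(self, rng: np.random.Generator, dtype):
        from .transformer_model import ModelParams

        self.rng = rng
        self.dtype = dtype
        self.params = ModelParams()

    def conv(self, name: str, c_out: int, c_in: int, k: int):
        scale = math.sqrt(2.0 / (c_in * k))
        self.params[f"{name}.weight"] = Tensor(
            self.rng.normal(0, scale, size=(c_out, c_in, k)).astype(self.dtype),
            requires_grad=True)
        self.params[f"{name}.bias"] = Tensor(
            np.zeros(c_out, dtype=self.dtype), requires_grad=True)

    def linear(self, name: str, n_in: int, n_out: int, zero: bool = False):
        scale = 0.0 if zero else math.sqrt(2.0 / n_in)
        self.params[f"{name}.weight"] = Tensor(
            self.rng.normal(0, scale, size=(n_in, n_out)).astype(self.dtype)
            if scale else np.zeros((n_in, n_out), dtype=self.dtype),
            requires_grad=True)
        self.params[f"{name}.bias"] = Tensor(
            np.zeros(n_out, dtype=self.dtype), requires_grad=True)

    def norm(self, name: str, c: int):
        self.params[f"{name}.gain"] = Tensor(np.ones(c, dtype=self.dtype),
                                             requires_grad=True)
        self.params[f"{name}.shift"] = Tensor(np.zeros(c, dtype=self.dtype),
                                              requires_grad=True)


def _adaptive_avg_pool(x: Tensor, target: int) -> Tensor:
    """Average-pool (B, C, L) down to (B, C, target) with equal bins."""
    b, c, length = x.shape
    if length % target == 0:
        return x.reshape(b, c, target, length // target).mean(axis=3)
    # unequal bins: trim to the largest multiple (spectra are long; the
    # few trailing channels carry no class information by construction)
    trim = (length // target) * target
    return x[:, :, :trim].reshape(b, c, target, trim // target).mean(axis=3)


class _ConvClassifier:
    """Shared plumbing: axis binding, batching, checkpoint metadata."""

    def __init__(self, cfg: ConvNetConfig, axis: np.ndarray,
                 class_names: Optional[Sequence[str]] = None):
        self.cfg = cfg
        self.axis = np.asarray(axis, dtype=float)
        self.class_names = list(class_names) if class_names else None
        if self.axis.size != cfg.input_length:
            raise ValueError("axis length must equal cfg.input_length")

    architecture = "convnet"

    def check_axis(self, axis: np.ndarray) -> None:
        if axis.size != self.axis.size or not np.allclose(axis, self.axis):
            raise ValueError("axis does not match model grid")

    def forward(self, intensities) -> np.ndarray:
        x = np.atleast_2d(np.asarray(intensities, dtype=float))
        probs = self.logits(x, train=False).softmax(axis=-1).data
        return probs[0] if np.ndim(intensities) == 1 else probs

    def config_dict(self) -> dict:
        return {"architecture": self.architecture, "config": asdict(self.cfg)}

    @property
    def dtype(self):
        return next(iter(self.params.values())).data.dtype


class AlexNet1D(_ConvClassifier):
    """AlexNet with 1D convolutions: 5 conv stages, 3 pools, 3 FC layers."""

    architecture = "alexnet1d"

    # (out_channels, kernel, stride, padding, pool_after)
    _STAGES = ((64, 11, 4, 2, True), (192, 5, 1, 2, True), (384, 3, 1, 1, False),
               (256, 3, 1, 1, False), (256, 3, 1, 1, True))
    _POOL = (3, 2)
    _FLAT = 6  # adaptive-pool target before the FC stack

    def __init__(self, cfg: ConvNetConfig, axis: np.ndarray, seed: int = 0,
                 dtype=np.float32, class_names: Optional[Sequence[str]] = None):
        super().__init__(cfg, axis, class_names)
        w = cfg.width_multiplier
        self._channels = [max(1, int(round(c * w))) for c, *_ in self._STAGES]
        # validate the receptive field: every stage must emit >= 1 sample
        length = cfg.input_length
        min_len = length
        for (c, k, s, p, pool) in self._STAGES:
            if length + 2 * p < k:
                raise ValueError(
                    f"input_length {cfg.input_length} too short for alexnet1d "
                    f"(minimum ≈ {self._min_input_length()})")
            length = _conv_out(length, k, s, p)
            if pool:
                if length < self._POOL[0]:
                    raise ValueError(
                        f"input_length {cfg.input_length} too short for alexnet1d "
                        f"(minimum ≈ {self._min_input_length()})")
                length = _conv_out(length, *self._POOL, 0)
        if length < self._FLAT:
            raise ValueError(
                f"input_length {cfg.input_length} too short for alexnet1d "
                f"(minimum ≈ {self._min_input_length()})")
        rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
        fac = _ParamFactory(rng, dtype)
        c_in = 1
        for i, ((c, k, s, p, pool), c_scaled) in enumerate(zip(self._STAGES, self._channels)):
            fac.conv(f"conv{i}", c_scaled, c_in, k)
            c_in = c_scaled
        fc = max(1, int(round(4096 * w)))
        fac.linear("fc0", c_in * self._FLAT, fc)
        fac.linear("fc1", fc, fc)
        fac.linear("head", fc, cfg.n_classes, zero=True)
        self.params = fac.params

    @classmethod
    def _min_input_length(cls) -> int:
        # invert the stage arithmetic for the smallest valid input
        length = cls._FLAT
        for (c, k, s, p, pool) in reversed(cls._STAGES):
            if pool:
                length = (length - 1) * cls._POOL[1] + cls._POOL[0]
            length = (length - 1) * s + k - 2 * p
        return length

    def logits(self, x_batch: np.ndarray, train: bool = False,
               rng: Optional[np.random.Generator] = None) -> Tensor:
        x = Tensor(np.asarray(x_batch, dtype=self.dtype)[:, None, :])
        for i, (c, k, s, p, pool) in enumerate(self._STAGES):
            x = x.conv1d(self.params[f"conv{i}.weight"],
                         self.params[f"conv{i}.bias"], stride=s, padding=p).relu()
            if pool:
                x = x.max_pool1d(*self._POOL)
        x = _adaptive_avg_pool(x, self._FLAT)
        x = x.reshape(x.shape[0], -1)
        x = (x @ self.params["fc0.weight"] + self.params["fc0.bias"]).relu()
        x = (x @ self.params["fc1.weight"] + self.params["fc1.bias"]).relu()
        return x @ self.params["head.weight"] + self.params["head.bias"]


class ResNet1D(_ConvClassifier):
    """ResNet-18 layout in 1D: stem + 4 stages of 2 basic blocks + GAP head."""

    architecture = "resnet1d"

    _STAGE_CHANNELS = (64, 128, 256, 512)

    def __init__(self, cfg: ConvNetConfig, axis: np.ndarray, seed: int = 0,
                 dtype=np.float32, class_names: Optional[Sequence[str]] = None):
        super().__init__(cfg, axis, class_names)
        if cfg.input_length < self._min_input_length():
            raise ValueError(
                f"input_length {cfg.input_length} too short for resnet1d "
                f"(minimum {self._min_input_length()})")
        w = cfg.width_multiplier
        self._channels = [max(1, int(round(c * w))) for c in self._STAGE_CHANNELS]
        rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
        fac = _ParamFactory(rng, dtype)
        self.running_stats: dict[str, dict[str, np.ndarray]] = {}

        def bn(name: str, c: int):
            fac.norm(name, c)
            self.running_stats[name] = {
                "mean": np.zeros(c, dtype=np.float64),
                "var": np.ones(c, dtype=np.float64),
            }

        fac.conv("stem", self._channels[0], 1, 7)
        bn("stem.bn", self._channels[0])
        c_in = self._channels[0]
        for s, c in enumerate(self._channels):
            for b in range(2):
                pre = f"stage{s}.block{b}"
                fac.conv(f"{pre}.conv1", c, c_in, 3)
                bn(f"{pre}.bn1", c)
                fac.conv(f"{pre}.conv2", c, c, 3)
                bn(f"{pre}.bn2", c)
                if c_in != c:
                    fac.conv(f"{pre}.down", c, c_in, 1)
                    bn(f"{pre}.down.bn", c)
                c_in = c
        fac.linear("head", c_in, cfg.n_classes, zero=True)
        self.params = fac.params

    @staticmethod
    def _min_input_length() -> int:
        # stem stride 2 + pool stride 2 + three stride-2 stages = /32
        return 32

    def _bn(self, x: Tensor, name: str, train: bool) -> Tensor:
        return x.batch_norm(self.params[f"{name}.gain"], self.params[f"{name}.shift"],
                            self.running_stats[name], train=train)

    def logits(self, x_batch: np.ndarray, train: bool = False,
               rng: Optional[np.random.Generator] = None) -> Tensor:
        x = Tensor(np.asarray(x_batch, dtype=self.dtype)[:, None, :])
        x = x.conv1d(self.params["stem.weight"], self.params["stem.bias"],
                     stride=2, padding=3)
        x = self._bn(x, "stem.bn", train).relu()
        x = x.max_pool1d(3, 2)
        for s, c in enumerate(self._channels):
            for b in range(2):
                pre = f"stage{s}.block{b}"
                stride = 2 if (s > 0 and b == 0) else 1
                out = x.conv1d(self.params[f"{pre}.conv1.weight"],
                               self.params[f"{pre}.conv1.bias"], stride=stride, padding=1)
                out = self._bn(out, f"{pre}.bn1", train).relu()
                out = out.conv1d(self.params[f"{pre}.conv2.weight"],
                                 self.params[f"{pre}.conv2.bias"], stride=1, padding=1)
                out = self._bn(out, f"{pre}.bn2", train)
                if f"{pre}.down.weight" in self.params:
                    shortcut = x.conv1d(self.params[f"{pre}.down.weight"],
                                        self.params[f"{pre}.down.bias"],
                                        stride=stride, padding=0)
                    shortcut = self._bn(shortcut, f"{pre}.down.bn", train)
                elif stride != 1:
                    shortcut = x[:, :, ::stride]
                else:
                    shortcut = x
                x = (out + shortcut).relu()
        x = x.mean(axis=2)  # global average pooling
        return x @ self.params["head.weight"] + self.params["head.bias"]


def build_classifier(cfg: ConvNetConfig, axis: np.ndarray, seed: int = 0,
                     dtype=np.float32,
                     class_names: Optional[Sequence[str]] = None):
    """Construct the configured baseline bound to a wavenumber grid."""
    cls = {"alexnet1d": AlexNet1D, "resnet1d": ResNet1D}[cfg.architecture]
    return cls(cfg, axis, seed=seed, dtype=dtype, class_names=class_names)
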