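"""Classifier architectures for raw-waveform and spectrogram pipelines.

Raw-waveform models all share one contract: input is a float32 batch of
waveforms shaped (batch, n_samples) and the probability output is
(batch, n_classes) with rows summing to one.

* :func:`build_elephant_caller_net` — the call-type network: a spatial
  feature-extraction block (SFEB) of strided 1-D convolutions pulls
  fine-grained frequency detail out of the waveform, a temporal block (TFEB)
  of 2-D conv/BN/ReLU stages with interleaved max and average pooling models
  time structure, and a permute-and-concatenate fusion merges both feature
  tensors before the integration convolution and the softmax head.
* :func:`build_mobilenet_v2_raw` — standard width-1.0 MobileNetV2 inverted
  residuals with a single-channel stem; the waveform is laid out on a 2-D
  grid before the stem (the grid choice does not change the parameter count).
* :func:`build_yamnet_1d` — a 1-D depthwise-separable convolution stack.
* :func:`build_rawnet_residual` — 1-D residual blocks (conv/BN/LeakyReLU
  pairs with identity or projection skips).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from . import nn
from .nn import Classifier, Module, Sequential, ShapeError


# ---------------------------------------------------------------------------
# ElephantCallerNet
# ---------------------------------------------------------------------------

@dataclass
class ElephantCallerNetConfig:
    """Architecture knobs; defaults land the parameter count near 4.7 M."""

    sfeb: tuple[tuple[int, int, int], ...] = ((8, 9, 2), (16, 5, 2))
    sfeb_pool: int = 8
    tfeb_channels: tuple[int, ...] = (32, 64, 128, 128, 256)
    tfeb_kernel: int = 3
    tfeb_pools: tuple[tuple[str, tuple[int, int]] | None, ...] = (
        ("max", (2, 2)), ("max", (2, 2)), ("avg", (1, 2)), ("max", (1, 2)), None,
    )
    fusion_grid: tuple[int, int] = (2, 14)
    integration_channels: int = 256
    hidden: int = 512
    dropout_p: float = 0.2
    n_classes: int = 3
    input_samples: int = 96_000

    def validate(self) -> None:
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        for c, k, s in self.sfeb:
            if k < 3 or k % 2 == 0:
                raise ValueError("SFEB kernel sizes must be odd and >= 3")
        if self.tfeb_kernel < 3 or self.tfeb_kernel % 2 == 0:
            raise ValueError("TFEB kernel size must be odd and >= 3")
        if len(self.tfeb_pools) != len(self.tfeb_channels):
            raise ValueError("one pooling slot per TFEB block required")


class ElephantCallerNet(Module):
    """SFEB -> (permute) -> TFEB -> fuse with pooled SFEB map -> classify."""

    def __init__(self, config: ElephantCallerNetConfig, seed: int = 0):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)

        sfeb_layers: list[Module] = []
        in_ch = 1
        for out_ch, k, s in config.sfeb:
            sfeb_layers += [
                nn.Conv1d(in_ch, out_ch, k, stride=s, padding=k // 2, bias=False, rng=rng),
                nn.BatchNorm1d(out_ch), nn.ReLU(),
            ]
            in_ch = out_ch
        sfeb_layers.append(nn.MaxPool1d(config.sfeb_pool))
        self.sfeb = Sequential(*sfeb_layers)
        self.sfeb_channels = in_ch

        tfeb_layers: list[Module] = []
        in_ch2 = 1
        k = config.tfeb_kernel
        for out_ch, pool in zip(config.tfeb_channels, config.tfeb_pools):
            tfeb_layers += [
                nn.Conv2d(in_ch2, out_ch, k, padding=k // 2, bias=False, rng=rng),
                nn.BatchNorm2d(out_ch), nn.ReLU(),
            ]
            if pool is not None:
                kind, size = pool
                tfeb_layers.append(nn.MaxPool2d(size) if kind == "max" else nn.AvgPool2d(size))
            in_ch2 = out_ch
        tfeb_layers.append(nn.AdaptiveAvgPool2d(config.fusion_grid))
        self.tfeb = Sequential(*tfeb_layers)

        gh, gw = config.fusion_grid
        self.sfeb_to_grid = nn.AdaptiveAvgPool1d(gh * gw)
        fused_ch = in_ch2 + self.sfeb_channels
        self.integrate = Sequential(
            nn.Conv2d(fused_ch, config.integration_channels, k, padding=k // 2, bias=False, rng=rng),
            nn.BatchNorm2d(config.integration_channels), nn.ReLU(),
            nn.Dropout(config.dropout_p, seed=seed),
            nn.Flatten(),
            nn.Linear(config.integration_channels * gh * gw, config.hidden, rng=rng),
            nn.ReLU(),
            nn.Linear(config.hidden, config.n_classes, rng=rng),
        )

    # forward/backward wire the fusion junction by hand
    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 2:
            raise ShapeError("expected a (batch, n_samples) waveform batch")
        B = x.shape[0]
        s = self.sfeb(x[:, None, :])                  # (B, Cs, T)
        self._s_shape = s.shape
        t = self.tfeb(s[:, None, :, :])               # (B, Ct, gh, gw)
        g = self.sfeb_to_grid(s)                      # (B, Cs, gh*gw)
        gh, gw = self.config.fusion_grid
        g2 = g.reshape(B, self.sfeb_channels, gh, gw)  # permute onto the TFEB grid
        fused = np.concatenate([t, g2], axis=1)
        self._split = t.shape[1]
        return self.integrate(fused)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        gf = self.integrate.backward(grad)
        gt, gg2 = gf[:, :self._split], gf[:, self._split:]
        B = gf.shape[0]
        gg = gg2.reshape(B, self.sfeb_channels, -1)
        gs = self.sfeb_to_grid.backward(np.ascontiguousarray(gg))
        gs_t = self.tfeb.backward(np.ascontiguousarray(gt))
        gs = gs + gs_t.reshape(self._s_shape)
        gx = self.sfeb.backward(gs)
        return gx[:, 0, :]

    def complexity(self, in_shape):
        (L,) = in_shape
        s_shape, fl = self.sfeb.complexity((1, L))
        t_shape, t_fl = self.tfeb.complexity((1,) + s_shape)
        g_shape, g_fl = self.sfeb_to_grid.complexity(s_shape)
        gh, gw = self.config.fusion_grid
        fused = (t_shape[0] + self.sfeb_channels, gh, gw)
        out_shape, i_fl = self.integrate.complexity(fused)
        return out_shape, fl + t_fl + g_fl + i_fl


def build_elephant_caller_net(config: ElephantCallerNetConfig | None = None,
                              seed: int = 0) -> Classifier:
    config = config or ElephantCallerNetConfig()
    return Classifier(ElephantCallerNet(config, seed=seed), config.n_classes)


# ---------------------------------------------------------------------------
# MobileNetV2 on a waveform grid
# ---------------------------------------------------------------------------

_MOBILENET_V2_CFG = (
    # (expansion t, out channels c, repeats n, first stride s)
    (1, 16, 1, 1),
    (6, 24, 2, 2),
    (6, 32, 3, 2),
    (6, 64, 4, 2),
    (6, 96, 3, 1),
    (6, 160, 3, 2),
    (6, 320, 1, 1),
)


def _inverted_residual(in_ch: int, out_ch: int, stride: int, expand: int,
                       rng: np.random.Generator) -> Module:
    hidden = in_ch * expand
    layers: list[Module] = []
    if expand != 1:
        layers += [nn.Conv2d(in_ch, hidden, 1, bias=False, rng=rng),
                   nn.BatchNorm2d(hidden), nn.ReLU6()]
    layers += [
        nn.Conv2d(hidden, hidden, 3, stride=stride, padding=1, groups=hidden,
                  bias=False, rng=rng),
        nn.BatchNorm2d(hidden), nn.ReLU6(),
        nn.Conv2d(hidden, out_ch, 1, bias=False, rng=rng),
        nn.BatchNorm2d(out_ch),
    ]
    body = Sequential(*layers)
    if stride == 1 and in_ch == out_ch:
        return nn.Residual(body)
    return body


def waveform_grid(n_samples: int) -> tuple[int, int]:
    """Factor a waveform length into the most square (H, W) grid."""
    best = None
    for h in range(int(math.isqrt(n_samples)), 0, -1):
        if n_samples % h == 0:
            best = (h, n_samples // h)
            break
    if best is None or best[0] < 8:
        raise ShapeError(f"waveform length {n_samples} has no usable 2-D grid")
    return best


def build_mobilenet_v2_raw(n_classes: int = 3, in_channels: int = 1,
                           input_samples: int = 96_000,
                           grid: tuple[int, int] | None = None,
                           seed: int = 0) -> Classifier:
    """Width-1.0 MobileNetV2 with a single-channel stem on a waveform grid.

    With ``n_classes=3`` and ``in_channels=1`` the trainable parameter count
    is 2,227,139. The grid layout is a free choice (parameters are
    grid-independent); the default factors the sample count near-square,
    96,000 -> (300, 320).
    """
    if n_classes < 2 or in_channels < 1:
        raise ValueError("need n_classes >= 2 and in_channels >= 1")
    rng = np.random.default_rng(seed)
    if grid is None:
        grid = waveform_grid(input_samples // in_channels)
    h, w = grid
    if in_channels * h * w != input_samples:
        raise ShapeError(f"grid {grid} x {in_channels} ch does not tile {input_samples} samples")

    layers: list[Module] = [
        nn.Reshape(in_channels, h, w),
        nn.Conv2d(in_channels, 32, 3, stride=2, padding=1, bias=False, rng=rng),
        nn.BatchNorm2d(32), nn.ReLU6(),
    ]
    ch = 32
    for t, c, n, s in _MOBILENET_V2_CFG:
        for i in range(n):
            layers.append(_inverted_residual(ch, c, s if i == 0 else 1, t, rng))
            ch = c
    layers += [
        nn.Conv2d(ch, 1280, 1, bias=False, rng=rng),
        nn.BatchNorm2d(1280), nn.ReLU6(),
        nn.GlobalAvgPool(),
        nn.Linear(1280, n_classes, rng=rng),
    ]
    return Classifier(Sequential(*layers), n_classes)


# ---------------------------------------------------------------------------
# YAMNet-style 1-D depthwise-separable stack
# ---------------------------------------------------------------------------

@dataclass
class YamNet1dConfig:
    stem_channels: int = 32
    stem_kernel: int = 9
    stem_stride: int = 4
    # (out_channels, stride) per depthwise-separable block
    blocks: tuple[tuple[int, int], ...] = (
        (64, 2), (128, 2), (128, 1), (256, 2), (256, 1), (512, 2),
    )
    depthwise_kernel: int = 9
    n_classes: int = 3


def build_yamnet_1d(config: YamNet1dConfig | None = None, seed: int = 0) -> Classifier:
    cfg = config or YamNet1dConfig()
    rng = np.random.default_rng(seed)
    layers: list[Module] = [
        _WaveformToChannels(),
        nn.Conv1d(1, cfg.stem_channels, cfg.stem_kernel, stride=cfg.stem_stride,
                  padding=cfg.stem_kernel // 2, bias=False, rng=rng),
        nn.BatchNorm1d(cfg.stem_channels), nn.ReLU(),
    ]
    ch = cfg.stem_channels
    for out_ch, stride in cfg.blocks:
        k = cfg.depthwise_kernel
        layers += [
            nn.Conv1d(ch, ch, k, stride=stride, padding=k // 2, groups=ch,
                      bias=False, rng=rng),
            nn.BatchNorm1d(ch), nn.ReLU(),
            nn.Conv1d(ch, out_ch, 1, bias=False, rng=rng),
            nn.BatchNorm1d(out_ch), nn.ReLU(),
        ]
        ch = out_ch
    layers += [nn.GlobalAvgPool(), nn.Linear(ch, cfg.n_classes, rng=rng)]
    return Classifier(Sequential(*layers), cfg.n_classes)


class _WaveformToChannels(Module):
    """(batch, n_samples) -> (batch, 1, n_samples)."""

    def forward(self, x):
        return x[:, None, :]

    def backward(self, gy):
        return gy[:, 0, :]

    def complexity(self, in_shape):
        (L,) = in_shape
        return (1, L), 0.0


# ---------------------------------------------------------------------------
# RawNet-style residual 1-D network
# ---------------------------------------------------------------------------

@dataclass
class RawNetConfig:
    stem_channels: int = 64
    stem_kernel: int = 3
    stem_stride: int = 4
    # (channels, n_blocks, pool after stage)
    stages: tuple[tuple[int, int, int], ...] = ((64, 2, 4), (128, 2, 4), (256, 2, 4))
    kernel: int = 3
    negative_slope: float = 0.2
    n_classes: int = 3


def residual_block_1d(in_ch: int, out_ch: int, kernel: int,
                      negative_slope: float, rng: np.random.Generator) -> nn.Residual:
    """Two conv/BN/LeakyReLU layers with an identity or projection skip."""
    body = Sequential(
        nn.Conv1d(in_ch, out_ch, kernel, padding=kernel // 2, bias=False, rng=rng),
        nn.BatchNorm1d(out_ch), nn.LeakyReLU(negative_slope),
        nn.Conv1d(out_ch, out_ch, kernel, padding=kernel // 2, bias=False, rng=rng),
        nn.BatchNorm1d(out_ch),
    )
    projection = None
    if in_ch != out_ch:
        projection = nn.Conv1d(in_ch, out_ch, 1, bias=False, rng=rng)
    return nn.Residual(body, projection)


def build_rawnet_residual(config: RawNetConfig | None = None, seed: int = 0) -> Classifier:
    cfg = config or RawNetConfig()
    rng = np.random.default_rng(seed)
    layers: list[Module] = [
        _WaveformToChannels(),
        nn.Conv1d(1, cfg.stem_channels, cfg.stem_kernel, stride=cfg.stem_stride,
                  padding=cfg.stem_kernel // 2, bias=False, rng=rng),
        nn.BatchNorm1d(cfg.stem_channels), nn.LeakyReLU(cfg.negative_slope),
    ]
    ch = cfg.stem_channels
    for out_ch, n_blocks, pool in cfg.stages:
        for i in range(n_blocks):
            layers.append(residual_block_1d(ch if i == 0 else out_ch, out_ch,
                                            cfg.kernel, cfg.negative_slope, rng))
        layers.append(nn.LeakyReLU(cfg.negative_slope))
        if pool > 1:
            layers.append(nn.MaxPool1d(pool))
        ch = out_ch
    layers += [nn.GlobalAvgPool(), nn.Linear(ch, cfg.n_classes, rng=rng)]
    return Classifier(Sequential(*layers), cfg.n_classes)


# ---------------------------------------------------------------------------
# Spectrogram-side classifiers
# ---------------------------------------------------------------------------

def build_spectrogram_cnn(input_shape: tuple[int, int], n_classes: int = 3,
                          seed: int = 0) -> Classifier:
    """Small 2-D CNN over stacked (MFCC + chroma) feature images."""
    rng = np.random.default_rng(seed)
    layers = [
        nn.Reshape(1, *input_shape),
        nn.Conv2d(1, 16, 3, padding=1, bias=False, rng=rng), nn.BatchNorm2d(16), nn.ReLU(),
        nn.MaxPool2d((2, 4)),
        nn.Conv2d(16, 32, 3, padding=1, bias=False, rng=rng), nn.BatchNorm2d(32), nn.ReLU(),
        nn.MaxPool2d((2, 4)),
        nn.Conv2d(32, 64, 3, padding=1, bias=False, rng=rng), nn.BatchNorm2d(64), nn.ReLU(),
        nn.AdaptiveAvgPool2d((2, 4)),
        nn.Flatten(),
        nn.Linear(64 * 8, n_classes, rng=rng),
    ]
    return Classifier(Sequential(*layers), n_classes)


def fit_svm_spectral(features: np.ndarray, labels: np.ndarray,
                     kernel: str = "rbf", C: float = 10.0,
                     gamma: str | float = "scale") -> SVC:
    """RBF-kernel SVM (one-vs-rest) over flattened feature images."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("SVM training requires at least two classes")
    clf = SVC(kernel=kernel, C=C, gamma=gamma, decision_function_shape="ovr")
    clf.fit(np.asarray(features, dtype=np.float64), labels)
    return clf
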