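"""Configurable 3D residual U-Net with Adam, built on the numpy autograd.

Topology (standard 3D-ResUNet composition, configurable so alternatives
can be swapped in): a stem convolution to ``base_filters`` channels, then
``depth`` encoder levels — each a residual block (two 3x3x3 convolutions
with instance normalization and leaky ReLU, identity shortcut, 1x1x1
projection when channel counts change) followed by a stride-2
downsampling convolution that doubles the filters. The decoder mirrors it
with 2x2x2 stride-2 transposed convolutions, skip concatenation, and a
residual block per level; a final 1x1x1 convolution projects to the three
region channels through a sigmoid.

Reference-scale hyperparameters: 30 base filters, Adam at lr = 5e-5,
128^3 patches, batch size 1 with a single fresh random augmented patch
per case per epoch. A tiny configuration (4 filters, depth 2, 16^3
patches) keeps whole federations runnable on one CPU core.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .labels import RegionChannels
from .preprocess import AugmentConfig, augment, sample_patch

__all__ = [
    "ModelConfig", "ModelParams", "AdamState", "ResUNet3D",
    "init_model", "tiny_config", "train_local_epoch",
    "save_checkpoint", "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    base_filters: int = 30
    depth: int = 4
    in_channels: int = 4
    out_channels: int = 3
    patch_size: int = 128
    lr: float = 5e-5
    seed: int = 0
    leaky_slope: float = 0.01
    grad_clip_norm: float | None = None  # global L2 norm; None disables

    def __post_init__(self) -> None:
        if self.base_filters < 1 or self.depth < 1:
            raise ValueError("base_filters and depth must be >= 1")
        if self.patch_size % (2 ** self.depth) != 0:
            raise ValueError(
                f"patch_size {self.patch_size} must be divisible by 2^depth = {2 ** self.depth}; "
                f"reduce depth or pad the patch"
            )

    @property
    def fingerprint(self) -> str:
        """Topology identity; two models are aggregable iff these match."""
        return (f"resunet3d:f{self.base_filters}:d{self.depth}"
                f":in{self.in_channels}:out{self.out_channels}")


def tiny_config(**overrides) -> ModelConfig:
    """A CPU-friendly configuration for desk-scale federations."""
    defaults = dict(base_filters=4, depth=2, patch_size=16, lr=5e-3)
    defaults.update(overrides)
    return ModelConfig(**defaults)


@dataclass
class ModelParams:
    """Named arrays defining one network state — the unit FedAvg averages."""

    arrays: dict
    fingerprint: str

    def copy(self) -> "ModelParams":
        return ModelParams({k: v.copy() for k, v in self.arrays.items()}, self.fingerprint)

    def n_parameters(self) -> int:
        return sum(int(v.size) for v in self.arrays.values())

    def check_aggregable(self, other: "ModelParams") -> None:
        if self.fingerprint != other.fingerprint:
            raise ValueError(
                f"fingerprint mismatch: {self.fingerprint!r} vs {other.fingerprint!r}"
            )
        if self.arrays.keys() != other.arrays.keys():
            raise ValueError("parameter name sets differ")
        for k in self.arrays:
            if self.arrays[k].shape != other.arrays[k].shape:
                raise ValueError(f"shape mismatch for parameter {k!r}")


@dataclass
class AdamState:
    """First/second-moment estimates and step count, mirroring the params."""

    m: dict
    v: dict
    step: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    @classmethod
    def for_params(cls, params: ModelParams) -> "AdamState":
        return cls(
            m={k: np.zeros_like(a) for k, a in params.arrays.items()},
            v={k: np.zeros_like(a) for k, a in params.arrays.items()},
        )

    def apply(self, params: ModelParams, grads: dict, lr: float) -> None:
        self.step += 1
        b1c = 1.0 - self.beta1 ** self.step
        b2c = 1.0 - self.beta2 ** self.step
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            params.arrays[k] -= lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def _channels_per_level(cfg: ModelConfig) -> list[int]:
    return [cfg.base_filters * (2 ** level) for level in range(cfg.depth + 1)]


def init_model(cfg: ModelConfig, dtype=np.float32) -> ModelParams:
    """He-normal initialization, deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    arrays: dict = {}

    def conv(name, cout, cin, k):
        fan_in = cin * k ** 3
        arrays[f"{name}.w"] = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                         size=(cout, cin, k, k, k)).astype(dtype)
        arrays[f"{name}.b"] = np.zeros(cout, dtype=dtype)

    def convT(name, cin, cout):
        fan_in = cin * 8
        arrays[f"{name}.w"] = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                         size=(cin, cout, 2, 2, 2)).astype(dtype)
        arrays[f"{name}.b"] = np.zeros(cout, dtype=dtype)

    def norm(name, c):
        arrays[f"{name}.g"] = np.ones(c, dtype=dtype)
        arrays[f"{name}.beta"] = np.zeros(c, dtype=dtype)

    def resblock(name, cin, cout):
        conv(f"{name}.conv1", cout, cin, 3)
        norm(f"{name}.in1", cout)
        conv(f"{name}.conv2", cout, cout, 3)
        norm(f"{name}.in2", cout)
        if cin != cout:
            conv(f"{name}.proj", cout, cin, 1)

    ch = _channels_per_level(cfg)
    conv("stem", ch[0], cfg.in_channels, 3)
    resblock("enc0", ch[0], ch[0])
    for level in range(1, cfg.depth + 1):
        conv(f"down{level}", ch[level], ch[level - 1], 3)
        resblock(f"enc{level}", ch[level], ch[level])
    for level in range(cfg.depth, 0, -1):
        convT(f"up{level}", ch[level], ch[level - 1])
        resblock(f"dec{level}", 2 * ch[level - 1], ch[level - 1])
    conv("head", cfg.out_channels, ch[0], 1)
    return ModelParams(arrays, cfg.fingerprint)


def expected_n_parameters(cfg: ModelConfig) -> int:
    """Layer-by-layer arithmetic tally of the parameter count."""

    def conv(cout, cin, k):
        return cout * cin * k ** 3 + cout

    def res(cin, cout):
        n = conv(cout, cin, 3) + conv(cout, cout, 3) + 4 * cout
        if cin != cout:
            n += conv(cout, cin, 1)
        return n

    ch = _channels_per_level(cfg)
    n = conv(ch[0], cfg.in_channels, 3) + res(ch[0], ch[0])
    for level in range(1, cfg.depth + 1):
        n += conv(ch[level], ch[level - 1], 3) + res(ch[level], ch[level])
    for level in range(cfg.depth, 0, -1):
        n += ch[level] * ch[level - 1] * 8 + ch[level - 1]  # transposed conv
        n += res(2 * ch[level - 1], ch[level - 1])
    n += conv(cfg.out_channels, ch[0], 1)
    return n


class ResUNet3D:
    """The segmentation network: parameters plus the forward graph."""

    def __init__(self, cfg: ModelConfig, params: ModelParams | None = None):
        self.cfg = cfg
        self.params = init_model(cfg) if params is None else params
        if self.params.fingerprint != cfg.fingerprint:
            raise ValueError("parameters do not match this configuration")

    # -- graph construction ------------------------------------------------
    def _wrap(self):
        return {k: nn.param(v, name=k) for k, v in self.params.arrays.items()}

    def _res(self, p, name, x):
        h = nn.conv3d(x, p[f"{name}.conv1.w"], p[f"{name}.conv1.b"], pad=1)
        h = nn.instance_norm(h, p[f"{name}.in1.g"], p[f"{name}.in1.beta"])
        h = nn.leaky_relu(h, self.cfg.leaky_slope)
        h = nn.conv3d(h, p[f"{name}.conv2.w"], p[f"{name}.conv2.b"], pad=1)
        h = nn.instance_norm(h, p[f"{name}.in2.g"], p[f"{name}.in2.beta"])
        if f"{name}.proj.w" in p:
            sc = nn.conv3d(x, p[f"{name}.proj.w"], p[f"{name}.proj.b"], pad=0)
        else:
            sc = x
        return nn.leaky_relu(nn.add(h, sc), self.cfg.leaky_slope)

    def _graph(self, x_np: np.ndarray):
        cfg = self.cfg
        if x_np.ndim != 4 or x_np.shape[0] != cfg.in_channels:
            raise ValueError(
                f"expected ({cfg.in_channels}, D, H, W) input, got shape {x_np.shape}"
            )
        if any(s % (2 ** cfg.depth) for s in x_np.shape[1:]):
            raise ValueError(
                f"spatial dims {x_np.shape[1:]} must be divisible by 2^depth = {2 ** cfg.depth}"
            )
        p = self._wrap()
        x = nn.const(x_np)
        h = nn.conv3d(x, p["stem.w"], p["stem.b"], pad=1)
        skips = []
        h = self._res(p, "enc0", h)
        for level in range(1, cfg.depth + 1):
            skips.append(h)
            h = nn.conv3d(h, p[f"down{level}.w"], p[f"down{level}.b"], stride=2, pad=1)
            h = self._res(p, f"enc{level}", h)
        for level in range(cfg.depth, 0, -1):
            h = nn.conv_transpose2(h, p[f"up{level}.w"], p[f"up{level}.b"])
            h = nn.concat(h, skips[level - 1])
            h = self._res(p, f"dec{level}", h)
        logits = nn.conv3d(h, p["head.w"], p["head.b"], pad=0)
        return nn.sigmoid(logits), p

    # -- inference ---------------------------------------------------------
    def forward(self, x: np.ndarray) -> RegionChannels:
        """Sigmoid region channels for one patch; shape-preserving."""
        out, _ = self._graph(np.asarray(x, dtype=np.float32))
        return RegionChannels(out.data, kind="sigmoid")

    def predict_volume(self, image: np.ndarray) -> RegionChannels:
        """Whole-volume inference: pad to a depth-compatible size, un-pad after."""
        image = np.asarray(image, dtype=np.float32)
        mult = 2 ** self.cfg.depth
        spatial = image.shape[1:]
        target = tuple(-(-s // mult) * mult for s in spatial)
        pads = [(0, 0)] + [((t - s) // 2, (t - s) - (t - s) // 2)
                           for s, t in zip(spatial, target)]
        padded = np.pad(image, pads)
        out = self.forward(padded).channels
        sl = tuple(slice(lo, lo + s) for (lo, _), s in zip(pads[1:], spatial))
        return RegionChannels(out[(slice(None),) + sl], kind="sigmoid")

    # -- training ----------------------------------------------------------
    def train_step(self, opt: AdamState, x: np.ndarray, ref: np.ndarray) -> float:
        """One Adam step on one patch; returns the mirrored-DSC loss."""
        out, p = self._graph(np.asarray(x, dtype=np.float32))
        loss = nn.mirrored_soft_dice_loss(out, ref)
        nn.backward(loss)
        grads = {k: t.grad for k, t in p.items() if t.grad is not None}
        if self.cfg.grad_clip_norm is not None:
            total = np.sqrt(sum(float((g.astype(np.float64) ** 2).sum())
                                for g in grads.values()))
            if total > self.cfg.grad_clip_norm:
                scale = np.float32(self.cfg.grad_clip_norm / total)
                grads = {k: g * scale for k, g in grads.items()}
        opt.apply(self.params, grads, self.cfg.lr)
        return float(loss.data)


def train_local_epoch(
    model: ResUNet3D,
    opt_state: AdamState,
    train_cases,
    aug_cfg: AugmentConfig,
    rng: np.random.Generator,
) -> float:
    """One local epoch: one optimizer step per case, batch size 1.

    Each case contributes a single fresh random augmented patch, in a
    seeded shuffled order. Returns the mean loss over the epoch. The model
    and optimizer state are updated in place.
    """
    cases = list(train_cases)
    if not cases:
        raise ValueError("empty training set")
    order = rng.permutation(len(cases))
    losses = []
    for idx in order:
        case = cases[idx]
        pp = sample_patch(case.image, case.labels, model.cfg.patch_size, rng)
        pp = augment(pp, aug_cfg, rng)
        losses.append(model.train_step(
            opt_state, pp.image, pp.reference.channels.astype(np.float32)
        ))
    return float(np.mean(losses))


def save_checkpoint(params: ModelParams, cfg: ModelConfig, path) -> None:
    """One archive per model: named arrays plus the config fingerprint."""
    meta = {"fingerprint": params.fingerprint, "config": cfg.__dict__}
    np.savez_compressed(path, __meta__=json.dumps(meta), **params.arrays)


def load_checkpoint(path) -> tuple[ModelParams, ModelConfig]:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        arrays = {k: z[k] for k in z.files if k != "__meta__"}
    cfg = ModelConfig(**meta["config"])
    return ModelParams(arrays, meta["fingerprint"]), cfg
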