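"""The Elastic YOLO network.

Backbone: five stages of EConv blocks (SiLU(BN(EConv))), each stage
halving resolution; stages 3-5 are tapped at strides 8/16/32.  Neck:
FPN top-down plus PANet bottom-up fusion, where each fusion node
concatenates two resized paths and may prune the weaker one at
evaluation time.  Heads: anchor-free, one per fused scale, emitting
objectness + per-class logits + (l, t, r, b) log-distances from the
location centre.

Elasticity has two axes.  *Architectural*: depth/width multipliers
lambda_d in {0.75, 1.0, 1.25} and lambda_w in {0.5, 1.0, 1.5} resize the
per-stage block counts and channel counts, with channels clamped to the
admissible band [D_min, D_max] around the base schedule.  *Spatial*:
deformable convolutions (learned sampling offsets) in the last block of
stages 3-5 and in every fusion block.
"""

from __future__ import annotations

import dataclasses
import io
import math
from pathlib import Path

import numpy as np
import yaml

from eyolo.nn import (
    BatchNorm2d, Concat, Conv2d, DeformConv2d, Layer, Param, SiLU, Tape,
    UpsampleNearest2x, to_cnhw,
)
from eyolo.nn.core import DTYPE, _col2im, _im2col

ALLOWED_DEPTH = (0.75, 1.0, 1.25)
ALLOWED_WIDTH = (0.5, 1.0, 1.5)
STRIDES = (8, 16, 32)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclasses.dataclass(frozen=True)
class ElasticScale:
    """Depth and width multipliers."""

    lambda_d: float = 1.0
    lambda_w: float = 1.0

    def __post_init__(self):
        if self.lambda_d not in ALLOWED_DEPTH:
            raise ValueError(f"lambda_d must be one of {ALLOWED_DEPTH}")
        if self.lambda_w not in ALLOWED_WIDTH:
            raise ValueError(f"lambda_w must be one of {ALLOWED_WIDTH}")


def effective_depth(base_depth: int, lambda_d: float) -> int:
    return max(1, _round_half_up(lambda_d * base_depth))


def effective_channels(base_channels: int, lambda_w: float,
                       d_min: int | None = None,
                       d_max: int | None = None) -> int:
    """clamp(round(lambda_w * C), D_min, D_max); defaults mirror the width set."""
    if d_min is None:
        d_min = _round_half_up(0.5 * base_channels)
    if d_max is None:
        d_max = _round_half_up(1.5 * base_channels)
    return int(np.clip(_round_half_up(lambda_w * base_channels), d_min, d_max))


@dataclasses.dataclass(frozen=True)
class ElasticConvSpec:
    """Run-time width-selectable convolution description."""

    d_in: int
    d_min: int
    d_max: int
    d_out: int
    kernel: tuple[int, int] = (3, 3)
    stride: int = 1
    deformable: bool = False

    def __post_init__(self):
        if not self.d_min <= self.d_out <= self.d_max:
            raise ValueError(
                f"D_out={self.d_out} outside [{self.d_min}, {self.d_max}]")
        if self.kernel[0] % 2 == 0 or self.kernel[1] % 2 == 0:
            raise ValueError("kernel must be odd-sized")


class ElasticConv2d(Layer):
    """Convolution over a channel-sliced super-kernel.

    The weight bank holds D_max output filters; only the first ``d_out``
    participate, so narrowing the width never changes the values of the
    retained channels.
    """

    def __init__(self, c_in: int, d_min: int, d_max: int, d_out: int | None = None,
                 k: int = 3, stride: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None, name: str = ""):
        if k % 2 == 0:
            raise ValueError("kernel must be odd-sized")
        self.c_in, self.d_min, self.d_max = c_in, d_min, d_max
        self.k, self.stride, self.pad = k, stride, k // 2
        rng = rng or np.random.default_rng(0)
        self.weight = Param(
            rng.normal(0.0, np.sqrt(2.0 / (c_in * k * k)), (d_max, c_in, k, k)),
            name + ".weight")
        self.bias = Param(np.zeros(d_max), name + ".bias") if bias else None
        self.d_out = d_out if d_out is not None else d_max
        self._cache = None

    @property
    def d_out(self) -> int:
        return self._d_out

    @d_out.setter
    def d_out(self, value: int):
        if not self.d_min <= value <= self.d_max:
            raise ValueError(f"d_out={value} outside [{self.d_min}, {self.d_max}]")
        self._d_out = int(value)

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, n, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        ho = (h + 2 * self.pad - self.k) // self.stride + 1
        wo = (w + 2 * self.pad - self.k) // self.stride + 1
        p = self.pad
        if p:
            xpad = np.zeros((c, n, h + 2 * p, w + 2 * p), dtype=DTYPE)
            xpad[:, :, p:p + h, p:p + w] = x
        else:
            xpad = np.asarray(x, dtype=DTYPE)
        cols = _im2col(xpad, self.k, self.k, self.stride, ho, wo)
        w2d = self.weight.data.reshape(self.d_max, -1)[:self.d_out]
        y = w2d @ cols
        if self.bias is not None:
            y += self.bias.data[:self.d_out, None]
        self._cache = (cols, xpad.shape, (h, w), (ho, wo))
        return y.reshape(self.d_out, n, ho, wo)

    def backward(self, dy: np.ndarray):
        cols, pad_shape, (h, w), (ho, wo) = self._cache
        dyf = np.ascontiguousarray(dy, dtype=DTYPE).reshape(self.d_out, -1)
        wshape = self.weight.data.shape
        self.weight.grad[:self.d_out] += (dyf @ cols.T).reshape(
            self.d_out, *wshape[1:])
        if self.bias is not None:
            self.bias.grad[:self.d_out] += dyf.sum(axis=1)
        w2d = self.weight.data.reshape(self.d_max, -1)[:self.d_out]
        dcols = w2d.T @ dyf
        dxpad = _col2im(dcols, pad_shape, self.k, self.k, self.stride, ho, wo)
        p = self.pad
        dx = dxpad[:, :, p:p + h, p:p + w] if p else dxpad
        self._cache = None
        return (np.ascontiguousarray(dx),)


# ---------------------------------------------------------------------------
# Functional single-map operations (FeatureMap = (H, W, D) array)
# ---------------------------------------------------------------------------

def elastic_conv(feature_map: np.ndarray, spec: ElasticConvSpec,
                 weights: np.ndarray, bias: np.ndarray | None = None
                 ) -> np.ndarray:
    """Apply a width-sliced convolution to one (H, W, D_in) feature map.

    ``weights`` is the full super-kernel bank (D_max, D_in, K_h, K_w); only
    the first ``spec.d_out`` filters participate.
    """
    if feature_map.shape[-1] != spec.d_in:
        raise ValueError(
            f"feature map has {feature_map.shape[-1]} channels, spec wants {spec.d_in}")
    if weights.shape != (spec.d_max, spec.d_in, *spec.kernel):
        raise ValueError(f"weight bank shape {weights.shape} does not match spec")
    layer = ElasticConv2d(spec.d_in, spec.d_min, spec.d_max, spec.d_out,
                          k=spec.kernel[0], stride=spec.stride,
                          bias=bias is not None)
    layer.weight.data = np.asarray(weights, dtype=DTYPE)
    if bias is not None:
        layer.bias.data = np.asarray(bias, dtype=DTYPE)
    x = to_cnhw(feature_map[None])  # batch of one
    y = layer.forward(x)
    return y[:, 0].transpose(1, 2, 0)


@dataclasses.dataclass
class DeformableKernel:
    """Weights plus learned displacements for one deformable convolution.

    ``weight``: (D_out, D_in, K_h, K_w) kernel omega; ``offsets``:
    (H, W, K_h*K_w, 2) learned displacement (dy, dx) per output location
    and base offset.
    """

    weight: np.ndarray
    offsets: np.ndarray
    bias: np.ndarray | None = None

    def __post_init__(self):
        if not np.all(np.isfinite(self.offsets)):
            raise ValueError("offsets must be finite")


def deformable_conv(feature_map: np.ndarray, kernel: DeformableKernel
                    ) -> np.ndarray:
    """f(xi_0) = sum_{xi in S} omega(xi) * g(xi_0 + xi + Delta_xi).

    Operates on one (H, W, D_in) map with bilinear interpolation at
    fractional positions; out-of-map samples contribute zero.  Stride 1,
    'same' padding.
    """
    h, w, c_in = feature_map.shape
    c_out, c_in_w, kh, kw = kernel.weight.shape
    if c_in_w != c_in:
        raise ValueError("kernel input channels do not match feature map")
    if kernel.offsets.shape != (h, w, kh * kw, 2):
        raise ValueError(
            f"offset field shape {kernel.offsets.shape} != {(h, w, kh * kw, 2)}")
    pad_h, pad_w = kh // 2, kw // 2
    g = feature_map.astype(np.float64)
    out = np.zeros((h, w, c_out))
    gy, gx = np.mgrid[0:h, 0:w].astype(np.float64)
    for t in range(kh * kw):
        i, j = divmod(t, kw)
        py = gy + (i - pad_h) + kernel.offsets[:, :, t, 0]
        px = gx + (j - pad_w) + kernel.offsets[:, :, t, 1]
        y0, x0 = np.floor(py).astype(int), np.floor(px).astype(int)
        wy, wx = py - y0, px - x0
        sample = np.zeros((h, w, c_in))
        for dy_c, dx_c, wgt in ((0, 0, (1 - wy) * (1 - wx)),
                                (0, 1, (1 - wy) * wx),
                                (1, 0, wy * (1 - wx)),
                                (1, 1, wy * wx)):
            yc, xc = y0 + dy_c, x0 + dx_c
            valid = (yc >= 0) & (yc < h) & (xc >= 0) & (xc < w)
            vals = g[np.clip(yc, 0, h - 1), np.clip(xc, 0, w - 1)]
            sample += vals * (wgt * valid)[..., None]
        out += sample @ kernel.weight[:, :, i, j].T
    if kernel.bias is not None:
        out += kernel.bias
    return out


# ---------------------------------------------------------------------------
# Network description and builder
# ---------------------------------------------------------------------------

DEFAULT_CONFIG_PATH = Path(__file__).parent / "configs" / "reference.yaml"


def load_config(path: str | Path | None = None) -> dict:
    with open(path or DEFAULT_CONFIG_PATH) as fh:
        return yaml.safe_load(fh)


@dataclasses.dataclass
class LayerDef:
    """One convolutional layer for profiling: shapes and placement."""

    name: str
    c_in: int
    c_out: int
    kh: int
    kw: int
    out_stride: int  # spatial stride of the output map relative to the input
    deformable: bool = False
    has_bn: bool = True
    has_bias: bool = True


@dataclasses.dataclass
class NetworkSpec:
    """Resolved architecture: scaled depths/channels plus a flat layer table."""

    scale: ElasticScale
    num_classes: int
    base_channels: list[int]
    base_depths: list[int]
    channels: list[int]      # effective per-stage channels after lambda_w
    depths: list[int]        # effective per-stage block counts after lambda_d
    head_channels: int
    epsilon: float
    layers: list[LayerDef]


class _Block:
    """EConv -> BN -> SiLU unit (deformable variant swaps the conv)."""

    def __init__(self, c_in, c_out, k, stride, deformable, rng, name):
        if deformable:
            if stride != 1:
                raise ValueError("deformable blocks are stride-1 only")
            self.conv = DeformConv2d(c_in, c_out, k, rng=rng, name=name)
        else:
            self.conv = Conv2d(c_in, c_out, k, stride, rng=rng, name=name)
        self.bn = BatchNorm2d(c_out, name=name)
        self.act = SiLU()
        self.name = name
        self.deformable = deformable

    def __call__(self, tape: Tape, x):
        return tape.apply(self.act, tape.apply(self.bn, tape.apply(self.conv, x)))

    def params(self):
        return self.conv.params() + self.bn.params()


class _FusionNode:
    """Concat two paths, fuse with a (deformable) block; prunable."""

    def __init__(self, name, path_names, path_channels, c_out, deformable, rng):
        self.name = name
        self.path_names = list(path_names)
        self.path_channels = list(path_channels)
        self.active = [True] * len(path_names)
        self.concat = Concat()
        self.block = _Block(sum(path_channels), c_out, 3, 1, deformable, rng,
                            name + ".fuse")

    def __call__(self, tape: Tape, inputs):
        kept = [x for x, a in zip(inputs, self.active) if a]
        if len(kept) == 1:
            return self.block(tape, kept[0])
        return self.block(tape, tape.apply(self.concat, *kept))

    def c_in(self) -> int:
        return sum(c for c, a in zip(self.path_channels, self.active) if a)

    def path_scores(self) -> np.ndarray:
        """Normalized L1 contribution of each incoming path's fusion weights."""
        w = self.block.conv.weight.data
        d_out = w.shape[0]
        scores, start = [], 0
        for c, a in zip(self.path_channels, self.active):
            if not a:
                scores.append(0.0)
                continue
            scores.append(float(np.abs(w[:d_out, start:start + c]).sum()))
            start += c
        total = sum(scores)
        return np.array(scores) / total if total > 0 else np.ones(len(scores)) / len(scores)

    def prune(self, epsilon: float) -> list[str]:
        """Drop paths whose score < epsilon; the strongest always survives."""
        scores = self.path_scores()
        strongest = int(np.argmax(scores))
        keep = [(s >= epsilon or i == strongest) and self.active[i]
                for i, s in enumerate(scores)]
        dropped = []
        # remove the pruned paths' input-channel slices from the fuse conv
        col_mask, start = [], 0
        for i, (c, a) in enumerate(zip(self.path_channels, self.active)):
            if not a:
                continue
            col_mask.extend([keep[i]] * c)
            start += c
        col_mask = np.array(col_mask, dtype=bool)
        if not col_mask.all():
            conv = self.block.conv
            conv.weight.data = np.ascontiguousarray(conv.weight.data[:, col_mask])
            conv.weight.grad = np.zeros_like(conv.weight.data)
            conv.c_in = int(col_mask.sum())
            if isinstance(conv, DeformConv2d):
                oc = conv.offset_conv
                oc.weight.data = np.ascontiguousarray(oc.weight.data[:, col_mask])
                oc.weight.grad = np.zeros_like(oc.weight.data)
                oc.c_in = int(col_mask.sum())
            for i, a in enumerate(self.active):
                if a and not keep[i]:
                    self.active[i] = False
                    dropped.append(f"{self.name}<-{self.path_names[i]}")
        return dropped


class EYOLONet:
    """Elastic YOLO detector (see module docstring for the topology)."""

    def __init__(self, config: dict, scale: ElasticScale, num_classes: int = 6,
                 seed: int = 0):
        self.config = dict(config)
        self.scale = scale
        self.num_classes = num_classes
        self.seed = seed
        rng = np.random.default_rng(seed)

        base_c = list(config["base_channels"])
        base_d = list(config["base_depths"])
        use_deform = bool(config.get("deformable", True))
        self.channels = [effective_channels(c, scale.lambda_w) for c in base_c]
        self.depths = [effective_depth(d, scale.lambda_d) for d in base_d]
        self.head_channels = effective_channels(config["head_channels"],
                                                scale.lambda_w)
        self.epsilon = float(config.get("epsilon", 0.01))

        c1, c2, c3, c4, c5 = self.channels
        hc = self.head_channels
        nc = num_classes

        # backbone: per-stage downsample conv + (depth-1) stride-1 blocks;
        # the last stride-1 block of stages 3-5 is deformable
        self.backbone: list[list[_Block]] = []
        c_prev = 3
        for s, (c_s, d_s) in enumerate(zip(self.channels, self.depths), start=1):
            stage = []
            for layer in range(d_s):
                deform = (use_deform and s >= 3 and d_s > 1
                          and layer == d_s - 1)
                stride = 2 if layer == 0 else 1
                stage.append(_Block(c_prev if layer == 0 else c_s, c_s, 3,
                                    stride, deform, rng, f"s{s}.l{layer}"))
            self.backbone.append(stage)
            c_prev = c_s
        # the stem consumes the image leaf; its input gradient is never used
        self.backbone[0][0].conv.needs_input_grad = False

    # neck ---------------------------------------------------------------
        self.lat5 = _Block(c5, c4, 1, 1, False, rng, "lat5")
        self.up5 = UpsampleNearest2x()
        self.fuse_u4 = _FusionNode("U4", ["up(lat5)", "F4"], [c4, c4], c4,
                                   use_deform, rng)
        self.lat4 = _Block(c4, c3, 1, 1, False, rng, "lat4")
        self.up4 = UpsampleNearest2x()
        self.fuse_u3 = _FusionNode("U3", ["up(lat4)", "F3"], [c3, c3], c3,
                                   use_deform, rng)
        self.down3 = _Block(c3, c3, 3, 2, False, rng, "down3")
        self.fuse_n4 = _FusionNode("N4", ["down(U3)", "U4"], [c3, c4], c4,
                                   use_deform, rng)
        self.down4 = _Block(c4, c4, 3, 2, False, rng, "down4")
        self.fuse_n5 = _FusionNode("N5", ["down(N4)", "lat5"], [c4, c4], c5,
                                   use_deform, rng)

        # anchor-free heads: stem block + 1x1 projection to
        # (4 box distances + 1 objectness + nc class logits)
        self.heads = []
        for stride, c_head in zip(STRIDES, (c3, c4, c5)):
            stem = _Block(c_head, hc, 3, 1, False, rng, f"head{stride}.stem")
            proj = Conv2d(hc, 4 + 1 + nc, 1, 1, rng=rng, name=f"head{stride}.proj")
            proj.bias.data[4] = -4.0  # objectness prior: rare positives
            self.heads.append((stride, stem, proj))

        self._training = True
        self.pruned_paths: list[str] = []

    # -- bookkeeping ------------------------------------------------------

    @property
    def fusion_nodes(self) -> list[_FusionNode]:
        return [self.fuse_u4, self.fuse_u3, self.fuse_n4, self.fuse_n5]

    def _blocks(self):
        for stage in self.backbone:
            yield from stage
        yield from (self.lat5, self.lat4, self.down3, self.down4)
        for node in self.fusion_nodes:
            yield node.block
        for _, stem, _ in self.heads:
            yield stem

    def params(self) -> list[Param]:
        ps = []
        for b in self._blocks():
            ps.extend(b.params())
        for _, _, proj in self.heads:
            ps.extend(proj.params())
        return ps

    def train(self):
        self._training = True
        for b in self._blocks():
            b.bn.training = True

    def eval(self):
        self._training = False
        for b in self._blocks():
            b.bn.training = False

    def deform_layers(self) -> list[DeformConv2d]:
        return [b.conv for b in self._blocks() if isinstance(b.conv, DeformConv2d)]

    # -- forward ----------------------------------------------------------

    def forward_train(self, images_nhwc: np.ndarray):
        """Run the graph on a normalized (N, H, W, C) batch.

        Returns (tape, {stride: head output Var of shape (5+nc, N, h, w)}).
        """
        n, h, w, _ = images_nhwc.shape
        if h % STRIDES[-1] or w % STRIDES[-1]:
            raise ValueError(f"input size {h}x{w} not divisible by {STRIDES[-1]}")
        tape = Tape()
        x = tape.leaf(to_cnhw(images_nhwc))
        taps = {}
        for s, stage in enumerate(self.backbone, start=1):
            for block in stage:
                x = block(tape, x)
            if s >= 3:
                taps[s] = x
        f3, f4, f5 = taps[3], taps[4], taps[5]

        p5 = self.lat5(tape, f5)
        u4 = self.fuse_u4(tape, [tape.apply(self.up5, p5), f4])
        l4 = self.lat4(tape, u4)
        u3 = self.fuse_u3(tape, [tape.apply(self.up4, l4), f3])
        n4 = self.fuse_n4(tape, [self.down3(tape, u3), u4])
        n5 = self.fuse_n5(tape, [self.down4(tape, n4), p5])

        outputs = {}
        for (stride, stem, proj), feat in zip(self.heads, (u3, n4, n5)):
            outputs[stride] = tape.apply(proj, stem(tape, feat))
        return tape, outputs

    def forward(self, images_nhwc: np.ndarray) -> dict[int, np.ndarray]:
        """Inference pass; returns {stride: (5+nc, N, h, w) raw outputs}."""
        _, outputs = self.forward_train(images_nhwc)
        return {k: v.data for k, v in outputs.items()}

    # -- pruning ----------------------------------------------------------

    def prune(self, epsilon: float | None = None) -> list[str]:
        """Adaptive fusion-path pruning (evaluation-time, structural)."""
        eps = self.epsilon if epsilon is None else float(epsilon)
        if eps < 0:
            raise ValueError("epsilon must be >= 0")
        dropped = []
        for node in self.fusion_nodes:
            dropped.extend(node.prune(eps))
        self.pruned_paths.extend(dropped)
        return dropped

    # -- profiling support -------------------------------------------------

    def spec(self) -> NetworkSpec:
        layers: list[LayerDef] = []
        out_stride = 1
        c_prev = 3
        for s, stage in enumerate(self.backbone, start=1):
            for li, block in enumerate(stage):
                if li == 0:
                    out_stride *= 2
                layers.append(LayerDef(
                    block.name, block.conv.c_in, _conv_cout(block.conv),
                    block.conv.k, block.conv.k, out_stride,
                    deformable=block.deformable))
        c1, c2, c3, c4, c5 = self.channels
        layers.append(LayerDef("lat5", self.lat5.conv.c_in, c4, 1, 1, 32))
        for node, stride in zip(self.fusion_nodes, (16, 8, 16, 32)):
            layers.append(LayerDef(node.name + ".fuse", node.block.conv.c_in,
                                   _conv_cout(node.block.conv), 3, 3, stride,
                                   deformable=node.block.deformable))
        layers.insert(len(layers) - 2,
                      LayerDef("lat4", self.lat4.conv.c_in, c3, 1, 1, 16))
        layers.append(LayerDef("down3", c3, c3, 3, 3, 16))
        layers.append(LayerDef("down4", c4, c4, 3, 3, 32))
        for (stride, stem, proj) in self.heads:
            layers.append(LayerDef(f"head{stride}.stem", stem.conv.c_in,
                                   self.head_channels, 3, 3, stride))
            layers.append(LayerDef(f"head{stride}.proj", self.head_channels,
                                   proj.c_out, 1, 1, stride, has_bn=False))
        return NetworkSpec(
            scale=self.scale, num_classes=self.num_classes,
            base_channels=list(self.config["base_channels"]),
            base_depths=list(self.config["base_depths"]),
            channels=list(self.channels), depths=list(self.depths),
            head_channels=self.head_channels, epsilon=self.epsilon,
            layers=layers)

    # -- checkpointing -----------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays = {}
        for i, p in enumerate(self.params()):
            arrays[f"param_{i:04d}"] = p.data
        for j, b in enumerate(self._blocks()):
            arrays[f"bn_{j:04d}_mean"] = b.bn.running_mean
            arrays[f"bn_{j:04d}_var"] = b.bn.running_var
        return arrays

    def save(self, path: str | Path):
        arrays = self.state_arrays()
        arrays["_config_yaml"] = np.frombuffer(
            yaml.safe_dump({
                "config": self.config,
                "scale": {"lambda_d": self.scale.lambda_d,
                          "lambda_w": self.scale.lambda_w},
                "num_classes": self.num_classes,
                "seed": self.seed,
            }).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "EYOLONet":
        with np.load(path) as data:
            meta = yaml.safe_load(io.BytesIO(data["_config_yaml"].tobytes()))
            net = cls(meta["config"],
                      ElasticScale(**meta["scale"]),
                      num_classes=meta["num_classes"], seed=meta["seed"])
            for i, p in enumerate(net.params()):
                p.data = np.asarray(data[f"param_{i:04d}"], dtype=DTYPE)
                p.grad = np.zeros_like(p.data)
            for j, b in enumerate(net._blocks()):
                b.bn.running_mean = np.asarray(data[f"bn_{j:04d}_mean"], dtype=DTYPE)
                b.bn.running_var = np.asarray(data[f"bn_{j:04d}_var"], dtype=DTYPE)
        net.eval()
        return net


def _conv_cout(conv) -> int:
    return conv.d_out if isinstance(conv, ElasticConv2d) else conv.c_out


def build_network(scale: ElasticScale, num_classes: int = 6,
                  config: dict | str | Path | None = None,
                  seed: int = 0) -> EYOLONet:
    """Instantiate Elastic YOLO from the (committed) base schedule.

    ``config`` may be a dict, a YAML path, or None for the packaged
    reference schedule.  Weight initialization is deterministic in ``seed``.
    """
    if config is None or isinstance(config, (str, Path)):
        config = load_config(config)
    return EYOLONet(config, scale, num_classes=num_classes, seed=seed)
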