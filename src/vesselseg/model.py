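"""Dense-block U-Net: channel algebra, construction, and introspection.

Architecture (all stages built from :mod:`vesselseg.nn` layers):

* initial 3x3 convolution ``input_channels -> initial_channels``
* contraction: ``n_blocks_down`` x [dense block -> transition-down], where
  transition-down = BN -> 1x1 conv (compression 0.5) -> 2x2 average pool
* bottleneck dense block
* expansion: ``n_blocks_down`` x [2x2 transposed conv (channel halving)
  -> concatenate skip -> dense block]
* head: 1x1 convolution -> sigmoid, one probability channel

Inside a dense block, layer l (1-based) sees ``k0 + k*(l-1)`` channels —
the concatenation of the block input and all previous layer outputs — and
emits ``k`` new channels through BN -> ReLU -> 3x3 conv. The block output
concatenates the input with all L layer outputs (``k0 + k*L`` channels).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Callable

import numpy as np

from . import nn

__all__ = [
    "NetworkSpec",
    "LayerPlan",
    "dense_block_plan",
    "DenseBlock",
    "DenseUNet",
    "build_network",
    "count_parameters",
    "layer_plan",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Hyperparameters of the dense-block U-Net."""

    growth_rate: int = 12
    layers_per_block: int = 4
    n_blocks_down: int = 2
    initial_channels: int = 16
    input_size: int = 48
    input_channels: int = 1
    output_activation: str = "sigmoid"

    def __post_init__(self) -> None:
        for name in ("growth_rate", "layers_per_block", "n_blocks_down", "initial_channels", "input_size", "input_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"NetworkSpec.{name} must be >= 1")
        if self.input_size % (2**self.n_blocks_down) != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by 2^{self.n_blocks_down}"
            )
        if self.output_activation != "sigmoid":
            raise ValueError("only a sigmoid output head is supported")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "NetworkSpec":
        return cls(**json.loads(s))


@dataclass
class LayerPlan:
    """Ordered (stage name, input channels, output channels) triples."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)


def dense_block_plan(k0: int, k: int, L: int) -> LayerPlan:
    """Channel algebra of one dense block with input width k0.

    Layer l receives ``k0 + k*(l-1)`` channels and emits ``k``; the block
    output is the full concatenation with ``k0 + k*L`` channels.
    """
    if k0 < 1 or k < 1 or L < 1:
        raise ValueError("k0, k and L must all be >= 1")
    stages = [(f"layer{l}", k0 + k * (l - 1), k) for l in range(1, L + 1)]
    stages.append(("concat_out", k0, k0 + k * L))
    return LayerPlan(stages=stages)


class DenseBlock(nn.Layer):
    """L densely-connected BN -> ReLU -> 3x3 conv layers.

    ``output_hooks[j]`` (0-based layer index) is applied to layer j's
    output during forward — used by tests to ablate inner layers. When
    ``record_inputs`` is set, the concatenated input of every layer is
    kept in ``last_inputs``.
    """

    def __init__(self, in_channels: int, growth_rate: int, n_layers: int, rng, dtype=np.float32):
        self.in_channels = in_channels
        self.growth_rate = growth_rate
        self.n_layers = n_layers
        self.sublayers = [
            nn.Sequential(
                nn.BatchNorm2d(in_channels + growth_rate * j, dtype=dtype),
                nn.ReLU(),
                nn.Conv2d(in_channels + growth_rate * j, growth_rate, 3, rng, dtype=dtype),
            )
            for j in range(n_layers)
        ]
        self.out_channels = in_channels + growth_rate * n_layers
        self.output_hooks: dict[int, Callable[[np.ndarray], np.ndarray]] = {}
        self.record_inputs = False
        self.last_inputs: list[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        feats = [x]
        self.last_inputs = []
        for j, sub in enumerate(self.sublayers):
            inp = feats[0] if j == 0 else np.concatenate(feats, axis=1)
            if self.record_inputs:
                self.last_inputs.append(inp.copy())
            out = sub.forward(inp)
            if j in self.output_hooks:
                out = self.output_hooks[j](out)
            feats.append(out)
        return np.concatenate(feats, axis=1)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        k = self.growth_rate
        c0 = self.in_channels
        # grad for each concatenated feature: [input, out_1 .. out_L]
        g_feats = [grad_out[:, :c0].copy()]
        for j in range(self.n_layers):
            g_feats.append(grad_out[:, c0 + j * k : c0 + (j + 1) * k].copy())
        for j in range(self.n_layers - 1, -1, -1):
            g_inp = self.sublayers[j].backward(g_feats[j + 1])
            g_feats[0] += g_inp[:, :c0]
            for m in range(j):
                g_feats[m + 1] += g_inp[:, c0 + m * k : c0 + (m + 1) * k]
        return g_feats[0]


class _TransitionDown(nn.Layer):
    """BN -> 1x1 conv (compression 0.5) -> 2x2 average pooling."""

    def __init__(self, in_channels: int, rng, dtype=np.float32):
        self.out_channels = max(1, in_channels // 2)
        self.body = nn.Sequential(
            nn.BatchNorm2d(in_channels, dtype=dtype),
            nn.Conv2d(in_channels, self.out_channels, 1, rng, dtype=dtype),
            nn.AvgPool2d(),
        )

    def forward(self, x):
        return self.body.forward(x)

    def backward(self, g):
        return self.body.backward(g)


class DenseUNet(nn.Layer):
    """Full encoder-decoder segmentation network; maps (N,1,H,W) -> (N,1,H,W)."""

    def __init__(self, spec: NetworkSpec, seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        k, L, nb, k0 = (
            spec.growth_rate,
            spec.layers_per_block,
            spec.n_blocks_down,
            spec.initial_channels,
        )
        self.init_conv = nn.Conv2d(spec.input_channels, k0, 3, rng, dtype=dtype)

        self.down_blocks: list[DenseBlock] = []
        self.down_transitions: list[_TransitionDown] = []
        c = k0
        skip_channels = []
        for _ in range(nb):
            block = DenseBlock(c, k, L, rng, dtype=dtype)
            self.down_blocks.append(block)
            skip_channels.append(block.out_channels)
            td = _TransitionDown(block.out_channels, rng, dtype=dtype)
            self.down_transitions.append(td)
            c = td.out_channels
        self.bottleneck = DenseBlock(c, k, L, rng, dtype=dtype)
        c = self.bottleneck.out_channels

        self.up_transitions: list[nn.ConvTranspose2d] = []
        self.up_blocks: list[DenseBlock] = []
        for d in range(nb - 1, -1, -1):
            up_out = max(1, c // 2)
            self.up_transitions.append(nn.ConvTranspose2d(c, up_out, rng, dtype=dtype))
            merged = up_out + skip_channels[d]
            block = DenseBlock(merged, k, L, rng, dtype=dtype)
            self.up_blocks.append(block)
            c = block.out_channels
        self.head = nn.Conv2d(c, 1, 1, rng, dtype=dtype)
        self.out_act = nn.Sigmoid()

    def forward(self, x: np.ndarray) -> np.ndarray:
        nb = self.spec.n_blocks_down
        h, w = x.shape[2], x.shape[3]
        div = 2**nb
        if h % div or w % div:
            raise ValueError(f"spatial dims {h}x{w} must be divisible by {div}")
        x = np.ascontiguousarray(x, dtype=self.dtype)
        x = self.init_conv.forward(x)
        skips = []
        for block, td in zip(self.down_blocks, self.down_transitions):
            s = block.forward(x)
            skips.append(s)
            x = td.forward(s)
        x = self.bottleneck.forward(x)
        self._up_concat_channels = []
        for i, (tu, block) in enumerate(zip(self.up_transitions, self.up_blocks)):
            u = tu.forward(x)
            skip = skips[nb - 1 - i]
            self._up_concat_channels.append(u.shape[1])
            x = block.forward(np.concatenate([u, skip], axis=1))
        return self.out_act.forward(self.head.forward(x))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        nb = self.spec.n_blocks_down
        g = self.head.backward(self.out_act.backward(grad_out))
        skip_grads: list[np.ndarray | None] = [None] * nb
        for i in range(nb - 1, -1, -1):
            g_merged = self.up_blocks[i].backward(g)
            cu = self._up_concat_channels[i]
            skip_grads[nb - 1 - i] = g_merged[:, cu:]
            g = self.up_transitions[i].backward(g_merged[:, :cu])
        g = self.bottleneck.backward(g)
        for d in range(nb - 1, -1, -1):
            g_skip = self.down_transitions[d].backward(g) + skip_grads[d]
            g = self.down_blocks[d].backward(g_skip)
        return self.init_conv.backward(g)

    # -- serialization ----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param.{n}": p.data for n, p in self.named_params()}
        state.update({f"buffer.{n}": b for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for n, p in self.named_params():
            src = state[f"param.{n}"]
            if src.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {n}")
            p.data[...] = src
        buf_owners = {}
        for n, _ in self.named_buffers():
            parts = n.rsplit(".", 1)
            buf_owners[n] = parts
        for n, b in self.named_buffers():
            b[...] = state[f"buffer.{n}"]


def build_network(spec: NetworkSpec, seed: int = 0, dtype=np.float32) -> DenseUNet:
    """Construct a seeded, trainable dense-block U-Net."""
    return DenseUNet(spec, seed=seed, dtype=dtype)


def count_parameters(model: DenseUNet) -> int:
    """Exact count of trainable parameters (BN running stats excluded)."""
    return int(sum(p.data.size for p in model.parameters()))


def layer_plan(model: DenseUNet) -> dict[str, LayerPlan]:
    """Introspect the built model's dense blocks into per-block LayerPlans.

    Channel counts are read from the actual convolution weight shapes, so
    this reflects what was built, not what was requested.
    """
    plans: dict[str, LayerPlan] = {}
    blocks = (
        [(f"down{d}", b) for d, b in enumerate(model.down_blocks)]
        + [("bottleneck", model.bottleneck)]
        + [(f"up{u}", b) for u, b in enumerate(model.up_blocks)]
    )
    for name, block in blocks:
        stages = []
        for j, sub in enumerate(block.sublayers):
            conv = sub.layers[2]
            stages.append((f"layer{j + 1}", conv.in_channels, conv.out_channels))
        stages.append(("concat_out", block.in_channels, block.out_channels))
        plans[name] = LayerPlan(stages=stages)
    return plans
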