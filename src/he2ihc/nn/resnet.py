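"""Modified ResNet18 three-class patch classifier and its dense (fully
convolutional) counterpart.

The classifier follows the standard 18-layer residual design with two
modifications: the global average pool is removed, so the 512x2x2 feature
map of a 64x64 patch is flattened straight into the final fully connected
layer, and that layer has 3 output nodes (negative cell / positive cell /
background).  Removing the pool is what makes the fully convolutional
rearrangement meaningful: the FC weight matrix over 512x2x2 features is
exactly a 2x2 convolution kernel over 512 channels, so a trained classifier
can be rewritten to emit a score map over an arbitrarily large region at an
output stride of 32.

Padding conventions (conv1 pad 3, pool1 pad 1, all block 3x3 convs pad 1)
are the unique choice that produces the 64->32->16->8->4->2 spatial chain on
a 64x64 input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .layers import BatchNorm2d, Conv2d, Linear, MaxPool2d, ReLU, conv_out_size

N_CLASSES = 3
PATCH_SIZE = 64
OUTPUT_STRIDE = 32


@dataclass(frozen=True)
class BlockSpec:
    """One basic residual block: `kernels` output channels, first-conv stride."""

    kernels: int
    stride: int

    def __post_init__(self) -> None:
        if self.kernels not in (64, 128, 256, 512):
            raise ValueError(f"unsupported block width {self.kernels}")
        if self.stride not in (1, 2):
            raise ValueError(f"block stride must be 1 or 2, got {self.stride}")


@dataclass(frozen=True)
class NetworkSpec:
    """Layer plan of the modified ResNet18 (3-channel input, 3 outputs)."""

    input_channels: int = 3
    patch_size: int = PATCH_SIZE
    n_classes: int = N_CLASSES
    stages: tuple[tuple[BlockSpec, BlockSpec], ...] = field(
        default_factory=lambda: (
            (BlockSpec(64, 1), BlockSpec(64, 1)),
            (BlockSpec(128, 2), BlockSpec(128, 1)),
            (BlockSpec(256, 2), BlockSpec(256, 1)),
            (BlockSpec(512, 2), BlockSpec(512, 1)),
        )
    )

    @property
    def feature_channels(self) -> int:
        return self.stages[-1][-1].kernels

    @property
    def fc_spatial(self) -> int:
        """Spatial side of the feature map the FC layer flattens (2 for 64 px)."""
        side = self.patch_size
        for kernel, stride, pad in ((7, 2, 3), (3, 2, 1)):
            side = conv_out_size(side, kernel, stride, pad)
        for stage in self.stages:
            for block in stage:
                side = conv_out_size(side, 3, block.stride, 1)
        return side

    def fingerprint(self) -> str:
        return json.dumps(
            {
                "input_channels": self.input_channels,
                "patch_size": self.patch_size,
                "n_classes": self.n_classes,
                "stages": [[(b.kernels, b.stride) for b in st] for st in self.stages],
            },
            sort_keys=True,
        )


def layer_output_shape(
    spec: NetworkSpec, input_shape: tuple[int, int]
) -> list[tuple[str, tuple[int, int, int], tuple[int, int, int]]]:
    """Per-layer (name, input CxHxW, output CxHxW) by pure shape arithmetic.

    Spatial sizes follow floor((n + 2p - k)/s) + 1 per conv/pool with the
    module's padding conventions; no forward pass is run.  Inputs smaller
    than the 64-px training patch are rejected: the final 2x2 window would
    be undefined.
    """
    h, w = input_shape
    if h < spec.patch_size or w < spec.patch_size:
        raise ValueError(f"input {h}x{w} smaller than minimum {spec.patch_size}x{spec.patch_size}")

    rows = []

    def step(name, c_in, c_out, kernel, stride, pad):
        nonlocal h, w
        h2 = conv_out_size(h, kernel, stride, pad)
        w2 = conv_out_size(w, kernel, stride, pad)
        rows.append((name, (c_in, h, w), (c_out, h2, w2)))
        h, w = h2, w2

    step("conv1", spec.input_channels, 64, 7, 2, 3)
    step("pool1", 64, 64, 3, 2, 1)
    c = 64
    for i, stage in enumerate(spec.stages, start=1):
        c_out = stage[0].kernels
        h_in, w_in, c_in = h, w, c
        for block in stage:
            h = conv_out_size(h, 3, block.stride, 1)
            w = conv_out_size(w, 3, block.stride, 1)
        rows.append((f"layer{i}", (c_in, h_in, w_in), (c_out, h, w)))
        c = c_out
    rows.append(("FC", (c, h, w), (spec.n_classes, 1, 1)))
    return rows


def score_map_size(spec: NetworkSpec, side: int) -> int:
    """Spatial size of the dense score map along one axis of `side` pixels."""
    if side < spec.patch_size:
        raise ValueError(f"input side {side} below minimum {spec.patch_size}")
    n = side
    n = conv_out_size(n, 7, 2, 3)
    n = conv_out_size(n, 3, 2, 1)
    for stage in spec.stages:
        for block in stage:
            n = conv_out_size(n, 3, block.stride, 1)
    return conv_out_size(n, spec.fc_spatial, 1, 0)


def receptive_interval(spec: NetworkSpec) -> tuple[int, int, int]:
    """(stride, lo, hi): dense output index i along one axis depends exactly on
    input pixels [stride*i + lo, stride*i + hi] (before clipping to the image).
    """
    plan = [(7, 2, 3), (3, 2, 1)]
    for stage in spec.stages:
        for block in stage:
            plan.append((3, block.stride, 1))  # first conv of the block
            plan.append((3, 1, 1))  # second conv
    plan.append((spec.fc_spatial, 1, 0))
    # compose top-down: start with identity mapping in final-output space
    stride, lo, hi = 1, 0, 0
    for kernel, s, pad in reversed(plan):
        # an index j in this layer's output depends on inputs [j*s - pad, j*s - pad + kernel - 1]
        lo = lo * s - pad
        hi = hi * s - pad + kernel - 1
        stride = stride * s
    return stride, lo, hi


class BasicBlock:
    """conv3x3-BN-ReLU-conv3x3-BN, additive shortcut, post-add ReLU."""

    def __init__(self, in_channels: int, out_channels: int, stride: int, rng: np.random.Generator):
        self.conv1 = Conv2d(in_channels, out_channels, 3, stride, 1, rng=rng)
        self.bn1 = BatchNorm2d(out_channels)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_channels, out_channels, 3, 1, 1, rng=rng)
        self.bn2 = BatchNorm2d(out_channels)
        self.relu2 = ReLU()
        if stride != 1 or in_channels != out_channels:
            self.down_conv = Conv2d(in_channels, out_channels, 1, stride, 0, rng=rng)
            self.down_bn = BatchNorm2d(out_channels)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x, train=True):
        out = self.conv1(x, train)
        out = self.bn1(out, train)
        out = self.relu1(out, train)
        out = self.conv2(out, train)
        out = self.bn2(out, train)
        if self.down_conv is not None:
            shortcut = self.down_bn(self.down_conv(x, train), train)
        else:
            shortcut = x
        return self.relu2(out + shortcut, train)

    def backward(self, dout):
        d = self.relu2.backward(dout)
        dmain = self.bn2.backward(d)
        dmain = self.conv2.backward(dmain)
        dmain = self.relu1.backward(dmain)
        dmain = self.bn1.backward(dmain)
        dx = self.conv1.backward(dmain)
        if self.down_conv is not None:
            dsc = self.down_bn.backward(d)
            dx = dx + self.down_conv.backward(dsc)
        else:
            dx = dx + d
        return dx

    def sublayers(self):
        names = ["conv1", "bn1", "conv2", "bn2"]
        if self.down_conv is not None:
            names += ["down_conv", "down_bn"]
        return [(n, getattr(self, n)) for n in names]


class _Trunk:
    """Shared convolutional body: conv1 .. layer4."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        self.spec = spec
        self.conv1 = Conv2d(spec.input_channels, 64, 7, 2, 3, rng=rng)
        self.bn1 = BatchNorm2d(64)
        self.relu = ReLU()
        self.pool1 = MaxPool2d(3, 2, 1)
        self.stages: list[list[BasicBlock]] = []
        c = 64
        for stage in spec.stages:
            blocks = []
            for block_spec in stage:
                blocks.append(BasicBlock(c, block_spec.kernels, block_spec.stride, rng))
                c = block_spec.kernels
            self.stages.append(blocks)

    def forward(self, x, train=True):
        out = self.conv1(x, train)
        out = self.bn1(out, train)
        out = self.relu(out, train)
        out = self.pool1(out, train)
        for blocks in self.stages:
            for block in blocks:
                out = block.forward(out, train)
        return out

    def backward(self, dout):
        for blocks in reversed(self.stages):
            for block in reversed(blocks):
                dout = block.backward(dout)
        dout = self.pool1.backward(dout)
        dout = self.relu.backward(dout)
        dout = self.bn1.backward(dout)
        return self.conv1.backward(dout)

    def sublayers(self):
        items = [("conv1", self.conv1), ("bn1", self.bn1)]
        for i, blocks in enumerate(self.stages, start=1):
            for j, block in enumerate(blocks):
                for name, layer in block.sublayers():
                    items.append((f"layer{i}.{j}.{name}", layer))
        return items


class ResNet18Classifier:
    """Fixed-input (64x64) three-class patch classifier."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        self.spec = spec
        self.trunk = _Trunk(spec, rng)
        side = spec.fc_spatial
        self.fc = Linear(spec.feature_channels * side * side, spec.n_classes, rng=rng)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.spec.input_channels:
            raise ValueError(
                f"expected (N, {self.spec.input_channels}, H, W) input, got shape {x.shape}"
            )
        feats = self.trunk.forward(x.astype(np.float32, copy=False), train)
        flat = feats.reshape(feats.shape[0], -1)  # (C, H, W) raveled row-major
        return self.fc(flat, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dflat = self.fc.backward(dlogits)
        side = self.spec.fc_spatial
        dfeats = dflat.reshape(-1, self.spec.feature_channels, side, side)
        self.trunk.backward(dfeats)

    def sublayers(self):
        return self.trunk.sublayers() + [("fc", self.fc)]

    def named_parameters(self):
        for lname, layer in self.sublayers():
            for pname in layer.params:
                yield f"{lname}.{pname}", layer, pname

    def num_parameters(self) -> int:
        return sum(layer.params[p].size for _, layer, p in self.named_parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for lname, layer in self.sublayers():
            for pname, arr in layer.params.items():
                state[f"{lname}.{pname}"] = arr
            if isinstance(layer, BatchNorm2d):
                state[f"{lname}.running_mean"] = layer.running_mean
                state[f"{lname}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for lname, layer in self.sublayers():
            for pname in layer.params:
                layer.params[pname] = np.asarray(state[f"{lname}.{pname}"], dtype=np.float32)
            if isinstance(layer, BatchNorm2d):
                layer.running_mean = np.asarray(state[f"{lname}.running_mean"], dtype=np.float32)
                layer.running_var = np.asarray(state[f"{lname}.running_var"], dtype=np.float32)


class DenseResNet18:
    """The classifier rewritten as a fully convolutional dense scorer.

    The final fully connected layer becomes a `fc_spatial` x `fc_spatial`
    convolution over the 512 trunk channels; its kernel is a pure reshape of
    the FC weight matrix and the bias is carried over unchanged.  On a 64x64
    input the 3x1x1 output equals the classifier's score vector; on larger
    inputs it scans the patch classifier densely at output stride 32.
    """

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator | None = None):
        self.spec = spec
        rng = rng or np.random.default_rng(0)
        self.trunk = _Trunk(spec, rng)
        side = spec.fc_spatial
        self.head = Conv2d(spec.feature_channels, spec.n_classes, side, 1, 0, bias=True, rng=rng)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        feats = self.trunk.forward(x.astype(np.float32, copy=False), train)
        return self.head(feats, train)

    def sublayers(self):
        return self.trunk.sublayers() + [("head", self.head)]

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for lname, layer in self.sublayers():
            for pname, arr in layer.params.items():
                state[f"{lname}.{pname}"] = arr
            if isinstance(layer, BatchNorm2d):
                state[f"{lname}.running_mean"] = layer.running_mean
                state[f"{lname}.running_var"] = layer.running_var
        return state


def build_classifier(
    spec: NetworkSpec | None = None,
    seed: int = 0,
    pretrained_weights: str | None = None,
) -> ResNet18Classifier:
    """Construct the patch classifier with seeded He-normal initialisation.

    `pretrained_weights` optionally points to a local `.npz` state file
    (e.g. a backbone exported elsewhere); nothing is ever downloaded.
    """
    spec = spec or NetworkSpec()
    net = ResNet18Classifier(spec, np.random.default_rng(seed))
    if pretrained_weights is not None:
        with np.load(pretrained_weights) as data:
            state = {k: data[k] for k in data.files if not k.startswith("__")}
        net.load_state_dict(state)
    return net


def convert_to_fully_convolutional(net: ResNet18Classifier) -> DenseResNet18:
    """Rearrange the trained classifier's FC layer into a convolution.

    The FC weight matrix (3 x 2048) is reshaped to a (3, 512, 2, 2) kernel —
    the flatten order of the classifier is (channel, row, col), so the
    reshape is exact — and all trunk weights and batch-norm running moments
    are copied over.  The result maps any HxW >= 64x64 input to a
    3 x S(H) x S(W) score map.
    """
    if not isinstance(net, ResNet18Classifier) or not hasattr(net, "fc"):
        raise TypeError("expected a ResNet18Classifier with a final fully connected layer")
    spec = net.spec
    dense = DenseResNet18(spec)
    src = dict(net.trunk.sublayers())
    for lname, layer in dense.trunk.sublayers():
        for pname in layer.params:
            layer.params[pname] = src[lname].params[pname].copy()
        if isinstance(layer, BatchNorm2d):
            layer.running_mean = src[lname].running_mean.copy()
            layer.running_var = src[lname].running_var.copy()
    side = spec.fc_spatial
    dense.head.params["W"] = (
        net.fc.params["W"].reshape(spec.n_classes, spec.feature_channels, side, side).copy()
    )
    dense.head.params["b"] = net.fc.params["b"].copy()
    return dense


def expected_parameter_count(spec: NetworkSpec) -> int:
    """Closed-form parameter tally from the layer table (used by callers that
    want a structural sanity check without walking a built network)."""
    total = spec.input_channels * 64 * 7 * 7 + 2 * 64  # conv1 + bn1
    c_in = 64
    for stage in spec.stages:
        for block in stage:
            c_out = block.kernels
            total += c_in * c_out * 9 + 2 * c_out  # conv1+bn1
            total += c_out * c_out * 9 + 2 * c_out  # conv2+bn2
            if block.stride != 1 or c_in != c_out:
                total += c_in * c_out + 2 * c_out  # 1x1 projection + bn
            c_in = c_out
    side = spec.fc_spatial
    total += spec.feature_channels * side * side * spec.n_classes + spec.n_classes
    return total
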