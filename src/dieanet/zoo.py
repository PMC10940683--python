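"""Backbone classifiers, attention injection and compute-budget accounting.

Three standard backbones are built in the package's own layer library with
channel/stage structure matching their torchvision definitions: ResNet-34,
MobileNetV2 (width 1.0) and EfficientNet-B0.  An attention operator (DIEA or
Coordinate Attention) can be injected after the final feature stage (default),
after every stage, or after every block.

Budgets: ``count_params`` sums trainable elements; ``count_macs`` instruments
an actual forward pass at the requested input size and sums per-layer
multiply-accumulates (one MAC = one FLOP).  Besides convolution/linear MACs
the counter also records elementwise work of batch norm, activations and
pooling so either convention can be reported; the default includes them,
which is the convention under which the published per-backbone figures at
256×256 are reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from . import nn
from .attention import DIEA, CoordinateAttention, DIEAConfig
from .autodiff import Tensor

__all__ = [
    "Architecture", "AttentionKind", "Placement", "BackboneSpec", "InjectionPolicy",
    "BudgetReport", "build_model", "build_tiny_cnn", "count_params", "count_macs",
    "budget_report", "StagedClassifier",
]


class Architecture(str, Enum):
    RESNET34 = "resnet34"
    MOBILENET_V2 = "mobilenet_v2"
    EFFICIENTNET_B0 = "efficientnet_b0"
    TINY = "tiny"


class AttentionKind(str, Enum):
    DIEA = "diea"
    CA = "ca"
    NONE = "none"


class Placement(str, Enum):
    FINAL_STAGE = "final_stage"
    EVERY_STAGE = "every_stage"
    PER_BLOCK = "per_block"


@dataclass
class BackboneSpec:
    architecture: Architecture = Architecture.RESNET34
    num_classes: int = 3
    seed: int = 0

    def __post_init__(self):
        self.architecture = Architecture(self.architecture)
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")


@dataclass
class InjectionPolicy:
    module_kind: AttentionKind = AttentionKind.NONE
    placement: Placement = Placement.FINAL_STAGE
    stage_indices: list[int] | None = None
    diea: dict = field(default_factory=dict)     # DIEAConfig overrides

    def __post_init__(self):
        self.module_kind = AttentionKind(self.module_kind)
        self.placement = Placement(self.placement)


@dataclass
class BudgetReport:
    architecture: str
    attention: str
    placement: str
    params_millions: float
    macs_giga: float
    input_size: tuple[int, int]

    def to_dict(self) -> dict:
        return {"architecture": self.architecture, "attention": self.attention,
                "placement": self.placement, "params_millions": self.params_millions,
                "macs_giga": self.macs_giga, "input_size": list(self.input_size)}


# --------------------------------------------------------------------------
# building blocks
# --------------------------------------------------------------------------

class ConvBNAct(nn.Module):
    def __init__(self, c_in, c_out, k, stride, groups=1, act="relu", rng=None):
        super().__init__()
        self.conv = nn.Conv2d(c_in, c_out, k, stride=stride, padding=(k - 1) // 2,
                              groups=groups, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(c_out)
        self.act = {"relu": nn.ReLU, "relu6": nn.ReLU6, "silu": nn.SiLU,
                    "none": nn.Identity}[act]()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class BasicBlock(nn.Module):
    """ResNet v1 basic block (two 3×3 convs + identity/projection shortcut)."""

    def __init__(self, c_in, c_out, stride, rng=None):
        super().__init__()
        self.conv1 = ConvBNAct(c_in, c_out, 3, stride, rng=rng)
        self.conv2 = nn.Conv2d(c_out, c_out, 3, padding=1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(c_out)
        self.down = None
        if stride != 1 or c_in != c_out:
            self.down = nn.Sequential(
                nn.Conv2d(c_in, c_out, 1, stride=stride, bias=False, rng=rng),
                nn.BatchNorm2d(c_out))
        self.relu = nn.ReLU()

    def forward(self, x):
        idt = x if self.down is None else self.down(x)
        return self.relu(self.bn2(self.conv2(self.conv1(x))) + idt)


class SqueezeExcite(nn.Module):
    def __init__(self, c, squeeze, rng=None):
        super().__init__()
        self.fc1 = nn.Conv2d(c, squeeze, 1, bias=True, rng=rng)
        self.fc2 = nn.Conv2d(squeeze, c, 1, bias=True, rng=rng)
        self.act = nn.SiLU()

    def forward(self, x):
        s = x.mean(axis=(2, 3), keepdims=True)
        s = self.fc2(self.act(self.fc1(s))).sigmoid()
        return x * s


class InvertedResidual(nn.Module):
    """MobileNetV2 inverted residual (ReLU6, no SE)."""

    def __init__(self, c_in, c_out, stride, expand, rng=None):
        super().__init__()
        hidden = c_in * expand
        self.use_res = stride == 1 and c_in == c_out
        layers = []
        if expand != 1:
            layers.append(ConvBNAct(c_in, hidden, 1, 1, act="relu6", rng=rng))
        layers.append(ConvBNAct(hidden, hidden, 3, stride, groups=hidden, act="relu6", rng=rng))
        layers.append(ConvBNAct(hidden, c_out, 1, 1, act="none", rng=rng))
        self.block = nn.Sequential(*layers)

    def forward(self, x):
        y = self.block(x)
        return x + y if self.use_res else y


class MBConv(nn.Module):
    """EfficientNet MBConv (SiLU + squeeze-excitation on the expanded channels)."""

    def __init__(self, c_in, c_out, kernel, stride, expand, rng=None):
        super().__init__()
        hidden = c_in * expand
        self.use_res = stride == 1 and c_in == c_out
        layers = []
        if expand != 1:
            layers.append(ConvBNAct(c_in, hidden, 1, 1, act="silu", rng=rng))
        layers.append(ConvBNAct(hidden, hidden, kernel, stride, groups=hidden, act="silu", rng=rng))
        layers.append(SqueezeExcite(hidden, max(1, c_in // 4), rng=rng))
        layers.append(ConvBNAct(hidden, c_out, 1, 1, act="none", rng=rng))
        self.block = nn.Sequential(*layers)

    def forward(self, x):
        y = self.block(x)
        return x + y if self.use_res else y


class StagedClassifier(nn.Module):
    """Feature stages (optionally interleaved with attention) + GAP head.

    Stage outputs of the latest forward are cached by name when
    ``cache_activations`` is set — Grad-CAM reads activations and their
    gradients from this cache.
    """

    def __init__(self, stages: list[tuple[str, nn.Module]], feature_dim: int,
                 num_classes: int, rng=None):
        super().__init__()
        self.stage_names = [n for n, _ in stages]
        self.stage_mods = [m for _, m in stages]
        self.pool = nn.GlobalAvgPool()
        self.flat = nn.Flatten()
        self.fc = nn.Linear(feature_dim, num_classes, rng=rng)
        self.cache_activations = False
        self.activation_cache: dict[str, Tensor] = {}

    def forward(self, x):
        if self.cache_activations:
            self.activation_cache = {}
        for name, mod in zip(self.stage_names, self.stage_mods):
            x = mod(x)
            if self.cache_activations:
                self.activation_cache[name] = x
        return self.fc(self.flat(self.pool(x)))


# --------------------------------------------------------------------------
# backbone stage lists: (name, module, out_channels)
# --------------------------------------------------------------------------

def _resnet34_stages(rng):
    def layer(c_in, c_out, n, stride):
        blocks = [BasicBlock(c_in, c_out, stride, rng=rng)]
        blocks += [BasicBlock(c_out, c_out, 1, rng=rng) for _ in range(n - 1)]
        return blocks

    stages = [("stem", nn.Sequential(ConvBNAct(3, 64, 7, 2, rng=rng),
                                     nn.MaxPool2d(3, 2, 1)), 64)]
    cfg = [(64, 64, 3, 1), (64, 128, 4, 2), (128, 256, 6, 2), (256, 512, 3, 2)]
    for i, (ci, co, n, s) in enumerate(cfg, 1):
        for j, b in enumerate(layer(ci, co, n, s)):
            stages.append((f"layer{i}.{j}", b, co))
    return stages, 512


def _mobilenet_v2_stages(rng):
    stages = [("stem", ConvBNAct(3, 32, 3, 2, act="relu6", rng=rng), 32)]
    cfg = [(1, 16, 1, 1), (6, 24, 2, 2), (6, 32, 3, 2), (6, 64, 4, 2),
           (6, 96, 3, 1), (6, 160, 3, 2), (6, 320, 1, 1)]
    c_in, idx = 32, 1
    for t, c, n, s in cfg:
        for j in range(n):
            stages.append((f"block{idx}", InvertedResidual(c_in, c, s if j == 0 else 1, t, rng=rng), c))
            c_in, idx = c, idx + 1
    stages.append(("head_conv", ConvBNAct(320, 1280, 1, 1, act="relu6", rng=rng), 1280))
    return stages, 1280


def _efficientnet_b0_stages(rng):
    stages = [("stem", ConvBNAct(3, 32, 3, 2, act="silu", rng=rng), 32)]
    cfg = [(1, 3, 1, 32, 16, 1), (6, 3, 2, 16, 24, 2), (6, 5, 2, 24, 40, 2),
           (6, 3, 2, 40, 80, 3), (6, 5, 1, 80, 112, 3), (6, 5, 2, 112, 192, 4),
           (6, 3, 1, 192, 320, 1)]
    idx = 1
    for t, k, s, ci, co, n in cfg:
        for j in range(n):
            c_in = ci if j == 0 else co
            stages.append((f"block{idx}",
                           MBConv(c_in, co, k, s if j == 0 else 1, t, rng=rng), co))
            idx += 1
    stages.append(("head_conv", ConvBNAct(320, 1280, 1, 1, act="silu", rng=rng), 1280))
    return stages, 1280


def _tiny_stages(rng):
    stages = [("stem", ConvBNAct(3, 16, 3, 2, rng=rng), 16),
              ("conv2", ConvBNAct(16, 32, 3, 2, rng=rng), 32),
              ("conv3", ConvBNAct(32, 64, 3, 2, rng=rng), 64)]
    return stages, 64

_BUILDERS = {
    Architecture.RESNET34: (_resnet34_stages, {"layer1", "layer2", "layer3", "layer4"}),
    Architecture.MOBILENET_V2: (_mobilenet_v2_stages, None),
    Architecture.EFFICIENTNET_B0: (_efficientnet_b0_stages, None),
    Architecture.TINY: (_tiny_stages, None),
}


def _attention_module(kind: AttentionKind, channels: int, policy: InjectionPolicy, rng):
    if kind is AttentionKind.DIEA:
        cfg = DIEAConfig(channels=channels, **policy.diea)
        return DIEA(cfg, rng=rng)
    return CoordinateAttention(channels, rng=rng)


def build_model(spec: BackboneSpec, policy: InjectionPolicy | None = None) -> StagedClassifier:
    """Build a classifier mapping 3×S×S images to ``num_classes`` logits.

    With ``module_kind`` none this is the bare published architecture with the
    classification head resized; otherwise attention modules are inserted at
    the sites selected by the injection policy.
    """
    policy = policy or InjectionPolicy()
    if not isinstance(spec.architecture, Architecture):
        raise ValueError(f"unknown architecture {spec.architecture!r}")
    rng = np.random.default_rng(spec.seed)
    builder, _ = _BUILDERS[spec.architecture]
    stages, feat_dim = builder(rng)

    if policy.module_kind is not AttentionKind.NONE:
        sites: list[int]
        if policy.placement is Placement.FINAL_STAGE:
            # after the last feature block; the 1x1 head conv (where present)
            # belongs to the classifier head and stays outside the gate
            last = len(stages) - 1
            if stages[last][0] == "head_conv":
                last -= 1
            sites = [last]
        elif policy.placement is Placement.PER_BLOCK:
            sites = [i for i, (name, _, _) in enumerate(stages) if name != "stem"]
        else:  # EVERY_STAGE: after the last block of each channel-width run
            sites = [i for i in range(len(stages))
                     if i == len(stages) - 1 or stages[i][2] != stages[i + 1][2]]
        if policy.stage_indices is not None:
            bad = [i for i in policy.stage_indices if not 0 <= i < len(stages)]
            if bad:
                raise ValueError(f"stage indices {bad} do not exist "
                                 f"(model has {len(stages)} stages)")
            sites = sorted(policy.stage_indices)
        out = []
        for i, (name, mod, c) in enumerate(stages):
            out.append((name, mod))
            if i in sites:
                out.append((f"{name}_{policy.module_kind.value}",
                            _attention_module(policy.module_kind, c, policy, rng)))
        named = out
    else:
        named = [(name, mod) for name, mod, _ in stages]

    return StagedClassifier(named, feat_dim, spec.num_classes, rng=rng)


def build_tiny_cnn(num_classes: int = 3, attention: AttentionKind | str = AttentionKind.DIEA,
                   seed: int = 0) -> StagedClassifier:
    """A three-conv classifier with optional attention — the smoke-test model."""
    policy = InjectionPolicy(module_kind=AttentionKind(attention),
                             placement=Placement.FINAL_STAGE,
                             diea={"reduction": 8})
    return build_model(BackboneSpec(Architecture.TINY, num_classes, seed), policy)


# --------------------------------------------------------------------------
# budgets
# --------------------------------------------------------------------------

def count_params(model: nn.Module) -> float:
    """Trainable parameter count in millions."""
    return model.num_params() / 1e6


def count_macs(model: nn.Module, input_size: int = 256,
               convention: str = "profiler") -> float:
    """Multiply-accumulates of one forward pass, in units of 1e9 (one MAC = one FLOP).

    ``conv_linear_only`` counts convolution and linear weight MACs alone.
    The default ``profiler`` convention additionally counts one op per
    conv/linear output element (the accumulator/bias slot), two per element
    for batch norm, one per element for activations and one per input
    element for pooling — the convention of the common FLOP-profiler tools,
    under which the published per-backbone figures at 256×256 are reproduced.
    """
    counter: list = []
    was_training = model.training
    model.eval()
    nn._MAC_COUNTER = counter
    try:
        model(Tensor(np.zeros((1, 3, input_size, input_size), dtype=np.float32)))
    finally:
        nn._MAC_COUNTER = None
        model.train(was_training)
    if convention == "conv_linear_only":
        total = sum(v for tag, v in counter if tag in ("conv", "linear"))
    elif convention == "profiler":
        total = sum(v for tag, v in counter)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return total / 1e9


def budget_report(architecture: Architecture | str = Architecture.RESNET34,
                  attention: AttentionKind | str = AttentionKind.NONE,
                  placement: Placement | str = Placement.FINAL_STAGE,
                  num_classes: int = 3, input_size: int = 256, seed: int = 0,
                  convention: str = "profiler") -> BudgetReport:
    spec = BackboneSpec(Architecture(architecture), num_classes, seed)
    policy = InjectionPolicy(AttentionKind(attention), Placement(placement))
    model = build_model(spec, policy)
    return BudgetReport(
        architecture=spec.architecture.value, attention=policy.module_kind.value,
        placement=policy.placement.value,
        params_millions=count_params(model),
        macs_giga=count_macs(model, input_size, convention),
        input_size=(input_size, input_size))
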