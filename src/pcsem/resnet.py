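"""ResNet50 assembly, attention injection, parameter accounting, Grad-CAM.

The backbone is the standard 50-layer residual network: a 7×7/2 stem with
batch norm and 3×3/2 max pooling, four stages of bottleneck residual blocks
(3/4/6/3 of them, output widths 256/512/1024/2048), global average pooling
and a fully connected head.  Convolutions inside the backbone carry no bias
(each is followed by batch norm); the head carries one.  Stages are numbered
2–5 here so that "convolutional block 1" is the stem, matching the usual
description of the architecture.

Attention blocks are inserted *after the residual addition and before the
final ReLU* of the chosen bottleneck blocks.  Three placement schemes are
supported:

* ``place1`` — after every bottleneck block (16 blocks; C = 256×3, 512×4,
  1024×6, 2048×3),
* ``place2`` — after the last bottleneck of conv blocks 2, 3 and 4
  (3 blocks; C = 256, 512, 1024),
* ``place3`` — after bottlenecks 1 and 2 of conv blocks 2 and 3
  (4 blocks; C = 256, 256, 512, 512).

The default head has 7 sigmoid outputs, one per surgical tool; an 8-unit
"no tool" variant and the original 1000-class head are both available via
``head_classes``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _resize

from . import nn
from .attention import AttentionConfig, make_block

STAGE_BLOCKS = {2: 3, 3: 4, 4: 6, 5: 3}
STAGE_WIDTH = {2: 256, 3: 512, 4: 1024, 5: 2048}
PLACEMENTS = ("none", "place1", "place2", "place3")


def insertion_points(name: str) -> list[tuple[int, int, int]]:
    """Ordered (stage, block index, channel width) insertion points.

    Stage numbering starts at 2 (the first bottleneck stage); block indices
    are 1-based within their stage.
    """
    name = name.lower()
    if name == "none":
        return []
    if name == "place1":
        return [(s, b, STAGE_WIDTH[s])
                for s in (2, 3, 4, 5) for b in range(1, STAGE_BLOCKS[s] + 1)]
    if name == "place2":
        return [(s, STAGE_BLOCKS[s], STAGE_WIDTH[s]) for s in (2, 3, 4)]
    if name == "place3":
        return [(s, b, STAGE_WIDTH[s]) for s in (2, 3) for b in (1, 2)]
    raise ValueError(f"unknown placement {name!r}; expected one of {PLACEMENTS}")


@dataclass
class ModelSpec:
    """Declarative description of a backbone + attention + head combination."""

    attention: str | None = None          # None | "se" | "cbam" | "pcsem"
    placement: str = "none"
    reduction: int = 16
    head_classes: int = 7
    input_size: tuple[int, int] = (224, 224)
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.attention is not None and self.attention.lower() not in ("se", "cbam", "pcsem"):
            raise ValueError(f"unknown attention kind {self.attention!r}")
        if self.placement.lower() not in PLACEMENTS:
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.attention is not None and self.placement == "none":
            self.placement = "place2"
        if self.attention is None:
            self.placement = "none"

    def to_json(self) -> str:
        return json.dumps({
            "attention": self.attention, "placement": self.placement,
            "reduction": self.reduction, "head_classes": self.head_classes,
            "input_size": list(self.input_size),
        })

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        d = json.loads(s)
        d["input_size"] = tuple(d.get("input_size", (224, 224)))
        return cls(**d)


class Bottleneck(nn.Module):
    """1×1 – 3×3 – 1×1 residual unit with optional post-addition attention."""

    def __init__(self, in_ch: int, mid_ch: int, out_ch: int, stride: int,
                 rng: np.random.Generator, attention: nn.Module | None = None):
        self.conv1 = nn.Conv2d(in_ch, mid_ch, 1, rng, bias=False)
        self.bn1 = nn.BatchNorm2d(mid_ch)
        self.conv2 = nn.Conv2d(mid_ch, mid_ch, 3, rng, stride=stride, padding=1,
                               bias=False)
        self.bn2 = nn.BatchNorm2d(mid_ch)
        self.conv3 = nn.Conv2d(mid_ch, out_ch, 1, rng, bias=False)
        self.bn3 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.down_conv = nn.Conv2d(in_ch, out_ch, 1, rng, stride=stride,
                                       bias=False)
            self.down_bn = nn.BatchNorm2d(out_ch)
        else:
            self.down_conv = None
            self.down_bn = None
        self.attention = attention

    def forward(self, x, train=False):
        out = self.bn1.forward(self.conv1.forward(x, train), train)
        self._m1 = out > 0
        out = np.where(self._m1, out, 0)
        out = self.bn2.forward(self.conv2.forward(out, train), train)
        self._m2 = out > 0
        out = np.where(self._m2, out, 0)
        out = self.bn3.forward(self.conv3.forward(out, train), train)
        if self.down_conv is not None:
            idt = self.down_bn.forward(self.down_conv.forward(x, train), train)
        else:
            idt = x
        s = out + idt
        if self.attention is not None:
            s = self.attention.forward(s, train)
        self._m3 = s > 0
        return np.where(self._m3, s, 0)

    def backward(self, dout):
        ds = np.where(self._m3, dout, 0)
        if self.attention is not None:
            ds = self.attention.backward(ds)
        d = self.conv3.backward(self.bn3.backward(ds))
        d = np.where(self._m2, d, 0)
        d = self.conv2.backward(self.bn2.backward(d))
        d = np.where(self._m1, d, 0)
        d_main = self.conv1.backward(self.bn1.backward(d))
        if self.down_conv is not None:
            return d_main + self.down_conv.backward(self.down_bn.backward(ds))
        return d_main + ds


class ResNet(nn.Module):
    """Executable ResNet50 (+ optional attention) on N×3×H×W images."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        self.spec = spec
        self.conv1 = nn.Conv2d(3, 64, 7, rng, stride=2, padding=3, bias=False)
        self.bn1 = nn.BatchNorm2d(64)
        self.maxpool = nn.MaxPool2d(3, 2, 1)
        points = {(s, b): c for s, b, c in insertion_points(spec.placement)}
        self.stages: list[list[Bottleneck]] = []
        in_ch = 64
        for stage in (2, 3, 4, 5):
            out_ch = STAGE_WIDTH[stage]
            mid_ch = out_ch // 4
            blocks = []
            for b in range(1, STAGE_BLOCKS[stage] + 1):
                stride = 2 if (stage > 2 and b == 1) else 1
                attn = None
                if spec.attention is not None and (stage, b) in points:
                    cfg = AttentionConfig(spec.attention, out_ch, spec.reduction)
                    attn = make_block(cfg, rng)
                blocks.append(Bottleneck(in_ch, mid_ch, out_ch, stride, rng, attn))
                in_ch = out_ch
            self.stages.append(blocks)
        self.gap = nn.GlobalAvgPool2d()
        self.fc = nn.Linear(2048, spec.head_classes, rng)

    # -- forward / backward ------------------------------------------------
    def forward(self, x, train=False, capture: bool = False):
        x = np.ascontiguousarray(x, dtype=nn.DTYPE)
        out = self.bn1.forward(self.conv1.forward(x, train), train)
        self._m0 = out > 0
        out = np.where(self._m0, out, 0)
        out = self.maxpool.forward(out)
        self._stage_out = {}
        for stage, blocks in zip((2, 3, 4, 5), self.stages):
            for blk in blocks:
                out = blk.forward(out, train)
            if capture:
                self._stage_out[stage] = out
        pooled = self.gap.forward(out)
        return self.fc.forward(pooled)

    def backward(self, dlogits, capture: bool = False):
        self._stage_grads = {}
        d = self.gap.backward(self.fc.backward(dlogits))
        for stage, blocks in zip((5, 4, 3, 2), reversed(self.stages)):
            if capture:
                self._stage_grads[stage] = d
            for blk in reversed(blocks):
                d = blk.backward(d)
        d = self.maxpool.backward(d)
        d = np.where(self._m0, d, 0)
        return self.conv1.backward(self.bn1.backward(d))

    # -- persistence -------------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.value for p in self.parameters()]
        for bn in self._batchnorms():
            arrays.extend([bn.running_mean, bn.running_var])
        return arrays

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        k = len(params)
        for p, a in zip(params, arrays[:k]):
            if p.value.shape != a.shape:
                raise ValueError(f"shape mismatch loading weights: {p.value.shape} vs {a.shape}")
            p.value[...] = a
        rest = arrays[k:]
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean[...] = rest[2 * i]
            bn.running_var[...] = rest[2 * i + 1]

    def save(self, path) -> None:
        arrays = {f"a{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez(path, spec=self.spec.to_json(), **arrays)

    def _batchnorms(self):
        out = [self.bn1]
        for blocks in self.stages:
            for blk in blocks:
                out.extend([blk.bn1, blk.bn2, blk.bn3])
                if blk.down_bn is not None:
                    out.append(blk.down_bn)
        return out

    def attention_blocks(self):
        return [blk.attention for blocks in self.stages for blk in blocks
                if blk.attention is not None]


def build_model(spec: ModelSpec, seed: int = 0,
                weights: list[np.ndarray] | None = None) -> ResNet:
    """Construct a seeded model; optionally load caller-supplied weights.

    Identical ``seed`` values give bitwise-identical initial parameters.
    ``weights`` (e.g. an ImageNet-pretrained state exported elsewhere) must
    match the architecture's parameter sequence exactly.
    """
    model = ResNet(spec, np.random.default_rng(seed))
    if weights is not None:
        model.load_state_arrays(weights)
    return model


def load_model(path) -> ResNet:
    with np.load(path, allow_pickle=False) as z:
        spec = ModelSpec.from_json(str(z["spec"]))
        arrays = [z[f"a{i}"] for i in range(len(z.files) - 1)]
    model = build_model(spec, seed=0)
    model.load_state_arrays(arrays)
    return model


def count_parameters(model: nn.Module) -> int:
    """Exact number of learnable scalars (batch-norm affine pairs included)."""
    return model.num_parameters()


def parameter_report(model: ResNet) -> dict:
    """JSON-ready count breakdown: total, millions (1 decimal), by module."""
    total = count_parameters(model)
    by_module = {
        "stem": self_count([model.conv1, model.bn1]),
        "head": self_count([model.fc]),
    }
    attn_total = 0
    for stage, blocks in zip((2, 3, 4, 5), model.stages):
        stage_attn = self_count([blk.attention for blk in blocks
                                 if blk.attention is not None])
        by_module[f"conv{stage}_x"] = self_count(blocks) - stage_attn
        attn_total += stage_attn
    if attn_total:
        by_module["attention"] = attn_total
    return {"total": total, "millions": round(total / 1e6, 1), "by_module": by_module}


def self_count(mods) -> int:
    return int(sum(m.num_parameters() for m in mods))


def grad_cam(model: ResNet, image: np.ndarray, class_index: int,
             target_stage: int = 5) -> np.ndarray:
    """Gradient-weighted class activation map, resized to the input size.

    The gradient of the chosen class logit is taken with respect to the
    activations of ``target_stage`` (default: the last bottleneck stage);
    channels are weighted by their spatially averaged gradient, summed,
    rectified, and max-normalised to [0, 1].
    """
    if not 0 <= class_index < model.spec.head_classes:
        raise ValueError(f"class index {class_index} out of range "
                         f"[0, {model.spec.head_classes})")
    if target_stage not in (2, 3, 4, 5):
        raise ValueError("target_stage must be one of 2, 3, 4, 5")
    x = np.asarray(image, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    h_in, w_in = x.shape[2], x.shape[3]
    logits = model.forward(x, train=False, capture=True)
    done = np.zeros_like(logits)
    done[:, class_index] = 1.0
    model.zero_grad()
    model.backward(done, capture=True)
    acts = model._stage_out[target_stage][0]
    grads = model._stage_grads[target_stage][0]
    weights = grads.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * acts).sum(axis=0), 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    cam = _resize(cam, (h_in, w_in), order=1, mode="edge", anti_aliasing=False)
    return np.clip(cam, 0.0, 1.0)
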