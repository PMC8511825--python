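"""Architecture construction: the VGG16 FCN family and its dilated variants.

``build_fcn`` emits the classic FCN-32s/16s/8s topologies.  ``convert_to_dfcn``
derives the dilated variants from an FCN-32s spec by the stride-removal /
dilation-compensation rule: walking the backbone from the shallow side, each
pool selected for conversion keeps its 2-element window but drops its stride
to 1; every layer downstream of a converted pool has its kernel elements
spread apart by the running product of removed strides, so that each output
unit still reads exactly the input pixels it would have read before the
conversion.  This keeps the receptive field identical while multiplying the
score-map resolution.

A converted pool that sits downstream of an *earlier* converted pool must
itself carry the running dilation (its 2 window elements are now that many
grid steps apart) — otherwise the output-for-output correspondence with the
undilated network is lost.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from fractions import Fraction

from .windowing import DEFAULT_WINDOW, WindowSpec

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "FCN_VARIANTS",
    "DFCN_VARIANTS",
    "ALL_VARIANTS",
    "build_fcn",
    "convert_to_dfcn",
    "build_variant",
    "output_stride",
    "receptive_field",
]

FCN_VARIANTS = ("fcn32s", "fcn16s", "fcn8s")
DFCN_VARIANTS = ("dfcn16s", "dfcn8s", "dfcn4s")
ALL_VARIANTS = FCN_VARIANTS + DFCN_VARIANTS

#: VGG16 backbone: (convs per block, channels per block)
_VGG_BLOCKS = ((2, 64), (2, 128), (3, 256), (3, 512), (3, 512))
_FC_CHANNELS = 4096
_TARGET_TO_POOLS = {16: ("pool5",), 8: ("pool4", "pool5"), 4: ("pool3", "pool4", "pool5")}
#: decoder staging for the dilated variants' trailing upsample cascade
_TARGET_TO_STAGES = {16: (4, 4), 8: (2, 4), 4: (2, 2)}


@dataclass
class LayerSpec:
    """One layer of a network description.

    ``kind`` is one of ``conv | pool | score | upsample | fuse | window``.
    For ``upsample`` layers ``stride`` is the upsampling factor.  ``source``
    names an earlier layer feeding this one instead of (for ``score``) or in
    addition to (for ``fuse``) the previous layer's output.
    """

    name: str
    kind: str
    kernel: int = 1
    stride: int = 1
    dilation: int = 1
    in_channels: int = 0
    out_channels: int = 0
    padding: str = "same"
    activation: str = "none"
    source: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("conv", "pool", "score", "upsample", "fuse", "window"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.dilation < 1 or self.stride < 1 or self.kernel < 1:
            raise ValueError(f"layer {self.name}: kernel/stride/dilation must be >= 1")

    @property
    def effective_kernel(self) -> int:
        """Kernel extent after dilation: k + (k-1)(d-1)."""
        return self.kernel + (self.kernel - 1) * (self.dilation - 1)

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "LayerSpec":
        return cls(**d)


@dataclass
class ArchitectureSpec:
    variant: str
    layers: list[LayerSpec]
    n_classes: int
    width_multiplier: float = 1.0
    fusion_points: list[tuple[str, int]] = field(default_factory=list)
    window: WindowSpec = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2 (background + at least one structure)")

    def layer(self, name: str) -> LayerSpec:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "n_classes": self.n_classes,
            "width_multiplier": float(self.width_multiplier),
            "fusion_points": [list(fp) for fp in self.fusion_points],
            "window": self.window.to_dict(),
            "layers": [l.to_dict() for l in self.layers],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        return cls(
            variant=d["variant"],
            layers=[LayerSpec.from_dict(l) for l in d["layers"]],
            n_classes=d["n_classes"],
            width_multiplier=d.get("width_multiplier", 1.0),
            fusion_points=[tuple(fp) for fp in d.get("fusion_points", [])],
            window=WindowSpec.from_dict(d["window"]) if "window" in d else DEFAULT_WINDOW,
        )


def _scaled(channels: int, multiplier) -> int:
    c = int(round(Fraction(channels) * Fraction(multiplier)))
    return max(c, 1)


def build_fcn(
    variant: str,
    n_classes: int = 7,
    width_multiplier=1.0,
    window: WindowSpec = DEFAULT_WINDOW,
) -> ArchitectureSpec:
    """Construct an FCN-32s/16s/8s architecture over a VGG16-style backbone.

    Five conv blocks (2,2,3,3,3 convs of 3x3; 64/128/256/512/512 channels
    scaled by ``width_multiplier``) each followed by a stride-2 pool, then the
    convolutionalised classifier (7x7 fc6, 1x1 fc7) and a 1x1 score layer.
    The 16s/8s variants add pool4/pool3 score fusion with intermediate 2x
    upsampling before the final restoration to input resolution.
    """
    if variant not in FCN_VARIANTS:
        raise ValueError(f"unknown FCN variant {variant!r}; expected one of {FCN_VARIANTS}")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if not Fraction(width_multiplier) > 0:
        raise ValueError("width_multiplier must be positive")

    m = width_multiplier
    layers: list[LayerSpec] = [
        LayerSpec("window", "window", in_channels=1, out_channels=window.n_channels)
    ]
    in_ch = window.n_channels
    for b, (n_convs, ch) in enumerate(_VGG_BLOCKS, start=1):
        out_ch = _scaled(ch, m)
        for c in range(1, n_convs + 1):
            layers.append(
                LayerSpec(
                    f"conv{b}_{c}", "conv", kernel=3,
                    in_channels=in_ch, out_channels=out_ch, activation="relu",
                )
            )
            in_ch = out_ch
        layers.append(LayerSpec(f"pool{b}", "pool", kernel=2, stride=2,
                                in_channels=in_ch, out_channels=in_ch))

    fc_ch = _scaled(_FC_CHANNELS, m)
    layers.append(LayerSpec("fc6", "conv", kernel=7, in_channels=in_ch,
                            out_channels=fc_ch, activation="relu"))
    layers.append(LayerSpec("fc7", "conv", kernel=1, in_channels=fc_ch,
                            out_channels=fc_ch, activation="relu"))
    layers.append(LayerSpec("score_fr", "score", kernel=1, in_channels=fc_ch,
                            out_channels=n_classes))

    fusion_points: list[tuple[str, int]] = []
    if variant == "fcn32s":
        layers.append(LayerSpec("upscore32", "upsample", kernel=64, stride=32,
                                in_channels=n_classes, out_channels=n_classes))
    else:
        pool4_ch = _scaled(_VGG_BLOCKS[3][1], m)
        layers.append(LayerSpec("upscore2", "upsample", kernel=4, stride=2,
                                in_channels=n_classes, out_channels=n_classes))
        layers.append(LayerSpec("score_pool4", "score", kernel=1, in_channels=pool4_ch,
                                out_channels=n_classes, source="pool4"))
        layers.append(LayerSpec("fuse_pool4", "fuse", in_channels=n_classes,
                                out_channels=n_classes, source="upscore2"))
        fusion_points.append(("pool4", 16))
        if variant == "fcn16s":
            layers.append(LayerSpec("upscore16", "upsample", kernel=32, stride=16,
                                    in_channels=n_classes, out_channels=n_classes))
        else:  # fcn8s
            pool3_ch = _scaled(_VGG_BLOCKS[2][1], m)
            layers.append(LayerSpec("upscore_pool4", "upsample", kernel=4, stride=2,
                                    in_channels=n_classes, out_channels=n_classes))
            layers.append(LayerSpec("score_pool3", "score", kernel=1, in_channels=pool3_ch,
                                    out_channels=n_classes, source="pool3"))
            layers.append(LayerSpec("fuse_pool3", "fuse", in_channels=n_classes,
                                    out_channels=n_classes, source="upscore_pool4"))
            fusion_points.append(("pool3", 8))
            layers.append(LayerSpec("upscore8", "upsample", kernel=16, stride=8,
                                    in_channels=n_classes, out_channels=n_classes))

    return ArchitectureSpec(
        variant=variant, layers=layers, n_classes=n_classes,
        width_multiplier=float(Fraction(width_multiplier)),
        fusion_points=fusion_points, window=window,
    )


def convert_to_dfcn(arch: ArchitectureSpec, target_stride: int) -> ArchitectureSpec:
    """Derive a dilated variant from an FCN-32s spec.

    Pools are converted (stride 2 -> 1) from ``pool5`` backwards until the
    backbone stride equals ``target_stride``; after each converted pool the
    running dilation factor doubles and multiplies the dilation of every
    subsequent conv/score/pool layer.  The single 32x upsampling is replaced
    by a cascade of learnable bilinear-initialised stages whose factors
    multiply to ``target_stride``; no pool-score fusion is used.
    """
    if arch.variant != "fcn32s":
        raise ValueError(f"conversion starts from an fcn32s spec, got {arch.variant!r}")
    if target_stride not in _TARGET_TO_POOLS:
        raise ValueError(f"target_stride must be one of {sorted(_TARGET_TO_POOLS)}, "
                         f"got {target_stride}")

    to_convert = set(_TARGET_TO_POOLS[target_stride])
    layers: list[LayerSpec] = []
    rate = 1  # product of removed strides upstream of the current layer
    for l in arch.layers:
        l = copy.deepcopy(l)
        if l.kind == "pool" and l.name in to_convert:
            # the pool window itself lives on the already-dilated grid
            l = replace(l, stride=1, dilation=l.dilation * rate)
            layers.append(l)
            rate *= 2
            continue
        if l.kind in ("conv", "score", "pool") and rate > 1:
            l = replace(l, dilation=l.dilation * rate)
        if l.kind == "upsample":
            continue  # the 32x upscore is replaced by the cascade below
        layers.append(l)

    n = arch.n_classes
    for i, f in enumerate(_TARGET_TO_STAGES[target_stride], start=1):
        layers.append(LayerSpec(f"upscore_stage{i}", "upsample", kernel=2 * f, stride=f,
                                in_channels=n, out_channels=n))

    return ArchitectureSpec(
        variant=f"dfcn{target_stride}s", layers=layers, n_classes=n,
        width_multiplier=arch.width_multiplier, fusion_points=[], window=arch.window,
    )


def build_variant(variant: str, n_classes: int = 7, width_multiplier=1.0,
                  window: WindowSpec = DEFAULT_WINDOW) -> ArchitectureSpec:
    """Build any of the six named variants."""
    if variant in FCN_VARIANTS:
        return build_fcn(variant, n_classes, width_multiplier, window)
    if variant in DFCN_VARIANTS:
        base = build_fcn("fcn32s", n_classes, width_multiplier, window)
        return convert_to_dfcn(base, int(variant[4:-1]))
    raise ValueError(f"unknown variant {variant!r}; expected one of {ALL_VARIANTS}")


def _trailing_upsample_start(arch: ArchitectureSpec) -> int:
    """Index of the first layer of the trailing (final) upsample cascade."""
    i = len(arch.layers)
    while i > 0 and arch.layers[i - 1].kind == "upsample":
        i -= 1
    return i


def output_stride(arch: ArchitectureSpec) -> int:
    """Input-to-score-map resolution ratio before the final upsampling.

    Product of backbone strides divided by any intermediate (skip-fusion)
    upsampling factors; the trailing upsample cascade that restores input
    resolution is excluded.
    """
    end = _trailing_upsample_start(arch)
    s = Fraction(1)
    for l in arch.layers[:end]:
        if l.kind == "upsample":
            s /= l.stride
        else:
            s *= l.stride
    if s.denominator != 1:
        raise ValueError(f"non-integer output stride {s} for {arch.variant}")
    return int(s)


def receptive_field(arch: ArchitectureSpec) -> int:
    """Input extent seen by one score-map unit (before final upsampling).

    Standard recurrence along the main path: rf += (effective_kernel - 1) *
    jump; jump *= stride.  Branch layers (those with a ``source``) contribute
    via shallower paths only and are skipped; fuse layers are pointwise.
    """
    rf, jump = 1, Fraction(1)
    end = _trailing_upsample_start(arch)
    for l in arch.layers[:end]:
        if l.source is not None and l.kind == "score":
            continue
        if l.kind == "upsample":
            jump /= l.stride
            rf += (l.effective_kernel - 1) * jump
            continue
        rf += (l.effective_kernel - 1) * jump
        jump *= l.stride
    return int(rf)
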