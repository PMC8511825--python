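"""Hounsfield-unit window adjustment.

A raw CT slice stores calibrated attenuation values (HU).  The network
consumes a multi-channel stack in which each channel is the same slice viewed
through its own display window: an HU range ``[lo, hi]`` is split into
``n_channels`` equal sub-ranges, and channel *i* linearly maps sub-range *i*
onto [0, 1], saturating outside it.  Each (level, width) pair follows the
radiological convention: *level* is the centre of the sub-range, *width* its
span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WindowSpec",
    "DEFAULT_WINDOW",
    "partition_window",
    "apply_window",
    "window_transform",
]


@dataclass(frozen=True)
class WindowSpec:
    """An HU range and its equal partition into per-channel sub-windows."""

    lo: float = -300.0
    hi: float = 600.0
    n_channels: int = 3

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"window requires lo < hi, got [{self.lo}, {self.hi}]")
        if int(self.n_channels) != self.n_channels or self.n_channels < 1:
            raise ValueError(f"n_channels must be a positive integer, got {self.n_channels}")

    @property
    def sub_width(self) -> float:
        return (self.hi - self.lo) / self.n_channels

    def to_dict(self) -> dict:
        return {"lo": self.lo, "hi": self.hi, "channels": self.n_channels}

    @classmethod
    def from_dict(cls, d: dict) -> "WindowSpec":
        return cls(lo=d["lo"], hi=d["hi"], n_channels=d.get("channels", d.get("n_channels", 3)))


DEFAULT_WINDOW = WindowSpec(-300.0, 600.0, 3)


def partition_window(spec: WindowSpec) -> list[tuple[float, float]]:
    """Split ``[spec.lo, spec.hi]`` into equal sub-windows.

    Returns ``n_channels`` pairs ``(level, width)`` ordered by ascending
    level; the sub-ranges tile the full range exactly.
    """
    if not isinstance(spec, WindowSpec):
        spec = WindowSpec(*spec)
    w = spec.sub_width
    return [(spec.lo + (i + 0.5) * w, w) for i in range(spec.n_channels)]


def apply_window(hu, level: float, width: float, out_gain: float = 1.0) -> np.ndarray:
    """Map HU values through one (level, width) display window onto [0, gain].

    ``out = clip((hu - (level - width/2)) / width, 0, 1) * out_gain`` —
    monotone non-decreasing in HU, saturating outside the window.
    """
    if width <= 0:
        raise ValueError(f"window width must be positive, got {width}")
    hu = np.asarray(hu, dtype=np.float32)
    lo = level - width / 2.0
    # 0-d inputs produce numpy scalars; re-wrap so in-place ops are legal
    out = np.asarray((hu - np.float32(lo)) / np.float32(width))
    np.clip(out, 0.0, 1.0, out=out)
    if out_gain != 1.0:
        out *= np.float32(out_gain)
    return out


def window_transform(hu, spec: WindowSpec = DEFAULT_WINDOW, out_gain: float = 1.0) -> np.ndarray:
    """Expand a single-channel HU raster into the per-channel-windowed stack.

    Channel ``i`` of the result is ``apply_window`` under the *i*-th pair from
    :func:`partition_window`; output shape is ``(n_channels, *hu.shape)``.
    """
    hu = np.asarray(hu, dtype=np.float32)
    parts = partition_window(spec)
    out = np.empty((len(parts),) + hu.shape, dtype=np.float32)
    for i, (level, width) in enumerate(parts):
        out[i] = apply_window(hu, level, width, out_gain=out_gain)
    return out
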