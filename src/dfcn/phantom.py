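"""Synthetic thoracic CT phantom.

Generates (HU slice, label mask) pairs with the geometry and intensity
structure a chest-CT segmenter has to cope with: an elliptical soft-tissue
body in air, two low-HU lungs, a heart between them, a small air-filled
trachea (branching into bronchi in the lower slices), a small esophagus
behind it, and a spinal cord sitting inside a high-HU vertebral ring.  HU
values are per-structure Gaussian draws plus global noise.  The small tubular
structures are kept under 2% of the body area so the small-organ difficulty
regime is preserved, and the default HU table deliberately straddles the
[-300, 600] window: lungs and tracheal air fall below it, vertebral bone
above it.

Rasterisation priority (highest wins): spine > trachea > esophagus > heart >
lungs > body.  Everything is deterministic given (config, seed); per-case
seeds for a dataset are spawned from a master seed via ``SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CLASS_NAMES",
    "PhantomConfig",
    "PhantomCase",
    "generate_phantom_case",
    "generate_cases",
    "generate_dataset",
]

#: class id -> structure name (0 is background: air, body tissue, bone)
CLASS_NAMES = {
    0: "background",
    1: "lung_left",
    2: "lung_right",
    3: "heart",
    4: "trachea",
    5: "esophagus",
    6: "spinal_cord",
}

#: structure -> (HU mean, HU stdev); vertebra/body/air are background-labelled
DEFAULT_HU = {
    "air": (-1000.0, 20.0),
    "body": (40.0, 15.0),
    "lung": (-700.0, 60.0),
    "heart": (45.0, 15.0),
    "trachea": (-950.0, 30.0),
    "esophagus": (40.0, 15.0),
    "vertebra": (400.0, 100.0),
    "cord": (35.0, 10.0),
}


@dataclass(frozen=True)
class PhantomConfig:
    image_size: tuple[int, int] = (96, 96)
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    slice_thickness: float = 3.0
    slices_per_case: tuple[int, int] = (4, 6)
    hu: dict = field(default_factory=lambda: dict(DEFAULT_HU))
    noise_sigma: float = 10.0
    #: centre jitter as a fraction of image size, per case
    jitter: float = 0.02
    max_retries: int = 10

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 32 or w < 32:
            raise ValueError("image_size must be at least 32x32")
        lo, hi = self.slices_per_case
        if not (1 <= lo <= hi):
            raise ValueError("slices_per_case must be a nonempty integer range")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    @property
    def foreground_classes(self) -> list[int]:
        return [1, 2, 3, 4, 5, 6]

    #: HU-table key used to fill each foreground class
    CLASS_HU_KEY = {1: "lung", 2: "lung", 3: "heart", 4: "trachea",
                    5: "esophagus", 6: "cord"}


@dataclass
class PhantomCase:
    case_id: str
    images: np.ndarray  # (S, H, W) int16 HU
    masks: np.ndarray   # (S, H, W) uint8 labels
    config: PhantomConfig
    seed: int

    @property
    def n_slices(self) -> int:
        return self.images.shape[0]


def _ellipse(h, w, cy, cx, ay, ax, theta=0.0) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    y = yy - cy
    x = xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * y + st * x
    v = -st * y + ct * x
    return (u / ay) ** 2 + (v / ax) ** 2 <= 1.0


def _case_geometry(rng: np.random.Generator, cfg: PhantomConfig):
    """Per-case jittered base geometry in relative (fraction-of-size) units."""
    j = cfg.jitter

    def jit(v, scale=1.0):
        return v + rng.uniform(-j, j) * scale

    geo = {
        "body": (jit(0.50), jit(0.50), jit(0.40, 0.5), jit(0.46, 0.5), rng.uniform(-0.06, 0.06)),
        "lung_l": (jit(0.44), jit(0.30), jit(0.24, 0.5), jit(0.15, 0.5), rng.uniform(-0.15, 0.15)),
        "lung_r": (jit(0.44), jit(0.70), jit(0.24, 0.5), jit(0.15, 0.5), rng.uniform(-0.15, 0.15)),
        "heart": (jit(0.58), jit(0.46), jit(0.13, 0.5), jit(0.15, 0.5), rng.uniform(-0.2, 0.2)),
        "trachea": (jit(0.30), jit(0.50), 0.030, 0.030, 0.0),
        "esophagus": (jit(0.46), jit(0.54), 0.025, 0.025, 0.0),
        "spine": (jit(0.78), jit(0.50), 0.085, 0.085, 0.0),
    }
    # smooth per-slice drift: amplitude (px-fraction) and phase per organ
    drift = {k: (rng.uniform(0.0, 0.01), rng.uniform(0, 2 * np.pi)) for k in geo}
    return geo, drift


def _rasterize_slice(rng, cfg, geo, drift, s, n_slices):
    h, w = cfg.image_size
    t = s / max(n_slices - 1, 1)

    def at(name):
        cy, cx, ay, ax, th = geo[name]
        amp, phase = drift[name]
        off = amp * np.sin(2 * np.pi * t + phase)
        return (cy + off) * h, (cx + off) * w, ay * h, ax * w, th

    mask = np.zeros((h, w), dtype=np.uint8)
    regions: list[tuple[np.ndarray, int, str]] = []

    body = _ellipse(h, w, *at("body"))
    regions.append((body, 0, "body"))

    lung_scale = 1.0 - 0.15 * abs(2 * t - 1)  # lungs taper toward case ends
    for name, cid in (("lung_l", 1), ("lung_r", 2)):
        cy, cx, ay, ax, th = at(name)
        regions.append((_ellipse(h, w, cy, cx, ay * lung_scale, ax * lung_scale, th),
                        cid, name))
    regions.append((_ellipse(h, w, *at("heart")), 3, "heart"))
    regions.append((_ellipse(h, w, *at("esophagus")), 5, "esophagus"))

    if t < 0.5:  # trachea: single lumen superiorly, two bronchi inferiorly
        regions.append((_ellipse(h, w, *at("trachea")), 4, "trachea"))
    else:
        cy, cx, ay, ax, _ = at("trachea")
        r = 0.75
        regions.append((_ellipse(h, w, cy + 0.06 * h, cx - 0.055 * w, ay * r, ax * r), 4,
                        "bronchus_l"))
        regions.append((_ellipse(h, w, cy + 0.06 * h, cx + 0.055 * w, ay * r, ax * r), 4,
                        "bronchus_r"))

    cy, cx, ay, ax, _ = at("spine")
    vertebra = _ellipse(h, w, cy, cx, ay, ax)
    cord = _ellipse(h, w, cy, cx, 0.045 * h, 0.045 * w)
    regions.append((vertebra, 0, "vertebra"))
    regions.append((cord, 6, "cord"))

    # containment: every structure must sit inside the body ellipse
    for reg, cid, name in regions[1:]:
        if np.any(reg & ~body):
            raise _GeometryError(f"structure {name!r} extends outside the body ellipse")

    hu = rng.normal(*cfg.hu["air"], size=(h, w))
    # paint in ascending priority so later structures overwrite earlier ones
    paint = [(body, 0, "body")]
    paint += [r for r in regions if r[2] in ("lung_l", "lung_r")]
    paint += [r for r in regions if r[2] == "heart"]
    paint += [r for r in regions if r[2] == "esophagus"]
    paint += [r for r in regions if r[2].startswith(("trachea", "bronchus"))]
    paint += [r for r in regions if r[2] in ("vertebra", "cord")]

    hu_key = {"body": "body", "lung_l": "lung", "lung_r": "lung", "heart": "heart",
              "esophagus": "esophagus", "trachea": "trachea", "bronchus_l": "trachea",
              "bronchus_r": "trachea", "vertebra": "vertebra", "cord": "cord"}
    for reg, cid, name in paint:
        mean, std = cfg.hu[hu_key[name]]
        vals = rng.normal(mean, std, size=int(reg.sum()))
        hu[reg] = vals
        mask[reg] = cid
    if cfg.noise_sigma > 0:
        hu += rng.normal(0.0, cfg.noise_sigma, size=hu.shape)
    hu = np.clip(np.rint(hu), -1024, 3071).astype(np.int16)
    return hu, mask


class _GeometryError(RuntimeError):
    pass


class PhantomGeometryError(RuntimeError):
    """Raised when no admissible geometry is found within the retry budget."""


def generate_phantom_case(cfg: PhantomConfig, case_seed: int,
                          case_id: str | None = None) -> PhantomCase:
    """One deterministic synthetic case: (S, H, W) HU volume + label masks."""
    rng = np.random.default_rng(case_seed)
    last_err: Exception | None = None
    for _ in range(cfg.max_retries):
        n_slices = int(rng.integers(cfg.slices_per_case[0], cfg.slices_per_case[1] + 1))
        geo, drift = _case_geometry(rng, cfg)
        try:
            slices = [_rasterize_slice(rng, cfg, geo, drift, s, n_slices)
                      for s in range(n_slices)]
        except _GeometryError as e:
            last_err = e
            continue
        images = np.stack([s[0] for s in slices])
        masks = np.stack([s[1] for s in slices])
        present = set(np.unique(masks))
        missing = [c for c in cfg.foreground_classes if c not in present]
        if missing:
            last_err = _GeometryError(f"classes {missing} absent from case")
            continue
        return PhantomCase(case_id=case_id or f"case_{case_seed}", images=images,
                           masks=masks, config=cfg, seed=case_seed)
    raise PhantomGeometryError(
        f"no admissible geometry within {cfg.max_retries} retries: {last_err}")


def _case_seeds(master_seed: int, n_cases: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0]) for child in ss.spawn(n_cases)]


def generate_cases(cfg: PhantomConfig, n_cases: int, master_seed: int) -> list[PhantomCase]:
    """In-memory dataset: per-case seeds spawned from ``master_seed``."""
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    seeds = _case_seeds(master_seed, n_cases)
    return [generate_phantom_case(cfg, s, case_id=f"case_{i:03d}")
            for i, s in enumerate(seeds)]


def generate_dataset(cfg: PhantomConfig, n_cases: int, master_seed: int, out_dir):
    """Generate and write a dataset; returns the manifest DataFrame.

    Writes one NIfTI volume and mask per case plus ``manifest.csv``
    (case_id, image, mask, n_slices, seed).  Re-running with the same
    arguments reproduces the files byte for byte.
    """
    import pandas as pd

    from .io_utils import write_mask, write_volume

    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in generate_cases(cfg, n_cases, master_seed):
        spacing = (cfg.slice_thickness,) + tuple(cfg.pixel_spacing)
        img_path = out / f"{case.case_id}_image.nii"
        mask_path = out / f"{case.case_id}_mask.nii"
        write_volume(img_path, case.images, spacing)
        write_mask(mask_path, case.masks, spacing)
        rows.append({"case_id": case.case_id, "image": img_path.name,
                     "mask": mask_path.name, "n_slices": case.n_slices,
                     "seed": case.seed})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
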