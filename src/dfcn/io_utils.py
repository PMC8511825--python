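"""Readers, writers, and contour extraction.

Volumes and masks travel as NIfTI (uncompressed ``.nii`` by default so that
repeated writes are byte-identical) with the array laid out (slice, row, col)
and spacing carried in the affine; per-slice 8-bit PNG stacks are supported
for masks.  Contours are closed polygons traced at the 0.5 iso-level of a
class indicator, outer boundaries counter-clockwise and holes clockwise in
(row, col) coordinates.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = [
    "save_checkpoint",
    "load_checkpoint",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "load_manifest",
    "extract_contours",
    "extract_contour_set",
    "rasterize_contours",
    "contours_to_json",
]


def _affine(spacing) -> np.ndarray:
    # array axes are (slice, row, col); zooms follow the same order
    a = np.diag(list(spacing) + [1.0]).astype(np.float64)
    return a


def write_volume(path, data: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> None:
    """Write a (S, H, W) HU volume as NIfTI; int16 preserves HU exactly."""
    import nibabel as nib

    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"expected a (S, H, W) volume, got shape {data.shape}")
    img = nib.Nifti1Image(np.asarray(data, dtype=np.int16 if
                                     np.issubdtype(data.dtype, np.integer) else np.float32),
                          _affine(spacing))
    img.header.set_zooms(tuple(float(s) for s in spacing))
    nib.save(img, str(path))


def read_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume -> ((S, H, W) float32 array, spacing)."""
    import nibabel as nib

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as e:  # corrupt file
        raise IOError(f"cannot read volume {path}: {e}") from e
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data.astype(np.float32), spacing


def write_mask(path, mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> None:
    """Write an integer label mask: NIfTI (.nii) or a per-slice PNG stack
    (path with ``{s}`` placeholder or a directory)."""
    mask = np.asarray(mask)
    if mask.ndim == 2:
        mask = mask[None]
    if mask.min() < 0 or mask.max() > 255:
        raise ValueError("mask labels must fit in uint8")
    path = Path(path)
    if path.suffix in (".png", "") or path.is_dir() or "{s}" in path.name:
        import imageio.v3 as iio

        if path.is_dir() or path.suffix == "":
            path.mkdir(parents=True, exist_ok=True)
            tpl = path / "slice_{s:03d}.png"
        else:
            tpl = path
        for s in range(mask.shape[0]):
            name = str(tpl).format(s=s)
            iio.imwrite(name, mask[s].astype(np.uint8))
        return
    import nibabel as nib

    img = nib.Nifti1Image(mask.astype(np.uint8), _affine(spacing))
    img.header.set_zooms(tuple(float(s) for s in spacing))
    nib.save(img, str(path))


def read_mask(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a label mask (NIfTI or PNG-stack directory) -> ((S, H, W) int32,
    spacing)."""
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(path.glob("*.png"))
        if not files:
            raise FileNotFoundError(f"no PNG slices in {path}")
        mask = np.stack([iio.imread(f) for f in files])
        return mask.astype(np.int32), (1.0, 1.0, 1.0)
    data, spacing = read_volume(path)
    mask = np.rint(data).astype(np.int32)
    return mask, spacing


def load_manifest(path, root=None, check_paths: bool = True):
    """Load a dataset manifest CSV; validates unique case ids and that the
    referenced files exist."""
    import pandas as pd

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    for col in ("case_id", "image", "mask"):
        if col not in df.columns:
            raise ValueError(f"manifest is missing required column {col!r}")
    if df["case_id"].duplicated().any():
        dupes = df.loc[df["case_id"].duplicated(), "case_id"].tolist()
        raise ValueError(f"duplicate case ids in manifest: {dupes}")
    root = Path(root) if root is not None else path.parent
    if check_paths:
        for _, row in df.iterrows():
            for col in ("image", "mask"):
                p = root / row[col]
                if not p.exists():
                    raise FileNotFoundError(f"manifest row {row['case_id']}: "
                                            f"missing file {p}")
    return df


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, record, meta: dict | None = None) -> None:
    """Write a checkpoint (.npz) embedding the architecture spec, iteration,
    validation Dice, and provenance metadata alongside the parameters."""
    header = {
        "arch": record.arch.to_dict(),
        "iteration": record.iteration,
        "validation_global_dice": record.validation_global_dice,
        "meta": meta or {},
    }
    arrays = {f"param/{k}": v for k, v in record.params.items()}
    np.savez(str(path), __header__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path):
    """Read a checkpoint written by :func:`save_checkpoint` -> (record, meta)."""
    from .arch import ArchitectureSpec
    from .train_eval import CheckpointRecord

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    with np.load(str(path)) as z:
        header = json.loads(bytes(z["__header__"]).decode())
        params = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    record = CheckpointRecord(
        iteration=int(header["iteration"]),
        params=params,
        arch=ArchitectureSpec.from_dict(header["arch"]),
        validation_global_dice=header.get("validation_global_dice"),
    )
    return record, header.get("meta", {})


# ---------------------------------------------------------------------------
# contours
# ---------------------------------------------------------------------------

def _signed_area(poly: np.ndarray) -> float:
    y, x = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.dot(y, np.roll(x, -1)) - np.dot(x, np.roll(y, -1)))


def _nesting_depth(poly: np.ndarray, others: list[np.ndarray]) -> int:
    from matplotlib.path import Path as MplPath

    pt = poly[0]
    return sum(1 for o in others
               if o is not poly and MplPath(o).contains_point(pt))


def extract_contours(mask, class_id: int, spacing=None) -> list[np.ndarray]:
    """Closed boundary polygons of one class region on a 2-D mask.

    Iso-contours at the 0.5 level of the class indicator; each polygon is an
    (V, 2) array of (row, col) vertices with first == last.  Outer boundaries
    are counter-clockwise, holes clockwise.  ``spacing`` (row_mm, col_mm)
    scales vertices to millimetres.
    """
    from skimage import measure

    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("extract_contours expects a single 2-D slice")
    ind = (mask == class_id).astype(np.float32)
    if not ind.any():
        return []
    # pad so regions touching the border still close
    ind = np.pad(ind, 1)
    raw = measure.find_contours(ind, 0.5)
    polys = [c - 1.0 for c in raw]
    out = []
    for p in polys:
        if not np.allclose(p[0], p[-1]):
            p = np.vstack([p, p[:1]])
        depth = _nesting_depth(p, polys)
        is_hole = depth % 2 == 1
        ccw = _signed_area(p) > 0
        if is_hole == ccw:  # outer must be ccw, hole cw
            p = p[::-1]
        if spacing is not None:
            p = p * np.asarray(spacing, dtype=float)
        out.append(p)
    return out


def extract_contour_set(mask, class_ids, spacing=None) -> dict:
    """Per-slice, per-class contour polygons for a (S, H, W) mask stack."""
    mask = np.asarray(mask)
    if mask.ndim == 2:
        mask = mask[None]
    return {
        s: {int(c): extract_contours(mask[s], c, spacing=spacing)
            for c in class_ids}
        for s in range(mask.shape[0])
    }


def rasterize_contours(polys: list[np.ndarray], shape) -> np.ndarray:
    """Fill polygons back into a binary mask (even-odd rule, so holes carved
    by nested polygons are respected)."""
    from skimage.draw import polygon2mask

    out = np.zeros(shape, dtype=bool)
    for p in polys:
        out ^= polygon2mask(shape, p)
    return out


def contours_to_json(contour_set: dict, path=None, meta: dict | None = None):
    """Serialise a contour set (vertex lists) to JSON."""
    doc = {"meta": meta or {}, "slices": {
        str(s): {str(c): [p.tolist() for p in per_class]
                 for c, per_class in classes.items()}
        for s, classes in contour_set.items()}}
    if path is not None:
        Path(path).write_text(json.dumps(doc))
    return doc
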