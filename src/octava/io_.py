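"""File I/O: grayscale images in, masks/tables/ground-truth JSON out."""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .segmentation import AngiogramImage, BinaryVesselMask
from .synth.tree import GroundTruth

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "write_table",
    "write_ground_truth",
]


def read_image(path: str | Path, fov_mm: float = 3.0) -> AngiogramImage:
    """Read a grayscale TIFF/PNG and normalize to [0, 1].

    Color inputs are converted to luminance with a warning; non-square
    images are rejected.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        warnings.warn(f"{path.name}: color image converted to grayscale")
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"{path.name}: expected a square grayscale image, got shape {arr.shape}")
    peak = {np.dtype(np.uint8): 255.0, np.dtype(np.uint16): 65535.0}.get(arr.dtype)
    arr = arr.astype(float)
    if peak is not None:
        arr = arr / peak
    elif arr.max() > 1.0:
        arr = arr / arr.max()
    return AngiogramImage(pixels=np.clip(arr, 0.0, 1.0), fov_mm=fov_mm)


def write_image(path: str | Path, pixels: np.ndarray, bit_depth: int = 8) -> None:
    """Write a [0, 1] grayscale array as 8-bit PNG or 8/16-bit TIFF."""
    path = Path(path)
    pixels = np.clip(np.asarray(pixels, dtype=float), 0.0, 1.0)
    if bit_depth == 16:
        data = (pixels * 65535).round().astype(np.uint16)
        if path.suffix.lower() not in (".tif", ".tiff"):
            raise ValueError("16-bit output requires a TIFF path")
        tifffile.imwrite(path, data)
        return
    data = (pixels * 255).round().astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        Image.fromarray(data).save(path)


def write_mask(path: str | Path, mask: BinaryVesselMask) -> None:
    """Binary mask as a 0/255 PNG plus a JSON sidecar with the
    segmentation log (threshold, scales, cleaning parameters)."""
    path = Path(path)
    Image.fromarray((mask.mask.astype(np.uint8)) * 255).save(path)
    sidecar = {
        "scale_um_per_px": mask.scale_um_per_px,
        "threshold": mask.threshold,
        "log": mask.log,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_mask(path: str | Path, scale_um_per_px: float | None = None) -> BinaryVesselMask:
    """Read a 0/255 PNG mask; scale comes from the JSON sidecar when present."""
    path = Path(path)
    arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    threshold = None
    log: dict = {}
    sidecar = path.with_suffix(".json")
    if scale_um_per_px is None:
        if not sidecar.exists():
            raise ValueError(f"{path.name}: no scale given and no sidecar JSON found")
        meta = json.loads(sidecar.read_text())
        scale_um_per_px = meta["scale_um_per_px"]
        threshold = meta.get("threshold")
        log = meta.get("log", {})
    return BinaryVesselMask(mask=arr > 127, scale_um_per_px=scale_um_per_px, threshold=threshold, log=log)


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def write_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    d = dataclasses.asdict(truth)
    d.pop("_levels", None)
    d.pop("_max_level", None)
    Path(path).write_text(json.dumps(d, indent=2, default=float))
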