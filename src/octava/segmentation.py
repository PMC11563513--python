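"""Vessel enhancement and binarization for en-face OCT-A images.

The enhancement step is a 2-D optimally-oriented-flux (OOF) filter: for
each pixel and each scale r, the outward flux of the (Gaussian-smoothed)
image gradient through a circle of radius r is assembled into a symmetric
2×2 matrix whose eigenvalues describe the local curvilinear contrast.
Bright vessels on a dark background yield strongly negative eigenvalues
across the vessel axis; vesselness is the scale-maximal negated smaller
eigenvalue, clipped at zero.  The response is then thresholded (Otsu by
default) into a binary vessel mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_holes, remove_small_objects

__all__ = [
    "AngiogramImage",
    "VesselnessResponse",
    "BinaryVesselMask",
    "oof_filter",
    "binarize",
    "clean_mask",
]


@dataclass
class AngiogramImage:
    """Grayscale en-face angiogram with its physical scale.

    ``scale_um_per_px`` is derived from the field of view: a 3 mm scan at
    512 px is 5.86 µm/px.
    """

    pixels: np.ndarray
    fov_mm: float = 3.0
    quality_index: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("angiogram must be a square 2-D grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("angiogram contains non-finite values")
        if self.fov_mm <= 0:
            raise ValueError("fov_mm must be > 0")

    @property
    def scale_um_per_px(self) -> float:
        return self.fov_mm * 1000.0 / self.pixels.shape[1]


@dataclass
class VesselnessResponse:
    response: np.ndarray            # scale-maximal vesselness per pixel
    best_scale_um: np.ndarray       # radius (µm) of the best-responding scale
    scales_px: tuple[float, ...]
    scale_um_per_px: float
    # blend of the input image with the normalized vesselness: the raw
    # flux response is smeared over the filter scale, so thresholding it
    # alone localizes vessel boundaries poorly; the blend keeps the
    # image's sharp edges while the vesselness bridges speckle dropout
    enhanced: np.ndarray | None = None


@dataclass
class BinaryVesselMask:
    mask: np.ndarray
    scale_um_per_px: float
    threshold: float | None = None
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


def _circle_kernels(radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit-normal-weighted annulus kernels (K_y, K_x) for the flux integral.

    Offsets h with |h| within half a pixel of ``radius`` approximate the
    circle; weights are the outward normal components h/|h|, normalized by
    the sample count so the matrix is an average flux density.
    """
    reach = int(np.ceil(radius + 0.5))
    dy, dx = np.mgrid[-reach : reach + 1, -reach : reach + 1].astype(float)
    rho = np.hypot(dy, dx)
    on = (rho >= radius - 0.5) & (rho < radius + 0.5) & (rho > 0)
    n = on.sum()
    ky = np.where(on, dy / np.maximum(rho, 1e-12), 0.0) / n
    kx = np.where(on, dx / np.maximum(rho, 1e-12), 0.0) / n
    return ky, kx


def _correlate(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return fftconvolve(img, kernel[::-1, ::-1], mode="same")


def oof_filter(
    image: AngiogramImage,
    radii_px: tuple[float, ...] = (1.5, 2, 3, 4, 5, 6, 8, 10),
    presmooth_sigma_px: float = 1.0,
    image_blend_weight: float = 0.5,
) -> VesselnessResponse:
    """Scale-maximal oriented-flux vesselness.

    Boundary handling: the image is reflect-padded beyond the largest flux
    circle so macula-centered scans get no edge artifacts.  A constant
    image has zero gradient field and returns an identically-zero response.
    """
    radii = tuple(float(r) for r in radii_px)
    if not radii or any(r < 1 for r in radii):
        raise ValueError("radii_px must be non-empty with every radius >= 1")
    if list(radii) != sorted(radii):
        raise ValueError("radii_px must be ascending")

    pad = int(np.ceil(max(radii) + 0.5)) + int(np.ceil(3 * presmooth_sigma_px)) + 2
    img = np.pad(image.pixels, pad, mode="reflect")
    if presmooth_sigma_px > 0:
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(img, presmooth_sigma_px, mode="nearest")
    gy, gx = np.gradient(img)

    best = np.full(image.pixels.shape, -np.inf)
    best_scale = np.zeros(image.pixels.shape)
    sl = slice(pad, -pad)
    for r in radii:
        ky, kx = _circle_kernels(r)
        q_yy = _correlate(gy, ky)
        q_xx = _correlate(gx, kx)
        q_xy = 0.5 * (_correlate(gy, kx) + _correlate(gx, ky))
        mean = 0.5 * (q_yy + q_xx)
        root = np.sqrt((0.5 * (q_yy - q_xx)) ** 2 + q_xy**2)
        lam_small = (mean - root)[sl, sl]
        v = np.clip(-lam_small, 0.0, None)
        better = v > best
        best = np.where(better, v, best)
        best_scale = np.where(better, r, best_scale)

    best = np.clip(best, 0.0, None)
    peak = best.max()
    w = image_blend_weight
    enhanced = (1.0 - w) * image.pixels + (w * best / peak if peak > 0 else 0.0)
    return VesselnessResponse(
        response=best,
        best_scale_um=best_scale * image.scale_um_per_px,
        scales_px=radii,
        scale_um_per_px=image.scale_um_per_px,
        enhanced=enhanced,
    )


def binarize(
    response: VesselnessResponse,
    method: str = "global-otsu",
    fixed_threshold: float | None = None,
    quantile: float | None = None,
    use_enhanced: bool = True,
) -> BinaryVesselMask:
    """Threshold a vesselness response into a binary vessel mask.

    Methods: ``global-otsu`` (parameter-free), ``fixed`` (absolute
    threshold), ``quantile`` (fraction of pixels below threshold).
    Thresholds the image/vesselness blend by default (better boundary
    localization); set ``use_enhanced=False`` to threshold the raw
    scale-max response.  The threshold used is logged in the returned
    mask.
    """
    r = response.enhanced if (use_enhanced and response.enhanced is not None) else response.response
    if method == "global-otsu":
        if np.ptp(r) == 0:
            raise ValueError("degenerate response (all values equal): Otsu undefined")
        thr = float(threshold_otsu(r))
    elif method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed method requires fixed_threshold")
        thr = float(fixed_threshold)
    elif method == "quantile":
        if quantile is None or not (0 <= quantile <= 1):
            raise ValueError("quantile method requires quantile in [0, 1]")
        thr = float(np.quantile(r, quantile))
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return BinaryVesselMask(
        mask=r > thr,
        scale_um_per_px=response.scale_um_per_px,
        threshold=thr,
        log={
            "method": method,
            "threshold": thr,
            "scales_px": list(response.scales_px),
            "use_enhanced": bool(use_enhanced and response.enhanced is not None),
        },
    )


def clean_mask(
    mask: BinaryVesselMask, min_component_px: int = 30, fill_holes_px: int = 20
) -> BinaryVesselMask:
    """Remove small connected components and fill small interior holes.

    Deterministic, idempotent stand-in for the manual mask editing step of
    clinical pipelines.
    """
    if min_component_px < 0 or fill_holes_px < 0:
        raise ValueError("thresholds must be >= 0")
    m = mask.mask
    if min_component_px > 0:
        # components strictly smaller than min_component_px are removed
        m = remove_small_objects(m, max_size=min_component_px - 1)
    if fill_holes_px > 0:
        m = remove_small_holes(m, max_size=fill_holes_px)
    log = dict(mask.log)
    log.update({"min_component_px": min_component_px, "fill_holes_px": fill_holes_px})
    return BinaryVesselMask(mask=m, scale_um_per_px=mask.scale_um_per_px, threshold=mask.threshold, log=log)
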