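"""Preprocessing of valve images into one-pixel-wide skeletons.

The processing chain mirrors standard SEM valve-pattern analysis:
crop a square window around the valve center, band-pass filter to
suppress granular noise and valve-scale shading, binarize with an
automatic global threshold, and thin the silica pattern to a skeleton
with short terminal spurs pruned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import skeletonize as _sk_skeletonize


@dataclass
class RasterImage:
    """A 2-D grayscale image with a physical pixel size.

    Parameters
    ----------
    pixels : ndarray
        2-D array of finite intensities.
    pixel_size_um : float
        Edge length of one pixel in micrometres.
    meta : dict
        Free-form metadata (generator ground truth, provenance, ...).
    """

    pixels: np.ndarray
    pixel_size_um: float = 1.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("RasterImage requires a non-empty 2-D array")
        if not np.all(np.isfinite(self.pixels.astype(float))):
            raise ValueError("intensities must be finite")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """Boolean foreground mask plus the processing provenance that made it.

    Foreground is 8-connected, background 4-connected (the standard
    duality needed for consistent hole counting).
    """

    pixels: np.ndarray
    pixel_size_um: float = 1.0
    provenance: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("BinaryMask requires a non-empty 2-D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class SkeletonMask(BinaryMask):
    """A thin (one-pixel-wide, 8-connected) skeleton mask."""


# 8-connectivity structuring element, shared by several helpers.
_S8 = np.ones((3, 3), dtype=bool)


def count_components(mask: np.ndarray) -> int:
    """Number of 8-connected foreground components."""
    _, n = ndimage.label(np.asarray(mask, bool), structure=_S8)
    return int(n)


def count_holes(mask: np.ndarray) -> int:
    """Number of 4-connected background components not touching the border."""
    bg = ~np.asarray(mask, bool)
    lab, n = ndimage.label(bg)  # 4-connectivity by default
    if n == 0:
        return 0
    border = np.unique(
        np.concatenate([lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]])
    )
    border = set(border[border > 0].tolist())
    return int(n - len(border))


def crop_valve_center(
    img: RasterImage,
    center: tuple[int, int] | None = None,
    side_px: int = 256,
) -> RasterImage:
    """Crop a square window around the valve center.

    ``center=None`` uses the intensity centroid of the image (background
    level subtracted), which for a centered valve pattern lands on the
    pattern center.  Coordinates are (row, col), 0-based.
    """
    if side_px <= 0:
        raise ValueError("side_px must be positive")
    h, w = img.shape
    if center is None:
        weights = img.pixels.astype(float) - float(img.pixels.min())
        if weights.sum() == 0:
            center = ((h - 1) / 2.0, (w - 1) / 2.0)
        else:
            center = ndimage.center_of_mass(weights)
    r0 = int(round(center[0] - side_px / 2.0))
    c0 = int(round(center[1] - side_px / 2.0))
    if r0 < 0 or c0 < 0 or r0 + side_px > h or c0 + side_px > w:
        raise ValueError(
            f"crop window {side_px}px at center {center} exceeds image bounds {img.shape}"
        )
    out = img.pixels[r0 : r0 + side_px, c0 : c0 + side_px].copy()
    meta = dict(img.meta)
    meta.setdefault("provenance", []).append(
        {"op": "crop_valve_center", "center": tuple(float(x) for x in center), "side_px": side_px}
    )
    return RasterImage(out, img.pixel_size_um, meta)


def bandpass_filter(img: RasterImage, small_px: int = 3, large_px: int = 40) -> RasterImage:
    """Difference-of-Gaussians band-pass.

    Structures smaller than ``small_px`` (shot noise, silica granularity)
    and larger than ``large_px`` (illumination gradients, valve-scale
    shading) are suppressed.  A constant image maps to zero contrast.
    """
    if not (0 < small_px < large_px):
        raise ValueError("require 0 < small_px < large_px")
    x = img.pixels.astype(float)
    lo = gaussian(x, sigma=small_px, preserve_range=True)
    hi = gaussian(x, sigma=large_px, preserve_range=True)
    out = lo - hi
    meta = dict(img.meta)
    meta.setdefault("provenance", []).append(
        {"op": "bandpass_filter", "small_px": small_px, "large_px": large_px}
    )
    return RasterImage(out, img.pixel_size_um, meta)


def binarize(img: RasterImage, method: str = "otsu") -> BinaryMask:
    """Binarize with an automatic global threshold (Otsu).

    Foreground is the bright phase (silica).  Raises on a constant
    image, which has no contrast to threshold.
    """
    x = img.pixels.astype(float)
    if np.unique(x).size < 2:
        raise ValueError("no contrast: image has fewer than 2 distinct intensities")
    if method != "otsu":
        raise ValueError(f"unknown binarization method {method!r}")
    t = threshold_otsu(x)
    mask = x > t
    prov = list(img.meta.get("provenance", []))
    prov.append({"op": "binarize", "method": method, "threshold": float(t)})
    return BinaryMask(mask, img.pixel_size_um, prov)


def _neighbor_count(mask: np.ndarray) -> np.ndarray:
    """Per-pixel count of 8-connected foreground neighbors."""
    m = mask.astype(np.uint8)
    k = np.ones((3, 3), np.uint8)
    k[1, 1] = 0
    return ndimage.convolve(m, k, mode="constant", cval=0) * m


def _prune_spurs(sk: np.ndarray, prune_px: int) -> np.ndarray:
    """Remove terminal spurs shorter than ``prune_px`` pixels.

    Walks from each endpoint along its degree-2 chain; if a junction
    (pixel with >= 3 neighbors) is met in fewer than ``prune_px`` steps
    the walked pixels are deleted.  Chains ending at another endpoint
    (whole isolated filaments) are kept.
    """
    sk = sk.copy()
    offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    changed = True
    while changed:
        changed = False
        deg = _neighbor_count(sk)
        endpoints = np.argwhere((deg == 1) & sk)
        for r, c in endpoints:
            if not sk[r, c]:
                continue
            path = [(int(r), int(c))]
            prev = None
            cur = (int(r), int(c))
            is_spur = False
            while len(path) <= prune_px:
                nbrs = [
                    (cur[0] + dr, cur[1] + dc)
                    for dr, dc in offs
                    if 0 <= cur[0] + dr < sk.shape[0]
                    and 0 <= cur[1] + dc < sk.shape[1]
                    and sk[cur[0] + dr, cur[1] + dc]
                    and (cur[0] + dr, cur[1] + dc) != prev
                ]
                if len(nbrs) == 0:
                    break  # isolated filament tip: keep
                if len(nbrs) >= 2 or deg[nbrs[0]] >= 3:
                    is_spur = True  # reached a junction
                    break
                prev = cur
                cur = nbrs[0]
                path.append(cur)
            if is_spur and len(path) < prune_px:
                for p in path:
                    sk[p] = False
                changed = True
    return sk


def skeletonize(mask: BinaryMask, prune_px: int = 4) -> SkeletonMask:
    """Thin a binary mask to a one-pixel-wide 8-connected skeleton.

    Thinning preserves homotopy (component and hole counts); terminal
    spurs shorter than ``prune_px`` — thinning artifacts at rib tips —
    are then removed.  ``prune_px=0`` disables pruning.
    """
    if not mask.pixels.any():
        raise ValueError("empty mask: nothing to skeletonize")
    if prune_px < 0:
        raise ValueError("prune_px must be >= 0")
    sk = _sk_skeletonize(mask.pixels)
    if prune_px > 0:
        sk = _prune_spurs(sk, prune_px)
        sk = _sk_skeletonize(sk)
    prov = list(mask.provenance)
    prov.append({"op": "skeletonize", "prune_px": prune_px})
    return SkeletonMask(sk, mask.pixel_size_um, prov)
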