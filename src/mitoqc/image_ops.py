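"""The four deterministic pre-processing operators, applied in order before
pixel segmentation: rolling-ball background subtraction, unsharp masking,
contrast-limited adaptive histogram equalization (CLAHE), and disc-median
filtering.

All operators work on floating-point copies, preserve shape, keep
non-negative inputs non-negative (clamping at 0), and are bit-deterministic.
Quantization back to integer types is the caller's concern at write time.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.restoration import rolling_ball

__all__ = [
    "subtract_background",
    "unsharp_mask",
    "enhance_local_contrast",
    "median_filter",
    "preprocess",
]


def _as_float(img) -> np.ndarray:
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D raster, got ndim {arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("raster contains non-finite values")
    return arr


def subtract_background(img, radius_px: float) -> np.ndarray:
    """Rolling-ball background subtraction.

    The background is the grayscale opening of the image by a ball of the
    given radius rolled under the intensity surface; the result is the image
    minus this estimate, clamped at 0.  Adding a constant offset to the input
    leaves the output unchanged.
    """
    if radius_px < 1:
        raise ValueError(f"rolling-ball radius must be >= 1 px, got {radius_px}")
    arr = _as_float(img)
    background = rolling_ball(arr, radius=radius_px)
    return np.clip(arr - background, 0.0, None)


def unsharp_mask(img, radius_px: float, weight: float) -> np.ndarray:
    """Normalized unsharp mask: ``(img - w * Gaussian(img, sigma=radius)) / (1 - w)``.

    ``weight`` must lie in [0, 1); output is clamped at 0 (overshoot above
    the input maximum is deliberately retained — it is the operator's point).
    """
    if not 0.0 <= weight < 1.0:
        raise ValueError(f"unsharp weight must lie in [0, 1), got {weight}")
    if radius_px <= 0:
        raise ValueError(f"unsharp radius must be positive, got {radius_px}")
    arr = _as_float(img)
    if weight == 0.0:
        return arr.copy()
    blurred = ndimage.gaussian_filter(arr, sigma=radius_px, mode="nearest")
    return np.clip((arr - weight * blurred) / (1.0 - weight), 0.0, None)


def _tile_slices(n: int, block: int) -> list:
    """Partition an axis of length n into ceil(n/block) near-equal tiles."""
    k = max(1, -(-n // block))
    edges = np.linspace(0, n, k + 1).round().astype(int)
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


def _clipped_cdf(tile: np.ndarray, bins: int, max_slope: float, vmin, vmax):
    """Per-tile clipped-histogram CDF mapping bin index -> [0, 1].

    The histogram is clipped at ``max_slope`` times the uniform bin count and
    the excess redistributed uniformly (one pass), which bounds the slope of
    the equalization transfer function.
    """
    hist, _ = np.histogram(tile, bins=bins, range=(vmin, vmax))
    n = hist.sum()
    if n == 0:
        return np.linspace(0.0, 1.0, bins)
    limit = max_slope * n / bins
    excess = np.clip(hist - limit, 0, None).sum()
    hist = np.minimum(hist, limit) + excess / bins
    cdf = np.cumsum(hist)
    return cdf / cdf[-1]


def enhance_local_contrast(img, block_px: int, bins: int, max_slope: float) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    The image is partitioned into ceil(dim/block) tiles per axis; each tile
    gets a clipped-histogram equalization mapping over ``bins`` bins, and
    pixel values are remapped by bilinear interpolation between the four
    surrounding tile mappings.  Output stays within the input's value range.
    Images smaller than one block are processed as a single tile; a constant
    image is returned unchanged.
    """
    if bins < 2:
        raise ValueError(f"bins must be >= 2, got {bins}")
    if max_slope < 1:
        raise ValueError(f"max_slope must be >= 1, got {max_slope}")
    if block_px < 1:
        raise ValueError(f"block size must be >= 1, got {block_px}")
    arr = _as_float(img)
    vmin, vmax = float(arr.min()), float(arr.max())
    if vmax == vmin:
        return arr.copy()

    h, w = arr.shape
    rows = _tile_slices(h, block_px)
    cols = _tile_slices(w, block_px)
    # per-tile transfer functions on the shared bin grid
    cdfs = np.empty((len(rows), len(cols), bins))
    for i, rs in enumerate(rows):
        for j, cs in enumerate(cols):
            cdfs[i, j] = _clipped_cdf(arr[rs, cs], bins, max_slope, vmin, vmax)

    bin_idx = np.clip(
        ((arr - vmin) / (vmax - vmin) * bins).astype(int), 0, bins - 1
    )

    # bilinear interpolation between tile-center mappings
    rc = np.array([(s.start + s.stop - 1) / 2.0 for s in rows])
    cc = np.array([(s.start + s.stop - 1) / 2.0 for s in cols])
    yy = np.arange(h, dtype=np.float64)
    xx = np.arange(w, dtype=np.float64)

    def _weights(coord, centers):
        """For each coordinate: flanking tile indices (i0, i1) and the
        fractional weight of i1; clamped beyond the outer tile centers."""
        i1 = np.searchsorted(centers, coord)
        i0 = np.clip(i1 - 1, 0, len(centers) - 1)
        i1 = np.clip(i1, 0, len(centers) - 1)
        denom = centers[i1] - centers[i0]
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(denom > 0, (coord - centers[i0]) / np.where(denom > 0, denom, 1.0), 0.0)
        return i0, i1, np.clip(t, 0.0, 1.0)

    r0, r1, tr = _weights(yy, rc)
    c0, c1, tc = _weights(xx, cc)

    R0 = r0[:, None]
    R1 = r1[:, None]
    TR = tr[:, None]
    C0 = c0[None, :]
    C1 = c1[None, :]
    TC = tc[None, :]

    v00 = cdfs[R0, C0, bin_idx]
    v01 = cdfs[R0, C1, bin_idx]
    v10 = cdfs[R1, C0, bin_idx]
    v11 = cdfs[R1, C1, bin_idx]
    out01 = (1 - TR) * ((1 - TC) * v00 + TC * v01) + TR * ((1 - TC) * v10 + TC * v11)
    return vmin + out01 * (vmax - vmin)


def disc_footprint(radius_px: float) -> np.ndarray:
    """Boolean disc of pixels whose centers lie within ``radius_px``."""
    r = int(np.floor(radius_px))
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    return (y * y + x * x) <= radius_px * radius_px


def median_filter(img, radius_px: float) -> np.ndarray:
    """Median over a disc neighborhood; borders by edge replication."""
    if radius_px < 1:
        raise ValueError(f"median radius must be >= 1 px, got {radius_px}")
    arr = _as_float(img)
    return ndimage.median_filter(arr, footprint=disc_footprint(radius_px), mode="nearest")


def preprocess(img, cfg) -> np.ndarray:
    """Full pre-processing chain with config parameters:
    subtract_background -> unsharp_mask -> enhance_local_contrast -> median_filter.
    """
    out = subtract_background(img, cfg.rolling_ball_radius_px)
    out = unsharp_mask(out, cfg.unsharp_radius_px, cfg.unsharp_weight)
    out = enhance_local_contrast(out, cfg.clahe_block_px, cfg.clahe_bins, cfg.clahe_max_slope)
    out = median_filter(out, cfg.median_radius_px)
    return out
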