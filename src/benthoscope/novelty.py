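"""Novelty maps: convolutional application of a background model.

The trained background model is slid over every patch position of an image
with a configurable stride; each patch's reconstruction error is stored at
the patch-centre coordinate.  The stride-reduced error grid is upscaled back
to the image resolution by bilinear interpolation (exact at grid centres,
edge-replicated into the margin where no patch centre exists), then dilated
by convolution with an all-ones kernel of the patch size to smooth region
boundaries before thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile
from numpy.lib.stride_tricks import sliding_window_view
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import uniform_filter1d

from .aen import DBM
from .image_store import grid_shape

__all__ = ["NoveltyMap", "apply_dbm", "novelty_grid", "upscale_grid",
           "dilate_novelty_map", "save_novelty_map", "load_novelty_map"]


@dataclass
class NoveltyMap:
    """Per-pixel reconstruction-error map for one image."""

    image_id: str
    values: np.ndarray  # (H, W) float32, >= 0
    dilated: bool = False


def novelty_grid(pixels: np.ndarray, dbm: DBM, stride: int = 2,
                 slice_rows: int = 16) -> np.ndarray:
    """Reconstruction error F at every stride-grid patch centre.

    Returns an ``(ny, nx)`` float32 array where cell ``(j, i)`` is the error
    of the patch centred at ``(half + i*stride, half + j*stride)``.
    Processing runs in horizontal slices of ``slice_rows`` grid rows to
    bound memory; sliced and unsliced results are identical.
    """
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    e = dbm.patch_edge
    h, w = pixels.shape[:2]
    if h < e or w < e:
        raise ValueError(f"image {w}x{h} smaller than patch edge {e}")
    ny, nx = grid_shape(w, h, e, stride)
    pixels = np.ascontiguousarray(pixels, dtype=np.float32)
    # all valid patch top-left corners, viewed without copying
    windows = sliding_window_view(pixels, (e, e, 3))[::stride, ::stride, 0]
    out = np.empty((ny, nx), dtype=np.float32)
    model = dbm.model
    for j0 in range(0, ny, slice_rows):
        j1 = min(j0 + slice_rows, ny)
        block = np.ascontiguousarray(windows[j0:j1]).reshape(-1, 3 * e * e)
        out[j0:j1] = model.score_samples(block).reshape(j1 - j0, nx)
    return out


def upscale_grid(grid: np.ndarray, width: int, height: int, edge: int,
                 stride: int) -> np.ndarray:
    """Bilinearly upscale a stride grid of patch-centre values to H×W.

    Values are exact at the grid centres; pixels beyond the outermost
    centres (the patch margin) replicate the nearest interpolated value.
    """
    ny, nx = grid.shape
    half = (edge - 1) // 2
    ys = half + stride * np.arange(ny)
    xs = half + stride * np.arange(nx)
    if ny == 1 and nx == 1:
        return np.full((height, width), grid[0, 0], dtype=np.float32)
    interp = RegularGridInterpolator((ys, xs), grid.astype(np.float64),
                                     method="linear", bounds_error=False)
    yy = np.clip(np.arange(height), ys[0], ys[-1])
    xx = np.clip(np.arange(width), xs[0], xs[-1])
    pts_y, pts_x = np.meshgrid(yy, xx, indexing="ij")
    vals = interp(np.stack([pts_y.ravel(), pts_x.ravel()], axis=1))
    return vals.reshape(height, width).astype(np.float32)


def apply_dbm(pixels: np.ndarray, dbm: DBM, stride: int = 2,
              image_id: str = "", slice_rows: int = 16) -> NoveltyMap:
    """Full-resolution novelty map of one image (not yet dilated)."""
    grid = novelty_grid(pixels, dbm, stride=stride, slice_rows=slice_rows)
    h, w = pixels.shape[:2]
    values = upscale_grid(grid, w, h, dbm.patch_edge, stride)
    np.maximum(values, 0.0, out=values)  # guard interpolation round-off
    return NoveltyMap(image_id=image_id, values=values, dilated=False)


def dilate_novelty_map(nm: NoveltyMap, kernel_edge: int) -> NoveltyMap:
    """Convolve with an all-ones ``kernel_edge``² kernel (zero padded).

    This is the plain unnormalised convolution: an isolated pixel of value v
    becomes a kernel-sized square of value v, spreading high novelty into a
    smooth neighbourhood.
    """
    if kernel_edge < 1 or kernel_edge % 2 == 0:
        raise ValueError(f"kernel edge must be odd and >= 1, got {kernel_edge}")
    v = nm.values.astype(np.float64)
    # separable all-ones kernel: mean filter with zero padding, times size
    v = uniform_filter1d(v, kernel_edge, axis=0, mode="constant", cval=0.0) * kernel_edge
    v = uniform_filter1d(v, kernel_edge, axis=1, mode="constant", cval=0.0) * kernel_edge
    np.maximum(v, 0.0, out=v)
    return NoveltyMap(image_id=nm.image_id, values=v.astype(np.float32),
                      dilated=True)


def save_novelty_map(nm: NoveltyMap, path) -> None:
    """Write the map as a 32-bit float TIFF."""
    tifffile.imwrite(path, nm.values.astype(np.float32),
                     metadata={"image_id": nm.image_id, "dilated": nm.dilated})


def load_novelty_map(path, image_id: str = "", dilated: bool = False) -> NoveltyMap:
    values = tifffile.imread(path).astype(np.float32)
    return NoveltyMap(image_id=image_id, values=values, dilated=dilated)
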