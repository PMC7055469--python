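"""Whole-image test-time decomposition: 50%-overlap tiling, background
exclusion and batched patch prediction.

Images are scanned with a 32x32 sliding window at stride 16, so most
interior pixels fall inside four different patches; patches of bare white
background are excluded by thresholding on raw intensities before any
normalization (the white level is defined in raw units).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import models as _models
from .patches import NormalizationStats, apply_normalization

PATCH_SIZE = 32
STRIDE = 16

WHITE_LEVEL = 230
COVERAGE_FRAC = 0.99


@dataclass(frozen=True)
class TilingGrid:
    patch_size: int
    stride: int
    grid_rows: int
    grid_cols: int
    pad_bottom: int
    pad_right: int
    padded_shape: tuple[int, int]

    def tile_bounds(self, i: int, j: int):
        """Half-open (row0, row1, col0, col1) footprint of tile (i, j)."""
        r0, c0 = i * self.stride, j * self.stride
        return r0, r0 + self.patch_size, c0, c0 + self.patch_size


@dataclass
class PatchPredictionGrid:
    probs: np.ndarray       # (grid_rows, grid_cols, 4)
    foreground: np.ndarray  # (grid_rows, grid_cols) bool
    grid: TilingGrid


def _pad_value(image: np.ndarray) -> np.ndarray:
    """Background estimate: median of the four 8x8 corner blocks."""
    h, w = image.shape[:2]
    corners = np.concatenate([
        image[:8, :8].reshape(-1, image.shape[-1]),
        image[:8, w - 8:].reshape(-1, image.shape[-1]),
        image[h - 8:, :8].reshape(-1, image.shape[-1]),
        image[h - 8:, w - 8:].reshape(-1, image.shape[-1]),
    ])
    return np.median(corners, axis=0)


def tile_image(image: np.ndarray, patch_size: int = PATCH_SIZE,
               stride: int = STRIDE, pad_value=None):
    """Tile an RGB image into overlapping patches.

    The image is padded on the bottom/right with the background colour up to
    a multiple of the stride (at least one full patch), and tile (i, j)
    covers rows [stride*i, stride*i + patch_size).  For dimensions divisible
    by the patch size this yields (H/stride - 1) * (W/stride - 1) tiles.

    Returns ``(grid, batch)`` with batch of shape (rows*cols, p, p, 3).
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected (H, W, 3) image, got {image.shape}")
    h, w = image.shape[:2]
    if h < 2 or w < 2:
        raise ValueError("degenerate image")
    hp = max(patch_size, stride * int(np.ceil(h / stride)))
    wp = max(patch_size, stride * int(np.ceil(w / stride)))
    if pad_value is None:
        pad_value = _pad_value(image)
    padded = np.empty((hp, wp, 3), dtype=image.dtype)
    padded[:] = np.asarray(pad_value, dtype=image.dtype)
    padded[:h, :w] = image
    rows = hp // stride - 1
    cols = wp // stride - 1
    grid = TilingGrid(patch_size, stride, rows, cols,
                      pad_bottom=hp - h, pad_right=wp - w,
                      padded_shape=(hp, wp))
    sr, sc, sch = padded.strides
    shape = (rows, cols, patch_size, patch_size, 3)
    strides = (sr * stride, sc * stride, sr, sc, sch)
    tiles = np.lib.stride_tricks.as_strided(padded, shape=shape, strides=strides)
    batch = np.ascontiguousarray(tiles).reshape(rows * cols, patch_size,
                                                patch_size, 3)
    return grid, batch


def is_background(patch: np.ndarray, white_level: int = WHITE_LEVEL,
                  coverage_frac: float = COVERAGE_FRAC) -> bool:
    """True iff the near-white pixel fraction exceeds ``coverage_frac``.

    A pixel counts as near-white when its minimum channel is at least
    ``white_level``; operates on raw (un-normalized) intensities.
    """
    white = patch.min(axis=-1) >= white_level
    return bool(white.mean() > coverage_frac)


def background_flags(batch: np.ndarray, white_level: int = WHITE_LEVEL,
                     coverage_frac: float = COVERAGE_FRAC) -> np.ndarray:
    white = batch.min(axis=-1) >= white_level
    return white.mean(axis=(1, 2)) > coverage_frac


def predict_image(model, image: np.ndarray, stats: NormalizationStats,
                  norm_mode: str = "zscore_then_mean_patch",
                  white_level: int = WHITE_LEVEL,
                  coverage_frac: float = COVERAGE_FRAC,
                  batch_size: int = 256) -> PatchPredictionGrid:
    """Tile, drop background tiles, normalize and classify the rest.

    Background tiles carry no class probabilities (rows of zeros, flagged
    False in ``foreground``).
    """
    grid, batch = tile_image(image)
    bg = background_flags(batch, white_level, coverage_frac)
    fg_idx = np.where(~bg)[0]
    probs = np.zeros((grid.grid_rows * grid.grid_cols, 4), dtype=np.float64)
    if fg_idx.size:
        x = apply_normalization(batch[fg_idx].astype(np.float32), stats,
                                mode=norm_mode)
        probs[fg_idx] = _models.predict_proba(model, x, batch_size=batch_size)
    return PatchPredictionGrid(
        probs=probs.reshape(grid.grid_rows, grid.grid_cols, 4),
        foreground=(~bg).reshape(grid.grid_rows, grid.grid_cols),
        grid=grid,
    )


def save_grid(path, grid: PatchPredictionGrid) -> None:
    """Write the grid as compressed arrays plus a JSON geometry sidecar."""
    import json
    from pathlib import Path as _Path

    np.savez_compressed(
        path, probs=grid.probs, foreground=grid.foreground,
        geometry=np.array([grid.grid.patch_size, grid.grid.stride,
                           grid.grid.grid_rows, grid.grid.grid_cols,
                           grid.grid.pad_bottom, grid.grid.pad_right,
                           grid.grid.padded_shape[0], grid.grid.padded_shape[1]]))
    sidecar = _Path(str(path)).with_suffix(".json")
    sidecar.write_text(json.dumps({
        "patch_size": grid.grid.patch_size,
        "stride": grid.grid.stride,
        "grid_rows": grid.grid.grid_rows,
        "grid_cols": grid.grid.grid_cols,
        "pad_bottom": grid.grid.pad_bottom,
        "pad_right": grid.grid.pad_right,
        "padded_shape": list(grid.grid.padded_shape),
        "class_order": ["base", "body", "stem", "tip"],
    }, indent=2))


def load_grid(path) -> PatchPredictionGrid:
    with np.load(path) as z:
        g = z["geometry"]
        tg = TilingGrid(int(g[0]), int(g[1]), int(g[2]), int(g[3]),
                        int(g[4]), int(g[5]), (int(g[6]), int(g[7])))
        return PatchPredictionGrid(probs=z["probs"],
                                   foreground=z["foreground"], grid=tg)
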