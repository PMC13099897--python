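"""Attention-heatmap rendering: map per-patch scores back onto the slide.

Scores are min-max normalized to [0, 1], painted over each patch footprint
at a chosen render downsample, then either Gaussian-smoothed (the CLAM-style
path) or bilinearly upsampled from patch-grid resolution (the ABMIL-style
path). The heat raster is colorized with the "jet" colormap and
alpha-blended over the slide image.

Degenerate score vectors: with a single patch the painted footprint is 1.0
against the 0 background; with several all-equal scores every footprint maps
to the neutral 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
from matplotlib import colormaps
from scipy import ndimage
from skimage.transform import resize


@dataclass
class HeatmapParams:
    render_downsample: float = 32.0
    smoothing_sigma: float | None = None  # px at render scale; None -> 2 patch widths
    mode: str = "gaussian"  # gaussian | bilinear
    colormap: str = "jet"
    overlay_alpha: float = 0.4

    def __post_init__(self):
        if not 0.0 <= self.overlay_alpha <= 1.0:
            raise ValueError("overlay_alpha must lie in [0, 1]")
        if self.smoothing_sigma is not None and self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")
        if self.mode not in ("gaussian", "bilinear"):
            raise ValueError(f"unknown heatmap mode {self.mode!r}")


def normalize_scores(scores: np.ndarray) -> np.ndarray:
    """Min-max to [0, 1]; singleton -> 1.0, several equal scores -> 0.5."""
    s = np.asarray(scores, dtype=float)
    if s.size == 1:
        return np.ones(1)
    lo, hi = s.min(), s.max()
    if hi == lo:
        return np.full(s.shape, 0.5)
    return (s - lo) / (hi - lo)


def scores_to_map(
    scores: np.ndarray,
    coords: np.ndarray,
    patch_size: int,
    params: HeatmapParams | None = None,
    slide_dims_level0: tuple[int, int] | None = None,
) -> np.ndarray:
    """Render normalized attention scores as a [0, 1] heat raster."""
    params = params or HeatmapParams()
    coords = np.asarray(coords, dtype=np.int64).reshape(-1, 2)
    scores = np.asarray(scores, dtype=float).reshape(-1)
    if len(scores) != len(coords):
        raise ValueError("scores and coords misaligned")
    if slide_dims_level0 is None:
        slide_dims_level0 = (
            int(coords[:, 0].max() + patch_size),
            int(coords[:, 1].max() + patch_size),
        )
    w0, h0 = slide_dims_level0
    ds = params.render_downsample
    wr, hr = max(1, round(w0 / ds)), max(1, round(h0 / ds))
    norm = normalize_scores(scores)

    if params.mode == "bilinear":
        # one cell per patch on the grid, then bilinear upsample to render dims
        nx, ny = int(np.ceil(w0 / patch_size)), int(np.ceil(h0 / patch_size))
        grid = np.zeros((ny, nx))
        for (x, y), v in zip(coords, norm):
            grid[y // patch_size, x // patch_size] = v
        heat = resize(grid, (hr, wr), order=1, anti_aliasing=False)
        return np.clip(heat, 0.0, 1.0)

    heat = np.zeros((hr, wr))
    for (x, y), v in zip(coords, norm):
        x0, y0 = int(round(x / ds)), int(round(y / ds))
        x1 = min(wr, int(round((x + patch_size) / ds)))
        y1 = min(hr, int(round((y + patch_size) / ds)))
        heat[y0:y1, x0:x1] = v
    sigma = params.smoothing_sigma
    if sigma is None:
        sigma = 2.0 * patch_size / ds
    if sigma > 0:
        heat = ndimage.gaussian_filter(heat, sigma=sigma, mode="reflect")
    return np.clip(heat, 0.0, 1.0)


def overlay(heat: np.ndarray, slide_rgb: np.ndarray, params: HeatmapParams | None = None) -> np.ndarray:
    """Jet-colormapped heat alpha-blended onto the slide image (uint8 RGB)."""
    params = params or HeatmapParams()
    heat = np.asarray(heat, dtype=float)
    slide = np.asarray(slide_rgb)
    if heat.shape != slide.shape[:2]:
        raise ValueError(f"heat {heat.shape} and slide {slide.shape[:2]} dimensions differ")
    if params.overlay_alpha == 0.0:
        return slide.copy()
    cmap = colormaps[params.colormap]
    colored = (cmap(np.clip(heat, 0.0, 1.0))[:, :, :3] * 255.0)
    blended = (1.0 - params.overlay_alpha) * slide.astype(float) + params.overlay_alpha * colored
    return np.clip(np.round(blended), 0, 255).astype(np.uint8)


def save_heatmap_png(path, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8), extension=".png")
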