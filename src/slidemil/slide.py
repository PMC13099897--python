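"""Minimal pyramidal-slide abstraction.

Production WSIs live in multi-resolution pyramid formats; the tests and the
synthetic pipeline use plain rasters. :class:`ArraySlide` wraps an in-memory
RGB array as a pyramid (extra levels synthesized by box downsampling), with
an OpenSlide-like surface: ``level_downsamples``, ``level_dimensions``,
``read_region`` addressed in level-0 coordinates. ``open_slide`` loads a
plain PNG/TIFF as a single-level pyramid.
"""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio
from skimage.transform import resize


class ArraySlide:
    def __init__(self, image: np.ndarray, level_downsamples: tuple[float, ...] = (1.0,)):
        image = np.asarray(image)
        if image.ndim != 3 or image.shape[2] != 3:
            raise ValueError("expected an H x W x 3 RGB array")
        if image.dtype != np.uint8:
            raise ValueError("expected 8-bit RGB")
        if list(level_downsamples) != sorted(level_downsamples) or level_downsamples[0] != 1:
            raise ValueError("downsamples must be ascending and start at 1")
        self._levels = [image]
        h, w = image.shape[:2]
        for ds in level_downsamples[1:]:
            lh, lw = max(1, round(h / ds)), max(1, round(w / ds))
            lvl = resize(image, (lh, lw), anti_aliasing=True, preserve_range=True)
            self._levels.append(np.clip(lvl, 0, 255).astype(np.uint8))
        self.level_downsamples = tuple(float(d) for d in level_downsamples)

    @property
    def dimensions(self) -> tuple[int, int]:
        """(width, height) at level 0."""
        h, w = self._levels[0].shape[:2]
        return (w, h)

    @property
    def level_count(self) -> int:
        return len(self._levels)

    @property
    def level_dimensions(self) -> tuple[tuple[int, int], ...]:
        return tuple((lvl.shape[1], lvl.shape[0]) for lvl in self._levels)

    def read_level(self, level: int) -> np.ndarray:
        return self._levels[level]

    def read_region(self, location: tuple[int, int], level: int, size: tuple[int, int]) -> np.ndarray:
        """Read a (w, h) region whose top-left is ``location`` in level-0 px."""
        x0, y0 = location
        ds = self.level_downsamples[level]
        xl, yl = int(round(x0 / ds)), int(round(y0 / ds))
        w, h = size
        lvl = self._levels[level]
        if xl < 0 or yl < 0 or xl + w > lvl.shape[1] or yl + h > lvl.shape[0]:
            raise ValueError(f"region {location} size {size} at level {level} outside slide bounds")
        return lvl[yl : yl + h, xl : xl + w]


def open_slide(path) -> ArraySlide:
    """Open a plain raster image (PNG/TIFF) as a single-level pyramid."""
    img = iio.imread(path)
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[:, :, :3]
    return ArraySlide(np.asarray(img, dtype=np.uint8))
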