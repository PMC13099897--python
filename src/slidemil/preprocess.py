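"""Tissue segmentation and patch-grid extraction for pyramidal slides.

Segmentation runs at a low-magnification pyramid level (default ~32x
downsample): Gaussian blur, RGB -> HSV, take the saturation channel (high
contrast between H&E stain and glass background), optionally boost stain
boundaries with a morphological gradient, Otsu-threshold, then clean up with
morphological closing, small-object removal and small-hole filling.

Patches are non-overlapping 256 x 256 level-0 squares kept when at least
``tissue_coverage_min`` of their footprint lies under the tissue mask.
Coordinates are 0-based (x, y) top-left corners in level-0 pixels with
half-open footprints [x, x+ps) x [y, y+ps); truncated edge patches are
dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk, remove_small_holes, remove_small_objects
from skimage.segmentation import find_boundaries


@dataclass
class SegmentationParams:
    target_downsample: float = 32.0
    blur_sigma: float = 2.0  # px at working level
    use_morph_gradient: bool = True
    gradient_radius: int = 2
    close_kernel: int = 2  # structuring-element radius, px at working level
    min_region_area: int = 1000  # px^2 at working level
    min_hole_area: int = 500  # px^2 at working level
    patch_size: int = 256  # level-0 px
    tissue_coverage_min: float = 0.5

    def __post_init__(self):
        if self.patch_size <= 0:
            raise ValueError("patch_size must be positive")
        if not 0.0 <= self.tissue_coverage_min <= 1.0:
            raise ValueError("tissue_coverage_min must lie in [0, 1]")


@dataclass
class TissueMask:
    mask: np.ndarray  # bool raster at working level
    level: int
    downsample: float
    slide_dims_level0: tuple[int, int]  # (width, height)
    threshold: float | None = None  # Otsu threshold on the 8-bit saturation image


@dataclass
class PatchGrid:
    coords: np.ndarray  # N x 2 int64 level-0 (x, y)
    patch_size: int
    level: int = 0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.coords)


def select_level(pyramid_downsamples, target_downsample: float) -> int:
    """Highest pyramid level whose downsample does not exceed the target."""
    ds = list(pyramid_downsamples)
    if not ds:
        raise ValueError("empty pyramid")
    best = 0
    for i, d in enumerate(ds):
        if d <= target_downsample:
            best = i
    return best


def saturation_image(image_rgb: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Blurred 8-bit saturation channel (the Otsu input when the gradient is off)."""
    img = np.asarray(image_rgb)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    blurred = ndimage.gaussian_filter(img.astype(np.float64), sigma=(params.blur_sigma, params.blur_sigma, 0))
    sat = rgb2hsv(np.clip(blurred, 0, 255).astype(np.uint8))[:, :, 1]
    return np.round(sat * 255.0).astype(np.uint8)


def segment_tissue(
    image_rgb: np.ndarray,
    params: SegmentationParams | None = None,
    level: int = 0,
    downsample: float = 1.0,
    slide_dims_level0: tuple[int, int] | None = None,
) -> TissueMask:
    """Binarize tissue vs background on a working-level RGB raster."""
    params = params or SegmentationParams()
    sat = saturation_image(image_rgb, params)
    if slide_dims_level0 is None:
        h, w = sat.shape
        slide_dims_level0 = (int(round(w * downsample)), int(round(h * downsample)))

    work = sat.astype(np.float64)
    if params.use_morph_gradient:
        selem = disk(params.gradient_radius)
        grad = ndimage.grey_dilation(sat, footprint=selem) - ndimage.grey_erosion(sat, footprint=selem)
        work = np.clip(work + grad, 0, 255)
    work = work.astype(np.uint8)

    if work.min() == work.max():
        warnings.warn("constant saturation image; returning empty tissue mask", stacklevel=2)
        return TissueMask(np.zeros(sat.shape, dtype=bool), level, downsample, slide_dims_level0, None)

    thr = threshold_otsu(work, nbins=256)
    mask = work > thr
    if params.close_kernel > 0:
        mask = closing(mask, disk(params.close_kernel))
    if params.min_region_area > 0:
        mask = remove_small_objects(mask, max_size=params.min_region_area)
    if params.min_hole_area > 0:
        mask = remove_small_holes(mask, max_size=params.min_hole_area)
    return TissueMask(mask, level, downsample, slide_dims_level0, float(thr))


def extract_patch_grid(mask: TissueMask, params: SegmentationParams | None = None) -> PatchGrid:
    """Level-0 patch coordinates whose tissue coverage meets the threshold.

    Coverage of a patch is the mean of the mask over its footprint mapped to
    the working level (index bounds rounded). Coordinates are emitted in
    row-major order.
    """
    params = params or SegmentationParams()
    ps = params.patch_size
    w0, h0 = mask.slide_dims_level0
    ds = mask.downsample
    coords = []
    for y in range(0, h0 - ps + 1, ps):
        y0l, y1l = int(round(y / ds)), int(round((y + ps) / ds))
        for x in range(0, w0 - ps + 1, ps):
            x0l, x1l = int(round(x / ds)), int(round((x + ps) / ds))
            footprint = mask.mask[y0l:y1l, x0l:x1l]
            if footprint.size == 0:
                continue
            if footprint.mean() >= params.tissue_coverage_min:
                coords.append((x, y))
    return PatchGrid(np.asarray(coords, dtype=np.int64).reshape(-1, 2), ps, level=0)


def render_qc_overlay(image_rgb: np.ndarray, mask: TissueMask, grid: PatchGrid) -> np.ndarray:
    """Mask contour (green) and patch boxes (blue) over the working-level image."""
    img = np.asarray(image_rgb).copy()
    if img.shape[:2] != mask.mask.shape:
        raise ValueError("image and mask dimensions differ")
    contour = find_boundaries(mask.mask, mode="thick")
    img[contour] = (0, 200, 0)
    ds = mask.downsample
    for x, y in grid.coords:
        x0, y0 = int(round(x / ds)), int(round(y / ds))
        x1 = min(int(round((x + grid.patch_size) / ds)), img.shape[1] - 1)
        y1 = min(int(round((y + grid.patch_size) / ds)), img.shape[0] - 1)
        img[y0, x0 : x1 + 1] = (30, 60, 220)
        img[y1, x0 : x1 + 1] = (30, 60, 220)
        img[y0 : y1 + 1, x0] = (30, 60, 220)
        img[y0 : y1 + 1, x1] = (30, 60, 220)
    return img


def write_grid(grid: PatchGrid, path, downsample: float = 1.0) -> None:
    """Store patch coordinates as HDF5 ('coords' N x 2 int64 + attrs)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("coords", data=np.asarray(grid.coords, dtype=np.int64))
        fh.attrs["patch_size"] = int(grid.patch_size)
        fh.attrs["level"] = int(grid.level)
        fh.attrs["downsample"] = float(downsample)


def read_grid(path) -> PatchGrid:
    with h5py.File(path, "r") as fh:
        if "coords" not in fh:
            raise ValueError(f"{path}: missing 'coords' dataset")
        return PatchGrid(fh["coords"][...], int(fh.attrs["patch_size"]), int(fh.attrs["level"]))
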