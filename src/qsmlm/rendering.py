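"""Super-resolution image reconstruction from localization tables.

Each localization contributes a unit-mass isotropic Gaussian whose width
is its localization uncertainty (or a fixed width). Kernels are
integrated analytically over each rendered pixel (difference of error
functions per axis) and truncated at 4 sigma, so the image integral
conserves localization count to better than 0.013% for interior points
regardless of sigma.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import erf

from .table import LocalizationTable

DEFAULT_PIXEL_NM = 20.0
DEFAULT_SIGMA_NM = 20.0
TRUNCATION_SIGMAS = 4.0


@dataclass
class IntensityImage:
    """A rendered 2-D intensity grid.

    ``pixels[i, j]`` covers ``[x0 + j*p, x0 + (j+1)*p) x [y0 + i*p, ...)``
    where ``p`` is ``pixel_size_render`` (row = y, column = x, origin at
    the lower-left corner of pixel (0, 0)).
    """

    pixels: np.ndarray
    pixel_size_render: float
    origin: tuple

    @property
    def total(self) -> float:
        return float(self.pixels.sum())


def _grid(table: LocalizationTable, pixel: float, pad: float):
    x, y = table.x, table.y
    x0 = np.floor((x.min() - pad) / pixel) * pixel
    y0 = np.floor((y.min() - pad) / pixel) * pixel
    nx = int(np.ceil((x.max() + pad - x0) / pixel)) + 1
    ny = int(np.ceil((y.max() + pad - y0) / pixel)) + 1
    return x0, y0, nx, ny


def render_gaussian(
    table: LocalizationTable,
    pixel_size_render: float = DEFAULT_PIXEL_NM,
    sigma_mode: str = "per_localization",
    fixed_sigma: Optional[float] = None,
) -> IntensityImage:
    """Render by analytic per-pixel integration of Gaussian kernels.

    Parameters
    ----------
    sigma_mode
        ``"per_localization"`` uses each record's uncertainty column;
        ``"fixed"`` uses ``fixed_sigma`` (default 20 nm) for all records.

    The grid covers the point-cloud bounding box padded by the kernel
    truncation radius (4 x the largest sigma), so no kernel is clipped.
    """
    if pixel_size_render <= 0:
        raise ValueError("pixel_size_render must be positive")
    if sigma_mode not in ("per_localization", "fixed"):
        raise ValueError("sigma_mode must be 'per_localization' or 'fixed'")
    if sigma_mode == "per_localization":
        if table.sigma is None:
            raise ValueError("per_localization rendering requires a sigma column")
        sigmas = table.sigma
    else:
        sigmas = np.full(len(table), DEFAULT_SIGMA_NM if fixed_sigma is None else fixed_sigma)
    if len(table) == 0:
        return IntensityImage(np.zeros((1, 1)), pixel_size_render, (0.0, 0.0))
    if (sigmas <= 0).any():
        raise ValueError("kernel sigma must be positive")

    p = pixel_size_render
    # pad by the truncation radius so no interior kernel is clipped
    x0, y0, nx, ny = _grid(table, p, TRUNCATION_SIGMAS * float(sigmas.max()))
    img = np.zeros((ny, nx))
    xs, ys = table.x, table.y
    sqrt2 = np.sqrt(2.0)
    for xi, yi, s in zip(xs, ys, sigmas):
        half = TRUNCATION_SIGMAS * s
        j0 = max(int(np.floor((xi - half - x0) / p)), 0)
        j1 = min(int(np.ceil((xi + half - x0) / p)), nx)
        i0 = max(int(np.floor((yi - half - y0) / p)), 0)
        i1 = min(int(np.ceil((yi + half - y0) / p)), ny)
        if j1 <= j0 or i1 <= i0:
            continue
        ex = x0 + np.arange(j0, j1 + 1) * p          # pixel edges, x
        ey = y0 + np.arange(i0, i1 + 1) * p
        cx = 0.5 * np.diff(erf((ex - xi) / (sqrt2 * s)))
        cy = 0.5 * np.diff(erf((ey - yi) / (sqrt2 * s)))
        img[i0:i1, j0:j1] += np.outer(cy, cx)
    return IntensityImage(img, p, (x0, y0))


def render_histogram(
    table: LocalizationTable, pixel_size_render: float = DEFAULT_PIXEL_NM
) -> IntensityImage:
    """2-D count histogram; the image sum equals the record count exactly.

    Bins are half-open ``[edge, edge + pixel)``: a point exactly on an
    edge belongs to the higher bin.
    """
    if pixel_size_render <= 0:
        raise ValueError("pixel_size_render must be positive")
    if len(table) == 0:
        return IntensityImage(np.zeros((1, 1)), pixel_size_render, (0.0, 0.0))
    p = pixel_size_render
    x0, y0, nx, ny = _grid(table, p, 0.0)
    j = np.floor((table.x - x0) / p).astype(int)
    i = np.floor((table.y - y0) / p).astype(int)
    img = np.zeros((ny, nx))
    np.add.at(img, (i, j), 1.0)
    return IntensityImage(img, p, (x0, y0))


# black -> red -> yellow -> white ramp ("red hot")
def _redhot_lut() -> np.ndarray:
    v = np.linspace(0.0, 1.0, 256)
    r = np.clip(3.0 * v, 0, 1)
    g = np.clip(3.0 * v - 1.0, 0, 1)
    b = np.clip(3.0 * v - 2.0, 0, 1)
    return (np.column_stack([r, g, b]) * 255 + 0.5).astype(np.uint8)


def export_image(image: IntensityImage, path, colormap: Optional[str] = None) -> None:
    """Write a 32-bit float grayscale TIFF, or a color-mapped 8-bit PNG.

    ``colormap="redhot"`` applies the black-red-yellow-white ramp used
    for conventional super-resolution reconstruction display; the
    maximum pixel maps to white, zero to black.
    """
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, image.pixels.astype(np.float32))
        return
    from PIL import Image as PILImage

    arr = image.pixels
    peak = arr.max()
    scaled = np.zeros_like(arr) if peak == 0 else arr / peak
    idx = (np.clip(scaled, 0, 1) * 255 + 0.5).astype(np.uint8)
    if colormap in (None, "gray", "grey"):
        out = idx
        mode = "L"
    elif colormap == "redhot":
        out = _redhot_lut()[idx]
        mode = "RGB"
    else:
        raise ValueError(f"unknown colormap {colormap!r}")
    # row 0 is the smallest y; flip so the image displays with y upward
    PILImage.fromarray(out[::-1], mode=mode).save(path)
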