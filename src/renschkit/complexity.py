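"""Genital-complexity metrics from binary outline images.

Two complementary complexity measures for aedeagus outlines:

* perimeter standardized by aedeagus length (complexity per unit length),
* Minkowski (box-counting) fractal dimension of the binary outline.

Box counting uses origin-anchored grids with power-of-two box sizes and an
ordinary least-squares fit of log(count) against log(size); the dimension
is the absolute slope.  Outlines are standardized to the measurement
convention of a 2100 x 2100 pixel canvas with the structure spanning 2000
pixels base to apex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.transform import resize

__all__ = [
    "OutlineImage",
    "FractalEstimate",
    "standardize_image",
    "box_count",
    "fractal_dimension",
    "perimeter_complexity",
]


@dataclass
class OutlineImage:
    """Binary raster of an outline plus pixel-scale metadata.

    ``pixels`` is a 2-D boolean array (True = foreground).  ``span`` is
    the base-to-apex extent in pixels; ``mm_per_pixel`` the optional
    physical scale.
    """

    pixels: np.ndarray
    span: int
    mm_per_pixel: float | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("outline image must be 2-D")
        if not self.pixels.any():
            raise ValueError("outline image has no foreground pixels")


@dataclass
class FractalEstimate:
    dimension: float
    sizes: np.ndarray
    counts: np.ndarray
    r2: float

    @property
    def n_scales(self) -> int:
        return len(self.sizes)


def binarize(img: np.ndarray, threshold_fraction: float = 0.5) -> np.ndarray:
    """Threshold a grayscale/boolean image at a fraction of its intensity range."""
    img = np.asarray(img)
    if img.dtype == bool:
        return img
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return img > lo  # all-equal image: empty foreground
    return img > lo + threshold_fraction * (hi - lo)


def standardize_image(
    img: np.ndarray,
    target_canvas: int = 2100,
    target_span: int = 2000,
    threshold_fraction: float = 0.5,
) -> OutlineImage:
    """Rescale an outline to the standard canvas and base-to-apex span.

    The image is binarized, cropped to its bounding box, isotropically
    scaled so the larger bounding-box extent equals ``target_span``, and
    centered on a ``target_canvas`` square.
    """
    fg = binarize(img, threshold_fraction)
    if not fg.any():
        raise ValueError("empty foreground after binarization")
    rows = np.flatnonzero(fg.any(axis=1))
    cols = np.flatnonzero(fg.any(axis=0))
    crop = fg[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    span = max(crop.shape)
    scale = target_span / span
    new_shape = (
        max(1, int(round(crop.shape[0] * scale))),
        max(1, int(round(crop.shape[1] * scale))),
    )
    scaled = resize(crop.astype(float), new_shape, order=1, anti_aliasing=scale < 1)
    scaled = scaled >= 0.5
    if not scaled.any():  # extreme downscale of a thin structure
        scaled = resize(crop.astype(float), new_shape, order=1, anti_aliasing=False) > 0
    canvas = np.zeros((target_canvas, target_canvas), dtype=bool)
    r0 = (target_canvas - scaled.shape[0]) // 2
    c0 = (target_canvas - scaled.shape[1]) // 2
    canvas[r0 : r0 + scaled.shape[0], c0 : c0 + scaled.shape[1]] = scaled
    return OutlineImage(pixels=canvas, span=target_span)


def box_count(img: OutlineImage | np.ndarray, box_sizes) -> list[tuple[int, int]]:
    """Number of occupied grid cells per box size (origin-anchored grids)."""
    fg = img.pixels if isinstance(img, OutlineImage) else np.asarray(img, dtype=bool)
    sizes = [int(s) for s in box_sizes]
    if sizes != sorted(set(sizes)) or any(s < 1 for s in sizes):
        raise ValueError("box sizes must be strictly increasing and >= 1")
    if any(s > max(fg.shape) // 2 for s in sizes) and max(sizes) > 1:
        raise ValueError("box sizes must not exceed half the canvas")
    out = []
    h, w = fg.shape
    for s in sizes:
        ph, pw = (-h) % s, (-w) % s
        padded = np.pad(fg, ((0, ph), (0, pw)))
        blocks = padded.reshape(padded.shape[0] // s, s, padded.shape[1] // s, s)
        occ = blocks.any(axis=(1, 3))
        out.append((s, int(occ.sum())))
    return out


def fractal_dimension(img: OutlineImage | np.ndarray) -> FractalEstimate:
    """Box-counting (Minkowski) dimension from a log-log OLS fit.

    Box sizes are powers of two from 2 up to canvas/4; the dimension is
    the absolute slope of log(count) on log(size).
    """
    fg = img.pixels if isinstance(img, OutlineImage) else np.asarray(img, dtype=bool)
    if not fg.any():
        raise ValueError("empty image")
    rows = np.flatnonzero(fg.any(axis=1))
    cols = np.flatnonzero(fg.any(axis=0))
    extent = max(rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1)
    if extent < 32:
        raise ValueError("foreground must span at least 32 pixels")
    max_size = max(fg.shape) // 4
    sizes = []
    s = 2
    while s <= max_size:
        sizes.append(s)
        s *= 2
    if len(sizes) < 4:
        raise ValueError("fewer than 4 usable scales")
    pairs = box_count(fg, sizes)
    sz = np.array([p[0] for p in pairs], dtype=float)
    ct = np.array([p[1] for p in pairs], dtype=float)
    fit = stats.linregress(np.log(sz), np.log(ct))
    return FractalEstimate(
        dimension=float(abs(fit.slope)),
        sizes=sz.astype(int),
        counts=ct.astype(int),
        r2=float(fit.rvalue**2),
    )


def perimeter_complexity(perimeter: float, aedeagus_length: float) -> float:
    """Perimeter standardized by aedeagus length (dimensionless)."""
    if perimeter <= 0 or aedeagus_length <= 0:
        raise ValueError("perimeter and length must be positive")
    return perimeter / aedeagus_length
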