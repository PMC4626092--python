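"""Image data model, 8-bit filter primitives, and file I/O.

All filters operate on 2-D float arrays and, by default, emulate an 8-bit
macro pipeline: after every stage the result is rounded half-up and clamped
to ``[0, 255]``.  A float mode (``eight_bit=False``) is available to study
precision loss.  Border handling is replicate padding throughout, and rank
filters use a Euclidean-disk neighborhood (all offsets with center distance
<= radius).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Micrograph",
    "FilterParams",
    "normalize_to_8bit",
    "gaussian_blur",
    "sobel_magnitude",
    "local_variance",
    "local_median",
    "subtract_saturate",
    "multiply_saturate",
    "invert8",
    "disk_offsets",
    "read_image",
    "write_image",
    "read_manifest",
]

# Sobel kernels, gradient along columns (x) and rows (y).
SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
SOBEL_Y = SOBEL_X.T


# ---------------------------------------------------------------------------
# data model


@dataclass
class Micrograph:
    """A 2-D (optionally multi-channel) intensity image.

    ``pixels`` has shape ``(H, W)`` for a single channel or ``(C, H, W)``
    for a multi-channel image; ``channels`` names each plane.  ``pixel_size``
    is micrometres per pixel (1.0 when unknown).
    """

    pixels: np.ndarray
    channels: tuple[str, ...] = ("0",)
    bit_depth: int = 8
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim == 2:
            if len(self.channels) != 1:
                raise ValueError("2-D pixels but multiple channel names")
        elif self.pixels.ndim == 3:
            if self.pixels.shape[0] != len(self.channels):
                raise ValueError(
                    f"{self.pixels.shape[0]} planes but "
                    f"{len(self.channels)} channel names"
                )
        else:
            raise ValueError("pixels must be 2-D or (C, H, W)")
        if self.pixels.size == 0:
            raise ValueError("empty image")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("non-finite intensities")
        if np.any(self.pixels < 0):
            raise ValueError("negative intensities")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[-2:]

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[0]

    def channel(self, name: str | None = None) -> np.ndarray:
        """Return one channel as a 2-D array."""
        if self.pixels.ndim == 2:
            if name is not None and name not in self.channels:
                raise KeyError(name)
            return self.pixels
        if name is None:
            raise ValueError(
                "multi-channel image: a channel name is required "
                f"(available: {', '.join(self.channels)})"
            )
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channels}"
            ) from None
        return self.pixels[idx]

    def field_area_mm2(self) -> float:
        h, w = self.shape
        return h * w * self.pixel_size**2 / 1.0e6


@dataclass
class FilterParams:
    """Parameters of the vessel-segmentation filter stack."""

    gaussian_sigma: float = 2.0
    variance_radius: int = 5
    median_radius: int = 3
    subtract_constant: float | str = "auto"
    multiply_factor: float = 255.0
    eight_bit_mode: bool = True

    def __post_init__(self) -> None:
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be > 0")
        if self.variance_radius < 1 or self.median_radius < 1:
            raise ValueError("filter radii must be >= 1")
        if self.subtract_constant != "auto" and float(self.subtract_constant) < 0:
            raise ValueError("subtract_constant must be >= 0 or 'auto'")
        if self.multiply_factor <= 0:
            raise ValueError("multiply_factor must be > 0")

    def resolve_subtract(self, img: np.ndarray) -> float:
        """Resolve the subtraction constant for a given image.

        ``"auto"`` means the sample standard deviation of the current
        image's intensities.
        """
        if self.subtract_constant == "auto":
            return float(np.std(np.asarray(img, dtype=float), ddof=1))
        return float(self.subtract_constant)


# ---------------------------------------------------------------------------
# helpers


def _round_half_up(a: np.ndarray) -> np.ndarray:
    # deterministic half-up rounding for nonnegative values
    return np.floor(np.asarray(a, dtype=float) + 0.5)


def _finish(a: np.ndarray, eight_bit: bool) -> np.ndarray:
    if eight_bit:
        return np.clip(_round_half_up(a), 0.0, 255.0)
    return a


def _as_image(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2:
        raise ValueError("expected a 2-D single-channel image")
    if a.size == 0:
        raise ValueError("empty image")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite intensities")
    return a


def disk_offsets(radius: int) -> np.ndarray:
    """Boolean footprint of the Euclidean disk of the given pixel radius."""
    r = int(radius)
    if r < 1:
        raise ValueError("radius must be >= 1")
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx) <= r * r


# ---------------------------------------------------------------------------
# filter primitives


def normalize_to_8bit(a) -> np.ndarray:
    """Linear min-max rescale to [0, 255] with half-up rounding.

    A constant image maps to all-zero (degenerate-range convention).
    """
    a = _as_image(a)
    lo = a.min()
    hi = a.max()
    if hi == lo:
        return np.zeros_like(a)
    return _round_half_up((a - lo) * (255.0 / (hi - lo)))


def gaussian_blur(a, sigma: float, eight_bit: bool = True) -> np.ndarray:
    """Gaussian convolution, kernel truncated at 3*sigma, replicate edges."""
    a = _as_image(a)
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    r = int(np.ceil(3.0 * sigma))
    x = np.arange(-r, r + 1, dtype=float)
    k = np.exp(-(x * x) / (2.0 * sigma * sigma))
    k /= k.sum()
    out = ndimage.correlate1d(a, k, axis=0, mode="nearest")
    out = ndimage.correlate1d(out, k, axis=1, mode="nearest")
    return _finish(out, eight_bit)


def sobel_magnitude(a, eight_bit: bool = True) -> np.ndarray:
    """Gradient magnitude with the standard 3x3 Sobel kernels."""
    a = _as_image(a)
    if a.shape[0] < 3 or a.shape[1] < 3:
        raise ValueError("sobel_magnitude requires at least a 3x3 image")
    gx = ndimage.correlate(a, SOBEL_X, mode="nearest")
    gy = ndimage.correlate(a, SOBEL_Y, mode="nearest")
    return _finish(np.hypot(gx, gy), eight_bit)


def local_variance(a, radius: int, eight_bit: bool = True) -> np.ndarray:
    """Population variance over the Euclidean-disk neighborhood."""
    a = _as_image(a)
    fp = disk_offsets(radius).astype(float)
    n = fp.sum()
    s = ndimage.correlate(a, fp, mode="nearest")
    s2 = ndimage.correlate(a * a, fp, mode="nearest")
    # (n*s2 - s^2)/n^2 is exact in float64 for 8-bit integer inputs
    var = (n * s2 - s * s) / (n * n)
    np.maximum(var, 0.0, out=var)
    return _finish(var, eight_bit)


def local_median(a, radius: int, eight_bit: bool = True) -> np.ndarray:
    """Median over the Euclidean-disk neighborhood.

    Even-count neighborhoods (not reachable with disk footprints, but kept
    for contract completeness) average the two central order statistics.
    """
    a = _as_image(a)
    fp = disk_offsets(radius)
    n = int(fp.sum())
    if n % 2 == 1:
        out = ndimage.median_filter(a, footprint=fp, mode="nearest")
    else:
        lo = ndimage.rank_filter(a, n // 2 - 1, footprint=fp, mode="nearest")
        hi = ndimage.rank_filter(a, n // 2, footprint=fp, mode="nearest")
        out = 0.5 * (lo + hi)
    return _finish(out, eight_bit)


def subtract_saturate(a, c: float, eight_bit: bool = True) -> np.ndarray:
    """Per-pixel max(v - c, 0)."""
    a = _as_image(a)
    if c < 0:
        raise ValueError("subtraction constant must be >= 0")
    return _finish(np.maximum(a - c, 0.0), eight_bit)


def multiply_saturate(a, factor: float, eight_bit: bool = True) -> np.ndarray:
    """Per-pixel min(v * factor, 255); factor 255 binarizes 8-bit input."""
    a = _as_image(a)
    if factor <= 0:
        raise ValueError("factor must be > 0")
    return _finish(np.minimum(a * factor, 255.0), eight_bit)


def invert8(a) -> np.ndarray:
    """Per-pixel 255 - v on an 8-bit image."""
    a = _as_image(a)
    if a.min() < 0 or a.max() > 255:
        raise ValueError("invert8 requires values in [0, 255]")
    return 255.0 - a


# ---------------------------------------------------------------------------
# I/O


def read_image(
    path: str | Path,
    channels: Sequence[str] | None = None,
    pixel_size: float = 1.0,
) -> Micrograph:
    """Read a TIFF (single or multi-page) or PNG into a :class:`Micrograph`.

    Multi-page TIFFs and ``(C, H, W)`` stacks become channels; RGB PNGs are
    read plane-per-channel.  Channel names come from ``channels`` when the
    file does not embed them.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
        if arr.ndim == 3:  # H, W, C -> C, H, W
            arr = np.moveaxis(arr, -1, 0)
    arr = np.asarray(arr)
    bit_depth = 16 if arr.dtype.itemsize >= 2 else 8
    if arr.ndim == 2:
        names = tuple(channels) if channels else ("0",)
    else:
        names = (
            tuple(channels)
            if channels
            else tuple(str(i) for i in range(arr.shape[0]))
        )
    return Micrograph(
        pixels=arr.astype(float),
        channels=names,
        bit_depth=bit_depth,
        pixel_size=pixel_size,
    )


def write_image(path: str | Path, img: Micrograph | np.ndarray) -> None:
    """Write an image as 8-bit TIFF (multi-page when multi-channel)."""
    import tifffile

    arr = img.pixels if isinstance(img, Micrograph) else np.asarray(img, float)
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    arr = np.clip(_round_half_up(arr), 0, 255).astype(np.uint8)
    kwargs = {"photometric": "minisblack"}
    tifffile.imwrite(Path(path), arr, **kwargs)


MANIFEST_COLUMNS = ("file", "animal_id", "group", "channel")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a sample manifest CSV (columns: file, animal_id, group, channel)."""
    df = pd.read_csv(path)
    missing = [c for c in ("file", "animal_id", "group") if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing required columns: {missing}")
    return df
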