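"""Grayscale radiograph I/O and intensity preprocessing.

Raw digital radiographs carry a large, exposure-dependent dynamic range.
Every downstream stage (spectral signatures, template matching) therefore
consumes images that have been linearly stretched to the full 16-bit range
and median-filtered for impulse-noise suppression:

    F_H(x, y) = round(65535 * (f(x, y) - A) / (B - A)),  A = min f, B = max f
    F_w(x, y) = median of the w x w neighbourhood of F_H,  w = 5

Optionally, contrast-limited adaptive histogram equalization (CLAHE) is
applied afterwards to flatten residual exposure variation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image
from scipy import ndimage

logger = logging.getLogger(__name__)

#: Canonical radiographic position names, in canonical (tie-break) order.
POSITIONS = ("head", "lungs", "lumbar", "pelvis", "joint", "limbs")

#: Smallest admissible image side: the default median window must fit.
MIN_SIDE = 5

FULL_RANGE_16 = 65535


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class RadiographImage:
    """A single-channel radiograph: a 2D grid of non-negative integers.

    Parameters
    ----------
    pixels
        2D integer array of shape (M, N); values in ``[0, 2**bit_depth - 1]``.
    bit_depth
        8 or 16.
    label
        Optional radiographic position name.
    source
        Optional origin path, for diagnostics.
    """

    pixels: np.ndarray
    bit_depth: int = 16
    label: Optional[str] = None
    source: Optional[str] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValidationError(f"pixels must be 2D, got shape {arr.shape}")
        if arr.size == 0:
            raise ValidationError("zero-sized raster")
        if self.bit_depth not in (8, 16):
            raise ValidationError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValidationError(f"pixels must be integer-typed, got {arr.dtype}")
        m, n = arr.shape
        if m < MIN_SIDE or n < MIN_SIDE:
            raise ValidationError(
                f"image {m}x{n} smaller than minimum {MIN_SIDE}x{MIN_SIDE}"
            )
        lo, hi = int(arr.min()), int(arr.max())
        limit = (1 << self.bit_depth) - 1
        if lo < 0 or hi > limit:
            raise ValidationError(
                f"pixel values [{lo}, {hi}] outside [0, {limit}] for {self.bit_depth}-bit"
            )
        self.pixels = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def astype_float(self) -> np.ndarray:
        return self.pixels.astype(np.float64)

    def with_pixels(self, pixels: np.ndarray, bit_depth: Optional[int] = None) -> "RadiographImage":
        return replace(
            self, pixels=pixels, bit_depth=self.bit_depth if bit_depth is None else bit_depth
        )


def _round_half_up(x: np.ndarray) -> np.ndarray:
    """Deterministic round-half-up to the nearest integer."""
    return np.floor(x + 0.5).astype(np.int64)


def read_image(path: str | Path, bit_depth_policy: str = "preserve") -> RadiographImage:
    """Read a grayscale radiograph from PNG, TIFF or DICOM.

    Multi-channel rasters are collapsed by the unweighted channel mean and
    rounded. With ``bit_depth_policy="force16"`` 8-bit inputs are rescaled by
    257 (so 255 maps to 65535) and reported as 16-bit.
    """
    if bit_depth_policy not in ("preserve", "force16"):
        raise ValidationError(f"unknown bit_depth_policy {bit_depth_policy!r}")
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if path.suffix.lower() in (".dcm", ".dicom"):
        arr, bit_depth = _read_dicom(path)
    else:
        try:
            with Image.open(path) as im:
                arr = np.asarray(im)
        except Exception as exc:  # noqa: BLE001 - surface decoder failures as I/O
            raise IOError(f"cannot decode {path}: {exc}") from exc
        if arr.ndim == 3:  # multi-channel: unweighted mean of channels
            arr = _round_half_up(arr.astype(np.float64).mean(axis=2))
        bit_depth = 8 if arr.max(initial=0) <= 255 and arr.dtype.itemsize == 1 else 16
    arr = arr.astype(np.int64)
    if bit_depth_policy == "force16" and bit_depth == 8:
        arr = arr * 257
        bit_depth = 16
    return RadiographImage(pixels=arr, bit_depth=bit_depth, source=str(path))


def _read_dicom(path: Path) -> tuple[np.ndarray, int]:
    import pydicom

    ds = pydicom.dcmread(path)
    arr = np.asarray(ds.pixel_array)
    if arr.ndim == 3:
        arr = _round_half_up(arr.astype(np.float64).mean(axis=2))
    bits = int(getattr(ds, "BitsStored", 16))
    return arr.astype(np.int64), 8 if bits <= 8 else 16


def write_image(img: RadiographImage, path: str | Path) -> None:
    """Write as 16-bit grayscale PNG (8-bit inputs are widened verbatim)."""
    arr = img.pixels.astype(np.uint16)
    Image.fromarray(arr).save(Path(path))


def stretch_histogram(img: RadiographImage) -> RadiographImage:
    """Linear histogram stretch onto the full 16-bit range.

    The minimum maps to 0, the maximum to 65535. A constant image has no
    stretch defined; it maps to all-zero with a warning.
    """
    f = img.astype_float()
    a, b = f.min(), f.max()
    if a == b:
        warnings.warn(
            "constant image: histogram stretch degenerate, returning zeros",
            RuntimeWarning,
            stacklevel=2,
        )
        out = np.zeros_like(f, dtype=np.int64)
    else:
        out = _round_half_up(FULL_RANGE_16 * (f - a) / (b - a))
    return img.with_pixels(out, bit_depth=16)


def median_filter(img: RadiographImage, w: int = 5) -> RadiographImage:
    """Median filter with a centred ``w x w`` window, edge-replicated borders."""
    if w % 2 == 0:
        raise ValidationError(f"median window must be odd, got {w}")
    m, n = img.shape
    if w > min(m, n):
        raise ValidationError(f"median window {w} exceeds image side min({m},{n})")
    out = ndimage.median_filter(img.pixels, size=w, mode="nearest")
    return img.with_pixels(out.astype(np.int64))


def apply_clahe(
    img: RadiographImage,
    clip_limit: float = 0.01,
    tiles: tuple[int, int] = (8, 8),
) -> RadiographImage:
    """Contrast-limited adaptive histogram equalization on the 16-bit grid.

    ``tiles`` is the tile grid (rows, cols) the image is divided into for the
    local histograms; ``clip_limit`` is the normalized clipping limit.
    """
    from skimage import exposure

    m, n = img.shape
    kernel = (max(1, m // tiles[0]), max(1, n // tiles[1]))
    f = img.astype_float() / FULL_RANGE_16
    eq = exposure.equalize_adapthist(f, kernel_size=kernel, clip_limit=clip_limit)
    return img.with_pixels(_round_half_up(eq * FULL_RANGE_16), bit_depth=16)


def preprocess(
    img: RadiographImage,
    apply_clahe_flag: bool = False,
    median_w: int = 5,
    clahe_clip: float = 0.01,
    clahe_tiles: tuple[int, int] = (8, 8),
) -> RadiographImage:
    """Full preprocessing chain: stretch, median filter, optional CLAHE.

    The chain is invariant to positive affine intensity maps of its input
    (gain/offset exposure changes) because the stretch renormalizes the range.
    """
    out = median_filter(stretch_histogram(img), w=median_w)
    if apply_clahe_flag:
        out = apply_clahe(out, clip_limit=clahe_clip, tiles=clahe_tiles)
    return out
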