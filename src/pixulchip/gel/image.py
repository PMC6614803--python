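"""Gel image loading and canonicalization.

Images are stored as non-negative float intensities in ``[0, 1]`` with rows
indexing migration distance.  The canonical orientation is ``wells_top``:
migration distance increases with the row index.  Orientation must be declared
by the caller — there is no auto-flip, because an ambiguous photograph flipped
silently would invert every size estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from pixulchip.errors import ValidationError

#: ITU-R BT.709 luminance weights used to collapse RGB to grayscale.
LUMA_WEIGHTS = (0.2126, 0.7152, 0.0722)

MIN_ROWS = 50
MIN_COLS = 50

ORIENTATIONS = ("wells_top", "wells_bottom")


@dataclass
class GelImage:
    """A 2-D intensity field in canonical ``wells_top`` orientation.

    Attributes
    ----------
    pixels : ndarray
        Float array of shape ``(rows, cols)`` with values in ``[0, 1]``.
        Rows index migration distance, columns lateral position.
    orientation : str
        Always ``"wells_top"`` after construction.
    bit_depth : int
        Bit depth of the source raster (8 or 16; 0 for float sources).
    source_path : str
        Provenance of the pixel data ("" for in-memory images).
    saturated_fraction : float
        Fraction of pixels at the source's full-scale value.
    """

    pixels: np.ndarray
    orientation: str = "wells_top"
    bit_depth: int = 8
    source_path: str = ""
    saturated_fraction: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValidationError(f"gel image must be 2-D, got shape {self.pixels.shape}")
        r, c = self.pixels.shape
        if r < MIN_ROWS or c < MIN_COLS:
            raise ValidationError(
                f"gel image must be at least {MIN_ROWS}x{MIN_COLS} pixels, got {r}x{c}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("gel image contains non-finite intensities")
        if np.any(self.pixels < 0):
            raise ValidationError("gel image contains negative intensities")
        if self.orientation != "wells_top":
            raise ValidationError(
                "GelImage must be canonical wells_top; use load_gel_image to flip"
            )

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]


def _to_luminance(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        return arr.astype(float)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = arr[..., :3].astype(float)
        w = np.asarray(LUMA_WEIGHTS)
        return rgb @ w
    raise ValidationError(f"unsupported raster shape {arr.shape}; expected 2-D or RGB(A)")


def _full_scale(dtype: np.dtype) -> tuple[float, int]:
    """Return (max representable value, bit depth) for a raster dtype."""
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        return float(info.max), int(info.bits)
    # float rasters are assumed pre-scaled to [0, 1]
    return 1.0, 0


def load_gel_image(path: str, orientation: str = "wells_top") -> GelImage:
    """Load a gel photograph and canonicalize it.

    RGB input is collapsed to luminance, intensities are scaled to ``[0, 1]``
    by the raster's full-scale value, and the image is flipped vertically when
    ``orientation="wells_bottom"`` so the result is always wells-top.

    Raises
    ------
    OSError
        If the file cannot be read or decoded.
    ValidationError
        If the decoded raster is smaller than 50x50 or has an unsupported
        shape, or ``orientation`` is unknown.
    """
    if orientation not in ORIENTATIONS:
        raise ValidationError(f"unknown orientation {orientation!r}; expected one of {ORIENTATIONS}")
    import imageio.v3 as iio

    try:
        raw = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read gel image {path!r}: {exc}") from exc

    full_scale, bit_depth = _full_scale(raw.dtype)
    gray = _to_luminance(raw)
    saturated = float(np.mean(gray >= full_scale)) if full_scale > 0 else 0.0
    pixels = np.clip(gray / full_scale, 0.0, None)
    if orientation == "wells_bottom":
        pixels = pixels[::-1, :]
    if saturated > 0:
        warnings.warn(
            f"{saturated:.1%} of pixels in {path!r} are saturated; "
            "quantification proceeds but in-band signal may be clipped",
            stacklevel=2,
        )
    return GelImage(
        pixels=pixels,
        orientation="wells_top",
        bit_depth=bit_depth if bit_depth else 8,
        source_path=str(path),
        saturated_fraction=saturated,
    )


def save_gel_image(img: GelImage, path: str, bit_depth: int = 16) -> None:
    """Write a gel image as an 8- or 16-bit grayscale raster."""
    import imageio.v3 as iio

    if bit_depth not in (8, 16):
        raise ValidationError(f"bit_depth must be 8 or 16, got {bit_depth}")
    scale = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    quantized = np.round(np.clip(img.pixels, 0.0, 1.0) * scale).astype(dtype)
    iio.imwrite(path, quantized)
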