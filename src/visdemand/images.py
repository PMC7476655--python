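"""Image loading and luminance preprocessing.

Frames are assumed already undistorted, white-balanced, and de-noised.
This module only decodes PNG/TIFF files, undoes the sRGB transfer
function, and collapses the linear RGB channels to a single luminance
channel on a fixed 16-bit scale, which is the substrate for all scene
metrics downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile

FULL_SCALE = 65535
#: ITU-R BT.601 luma weights, truncated to three decimals so they sum to 1.
GRAY_WEIGHTS = (0.299, 0.587, 0.114)

_SRGB_ENCODED_BREAK = 0.04045
_SRGB_LINEAR_BREAK = 0.0031308


class ImageFormatError(ValueError):
    """Raised when a decoded file has an unsupported layout."""


@dataclass
class RawColorImage:
    """H×W×3 gamma-encoded (or, after :func:`linearize_srgb`, linear) frame.

    Pixel values live on the 16-bit scale ``[0, 65535]`` regardless of the
    source bit depth; ``bit_depth`` records the depth of the decoded file.
    """

    pixels: np.ndarray
    bit_depth: int
    source_path: str = ""
    linear: bool = False

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ImageFormatError(
                f"expected H×W×3 pixel array, got shape {px.shape}"
            )
        if px.shape[0] < 3 or px.shape[1] < 3:
            raise ImageFormatError(
                f"image must be at least 3×3, got {px.shape[0]}×{px.shape[1]}"
            )
        if self.bit_depth not in (8, 16):
            raise ImageFormatError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if px.size and (px.min() < 0 or px.max() > FULL_SCALE):
            raise ImageFormatError(
                f"pixel values outside [0, {FULL_SCALE}]: "
                f"min={px.min()}, max={px.max()}"
            )
        self.pixels = px

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


@dataclass
class LinearGrayImage:
    """2-D linear-luminance raster, integer-valued on ``[0, 65535]``."""

    pixels: np.ndarray
    source_path: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ImageFormatError(f"expected 2-D pixel array, got shape {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            raise ImageFormatError(f"expected integer pixels, got dtype {px.dtype}")
        if px.size and (int(px.min()) < 0 or int(px.max()) > FULL_SCALE):
            raise ImageFormatError(
                f"pixel values outside [0, {FULL_SCALE}]: "
                f"min={px.min()}, max={px.max()}"
            )
        self.pixels = px.astype(np.uint16)

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


def load_image(path: str) -> RawColorImage:
    """Decode a PNG or TIFF file into a :class:`RawColorImage`.

    8-bit inputs are rescaled to the 16-bit range (×257); grayscale files
    are replicated to three identical channels. RGBA is accepted only when
    the alpha channel is fully opaque.
    """
    import imageio.v3 as iio

    try:
        arr = iio.imread(path)
    except OSError:
        raise
    except Exception as exc:  # decoder-specific failures → uniform I/O error
        raise OSError(f"cannot decode image file {path!r}: {exc}") from exc

    if arr.dtype == np.uint8:
        bit_depth = 8
        arr = arr.astype(np.uint16) * 257
    elif arr.dtype == np.uint16:
        bit_depth = 16
    else:
        raise ImageFormatError(
            f"unsupported sample type {arr.dtype} in {path!r}; expected 8- or 16-bit"
        )

    if arr.ndim == 2:
        arr = np.stack([arr, arr, arr], axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 1:
        arr = np.repeat(arr, 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        alpha = arr[..., 3]
        if not np.all(alpha == FULL_SCALE):
            raise ImageFormatError(
                f"RGBA image with non-opaque alpha channel in {path!r}"
            )
        arr = arr[..., :3]
    elif not (arr.ndim == 3 and arr.shape[2] == 3):
        raise ImageFormatError(
            f"unsupported channel layout {arr.shape} in {path!r}; "
            "expected 1 or 3 channels"
        )

    return RawColorImage(pixels=arr, bit_depth=bit_depth, source_path=str(path))


def _srgb_decode_unit(u: np.ndarray) -> np.ndarray:
    return np.where(
        u <= _SRGB_ENCODED_BREAK,
        u / 12.92,
        ((u + 0.055) / 1.055) ** 2.4,
    )


def _srgb_encode_unit(v: np.ndarray) -> np.ndarray:
    return np.where(
        v <= _SRGB_LINEAR_BREAK,
        v * 12.92,
        1.055 * np.power(v, 1.0 / 2.4) - 0.055,
    )


def linearize_srgb(img: RawColorImage) -> RawColorImage:
    """Undo the sRGB transfer function per channel.

    Values are mapped to the unit interval, passed through the standard
    piecewise inverse (linear below the 0.04045 breakpoint, power-2.4
    branch above), and rescaled to ``[0, 65535]``. 0 and full scale are
    exact fixed points.
    """
    unit = np.asarray(img.pixels, dtype=np.float64) / FULL_SCALE
    lin = _srgb_decode_unit(unit) * FULL_SCALE
    return RawColorImage(
        pixels=lin,
        bit_depth=img.bit_depth,
        source_path=img.source_path,
        linear=True,
    )


def srgb_encode(img: RawColorImage) -> RawColorImage:
    """Forward sRGB transfer function (inverse of :func:`linearize_srgb`)."""
    if not img.linear:
        raise ValueError("srgb_encode expects a linear image")
    unit = np.asarray(img.pixels, dtype=np.float64) / FULL_SCALE
    enc = _srgb_encode_unit(unit) * FULL_SCALE
    return RawColorImage(
        pixels=enc,
        bit_depth=img.bit_depth,
        source_path=img.source_path,
        linear=False,
    )


def to_grayscale(img: RawColorImage) -> LinearGrayImage:
    """Collapse a linear RGB frame to luminance with BT.601 weights.

    The weighted sum is rounded to the nearest integer on the 16-bit
    scale. The weights (0.299, 0.587, 0.114) sum to exactly 1, so a frame
    with all three channels equal to ``v`` maps to ``v``.
    """
    if not img.linear:
        raise ValueError("to_grayscale expects a linearized image; call linearize_srgb first")
    px = np.asarray(img.pixels, dtype=np.float64)
    wr, wg, wb = GRAY_WEIGHTS
    y = wr * px[..., 0] + wg * px[..., 1] + wb * px[..., 2]
    y = np.clip(np.rint(y), 0, FULL_SCALE).astype(np.uint16)
    return LinearGrayImage(pixels=y, source_path=img.source_path)


def prepare_luminance(path: str) -> LinearGrayImage:
    """Full preprocessing chain: decode, linearize, convert to luminance."""
    return to_grayscale(linearize_srgb(load_image(path)))


def write_gray_tiff(img: LinearGrayImage, path: str) -> None:
    """Write a :class:`LinearGrayImage` as a 16-bit grayscale TIFF."""
    tifffile.imwrite(path, img.pixels.astype(np.uint16))
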