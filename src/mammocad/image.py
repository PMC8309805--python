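"""Core image container and PNG I/O.

Intensities are kept in floating point on [0, 1] for all in-memory
processing; PNG files are written at the source bit depth (8 or 16 bit).
The coordinate convention is row-major, 0-based ``(row, col)``; shapes are
reported height x width (x channels).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image

__all__ = ["MammogramImage", "load_png", "save_png"]

_VIEWS = {"CC", "MLO"}


@dataclass
class MammogramImage:
    """A mammogram (or phantom) with optional physical and clinical metadata.

    Parameters
    ----------
    pixels
        ``(H, W)`` grayscale or ``(H, W, 3)`` RGB array of finite
        intensities, nominally on ``[0, 1]``.
    pixel_spacing_mm
        Physical size of one pixel in millimetres, if known. Required by
        any operation that reasons about lesion diameters.
    view
        Mammographic projection, ``"CC"`` or ``"MLO"``, if known.
    label
        Image-level pathology label: 0 = benign, 1 = malignant.
    image_id
        Free-form identifier (typically the source filename stem).
    """

    pixels: np.ndarray
    pixel_spacing_mm: Optional[float] = None
    view: Optional[str] = None
    label: Optional[int] = None
    image_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise ValueError(
                f"RGB image must have exactly 3 planes, got {self.pixels.shape[2]}"
            )
        if self.pixels.ndim not in (2, 3):
            raise ValueError(f"pixels must be 2-D or 3-D, got ndim={self.pixels.ndim}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")
        if self.view is not None and self.view not in _VIEWS:
            raise ValueError(f"view must be one of {sorted(_VIEWS)}, got {self.view!r}")
        if self.pixel_spacing_mm is not None and self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError("label must be 0 (benign) or 1 (malignant)")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    @property
    def is_grayscale(self) -> bool:
        return self.pixels.ndim == 2

    def with_pixels(self, pixels: np.ndarray) -> "MammogramImage":
        """Copy of this image with replaced pixel data, metadata preserved."""
        return replace(self, pixels=pixels)


def save_png(img: MammogramImage, path: str | Path, bit_depth: int = 8) -> Path:
    """Write ``img`` to a PNG at 8 or 16 bit, scaling [0, 1] to full range."""
    path = Path(path)
    if bit_depth == 8:
        arr = np.clip(np.round(img.pixels * 255.0), 0, 255).astype(np.uint8)
        pil = Image.fromarray(arr, mode="RGB" if arr.ndim == 3 else "L")
    elif bit_depth == 16:
        if not img.is_grayscale:
            raise ValueError("16-bit PNG output supports grayscale images only")
        arr = np.clip(np.round(img.pixels * 65535.0), 0, 65535).astype(np.uint16)
        pil = Image.fromarray(arr)  # PIL maps uint16 to I;16
    else:
        raise ValueError("bit_depth must be 8 or 16")
    pil.save(path)
    return path


def load_png(path: str | Path, **meta) -> MammogramImage:
    """Read a PNG into a [0, 1] float image; extra kwargs become metadata."""
    arr = np.asarray(Image.open(path))
    if arr.dtype == np.uint8:
        scale = 255.0
    else:
        scale = 65535.0
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha if present
        arr = arr[..., :3]
    return MammogramImage(arr.astype(np.float64) / scale,
                          image_id=Path(path).stem, **meta)
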