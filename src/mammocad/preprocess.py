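"""Preprocessing: DICOM ingestion, bilinear resizing and channel conversions.

The ingestion path mirrors a routine mammography workflow: read each DICOM,
preserve its integer pixel array losslessly as a PNG, and accumulate the
patient/image header fields into a metadata CSV. Resizing is plain bilinear
interpolation with half-pixel sample centers (the convention used by the
common imaging libraries' linear resamplers). Channel conversions implement
the arithmetic-mean grayscale G = (r+g+b)/3, the weighted variant
NG = r*Pr + g*Pg + b*Pb, and grayscale-to-RGB replication.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pydicom
from PIL import Image

from .image import MammogramImage

__all__ = [
    "PatientRecord",
    "GrayWeights",
    "BT601_WEIGHTS",
    "dicom_to_png",
    "resize_image",
    "rgb_to_gray_average",
    "rgb_to_gray_weighted",
    "gray_to_rgb",
]


@dataclass(frozen=True)
class PatientRecord:
    """Header fields extracted from one DICOM file."""

    patient_id: str
    source_file: str
    age: Optional[int] = None
    view: Optional[str] = None
    extra: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")


@dataclass(frozen=True)
class GrayWeights:
    """Per-channel weights for the weighted grayscale conversion.

    The three channel percentages must sum to 1. The default is the BT.601
    luma convention used by mainstream imaging libraries.
    """

    pr: float = 0.299
    pg: float = 0.587
    pb: float = 0.114

    def __post_init__(self) -> None:
        if abs(self.pr + self.pg + self.pb - 1.0) > 1e-9:
            raise ValueError(
                f"channel weights must sum to 1, got {self.pr + self.pg + self.pb!r}"
            )


BT601_WEIGHTS = GrayWeights()

_CSV_COLUMNS = ["patient_id", "age", "view", "source_file"]


def _parse_age(value) -> Optional[int]:
    # DICOM PatientAge is e.g. "048Y"
    s = str(value).strip()
    digits = "".join(ch for ch in s if ch.isdigit())
    return int(digits) if digits else None


def dicom_to_png(
    dicom_path: str | Path,
    out_dir: str | Path,
    csv_path: str | Path | None = None,
) -> Tuple[MammogramImage, PatientRecord]:
    """Convert one DICOM to a lossless PNG and log its header to a CSV.

    The stored PNG carries the raw integer pixel values unchanged (no
    window/level is applied); the returned image is scaled to [0, 1] by the
    stored bit depth. The patient record is appended to ``csv_path``
    (default ``out_dir/metadata.csv``), creating the file with a header row
    on first use.
    """
    dicom_path = Path(dicom_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ds = pydicom.dcmread(dicom_path)

    if "PixelData" not in ds:
        raise ValueError(f"{dicom_path.name}: DICOM file has no pixel data")
    photometric = str(getattr(ds, "PhotometricInterpretation", ""))
    if not photometric.startswith("MONOCHROME"):
        raise ValueError(
            f"{dicom_path.name}: unsupported photometric interpretation "
            f"{photometric!r} (expected MONOCHROME1/2)"
        )

    arr = ds.pixel_array
    bits = int(getattr(ds, "BitsStored", 8 if arr.dtype == np.uint8 else 16))
    if bits <= 8:
        pil = Image.fromarray(arr.astype(np.uint8), mode="L")
    else:
        pil = Image.fromarray(arr.astype(np.uint16))  # PIL maps uint16 to I;16
    png_path = out_dir / (dicom_path.stem + ".png")
    pil.save(png_path)

    spacing = None
    for tag in ("PixelSpacing", "ImagerPixelSpacing"):
        if tag in ds:
            spacing = float(ds[tag].value[0])
            break
    view = str(getattr(ds, "ViewPosition", "")) or None
    if view not in (None, "CC", "MLO"):
        view = None

    record = PatientRecord(
        patient_id=str(getattr(ds, "PatientID", "")),
        source_file=dicom_path.name,
        age=_parse_age(getattr(ds, "PatientAge", "")),
        view=view,
        extra={
            "Modality": str(getattr(ds, "Modality", "")),
            "StudyDate": str(getattr(ds, "StudyDate", "")),
        },
    )

    csv_path = Path(csv_path) if csv_path is not None else out_dir / "metadata.csv"
    new_file = not csv_path.exists()
    with open(csv_path, "a", newline="") as fh:
        writer = csv.writer(fh)
        if new_file:
            writer.writerow(_CSV_COLUMNS + sorted(record.extra))
        writer.writerow(
            [record.patient_id, record.age, record.view, record.source_file]
            + [record.extra[k] for k in sorted(record.extra)]
        )

    img = MammogramImage(
        arr.astype(np.float64) / float(2**bits - 1),
        pixel_spacing_mm=spacing,
        view=view,
        image_id=dicom_path.stem,
    )
    return img, record


def _bilinear_resize(a: np.ndarray, target_h: int, target_w: int) -> np.ndarray:
    """Bilinear resample with half-pixel centers (cv2 INTER_LINEAR convention)."""
    h, w = a.shape[:2]
    rows = (np.arange(target_h) + 0.5) * (h / target_h) - 0.5
    cols = (np.arange(target_w) + 0.5) * (w / target_w) - 0.5
    r0 = np.clip(np.floor(rows).astype(int), 0, h - 1)
    c0 = np.clip(np.floor(cols).astype(int), 0, w - 1)
    r1 = np.clip(r0 + 1, 0, h - 1)
    c1 = np.clip(c0 + 1, 0, w - 1)
    fr = np.clip(rows - r0, 0.0, 1.0)[:, None]
    fc = np.clip(cols - c0, 0.0, 1.0)[None, :]
    if a.ndim == 3:
        fr = fr[..., None]
        fc = fc[..., None]
    top = a[r0][:, c0] * (1 - fc) + a[r0][:, c1] * fc
    bot = a[r1][:, c0] * (1 - fc) + a[r1][:, c1] * fc
    return top * (1 - fr) + bot * fr


def resize_image(img: MammogramImage, target_w: int, target_h: int) -> MammogramImage:
    """Resize to exactly ``target_w x target_h`` with bilinear interpolation.

    When the target equals the source dimensions the pixels pass through
    unchanged. The physical pixel spacing is rescaled accordingly (using the
    width ratio; anisotropic targets lose exact physical calibration).
    """
    if target_w <= 0 or target_h <= 0:
        raise ValueError("target dimensions must be positive")
    if (target_h, target_w) == (img.height_px, img.width_px):
        return img.with_pixels(img.pixels.copy())
    out = _bilinear_resize(img.pixels, target_h, target_w)
    spacing = (
        img.pixel_spacing_mm * (img.width_px / target_w)
        if img.pixel_spacing_mm is not None
        else None
    )
    from dataclasses import replace

    return replace(img, pixels=out, pixel_spacing_mm=spacing)


def rgb_to_gray_average(img: MammogramImage) -> MammogramImage:
    """Arithmetic-mean grayscale conversion G = (r + g + b) / 3."""
    if img.is_grayscale:
        raise ValueError("image is already single-channel")
    return img.with_pixels(img.pixels.mean(axis=2))


def rgb_to_gray_weighted(
    img: MammogramImage, weights: GrayWeights = BT601_WEIGHTS
) -> MammogramImage:
    """Weighted grayscale conversion NG = r*Pr + g*Pg + b*Pb."""
    if img.is_grayscale:
        raise ValueError("image is already single-channel")
    px = img.pixels
    out = px[:, :, 0] * weights.pr + px[:, :, 1] * weights.pg + px[:, :, 2] * weights.pb
    return img.with_pixels(out)


def gray_to_rgb(img: MammogramImage) -> MammogramImage:
    """Replicate a single grayscale plane into three identical RGB planes."""
    if not img.is_grayscale:
        raise ValueError("image is already 3-channel")
    return img.with_pixels(np.repeat(img.pixels[:, :, None], 3, axis=2))
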