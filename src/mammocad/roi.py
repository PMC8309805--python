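"""Microcalcification candidate detection and ROI patch extraction.

Candidate detection is classical: a white top-hat filter with a structuring
element slightly larger than the largest expected MC (0.7 mm) suppresses
the parenchymal background, a relative threshold (mean + k*sd of the
filtered image) binarizes, and connected-component analysis yields one
candidate per bright blob with an equivalent-circle diameter in mm.
Candidates outside the 0.1-0.5 mm diameter window are discarded — deposits
larger than 0.5 mm are coarse calcifications, not the MC targets of this
pipeline. Patches are square windows centered on candidates, zero-padded at
image borders, and inherit the image-level pathology label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from skimage import measure, morphology

from .image import MammogramImage

__all__ = [
    "TranslationSpec",
    "DetectorParams",
    "Candidate",
    "RoiPatch",
    "translate_pixels",
    "detect_candidates",
    "extract_roi_patches",
]


@dataclass(frozen=True)
class TranslationSpec:
    """Integer pixel shift: ``bx`` along x (columns), ``my`` along y (rows)."""

    bx: int = 0
    my: int = 0


@dataclass(frozen=True)
class DetectorParams:
    """Tunables of the top-hat candidate detector.

    ``se_radius_mm`` sets the structuring-element radius; the default 0.45
    mm gives a footprint slightly wider than the 0.7 mm maximum MC so whole
    spots survive the top-hat. ``k_sigma`` is the relative threshold in
    standard deviations above the mean of the filtered image. The diameter
    window keeps candidates in the 0.1-0.5 mm MC range.
    """

    se_radius_mm: float = 0.45
    k_sigma: float = 3.0
    min_diameter_mm: float = 0.1
    max_diameter_mm: float = 0.5


@dataclass(frozen=True)
class Candidate:
    center: Tuple[int, int]  # (row, col)
    diameter_mm: float
    score: float  # peak top-hat response inside the component


@dataclass(frozen=True)
class RoiPatch:
    """Square sub-image centered on a candidate, carrying the image label."""

    pixels: np.ndarray
    center: Tuple[int, int]
    diameter_mm: float
    label: int
    source_image: str

    def __post_init__(self) -> None:
        if self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("ROI patch must be square")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


def translate_pixels(img: MammogramImage, t: TranslationSpec) -> MammogramImage:
    """Shift the image by (bx, my) pixels; vacated pixels are filled with 0.

    A pixel at (row, col) moves to (row + my, col + bx); content shifted
    past the border is lost and output dimensions are unchanged. Zero shift
    is an exact identity.
    """
    h, w = img.height_px, img.width_px
    if abs(t.bx) >= w or abs(t.my) >= h:
        raise ValueError("shift magnitude must be smaller than the image dimensions")
    out = np.zeros_like(img.pixels)
    sr0, sr1 = max(0, -t.my), min(h, h - t.my)
    sc0, sc1 = max(0, -t.bx), min(w, w - t.bx)
    dr0, dc0 = max(0, t.my), max(0, t.bx)
    out[dr0 : dr0 + (sr1 - sr0), dc0 : dc0 + (sc1 - sc0)] = img.pixels[
        sr0:sr1, sc0:sc1
    ]
    return img.with_pixels(out)


def detect_candidates(
    img: MammogramImage,
    spacing_mm: Optional[float] = None,
    params: DetectorParams = DetectorParams(),
) -> List[Candidate]:
    """Detect bright MC-like blobs and report centers, diameters and scores.

    The diameter is the equivalent-circle diameter of each connected
    component of the thresholded top-hat response, converted to mm via the
    pixel spacing; components outside ``[min_diameter_mm, max_diameter_mm]``
    are discarded. Requires a known pixel spacing (from the argument or the
    image), since the diameter filter is meaningless without it.
    """
    if not img.is_grayscale:
        raise ValueError("detector requires a single-plane image")
    spacing = spacing_mm if spacing_mm is not None else img.pixel_spacing_mm
    if spacing is None:
        raise ValueError("pixel spacing is unknown; the diameter filter is undefined")

    se_radius_px = max(1, int(math.ceil(params.se_radius_mm / spacing)))
    tophat = morphology.white_tophat(img.pixels, morphology.disk(se_radius_px))
    thr = tophat.mean() + params.k_sigma * tophat.std()
    mask = tophat > thr
    labels = measure.label(mask, connectivity=2)

    out: List[Candidate] = []
    for region in measure.regionprops(labels, intensity_image=tophat):
        diameter = region.equivalent_diameter_area * spacing
        if not (params.min_diameter_mm <= diameter <= params.max_diameter_mm):
            continue
        r, c = region.centroid
        out.append(
            Candidate(
                center=(int(round(r)), int(round(c))),
                diameter_mm=float(diameter),
                score=float(region.intensity_max),
            )
        )
    out.sort(key=lambda cand: -cand.score)
    return out


def extract_roi_patches(
    img: MammogramImage,
    candidates: Sequence[Candidate],
    patch_px: int = 32,
    label: Optional[int] = None,
) -> List[RoiPatch]:
    """Cut a ``patch_px x patch_px`` window around each candidate.

    ``patch_px`` must be even and no larger than the image; windows are
    placed so that patch index ``patch_px // 2`` lands on the candidate
    center, and out-of-image regions are zero-padded. Each patch carries the
    image-level label (pass ``label`` to override the image's own).
    """
    if patch_px % 2 != 0:
        raise ValueError("patch_px must be even")
    if patch_px > min(img.height_px, img.width_px):
        raise ValueError("patch_px exceeds the image dimensions")
    lab = label if label is not None else img.label
    if lab is None:
        raise ValueError("no label available for the patches")
    half = patch_px // 2
    patches: List[RoiPatch] = []
    for cand in candidates:
        r, c = cand.center
        patch = np.zeros((patch_px, patch_px), dtype=img.pixels.dtype)
        r0, r1 = r - half, r + half
        c0, c1 = c - half, c + half
        sr0, sr1 = max(0, r0), min(img.height_px, r1)
        sc0, sc1 = max(0, c0), min(img.width_px, c1)
        if sr0 < sr1 and sc0 < sc1:
            patch[sr0 - r0 : sr1 - r0, sc0 - c0 : sc1 - c0] = img.pixels[
                sr0:sr1, sc0:sc1
            ]
        patches.append(
            RoiPatch(
                pixels=patch,
                center=(r, c),
                diameter_mm=cand.diameter_mm,
                label=lab,
                source_image=img.image_id or "",
            )
        )
    return patches
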