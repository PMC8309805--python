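"""Offline dataset inflation by rotation and flips.

Each source image yields the original plus one image per rotation angle
(default 45, 90, 180 and 360 degrees — the full-turn copy is kept as a
distinct output on purpose, so one source inflates to exactly five images).
Rotation expands the canvas to the full rotated bounding box (no corner
cropping), fills vacated background with 0, and resizes back to the target
frame. Labels are inherited from the source image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .image import MammogramImage
from .preprocess import resize_image

__all__ = ["AugmentPlan", "rotate_keep_frame", "augment_dataset"]

DEFAULT_ANGLES = (45.0, 90.0, 180.0, 360.0)


@dataclass(frozen=True)
class AugmentPlan:
    """Offline augmentation recipe.

    ``target_w``/``target_h`` of ``None`` means "keep each source image's
    own dimensions".
    """

    angles_deg: Tuple[float, ...] = DEFAULT_ANGLES
    include_original: bool = True
    hflip: bool = False
    vflip: bool = False
    target_w: Optional[int] = None
    target_h: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.angles_deg and not (self.include_original or self.hflip or self.vflip):
            raise ValueError("plan produces no output images")

    @property
    def outputs_per_image(self) -> int:
        return (
            int(self.include_original)
            + len(self.angles_deg)
            + int(self.hflip)
            + int(self.vflip)
        )


def rotate_keep_frame(
    img: MammogramImage,
    angle_deg: float,
    target_w: Optional[int] = None,
    target_h: Optional[int] = None,
) -> MammogramImage:
    """Rotate about the image center, fitting the full extent in the frame.

    The rotated bounding box is computed first (so no corners are cropped),
    vacated pixels are filled with 0, and the result is resized to
    ``target_w x target_h`` (defaults: the source dimensions) with bilinear
    interpolation.
    """
    if not np.isfinite(angle_deg):
        raise ValueError("angle must be finite")
    target_w = img.width_px if target_w is None else target_w
    target_h = img.height_px if target_h is None else target_h
    # positive angles rotate counterclockwise as displayed (origin top-left),
    # so 90 degrees agrees with np.rot90(k=1)
    rotated = ndimage.rotate(
        img.pixels,
        float(angle_deg),
        axes=(1, 0),
        reshape=True,
        order=1,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    out = img.with_pixels(np.clip(rotated, 0.0, 1.0))
    return resize_image(out, target_w, target_h)


def augment_dataset(
    images: Sequence[MammogramImage],
    plan: AugmentPlan = AugmentPlan(),
) -> Tuple[List[MammogramImage], List[Tuple[str, str]]]:
    """Inflate a labeled collection per ``plan``.

    Returns the augmented images plus a manifest of ``(source_id,
    transform)`` pairs, one per output, in output order. With the default
    plan every input yields five outputs (original + four rotations) and
    class proportions are therefore unchanged.
    """
    out: List[MammogramImage] = []
    manifest: List[Tuple[str, str]] = []
    for idx, img in enumerate(images):
        src = img.image_id or f"image_{idx:05d}"
        tw = plan.target_w or img.width_px
        th = plan.target_h or img.height_px
        if plan.include_original:
            out.append(resize_image(img, tw, th))
            manifest.append((src, "original"))
        for ang in plan.angles_deg:
            out.append(rotate_keep_frame(img, ang, tw, th))
            manifest.append((src, f"rot{ang:g}"))
        if plan.hflip:
            out.append(resize_image(img.with_pixels(img.pixels[:, ::-1].copy()), tw, th))
            manifest.append((src, "hflip"))
        if plan.vflip:
            out.append(resize_image(img.with_pixels(img.pixels[::-1].copy()), tw, th))
            manifest.append((src, "vflip"))
    return out, manifest
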