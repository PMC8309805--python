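"""Resize, channel conversions, and five-fold rotation augmentation.

Shows the preprocessing contract (bilinear resize to 320 x 240, grayscale /
RGB conversions) and the offline augmentation arithmetic: each source image
yields the original plus rotations by 45, 90, 180 and 360 degrees, so a
cohort inflates exactly five-fold with class proportions unchanged.
"""

import numpy as np

from mammocad import (
    MammogramImage,
    augment_dataset,
    gray_to_rgb,
    resize_image,
    rgb_to_gray_average,
)

rng = np.random.default_rng(0)

# resize a high-resolution mammogram-sized image down to the network frame
big = MammogramImage(rng.random((2047, 4096)), pixel_spacing_mm=0.07)
small = resize_image(big, target_w=320, target_h=240)
print(f"resized {big.height_px}x{big.width_px} -> {small.height_px}x{small.width_px} "
      f"(spacing now {small.pixel_spacing_mm:.3f} mm/px)")

# grayscale -> RGB -> grayscale is lossless
rgb = gray_to_rgb(small)
back = rgb_to_gray_average(rgb)
print("gray -> rgb -> gray max error:", np.abs(back.pixels - small.pixels).max())

# augmentation arithmetic on a toy cohort: 5 benign + 2 malignant
cohort = [MammogramImage(rng.random((24, 32)), label=0) for _ in range(5)]
cohort += [MammogramImage(rng.random((24, 32)), label=1) for _ in range(2)]
out, manifest = augment_dataset(cohort)
labels = [img.label for img in out]
print(f"{len(cohort)} inputs -> {len(out)} outputs "
      f"({labels.count(0)} benign, {labels.count(1)} malignant)")
print("transforms per source:", [t for _, t in manifest[:5]])
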