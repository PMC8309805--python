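"""Synthetic mammogram phantoms with ground-truth microcalcification annotations.

A phantom is a breast-like grayscale background (a low-frequency smoothed
noise field standing in for parenchymal texture) carrying bright spots that
emulate microcalcifications (MCs): calcium deposits of 0.1-0.7 mm diameter.
The spatial arrangement of the spots follows one of four archetypes observed
clinically — ``clustered`` and ``segmental`` distributions indicate
malignancy, ``regional`` and ``diffuse`` distributions indicate benignity —
so every phantom comes with an unambiguous class label derived purely from
its archetype.

Spots are rendered as Gaussian-profile disks truncated at the nominal
radius, with the Gaussian sigma chosen so the full width at half maximum
equals the nominal diameter; thresholding a noise-free phantom at half peak
therefore recovers the annotated diameter, which is what the detector tests
exploit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .image import MammogramImage, save_png

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "MALIGNANT_ARCHETYPES",
    "BENIGN_ARCHETYPES",
    "archetype_label",
    "render_spots",
    "generate_phantom",
    "generate_dataset",
    "save_dataset",
]

MALIGNANT_ARCHETYPES = ("clustered", "segmental")
BENIGN_ARCHETYPES = ("regional", "diffuse", "none")
_ALL_ARCHETYPES = MALIGNANT_ARCHETYPES + BENIGN_ARCHETYPES

#: FWHM of a Gaussian = 2 sqrt(2 ln 2) sigma
_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


def archetype_label(archetype: str) -> int:
    """Class label implied by a spot-distribution archetype.

    Clustered and segmental distributions are malignant (1); regional,
    diffuse and spot-free images are benign (0).
    """
    if archetype in MALIGNANT_ARCHETYPES:
        return 1
    if archetype in BENIGN_ARCHETYPES:
        return 0
    raise ValueError(f"unknown archetype {archetype!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic mammogram.

    Defaults render a 320x240 px field at 0.1 mm/px (a 32x24 mm breast
    region) carrying 12 spots of 0.2-0.5 mm diameter at 0.5 contrast over a
    0.35 background with gentle parenchyma-like texture.
    """

    width_px: int = 320
    height_px: int = 240
    pixel_spacing_mm: float = 0.1
    n_spots: int = 12
    diameter_range_mm: Tuple[float, float] = (0.2, 0.5)
    archetype: str = "clustered"
    spot_contrast: float = 0.5
    noise_sd: float = 0.01
    background_level: float = 0.35
    seed: int = 0
    # texture of the parenchymal background field
    texture_amplitude: float = 0.04
    texture_scale_mm: float = 2.0
    # archetype geometry (mm); the clinical literature bounds a "cluster"
    # at roughly a 5 mm radius, a "regional" spread at ~20 mm
    cluster_radius_mm: float = 5.0
    segment_length_mm: float = 15.0
    segment_jitter_mm: float = 0.5
    regional_extent_mm: float = 20.0
    min_separation_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if self.n_spots < 0:
            raise ValueError("n_spots must be non-negative")
        lo, hi = self.diameter_range_mm
        if not (0.1 <= lo <= hi <= 0.7):
            raise ValueError(
                "diameter_range_mm must lie within the 0.1-0.7 mm MC span"
            )
        if self.archetype not in _ALL_ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if not (0.0 < self.spot_contrast <= 1.0):
            raise ValueError("spot_contrast must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0.0 <= self.background_level <= 1.0):
            raise ValueError("background_level must be in [0, 1]")
        if self.archetype != "none" and self.n_spots > 0:
            min_radius_px = lo / (2.0 * self.pixel_spacing_mm)
            if min_radius_px < 0.5:
                raise ValueError(
                    f"smallest spot radius {min_radius_px:.2f} px is below half a "
                    f"pixel at {self.pixel_spacing_mm} mm/px; spots would be "
                    "sub-resolution"
                )


@dataclass(frozen=True)
class GroundTruth:
    """Annotation of every rendered spot plus the image-level label."""

    spot_centers: Tuple[Tuple[int, int], ...]  # (row, col) pixel coordinates
    spot_diameters_mm: Tuple[float, ...]
    archetype: str
    class_label: int

    def __post_init__(self) -> None:
        if len(self.spot_centers) != len(self.spot_diameters_mm):
            raise ValueError("centers and diameters must have equal length")
        if self.class_label != archetype_label(self.archetype):
            raise ValueError(
                f"class_label {self.class_label} inconsistent with archetype "
                f"{self.archetype!r}"
            )

    @property
    def n_spots(self) -> int:
        return len(self.spot_centers)


def render_spots(
    canvas: np.ndarray,
    centers: Sequence[Tuple[int, int]],
    diameters_px: Sequence[float],
    contrast: float,
) -> np.ndarray:
    """Additively render Gaussian-profile spots onto ``canvas`` (in place).

    Each spot has FWHM equal to its nominal diameter and is truncated at the
    nominal radius, so its support is exactly ``diameter_px`` wide and the
    intensity at the support edge is half the peak. Overlapping spots
    combine by maximum so each annotated center stays a local maximum.

    This renderer accepts arbitrary diameters (it is also used to draw
    out-of-range distractor spots in tests); :class:`PhantomSpec` enforces
    the physiological 0.1-0.7 mm span for generated phantoms.
    """
    h, w = canvas.shape
    layer = np.zeros_like(canvas)
    for (r0, c0), d in zip(centers, diameters_px):
        radius = d / 2.0
        sigma = d / _FWHM_FACTOR
        lo_r = max(0, int(math.floor(r0 - radius - 1)))
        hi_r = min(h, int(math.ceil(r0 + radius + 2)))
        lo_c = max(0, int(math.floor(c0 - radius - 1)))
        hi_c = min(w, int(math.ceil(c0 + radius + 2)))
        if lo_r >= hi_r or lo_c >= hi_c:
            continue
        rr, cc = np.meshgrid(
            np.arange(lo_r, hi_r), np.arange(lo_c, hi_c), indexing="ij"
        )
        dist2 = (rr - r0) ** 2 + (cc - c0) ** 2
        profile = contrast * np.exp(-dist2 / (2.0 * sigma**2))
        profile[dist2 > radius**2] = 0.0
        np.maximum(
            layer[lo_r:hi_r, lo_c:hi_c], profile, out=layer[lo_r:hi_r, lo_c:hi_c]
        )
    canvas += layer
    return canvas


def _place_centers(spec: PhantomSpec, rng: np.random.Generator) -> List[Tuple[int, int]]:
    """Draw integer spot centers following the archetype geometry."""
    h, w, sp = spec.height_px, spec.width_px, spec.pixel_spacing_mm
    margin = max(1.0, spec.diameter_range_mm[1] / sp)  # keep spots inside
    min_sep = spec.min_separation_mm / sp

    def _in_bounds(r: float, c: float) -> bool:
        return margin <= r < h - margin and margin <= c < w - margin

    def _uniform_box(lo_r, hi_r, lo_c, hi_c):
        return rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c)

    if spec.archetype == "clustered":
        rad = spec.cluster_radius_mm / sp
        ctr_r = rng.uniform(margin + rad, h - margin - rad)
        ctr_c = rng.uniform(margin + rad, w - margin - rad)

        def _draw():
            ang = rng.uniform(0, 2 * math.pi)
            rho = rad * math.sqrt(rng.uniform())
            return ctr_r + rho * math.sin(ang), ctr_c + rho * math.cos(ang)

    elif spec.archetype == "segmental":
        seg = spec.segment_length_mm / sp
        jit = spec.segment_jitter_mm / sp
        ang = rng.uniform(0, math.pi)
        dr, dc = math.sin(ang), math.cos(ang)
        pad = margin + seg / 2 + 3 * jit
        mid_r = rng.uniform(pad, h - pad) if h > 2 * pad else h / 2
        mid_c = rng.uniform(pad, w - pad) if w > 2 * pad else w / 2

        def _draw():
            t = rng.uniform(-seg / 2, seg / 2)
            return (
                mid_r + t * dr + rng.normal(0, jit),
                mid_c + t * dc + rng.normal(0, jit),
            )

    elif spec.archetype == "regional":
        rad = spec.regional_extent_mm / (2.0 * sp)
        ctr_r = rng.uniform(margin + rad, h - margin - rad) if h > 2 * (margin + rad) else h / 2
        ctr_c = rng.uniform(margin + rad, w - margin - rad) if w > 2 * (margin + rad) else w / 2

        def _draw():
            return _uniform_box(
                max(margin, ctr_r - rad), min(h - margin, ctr_r + rad),
                max(margin, ctr_c - rad), min(w - margin, ctr_c + rad),
            )

    else:  # diffuse: uniform over the whole field
        def _draw():
            return _uniform_box(margin, h - margin, margin, w - margin)

    centers: List[Tuple[int, int]] = []
    attempts = 0
    while len(centers) < spec.n_spots and attempts < 500 * max(1, spec.n_spots):
        attempts += 1
        r, c = _draw()
        if not _in_bounds(r, c):
            continue
        ri, ci = int(round(r)), int(round(c))
        if any((ri - r2) ** 2 + (ci - c2) ** 2 < min_sep**2 for r2, c2 in centers):
            continue
        centers.append((ri, ci))
    return centers


def generate_phantom(spec: PhantomSpec) -> Tuple[MammogramImage, GroundTruth]:
    """Render one phantom and its ground truth.

    The output image is ``height_px x width_px`` with intensities clipped to
    [0, 1]; identical specs (including seed) give bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px

    # Parenchyma-like background: smoothed white noise, renormalized so its
    # standard deviation equals texture_amplitude regardless of scale.
    canvas = np.full((h, w), float(spec.background_level))
    if spec.texture_amplitude > 0:
        field = rng.normal(size=(h, w))
        field = gaussian_filter(field, sigma=spec.texture_scale_mm / spec.pixel_spacing_mm)
        sd = field.std()
        if sd > 0:
            canvas += field * (spec.texture_amplitude / sd)

    if spec.archetype == "none" or spec.n_spots == 0:
        centers: List[Tuple[int, int]] = []
        diameters: List[float] = []
    else:
        centers = _place_centers(spec, rng)
        lo, hi = spec.diameter_range_mm
        diameters = [float(rng.uniform(lo, hi)) for _ in centers]
        render_spots(
            canvas,
            centers,
            [d / spec.pixel_spacing_mm for d in diameters],
            spec.spot_contrast,
        )

    if spec.noise_sd > 0:
        canvas += rng.normal(0.0, spec.noise_sd, size=(h, w))
    np.clip(canvas, 0.0, 1.0, out=canvas)

    label = archetype_label(spec.archetype)
    gt = GroundTruth(
        spot_centers=tuple(centers),
        spot_diameters_mm=tuple(diameters),
        archetype=spec.archetype,
        class_label=label,
    )
    img = MammogramImage(
        canvas,
        pixel_spacing_mm=spec.pixel_spacing_mm,
        label=label,
        image_id=f"phantom_{spec.archetype}_{spec.seed}",
    )
    return img, gt


def generate_dataset(
    n_benign: int,
    n_malignant: int,
    base_spec: PhantomSpec = PhantomSpec(),
    seed: int = 0,
) -> List[Tuple[MammogramImage, GroundTruth]]:
    """Generate a labeled phantom collection.

    Benign images cycle through the regional and diffuse archetypes,
    malignant ones through clustered and segmental, so both classes contain
    spots and the classes differ only in spot arrangement. Per-image seeds
    and spot counts are derived deterministically from ``seed``.
    """
    if n_benign < 0 or n_malignant < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    out: List[Tuple[MammogramImage, GroundTruth]] = []
    plan = [("regional", "diffuse")[i % 2] for i in range(n_benign)]
    plan += [("clustered", "segmental")[i % 2] for i in range(n_malignant)]
    for arche in plan:
        child_seed = int(rng.integers(0, 2**31 - 1))
        n_spots = int(rng.integers(max(3, base_spec.n_spots - 4),
                                   base_spec.n_spots + 5))
        spec = replace(base_spec, archetype=arche, seed=child_seed, n_spots=n_spots)
        out.append(generate_phantom(spec))
    return out


def save_dataset(
    dataset: Sequence[Tuple[MammogramImage, GroundTruth]],
    out_dir: str | Path,
) -> pd.DataFrame:
    """Write PNGs, a manifest CSV and a per-image ground-truth CSV.

    Returns the manifest (columns: filename, label, archetype, n_spots, seed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    gt_rows = []
    for i, (img, gt) in enumerate(dataset):
        fname = f"phantom_{i:05d}.png"
        save_png(img, out_dir / fname, bit_depth=16)
        rows.append(
            {
                "filename": fname,
                "label": gt.class_label,
                "archetype": gt.archetype,
                "n_spots": gt.n_spots,
                "seed": img.image_id.rsplit("_", 1)[-1] if img.image_id else "",
            }
        )
        for (r, c), d in zip(gt.spot_centers, gt.spot_diameters_mm):
            gt_rows.append(
                {"filename": fname, "row": r, "col": c, "diameter_mm": d}
            )
    manifest = pd.DataFrame(
        rows, columns=["filename", "label", "archetype", "n_spots", "seed"]
    )
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    pd.DataFrame(gt_rows, columns=["filename", "row", "col", "diameter_mm"]).to_csv(
        out_dir / "ground_truth.csv", index=False
    )
    return manifest
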