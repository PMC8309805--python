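"""Generate synthetic mammogram phantoms with ground-truth annotations.

Builds a tiny labeled cohort of breast-like images carrying bright
microcalcification (MC) spots in the four clinical distribution archetypes,
then writes PNGs plus manifest/ground-truth CSVs.
"""

from pathlib import Path

from mammocad import PhantomSpec, generate_dataset, generate_phantom, save_dataset

# one phantom, inspected by hand
img, gt = generate_phantom(PhantomSpec(archetype="clustered", n_spots=8, seed=5))
print(f"phantom: {img.height_px}x{img.width_px} px at {img.pixel_spacing_mm} mm/px")
print(f"archetype {gt.archetype!r} -> class label {gt.class_label} (1 = malignant)")
print(f"{gt.n_spots} spots, diameters "
      f"{min(gt.spot_diameters_mm):.2f}-{max(gt.spot_diameters_mm):.2f} mm")

# a small balanced cohort on disk
out_dir = Path("scratch/phantoms")
dataset = generate_dataset(n_benign=6, n_malignant=4, seed=42)
manifest = save_dataset(dataset, out_dir)
print(f"\nwrote {len(manifest)} phantoms to {out_dir}/ with manifest:")
print(manifest.to_string(index=False))
# Labels follow the archetype rule: clustered/segmental arrangements are
# malignant (1), regional/diffuse are benign (0).
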