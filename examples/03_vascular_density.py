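"""Segment lectin-labelled vessels and quantify density per wall zone.

A high-resolution wall patch carries 250/400/600 µm bands seeded with
tubular vessels (< 10 µm lumen) at the volume fractions reported for a
vehicle-treated infarcted LV: ~7 % (infarct), ~15.6 % (border) and
~21.9 % (remote).  The Frangi-type vesselness filter plus hysteresis
thresholding recovers the per-zone densities.
"""

from cardiomorph import (
    generate_wall_patch,
    infarct_wall_patch_spec,
    segment_vessels,
    vesselness,
    zone_vascular_density,
)

spec = infarct_wall_patch_spec(seed=3)  # designed fractions 7 / 15.6 / 21.9 %
bundle = generate_wall_patch(spec)

vmap = vesselness(bundle.vessel_image, scales_um=(2.0, 3.5, 5.0))
vessels = segment_vessels(vmap, bundle.truth_tissue)  # Otsu + hysteresis
result = zone_vascular_density(vessels, bundle.truth_zones, bundle.image.spacing_um)

dice = (
    2 * (vessels & bundle.truth_vessels).sum()
    / (vessels.sum() + bundle.truth_vessels.sum())
)
print(f"vessel segmentation Dice vs ground truth: {dice:.3f}")
print("vascular density (% of zone tissue volume):")
for zone, designed in zip(("infarct", "border", "remote"), (7.0, 15.6, 21.9)):
    print(f"  {zone:8s}: {result.density_pct[zone]:5.2f} %  (designed {designed} %)")
print(f"whole-wall density: {result.whole_wall_density_pct:.2f} %")
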