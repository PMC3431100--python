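"""Segment a synthetic pendant breast into fat and gland, three ways.

Builds a pendant-breast phantom with 35% glandular tissue, renders its CT
attenuation volume, strips the skin, and compares the three histogram
thresholds: whole-breast minimum, per-slice cross-point, per-slice 95%
purity.
"""

import mibiquant as mq

spec = mq.PhantomSpec(voxel_mm=1.0, radius_cm=4.0, length_cm=5.0,
                      glandular_fraction=0.35, seed=7)
labels = mq.make_phantom(spec)
ct = mq.ct_from_labels(labels, spec)
mask = mq.strip_skin(ct, skin_peel_mm=2.0)

truth = ((labels.grid == 2) & mask.mask).sum() / mask.n_voxels
print(f"programmed glandular fraction inside the analysed breast: "
      f"{truth:.3f}")

for method, scope in [("minimum", "global"), ("crosspoint", "per_slice"),
                      ("purity95", "per_slice")]:
    tm = mq.segment_volume(ct, mask, method=method, scope=scope,
                           min_slice_voxels=300)
    print(f"{method:>10} ({scope:>9}): gland fraction "
          f"{tm.gland_fraction():.3f}")

# Each method should land within a couple of percentage points of the
# programmed fraction; the per-slice methods additionally absorb any
# object-size-dependent shift of the attenuation values.
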