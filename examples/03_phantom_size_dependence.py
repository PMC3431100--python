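"""Centroid-vs-size validation on uniform cylinder and cone phantoms.

Reconstructed attenuation values can carry a residual dependence on object
size.  A uniform cylinder (constant radius) should show a flat per-slice
fitted centroid; a cone (radius shrinking along the axis) exposes the
programmed radius-dependent shift, which the analysis recovers as the
slope of centroid vs slice equivalent radius.
"""

from dataclasses import replace

from scipy import stats

import mibiquant as mq

base = mq.PhantomSpec(shape="cylinder", radius_cm=5.0, length_cm=8.0,
                      voxel_mm=1.5, glandular_fraction=0.0,
                      radial_shift_slope=0.01, noise_sd=0.002, seed=3)

cyl = mq.ct_from_labels(mq.make_phantom(base), base)
series = mq.centroid_vs_size(cyl, "cylinder")
reg = stats.linregress(series.table["slice_index"],
                       series.table["centroid"])
print(f"cylinder: centroid trend along axis {reg.slope:+.2e} per slice "
      f"({abs(reg.slope) / reg.stderr:.2f} SE) -> flat, as expected")

cone_spec = replace(base, shape="cone")
cone = mq.ct_from_labels(mq.make_phantom(cone_spec), cone_spec)
s = mq.centroid_vs_size(cone, "cone", min_slice_voxels=100)
print(f"cone    : centroid-vs-radius slope {s.slope:.4f} /cm "
      f"(programmed {cone_spec.radial_shift_slope:.4f} /cm)")
# The recovered slope quantifies the size dependence that motivates the
# per-slice segmentation thresholds.
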