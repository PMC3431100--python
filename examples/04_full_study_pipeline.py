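"""End-to-end single-subject study: CT segmentation, fiducial registration,
SPECT quantification, per-tissue report, cohort table.

Simulates one subject (coregistered CT + SPECT of a pendant breast),
segments the CT, registers the masks onto the SPECT grid via fiducials,
corrects the SPECT counts to uCi/mL, and prints the per-tissue
concentration table.
"""

import numpy as np

import mibiquant as mq

spec = mq.PhantomSpec(voxel_mm=1.0, radius_cm=4.0, length_cm=5.0,
                      glandular_fraction=0.35, seed=42)
labels = mq.make_phantom(spec)
meta = mq.AcquisitionMeta(injection_time=0.0, scan_reference_time=0.5,
                          calibration_factor=1.4)

# CT side: render, strip skin, truncate artifact-prone end slices, segment
ct = mq.ct_from_labels(labels, spec)
mask = mq.strip_skin(ct, skin_peel_mm=2.0)
n_ant, n_post = mq.default_truncation(mask)
mask = mq.truncate_axial(mask, n_ant, n_post)
seg = {m: mq.segment_volume(ct, mask, m, s, min_slice_voxels=300)
       for m, s in [("minimum", "global"), ("crosspoint", "per_slice"),
                    ("purity95", "per_slice")]}

# SPECT side: simulate the two energy windows and correct to uCi/mL
photopeak, scatter = mq.spect_from_labels(labels, spec, meta)
conc, spect_mask, log = mq.quantify_concentration(photopeak, scatter, meta)
print(f"SPECT corrections: {log['subtracted_counts']:.0f} scatter counts "
      f"removed, mean Chang factor {log['mean_chang_factor']:.2f}")

# coregistration: the CT and SPECT frames differ by a rigid transform
truth = mq.RigidTransform.from_euler_z(0.0, (0.0, 0.0, 0.0))
ct_fids, spect_fids = mq.place_fiducials(labels, 6, truth, seed=1)
transform = mq.estimate_rigid(ct_fids, spect_fids)
print(f"registration FRE: {transform.fre_mm:.2e} mm")

target = mq.VoxelGrid(np.zeros(conc.shape), conc.spacing, conc.origin)
masks_sp = {m: mq.resample_mask(tm, transform, target)
            for m, tm in seg.items()}

report = mq.tissue_stats(conc, masks_sp, spect_mask, subject_id="synthetic")
summary = mq.aggregate_cohort([report])
df = mq.render_table(summary, [report])
print()
print(df.round(3).to_string(index=False))
# Equal fat and gland activity were programmed (0.10 uCi/mL each): the
# adipose and glandular columns should agree within the low-count noise.
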