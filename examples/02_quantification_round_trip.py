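"""SPECT correction chain round trip on a known activity distribution.

Simulates photopeak and scatter-window count volumes from a breast phantom
filled uniformly with 0.10 uCi/mL of Tc-99m sestamibi, then runs the full
correction chain (dual-energy-window scatter subtraction, first-order Chang
attenuation correction, calibration, decay correction) and compares the
recovered concentration with the programmed one.
"""

import numpy as np

import mibiquant as mq
from mibiquant.grid import BreastMask
from mibiquant.phantoms import _resample_nearest, activity_from_labels

spec = mq.PhantomSpec(voxel_mm=1.0, radius_cm=4.0, length_cm=5.0,
                      glandular_fraction=0.35, noise_sd=0.0,
                      radial_shift_slope=0.0, seed=11)
labels = mq.make_phantom(spec)
meta = mq.AcquisitionMeta(injection_time=0.0, scan_reference_time=0.5,
                          calibration_factor=1.4)

support = _resample_nearest(activity_from_labels(labels, spec),
                            2.5).values > 0
voi = BreastMask(support, (2.5, 2.5, 2.5), provenance="attenuation_mask")

# expectation mode: no Poisson noise, so the chain should invert exactly
pp, sc = mq.spect_from_labels(labels, spec, meta, expectation=True)
conc, _, log = mq.quantify_concentration(pp, sc, meta, mask=voi)
print(f"programmed concentration : 0.100 uCi/mL")
print(f"recovered  (expectation) : {conc.values[support].mean():.4f} uCi/mL")
print(f"mean Chang factor        : {log['mean_chang_factor']:.3f}")

# one Poisson realisation: voxelwise noisy (most voxels record 0 counts),
# but the whole-breast mean remains accurate
pp, sc = mq.spect_from_labels(labels, spec, meta)
conc, _, _ = mq.quantify_concentration(pp, sc, meta, mask=voi)
vals = conc.values[support]
print(f"recovered  (one Poisson) : {vals.mean():.4f} uCi/mL "
      f"(voxel std {vals.std():.3f}, "
      f"{(pp.values[support] == 0).mean():.0%} of voxels saw 0 counts)")
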