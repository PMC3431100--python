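"""Shared synthetic-phantom fixtures.

Phantoms are generated at 1 mm voxels (coarser than the scanner's 0.508 mm
CT grid) to keep the suite fast; every quantity tested is resolution-
independent or compared against ground truth computed on the same grid.
"""

import numpy as np
import pytest

import mibiquant as mq


@pytest.fixture(scope="session")
def breast_spec():
    return mq.PhantomSpec(voxel_mm=1.0, radius_cm=4.0, length_cm=5.0,
                          glandular_fraction=0.3, seed=7)


@pytest.fixture(scope="session")
def breast_labels(breast_spec):
    return mq.make_phantom(breast_spec)


@pytest.fixture(scope="session")
def breast_ct(breast_labels, breast_spec):
    return mq.ct_from_labels(breast_labels, breast_spec)


@pytest.fixture(scope="session")
def breast_mask(breast_ct):
    return mq.strip_skin(breast_ct, skin_peel_mm=2.0)


@pytest.fixture(scope="session")
def meta():
    # ~1.4 cps per uCi: a realistic CZT breast-camera sensitivity; at
    # ~0.1 uCi/mL it puts most SPECT voxels in the zero-count regime
    return mq.AcquisitionMeta(injection_time=0.0, scan_reference_time=0.5,
                              calibration_factor=1.4)


@pytest.fixture(scope="session")
def noiseless_spec():
    return mq.PhantomSpec(voxel_mm=1.0, radius_cm=4.0, length_cm=5.0,
                          glandular_fraction=0.35, radial_shift_slope=0.0,
                          noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def noiseless_labels(noiseless_spec):
    return mq.make_phantom(noiseless_spec)
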