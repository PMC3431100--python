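"""CT preprocessing: skin stripping and end-slice truncation.

The skin is denser than fat, so leaving it in the histogram inflates the
gland component; the most anterior (nipple) and posterior (chest-wall)
slices carry reconstruction artifacts.  Both are removed before any
histogram is built.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .grid import BreastMask, VoxelGrid


def strip_skin(ct: VoxelGrid, skin_peel_mm: float = 2.0) -> BreastMask:
    """Segment the breast from the air background and peel off the skin.

    The air/tissue boundary is found by Otsu thresholding (shift-invariant:
    adding a uniform offset to the volume moves the threshold by the same
    offset), closed morphologically per slice, and reduced to its largest
    connected component; the outer shell is then eroded inward by
    ``skin_peel_mm`` using the Euclidean distance transform, guaranteeing
    exclusion of partial-volume skin voxels that would distort the fat
    component of the histogram.  ``skin_peel_mm=0`` returns the full tissue
    segmentation including skin.
    """
    if skin_peel_mm < 0:
        raise ValueError("skin_peel_mm must be >= 0")
    vals = ct.values
    if np.ptp(vals) <= 0:
        raise ValueError("volume is uniform; no air/tissue boundary found")
    thr = threshold_otsu(vals)
    fg = vals > thr
    if not fg.any():
        raise ValueError("no foreground voxels above the air threshold")
    for z in range(fg.shape[0]):
        if fg[z].any():
            fg[z] = ndimage.binary_closing(fg[z], iterations=2)
            fg[z] = ndimage.binary_fill_holes(fg[z])
    lab, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(fg, lab, index=np.arange(1, n + 1))
        order = np.argsort(sizes)[::-1]
        if sizes[order[1]] > 0.05 * sizes[order[0]]:
            import warnings
            warnings.warn("breast mask fragmented; keeping largest "
                          "component", stacklevel=2)
        fg = lab == (1 + int(order[0]))
    if skin_peel_mm > 0:
        # pad the chest-wall face so the peel acts only on exposed surface
        padded = np.concatenate([fg[:1], fg], axis=0)
        depth = ndimage.distance_transform_edt(padded,
                                               sampling=ct.spacing)[1:]
        fg = depth > skin_peel_mm
    if not fg.any():
        raise ValueError("skin peel removed the entire breast")
    return BreastMask(fg, ct.spacing, ct.origin, provenance="skin_stripped")


def truncate_axial(mask: BreastMask, n_anterior: int, n_posterior: int
                   ) -> BreastMask:
    """Zero out end slices of the breast mask to skip artifact-prone
    regions: ``n_posterior`` slices at the chest-wall end (axis start) and
    ``n_anterior`` at the nipple end, counted over the breast-containing
    slice range.  Voxel values are untouched; only the mask shrinks."""
    if n_anterior < 0 or n_posterior < 0:
        raise ValueError("truncation counts must be >= 0")
    occupied = np.flatnonzero(mask.mask.any(axis=(1, 2)))
    if occupied.size == 0:
        raise ValueError("mask is empty")
    if n_anterior + n_posterior >= occupied.size:
        raise ValueError("truncation would remove every breast slice")
    out = mask.copy()
    if n_posterior > 0:
        out.mask[occupied[:n_posterior]] = False
    if n_anterior > 0:
        out.mask[occupied[occupied.size - n_anterior:]] = False
    return out


def default_truncation(mask: BreastMask, frac: float = 0.05
                       ) -> tuple[int, int]:
    """Default truncation extent: ``frac`` (5%) of breast-containing slices
    at each end, at least 1."""
    n = int(mask.mask.any(axis=(1, 2)).sum())
    k = max(int(round(frac * n)), 1)
    return k, k
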