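"""Fiducial-based rigid CT->SPECT coregistration and mask resampling.

The CT and SPECT volumes are acquired on the same gantry but reconstructed
in different frames; dual-modality fiducial markers visible in both give
point correspondences from which the least-squares rigid transform is
estimated (orthogonal Procrustes / Kabsch with reflection guard).  CT-derived
tissue masks are then pulled onto the coarser SPECT grid by
nearest-neighbour sampling of the fat/gland label image, which preserves
hard class membership and fat/gland disjointness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import VoxelGrid


@dataclass
class FiducialSet:
    """Labelled fiducial coordinates (mm) in one modality's frame."""

    labels: list[str]
    points_mm: np.ndarray

    def __post_init__(self) -> None:
        self.points_mm = np.atleast_2d(np.asarray(self.points_mm,
                                                  dtype=float))
        if self.points_mm.shape != (len(self.labels), 3):
            raise ValueError("points_mm must be (n_labels, 3)")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("fiducial labels must be unique")

    def __len__(self) -> int:
        return len(self.labels)

    def to_csv(self, path: str) -> None:
        pd.DataFrame({"label": self.labels,
                      "x_mm": self.points_mm[:, 0],
                      "y_mm": self.points_mm[:, 1],
                      "z_mm": self.points_mm[:, 2]}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "FiducialSet":
        df = pd.read_csv(path)
        return cls(labels=[str(x) for x in df["label"]],
                   points_mm=df[["x_mm", "y_mm", "z_mm"]].to_numpy())


@dataclass
class RigidTransform:
    """Rotation + translation (no scale/shear), with the fiducial
    registration error (FRE, mm RMS) of the fit that produced it."""

    rotation: np.ndarray
    translation: np.ndarray
    fre_mm: float = 0.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).ravel()
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3),
                           atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det=+1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_euler_z(cls, angle_deg: float,
                     translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        a = np.deg2rad(angle_deg)
        rot = np.array([[np.cos(a), -np.sin(a), 0.0],
                        [np.sin(a), np.cos(a), 0.0],
                        [0.0, 0.0, 1.0]])
        return cls(rot, np.asarray(translation, dtype=float))

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.T
        return RigidTransform(rinv, -rinv @ self.translation, self.fre_mm)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"rotation": self.rotation.tolist(),
                       "translation": self.translation.tolist(),
                       "fre_mm": self.fre_mm}, fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "RigidTransform":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation"]),
                   float(d.get("fre_mm", 0.0)))


def estimate_rigid(moving: FiducialSet, fixed: FiducialSet) -> RigidTransform:
    """Least-squares rigid transform mapping ``moving`` points onto
    ``fixed`` (SVD-based orthogonal Procrustes with reflection guard).

    Points are matched by label.  Requires >= 3 non-collinear pairs;
    reports the fiducial registration error (RMS residual, mm).
    """
    common = [l for l in moving.labels if l in set(fixed.labels)]
    if len(common) < 3:
        raise ValueError("need at least 3 matched fiducial pairs")
    a = np.array([moving.points_mm[moving.labels.index(l)] for l in common])
    b = np.array([fixed.points_mm[fixed.labels.index(l)] for l in common])
    ac, bc = a - a.mean(axis=0), b - b.mean(axis=0)
    s = np.linalg.svd(ac, compute_uv=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise ValueError("fiducials are collinear; rigid transform "
                         "underdetermined")
    u, _, vt = np.linalg.svd(bc.T @ ac)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    trans = b.mean(axis=0) - rot @ a.mean(axis=0)
    resid = a @ rot.T + trans - b
    fre = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return RigidTransform(rot, trans, fre)


def resample_labels(label_image: np.ndarray, source: VoxelGrid,
                    transform: RigidTransform, target: VoxelGrid
                    ) -> np.ndarray:
    """Pull an integer label image from the source (CT) grid onto the target
    (SPECT) grid through a rigid source->target transform, assigning each
    target voxel the label at the source location of its centre
    (nearest-neighbour)."""
    tz, ty, tx = np.meshgrid(*(np.arange(n) for n in target.shape),
                             indexing="ij")
    idx = np.stack([tz, ty, tx], axis=-1).reshape(-1, 3).astype(float)
    mm = target.index_to_mm(idx)
    src_mm = transform.inverse().apply(mm)
    src_idx = source.mm_to_index(src_mm)
    coords = src_idx.T
    out = ndimage.map_coordinates(label_image.astype(np.int16), coords,
                                  order=0, mode="constant", cval=0)
    return out.reshape(target.shape)


def resample_mask(masks, transform: RigidTransform, target: VoxelGrid):
    """Resample CT-grid tissue masks onto the SPECT grid.

    The fat/gland masks are combined into a single label image
    (0 = neither, 1 = fat, 2 = gland) and resampled nearest-neighbour so
    disjointness is preserved by construction.  Raises if the resampled
    breast support is empty.
    """
    from .segmentation import TissueMasks  # local import; avoids cycle

    lab = np.zeros(masks.fat_mask.shape, dtype=np.int16)
    lab[masks.fat_mask] = 1
    lab[masks.gland_mask] = 2
    source = VoxelGrid(np.zeros(masks.fat_mask.shape), masks.spacing,
                       masks.origin)
    out = resample_labels(lab, source, transform, target)
    if not (out > 0).any():
        raise ValueError("resampled mask is empty on the target grid")
    return TissueMasks(fat_mask=out == 1, gland_mask=out == 2,
                       method=masks.method, spacing=target.spacing,
                       origin=target.origin, thresholds=masks.thresholds)
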