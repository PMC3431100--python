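"""Synthetic pendant-breast and bench phantoms for the quantification pipeline.

The package's analyses operate on reconstructed volumes: a CT attenuation
volume (cm^-1), a pair of SPECT energy-window count volumes, and fiducial
coordinates in both frames.  This module generates all of them with the
statistical structure the downstream methods assume:

* a pendant-breast label volume with a bimodal fat/gland interior and a thin
  skin shell;
* a CT volume whose voxel values carry a programmable radius-dependent shift
  (emulating the residual object-size dependence of reconstructed attenuation
  coefficients) plus Gaussian noise;
* SPECT photopeak and scatter-window count volumes Poisson-sampled from a
  programmed activity map, with attenuation losses that are the exact inverse
  of the first-order Chang correction and a scatter contamination term sized
  so the dual-energy-window subtraction removes it in expectation;
* uniform cylinder and cone phantoms for the centroid-vs-size validation.

All randomness is driven by ``PhantomSpec.seed``; identical spec and seed give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml
from scipy import ndimage

from .corrections import AcquisitionMeta, AttenuationModel, chang_survival
from .grid import VoxelGrid
from .registration import FiducialSet, RigidTransform

AIR, FAT, GLAND, SKIN, FIDUCIAL = 0, 1, 2, 3, 4

_SHAPES = ("pendant_breast", "cylinder", "cone")


@dataclass
class PhantomSpec:
    """Parameters of a synthetic phantom.

    Attenuation defaults (0.20 / 0.28 cm^-1) are representative fat and
    fibroglandular linear attenuation coefficients at a quasimonochromatic
    ~35 keV CT beam.  ``radial_shift_slope`` adds ``slope * r_eq`` (cm^-1,
    with r_eq the slice equivalent radius in cm) to every tissue value in a
    slice, reproducing the object-size dependence of reconstructed
    attenuation values.  Activities are in uCi/mL.
    """

    shape: str = "pendant_breast"
    radius_cm: float = 5.0
    length_cm: float = 6.0
    glandular_fraction: float = 0.3
    mu_fat: float = 0.20
    mu_gland: float = 0.28
    mu_skin: float = 0.28
    skin_thickness_mm: float = 2.0
    radial_shift_slope: float = 0.005
    noise_sd: float = 0.015
    activity_fat: float = 0.10
    activity_gland: float = 0.10
    scatter_fraction: float = 0.2
    voxel_mm: float = 0.508
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"shape must be one of {_SHAPES}")
        if self.radius_cm <= 0 or self.length_cm <= 0 or self.voxel_mm <= 0:
            raise ValueError("radius_cm, length_cm and voxel_mm must be > 0")
        if not 0.0 <= self.glandular_fraction <= 1.0:
            raise ValueError("glandular_fraction must lie in [0, 1]")
        if self.mu_fat >= self.mu_gland:
            raise ValueError("mu_fat must be < mu_gland")
        if self.activity_fat < 0 or self.activity_gland < 0:
            raise ValueError("activity concentrations must be >= 0")
        if not 0.0 <= self.scatter_fraction <= 1.0:
            raise ValueError("scatter_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh)

    @classmethod
    def from_yaml(cls, path: str) -> "PhantomSpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class LabelVolume:
    """Integer tissue labels (0=air, 1=fat, 2=gland, 3=skin, 4=fiducial)."""

    grid: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int8)
        if self.grid.ndim != 3:
            raise ValueError("LabelVolume requires a 3-D array")
        if self.grid.min() < 0 or self.grid.max() > 4:
            raise ValueError("labels must lie in {0..4}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def glandular_fraction(self) -> float:
        """Gland voxels / (gland + fat) voxels, counted exactly."""
        n_gland = int((self.grid == GLAND).sum())
        n_fat = int((self.grid == FAT).sum())
        if n_gland + n_fat == 0:
            raise ValueError("phantom has no fat or gland voxels")
        return n_gland / (n_gland + n_fat)

    def to_nifti(self, path: str) -> None:
        VoxelGrid(self.grid.astype(float), self.spacing, self.origin
                  ).to_nifti(path)


def _radius_profile(spec: PhantomSpec, z_mm: np.ndarray) -> np.ndarray:
    """Breast/phantom radius (mm) at each axial position (mm from chest wall)."""
    r_mm = spec.radius_cm * 10.0
    length_mm = spec.length_cm * 10.0
    t = np.clip(z_mm / length_mm, 0.0, 1.0)
    if spec.shape == "cylinder":
        return np.full_like(z_mm, r_mm)
    if spec.shape == "cone":
        return r_mm * (1.0 - t)
    # pendant breast: hemi-ellipsoid profile, widest at the chest wall
    return r_mm * np.sqrt(np.clip(1.0 - t**2, 0.0, None))


def make_phantom(spec: PhantomSpec) -> LabelVolume:
    """Build the label volume for a phantom spec.

    For the pendant breast the interior is split into fat and gland so that
    the global gland/(gland+fat) voxel ratio equals ``glandular_fraction``
    exactly (quantile thresholding of a structured random field), with the
    gland concentrated in a central blob plus seeded strands so that
    per-slice composition varies along the axis.  Cylinder and cone phantoms
    are single-material (all-fat labels, no skin), emulating uniform
    methanol/water mixtures.
    """
    vox = spec.voxel_mm
    margin_mm = 3.0 * vox
    r_mm = spec.radius_cm * 10.0
    nz = max(int(round(spec.length_cm * 10.0 / vox)), 4)
    nxy = int(np.ceil(2 * (r_mm + margin_mm) / vox))
    z_mm = (np.arange(nz) + 0.5) * vox
    yx = (np.arange(nxy) + 0.5) * vox - (nxy * vox) / 2.0
    yy, xx = np.meshgrid(yx, yx, indexing="ij")
    dist = np.sqrt(yy**2 + xx**2)

    prof = _radius_profile(spec, z_mm)
    support = dist[None, :, :] <= prof[:, None, None]

    labels = np.zeros((nz, nxy, nxy), dtype=np.int8)
    if spec.shape in ("cylinder", "cone"):
        labels[support] = FAT
        return LabelVolume(labels, (vox, vox, vox))

    # skin shell: voxels within skin_thickness_mm of the outer surface.
    # Pad the chest-wall face by replication so the shell stays open there
    # (the breast continues into the torso) but closes over the nipple.
    padded = np.concatenate([support[:1], support], axis=0)
    depth = ndimage.distance_transform_edt(padded, sampling=(vox,) * 3)[1:]
    interior = depth > spec.skin_thickness_mm
    skin = support & ~interior
    labels[skin] = SKIN

    gf = spec.glandular_fraction
    n_int = int(interior.sum())
    if n_int == 0:
        raise ValueError("phantom too small: no interior voxels inside skin")
    if gf == 0.0:
        labels[interior] = FAT
    elif gf == 1.0:
        labels[interior] = GLAND
    else:
        rng = np.random.default_rng(spec.seed)
        # central blob + smoothed-noise strands; quantile threshold fixes
        # the global fraction exactly while composition varies per slice
        zz = (z_mm[:, None, None] - 0.35 * spec.length_cm * 10.0)
        blob = np.exp(-(dist[None] ** 2 / (0.45 * r_mm) ** 2
                        + zz**2 / (0.45 * spec.length_cm * 10.0) ** 2))
        strands = ndimage.gaussian_filter(
            rng.standard_normal(labels.shape), sigma=3.0 / vox)
        strands /= max(strands.std(), 1e-12)
        f = 1.2 * blob + strands
        vals = f[interior]
        thr = np.quantile(vals, 1.0 - gf)
        gland = interior & (f >= thr)
        labels[interior] = FAT
        labels[gland] = GLAND
    return LabelVolume(labels, (vox, vox, vox))


def slice_equivalent_radius_cm(foreground: np.ndarray,
                               spacing: tuple[float, float, float]
                               ) -> np.ndarray:
    """Per-slice equivalent radius sqrt(area / pi), in cm, 0 for empty slices."""
    fg = np.asarray(foreground, dtype=bool)
    area_cm2 = fg.sum(axis=(1, 2)) * spacing[1] * spacing[2] / 100.0
    return np.sqrt(area_cm2 / np.pi)


def ct_from_labels(labels: LabelVolume, spec: PhantomSpec) -> VoxelGrid:
    """Render a CT attenuation volume (cm^-1) from tissue labels.

    Voxel value = class mean mu + radial_shift_slope * (slice equivalent
    radius in cm) + N(0, noise_sd); air stays at 0.  The linear radius term
    reproduces the centroid-vs-object-size effect the per-slice segmentation
    methods are designed to absorb.
    """
    lab = labels.grid
    mu = np.zeros(lab.shape, dtype=float)
    mu[lab == FAT] = spec.mu_fat
    mu[lab == GLAND] = spec.mu_gland
    mu[lab == SKIN] = spec.mu_skin

    fg = lab > 0
    r_eq = slice_equivalent_radius_cm(fg, labels.spacing)
    shift = spec.radial_shift_slope * r_eq[:, None, None]
    values = mu + np.where(fg, shift, 0.0)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed + 1)
        values = values + np.where(
            fg, rng.normal(0.0, spec.noise_sd, lab.shape), 0.0)
    return VoxelGrid(values, labels.spacing, labels.origin)


def activity_from_labels(labels: LabelVolume, spec: PhantomSpec) -> VoxelGrid:
    """Programmed activity concentration map (uCi/mL) on the label grid."""
    lab = labels.grid
    conc = np.zeros(lab.shape, dtype=float)
    conc[lab == FAT] = spec.activity_fat
    conc[lab == GLAND] = spec.activity_gland
    conc[lab == SKIN] = spec.activity_fat
    return VoxelGrid(conc, labels.spacing, labels.origin)


def _resample_nearest(src: VoxelGrid, new_spacing: float) -> VoxelGrid:
    """Nearest-neighbour resampling onto a coarser isotropic grid covering
    the same physical extent (voxel-centre sampling)."""
    extent = np.asarray(src.shape) * np.asarray(src.spacing)
    new_shape = np.maximum(np.ceil(extent / new_spacing).astype(int), 1)
    axes = [
        np.clip(np.round(((np.arange(n) + 0.5) * new_spacing) / s - 0.5
                         ).astype(int), 0, src.shape[k] - 1)
        for k, (n, s) in enumerate(zip(new_shape, src.spacing))
    ]
    vals = src.values[np.ix_(axes[0], axes[1], axes[2])]
    return VoxelGrid(vals, (new_spacing,) * 3, src.origin)


def spect_from_labels(labels: LabelVolume, spec: PhantomSpec,
                      meta: AcquisitionMeta, spect_voxel_mm: float = 2.5,
                      scatter_sigma_mm: float = 10.0,
                      expectation: bool = False,
                      attenuation: AttenuationModel | None = None,
                      ) -> tuple[VoxelGrid, VoxelGrid]:
    """Simulate SPECT photopeak and scatter-window count volumes.

    The forward model on the SPECT grid is, per voxel ``v``::

        primary(v)   = conc(v) * V_mL * calibration * duration
                       * decay(scan - injection) * survival(v)
        scatter(v)   = scatter_fraction * smooth(primary)(v)
        photopeak(v) = primary(v) + dew_k * (w_p / w_s) * scatter(v)

    ``survival`` is the mean photon survival fraction over in-plane ray
    directions — the exact inverse of the first-order Chang factor the
    correction chain multiplies by — so that in expectation mode the full
    correction chain returns the programmed concentration map.  With
    ``expectation=False`` both windows are independently Poisson-sampled
    using ``spec.seed``.
    """
    if meta.calibration_factor is None or meta.calibration_factor <= 0:
        raise ValueError("AcquisitionMeta.calibration_factor required")
    conc_ct = activity_from_labels(labels, spec)
    conc = _resample_nearest(conc_ct, spect_voxel_mm)
    support = conc.values > 0

    model = attenuation if attenuation is not None else \
        AttenuationModel(mask=None)
    survival = np.ones(conc.shape)
    if model.mu > 0 and support.any():
        survival = chang_survival(support, conc.spacing, model)

    elapsed_h = meta.scan_reference_time - meta.injection_time
    decay = 2.0 ** (-elapsed_h / meta.half_life_h)
    primary = (conc.values * conc.voxel_volume_ml * meta.calibration_factor
               * meta.acquisition_duration_s * decay * survival)

    sigma_vox = scatter_sigma_mm / spect_voxel_mm
    scatter = spec.scatter_fraction * ndimage.gaussian_filter(primary,
                                                              sigma_vox)
    from .corrections import EnergyWindowSet  # default window geometry
    win = EnergyWindowSet()
    photopeak = primary + win.dew_k * win.width_ratio * scatter

    if not expectation:
        rng = np.random.default_rng(spec.seed + 2)
        photopeak = rng.poisson(photopeak).astype(float)
        scatter = rng.poisson(scatter).astype(float)
    return (conc.copy_with(photopeak), conc.copy_with(scatter))


def place_fiducials(labels: LabelVolume, n: int, transform: RigidTransform,
                    seed: int = 0, jitter_mm: float = 0.0,
                    ) -> tuple[FiducialSet, FiducialSet]:
    """Place ``n`` dual-modality fiducial markers on the skin surface.

    Returns (CT-frame set, SPECT-frame set); the SPECT set is the rigid
    transform applied to the CT set plus optional isotropic Gaussian
    localisation jitter.  Placement is rejected and resampled if the points
    are (near-)collinear, since three collinear markers leave the rigid
    transform underdetermined.
    """
    if n < 3:
        raise ValueError("at least 3 fiducials are required")
    surface = np.argwhere(labels.grid == SKIN)
    if surface.size == 0:
        surface = np.argwhere(labels.grid > 0)
    if surface.size == 0:
        raise ValueError("phantom has no surface to place fiducials on")
    rng = np.random.default_rng(seed)
    spacing = np.asarray(labels.spacing)
    for _ in range(100):
        pick = surface[rng.choice(len(surface), size=n, replace=False)]
        pts = pick * spacing + np.asarray(labels.origin)
        centered = pts - pts.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        if s[1] > 1e-6 * max(s[0], 1.0):  # non-collinear
            break
    else:
        raise ValueError("could not place non-collinear fiducials")
    names = [f"F{i}" for i in range(n)]
    ct_set = FiducialSet(labels=names, points_mm=pts)
    moved = transform.apply(pts)
    if jitter_mm > 0:
        moved = moved + rng.normal(0.0, jitter_mm, moved.shape)
    return ct_set, FiducialSet(labels=names, points_mm=moved)
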