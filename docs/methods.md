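# Methods

This note documents the models, parameter choices and numerical decisions
behind `mibiquant`, and what the synthetic studies do and do not establish
about real data.

## Imaging model and coordinate conventions

All volumes are `VoxelGrid`s indexed `(slice, row, col)` with the slice
axis running chest wall → nipple, voxel-centred coordinates in mm.  CT
volumes carry linear attenuation coefficients in cm⁻¹ (nominal voxel
0.508 mm isotropic); SPECT volumes carry window counts or µCi/mL (nominal
voxel 2.5 mm).  NIfTI is used for on-disk volumes, CSV for fiducials and
per-slice tables, JSON for transforms and correction logs, YAML for
phantom specifications.

## Synthetic phantoms

`PhantomSpec`/`make_phantom` generate three geometries: a pendant breast
(hemi-ellipsoidal profile, widest at the chest wall), and uniform cylinder
and cone bench phantoms emulating methanol/water mixtures.  The pendant
breast has a 2 mm skin shell, open at the chest-wall face (the breast
continues into the torso) and closed over the nipple.  The interior is
split into fat and gland by thresholding a structured random field — a
central ellipsoidal blob plus seeded, smoothed-noise strands — at the
quantile that makes the global gland/(gland+fat) voxel ratio equal the
programmed `glandular_fraction` exactly, while per-slice composition
varies along the axis (this is what stresses per-slice fitting).

CT rendering assigns class means (defaults µ_fat = 0.20, µ_gland = µ_skin
= 0.28 cm⁻¹, representative of fat and fibroglandular tissue for a ~35 keV
quasimonochromatic beam), adds `radial_shift_slope · r_eq(z)` where
`r_eq = √(slice area/π)` is the slice equivalent radius in cm, and adds
Gaussian noise (default σ = 0.015 cm⁻¹, giving a two-class Bayes error of
~0.4% at the 0.08 cm⁻¹ class separation).  The radius-dependent term is a
phenomenological stand-in for the residual object-size dependence of
reconstructed attenuation values after projection-domain scatter
correction; its true magnitude is not established, so the slope is a free
simulation parameter (default 0.005 cm⁻¹ per cm; the size-dependence
studies set it explicitly).  The linear form is the simplest monotone
choice and is what the validation analysis estimates back.

The SPECT forward model works on the reconstructed domain (tomographic
reconstruction itself is out of scope).  The activity map (defaults: 0.10
µCi/mL in both tissues; skin carries the fat value) is sampled at SPECT
voxel centres (nearest CT label, so in-support voxels carry the full
concentration), and expected primary counts per voxel are

    primary = conc · V_mL · calibration · duration · decay · survival

with `survival` the mean in-plane photon survival fraction — by
construction the exact inverse of the first-order Chang factor the
correction chain multiplies by, making the chain exactly invertible in
expectation.  The scatter window is `scatter_fraction` (default 0.2) times
a 10 mm-smoothed copy of the primary, and the photopeak additionally
contains `k·(w_p/w_s)` times that scatter estimate, so the dual-energy
window subtraction removes the contamination exactly in expectation.  Both
windows are independently Poisson-sampled unless `expectation=True` (the
flag exists to enable exact oracle tests).  Modelling scatter in the
reconstructed domain, rather than in projections, is a deliberate
simplification: it preserves what the DEW correction actually operates on.

The calibration factor default used in the synthetic studies is 1.4 counts
s⁻¹ µCi⁻¹, a typical CZT breast-camera sensitivity (~38 cps/MBq).  At 0.10
µCi/mL and a 128 × 5 s acquisition this yields ≲1 expected count per 2.5 mm
voxel, so zero is the modal voxel measurement — the low-count regime of
in vivo breast SPECT, which is why per-voxel concentrations are noisy while
whole-breast means are stable.

## Skin stripping and truncation

The air/tissue boundary is found by Otsu thresholding (equivariant under a
uniform value offset), closed per slice, reduced to the largest connected
component, and eroded inward by `skin_peel_mm` (default 2 mm) using the
Euclidean distance transform with the chest-wall face padded so the peel
acts only on exposed surface.  Erosion guarantees the exclusion of
partial-volume skin voxels that would otherwise inflate the gland
component of the histogram.  Skin voxels are excluded from analysis, not
reassigned.  End-slice truncation removes a configurable number of
breast-containing slices at each end (default 5% per end) from all masks;
voxel values are never modified.

## Dual-Gaussian segmentation

Histograms use a fixed 0.002 cm⁻¹ bin width — fine enough to resolve peaks
0.03–0.08 cm⁻¹ apart with ≥15 bins per component.  The six-parameter model
is written `A exp(−(x−B)²/C²)`, so C = √2 σ; all widths in code and output
use the C convention.  Nonlinear least squares (`scipy.optimize.curve_fit`,
nonnegative amplitude bounds) is seeded from the two most prominent local
maxima of a lightly smoothed histogram, with widths from an FWHM estimate;
components are reordered so B₁ < B₂.  Three degenerate regimes are handled
explicitly:

* **< 2 nonzero bins** — unfittable; the slice falls back to the global
  threshold and is flagged.
* **2–5 nonzero bins** (noiseless two-value data) — a narrow component is
  placed on each of the two tallest bins; a free 6-parameter fit is
  underdetermined there.
* **near-coincident components** (|B₂−B₁| < 0.2·max C) — the dual model is
  not identifiable on effectively single-Gaussian data, so a single
  component is refitted and the second amplitude reported as zero, which
  downstream thresholds flag.

The **minimum** threshold is the interior minimiser of the fitted sum on
(B₁, B₂), located by grid search at bin_width/100 resolution plus a
bounded polish; a monotone mixture (no interior minimum) raises a flag
rather than producing a threshold.  The **cross-point** solves
`A₁e^{−(x−B₁)²/C₁²} = A₂e^{−(x−B₂)²/C₂²}` in closed form via the quadratic
in x obtained by taking logs, returning the root between the centroids
(unique there, since the component log-ratio is strictly decreasing on
(B₁, B₂)); with equal widths the equation is linear and the root exists in
(B₁, B₂) iff (B₂−B₁)² > C²|ln(A₁/A₂)|.  The cross-point may legitimately
fall on either side of the mixture minimum.  The "crossing point between
the centroids" is implemented as this component intersection; the centroid
midpoint (B₁+B₂)/2 is available separately for comparison.  **Purity**
thresholds use the fitted components as the tissue-membership model: the
fat purity below t is ∫₋∞ᵗg₁ / (∫₋∞ᵗg₁ + ∫₋∞ᵗg₂) with the Gaussian masses
evaluated by the error function; t_fat is the largest t with purity ≥ 0.95
(grid bracketing plus bisection to bin_width/100), t_gland symmetrically
the smallest, and where the target is unattainable the purity-maximising
threshold is returned with its achieved purity, flagged.  Two thresholds
per slice are produced (one per tissue); when the pure bands overlap
(well-separated components, t_fat ≥ t_gland) the overlap is split at the
band midpoint so the binary partition is preserved, and when t_fat <
t_gland the ambiguous middle band is left unassigned.

Scope rules: the global histogram is used with the minimum method (one
threshold for the volume); cross-point and purity operate per slice
(minimum per-slice is also available).  Slices with fewer than 500 voxels
(configurable) or failed fits fall back to the global minimum threshold
and are flagged in the per-slice threshold table.  Ties (voxel exactly at
a threshold) go to fat; the choice is arbitrary but deterministic and
documented.

## SPECT corrections

DEW subtraction scales the scatter window by `dew_k · (w_p/w_s)` — the
canonical k = 0.5 with an explicit window-width ratio (0.08/0.30) so k is
window-independent — and clamps negative results to zero (counts are
nonnegative; at low counts the clamp introduces a small positive bias,
≈+1% in the whole-breast mean in the replicate studies, well inside the
Poisson spread).  The attenuation mask is emission-defined ("SPECT-based"):
the photopeak volume lightly smoothed (2.5 mm) and thresholded at 25% of
its 99th-percentile maximum, hole-filled, largest component kept.  A
fraction-of-maximum threshold is used instead of a bimodal (Otsu)
criterion because zero-inflated low-count histograms are not bimodal and
in-breast count levels vary with depth.  The Chang correction is
slice-wise 2D: for each in-mask voxel, chords to the mask boundary are
ray-marched in 64 equally spaced in-plane directions at half-voxel steps
with bilinear mask sampling (effective boundary = half-maximum surface),
and the voxel is multiplied by `F = N/Σᵢ exp(−µLᵢ)` with µ = 0.1545 cm⁻¹.
Against the closed form for the centre of a 5 cm disc (F = e^{µR} = 2.165)
the ray-marched factor agrees to 0.1% on a 1.25 mm grid.  Decay correction
multiplies by `2^{(t_scan−t_inj)/T½}` with T½ = 6.0058 h.  Survival maps
are memoised on the mask, since replicate studies correct many noise
realisations inside one support.

## Registration and resampling

`estimate_rigid` is the SVD-based orthogonal Procrustes solution with a
determinant guard against reflections, requiring ≥3 non-collinear matched
fiducial pairs and reporting the RMS fiducial registration error.  Tissue
masks are resampled by combining fat/gland into one label image and
pulling it nearest-neighbour through the inverse transform — hard class
membership and disjointness are preserved by construction.  Each SPECT
voxel takes the class of the CT label at its centre; since a 2.5 mm SPECT
voxel contains ~125 CT voxels this is a point sample, not a majority vote,
which is deterministic and adequate for fraction-level statistics (the
resampling tests bound the fraction distortion at 2 points).

## Reporting

Per-region statistics are the mean and population std (ddof = 0 by
default, configurable) of in-mask voxel concentrations; zero-valued voxels
are genuine measurements and are always included.  Empty regions are
reported as absent, never as zero.  The cohort Total row is the unweighted
arithmetic mean of per-subject means, per column, with subjects lacking a
column contributing only where they have data; display values are rounded
to two decimals while machine-precision values are retained.  The
across-subject std of the means is reported as such and is deliberately
not labelled as a pooled voxel std — the two are different quantities.

## Problem sizes in the tests and acceptance script

Synthetic breasts are generated at 1 mm voxels (radius 4 cm, length 5 cm,
~150k tissue voxels) and bench phantoms at 1.25–1.5 mm; SPECT is always on
the 2.5 mm grid.  Replicate studies use 20 seeds; the dual-Gaussian noise
study uses 50 seeds at 10⁵ voxels.  These sizes keep the full suite under
a minute while leaving every tested quantity resolution-independent or
compared against ground truth computed on the same grid.

## What the synthetic studies do not show

The generator reproduces the statistical structure the analysis assumes —
bimodal attenuation, per-slice composition variation, a monotone
size-dependent shift, Poisson counting with attenuation and a
spatially-smooth scatter term — but not the physics that causes it: no
beam hardening, no energy-resolved scatter, no detector response, no
reconstruction artifacts, no motion.  Passing the round-trip tests shows
the correction chain correctly inverts its own forward model and that the
segmentation recovers programmed compositions under realistic noise; it
does not validate the corrections against real acquisitions, and the
radial-shift magnitude in real reconstructions remains uncharacterised.
Skin-voxel handling (excluded here) and the exact DEW constant of the
original acquisition system are conventions that a user fitting real data
may need to revisit.
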