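# Methods

## Model and assumptions

`sphtex` treats the texture of a segmented object as the angular
distribution of its intensity as seen from the object center. The object is
assumed star-shaped enough that center-to-surface rays are meaningful: rays
stop at their *first* exit from the mask, so concave re-entrant regions
(e.g. the synthetic star shape) are deliberately ignored rather than
re-entered. The segmentation is taken as given and correct; a label with
several connected components is processed as one object, and an object whose
cube-center sample is background is rejected (`CentroidOutsideMaskError`) —
the projection is undefined for it.

The pipeline is: bounding-box crop → rescale to a standard cube → ray-cast
angular mean-intensity projection → mean-0/variance-1 normalization →
spherical-harmonic (3D) or Fourier (2D) power spectrum → wavelength mapping →
log₂ binning. Because the spectrum integrates out the harmonic order m, the
descriptor is exactly invariant to rotations about the polar axis and, in
practice, nearly invariant to arbitrary rotations (the grid resamples the
sphere anisotropically near the poles, so full rotational invariance is only
approximate at finite bandlimit). Because each axis of the bounding box is
rescaled to the cube side independently, the descriptor measures pattern
scale *relative to object size* and tolerates anisotropic voxels.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `cube_side` | 80 voxels | side of the standard resampling cube; sets the finest resolvable pattern scale |
| `nlat`, `nlon` | 251, 512 | Gauss–Legendre quadrature grid (colatitudes × longitudes); bandlimit L = nlat − 1 = 250 |
| `n_circle` | 251 | circle samples for 2D objects; frequencies up to 125 |
| `nbins` | 20 | log₂-spaced wavelength bins in the descriptor |
| ray step | 0.5 voxel | fixed sampling step along rays |
| `weighted` | true | area-weighted statistics in the normalization |
| `zero_variance` | `"error"` | `"zero"` maps constant objects to an all-zero descriptor in batch runs |

The number of retained degree values at the default grid is 251 (ℓ = 0…250).
A 251-latitude quadrature grid supports bandlimit 250 exactly; the longitude
count 512 oversamples the minimal 2L + 1 = 501, and longitudinal frequencies
above L are discarded.

## Numerical choices

**Ray casting.** Rays start at the geometric cube center, coordinate
(S − 1)/2 per axis, so the projection depends only on the mask and
intensity, not on where intensity happens to sit. The center sample always
contributes, so no ray is empty. The mask is looked up by nearest neighbor;
intensity at a sample point is the *mask-weighted* multilinear interpolation
`interp(values · mask) / interp(mask)`. Plain interpolation of the masked
intensity would dilute boundary samples with the zeroed background; the
weighted form estimates the in-mask intensity and preserves constants
exactly (a constant object projects to an exactly constant map). A dense-step
reference integrator (10× finer step, independent implementation) agrees
with the production caster within 0.05 of a normalized unit on noise-filled
spheres.

**Spherical-harmonic transform.** Analysis is an FFT in longitude followed
by Gauss–Legendre quadrature in latitude against geodesy 4π-normalized
associated Legendre functions (each basis function has unit mean square over
the sphere, so summed squared coefficients equal the map's variance). With
nlat nodes the quadrature is exact for products of functions band-limited to
L = nlat − 1, so analysis followed by synthesis reproduces any band-limited
map to machine precision; the transform is verified against brute-force
quadrature of f·Y<sub>ℓm</sub> built from scipy's complex harmonics.

**Band-limited normalization.** A ray-cast map is not band-limited; the part
of it outside the transform's range (latitude residuals at m > 0 and
longitudinal frequencies above L) is invisible to the spectrum — roughly
10⁻⁴ of the variance for typical objects. `normalize` therefore first
restricts the spherical map to its band-limited component and then applies
(F − μ)/σ with area-weighted μ, σ². This makes the descriptor's defining
property — binned values summing to exactly 1 (Parseval) — hold at machine
precision rather than to ~10⁻⁴. The circle's discrete Fourier basis is
complete, so 2D maps need no restriction. Plain (unweighted) statistics are
available via `weighted=False`; they differ from the weighted ones by a few
percent on patterns with strong polar structure and do not give exact
Parseval.

**Wavelength mapping and binning.** λ(ℓ) = 1/√(ℓ(ℓ+1)) in rad/2π with the
anchor λ(1) = 1, where the Jeans relation breaks down (the degree-1 basis has
exactly one peak and one valley). In 2D, λ(k) = 1/k with the same anchor.
Bin edges are uniform in log₂λ from λ(1) down to λ(L); each degree's power is
assigned wholly to the bin containing its wavelength (whole-degree
assignment — the discrete spectrum has no sub-degree resolution — so the
total is conserved exactly), and boundary ties go to the longer-wavelength
bin. Consequences worth knowing: bins 2–3 are structurally empty in 3D
(there is no degree between λ(1) = 1 and λ(2) ≈ 0.41), and the coarsest bin
holds exactly the degree-1 power. ℓ = 0 is excluded — it is zero after
normalization and has no wavelength.

**Degenerate inputs.** Constant projections have no defined texture; the
library raises `ZeroVarianceError` (variance below 10⁻¹² relative), and the
batch runner/CLI can map such objects to an all-zero descriptor so one flat
object does not abort a screen. Peak extraction on a constant projection
warns and returns the first grid point. Peak directions are grid-resolution
only (the angle of the maximum value), with ties broken toward the smallest
colatitude, then smallest longitude.

## Synthetic data

The generators reproduce the validation conditions the descriptor was
designed under, so the entire pipeline is testable without image data:

* **Perlin noise** — classical gradient-lattice noise (seeded unit
  gradients, quintic fade) on a 128-voxel grid; `periods` per axis is the
  coarseness dial and must divide the grid side. Values are exactly 0 at
  lattice corners and bounded by ±√d/2. The coarseness ladder used in tests
  is periods {16, 8, 4, 2} (fine → coarse).
* **Shape masks** — sphere (radius 40 of an 80 cube), cone (base diameter =
  height = 80), and a star built from eight sphere-octants (radius 0.35·side)
  pushed outward along their diagonals (offset 0.15·side) over a central
  ball: pointed, concave, and genuinely non-star-convex (center rays exit
  and re-enter), which is what makes it hard to map back to a sphere.
* **Harmonic patterns** — a sphere painted with a single 4π-normalized basis
  function of each voxel's direction (radially constant). Projecting such a
  cube recovers the basis function; rendering fidelity is voxel-limited
  (max error ≈ 0.1 at side 80 for low degrees, ≈ 0.05 at side 160), so
  analytic-recovery tests render at side 160 while caster correctness is
  checked against the dense-step oracle at the default side.
* **Radial clipping** — zeroing intensity outside a spherical shell probes
  signal placement: the same pattern confined nearer the center subtends
  larger angles and reads as coarser.
* **2D variants** are the middle plane of the 3D fields; the anisotropy
  fixture stretches one axis by 1.5–2× before the pipeline.

What the synthetic data does *not* emulate: microscope noise models, point
spread functions, intensity gradients across fields of view, or realistic
chromatin/expression morphologies. Passing tests demonstrate the mathematics
of the descriptor (normalization, invariance, scale response), not
classification performance on real images.

## Known limitations

* **Shape sensitivity at coarse scales.** The mean over a longer ray has
  lower variance, so elongated masks (e.g. cones) imprint a low-degree
  variance modulation on the projection: descriptors of the same noise field
  under sphere vs cone masks differ by a mean L1 of ≈ 0.55 (of a possible 2),
  concentrated in the coarsest bin, at every noise scale tested and under
  either ray-origin convention. Spectra remain comparable — peak bins
  coincide — but the descriptor is not shape-neutral in the coarsest bins,
  and the corresponding acceptance test (mean L1 < 0.2) documents this gap
  honestly by failing.
* First-exit rays ignore structure in concave re-entrant lobes.
* Rescaling to an 80-voxel cube erases patterns finer than the resulting
  grid; raise `cube_side` for very fine textures.
* The Jeans wavelength is approximate at small ℓ and the λ(1) anchor is a
  convention; wavelengths are relative (fractions of the object's angular
  circumference), not physical units.

## Problem sizes used in tests

Unit tests run on a reduced 25×52 quadrature grid and 32–40 voxel cubes
where the property under test allows it; end-to-end checks (normalization,
invariance, coarseness ordering over 5 seeds × 4 scales × {2D, 3D}, shape
robustness over 5 seeds) use the full default conditions: 128-grid noise,
80-voxel masks, the 251×512 grid, and 20 bins.
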