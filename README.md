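# sphtex

Rotationally invariant, scale-normalized texture descriptors for segmented
objects in 2D and 3D microscopy images.

## The problem

Many biological phenotypes are textures: the striped expression pattern of a
developmental enhancer across an embryo, the crescent-shaped chromatin of a
*C. elegans* transition-zone nucleus versus the separated chromosome strands
of pachytene, the polarized actin of a migrating cell. Classical texture
features are built for 2D natural images and transfer poorly to segmented 3D
objects of varying size, shape, and orientation. `sphtex` quantifies the
radial texture of each segmented object as a compact spectrum of *variance
per angular wavelength* that is invariant to object rotation and normalized
for object size and intensity scale — a 20-value feature vector suitable for
plotting, statistics, or a Random Forest object classifier.

## The method

For each labeled object:

1. **Standardize.** Crop the object's bounding box and rescale it to an
   80×80×80 voxel cube (80×80 in 2D): intensity multilinearly, the mask by
   nearest neighbor. Per-axis stretching makes the result robust to
   anisotropic voxels.
2. **Project.** Cast rays from the cube center toward the 251×512 directions
   of a Gauss–Legendre quadrature grid (251 uniform circle angles in 2D) and
   record the mean in-mask intensity along each ray until it first leaves
   the mask. This *spherical projection* F(θ, φ) keeps angular structure
   while collapsing the radial dimension.
3. **Normalize.** F ← (F − ⟨F⟩) / √Var(F), with area-weighted statistics, so
   the map has mean 0 and variance 1.
4. **Decompose.** Expand F in geodesy 4π-normalized spherical harmonics
   Y<sub>ℓm</sub> and integrate out the order m:
   S(ℓ) = Σ<sub>m</sub> (c<sub>ℓm</sub>² + s<sub>ℓm</sub>²). Each S(ℓ) is
   invariant to rotations about the polar axis and, by Parseval,
   Σ<sub>ℓ≥1</sub> S(ℓ) = 1. In 2D the discrete Fourier power spectrum plays
   the same role.
5. **Map to wavelength.** The Jeans relation λ = 2πR/√(ℓ(ℓ+1)) (unit sphere,
   R = 1, in rad/2π — fractions of the full circle) gives each degree an
   approximate cartesian wavelength, anchored at λ = 1 for ℓ = 1.
6. **Bin.** Integrate the spectrum into 20 log₂-spaced wavelength bins.
   The binned values sum to 1: the descriptor reads as the fraction of
   intensity variance at each angular scale.

A separate polarization module extracts the *peak direction* (grid direction
of the projection maximum, optionally band-passed to a degree range) and the
shortest angle between it and a reference direction (at most π).

## Worked example

```python
import numpy as np
import sphtex
from sphtex.synthetic import perlin_object

cube = perlin_object(periods=8, seed=0)          # noise-filled 80px sphere
proj = sphtex.normalize(sphtex.spherical_project(cube))
spec = sphtex.sh_power_spectrum(proj)
binned = sphtex.bin_log2(spec)

print(np.round(binned.values, 3))
print("sum:", round(binned.values.sum(), 6))
print("centroid wavelength:", round(binned.centroid_wavelength(), 3))
```

prints

```
[0.069 0.    0.    0.161 0.175 0.194 0.183 0.116 0.073 0.027 0.001 0.
 0.    0.    0.    0.    0.    0.    0.    0.   ]
sum: 1.0
centroid wavelength: 0.224
```

The 20 values are variance fractions from the coarsest bin (wavelength 1,
one peak and one valley across the object) down to single-pixel scales; this
medium-scale noise concentrates its variance around bins 4–7 (wavelengths
≈ 0.1–0.4), the values sum to 1, and the power-weighted centroid wavelength
summarizes the overall coarseness.

The same API works as a scikit-learn transformer:

```python
from sphtex import SphericalTextureExtractor
est = SphericalTextureExtractor()
features = est.fit_transform([(cube.values, cube.mask)])  # (1, 20)
```

and from the shell:

```bash
sphtex run --image stack.tif --labels masks.tif --out features.csv --peaks
sphtex synth --kind perlin --seed 1 --out fixtures/
```

`sphtex run` writes one row per label (`label,size_pixels,bin_01..bin_20`,
plus peak columns with `--peaks`) and a sidecar JSON with the bin edges and
configuration.

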