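"""Scikit-learn style transformer exposing the texture descriptor.

``SphericalTextureExtractor`` maps segmented objects — ``(intensity, mask)``
crop pairs — to their fixed-length texture feature vectors, so descriptors
compose directly with sklearn pipelines and model selection (the descriptor
plus object size is the feature set typically fed to a Random Forest object
classifier).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .projection import (
    DEFAULT_CUBE_SIDE,
    DEFAULT_NCIRCLE,
    DEFAULT_NLAT,
    DEFAULT_NLON,
    circular_project,
    normalize,
    rescale_to_cube,
    spherical_project,
)
from .errors import ZeroVarianceError
from .spectra import (
    DEFAULT_NBINS,
    bin_log2,
    fourier_power_spectrum,
    sh_power_spectrum,
)


class SphericalTextureExtractor(TransformerMixin, BaseEstimator):
    """Rotationally invariant, scale-normalized texture features.

    Each sample is one segmented object given as an ``(intensity, mask)``
    pair of co-registered 2D or 3D arrays (any shape; the object is
    resampled to a standard cube internally). ``transform`` returns an
    ``(n_samples, nbins)`` array of per-wavelength-bin variance fractions
    that sum to 1 per object (0 for constant objects when
    ``zero_variance="zero"``).

    Parameters
    ----------
    cube_side : side of the standard resampling cube (voxels).
    nlat, nlon : quadrature sphere grid for 3D objects.
    n_circle : number of circle angles for 2D objects.
    nbins : number of log2-spaced wavelength bins in the descriptor.
    weighted : use area-weighted statistics in the normalization step
        (exact Parseval); plain sample statistics when False.
    zero_variance : ``"error"`` raises on constant objects, ``"zero"`` maps
        them to an all-zero feature vector.
    """

    def __init__(
        self,
        cube_side: int = DEFAULT_CUBE_SIDE,
        nlat: int = DEFAULT_NLAT,
        nlon: int = DEFAULT_NLON,
        n_circle: int = DEFAULT_NCIRCLE,
        nbins: int = DEFAULT_NBINS,
        weighted: bool = True,
        zero_variance: str = "error",
    ):
        self.cube_side = cube_side
        self.nlat = nlat
        self.nlon = nlon
        self.n_circle = n_circle
        self.nbins = nbins
        self.weighted = weighted
        self.zero_variance = zero_variance

    def _validate_params(self):
        for name in ("cube_side", "nlat", "nlon", "n_circle", "nbins"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be positive")
        if self.nlon < 2 * (self.nlat - 1) + 1:
            raise ValueError(
                "nlon must be >= 2*(nlat - 1) + 1 to support the bandlimit"
            )
        if self.zero_variance not in ("error", "zero"):
            raise ValueError("zero_variance must be 'error' or 'zero'")

    def fit(self, X, y=None):
        """Validate parameters; the transform is stateless otherwise."""
        self._validate_params()
        self.n_features_out_ = int(self.nbins)
        self.is_fitted_ = True
        return self

    def transform(self, X) -> np.ndarray:
        """Descriptors for a sequence of ``(intensity, mask)`` object pairs."""
        self.fit(X)
        rows = [self.transform_object(intensity, mask) for intensity, mask in X]
        return np.vstack(rows) if rows else np.empty((0, self.nbins))

    def transform_object(self, intensity, mask) -> np.ndarray:
        """Descriptor of a single object crop (1D array of nbins values)."""
        self._validate_params()
        binned, _ = self.describe_object(intensity, mask)
        return binned.values

    def describe_object(self, intensity, mask, label: int = 1):
        """Full result for one object: (BinnedSpectrum, projection or None).

        The projection is returned normalized when possible, raw for
        constant objects under ``zero_variance="zero"`` (useful for peak
        extraction), and carries the object's original pixel count in the
        descriptor metadata.
        """
        from .spectra import DegreeSpectrum, _wavelength_axis  # local: avoid cycle

        mask = np.asarray(mask)
        size_pixels = int(np.count_nonzero(mask))
        cube = rescale_to_cube(intensity, mask, side=self.cube_side, label=label)
        if cube.ndim == 3:
            proj = spherical_project(cube, self.nlat, self.nlon)
        else:
            proj = circular_project(cube, self.n_circle)
        try:
            proj = normalize(proj, weighted=self.weighted)
            if cube.ndim == 3:
                spec = sh_power_spectrum(proj)
            else:
                spec = fourier_power_spectrum(proj)
            binned = bin_log2(spec, nbins=self.nbins)
        except ZeroVarianceError:
            if self.zero_variance == "error":
                raise
            lmax = self.nlat - 1 if cube.ndim == 3 else self.n_circle // 2
            empty = DegreeSpectrum(
                power=np.zeros(lmax + 1),
                wavelengths=_wavelength_axis(lmax, cube.ndim),
                ndim=cube.ndim,
            )
            binned = bin_log2(empty, nbins=self.nbins)
        binned.label = label
        binned.size_pixels = size_pixels
        return binned, proj

    def get_feature_names_out(self, input_features=None):
        return np.array([f"bin_{i + 1:02d}" for i in range(int(self.nbins))])

    def _more_tags(self):
        return {"X_types": ["list"], "allow_nan": False}
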