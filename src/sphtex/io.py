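"""File formats, run configuration, and batch extraction.

Reads TIFF (single- and multi-page) and HDF5 rasters (axis order ZYX / YX),
runs the descriptor over every label, and writes a CSV feature table
(``label,size_pixels,bin_01..bin_20`` plus optional peak columns) with a
sidecar JSON of bin edges and configuration. Results are independent of the
order objects are processed in; rows are ordered by label.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SphtexError
from .estimator import SphericalTextureExtractor
from .polarization import PeakDirection, angle_between, peak_direction
from .projection import (
    DEFAULT_CUBE_SIDE,
    DEFAULT_NCIRCLE,
    DEFAULT_NLAT,
    DEFAULT_NLON,
    LabeledImage,
    extract_object,
)
from .spectra import DEFAULT_NBINS

logger = logging.getLogger("sphtex")


def read_raster(path, dataset: str | None = None) -> np.ndarray:
    """Read a 2D/3D raster from TIFF or HDF5.

    For HDF5, ``dataset`` names the dataset; defaults to the first one found.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(path))
    if suffix in (".h5", ".hdf5", ".hdf"):
        import h5py

        with h5py.File(path, "r") as f:
            if dataset is None:
                names = []
                f.visititems(
                    lambda n, o: names.append(n) if isinstance(o, h5py.Dataset) else None
                )
                if not names:
                    raise SphtexError(f"no datasets in {path}")
                dataset = names[0]
            return f[dataset][()]
    raise SphtexError(f"unsupported raster format: {path.suffix!r}")


@dataclass
class RunConfig:
    """Configuration of one batch extraction run."""

    image_path: str
    labels_path: str
    out_path: str
    ndim: int | str = "auto"  # 2, 3, or "auto" (from raster dimensionality)
    cube_side: int = DEFAULT_CUBE_SIDE
    nlat: int = DEFAULT_NLAT
    nlon: int = DEFAULT_NLON
    n_circle: int = DEFAULT_NCIRCLE
    nbins: int = DEFAULT_NBINS
    peaks: bool = False
    band: tuple[int, int] | None = None  # band-pass before peak extraction
    reference: tuple[float, ...] | None = None  # angle (2D) / colat, lon (3D)
    zero_variance: str = "error"  # or "zero": all-zero descriptor, keep going
    image_dataset: str | None = None
    labels_dataset: str | None = None
    projections_path: str | None = None  # optional HDF5 dump of projections

    def __post_init__(self):
        for name in ("cube_side", "nlat", "nlon", "n_circle", "nbins"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be positive")
        if self.nlon < 2 * (self.nlat - 1) + 1:
            raise ValueError("nlon must be >= 2*(nlat - 1) + 1")
        if self.ndim not in (2, 3, "auto"):
            raise ValueError("ndim must be 2, 3, or 'auto'")


def _reference_direction(config: RunConfig, ndim: int) -> PeakDirection | None:
    if config.reference is None:
        return None
    ref = tuple(float(v) for v in np.atleast_1d(config.reference))
    if ndim == 2:
        return PeakDirection(angle=ref[0], peak_value=np.nan)
    if len(ref) != 2:
        raise ValueError("3D reference needs (colatitude, longitude)")
    return PeakDirection(angle=ref[1], colatitude=ref[0], peak_value=np.nan)


def run_batch(config: RunConfig) -> pd.DataFrame:
    """Extract descriptors for every label and write CSV + sidecar JSON.

    One row per label >= 1, ordered by label. Per-object failures abort the
    batch unless ``zero_variance="zero"`` handles them; all other errors
    propagate (shape mismatch, unreadable file, no labels).
    """
    intensity = read_raster(config.image_path, config.image_dataset)
    labels = read_raster(config.labels_path, config.labels_dataset)
    if intensity.shape != labels.shape:
        raise SphtexError(
            f"shape mismatch: image {intensity.shape} vs labels {labels.shape}"
        )
    image = LabeledImage(intensity=intensity, labels=np.asarray(labels))
    if config.ndim != "auto" and int(config.ndim) != image.ndim:
        raise SphtexError(
            f"configured ndim={config.ndim} but data is {image.ndim}D"
        )
    ids = image.label_ids()
    if ids.size == 0:
        raise SphtexError("no labels: label image contains only background")

    est = SphericalTextureExtractor(
        cube_side=config.cube_side, nlat=config.nlat, nlon=config.nlon,
        n_circle=config.n_circle, nbins=config.nbins,
        zero_variance=config.zero_variance,
    )
    reference = _reference_direction(config, image.ndim)
    rows = []
    bin_edges = None
    projections = {}
    for label in ids.tolist():
        t0 = time.perf_counter()
        crop, mask = extract_object(image, label)
        binned, proj = est.describe_object(crop, mask, label=label)
        bin_edges = binned.bin_edges
        row = {"label": label, "size_pixels": binned.size_pixels}
        for i, v in enumerate(binned.values):
            row[f"bin_{i + 1:02d}"] = v
        if binned.values.sum() == 0:
            logger.warning("label %d: zero-variance object, descriptor all-zero", label)
        if config.peaks:
            band = tuple(config.band) if config.band else None
            peak = peak_direction(proj, band=band)
            if peak.is_3d:
                row["peak_colatitude"] = peak.colatitude
            row["peak_angle"] = peak.angle
            row["peak_value"] = peak.peak_value
            if reference is not None:
                row["angle_to_reference"] = angle_between(peak, reference)
        if config.projections_path:
            projections[label] = proj.values
        rows.append(row)
        logger.info("label %d done in %.3f s", label, time.perf_counter() - t0)

    table = pd.DataFrame(rows).sort_values("label").reset_index(drop=True)
    out_path = Path(config.out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_path, index=False)
    sidecar = {
        "bin_edges_wavelength": [float(v) for v in bin_edges],
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
    }
    out_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    if config.projections_path:
        import h5py

        with h5py.File(config.projections_path, "w") as f:
            for label, values in projections.items():
                f.create_dataset(f"label_{label}", data=values)
    return table


def read_descriptors(path) -> pd.DataFrame:
    """Read a descriptor CSV back (round-trips values written by run_batch)."""
    return pd.read_csv(path)
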