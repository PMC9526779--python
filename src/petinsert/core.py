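"""Shared domain types for the lesion-insertion pipeline.

Everything downstream (sphere masks, projection, insertion, reconstruction,
analysis) is expressed in terms of a handful of carriers defined here:

* :class:`VoxelGrid` — the image sampling lattice (dims, spacing, origin).
* :class:`VolumeImage` — a 3-D array bound to a grid, with declared units
  (Bq/mL for activity, cm^-1 for attenuation, unitless for masks).
* :class:`Sinogram` — raw-data-domain counts (slice x angle x radial) with
  acquisition metadata.
* :class:`DicomLikeSeries` — per-slice intensity arrays with per-slice
  RescaleSlope / RescaleIntercept, mimicking how clinical consoles encode
  activity concentration in integer DICOM pixels.
* :class:`RunConfig` — the knobs of a full pipeline run.

Coordinate convention (used consistently by masks, VOIs and the projector):
voxel indices are 0-based; voxel (i, j, k) spans ``[i*d, (i+1)*d)`` along each
axis relative to ``origin``, so its center sits at ``origin + (i + 0.5) * d``.
Axis order of arrays is (x, y, z) == (i, j, k); sinogram slices index z.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "VoxelGrid",
    "VolumeImage",
    "Sinogram",
    "DicomLikeSeries",
    "RunConfig",
    "GridMismatchError",
    "FormatError",
]


class GridMismatchError(ValueError):
    """Two objects that must share a grid (or shape) do not."""


class FormatError(ValueError):
    """A container file is missing a required dataset or attribute."""


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3-D voxel lattice.

    Parameters
    ----------
    dims : (nx, ny, nz) voxel counts, each >= 1.
    spacing : voxel edge lengths in mm. The default (1.042, 1.042, 2.8)
        is a common clinical PET matrix sampling (voxel volume ~3.04 mm^3).
    origin : mm position of the outer corner of voxel (0, 0, 0).
    """

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.042, 1.042, 2.8)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise ValueError(f"dims must be three integers >= 1, got {self.dims}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positives, got {self.spacing}")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    def centers(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates (mm) along one axis."""
        n = self.dims[axis]
        d = self.spacing[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * d

    def extent(self, axis: int) -> tuple[float, float]:
        """Physical span (mm) of the grid along one axis."""
        lo = self.origin[axis]
        return lo, lo + self.dims[axis] * self.spacing[axis]

    def center_mm(self) -> tuple[float, float, float]:
        """Geometric center of the grid in mm."""
        return tuple(
            self.origin[a] + 0.5 * self.dims[a] * self.spacing[a] for a in range(3)
        )

    def contains_sphere(self, center: Sequence[float], diameter: float) -> bool:
        r = diameter / 2.0
        for a in range(3):
            lo, hi = self.extent(a)
            if center[a] - r < lo or center[a] + r > hi:
                return False
        return True


@dataclass
class VolumeImage:
    """A 3-D scalar field on a :class:`VoxelGrid`.

    ``units`` is free text but the pipeline uses "Bq/mL" for activity,
    "1/cm" for attenuation coefficients and "" for masks/fractions.
    """

    grid: VoxelGrid
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.dims:
            raise GridMismatchError(
                f"array shape {self.values.shape} != grid dims {self.grid.dims}"
            )

    def copy(self) -> "VolumeImage":
        return VolumeImage(self.grid, self.values.copy(), self.units)

    def total_activity_bq(self) -> float:
        """Integral of the field over the grid: value * voxel volume.

        For a Bq/mL image this is total activity in Bq (1 mm^3 == 1e-3 mL,
        hence the 1e-3 factor).
        """
        return float(self.values.sum() * self.grid.voxel_volume * 1e-3)


@dataclass
class Sinogram:
    """Raw-data-domain counts: slice x angle x radial.

    ``is_expected`` distinguishes expected (real-valued mean) sinograms from
    realized (integer-count) ones; Poisson realization maps the former to the
    latter.
    """

    counts: np.ndarray
    duration_s: float
    model_id: str = ""
    is_expected: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 3:
            raise ValueError(f"counts must be 3-D, got ndim={self.counts.ndim}")
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")
        if np.any(self.counts < 0):
            raise ValueError("sinogram counts must be >= 0")
        if not self.is_expected:
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("realized sinogram must contain integer counts")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    def copy(self) -> "Sinogram":
        return Sinogram(self.counts.copy(), self.duration_s, self.model_id, self.is_expected)


@dataclass
class DicomLikeSeries:
    """Per-slice integer-intensity images with per-slice rescale tags.

    Activity concentration is recovered voxelwise per slice S as::

        AC(Bq/mL) = intensity * rescale_slope[S] + rescale_intercept[S]

    mirroring the DICOM RescaleSlope (0028,1053) / RescaleIntercept
    (0028,1052) convention, where the tags may vary slice to slice.
    Slices are 2-D arrays of shape (nx, ny); slice index is z.
    """

    slices: list[np.ndarray]
    rescale_slope: np.ndarray
    rescale_intercept: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        self.slices = [np.asarray(s) for s in self.slices]
        self.rescale_slope = np.asarray(self.rescale_slope, dtype=np.float64)
        self.rescale_intercept = np.asarray(self.rescale_intercept, dtype=np.float64)
        nz = self.grid.dims[2]
        if len(self.slices) != nz:
            raise GridMismatchError(f"{len(self.slices)} slices for grid nz={nz}")
        if self.rescale_slope.shape != (nz,) or self.rescale_intercept.shape != (nz,):
            raise FormatError("need exactly one RescaleSlope and one RescaleIntercept per slice")
        nx, ny = self.grid.dims[:2]
        for s, arr in enumerate(self.slices):
            if arr.shape != (nx, ny):
                raise GridMismatchError(f"slice {s} shape {arr.shape} != ({nx}, {ny})")

    @property
    def n_slices(self) -> int:
        return len(self.slices)


@dataclass
class RunConfig:
    """Parameters of a full phantom/insert/reconstruct/analyze run.

    Defaults follow the study protocol this package emulates: three replicate
    acquisitions of 323/334/346 s, OSEM with 4 iterations and a 2 mm FWHM
    Gaussian post-filter, mask upsampling factor 16, sphere-to-background
    ratios near 2/4/6/8 plus a cold-sphere (0:1) baseline.
    """

    grid_dims: tuple[int, int, int] = (128, 128, 15)
    grid_spacing: tuple[float, float, float] = (2.6, 2.6, 2.8)
    durations_s: tuple[float, ...] = (323.0, 334.0, 346.0)
    algorithm: str = "OSEM"
    iterations: int = 4
    subsets: int = 34
    post_filter_fwhm_mm: float = 2.0
    seed: int = 0
    upsampling_factor: int = 16
    sbr_list: tuple[float, ...] = (2.07, 3.93, 6.03, 7.97)

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.durations_s):
            raise ValueError("durations must be positive")
        if self.subsets < 1:
            raise ValueError("subsets must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.upsampling_factor < 1:
            raise ValueError("upsampling factor must be >= 1")

    def grid(self) -> VoxelGrid:
        return VoxelGrid(self.grid_dims, self.grid_spacing)

    def with_(self, **kw) -> "RunConfig":
        return replace(self, **kw)
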