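"""Synthetic-lesion insertion into acquired raw data.

The hybrid step: starting from a reconstructed baseline series (radioactive
background, cold spheres) and its raw data,

1. decode the series to activity concentration with the per-slice rescale
   tags (``AC = intensity * slope[S] + intercept[S]``),
2. estimate a background AC baseline as the mean over 12 spherical
   background VOIs of each VOI's fraction-weighted mean AC,
3. build the insertion activity map: (sum of fractional sphere masks) x
   baseline x target sphere-to-background ratio,
4. forward-project the map through the same system model, optionally apply
   a Poisson realization, and sum the result with the original sinogram.

The modified raw data are then reconstructed exactly like the original.
Inserted data add no scatter or random coincidences; the summed sinogram
keeps only whatever the original acquisition contained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import DicomLikeSeries, GridMismatchError, Sinogram, VolumeImage, VoxelGrid
from .io import log_stage
from .spheres import FractionalMask, SphereSpec, generate_sphere_mask
from .system import EfficiencyMap, SystemModel, forward_project, poisson_realize

__all__ = [
    "VoiSpec",
    "InsertionPlan",
    "series_to_activity",
    "estimate_background_ac",
    "build_insertion_map",
    "insert_into_sinogram",
]


@dataclass(frozen=True)
class VoiSpec:
    """A spherical volume of interest: center (mm) and diameter (mm)."""

    center: tuple[float, float, float]
    diameter: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"VOI diameter must be > 0, got {self.diameter}")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    def as_sphere(self) -> SphereSpec:
        return SphereSpec(self.center, self.diameter)


@dataclass
class InsertionPlan:
    """What to insert: spheres, baseline activity, target SBR, noise policy.

    ``sbr`` is the *exact* (measured) sphere-to-background ratio to apply,
    not the nominal one. ``noise_domain`` selects where the Poisson
    realization happens: "sinogram" (default; draws on the expected
    projected counts, statistically standard for count data) or "image"
    (draws per-voxel disintegration counts on the insertion map before
    projection).
    """

    spheres: Sequence[SphereSpec]
    baseline_ac: float
    sbr: float
    noise: bool = True
    seed: int = 0
    noise_domain: str = "sinogram"

    def __post_init__(self) -> None:
        if self.baseline_ac < 0:
            raise ValueError("baseline_ac must be >= 0")
        if self.sbr < 0:
            raise ValueError("sbr must be >= 0")
        if self.noise_domain not in ("sinogram", "image"):
            raise ValueError(f"unknown noise_domain {self.noise_domain!r}")


def series_to_activity(series: DicomLikeSeries) -> VolumeImage:
    """Decode a rescale-tagged series to a Bq/mL activity image, applying
    each slice's slope and intercept voxelwise."""
    nz = series.n_slices
    out = np.empty(series.grid.dims, dtype=np.float64)
    for s in range(nz):
        slope = series.rescale_slope[s]
        icpt = series.rescale_intercept[s]
        if not np.isfinite(slope) or not np.isfinite(icpt):
            raise ValueError(f"non-finite rescale tags at slice S={s}")
        out[:, :, s] = series.slices[s] * slope + icpt
    return VolumeImage(series.grid, out, units="Bq/mL")


def _voi_mask(grid: VoxelGrid, voi: VoiSpec, factor: int) -> FractionalMask:
    return generate_sphere_mask(grid, voi.as_sphere(), factor)


def estimate_background_ac(
    img: VolumeImage, vois: Sequence[VoiSpec], factor: int = 4
) -> float:
    """Background AC baseline (Bq/mL): mean over VOIs of each VOI's
    fraction-weighted mean AC.

    VOI membership uses the same fractional-mask machinery as the sphere
    modeling, so partially covered edge voxels are weighted by their
    occupancy. On a uniform image the result equals the uniform value for
    any VOI placement.
    """
    if not vois:
        raise ValueError("need at least one VOI")
    means = []
    for voi in vois:
        mask = _voi_mask(img.grid, voi, factor)
        w = mask.values
        total = w.sum()
        if total == 0:
            raise ValueError(f"VOI {voi} covers no voxels")
        means.append(float((w * img.values).sum() / total))
    return float(np.mean(means))


def build_insertion_map(
    masks: Sequence[FractionalMask], baseline_ac: float, sbr: float
) -> VolumeImage:
    """Insertion activity map: (sum of masks) * baseline_ac * sbr, Bq/mL.

    A voxel fully inside a sphere carries exactly ``baseline_ac * sbr``.
    Raises if the masks overlap (any summed occupancy > 1).
    """
    if baseline_ac < 0 or sbr < 0:
        raise ValueError("baseline_ac and sbr must be >= 0")
    if not masks:
        raise ValueError("need at least one mask")
    grid = masks[0].grid
    for m in masks[1:]:
        if m.grid.dims != grid.dims or m.grid.spacing != grid.spacing:
            raise GridMismatchError("masks must share one grid")
    summed = np.sum([m.values for m in masks], axis=0)
    if summed.max() > 1.0 + 1e-12:
        raise ValueError("sphere masks overlap (summed occupancy > 1)")
    return VolumeImage(grid, summed * baseline_ac * sbr, units="Bq/mL")


def insert_into_sinogram(
    original: Sinogram,
    insertion_map: VolumeImage,
    model: SystemModel,
    mu: Optional[VolumeImage] = None,
    eff: Optional[EfficiencyMap] = None,
    plan: Optional[InsertionPlan] = None,
) -> Sinogram:
    """Sum the original raw data with the (optionally noise-realized)
    forward projection of the insertion map.

    With ``plan.noise`` False the added term is the expected projection
    (real-valued output); with noise on, a Poisson realization of it
    (integer-count output when the original is integer). The acquisition
    duration is taken from the original sinogram; metadata are preserved.
    Output >= original binwise.
    """
    if original.is_expected and plan is not None and plan.noise:
        raise ValueError("noisy insertion expects a realized original sinogram")
    if original.shape != model.sino_shape(insertion_map.grid):
        raise GridMismatchError(
            f"original sinogram shape {original.shape} != "
            f"{model.sino_shape(insertion_map.grid)}"
        )
    noise = plan.noise if plan is not None else False
    seed = plan.seed if plan is not None else 0
    noise_domain = plan.noise_domain if plan is not None else "sinogram"

    amap = insertion_map
    if noise and noise_domain == "image":
        amap = _realize_image_domain(insertion_map, original.duration_s, seed)

    simulated = forward_project(
        amap, model, mu=mu, eff=eff, duration_s=original.duration_s
    )
    if noise and noise_domain == "sinogram":
        simulated = poisson_realize(simulated, seed)

    log_stage(
        "insert",
        seed=seed if noise else None,
        noise=noise,
        noise_domain=noise_domain,
        added_counts=float(simulated.counts.sum()),
        original=original.counts,
    )
    counts = original.counts + simulated.counts
    is_expected = original.is_expected or simulated.is_expected
    return Sinogram(counts, original.duration_s, original.model_id, is_expected)


def _realize_image_domain(
    amap: VolumeImage, duration_s: float, seed: int
) -> VolumeImage:
    """Poisson-realize per-voxel disintegration counts of the insertion map
    (counts per voxel over the acquisition), then convert back to Bq/mL.

    This follows the literal image-domain reading of noise placement; the
    projected sinogram is then a weighted sum of Poisson variables rather
    than Poisson per bin, which is why the sinogram-domain realization is
    the default.
    """
    rng = np.random.default_rng(seed)
    vox_ml = amap.grid.voxel_volume * 1e-3
    mean_counts = amap.values * vox_ml * duration_s  # Bq/mL * mL * s
    counts = rng.poisson(mean_counts)
    return VolumeImage(amap.grid, counts / (vox_ml * duration_s), amap.units)
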