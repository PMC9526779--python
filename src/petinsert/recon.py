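"""MLEM / OSEM iterative reconstruction.

Standard multiplicative EM updates for Poisson data: per subset S of angles,

    x  <-  x * A_S^T( y_S / A_S x ) / A_S^T 1        (0/0 -> 0)

where A is the same forward model used for data generation (geometry,
attenuation, efficiency; optionally the intrinsic resolution blur when PSF
modeling is requested). Because A carries the full physical scale
(sensitivity x duration x bin cross-section), the iterate is an activity
image in Bq/mL directly. MLEM is OSEM with a single subset; OSEM subsets
partition the angles in interleaved fashion and must divide the angle count
exactly — no silent remainder handling.

Convergence is by fixed iteration count, as on a clinical console; the
Gaussian post-filter is applied once, after the final iteration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import GridMismatchError, Sinogram, VolumeImage, VoxelGrid
from .system import (
    EfficiencyMap,
    SystemModel,
    _blur_array,
    _combined_scale,
    blur_image,
    get_geometry,
)

__all__ = [
    "ReconSettings",
    "osem_reconstruct",
    "mlem_reconstruct",
    "poisson_loglik",
    "average_frames",
    "nearest_divisor_subsets",
]


@dataclass(frozen=True)
class ReconSettings:
    """Reconstruction knobs.

    Defaults follow the emulated console protocol: 4 iterations, a 2 mm
    FWHM Gaussian post-filter, and no PSF modeling in the reconstruction
    operator. ``subsets`` must divide the model's angle count; use
    :func:`nearest_divisor_subsets` to map a nominal count (e.g. the
    console's 34) onto the model geometry.
    """

    algorithm: str = "OSEM"
    iterations: int = 4
    subsets: int = 32
    post_filter_fwhm_mm: float = 2.0
    psf: bool = False
    init_value: float = 1.0

    def __post_init__(self) -> None:
        if self.algorithm not in ("OSEM", "MLEM"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.subsets < 1:
            raise ValueError("subsets must be >= 1")
        if self.post_filter_fwhm_mm < 0:
            raise ValueError("post-filter FWHM must be >= 0")
        if self.init_value <= 0:
            raise ValueError("init_value must be > 0")
        if self.algorithm == "MLEM" and self.subsets != 1:
            raise ValueError("MLEM uses subsets=1")


def nearest_divisor_subsets(n_angles: int, requested: int) -> int:
    """The divisor of ``n_angles`` closest to ``requested`` (ties go to the
    larger divisor)."""
    divs = [d for d in range(1, n_angles + 1) if n_angles % d == 0]
    return min(divs, key=lambda d: (abs(d - requested), -d))


def _subset_angle_lists(n_angles: int, subsets: int) -> list[np.ndarray]:
    if n_angles % subsets != 0:
        raise ValueError(
            f"subsets={subsets} does not partition n_angles={n_angles}"
        )
    return [np.arange(s, n_angles, subsets) for s in range(subsets)]


def osem_reconstruct(
    sino: Sinogram,
    model: SystemModel,
    grid: VoxelGrid,
    mu: Optional[VolumeImage] = None,
    eff: Optional[EfficiencyMap] = None,
    settings: ReconSettings = ReconSettings(),
) -> VolumeImage:
    """OSEM/MLEM reconstruction of a sinogram into a Bq/mL image.

    Deterministic; non-negativity is preserved at every sub-iteration, and
    voxels the system never sees (zero sensitivity) stay at zero.
    """
    if sino.shape != model.sino_shape(grid):
        raise GridMismatchError(
            f"sinogram shape {sino.shape} != {model.sino_shape(grid)}"
        )
    if np.any(sino.counts < 0):
        raise ValueError("sinogram counts must be >= 0")
    subsets = 1 if settings.algorithm == "MLEM" else settings.subsets
    angle_lists = _subset_angle_lists(model.n_angles, subsets)

    nx, ny, nz = grid.dims
    G = get_geometry(grid, model)
    scale = _combined_scale(grid, model, mu, eff, sino.duration_s)
    fwhm = model.intrinsic_fwhm_mm if settings.psf else 0.0

    y = sino.counts  # (nz, nA, nR)
    # Per-subset row slices of the geometry matrix and data/scale views.
    sub = []
    for angles in angle_lists:
        rows = (angles[:, None] * model.n_radial + np.arange(model.n_radial)).ravel()
        Gs = G[rows]
        GsT = Gs.T.tocsr()
        ys = y[:, angles, :].reshape(nz, -1).T            # (bins_s, nz)
        ss = scale[:, angles, :].reshape(nz, -1).T        # (bins_s, nz)
        # Sensitivity image A_S^T 1 (blur is self-adjoint).
        sens = _blur_array((GsT @ ss).reshape(nx, ny, nz), fwhm, grid)
        sub.append((Gs, GsT, ys, ss, sens))

    support = np.zeros((nx, ny, nz), dtype=bool)
    for _, _, _, _, sens in sub:
        support |= sens > 0

    x = np.where(support, float(settings.init_value), 0.0)
    for _ in range(settings.iterations):
        for Gs, GsT, ys, ss, sens in sub:
            proj = ss * (Gs @ _blur_array(x, fwhm, grid).reshape(nx * ny, nz))
            ratio = np.divide(ys, proj, out=np.zeros_like(ys), where=proj > 0)
            bp = _blur_array((GsT @ (ss * ratio)).reshape(nx, ny, nz), fwhm, grid)
            upd = np.divide(bp, sens, out=np.zeros_like(bp), where=sens > 0)
            x = x * upd

    img = VolumeImage(grid, x, units="Bq/mL")
    if settings.post_filter_fwhm_mm > 0:
        img = blur_image(img, settings.post_filter_fwhm_mm)
    return img


def mlem_reconstruct(
    sino: Sinogram,
    model: SystemModel,
    grid: VoxelGrid,
    mu: Optional[VolumeImage] = None,
    eff: Optional[EfficiencyMap] = None,
    iterations: int = 4,
    post_filter_fwhm_mm: float = 0.0,
    psf: bool = False,
) -> VolumeImage:
    """Convenience wrapper: OSEM with a single subset."""
    settings = ReconSettings(
        algorithm="MLEM",
        iterations=iterations,
        subsets=1,
        post_filter_fwhm_mm=post_filter_fwhm_mm,
        psf=psf,
    )
    return osem_reconstruct(sino, model, grid, mu, eff, settings)


def poisson_loglik(sino: Sinogram, expected: Sinogram) -> float:
    """Poisson log-likelihood sum(y log lam - lam) with y log lam := 0 when
    y = 0; returns -inf if some bin has lam = 0 with y > 0."""
    y = sino.counts
    lam = expected.counts
    if y.shape != lam.shape:
        raise GridMismatchError("sinogram shapes differ")
    bad = (lam == 0) & (y > 0)
    if np.any(bad):
        return float("-inf")
    term = np.zeros_like(lam)
    pos = y > 0
    term[pos] = y[pos] * np.log(lam[pos])
    return float(term.sum() - lam.sum())


def average_frames(frames: Sequence[VolumeImage]) -> VolumeImage:
    """Voxelwise arithmetic mean of replicate reconstructions."""
    if not frames:
        raise ValueError("no frames to average")
    grid = frames[0].grid
    for f in frames[1:]:
        if f.grid.dims != grid.dims or f.grid.spacing != grid.spacing:
            raise GridMismatchError("frames must share a grid")
    vals = np.mean([f.values for f in frames], axis=0)
    return VolumeImage(grid, vals, frames[0].units)
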