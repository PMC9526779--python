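"""File containers: HDF5 sinograms, rescale-tagged image series, configs.

Sinograms live in a single HDF5 file (dataset ``/counts`` plus scalar
attributes); reconstructed series are written as a NIfTI volume of integer
intensities plus a JSON sidecar carrying per-slice ``RescaleSlope`` /
``RescaleIntercept`` arrays — the same two tags a DICOM console writes,
without the rest of the DICOM envelope. Both round-trip losslessly (counts
bit-exact; series within one intensity quantization step).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import h5py
import numpy as np
import yaml

from .core import DicomLikeSeries, FormatError, RunConfig, Sinogram, VolumeImage, VoxelGrid

__all__ = [
    "write_sinogram",
    "read_sinogram",
    "write_series",
    "read_series",
    "load_config",
    "save_config",
    "array_checksum",
    "log_stage",
]

logger = logging.getLogger("petinsert")

_SINO_ATTRS = ("duration_s", "model_id", "is_expected")
INTENSITY_MAX = 32000  # int16 headroom for the quantized series


def write_sinogram(sino: Sinogram, path: str | Path, **extra_attrs) -> None:
    """Write a sinogram to an HDF5 container (dataset /counts + attrs)."""
    path = Path(path)
    counts = sino.counts if sino.is_expected else sino.counts.astype(np.int64)
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=counts)
        f.attrs["duration_s"] = sino.duration_s
        f.attrs["model_id"] = sino.model_id
        f.attrs["is_expected"] = bool(sino.is_expected)
        for k, v in extra_attrs.items():
            f.attrs[k] = v


def read_sinogram(path: str | Path) -> Sinogram:
    """Read a sinogram written by :func:`write_sinogram`.

    Raises :class:`FormatError` naming the first missing dataset/attribute.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "counts" not in f:
            raise FormatError(f"{path}: missing dataset 'counts'")
        for attr in _SINO_ATTRS:
            if attr not in f.attrs:
                raise FormatError(f"{path}: missing attribute '{attr}'")
        counts = np.asarray(f["counts"], dtype=np.float64)
        return Sinogram(
            counts=counts,
            duration_s=float(f.attrs["duration_s"]),
            model_id=str(f.attrs["model_id"]),
            is_expected=bool(f.attrs["is_expected"]),
        )


# --------------------------------------------------------------------------
# Rescale-tagged image series.

def activity_to_series(img: VolumeImage) -> DicomLikeSeries:
    """Quantize a Bq/mL image into per-slice integer intensities with
    per-slice RescaleSlope / RescaleIntercept (intercept 0).

    The slope is chosen per slice so the slice maximum maps to
    ``INTENSITY_MAX``; decoding recovers the image within slope/2 per voxel.
    """
    if np.any(img.values < 0):
        raise ValueError("activity image must be >= 0")
    nz = img.grid.dims[2]
    slices: list[np.ndarray] = []
    slopes = np.empty(nz)
    intercepts = np.zeros(nz)
    for k in range(nz):
        sl = img.values[:, :, k]
        mx = float(sl.max())
        slope = mx / INTENSITY_MAX if mx > 0 else 1.0
        slopes[k] = slope
        slices.append(np.round(sl / slope).astype(np.int32))
    return DicomLikeSeries(slices, slopes, intercepts, img.grid)


def write_series(img: VolumeImage, path: str | Path) -> DicomLikeSeries:
    """Write an activity image as NIfTI intensities + JSON rescale sidecar.

    ``path`` is a basename: ``<path>.nii`` and ``<path>.json`` are created.
    Returns the in-memory series that was written.
    """
    import nibabel as nib

    path = Path(path)
    series = activity_to_series(img)
    vol = np.stack(series.slices, axis=2).astype(np.int32)
    affine = np.diag(list(img.grid.spacing) + [1.0])
    affine[:3, 3] = img.grid.origin
    nib.save(nib.Nifti1Image(vol, affine), str(path.with_suffix(".nii")))
    sidecar = {
        "RescaleSlope": series.rescale_slope.tolist(),
        "RescaleIntercept": series.rescale_intercept.tolist(),
        "grid": {
            "dims": list(img.grid.dims),
            "spacing": list(img.grid.spacing),
            "origin": list(img.grid.origin),
        },
        "units": "Bq/mL",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return series


def read_series(path: str | Path) -> DicomLikeSeries:
    """Read a series written by :func:`write_series`."""
    import nibabel as nib

    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"{sidecar_path}: sidecar not found")
    sidecar = json.loads(sidecar_path.read_text())
    for key in ("RescaleSlope", "RescaleIntercept", "grid"):
        if key not in sidecar:
            raise FormatError(f"{sidecar_path}: missing field '{key}'")
    g = sidecar["grid"]
    grid = VoxelGrid(tuple(g["dims"]), tuple(g["spacing"]), tuple(g["origin"]))
    vol = np.asarray(nib.load(str(path.with_suffix(".nii"))).dataobj)
    slices = [vol[:, :, k] for k in range(grid.dims[2])]
    return DicomLikeSeries(
        slices,
        np.asarray(sidecar["RescaleSlope"], dtype=np.float64),
        np.asarray(sidecar["RescaleIntercept"], dtype=np.float64),
        grid,
    )


# --------------------------------------------------------------------------
# Config + provenance logging.

def save_config(config: RunConfig, path: str | Path) -> None:
    d = {
        "grid": {"dims": list(config.grid_dims), "spacing": list(config.grid_spacing)},
        "acquisition": {"durations_s": list(config.durations_s)},
        "reconstruction": {
            "algorithm": config.algorithm,
            "iterations": config.iterations,
            "subsets": config.subsets,
            "post_filter_fwhm_mm": config.post_filter_fwhm_mm,
        },
        "insertion": {
            "upsampling_factor": config.upsampling_factor,
            "sbr_list": list(config.sbr_list),
        },
        "seed": config.seed,
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    d = yaml.safe_load(Path(path).read_text())
    try:
        return RunConfig(
            grid_dims=tuple(d["grid"]["dims"]),
            grid_spacing=tuple(d["grid"]["spacing"]),
            durations_s=tuple(d["acquisition"]["durations_s"]),
            algorithm=d["reconstruction"]["algorithm"],
            iterations=int(d["reconstruction"]["iterations"]),
            subsets=int(d["reconstruction"]["subsets"]),
            post_filter_fwhm_mm=float(d["reconstruction"]["post_filter_fwhm_mm"]),
            seed=int(d.get("seed", 0)),
            upsampling_factor=int(d["insertion"]["upsampling_factor"]),
            sbr_list=tuple(d["insertion"]["sbr_list"]),
        )
    except KeyError as e:
        raise FormatError(f"{path}: missing config field {e}") from e


def array_checksum(arr: np.ndarray) -> str:
    """Short sha256 of an array's bytes, for provenance logs."""
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:12]


def log_stage(stage: str, seed: int | None = None, **items) -> None:
    """One provenance log line per pipeline stage: parameters, seed, and
    checksums of array inputs, so replicate runs are traceable."""
    parts = [f"stage={stage}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    for k, v in items.items():
        if isinstance(v, np.ndarray):
            parts.append(f"{k}_sha={array_checksum(v)}")
        else:
            parts.append(f"{k}={v}")
    logger.info(" ".join(parts))
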