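"""File I/O: NIfTI images/label maps, sinogram archives, JSON sidecars.

Images are written as float32 NIfTI (.nii or .nii.gz) with the voxel
spacing in the affine/zooms; computations stay float64 in memory.  Label
maps are int16 NIfTI plus a JSON legend.  Sinograms are stored as a .npz
array file next to a JSON sidecar holding the geometry, normalization,
background and dose fraction, so a reconstruction can be re-run from disk
alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import ImageGrid, RoiLabelMap
from .projection import SystemModel, Sinogram

__all__ = [
    "write_nifti",
    "read_nifti",
    "write_label_map",
    "read_label_map",
    "write_sinogram",
    "read_sinogram",
]


def _affine(spacing: tuple[float, ...]) -> np.ndarray:
    zooms = list(spacing) + [1.0] * (3 - len(spacing))
    return np.diag(list(zooms[:3]) + [1.0])


def write_nifti(img: ImageGrid, path: "str | Path") -> Path:
    """Write an image as float32 NIfTI; 2-D images gain a singleton axis."""
    path = Path(path)
    data = np.asarray(img.values, dtype=np.float32)
    if data.ndim == 2:
        data = data[..., None]
    nib.save(nib.Nifti1Image(data, _affine(img.spacing_mm)), str(path))
    return path


def read_nifti(path: "str | Path") -> ImageGrid:
    try:
        nii = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise ValueError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asarray(nii.dataobj, dtype=np.float64)
    zooms = nii.header.get_zooms()[: data.ndim]
    if data.ndim == 3 and data.shape[-1] == 1:
        data = data[..., 0]
        zooms = zooms[:2]
    return ImageGrid(data, tuple(float(z) for z in zooms))


def write_label_map(rois: RoiLabelMap, path: "str | Path") -> Path:
    """Integer NIfTI plus a ``<stem>.legend.json`` sidecar."""
    path = Path(path)
    data = np.asarray(rois.labels, dtype=np.int16)
    if data.ndim == 2:
        data = data[..., None]
    nib.save(nib.Nifti1Image(data, _affine(rois.spacing_mm)), str(path))
    legend_path = path.with_suffix("").with_suffix("")  # strip .nii[.gz]
    legend_path = legend_path.parent / (legend_path.name + ".legend.json")
    legend_path.write_text(json.dumps({str(k): v for k, v in rois.legend.items()}))
    return path


def read_label_map(path: "str | Path") -> RoiLabelMap:
    path = Path(path)
    nii = nib.load(str(path))
    data = np.asarray(nii.dataobj).astype(np.int16)
    zooms = nii.header.get_zooms()[: data.ndim]
    if data.ndim == 3 and data.shape[-1] == 1:
        data = data[..., 0]
        zooms = zooms[:2]
    stem = path.with_suffix("").with_suffix("")
    legend_path = stem.parent / (stem.name + ".legend.json")
    legend = {}
    if legend_path.exists():
        legend = {int(k): v for k, v in json.loads(legend_path.read_text()).items()}
    return RoiLabelMap(data, legend, tuple(float(z) for z in zooms))


def write_sinogram(sino: Sinogram, model: SystemModel, path: "str | Path") -> Path:
    """``path.npz`` with the counts + ``path.json`` with model/dose metadata."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    np.savez_compressed(path, values=sino.values)
    meta = {
        "n_angles": model.n_angles,
        "n_radial_bins": model.n_radial_bins,
        "bin_spacing_mm": model.bin_spacing_mm,
        "psf_fwhm_mm": model.psf_fwhm_mm,
        "normalization": np.asarray(model.normalization).tolist(),
        "background": np.asarray(model.background).tolist(),
        "dose_fraction": sino.dose_fraction,
    }
    path.with_suffix(".json").write_text(json.dumps(meta))
    return path


def read_sinogram(path: "str | Path") -> tuple[Sinogram, SystemModel]:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    try:
        values = np.load(path)["values"]
        meta = json.loads(path.with_suffix(".json").read_text())
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"cannot read sinogram archive {path}: {exc}") from exc
    model = SystemModel(
        n_angles=int(meta["n_angles"]),
        n_radial_bins=int(meta["n_radial_bins"]),
        bin_spacing_mm=float(meta["bin_spacing_mm"]),
        psf_fwhm_mm=float(meta["psf_fwhm_mm"]),
        normalization=np.asarray(meta["normalization"], dtype=np.float64),
        background=np.asarray(meta["background"], dtype=np.float64),
    )
    return Sinogram(values, float(meta["dose_fraction"])), model
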