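"""NIfTI + FSL bval/bvec readers and writers, and run metadata."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

from .__about__ import __version__
from .acquisition import AcquisitionScheme
from .errors import GeometryError
from .fitting import ParameterMaps

__all__ = ["read_bvals_bvecs", "write_bvals_bvecs", "read_dataset", "write_maps"]


def read_bvals_bvecs(bval_path, bvec_path):
    """Parse FSL row-major .bval/.bvec text files.

    b-vector columns are renormalized to unit length; zero vectors (b = 0
    volumes) are preserved.
    """
    bvals = np.loadtxt(bval_path, ndmin=1).ravel()
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        bvecs = bvecs.T  # FSL convention: one row per axis
    if bvecs.shape != (bvals.size, 3):
        raise GeometryError(f"bvec entries {bvecs.shape} inconsistent with {bvals.size} bvals")
    norms = np.linalg.norm(bvecs, axis=1)
    nz = norms > 0
    bvecs[nz] /= norms[nz, None]
    return bvals, bvecs


def write_bvals_bvecs(scheme: AcquisitionScheme, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.8f")


def read_dataset(dwi_path, bval_path, bvec_path, mask_path=None):
    """Load a 4-D NIfTI volume with its acquisition scheme and mask.

    Returns ``(data, scheme, mask, img)`` where ``img`` is the nibabel image
    (carrying the affine/header for output writing).  A missing mask yields
    a full-extent mask with a warning.
    """
    img = nib.load(str(dwi_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise GeometryError(f"expected a 4-D volume, got shape {data.shape}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"non-finite voxels in {dwi_path}")
    bvals, bvecs = read_bvals_bvecs(bval_path, bvec_path)
    if bvals.size != data.shape[-1]:
        raise GeometryError(
            f"bval count {bvals.size} != volume count {data.shape[-1]} in {dwi_path}")
    scheme = AcquisitionScheme(bvals=bvals, bvecs=bvecs)
    if mask_path is not None:
        mask_img = nib.load(str(mask_path))
        mask = np.asarray(mask_img.dataobj) > 0
        if mask.shape != data.shape[:-1]:
            raise GeometryError(f"mask shape {mask.shape} != spatial dims {data.shape[:-1]}")
    else:
        warnings.warn("no mask supplied; fitting the full image extent", stacklevel=2)
        mask = np.ones(data.shape[:-1], dtype=bool)
    return data, scheme, mask, img


def write_maps(maps: ParameterMaps, reference, out_dir, metadata: dict | None = None):
    """Write parameter maps as NIfTI next to a JSON metadata record.

    ``reference`` is a nibabel image (or (affine, header) pair) whose
    geometry the outputs inherit.  The NaN sentinel is stored as-is.
    Returns the list of written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(reference, tuple):
        affine, header = reference
    else:
        affine, header = reference.affine, reference.header
    written = []
    arrays = {"d12": maps.d12_map, "alpha": maps.alpha_map,
              "ip": maps.ip_map, "mse": maps.mse_map,
              "mask": maps.mask.astype(np.uint8)}
    for name, arr in arrays.items():
        path = out / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine, header), str(path))
        written.append(path)
    meta = {"software": "qdi", "version": __version__}
    meta.update(metadata or {})
    meta_path = out / "qdi_fit.json"
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    written.append(meta_path)
    return written


def read_maps(map_dir) -> ParameterMaps:
    """Load a map set previously written by :func:`write_maps`."""
    d = Path(map_dir)
    arrays = {}
    for name in ("d12", "alpha", "ip", "mse", "mask"):
        path = d / f"{name}.nii.gz"
        if not path.exists():
            raise FileNotFoundError(f"missing map file {path}")
        arrays[name] = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    return ParameterMaps(d12_map=arrays["d12"], alpha_map=arrays["alpha"],
                         ip_map=arrays["ip"], mse_map=arrays["mse"],
                         mask=arrays["mask"] > 0)
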