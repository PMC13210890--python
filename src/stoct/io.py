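"""Readers and writers for interferogram stacks and reconstructed volumes.

HDF5 is the primary container (datasets ``/data`` (ny, nx, n_k) and
``/k_axis``, attributes ``mask_id``, ``mode``, ``config`` JSON); multi-page
TIFF (one page per wavelength) with a JSON sidecar carrying the wavenumber
axis is supported for interoperability with microscopy viewers.
"""

from __future__ import annotations

import json
import os

import h5py
import numpy as np
import tifffile

from .forward import SpectralStack
from .recon import ReconVolume


def write_stack(stack: SpectralStack, path: str, dtype: str = "float32",
                config_json: str | None = None) -> str:
    """Write a stack to HDF5 (``.h5``/``.hdf5``) or multi-page TIFF + JSON
    sidecar (any other extension).

    float32 round-trips losslessly; uint16 export applies an affine scaling
    recorded in the attributes (``scale``, ``offset``:
    stored = (data − offset)/scale).
    """
    ext = os.path.splitext(path)[1].lower()
    data = stack.data
    if dtype == "float32":
        out, scale, offset = data.astype(np.float32), 1.0, 0.0
    elif dtype == "uint16":
        offset = float(data.min())
        rng = float(data.max() - offset)
        scale = rng / 65535.0 if rng > 0 else 1.0
        out = np.round((data - offset) / scale).astype(np.uint16)
    else:
        raise ValueError("dtype must be 'float32' or 'uint16'")
    meta = {
        "mask_id": stack.mask_id,
        "mode": stack.acquisition_mode,
        "dc_removed": stack.dc_removed,
        "scale": scale,
        "offset": offset,
    }
    if ext in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=out)
            f.create_dataset("k_axis", data=np.asarray(stack.k_axis, dtype=np.float64))
            for key, val in meta.items():
                f.attrs[key] = val
            if config_json is not None:
                f.attrs["config"] = config_json
        return path
    # TIFF: one page per wavelength
    pages = np.moveaxis(out, 2, 0)
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {**meta, "k_axis": np.asarray(stack.k_axis, dtype=float).tolist()}
    if config_json is not None:
        sidecar["config"] = config_json
    with open(_sidecar_path(path), "w") as f:
        json.dump(sidecar, f)
    return path


def _sidecar_path(path: str) -> str:
    return os.path.splitext(path)[0] + ".json"


def read_stack(path: str) -> SpectralStack:
    """Read a stack written by :func:`write_stack`."""
    ext = os.path.splitext(path)[1].lower()
    if ext in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "k_axis" not in f:
                raise KeyError(f"{path}: missing dataset 'k_axis'")
            if "data" not in f:
                raise KeyError(f"{path}: missing dataset 'data'")
            data = f["data"][...]
            k_axis = f["k_axis"][...]
            meta = dict(f.attrs)
    else:
        pages = tifffile.imread(path)
        if pages.ndim == 2:
            pages = pages[None]
        data = np.moveaxis(pages, 0, 2)
        sidecar = _sidecar_path(path)
        if not os.path.exists(sidecar):
            raise FileNotFoundError(f"{path}: missing JSON sidecar with 'k_axis'")
        with open(sidecar) as f:
            meta = json.load(f)
        if "k_axis" not in meta:
            raise KeyError(f"{sidecar}: missing 'k_axis'")
        k_axis = np.asarray(meta["k_axis"], dtype=float)
    if len(k_axis) != data.shape[2]:
        raise ValueError(
            f"{path}: k_axis has {len(k_axis)} entries for {data.shape[2]} pages"
        )
    scale = float(meta.get("scale", 1.0))
    offset = float(meta.get("offset", 0.0))
    if data.dtype == np.uint16:
        data = data.astype(np.float64) * scale + offset
    else:
        data = data.astype(np.float32)
    mask_id = meta.get("mask_id", 0)
    if isinstance(mask_id, (np.integer, int)):
        mask_id = int(mask_id)
    return SpectralStack(
        data,
        np.asarray(k_axis, dtype=float),
        mask_id=mask_id,
        acquisition_mode=str(meta.get("mode", "sequential")),
        dc_removed=bool(meta.get("dc_removed", False)),
    )


def write_volume(volume: ReconVolume, path: str, magnitude_uint16: bool = True) -> str:
    """Write a complex reconstruction to HDF5: ``/real``, ``/imag``,
    ``/z_axis``, optional ``/magnitude`` uint16 export, and the provenance
    chain as a JSON attribute."""
    with h5py.File(path, "w") as f:
        f.create_dataset("real", data=volume.data.real.astype(np.float32))
        f.create_dataset("imag", data=volume.data.imag.astype(np.float32))
        f.create_dataset("z_axis", data=np.asarray(volume.z_axis, dtype=np.float64))
        if magnitude_uint16:
            mag = np.abs(volume.data)
            peak = mag.max()
            scale = peak / 65535.0 if peak > 0 else 1.0
            f.create_dataset("magnitude", data=np.round(mag / scale).astype(np.uint16))
            f.attrs["magnitude_scale"] = scale
        f.attrs["provenance"] = json.dumps(volume.provenance)
    return path


def read_volume(path: str) -> ReconVolume:
    with h5py.File(path, "r") as f:
        for name in ("real", "imag", "z_axis"):
            if name not in f:
                raise KeyError(f"{path}: missing dataset {name!r}")
        data = f["real"][...].astype(np.float64) + 1j * f["imag"][...].astype(np.float64)
        z_axis = f["z_axis"][...]
        prov = json.loads(f.attrs.get("provenance", "[]"))
    return ReconVolume(data, z_axis, prov)


def write_gmatrix(gamma: np.ndarray, path: str, roi_desc: str = "") -> str:
    """Save a coherence matrix as paired real datasets with ROI metadata."""
    with h5py.File(path, "w") as f:
        f.create_dataset("gamma_real", data=gamma.real)
        f.create_dataset("gamma_imag", data=gamma.imag)
        f.attrs["roi"] = roi_desc
    return path
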