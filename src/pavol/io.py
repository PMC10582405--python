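"""File I/O: volumes as NIfTI-1 or multi-page TIFF, sinogram stacks as HDF5.

NIfTI carries the voxel spacing in its header affine; TIFF volumes get a
JSON sidecar (``<name>.json``) with the grid metadata, since multi-page TIFF
has no standard 3D spacing fields. Sinogram stacks live in one HDF5 file
with dataset ``/sinogram`` shaped (positions, elements, samples) and the
transducer/scan configuration stored as attributes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import tifffile

from .acoustics import ScanConfig, Sinogram, TransducerSpec
from .grid import VoxelGrid
from .recon import ReconVolume

__all__ = [
    "save_volume",
    "load_volume",
    "save_sinograms",
    "load_sinograms",
]


def save_volume(vol: ReconVolume, path, centerlines: list | None = None) -> None:
    """Write a volume as .nii/.nii.gz or .tif/.tiff (with JSON sidecar)."""
    path = Path(path)
    meta = {
        "grid": vol.grid.to_dict(),
        "normalized": vol.normalized,
    }
    if centerlines is not None:
        meta["centerlines"] = centerlines
    if path.suffix in (".nii", ".gz"):
        affine = np.diag(list(vol.grid.spacing_mm) + [1.0])
        img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), affine)
        img.header.set_zooms(vol.grid.spacing_mm)
        nib.save(img, str(path))
        if centerlines is not None:
            path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))
    elif path.suffix in (".tif", ".tiff"):
        # pages along axial so each page is a (lateral, elevation) section
        tifffile.imwrite(str(path), np.asarray(vol.data, dtype=np.float32))
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))
    else:
        raise ValueError(f"unsupported volume format: {path.suffix!r}")


def load_volume(path) -> ReconVolume:
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float32)
        zooms = img.header.get_zooms()[:3]
        sidecar = path.with_suffix(path.suffix + ".json")
        standoff = 30.0
        normalized = False
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            standoff = meta["grid"].get("standoff_mm", 30.0)
            normalized = bool(meta.get("normalized", False))
        grid = VoxelGrid(shape=data.shape, spacing_mm=tuple(float(z) for z in zooms),
                         standoff_mm=standoff)
        return ReconVolume(data=data, grid=grid, normalized=normalized)
    if path.suffix in (".tif", ".tiff"):
        data = tifffile.imread(str(path)).astype(np.float32)
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            grid = VoxelGrid.from_dict(meta["grid"])
            normalized = bool(meta.get("normalized", False))
        else:
            grid = VoxelGrid(shape=data.shape)
            normalized = False
        return ReconVolume(data=data, grid=grid, normalized=normalized)
    raise ValueError(f"unsupported volume format: {path.suffix!r}")


def save_sinograms(
    sinos: list[Sinogram],
    path,
    spec: TransducerSpec,
    scan: ScanConfig,
) -> None:
    """Write one scan's sinogram stack to HDF5."""
    stack = np.stack([s.data for s in sinos])
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("sinogram", data=stack, compression="gzip")
        ds.attrs["sampling_rate_MHz"] = sinos[0].sampling_rate_MHz
        ds.attrs["t0_us"] = sinos[0].t0_us
        f.attrs["transducer"] = json.dumps(dataclasses.asdict(spec))
        f.attrs["scan"] = json.dumps(dataclasses.asdict(scan))


def load_sinograms(path) -> tuple[list[Sinogram], TransducerSpec, ScanConfig]:
    with h5py.File(path, "r") as f:
        ds = f["sinogram"]
        fs = float(ds.attrs["sampling_rate_MHz"])
        t0 = float(ds.attrs["t0_us"])
        stack = ds[()]
        spec = TransducerSpec(**json.loads(f.attrs["transducer"]))
        scan = ScanConfig(**json.loads(f.attrs["scan"]))
    sinos = [
        Sinogram(data=stack[k], sampling_rate_MHz=fs, t0_us=t0, position_index=k)
        for k in range(stack.shape[0])
    ]
    return sinos, spec, scan
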