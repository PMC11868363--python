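"""File I/O: HDF5 containers for masks and k-space, NIfTI images, CSV curves."""

from __future__ import annotations

import json

import h5py
import nibabel as nib
import numpy as np

from .recon import ImageVolume, KSpaceVolume
from .sampling import SamplingMask


def save_mask(path, mask: SamplingMask):
    """Write a sampling mask to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("mask", data=mask.sampled.astype(np.uint8))
        if mask.acquisition_order:
            order = np.concatenate(mask.acquisition_order, axis=0)
            lens = np.array([len(g) for g in mask.acquisition_order],
                            dtype=np.int32)
        else:
            order = np.zeros((0, 2), dtype=np.int32)
            lens = np.zeros(0, dtype=np.int32)
        f.create_dataset("order", data=order.astype(np.int32))
        f.create_dataset("group_lengths", data=lens)
        f.attrs["factor"] = mask.undersampling_factor
        f.attrs["angle"] = mask.golden_angle_deg
        f.attrs["scheme"] = mask.scheme


def load_mask(path) -> SamplingMask:
    with h5py.File(path, "r") as f:
        sampled = f["mask"][()].astype(bool)
        order_flat = f["order"][()]
        lens = f["group_lengths"][()]
        order = []
        pos = 0
        for n in lens:
            order.append(order_flat[pos:pos + n])
            pos += n
        return SamplingMask(
            grid_shape=sampled.shape, sampled=sampled,
            undersampling_factor=float(f.attrs["factor"]),
            acquisition_order=order,
            golden_angle_deg=float(f.attrs["angle"]),
            scheme=str(f.attrs["scheme"]),
        )


def save_kspace(path, kspace: KSpaceVolume):
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=kspace.data.astype(np.complex64))
        g = f.create_group("mask")
        g.create_dataset("mask", data=kspace.mask.sampled.astype(np.uint8))
        g.attrs["factor"] = kspace.mask.undersampling_factor
        g.attrs["angle"] = kspace.mask.golden_angle_deg
        g.attrs["scheme"] = kspace.mask.scheme
        if "phase_spacing" in kspace.mask.metadata:
            g.attrs["phase_spacing"] = kspace.mask.metadata["phase_spacing"]


def load_kspace(path) -> KSpaceVolume:
    with h5py.File(path, "r") as f:
        data = f["kspace"][()].astype(np.complex128)
        g = f["mask"]
        sampled = g["mask"][()].astype(bool)
        metadata = {}
        if "phase_spacing" in g.attrs:
            metadata["phase_spacing"] = int(g.attrs["phase_spacing"])
        mask = SamplingMask(
            grid_shape=sampled.shape, sampled=sampled,
            undersampling_factor=float(g.attrs["factor"]),
            acquisition_order=[],
            golden_angle_deg=float(g.attrs["angle"]),
            scheme=str(g.attrs["scheme"]), metadata=metadata,
        )
        return KSpaceVolume(data=data, mask=mask, n_coils=data.shape[0])


def save_image(path, image: ImageVolume):
    """Write an image volume as NIfTI-1 with mm voxel spacing."""
    vals = np.asarray(image.values)
    if np.iscomplexobj(vals):
        vals = np.abs(vals)
    spacing = list(image.voxel_spacing_mm) + [1.0] * (3 - vals.ndim)
    affine = np.diag(list(spacing[:3]) + [1.0])
    nib.save(nib.Nifti1Image(vals.astype(np.float64), affine), str(path))


def load_image(path) -> ImageVolume:
    img = nib.load(str(path))
    vals = np.asarray(img.get_fdata())
    spacing = tuple(float(z) for z in img.header.get_zooms()[:vals.ndim])
    fov = spacing[0] * vals.shape[0]
    return ImageVolume(values=vals, fov_mm=fov, voxel_spacing_mm=spacing)


def save_curve_csv(path, xs, ys, header=("x", "y")):
    with open(path, "w") as f:
        f.write(",".join(header) + "\n")
        for x, y in zip(xs, ys):
            f.write(f"{x:.8g},{y:.8g}\n")


def save_report_json(path, report: dict):
    """Deterministic JSON dump (sorted keys, native types)."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as f:
        json.dump(report, f, indent=2, sort_keys=True, default=default)
        f.write("\n")
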