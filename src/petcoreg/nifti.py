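"""NIfTI-1 read/write for :class:`~petcoreg.geometry.Volume`.

The geometry maps to the NIfTI affine as ``A[:3, :3] = direction @ diag(spacing)``
and ``A[:3, 3] = origin``, consistent with the voxel-center origin convention
used throughout the package (NIfTI likewise addresses voxel centers).
"""

from __future__ import annotations

import numpy as np
import nibabel as nib

from .geometry import ImageGeometry, Volume

__all__ = ["volume_to_nifti", "nifti_to_volume", "write_volume", "read_volume"]


def volume_to_nifti(vol: Volume) -> nib.Nifti1Image:
    g = vol.geometry
    affine = np.eye(4)
    affine[:3, :3] = g.direction @ np.diag(g.spacing)
    affine[:3, 3] = g.origin
    img = nib.Nifti1Image(vol.values.astype(np.float64), affine)
    img.header.set_xyzt_units("mm")
    if vol.label:
        img.header["descrip"] = vol.label.encode()[:79]
    return img


def nifti_to_volume(img: nib.Nifti1Image, label: str = "") -> Volume:
    affine = np.asarray(img.affine, dtype=float)
    M = affine[:3, :3]
    spacing = np.linalg.norm(M, axis=0)
    if np.any(spacing <= 0):
        raise ValueError("degenerate NIfTI affine (zero column norm)")
    direction = M / spacing
    if np.linalg.det(direction) < 0:
        raise ValueError(
            "left-handed NIfTI orientation not supported; re-orient the image first"
        )
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    geom = ImageGeometry(
        shape=data.shape,
        spacing=tuple(spacing),
        origin=tuple(affine[:3, 3]),
        direction=direction,
    )
    return Volume(geometry=geom, values=data, label=label)


def write_volume(vol: Volume, path) -> None:
    nib.save(volume_to_nifti(vol), str(path))


def read_volume(path, label: str = "") -> Volume:
    return nifti_to_volume(nib.load(str(path)), label=label)
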