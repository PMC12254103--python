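"""NIfTI-1 image I/O and YAML experiment configuration."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .phantom import GridSpec, VoxelImage


def save_image(image: VoxelImage, path: str | Path) -> None:
    """Write a VoxelImage as NIfTI-1; the diagonal affine carries the voxel
    sizes (mm) and the origin the coordinate of voxel (0, 0, 0)."""
    affine = np.diag(list(image.grid.voxel_size) + [1.0])
    affine[:3, 3] = image.grid.origin
    img = nib.Nifti1Image(image.values.astype(np.float32), affine)
    img.header.set_zooms(image.grid.voxel_size)
    nib.save(img, str(path))


def load_image(path: str | Path) -> VoxelImage:
    """Read a NIfTI-1 file written by :func:`save_image`.

    Only axis-aligned, positively-oriented affines are accepted; anything
    else is an explicit error rather than a silent reorientation.
    """
    img = nib.load(str(path))
    affine = img.affine
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if not np.allclose(off_diag, 0.0, atol=1e-6) or np.any(np.diag(rot) <= 0):
        raise ValueError(
            f"unsupported NIfTI orientation in {path}: affine rotation block "
            f"{rot.tolist()} is not a positive diagonal; reorient the image "
            "explicitly before loading")
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D image, got shape {data.shape} in {path}")
    grid = GridSpec(shape=data.shape,
                    voxel_size=tuple(float(v) for v in np.diag(rot)),
                    origin=tuple(float(v) for v in affine[:3, 3]))
    return VoxelImage(grid=grid, values=data, meta={"source": str(path)})


def load_config_file(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration in {path} must be a mapping")
    return cfg
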