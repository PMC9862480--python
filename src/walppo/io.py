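"""NIfTI and tabular I/O.

Volumes are stored and read as NIfTI (.nii/.nii.gz) and reoriented to the
closest RAS orientation on load, so a CT volume and its lobe label map always
align.  Spacing comes from the header; HU grids round-trip bit-identically as
int16.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np

from .errors import FormatError, MissingFileError, ShapeMismatchError
from .qct import CTVolume, LobeLabelMap


def _load_canonical(path) -> tuple[np.ndarray, tuple[float, float, float], np.ndarray]:
    if not os.path.exists(path):
        raise MissingFileError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as err:  # nibabel raises a zoo of types
        raise FormatError(f"cannot read NIfTI {path}: {err}") from err
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got {data.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing, img.affine


def read_ct(path) -> CTVolume:
    """Read a CT volume; HU values are rounded to int16."""
    data, spacing, affine = _load_canonical(path)
    values = np.rint(np.asarray(data, dtype=float)).astype(np.int16)
    return CTVolume(values, spacing, affine)


def read_lobes(path) -> LobeLabelMap:
    """Read a lobe label map; labels validated against {0..5}."""
    data, spacing, affine = _load_canonical(path)
    values = np.rint(np.asarray(data, dtype=float)).astype(np.int16)
    return LobeLabelMap(values, spacing, affine)


def check_aligned(ct: CTVolume, lobes: LobeLabelMap) -> None:
    if ct.shape != lobes.shape:
        raise ShapeMismatchError(
            f"CT shape {ct.shape} != lobe map shape {lobes.shape}"
        )


def write_nifti(volume: CTVolume | LobeLabelMap, path) -> None:
    """Write a volume as NIfTI with spacing encoded in a diagonal RAS affine."""
    affine = volume.affine
    if affine is None:
        affine = np.diag([*volume.spacing_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(volume.values, dtype=np.int16), affine)
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))
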