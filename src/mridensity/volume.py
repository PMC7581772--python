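"""3D scalar volumes with isotropic spacing, plus NIfTI round-trip I/O.

The :class:`Volume` is the in-memory currency of the whole pipeline: the
phantom renderer produces one, preprocessing transforms it, the CNN consumes
it, and attribution maps are written back on its grid.  Every operation that
touches a volume appends a line to its provenance so a label or a prediction
can always be traced to the exact chain of transforms that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = ["Volume", "read_volume", "write_volume", "read_mask", "write_mask"]


@dataclass
class Volume:
    """A 3D scalar grid with isotropic voxel spacing.

    Parameters
    ----------
    values
        3D array of voxel intensities (any float dtype; finite).
    voxel_size_mm
        Isotropic spacing in millimetres, strictly positive.
    provenance
        Ordered record of the operations applied so far.
    """

    values: np.ndarray
    voxel_size_mm: float = 1.35
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.values.ndim}D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        if not self.voxel_size_mm > 0:
            raise ValueError("voxel size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.values.shape)  # type: ignore[return-value]

    def with_values(self, values: np.ndarray, note: str) -> "Volume":
        """New volume on the same grid with `note` appended to provenance."""
        return replace(self, values=values, provenance=[*self.provenance, note])


def read_volume(path) -> Volume:
    """Read a 3D NIfTI file; spacing is taken from the header zooms."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D NIfTI, got {data.ndim}D data in {path}")
    zooms = img.header.get_zooms()[:3]
    return Volume(
        values=np.asarray(data, dtype=np.float64),
        voxel_size_mm=float(zooms[0]),
        provenance=[f"read:{path}"],
    )


def write_volume(volume: Volume, path) -> None:
    """Write a volume as NIfTI with the voxel size in the header."""
    affine = np.diag([volume.voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(volume.values, dtype=np.float64), affine)
    img.header.set_zooms((volume.voxel_size_mm,) * 3)
    nib.save(img, str(path))


def read_mask(path) -> np.ndarray:
    """Read a binary mask stored as NIfTI; any nonzero voxel is True."""
    return np.asanyarray(nib.load(str(path)).dataobj) > 0


def write_mask(mask: np.ndarray, voxel_size_mm: float, path) -> None:
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
    img.header.set_zooms((voxel_size_mm,) * 3)
    nib.save(img, str(path))
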