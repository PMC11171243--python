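"""Voxel label grids and file I/O.

A :class:`LabelGrid` is the geometric substrate shared by the phantom
generator, the thermal solver and the mask metrics: an integer label array
(3-D, or 2-D for axisymmetric ``(r, z)`` sections) with per-axis voxel spacing
in millimetres and a physical origin.  Voxel centres sit at
``origin + (index + 0.5) * spacing``; labels are mutually exclusive.

I/O goes through the standard neuroimaging containers: NIfTI via nibabel and
NRRD via SimpleITK.  Scalar fields can additionally be dumped as legacy ASCII
VTK structured points for quick inspection in ParaView.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import SimpleITK as sitk


class Tissue(enum.IntEnum):
    """Label legend used by every phantom and solver in the package."""

    BACKGROUND = 0
    LIVER = 1
    TUMOR = 2
    VESSEL = 3
    ANTENNA_INNER_CONDUCTOR = 4
    ANTENNA_DIELECTRIC = 5
    ANTENNA_OUTER_CONDUCTOR = 6
    ANTENNA_SLOT = 7
    CATHETER = 8


@dataclass
class LabelGrid:
    """Integer label map on a regular axis-aligned grid.

    Parameters
    ----------
    labels
        Integer array, ``(nx, ny, nz)`` for volumes or ``(nr, nz)`` for
        axisymmetric sections (``r`` first, ``r = 0`` on the axis).
    spacing
        Voxel spacing per axis in mm; strictly positive.
    origin
        Physical coordinate (mm) of the grid corner (face of voxel 0).
    """

    labels: np.ndarray
    spacing: tuple[float, ...]
    origin: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise TypeError("labels must be an integer array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.labels.ndim:
            raise ValueError("spacing must have one entry per array axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if self.origin is None:
            self.origin = (0.0,) * self.labels.ndim
        self.origin = tuple(float(o) for o in self.origin)
        legend = {int(t) for t in Tissue}
        present = set(np.unique(self.labels).tolist())
        if not present <= legend:
            raise ValueError(f"unknown labels {sorted(present - legend)}")

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates (mm) along one axis."""
        n = self.labels.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def label_volume_cm3(self, label: int) -> float:
        """Volume of one label as voxel count x voxel volume, in cm^3."""
        return float(np.count_nonzero(self.labels == int(label))) * self.voxel_volume_mm3 / 1000.0

    def mask(self, label: int) -> np.ndarray:
        return self.labels == int(label)

    # -- I/O --------------------------------------------------------------

    def _affine(self) -> np.ndarray:
        aff = np.eye(4)
        for i, s in enumerate(self.spacing):
            aff[i, i] = s
            aff[i, 3] = self.origin[i] + 0.5 * s  # nibabel indexes voxel centres
        return aff

    def save(self, path: str) -> None:
        """Write to ``.nii``/``.nii.gz`` (nibabel) or ``.nrrd`` (SimpleITK)."""
        path = str(path)
        if path.endswith((".nii", ".nii.gz")):
            img = nib.Nifti1Image(self.labels.astype(np.int16), self._affine())
            nib.save(img, path)
        elif path.endswith(".nrrd"):
            img = sitk.GetImageFromArray(np.ascontiguousarray(self.labels.T.astype(np.int16)))
            img.SetSpacing(tuple(self.spacing))
            img.SetOrigin(tuple(o + 0.5 * s for o, s in zip(self.origin, self.spacing)))
            sitk.WriteImage(img, path)
        else:
            raise ValueError(f"unsupported mask format: {path}")

    @classmethod
    def load(cls, path: str) -> "LabelGrid":
        path = str(path)
        if path.endswith((".nii", ".nii.gz")):
            img = nib.load(path)
            data = np.asarray(img.dataobj).astype(np.int16)
            aff = img.affine
            spacing = tuple(float(aff[i, i]) for i in range(data.ndim))
            origin = tuple(float(aff[i, 3]) - 0.5 * spacing[i] for i in range(data.ndim))
            return cls(data, spacing, origin)
        if path.endswith(".nrrd"):
            img = sitk.ReadImage(path)
            data = sitk.GetArrayFromImage(img).T.astype(np.int16)
            spacing = tuple(float(s) for s in img.GetSpacing())
            origin = tuple(float(o) - 0.5 * s for o, s in zip(img.GetOrigin(), spacing))
            return cls(np.ascontiguousarray(data), spacing, origin)
        raise ValueError(f"unsupported mask format: {path}")


def save_mask(mask: np.ndarray, grid: LabelGrid, path: str) -> None:
    """Write a binary mask with the geometry of an existing grid."""
    LabelGrid(mask.astype(np.int16), grid.spacing, grid.origin).save(path)


def write_vtk_image(path: str, fields: dict[str, np.ndarray], spacing, origin=(0.0, 0.0, 0.0)) -> None:
    """Minimal legacy-VTK STRUCTURED_POINTS ASCII writer for 3-D scalar fields.

    Good enough for ParaView inspection of temperature / SAR / damage
    snapshots; spacing and origin are in mm.
    """
    first = next(iter(fields.values()))
    nx, ny, nz = first.shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nmwasim field snapshot\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {origin[0]} {origin[1]} {origin[2]}\n")
        fh.write(f"SPACING {spacing[0]} {spacing[1]} {spacing[2]}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr in fields.items():
            if arr.shape != first.shape:
                raise ValueError("all fields must share one shape")
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            flat = np.asarray(arr, dtype=np.float32).transpose(2, 1, 0).ravel()
            np.savetxt(fh, flat, fmt="%.6e")
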