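"""Image geometry for 2D cardiac slices.

Conventions used throughout the package:

* voxel indices are 0-based ``(row, col)``; physical coordinates are in mm,
  centered on the image center, with ``y`` along rows and ``x`` along columns;
* for short-axis views the row axis runs anterior (top) to inferior (bottom);
* extents are half-open: a voxel ``(i, j)`` covers
  ``[i*dy, (i+1)*dy) x [j*dx, (j+1)*dx)`` of the field of view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

ORIENTATIONS = ("short-axis", "four-chamber", "axial")


@dataclass(frozen=True)
class ImageGeometry:
    """Matrix size, field of view and slice prescription of a 2D image.

    Defaults reproduce the in vivo protocol: 256 x 224 matrix over a
    (288 x 252) mm^2 field of view at 4 mm slice thickness, i.e. 1.125 mm
    in-plane voxels (printed as 1.1 mm in protocol summaries).
    """

    matrix: tuple[int, int] = (256, 224)  # (rows, cols)
    fov_mm: tuple[float, float] = (288.0, 252.0)  # (row extent, col extent)
    slice_thickness_mm: float = 4.0
    orientation: str = "short-axis"

    def __post_init__(self):
        rows, cols = self.matrix
        if rows <= 0 or cols <= 0:
            raise ValidationError(f"matrix must be positive, got {self.matrix}")
        if min(self.fov_mm) <= 0:
            raise ValidationError(f"FOV must be positive, got {self.fov_mm}")
        if self.slice_thickness_mm <= 0:
            raise ValidationError("slice thickness must be positive")
        if self.orientation not in ORIENTATIONS:
            raise ValidationError(
                f"orientation {self.orientation!r} not one of {ORIENTATIONS}"
            )

    @property
    def resolution_mm(self) -> tuple[float, float]:
        """In-plane voxel size (dy, dx) = FOV / matrix on each axis."""
        return (self.fov_mm[0] / self.matrix[0], self.fov_mm[1] / self.matrix[1])

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix

    def coordinate_grids(self, origin: tuple[float, float] | None = None):
        """Physical (y, x) coordinate grids in mm.

        By default the origin sits at the image center; pass ``origin`` in
        voxel units (row, col) to recenter.
        """
        rows, cols = self.matrix
        dy, dx = self.resolution_mm
        if origin is None:
            origin = ((rows - 1) / 2.0, (cols - 1) / 2.0)
        y = (np.arange(rows) - origin[0]) * dy
        x = (np.arange(cols) - origin[1]) * dx
        return np.meshgrid(y, x, indexing="ij")

    def to_dict(self) -> dict:
        return {
            "matrix": list(self.matrix),
            "fov_mm": list(self.fov_mm),
            "slice_thickness_mm": self.slice_thickness_mm,
            "orientation": self.orientation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ImageGeometry":
        return cls(
            matrix=tuple(d["matrix"]),
            fov_mm=tuple(d["fov_mm"]),
            slice_thickness_mm=d.get("slice_thickness_mm", 4.0),
            orientation=d.get("orientation", "short-axis"),
        )


def in_vivo_geometry(slice_thickness_mm: float = 4.0) -> ImageGeometry:
    """The volunteer-study prescription (256 x 224, (288 x 252) mm^2)."""
    return ImageGeometry(slice_thickness_mm=slice_thickness_mm)


def phantom_geometry(slice_thickness_mm: float = 8.0) -> ImageGeometry:
    """The phantom-study prescription (320 x 240, (360 x 270) mm^2)."""
    return ImageGeometry(
        matrix=(320, 240),
        fov_mm=(360.0, 270.0),
        slice_thickness_mm=slice_thickness_mm,
        orientation="axial",
    )
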