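"""Regular-grid scalar volumes (Zeff / RED / RSP / labels) and NIfTI I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import GridMismatchError, InvalidInputError

__all__ = ["PropertyVolume", "QUANTITIES"]

QUANTITIES = ("zeff", "red", "rsp", "label")


@dataclass
class PropertyVolume:
    """A 3-D scalar field on a regular grid with physical spacing.

    ``values`` is indexed ``[x, y, z]``; ``spacing`` is the voxel size in mm
    and ``origin`` the physical position (mm) of the center of voxel
    ``(0, 0, 0)``. Phantom coordinates put (0, 0) at the phantom axis, so a
    volume centered on the phantom has ``origin = -(shape - 1)/2 * spacing``
    in plane. ``quantity`` names what the field holds (zeff/red/rsp/label).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    quantity: str
    origin: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise InvalidInputError("volume must be 3-D")
        if any(s <= 0 for s in self.spacing):
            raise InvalidInputError("spacing must be > 0")
        if not self.quantity:
            raise InvalidInputError("quantity label required")
        if self.quantity != "label" and np.any(np.isinf(self.values)):
            # NaN is tolerated as an explicit missing-voxel marker; infinities
            # always indicate a bug upstream
            raise InvalidInputError("infinite voxel values")

    # -- grid helpers -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @classmethod
    def centered(cls, values, spacing, quantity) -> "PropertyVolume":
        """Build a volume whose grid is centered on the physical origin."""
        values = np.asarray(values)
        origin = tuple(
            -(n - 1) / 2.0 * s for n, s in zip(values.shape, spacing)
        )
        return cls(values=values, spacing=tuple(spacing), quantity=quantity, origin=origin)

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical voxel-center coordinates (mm) along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def inplane_distance(self, center_xy_mm=(0.0, 0.0)) -> np.ndarray:
        """2-D array of in-plane distances (mm) from a point to voxel centers."""
        x = self.axis_coords(0) - center_xy_mm[0]
        y = self.axis_coords(1) - center_xy_mm[1]
        return np.hypot(x[:, None], y[None, :])

    def same_grid(self, other: "PropertyVolume", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def require_same_grid(self, other: "PropertyVolume"):
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grids differ: {self.shape}/{self.spacing}/{self.origin} vs "
                f"{other.shape}/{other.spacing}/{other.origin}"
            )

    def with_values(self, values, quantity: str | None = None) -> "PropertyVolume":
        return PropertyVolume(
            values=values,
            spacing=self.spacing,
            quantity=quantity or self.quantity,
            origin=self.origin,
        )

    # -- NIfTI ------------------------------------------------------------

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag([*self.spacing, 1.0])
        affine[:3, 3] = self.origin
        dtype = np.int16 if self.quantity == "label" else np.float32
        img = nib.Nifti1Image(self.values.astype(dtype), affine)
        img.header["descrip"] = f"quantity={self.quantity}".encode()
        return img

    def save(self, path):
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path, quantity: str | None = None) -> "PropertyVolume":
        img = nib.load(str(Path(path)))
        affine = img.affine
        spacing = tuple(float(affine[i, i]) for i in range(3))
        origin = tuple(float(affine[i, 3]) for i in range(3))
        if quantity is None:
            descrip = img.header["descrip"].tobytes().rstrip(b"\x00").decode()
            quantity = descrip.removeprefix("quantity=") or "unknown"
        values = np.asanyarray(img.dataobj)
        if quantity != "label":
            values = values.astype(np.float64)
        return cls(values=values, spacing=spacing, quantity=quantity, origin=origin)
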