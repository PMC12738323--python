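"""Regular 3-D scalar grids for dose and dose-averaged LET fields."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

QUANTITIES = ("dose_Gy", "let_kev_per_um", "sigma")


@dataclass
class VoxelGrid3D:
    """A scalar field on a regular grid.

    ``values`` is indexed ``[ix, iy, iz]``; ``origin`` is the position (mm)
    of the center of voxel ``[0, 0, 0]``; voxel centers are
    ``origin + index * spacing``.
    """

    values: np.ndarray
    origin: tuple = (0.0, 0.0, 0.0)
    spacing: tuple = (1.0, 1.0, 1.0)
    quantity: str = "dose_Gy"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        self.origin = tuple(float(x) for x in self.origin)
        self.spacing = tuple(float(x) for x in self.spacing)
        if len(self.origin) != 3 or len(self.spacing) != 3:
            raise ValueError("origin and spacing must be 3-vectors")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive componentwise")
        if self.quantity not in QUANTITIES:
            raise ValueError(f"unknown quantity {self.quantity!r}")
        if self.quantity in ("dose_Gy", "let_kev_per_um") and np.any(self.values < 0):
            raise ValueError(f"{self.quantity} values must be non-negative")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates (mm) along ``axis``."""
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def same_geometry(self, other: "VoxelGrid3D", tol: float = 1e-9) -> bool:
        return (self.dims == other.dims
                and np.allclose(self.origin, other.origin, atol=tol)
                and np.allclose(self.spacing, other.spacing, atol=tol))

    def nearest_index(self, axis: int, coord: float) -> int:
        i = int(np.floor((coord - self.origin[axis]) / self.spacing[axis] + 0.5))
        return min(max(i, 0), self.values.shape[axis] - 1)

    def like(self, values: np.ndarray, quantity: str | None = None) -> "VoxelGrid3D":
        """A new grid sharing this geometry with different values."""
        return VoxelGrid3D(values=values, origin=self.origin,
                           spacing=self.spacing,
                           quantity=quantity or self.quantity)


@dataclass
class PhantomDataset:
    """Paired fine dose grid, coarse LET grid and their uncertainty grids,
    with the generating specs kept for provenance."""

    dose: VoxelGrid3D
    dose_sigma: VoxelGrid3D
    let: VoxelGrid3D
    let_sigma: VoxelGrid3D
    beam: object = None
    collimator: object = None
    geometry: object = None
    params: object = None
    prescription: float = 2.0
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.dose.same_geometry(self.dose_sigma):
            raise ValueError("dose and dose_sigma grids must share geometry")
        if not self.let.same_geometry(self.let_sigma):
            raise ValueError("let and let_sigma grids must share geometry")
        if self.prescription <= 0:
            raise ValueError("prescription must be positive")
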