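"""Chamber geometry, fluid properties and the Cartesian grid.

The physical system is a liquid-filled vertical well (5 mm deep, 5.6 mm
across in the default device) holding a spherical organoid of 1.8 mm
diameter.  Perfusate enters through an inlet port on the left boundary and
leaves through an outlet port on the right boundary.  The default model is
the 2D frontal plane of the chamber; all lengths are in metres (SI).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .errors import GeometryError, ResolutionError

__all__ = [
    "ChamberGeometry",
    "FluidProperties",
    "CellLabel",
    "BoundaryLabel",
    "Grid",
    "build_grid",
    "reynolds_number",
]


class CellLabel(IntEnum):
    MEDIUM = 0
    ORGANOID = 1
    WALL = 2


class BoundaryLabel(IntEnum):
    NO_FLUX_WALL = 0
    INLET = 1
    OUTLET = 2
    OPEN_TOP = 3


@dataclass(frozen=True)
class ChamberGeometry:
    """Physical dimensions of the well, organoid and flow ports.

    ``well_diameter`` spans the x axis, ``well_depth`` the y axis.  The
    inlet port is a segment of the left boundary (y-range ``inlet_span``),
    the outlet a segment of the right boundary (``outlet_span``).  Port
    placement is not a stated device parameter; the defaults put both
    ports in the upper half of the chamber so the perfusion jet sweeps
    over the top of the organoid toward the outlet, matching the observed
    entry of solute from the left and the faster loading of the top and
    downstream (right) organoid surfaces.
    """

    well_depth: float = 5.0e-3
    well_diameter: float = 5.6e-3
    organoid_diameter: float = 1.8e-3
    organoid_center: tuple[float, float] | None = None
    inlet_span: tuple[float, float] = (4.2e-3, 5.0e-3)
    outlet_span: tuple[float, float] = (3.6e-3, 4.4e-3)
    dimensionality: int = 2

    def __post_init__(self) -> None:
        if self.well_depth <= 0 or self.well_diameter <= 0:
            raise GeometryError("well dimensions must be positive")
        if self.organoid_diameter < 0:
            raise GeometryError("organoid_diameter must be >= 0")
        if self.dimensionality != 2:
            raise GeometryError("only the 2D frontal-plane model is supported")
        if self.organoid_center is None:
            object.__setattr__(
                self,
                "organoid_center",
                (self.well_diameter / 2.0, self.well_depth / 2.0),
            )
        cx, cy = self.organoid_center
        r = self.organoid_diameter / 2.0
        if self.organoid_diameter > 0:
            if not (r < cx < self.well_diameter - r and r < cy < self.well_depth - r):
                raise GeometryError("organoid must lie strictly inside the well")
        for name, span in (("inlet_span", self.inlet_span), ("outlet_span", self.outlet_span)):
            lo, hi = span
            if not (0.0 <= lo < hi <= self.well_depth):
                raise GeometryError(f"{name} must be an increasing segment of the boundary")

    @property
    def organoid_radius(self) -> float:
        return self.organoid_diameter / 2.0


@dataclass(frozen=True)
class FluidProperties:
    """Carrier-medium properties.

    The default viscosity is the device's reference value 6.92e-3 kg/(m s);
    note this is roughly ten times that of water at 37 C (6.92e-4 Pa s),
    which is also accepted.  Either way the Reynolds number stays far
    below the laminar-turbulent transition, so the creeping-flow model is
    unaffected.
    """

    density: float = 997.0          # kg/m^3
    dynamic_viscosity: float = 6.92e-3  # Pa s
    temperature: float = 37.0       # deg C

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise GeometryError("density must be positive")
        if self.dynamic_viscosity <= 0:
            raise GeometryError("viscosity must be positive")


@dataclass
class Grid:
    """Uniform Cartesian cell grid with cell and boundary labels.

    ``cell_label[i, j]`` covers the cell whose centre is at
    ``((i + 1/2) hx, (j + 1/2) hy)``.  ``left_bc``/``right_bc`` label each
    boundary row of the left/right domain edges; top and bottom edges are
    no-flux walls (the physical open top is modelled as a no-flux lid,
    since the chamber is treated as fully liquid-filled).
    """

    nx: int
    ny: int
    hx: float
    hy: float
    cell_label: np.ndarray          # (nx, ny) uint8, CellLabel values
    left_bc: np.ndarray             # (ny,) uint8, BoundaryLabel values
    right_bc: np.ndarray            # (ny,) uint8
    geometry: ChamberGeometry | None = None
    top_bc: int = int(BoundaryLabel.OPEN_TOP)
    bottom_bc: int = int(BoundaryLabel.NO_FLUX_WALL)

    def __post_init__(self) -> None:
        if self.hx <= 0 or self.hy <= 0:
            raise GeometryError("grid spacings must be positive")
        if self.cell_label.shape != (self.nx, self.ny):
            raise GeometryError("cell_label shape mismatch")

    @property
    def extent(self) -> tuple[float, float]:
        return self.nx * self.hx, self.ny * self.hy

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        x = (np.arange(self.nx) + 0.5) * self.hx
        y = (np.arange(self.ny) + 0.5) * self.hy
        return x, y

    @property
    def organoid_mask(self) -> np.ndarray:
        return self.cell_label == CellLabel.ORGANOID

    @property
    def medium_mask(self) -> np.ndarray:
        return self.cell_label == CellLabel.MEDIUM

    @property
    def inlet_rows(self) -> np.ndarray:
        return self.left_bc == BoundaryLabel.INLET

    @property
    def outlet_rows(self) -> np.ndarray:
        return self.right_bc == BoundaryLabel.OUTLET


def build_grid(geometry: ChamberGeometry, resolution: int | tuple[int, int]) -> Grid:
    """Rasterize the chamber onto a uniform Cartesian grid.

    ``resolution`` is the cell count along x, or an explicit ``(nx, ny)``
    pair; when a single count is given ny is chosen to keep cells square.
    Organoid cells are exactly those whose centres lie inside the organoid
    disc (cell-centre inclusion, no cut cells).
    """
    if isinstance(resolution, tuple):
        nx, ny = resolution
    else:
        nx = int(resolution)
        ny = int(round(nx * geometry.well_depth / geometry.well_diameter))
    if nx < 8 or ny < 8:
        raise ResolutionError("resolution must be at least 8 cells per axis")
    hx = geometry.well_diameter / nx
    hy = geometry.well_depth / ny

    label = np.full((nx, ny), int(CellLabel.MEDIUM), dtype=np.uint8)
    r = geometry.organoid_radius
    if r > 0:
        if geometry.organoid_diameter < 3 * max(hx, hy):
            raise ResolutionError(
                "organoid under-resolved: fewer than 3 cells across its diameter"
            )
        cx, cy = geometry.organoid_center
        x, y = (np.arange(nx) + 0.5) * hx, (np.arange(ny) + 0.5) * hy
        xx, yy = np.meshgrid(x, y, indexing="ij")
        label[(xx - cx) ** 2 + (yy - cy) ** 2 <= r**2] = int(CellLabel.ORGANOID)

    yc = (np.arange(ny) + 0.5) * hy
    left = np.full(ny, int(BoundaryLabel.NO_FLUX_WALL), dtype=np.uint8)
    right = np.full(ny, int(BoundaryLabel.NO_FLUX_WALL), dtype=np.uint8)
    left[(yc >= geometry.inlet_span[0]) & (yc <= geometry.inlet_span[1])] = int(
        BoundaryLabel.INLET
    )
    right[(yc >= geometry.outlet_span[0]) & (yc <= geometry.outlet_span[1])] = int(
        BoundaryLabel.OUTLET
    )
    if not left.any() or not right.any():
        raise ResolutionError("grid too coarse to resolve inlet/outlet ports")
    return Grid(nx=nx, ny=ny, hx=hx, hy=hy, cell_label=label,
                left_bc=left, right_bc=right, geometry=geometry)


def reynolds_number(fluid: FluidProperties, characteristic_length: float, speed: float) -> float:
    """Re = rho u L / mu.  Re << 2000 here justifies the creeping-flow model."""
    if characteristic_length <= 0:
        raise ValueError("characteristic_length must be positive")
    if speed < 0:
        raise ValueError("speed must be non-negative")
    return fluid.density * speed * characteristic_length / fluid.dynamic_viscosity
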