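"""Steady incompressible creeping-flow (Stokes) solver on a staggered grid.

At the device's flow speed (5e-3 m/s) and length scale (~5 mm) the Reynolds
number is of order 1-10, so inertia is negligible and the steady Stokes
equations

    mu lap(u) = grad(p),   div(u) = 0

describe the perfusion field.  Discretization is a standard MAC (marker
and cell) staggered arrangement: u on vertical cell faces, v on horizontal
cell faces, p at cell centres.  Boundary conditions are uniform normal
inflow on the inlet port, a uniform outflow on the outlet port whose speed
is scaled so net outflow equals net inflow exactly, and no-slip on every
other wall.  The no-slip organoid surface is enforced by Brinkman
penalization (a large drag coefficient in organoid cells), which drives
the interior velocity to ~1e-8 of the inlet speed; the transport solver
then zeroes those faces outright so solute enters the organoid by
diffusion only.

The resulting saddle-point system is solved with a sparse direct
factorization, so the discrete divergence is zero to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import SolverError
from .geometry import BoundaryLabel, CellLabel, FluidProperties, Grid

__all__ = ["FlowField", "solve_flow"]

_PENALTY = 1.0e8  # Brinkman drag = _PENALTY * mu / h^2 in organoid cells


@dataclass
class FlowField:
    """Face-centred velocity field on a :class:`Grid`.

    ``u`` has shape (nx+1, ny) (x-faces), ``v`` shape (nx, ny+1) (y-faces),
    both in m/s.  ``p`` is the cell-centred pressure (defined up to the
    pinned gauge).
    """

    grid: Grid
    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    inlet_speed: float

    def divergence(self) -> np.ndarray:
        """Per-cell discrete divergence (1/s)."""
        g = self.grid
        return (self.u[1:, :] - self.u[:-1, :]) / g.hx + (
            self.v[:, 1:] - self.v[:, :-1]
        ) / g.hy

    def max_speed(self) -> float:
        return max(float(np.abs(self.u).max()), float(np.abs(self.v).max()))

    def cell_velocity(self) -> tuple[np.ndarray, np.ndarray]:
        """Velocity interpolated to cell centres."""
        uc = 0.5 * (self.u[1:, :] + self.u[:-1, :])
        vc = 0.5 * (self.v[:, 1:] + self.v[:, :-1])
        return uc, vc

    def inflow_flux(self) -> float:
        """Net volumetric inflow per unit depth (m^2/s)."""
        return float(self.u[0, :].sum() * self.grid.hy)

    def outflow_flux(self) -> float:
        return float(self.u[-1, :].sum() * self.grid.hy)

    def to_dataframe(self):
        import pandas as pd

        g = self.grid
        x, y = g.cell_centers()
        xx, yy = np.meshgrid(x, y, indexing="ij")
        uc, vc = self.cell_velocity()
        return pd.DataFrame(
            {"x_m": xx.ravel(), "y_m": yy.ravel(), "u_m_s": uc.ravel(), "v_m_s": vc.ravel()}
        )


def solve_flow(grid: Grid, fluid: FluidProperties, inlet_speed: float,
               out_of_plane_depth: float | None = None) -> FlowField:
    """Solve steady Stokes flow through the chamber.

    Uniform inflow ``inlet_speed`` is imposed on the inlet port; the
    outflow speed is ``inlet_speed * n_inlet / n_outlet`` so global mass
    balance holds identically.

    ``out_of_plane_depth`` turns on a depth-averaged lateral-wall drag
    (Brinkman term, ``12 mu / b^2`` with ``b`` the out-of-plane extent of
    the chamber).  A strictly planar cavity grossly over-predicts the
    recirculation driven by the perfusion jet; the drag term represents
    the shear on the cylindrical well's front/back walls, which is what
    limits convective stirring in the real device.  Pass ``None`` for a
    true 2D solution (e.g. channel benchmarks).

    Raises :class:`SolverError` if the direct solve returns a non-finite
    field.
    """
    if inlet_speed < 0:
        raise ValueError("inlet_speed must be >= 0")
    nx, ny = grid.nx, grid.ny
    if inlet_speed == 0.0:
        return FlowField(grid, np.zeros((nx + 1, ny)), np.zeros((nx, ny + 1)),
                         np.zeros((nx, ny)), 0.0)
    if grid.hx != grid.hy:
        raise SolverError("flow solver requires square cells (hx == hy)")
    h = grid.hx
    mu = fluid.dynamic_viscosity

    inlet = grid.inlet_rows
    outlet = grid.outlet_rows
    n_in, n_out = int(inlet.sum()), int(outlet.sum())
    u_out = inlet_speed * n_in / n_out

    organoid = grid.cell_label == CellLabel.ORGANOID
    wall_cell = grid.cell_label == CellLabel.WALL
    solid = organoid | wall_cell

    nu, nv = (nx + 1) * ny, nx * (ny + 1)
    ntot = nu + nv + nx * ny

    def iu(i, j):
        return i * ny + j

    def iv(i, j):
        return nu + i * (ny + 1) + j

    def ip(i, j):
        return nu + nv + i * ny + j

    rows, cols, vals = [], [], []
    rhs = np.zeros(ntot)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    inv_h2 = mu / h**2
    alpha = _PENALTY * mu / h**2
    drag = 0.0 if out_of_plane_depth is None else 12.0 * mu / out_of_plane_depth**2

    # --- x-momentum on u-faces ------------------------------------------
    for i in range(nx + 1):
        for j in range(ny):
            r = iu(i, j)
            if i == 0:
                add(r, r, 1.0)
                rhs[r] = inlet_speed if inlet[j] else 0.0
                continue
            if i == nx:
                add(r, r, 1.0)
                rhs[r] = u_out if outlet[j] else 0.0
                continue
            diag = -4.0 * inv_h2
            # east / west neighbours always exist for interior x-faces
            add(r, iu(i + 1, j), inv_h2)
            add(r, iu(i - 1, j), inv_h2)
            # north / south: no-slip ghost (u_ghost = -u) at top/bottom lids
            if j + 1 < ny:
                add(r, iu(i, j + 1), inv_h2)
            else:
                diag -= inv_h2
            if j - 1 >= 0:
                add(r, iu(i, j - 1), inv_h2)
            else:
                diag -= inv_h2
            diag -= drag
            if solid[i - 1, j] or solid[i, j]:
                diag -= alpha
            add(r, r, diag)
            add(r, ip(i, j), -1.0 / h)
            add(r, ip(i - 1, j), 1.0 / h)

    # --- y-momentum on v-faces ------------------------------------------
    for i in range(nx):
        for j in range(ny + 1):
            r = iv(i, j)
            if j == 0 or j == ny:
                add(r, r, 1.0)
                continue
            diag = -4.0 * inv_h2
            if i + 1 < nx:
                add(r, iv(i + 1, j), inv_h2)
            else:
                diag -= inv_h2  # no-slip ghost on right wall (tangential)
            if i - 1 >= 0:
                add(r, iv(i - 1, j), inv_h2)
            else:
                diag -= inv_h2  # left wall
            add(r, iv(i, j + 1), inv_h2)
            add(r, iv(i, j - 1), inv_h2)
            diag -= drag
            if solid[i, j - 1] or solid[i, j]:
                diag -= alpha
            add(r, r, diag)
            add(r, ip(i, j), -1.0 / h)
            add(r, ip(i, j - 1), 1.0 / h)

    # --- continuity at cells (one cell pinned as pressure gauge) --------
    for i in range(nx):
        for j in range(ny):
            r = ip(i, j)
            if i == 0 and j == 0:
                add(r, r, 1.0)  # p gauge; continuity here is redundant
                continue
            add(r, iu(i + 1, j), 1.0 / h)
            add(r, iu(i, j), -1.0 / h)
            add(r, iv(i, j + 1), 1.0 / h)
            add(r, iv(i, j), -1.0 / h)

    A = sp.csr_matrix((vals, (rows, cols)), shape=(ntot, ntot))
    sol = spla.spsolve(A, rhs)
    if not np.all(np.isfinite(sol)):
        raise SolverError("Stokes solve returned non-finite values")

    u = sol[:nu].reshape(nx + 1, ny)
    v = sol[nu : nu + nv].reshape(nx, ny + 1)
    p = sol[nu + nv :].reshape(nx, ny)
    field = FlowField(grid, u, v, p, inlet_speed)

    div = field.divergence()
    q_in = field.inflow_flux()
    resid = float(np.abs(div).max()) * h * h
    if q_in > 0 and resid > 1e-6 * q_in:
        raise SolverError(f"divergence residual too large: {resid:.3e} (inflow {q_in:.3e})")
    return field
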