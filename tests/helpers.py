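"""Shared construction helpers for the test suite."""

from __future__ import annotations

import numpy as np

from organoflow.geometry import BoundaryLabel, CellLabel, Grid
from organoflow.stokes import FlowField


def channel_grid(nx: int, ny: int, length: float, height: float) -> Grid:
    """Straight obstacle-free channel: full-width inlet left, outlet right."""
    hx = length / nx
    hy = height / ny
    return Grid(
        nx=nx, ny=ny, hx=hx, hy=hy,
        cell_label=np.full((nx, ny), int(CellLabel.MEDIUM), dtype=np.uint8),
        left_bc=np.full(ny, int(BoundaryLabel.INLET), dtype=np.uint8),
        right_bc=np.full(ny, int(BoundaryLabel.OUTLET), dtype=np.uint8),
    )


def closed_box_grid(nx: int, ny: int, h: float) -> Grid:
    """All-wall box with no inlet or outlet (for conservation checks)."""
    return Grid(
        nx=nx, ny=ny, hx=h, hy=h,
        cell_label=np.full((nx, ny), int(CellLabel.MEDIUM), dtype=np.uint8),
        left_bc=np.full(ny, int(BoundaryLabel.NO_FLUX_WALL), dtype=np.uint8),
        right_bc=np.full(ny, int(BoundaryLabel.NO_FLUX_WALL), dtype=np.uint8),
    )


def plug_flow(grid: Grid, u0: float) -> FlowField:
    """Uniform horizontal velocity everywhere (divergence-free by construction)."""
    u = np.full((grid.nx + 1, grid.ny), float(u0))
    v = np.zeros((grid.nx, grid.ny + 1))
    return FlowField(grid, u, v, np.zeros((grid.nx, grid.ny)), float(u0))


def zero_flow(grid: Grid) -> FlowField:
    return FlowField(grid, np.zeros((grid.nx + 1, grid.ny)),
                     np.zeros((grid.nx, grid.ny + 1)),
                     np.zeros((grid.nx, grid.ny)), 0.0)


def match_spots(detected: np.ndarray, truth: np.ndarray, radius: float) -> tuple[float, float]:
    """(recall, precision) with greedy nearest matching at the given radius."""
    from scipy.spatial import cKDTree

    if len(detected) == 0:
        return 0.0, 0.0
    d, _ = cKDTree(truth).query(detected)
    precision = float(np.count_nonzero(d <= radius)) / len(detected)
    d2, _ = cKDTree(detected).query(truth)
    recall = float(np.count_nonzero(d2 <= radius)) / len(truth)
    return recall, precision
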