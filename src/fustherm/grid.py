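"""Structured grids for the bioheat solver.

Two modes are supported:

* ``"3d"`` — a Cartesian cell-centred grid (x, y transverse, z = beam axis).
* ``"axisym"`` — a cylindrical (r, z) grid for scenarios whose geometry and
  source are rotationally symmetric about the beam axis (single coaxial
  vessel, on-axis focus). Radial cells are annular shells with faces at
  ``r = i*dr``, so the first cell centre sits at ``dr/2`` and the r = 0
  regularity condition (zero radial flux through a zero-area face) is
  automatic.

Node coordinates are cell centres with 0-based indices: ``x_i = (i + 1/2) dx``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Grid"]


@dataclass(frozen=True)
class Grid:
    """Cell-centred structured grid.

    Parameters
    ----------
    spacing : tuple of float
        Cell size per axis in metres: (dx, dy, dz) in 3-D mode, (dr, dz) in
        axisymmetric mode.
    shape : tuple of int
        Number of cells per axis, same ordering as ``spacing``.
    mode : {"3d", "axisym"}
    """

    spacing: tuple[float, ...]
    shape: tuple[int, ...]
    mode: str = "3d"

    def __post_init__(self) -> None:
        if self.mode not in ("3d", "axisym"):
            raise ValueError(f"unknown grid mode {self.mode!r}")
        ndim = 3 if self.mode == "3d" else 2
        if len(self.spacing) != ndim or len(self.shape) != ndim:
            raise ValueError(f"{self.mode} grid needs {ndim} spacings and extents")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("grid spacing must be positive")
        if any(n < 1 for n in self.shape):
            raise ValueError("grid extents must be >= 1")
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))

    # -- constructors -----------------------------------------------------

    @classmethod
    def for_box(cls, domain_size, spacing) -> "Grid":
        """Grid covering a 3-D box of ``domain_size`` (m) at ~``spacing``.

        ``spacing`` may be a scalar or a 3-sequence. The number of cells is
        rounded so the grid tiles the box; the spacing is adjusted (by less
        than half a cell) so that ``shape * spacing == domain_size`` exactly.
        """
        size = np.asarray(domain_size, dtype=float)
        sp = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
        shape = np.maximum(1, np.rint(size / sp).astype(int))
        return cls(spacing=tuple(size / shape), shape=tuple(shape), mode="3d")

    @classmethod
    def for_cylinder(cls, radial_extent: float, z_extent: float, spacing) -> "Grid":
        """Axisymmetric (r, z) grid for a cylinder of given radius and height."""
        sp = np.broadcast_to(np.asarray(spacing, dtype=float), (2,))
        nr = max(1, round(radial_extent / sp[0]))
        nz = max(1, round(z_extent / sp[1]))
        return cls(spacing=(radial_extent / nr, z_extent / nz), shape=(nr, nz), mode="axisym")

    # -- geometry helpers -------------------------------------------------

    @property
    def extent(self) -> tuple[float, ...]:
        """Physical size per axis (m)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Cell-centre coordinates along ``axis`` (m)."""
        n, d = self.shape[axis], self.spacing[axis]
        return (np.arange(n) + 0.5) * d

    def cell_centers(self):
        """Broadcastable cell-centre coordinate arrays (open meshgrid)."""
        coords = [self.axis_coords(a) for a in range(len(self.shape))]
        return np.meshgrid(*coords, indexing="ij", sparse=True)

    @property
    def midplane_index(self) -> int:
        """Index of the transverse plane nearest the axial (z) midpoint."""
        return self.shape[-1] // 2

    @property
    def cell_volume(self):
        """Cell volume(s), m^3. Scalar in 3-D; per-radial-cell array in axisym."""
        if self.mode == "3d":
            dx, dy, dz = self.spacing
            return dx * dy * dz
        dr, dz = self.spacing
        i = np.arange(self.shape[0])
        return np.pi * dr**2 * (2 * i + 1) * dz
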