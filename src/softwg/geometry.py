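"""Discretized soft-material waveguide model.

The model is a dielectric tube (the "myelin sheath" of a simplified
myelinated-axon segment) immersed in ionic fluid: an inner solution fills the
tube, an outer solution surrounds it, and the tube wall itself is a lossless
low-permittivity dielectric shell.  All three regions are voxelized onto a
uniform cubic grid by cell-center membership, producing per-cell relative
permittivity and conductivity maps that the FDTD solver consumes directly.

Default dimensions and material parameters correspond to the scaled-up axon
model used throughout the package: internal diameter 48 mm, external diameter
96 mm, internode length 240 mm; relative permittivities 136.0 (both
solutions) and 10.3 (shell); conductivities 0.487 S/m (intracellular),
1.454 S/m (extracellular) and 0 (shell).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .errors import DomainError, ResolutionError


class Region(IntEnum):
    """Region labels for the three media of the tube model."""

    INNER_SOLUTION = 0
    DIELECTRIC = 1
    OUTER_SOLUTION = 2


@dataclass(frozen=True)
class TubeGeometry:
    """Tube dimensions in millimetres plus the grid axis of the tube.

    ``axis`` indexes the grid dimension the tube runs along (0, 1 or 2);
    the tube is centered on the two transverse axes.
    """

    inner_diameter_mm: float = 48.0
    outer_diameter_mm: float = 96.0
    internode_length_mm: float = 240.0
    axis: int = 2

    def __post_init__(self):
        if not 0.0 < self.inner_diameter_mm < self.outer_diameter_mm:
            raise DomainError(
                "require 0 < inner diameter < outer diameter, got "
                f"d={self.inner_diameter_mm}, D={self.outer_diameter_mm}"
            )
        if self.internode_length_mm <= 0.0:
            raise DomainError("internode length must be positive")
        if self.axis not in (0, 1, 2):
            raise DomainError("axis must be one of the three grid axes (0, 1, 2)")

    @property
    def wall_thickness_mm(self) -> float:
        return 0.5 * (self.outer_diameter_mm - self.inner_diameter_mm)


@dataclass(frozen=True)
class RegionMaterial:
    """Relative permittivity and conductivity of one region (mu_r fixed at 1)."""

    eps_r: float
    sigma: float

    def __post_init__(self):
        if self.eps_r < 1.0:
            raise DomainError(f"relative permittivity must be >= 1, got {self.eps_r}")
        if self.sigma < 0.0:
            raise DomainError(f"conductivity must be >= 0, got {self.sigma}")


@dataclass(frozen=True)
class MaterialAssignment:
    """Material parameters for the three regions of the tube model."""

    inner_solution: RegionMaterial = field(
        default_factory=lambda: RegionMaterial(136.0, 0.487)
    )
    dielectric: RegionMaterial = field(
        default_factory=lambda: RegionMaterial(10.3, 0.0)
    )
    outer_solution: RegionMaterial = field(
        default_factory=lambda: RegionMaterial(136.0, 1.454)
    )

    def for_region(self, region: Region) -> RegionMaterial:
        return (self.inner_solution, self.dielectric, self.outer_solution)[int(region)]

    def lookup_tables(self) -> tuple[np.ndarray, np.ndarray]:
        """(eps_r, sigma) arrays indexable by region label."""
        mats = [self.for_region(r) for r in Region]
        return (
            np.array([m.eps_r for m in mats]),
            np.array([m.sigma for m in mats]),
        )


@dataclass
class MaterialGrid:
    """Per-cell material maps on a uniform cubic grid.

    ``labels`` holds a :class:`Region` value per cell; ``eps_r`` and ``sigma``
    are derived from it through a :class:`MaterialAssignment` and share its
    shape.  ``cell_size`` is in metres.
    """

    eps_r: np.ndarray
    sigma: np.ndarray
    labels: np.ndarray
    cell_size: float
    axis: int = 2

    def __post_init__(self):
        if not (self.eps_r.shape == self.sigma.shape == self.labels.shape):
            raise DomainError("eps_r, sigma and labels must share one shape")
        if self.cell_size <= 0.0:
            raise DomainError("cell size must be positive")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.eps_r.shape

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.dims))

    def region_counts(self) -> dict[Region, int]:
        return {r: int(np.count_nonzero(self.labels == int(r))) for r in Region}

    def shell_volume(self) -> float:
        """Voxelized dielectric-shell volume in m^3."""
        n = int(np.count_nonzero(self.labels == int(Region.DIELECTRIC)))
        return n * self.cell_size**3


def _cell_center_coords(n: int, dx: float) -> np.ndarray:
    return (np.arange(n) + 0.5) * dx


def build_waveguide_grid(
    geometry: TubeGeometry,
    materials: MaterialAssignment,
    cell_size: float,
    padding: int,
    dims: tuple[int, int, int] | None = None,
) -> MaterialGrid:
    """Voxelize the fluid / shell / fluid tube model.

    Labelling rule (cell-center membership, radius measured from the cell
    center to the tube axis):

    * ``r < d/2``                       -> inner solution (full axial extent,
      the tube is open at both ends),
    * ``d/2 <= r < D/2`` within the internode span -> dielectric shell,
    * everything else                   -> outer solution.

    ``cell_size`` is in metres, ``padding`` in cells and is applied on every
    face; it must leave room for the absorbing boundary (PML thickness plus a
    few working cells).  ``dims`` may be given explicitly for paired
    waveguide/control setups; the tube is then centered in the grid.
    """
    d = geometry.inner_diameter_mm * 1e-3
    D = geometry.outer_diameter_mm * 1e-3
    L = geometry.internode_length_mm * 1e-3
    dx = float(cell_size)

    if 0.5 * (D - d) < 4.0 * dx:
        raise ResolutionError(
            f"dielectric shell ({0.5 * (D - d) * 1e3:.2f} mm) thinner than 4 cells "
            f"at cell size {dx * 1e3:.2f} mm"
        )
    if padding < 4:
        raise ResolutionError("padding must be at least 4 cells")

    axis = geometry.axis
    trans_axes = tuple(a for a in range(3) if a != axis)

    if dims is None:
        n_trans = math.ceil(D / dx) + 2 * padding
        n_axial = math.ceil(L / dx) + 2 * padding
        shape = [0, 0, 0]
        shape[axis] = n_axial
        for a in trans_axes:
            shape[a] = n_trans
        dims = tuple(shape)
    else:
        if len(dims) != 3:
            raise DomainError("dims must have three entries")
        for a in trans_axes:
            if D > (dims[a] - 2 * padding) * dx:
                raise DomainError("tube cross-section exceeds the padded grid")
        if L > (dims[axis] - 2 * padding) * dx:
            raise DomainError("internode length exceeds the padded grid")

    coords = [_cell_center_coords(dims[a], dx) for a in range(3)]
    centers = [dims[a] * dx / 2.0 for a in range(3)]

    u = coords[trans_axes[0]] - centers[trans_axes[0]]
    v = coords[trans_axes[1]] - centers[trans_axes[1]]
    shp_u = [1, 1, 1]
    shp_u[trans_axes[0]] = dims[trans_axes[0]]
    shp_v = [1, 1, 1]
    shp_v[trans_axes[1]] = dims[trans_axes[1]]
    r = np.sqrt(u.reshape(shp_u) ** 2 + v.reshape(shp_v) ** 2)

    z = coords[axis]
    z_start = centers[axis] - L / 2.0
    in_span = (z >= z_start) & (z < z_start + L)
    shp_z = [1, 1, 1]
    shp_z[axis] = dims[axis]
    in_span = in_span.reshape(shp_z)

    labels = np.full(dims, int(Region.OUTER_SOLUTION), dtype=np.uint8)
    labels[np.broadcast_to((r >= d / 2) & (r < D / 2), dims) & np.broadcast_to(in_span, dims)] = int(
        Region.DIELECTRIC
    )
    labels[np.broadcast_to(r < d / 2, dims)] = int(Region.INNER_SOLUTION)

    lut_eps, lut_sig = materials.lookup_tables()
    return MaterialGrid(
        eps_r=lut_eps[labels],
        sigma=lut_sig[labels],
        labels=labels,
        cell_size=dx,
        axis=axis,
    )


def build_control_grid(
    materials: MaterialAssignment,
    dims: tuple[int, int, int],
    cell_size: float,
    region: Region = Region.OUTER_SOLUTION,
    axis: int = 2,
) -> MaterialGrid:
    """Homogeneous-solution control grid paired with a waveguide grid.

    The control mimics the bath without the tube: every cell carries one
    solution's parameters (extracellular by default, intracellular available
    through ``region``).
    """
    if region == Region.DIELECTRIC:
        raise DomainError("control medium must be one of the two solutions")
    labels = np.full(dims, int(region), dtype=np.uint8)
    lut_eps, lut_sig = materials.lookup_tables()
    return MaterialGrid(
        eps_r=lut_eps[labels],
        sigma=lut_sig[labels],
        labels=labels,
        cell_size=float(cell_size),
        axis=axis,
    )
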