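"""Grid and time-step specification for the FDTD solver.

The solver uses a uniform cubic Yee lattice (dx = dy = dz enforced) with the
time step coupled to the cell size by ``dx = 2 c0 dt``, i.e. a Courant number
of 0.5, comfortably inside the 3D stability bound
``c0 dt <= dx / sqrt(3)``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.constants import c as C0

from ..errors import ConfigurationError


@dataclass(frozen=True)
class PmlSpec:
    """Absorbing-boundary parameters.

    ``thickness`` cells per face, polynomial conductivity grading of order
    ``order``, and a theoretical normal-incidence reflection target ``r0``
    used to set the peak PML conductivity.  ``thickness = 0`` disables the
    PML, leaving perfectly conducting walls.
    """

    thickness: int = 10
    order: int = 3
    r0: float = 1e-4

    def __post_init__(self):
        if self.thickness < 0:
            raise ConfigurationError("PML thickness must be >= 0")
        if not 0.0 < self.r0 < 1.0:
            raise ConfigurationError("target reflection must lie in (0, 1)")


@dataclass(frozen=True)
class GridSpec:
    """Cell size, time step, grid dimensions and boundary settings."""

    cell_size: float
    dims: tuple[int, int, int]
    steps: int
    dt: float
    pml: PmlSpec = field(default_factory=PmlSpec)
    periodic: tuple[bool, bool, bool] = (False, False, False)

    @property
    def courant_number(self) -> float:
        return C0 * self.dt / self.cell_size

    def courant_ok(self) -> bool:
        """Stability predicate: v_p dt <= 1/sqrt(3/dx^2) with v_p = c0."""
        bound = self.cell_size / math.sqrt(3.0)
        return C0 * self.dt <= bound * (1.0 + 1e-12)


def make_grid_spec(
    cell_size,
    dims: tuple[int, int, int],
    steps: int,
    pml: PmlSpec | None = None,
    dt: float | None = None,
    periodic: tuple[bool, bool, bool] = (False, False, False),
) -> GridSpec:
    """Build and validate a :class:`GridSpec`.

    ``cell_size`` may be a scalar or a 3-tuple; a tuple with unequal entries
    is rejected because the lattice is uniform by construction.  The default
    time step is ``dx / (2 c0)``.
    """
    if isinstance(cell_size, (tuple, list)):
        if len(set(float(c) for c in cell_size)) != 1:
            raise ConfigurationError("dx, dy and dz must be equal on this lattice")
        cell_size = float(cell_size[0])
    cell_size = float(cell_size)
    if cell_size <= 0.0:
        raise ConfigurationError("cell size must be positive")
    if len(dims) != 3 or any(int(n) < 3 for n in dims):
        raise ConfigurationError("dims must be three integers >= 3")
    dims = tuple(int(n) for n in dims)
    if steps < 0:
        raise ConfigurationError("step count must be >= 0")
    pml = pml or PmlSpec()
    for a in range(3):
        if periodic[a]:
            continue
        if dims[a] < 2 * pml.thickness + 8:
            raise ConfigurationError(
                f"axis {a}: {dims[a]} cells cannot hold two PML slabs of "
                f"{pml.thickness} cells plus 8 working cells"
            )
    if dt is None:
        dt = cell_size / (2.0 * C0)
    spec = GridSpec(
        cell_size=cell_size,
        dims=dims,
        steps=int(steps),
        dt=float(dt),
        pml=pml,
        periodic=tuple(bool(p) for p in periodic),
    )
    if not spec.courant_ok():
        raise ConfigurationError(
            f"time step {dt} violates the Courant bound for dx = {cell_size}"
        )
    return spec
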