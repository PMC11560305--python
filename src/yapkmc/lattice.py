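"""Lattice geometry, boundary arithmetic and unit conversions.

The simulation domain is a 3D cubic lattice of ``nx × ny × nz`` sites with
node spacing ``l`` (μm).  Coordinates are 1-based.  The plasma membrane is the
``z = 1`` plane; the cytosol is ``z ∈ [2, nz]``.  The x and y directions are
periodic; z is closed at both the membrane and the top surface.  Each site
holds at most one molecule (excluded volume).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import TYPE_CHECKING, Tuple

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .adhesions import AdhesionLayout

AVOGADRO = 6.02214076e23

#: litres per cubic micrometre
_L_PER_UM3 = 1e-15


@dataclass(frozen=True)
class LatticeGeometry:
    """Site counts per axis and the node spacing in μm."""

    nx: int = 40
    ny: int = 40
    nz: int = 20
    l: float = 0.2

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 2:
            raise ValueError("lattice needs at least 2 sites per axis")
        if self.l <= 0:
            raise ValueError("node spacing l must be positive")

    @property
    def n_sites(self) -> int:
        return self.nx * self.ny * self.nz

    @property
    def n_cytosol_sites(self) -> int:
        """Sites available to unbound molecules (z ∈ [2, nz])."""
        return self.nx * self.ny * (self.nz - 1)

    @property
    def membrane_area(self) -> float:
        """Membrane (z = 1) area in μm²."""
        return self.nx * self.ny * self.l ** 2


class Region(enum.Enum):
    """Classification of a lattice site by the events possible there."""

    BULK = "bulk"                    # z > 2: diffusion (+ dephosphorylation)
    JUXTAMEMBRANE = "juxtamembrane"  # z = 2: diffusion, binding, dephosph.
    ADHESION_SITE = "adhesion_site"  # z = 1 inside a footprint
    FORBIDDEN = "forbidden"          # z = 1 outside all footprints


def wrap_xy(geom: LatticeGeometry, x: int, y: int, z: int) -> Tuple[int, int, int]:
    """Map possibly out-of-range x/y onto the periodic membrane plane.

    z is returned unchanged; callers treat out-of-range z as an invalid move.
    """
    return ((x - 1) % geom.nx + 1, (y - 1) % geom.ny + 1, z)


def site_class(
    geom: LatticeGeometry, layout: "AdhesionLayout", coord: Tuple[int, int, int]
):
    """Return the :class:`Region` of ``coord`` and, for adhesion sites, the
    id of the owning adhesion (``None`` otherwise)."""
    x, y, z = coord
    if not (1 <= x <= geom.nx and 1 <= y <= geom.ny and 1 <= z <= geom.nz):
        raise ValueError(f"coordinate {coord} outside the lattice")
    if z > 2:
        return Region.BULK, None
    if z == 2:
        return Region.JUXTAMEMBRANE, None
    owner = layout.adhesion_at(x, y)
    if owner is None:
        return Region.FORBIDDEN, None
    return Region.ADHESION_SITE, owner


def box_volume(geom: LatticeGeometry) -> float:
    """Simulation box volume in μm³ (``nx·ny·nz·l³``)."""
    return geom.nx * geom.ny * geom.nz * geom.l ** 3


def molecules_to_nanomolar(n: int, volume_um3: float) -> float:
    """Concentration in nM of ``n`` molecules in ``volume_um3`` μm³."""
    if n < 0:
        raise ValueError("molecule count must be non-negative")
    if volume_um3 <= 0:
        raise ValueError("volume must be positive")
    molar = n / (AVOGADRO * volume_um3 * _L_PER_UM3)
    return molar * 1e9


class OccupancyGrid:
    """One-molecule-per-site occupancy bookkeeping.

    Backed by an int32 array with value -1 for empty sites; the 1-based
    coordinate convention is converted at this boundary.
    """

    EMPTY = -1

    def __init__(self, geom: LatticeGeometry):
        self.geom = geom
        self.array = np.full((geom.nx, geom.ny, geom.nz), self.EMPTY, dtype=np.int32)

    def occupant(self, x: int, y: int, z: int) -> int | None:
        v = int(self.array[x - 1, y - 1, z - 1])
        return None if v == self.EMPTY else v

    def is_free(self, x: int, y: int, z: int) -> bool:
        return self.array[x - 1, y - 1, z - 1] == self.EMPTY

    def place(self, mol_id: int, x: int, y: int, z: int) -> None:
        if not self.is_free(x, y, z):
            raise ValueError(f"site ({x},{y},{z}) already occupied")
        self.array[x - 1, y - 1, z - 1] = mol_id

    def remove(self, x: int, y: int, z: int) -> None:
        self.array[x - 1, y - 1, z - 1] = self.EMPTY

    def move(self, mol_id: int, src, dst) -> None:
        self.remove(*src)
        self.place(mol_id, *dst)

    @property
    def n_occupied(self) -> int:
        return int((self.array != self.EMPTY).sum())
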