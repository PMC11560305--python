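"""Integrin-adhesion footprints on the membrane plane.

Adhesions are rectangular footprints of binding sites on the ``z = 1`` plane.
They are placed uniformly at random with volume exclusion, either anywhere on
the membrane or confined to a square sub-region covering a fraction ``r`` of
the membrane area.  Under the ``spaced`` policy no two footprints touch
(≥ 1 empty site between perimeters); under ``clumping_allowed`` they may be
adjacent but never overlap.  Footprints may wrap across the periodic x/y edges
when placed on the full membrane, but never across a confinement-region
boundary.

Each adhesion can carry a finite lifetime: on disassembly all bound molecules
are released and a same-size footprint reappears at a new random admissible
position (see :mod:`yapkmc.engine` for the state-level release).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Tuple

import numpy as np
from scipy.spatial.distance import pdist

from .lattice import LatticeGeometry, wrap_xy

ClumpPolicy = Literal["spaced", "clumping_allowed"]


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot realize a requested layout."""


@dataclass(frozen=True)
class ConfinementRegion:
    """Square sub-area of the membrane (1-based origin, no wrap)."""

    x0: int
    y0: int
    side: int

    def contains(self, x: int, y: int) -> bool:
        return self.x0 <= x < self.x0 + self.side and self.y0 <= y < self.y0 + self.side

    def area_um2(self, l: float) -> float:
        return self.side ** 2 * l ** 2


@dataclass
class AdhesionFootprint:
    """One rectangular adhesion: origin is the lower-left site (1-based)."""

    id: int
    origin: Tuple[int, int]
    width: int
    height: int
    geom: LatticeGeometry

    def sites(self) -> List[Tuple[int, int]]:
        """Member membrane sites (wrapped onto the lattice)."""
        x0, y0 = self.origin
        out = []
        for dx in range(self.width):
            for dy in range(self.height):
                x, y, _ = wrap_xy(self.geom, x0 + dx, y0 + dy, 1)
                out.append((x, y))
        return out

    @property
    def n_binding_sites(self) -> int:
        return self.width * self.height


@dataclass
class AdhesionLayout:
    """A set of non-overlapping footprints plus the confinement geometry."""

    geom: LatticeGeometry
    footprints: Dict[int, AdhesionFootprint] = field(default_factory=dict)
    r: float = 1.0
    region: Optional[ConfinementRegion] = None
    clump_policy: ClumpPolicy = "spaced"

    def __post_init__(self) -> None:
        self._rebuild_map()

    def _rebuild_map(self) -> None:
        # int32 map of membrane sites -> adhesion id (-1 outside footprints)
        m = np.full((self.geom.nx, self.geom.ny), -1, dtype=np.int32)
        for fp in self.footprints.values():
            for x, y in fp.sites():
                if m[x - 1, y - 1] != -1:
                    raise ValueError("footprints overlap")
                m[x - 1, y - 1] = fp.id
        self.site_map = m

    def adhesion_at(self, x: int, y: int) -> Optional[int]:
        v = int(self.site_map[x - 1, y - 1])
        return None if v == -1 else v

    @property
    def n_binding_sites(self) -> int:
        return sum(fp.n_binding_sites for fp in self.footprints.values())

    def binding_sites(self) -> List[Tuple[int, int]]:
        out: List[Tuple[int, int]] = []
        for fid in sorted(self.footprints):
            out.extend(self.footprints[fid].sites())
        return out

    def replace_footprint(
        self, adhesion_id: int, rng: np.random.Generator, max_attempts: int = 100_000
    ) -> AdhesionFootprint:
        """Remove one footprint and place a same-size one at a new random
        admissible position (volume exclusion against the survivors)."""
        old = self.footprints.pop(adhesion_id)
        self._rebuild_map()
        try:
            new = _place_one(
                self.geom,
                old.width,
                old.height,
                self.region,
                self.clump_policy,
                self.site_map,
                rng,
                max_attempts,
            )
        except PlacementError:
            self.footprints[adhesion_id] = old  # restore before failing
            self._rebuild_map()
            raise
        new.id = adhesion_id
        self.footprints[adhesion_id] = new
        self._rebuild_map()
        return new


def sample_confinement_region(
    geom: LatticeGeometry, r: float, rng: np.random.Generator
) -> Optional[ConfinementRegion]:
    """Square region of area ``r`` × membrane area, uniformly positioned.

    ``r = 1`` means the whole membrane (returns ``None``: no confinement).
    """
    if not 0 < r <= 1:
        raise ValueError("confinement fraction r must be in (0, 1]")
    if r == 1:
        return None
    side = round(math.sqrt(r * geom.nx * geom.ny))
    if side < 1 or side > min(geom.nx, geom.ny):
        raise ValueError(f"confinement fraction {r} yields side {side} that "
                         f"does not fit the {geom.nx}×{geom.ny} membrane")
    x0 = int(rng.integers(1, geom.nx - side + 2))
    y0 = int(rng.integers(1, geom.ny - side + 2))
    return ConfinementRegion(x0, y0, side)


def _candidate_sites(
    geom: LatticeGeometry,
    x0: int,
    y0: int,
    width: int,
    height: int,
    halo: int,
) -> List[Tuple[int, int]]:
    """Footprint sites dilated by ``halo``, wrapped onto the membrane."""
    out = []
    for dx in range(-halo, width + halo):
        for dy in range(-halo, height + halo):
            x, y, _ = wrap_xy(geom, x0 + dx, y0 + dy, 1)
            out.append((x, y))
    return out


def _place_one(
    geom: LatticeGeometry,
    width: int,
    height: int,
    region: Optional[ConfinementRegion],
    clump_policy: ClumpPolicy,
    site_map: np.ndarray,
    rng: np.random.Generator,
    max_attempts: int,
) -> AdhesionFootprint:
    halo = 1 if clump_policy == "spaced" else 0
    for _ in range(max_attempts):
        if region is None:
            # may wrap across periodic edges
            x0 = int(rng.integers(1, geom.nx + 1))
            y0 = int(rng.integers(1, geom.ny + 1))
        else:
            hi_x = region.x0 + region.side - width
            hi_y = region.y0 + region.side - height
            if hi_x < region.x0 or hi_y < region.y0:
                raise PlacementError(
                    f"{width}×{height} footprint does not fit in the "
                    f"{region.side}×{region.side} confinement region")
            x0 = int(rng.integers(region.x0, hi_x + 1))
            y0 = int(rng.integers(region.y0, hi_y + 1))
        cand = _candidate_sites(geom, x0, y0, width, height, halo)
        if all(site_map[x - 1, y - 1] == -1 for x, y in cand):
            return AdhesionFootprint(-1, (x0, y0), width, height, geom)
    raise PlacementError(
        f"could not place a {width}×{height} footprint after {max_attempts} "
        f"attempts (policy={clump_policy}, region={region})")


def place_adhesions(
    geom: LatticeGeometry,
    n: int,
    width: int,
    height: int,
    region: Optional[ConfinementRegion] = None,
    clump_policy: ClumpPolicy = "spaced",
    rng: Optional[np.random.Generator] = None,
    max_attempts: int = 100_000,
) -> AdhesionLayout:
    """Place ``n`` same-size footprints uniformly at random with volume
    exclusion, restarting the whole layout when sequential sampling jams."""
    rng = np.random.default_rng() if rng is None else rng
    area = (region.side ** 2) if region is not None else geom.nx * geom.ny
    if n * width * height > area:
        raise PlacementError(
            f"{n} footprints of {width}×{height} exceed the available "
            f"{area}-site area")
    r = (region.side ** 2) / (geom.nx * geom.ny) if region is not None else 1.0

    attempts_left = max_attempts
    per_adhesion = max(100, max_attempts // (10 * max(n, 1)))
    while attempts_left > 0:
        site_map = np.full((geom.nx, geom.ny), -1, dtype=np.int32)
        placed: List[AdhesionFootprint] = []
        try:
            for i in range(n):
                budget = min(per_adhesion, attempts_left)
                fp = _place_one(geom, width, height, region, clump_policy,
                                site_map, rng, budget)
                fp.id = i
                for x, y in fp.sites():
                    site_map[x - 1, y - 1] = i
                placed.append(fp)
            layout = AdhesionLayout(
                geom, {fp.id: fp for fp in placed}, r, region, clump_policy)
            return layout
        except PlacementError:
            attempts_left -= per_adhesion
    raise PlacementError(
        f"could not place {n} {width}×{height} footprints under policy "
        f"{clump_policy} within {max_attempts} attempts")


@dataclass
class TurnoverSchedule:
    """Per-adhesion absolute disassembly times (empty when no turnover)."""

    lifetime: Optional[float]
    next_disassembly: Dict[int, float] = field(default_factory=dict)

    def next_event(self) -> Tuple[float, int]:
        """(time, adhesion id) of the earliest scheduled disassembly."""
        if not self.next_disassembly:
            return math.inf, -1
        aid = min(self.next_disassembly, key=lambda k: (self.next_disassembly[k], k))
        return self.next_disassembly[aid], aid

    def reschedule(self, adhesion_id: int, now: float) -> None:
        assert self.lifetime is not None
        self.next_disassembly[adhesion_id] = now + self.lifetime


def initial_turnover_times(
    lifetime: Optional[float], adhesion_ids, rng: np.random.Generator
) -> TurnoverSchedule:
    """Desynchronized initial schedule: each adhesion starts with a random
    elapsed age ``tl ~ Uniform(0, lifetime)`` so it disassembles at
    ``lifetime − tl``."""
    if lifetime is None:
        return TurnoverSchedule(None)
    if lifetime <= 0:
        raise ValueError("lifetime must be positive")
    times = {int(a): lifetime - float(rng.uniform(0, lifetime)) for a in adhesion_ids}
    return TurnoverSchedule(lifetime, times)


def save_layout_csv(layout: AdhesionLayout, path) -> None:
    """Write one row per binding site: adhesion_id, x, y."""
    import pandas as pd

    rows = [(fid, x, y) for fid in sorted(layout.footprints)
            for x, y in layout.footprints[fid].sites()]
    pd.DataFrame(rows, columns=["adhesion_id", "x", "y"]).to_csv(path,
                                                                 index=False)


def load_layout_csv(geom: LatticeGeometry, path,
                    r: float = 1.0,
                    region: Optional[ConfinementRegion] = None,
                    clump_policy: ClumpPolicy = "spaced") -> AdhesionLayout:
    """Rebuild a layout from a binding-site CSV (adhesion_id, x, y rows).

    Each adhesion's sites must form a w×h rectangle, possibly wrapped across
    the periodic edges.
    """
    import pandas as pd

    df = pd.read_csv(path)
    footprints = {}
    for fid, grp in df.groupby("adhesion_id"):
        sites = {(int(x), int(y)) for x, y in zip(grp.x, grp.y)}
        fp = _rectangle_from_sites(geom, int(fid), sites)
        footprints[int(fid)] = fp
    return AdhesionLayout(geom, footprints, r, region, clump_policy)


def _rectangle_from_sites(geom: LatticeGeometry, fid: int, sites) -> AdhesionFootprint:
    m = len(sites)
    for w in range(1, m + 1):
        if m % w:
            continue
        h = m // w
        for (ox, oy) in sites:
            cand = AdhesionFootprint(fid, (ox, oy), w, h, geom)
            if set(cand.sites()) == sites:
                return cand
    raise ValueError(f"adhesion {fid}: sites do not form a rectangle")


def average_pairwise_distance(layout: AdhesionLayout, l: Optional[float] = None) -> float:
    """Mean Euclidean distance (μm) between all unordered pairs of binding-site
    centers: ``(2 / m(m−1)) Σ_{i<j} d_ij``.

    Distances are plain Euclidean in the stored (wrapped) coordinates; no
    periodic minimum-image convention is applied.
    """
    l = layout.geom.l if l is None else l
    sites = np.asarray(layout.binding_sites(), dtype=float)
    if len(sites) < 2:
        raise ValueError("need at least 2 binding sites")
    return float(pdist(sites).mean() * l)


def total_adhesion_area(layout: AdhesionLayout, l: Optional[float] = None) -> float:
    """Total footprint area in μm² (Σ width·height·l²)."""
    if not layout.footprints:
        raise ValueError("layout has no footprints")
    l = layout.geom.l if l is None else l
    return sum(fp.width * fp.height for fp in layout.footprints.values()) * l ** 2
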