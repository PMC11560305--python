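"""Next-event stochastic simulation of YAP phosphorylation at adhesions.

Each molecule carries an absolute next-event time drawn as
``τ = −log(rand)/(ri + di)`` where ``ri`` sums its reaction-channel rates and
``di`` is its diffusion rate (0 when bound).  The molecule with the globally
smallest time fires; with probability ``ri/(ri+di)`` a reaction is chosen
(channels proportionally to rate), otherwise a hop to one of six neighbours
picked uniformly.  Only the executed molecule's clock is redrawn; other clocks
remain valid by memorylessness.  Rates are re-evaluated lazily at execution
time, so eligibility changes caused by other molecules (e.g. a binding site
freed) are honoured without touching other clocks.

Rejected attempts — hops into occupied or out-of-bounds sites, release under
an occupied z=2 site — consume the event: time advances and the clock is
redrawn, which keeps the hop rate at the fixed ``6D/l²``.

Scheduled adhesion disassemblies interleave with molecule events by absolute
time; a disassembly beats a molecule event at exactly equal times.

The production run loop is a compiled kernel (:mod:`yapkmc._kernel`); the
functions here also implement every event rule in plain Python on
:class:`SimulationState`, which is what the exact-CTMC oracle and the unit
tests exercise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from . import _kernel
from .adhesions import (AdhesionLayout, TurnoverSchedule, initial_turnover_times,
                        place_adhesions, sample_confinement_region,
                        total_adhesion_area)
from .config import SimulationConfig
from .lattice import LatticeGeometry, OccupancyGrid, wrap_xy
from .observables import (TrajectorySeries, aggregate_replicates,
                          steady_state_mean)

YAP = 0
PYAP = 1

#: (dx, dy, dz) for the six hop directions, in the kernel's order
DIRECTIONS = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1),
              (0, 0, -1))


class ConsistencyError(RuntimeError):
    """An event was invoked for a molecule that cannot perform it."""


def hop_rate(D: float, l: float) -> float:
    """Total lattice hop rate d = 6·D/l² (each direction attempted at d/6)."""
    if D < 0:
        raise ValueError("diffusion coefficient must be >= 0")
    if l <= 0:
        raise ValueError("node spacing must be > 0")
    return 6.0 * D / l ** 2


@dataclass
class RateBundle:
    """Named channel rates (s⁻¹) for one molecule in its current state."""

    diffuse: float = 0.0
    bind: float = 0.0
    phosphorylate: float = 0.0
    unbind: float = 0.0
    dephosphorylate: float = 0.0

    @property
    def ri(self) -> float:
        return (self.bind + self.phosphorylate + self.unbind
                + self.dephosphorylate)

    @property
    def di(self) -> float:
        return self.diffuse

    @property
    def total(self) -> float:
        return self.ri + self.di


@dataclass
class Molecule:
    """Read-only view of one molecule (1-based coordinates)."""

    id: int
    coordinate: Tuple[int, int, int]
    phospho_state: str                # "YAP" or "pYAP"
    bound_adhesion: Optional[int]
    next_event_time: float


class SimulationState:
    """Mutable simulation state: grid, molecule roster, layout, clocks."""

    def __init__(self, config: SimulationConfig, layout: AdhesionLayout,
                 schedule: TurnoverSchedule):
        self.config = config
        self.geom: LatticeGeometry = config.geometry
        self.layout = layout
        self.schedule = schedule
        self.time = 0.0
        n = config.n_yap
        self.grid = OccupancyGrid(self.geom)
        self.pos = np.zeros((n, 3), dtype=np.int32)      # 0-based
        self.phospho = np.zeros(n, dtype=np.uint8)
        self.bound = np.full(n, -1, dtype=np.int32)
        self.times = np.zeros(n, dtype=np.float64)
        self.disp = np.zeros((n, 3), dtype=np.int64)     # unwrapped hops
        self.counters = np.zeros(_kernel.N_COUNTERS, dtype=np.int64)
        self.n_turnovers = 0

    # -- molecule views -------------------------------------------------
    @property
    def n_molecules(self) -> int:
        return len(self.times)

    def molecule(self, i: int) -> Molecule:
        x, y, z = (int(v) + 1 for v in self.pos[i])
        b = int(self.bound[i])
        return Molecule(
            id=i, coordinate=(x, y, z),
            phospho_state="pYAP" if self.phospho[i] else "YAP",
            bound_adhesion=None if b < 0 else b,
            next_event_time=float(self.times[i]))

    # -- observables -----------------------------------------------------
    def n_pyap_total(self) -> int:
        return int((self.phospho == PYAP).sum())

    def n_pyap_inside(self) -> int:
        return int(((self.phospho == PYAP) & (self.bound >= 0)).sum())

    def counter_dict(self) -> dict:
        return {name: int(v)
                for name, v in zip(_kernel.COUNTER_NAMES, self.counters)}

    def snapshot_dataframe(self):
        """One row per molecule: id, 1-based position, state, bound adhesion."""
        import pandas as pd

        return pd.DataFrame({
            "molecule_id": np.arange(self.n_molecules),
            "x": self.pos[:, 0] + 1,
            "y": self.pos[:, 1] + 1,
            "z": self.pos[:, 2] + 1,
            "state": np.where(self.phospho == PYAP, "pYAP", "YAP"),
            "bound_adhesion_id": self.bound,
        })

    # -- invariants -------------------------------------------------------
    def check_invariants(self) -> None:
        n = self.n_molecules
        if self.grid.n_occupied != n:
            raise ConsistencyError(
                f"grid holds {self.grid.n_occupied} occupants for {n} molecules")
        adh_map = self.layout.site_map
        for i in range(n):
            x, y, z = self.pos[i]
            if self.grid.array[x, y, z] != i:
                raise ConsistencyError(f"molecule {i} not on its grid site")
            if z == 0:
                if self.bound[i] < 0:
                    raise ConsistencyError(
                        f"molecule {i} on the membrane but not bound")
                if adh_map[x, y] != self.bound[i]:
                    raise ConsistencyError(
                        f"molecule {i} bound to adhesion {self.bound[i]} but "
                        f"sits on a site of {adh_map[x, y]}")
            elif self.bound[i] >= 0:
                raise ConsistencyError(f"molecule {i} bound but z > 1")


# ---------------------------------------------------------------------------
# channel rates and event selection
# ---------------------------------------------------------------------------

def channel_rates(state: SimulationState, i: int) -> RateBundle:
    """Per-channel rates of molecule ``i`` given the current grid.

    This is the reference rate definition: the compiled kernel and the exact
    CTMC oracle both follow it.
    """
    cfg = state.config
    if state.bound[i] >= 0:
        if state.phospho[i] == YAP:
            return RateBundle(phosphorylate=cfg.Rp, unbind=cfg.Ru_YAP)
        return RateBundle(unbind=cfg.Ru_pYAP)
    x, y, z = state.pos[i]
    if z == 0:
        raise ConsistencyError(
            f"unbound molecule {i} in the forbidden z=1 plane")
    d = hop_rate(cfg.D, cfg.l)
    if state.phospho[i] == PYAP:
        return RateBundle(diffuse=d, dephosphorylate=cfg.Rdeph)
    if (z == 1 and state.layout.site_map[x, y] >= 0
            and state.grid.array[x, y, 0] == OccupancyGrid.EMPTY):
        return RateBundle(diffuse=d, bind=cfg.Rb)
    return RateBundle(diffuse=d)


def draw_event_time(rates: RateBundle, t_now: float,
                    rng: np.random.Generator) -> float:
    """Absolute next-event time ``t_now − log(rand)/(ri+di)``; +inf for an
    inert molecule (total rate 0)."""
    total = rates.total
    if total <= 0:
        return math.inf
    return t_now - math.log(1.0 - rng.random()) / total


def next_event(state: SimulationState):
    """The globally earliest pending event.

    Returns ``("turnover", adhesion_id, time)`` or ``("molecule", id, time)``.
    A scheduled disassembly beats a molecule event at exactly equal times;
    molecule ties break to the lowest id.
    """
    i = int(np.argmin(state.times))
    t_mol = float(state.times[i])
    t_turn, aid = state.schedule.next_event()
    if t_turn <= t_mol:
        return ("turnover", aid, t_turn)
    return ("molecule", i, t_mol)


# ---------------------------------------------------------------------------
# event execution (Python reference path)
# ---------------------------------------------------------------------------

def attempt_diffusion(state: SimulationState, i: int, direction) -> bool:
    """Hop molecule ``i`` one site; returns False on a rejected attempt.

    Rejection: target occupied, or z would leave the cytosol [2, nz] (the
    membrane plane is reachable only through the binding channel).
    """
    if state.bound[i] >= 0:
        raise ConsistencyError(f"bound molecule {i} cannot diffuse")
    if isinstance(direction, int):
        direction = DIRECTIONS[direction]
    dx, dy, dz = direction
    x, y, z = (int(v) for v in state.pos[i])
    zt = z + dz
    if zt < 1 or zt > state.geom.nz - 1:
        return False
    xt, yt, _ = wrap_xy(state.geom, x + dx + 1, y + dy + 1, 1)
    xt -= 1
    yt -= 1
    if state.grid.array[xt, yt, zt] != OccupancyGrid.EMPTY:
        return False
    state.grid.array[x, y, z] = OccupancyGrid.EMPTY
    state.grid.array[xt, yt, zt] = i
    state.pos[i] = (xt, yt, zt)
    state.disp[i] += (dx, dy, dz)
    return True


def execute_binding(state: SimulationState, i: int) -> bool:
    """YAP at z=2 jumps onto the free adhesion site directly below.

    Returns False (rejected attempt) if the site was taken since the rates
    were computed.
    """
    x, y, z = (int(v) for v in state.pos[i])
    if (state.bound[i] >= 0 or state.phospho[i] != YAP or z != 1
            or state.layout.site_map[x, y] < 0):
        raise ConsistencyError(f"molecule {i} is not eligible to bind")
    if state.grid.array[x, y, 0] != OccupancyGrid.EMPTY:
        return False
    state.grid.array[x, y, 1] = OccupancyGrid.EMPTY
    state.grid.array[x, y, 0] = i
    state.pos[i, 2] = 0
    state.bound[i] = state.layout.site_map[x, y]
    return True


def execute_phosphorylation(state: SimulationState, i: int) -> None:
    if state.bound[i] < 0 or state.phospho[i] != YAP:
        raise ConsistencyError(f"molecule {i} is not a bound YAP")
    state.phospho[i] = PYAP


def execute_unbinding(state: SimulationState, i: int) -> bool:
    """Release a bound molecule to the z=2 site directly above; rejected
    (returns False, molecule stays bound) if that site is occupied.
    The phosphorylation state is preserved."""
    if state.bound[i] < 0:
        raise ConsistencyError(f"molecule {i} is not bound")
    x, y, _ = (int(v) for v in state.pos[i])
    if state.grid.array[x, y, 1] != OccupancyGrid.EMPTY:
        return False
    state.grid.array[x, y, 0] = OccupancyGrid.EMPTY
    state.grid.array[x, y, 1] = i
    state.pos[i, 2] = 1
    state.bound[i] = -1
    return True


def execute_dephosphorylation(state: SimulationState, i: int) -> None:
    if state.bound[i] >= 0 or state.phospho[i] != PYAP:
        raise ConsistencyError(f"molecule {i} is not a cytosolic pYAP")
    state.phospho[i] = YAP


def choose_and_execute(state: SimulationState, i: int,
                       rng: np.random.Generator) -> str:
    """Select and execute one event for molecule ``i`` (reference path).

    Reaction with probability ri/(ri+di); within reactions, channels
    proportionally to rate; within diffusion, one of six directions uniformly.
    Advances the clock to the event time and redraws molecule ``i``'s clock
    from its post-event rates, whether or not the attempt was rejected.
    """
    t = float(state.times[i])
    rates = channel_rates(state, i)
    if rates.total <= 0:
        state.times[i] = math.inf
        return "inert"
    state.time = t
    if rng.random() * rates.total < rates.ri:
        v = rng.random() * rates.ri
        if v < rates.phosphorylate:
            execute_phosphorylation(state, i)
            outcome = "phosphorylate"
        elif v < rates.phosphorylate + rates.unbind:
            ok = execute_unbinding(state, i)
            outcome = "unbind" if ok else "unbind_rejected"
        elif v < rates.phosphorylate + rates.unbind + rates.bind:
            ok = execute_binding(state, i)
            outcome = "bind" if ok else "bind_rejected"
        else:
            execute_dephosphorylation(state, i)
            outcome = "dephosphorylate"
    else:
        k = int(rng.random() * 6.0)
        ok = attempt_diffusion(state, i, k)
        outcome = "diffuse" if ok else "diffuse_rejected"
    state.times[i] = draw_event_time(channel_rates(state, i), t, rng)
    return outcome


# ---------------------------------------------------------------------------
# adhesion turnover
# ---------------------------------------------------------------------------

def _free_cytosolic_site_near(state: SimulationState, x: int, y: int):
    """First free cytosolic site scanning outward from (x, y, z=2) in
    increasing Chebyshev distance, ties broken by sorted coordinates
    (0-based inputs and outputs)."""
    geom = state.geom
    arr = state.grid.array
    max_radius = max(geom.nx, geom.ny, geom.nz)
    for radius in range(max_radius + 1):
        shell = set()
        for dx in range(-radius, radius + 1):
            for dy in range(-radius, radius + 1):
                for dz in range(-radius, radius + 1):
                    if max(abs(dx), abs(dy), abs(dz)) != radius:
                        continue
                    zt = 1 + dz
                    if zt < 1 or zt > geom.nz - 1:
                        continue
                    shell.add(((x + dx) % geom.nx, (y + dy) % geom.ny, zt))
        for site in sorted(shell):
            if arr[site] == OccupancyGrid.EMPTY:
                return site
    raise ConsistencyError("no free cytosolic site for a released molecule")


def execute_turnover(state: SimulationState, adhesion_id: int,
                     rng: np.random.Generator) -> List[int]:
    """Disassemble one adhesion at the current time.

    Every bound molecule is relocated to the cytosol (z=2 above its site, or
    the nearest free site by Chebyshev scan), keeping its phosphorylation
    state; a same-size footprint is placed at a new random admissible
    position and its next disassembly is scheduled one lifetime from now.
    Returns the ids of the released molecules.
    """
    released = [i for i in range(state.n_molecules)
                if state.bound[i] == adhesion_id]
    for i in sorted(released):
        x, y, _ = (int(v) for v in state.pos[i])
        site = _free_cytosolic_site_near(state, x, y)
        state.grid.array[x, y, 0] = OccupancyGrid.EMPTY
        state.grid.array[site] = i
        state.pos[i] = site
        state.bound[i] = -1
    state.layout.replace_footprint(adhesion_id, rng)
    if state.schedule.lifetime is not None:
        state.schedule.reschedule(adhesion_id, state.time)
    for i in sorted(released):
        state.times[i] = draw_event_time(channel_rates(state, i), state.time,
                                         rng)
    state.n_turnovers += 1
    return released


# ---------------------------------------------------------------------------
# initialization and full runs
# ---------------------------------------------------------------------------

def _kernel_seed(seed: int) -> int:
    return int(np.random.SeedSequence(seed).generate_state(2)[1] & 0x7FFFFFFF)


def initialize_state(config: SimulationConfig, rng: np.random.Generator,
                     layout: Optional[AdhesionLayout] = None) -> SimulationState:
    """Place adhesions and all molecules, draw the initial clocks.

    Molecules start unphosphorylated on distinct uniformly random cytosolic
    (z ≥ 2) sites; the initial pYAP count is zero.
    """
    config.validate()
    geom = config.geometry
    if layout is None:
        region = sample_confinement_region(geom, config.r, rng)
        layout = place_adhesions(
            geom, config.n_adhesions, config.adhesion_width,
            config.adhesion_height, region=region,
            clump_policy=config.clump_policy, rng=rng)
    schedule = initial_turnover_times(
        config.lifetime, sorted(layout.footprints), rng)
    state = SimulationState(config, layout, schedule)

    n_cyt = geom.nx * geom.ny * (geom.nz - 1)
    if config.n_yap > n_cyt:
        raise ValueError("more molecules than free cytosolic sites")
    flat = rng.choice(n_cyt, size=config.n_yap, replace=False)
    for i, f in enumerate(flat):
        x = int(f % geom.nx)
        y = int((f // geom.nx) % geom.ny)
        z = int(f // (geom.nx * geom.ny)) + 1     # 0-based z in [1, nz-1]
        state.grid.array[x, y, z] = i
        state.pos[i] = (x, y, z)
    for i in range(config.n_yap):
        state.times[i] = draw_event_time(channel_rates(state, i), 0.0, rng)
    return state


@dataclass
class SimulationResult:
    config: SimulationConfig
    seed: int
    series: TrajectorySeries
    state: SimulationState = field(repr=False)
    counters: dict
    n_turnovers: int
    realized_adhesion_area: float
    steps_run: int


_EMPTY_TRACE_F = np.zeros(0, dtype=np.float64)
_EMPTY_TRACE_I = np.zeros(0, dtype=np.int64)


def run_simulation(config: SimulationConfig, seed: Optional[int] = None,
                   layout: Optional[AdhesionLayout] = None,
                   check_invariants: bool = False) -> SimulationResult:
    """Run one full trajectory for ``config.steps`` molecule events.

    Counts are recorded every ``config.record_every`` events; adhesion
    disassemblies interleave by absolute time between kernel segments.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    _kernel.seed_kernel(_kernel_seed(seed))
    state = initialize_state(config, rng, layout=layout)
    cfg = config
    d = hop_rate(cfg.D, cfg.l)

    rec_steps = [0]
    rec_times = [0.0]
    rec_total = [state.n_pyap_total()]
    rec_inside = [state.n_pyap_inside()]

    done = 0
    next_rec = min(cfg.record_every, cfg.steps)
    while done < cfg.steps:
        t_turn, aid = state.schedule.next_event()
        done, t_new = _kernel.advance(
            state.pos, state.phospho, state.bound, state.times,
            state.grid.array, state.layout.site_map, state.disp,
            state.counters,
            d, cfg.Rb, cfg.Rp, cfg.Ru_YAP, cfg.Ru_pYAP, cfg.Rdeph,
            done, next_rec, t_turn, state.time,
            False, _EMPTY_TRACE_F, _EMPTY_TRACE_I)
        state.time = t_new
        if done == next_rec:
            rec_steps.append(done)
            rec_times.append(state.time)
            rec_total.append(state.n_pyap_total())
            rec_inside.append(state.n_pyap_inside())
            if check_invariants:
                state.check_invariants()
            next_rec = min(next_rec + cfg.record_every, cfg.steps)
            continue
        # kernel stopped early: a disassembly is due, or everything is inert
        if t_turn < math.inf and float(state.times.min()) >= t_turn:
            state.time = t_turn
            execute_turnover(state, aid, rng)
        else:
            break  # all molecules inert; nothing can ever fire again

    series = TrajectorySeries(
        steps=np.asarray(rec_steps), times=np.asarray(rec_times),
        n_pyap_total=np.asarray(rec_total),
        n_pyap_inside=np.asarray(rec_inside),
        n_pyap_outside=np.asarray(rec_total) - np.asarray(rec_inside),
        n_yap=cfg.n_yap)
    return SimulationResult(
        config=cfg, seed=seed, series=series, state=state,
        counters=state.counter_dict(), n_turnovers=state.n_turnovers,
        realized_adhesion_area=(total_adhesion_area(state.layout)
                                if state.layout.footprints else 0.0),
        steps_run=done)


@dataclass
class ReplicateResult:
    results: List[SimulationResult]
    ss_means: np.ndarray          # per-replicate steady-state total ratios
    mean: float
    sd: float
    inside_mean: float
    inside_sd: float
    outside_mean: float
    outside_sd: float


def run_replicates(config: SimulationConfig, k: Optional[int] = None,
                   layout: Optional[AdhesionLayout] = None) -> ReplicateResult:
    """Run ``k`` replicates with seeds base+0 … base+k−1 and fresh random
    adhesion positions each, and aggregate the steady-state ratios."""
    k = config.replicates if k is None else k
    if k < 1:
        raise ValueError("need at least one replicate")
    results = []
    ss_tot, ss_in, ss_out = [], [], []
    for i in range(k):
        res = run_simulation(config, seed=config.seed + i, layout=layout)
        results.append(res)
        bf = config.burn_in_fraction
        ss_tot.append(steady_state_mean(res.series.ratio_total, bf)[0])
        ss_in.append(steady_state_mean(res.series.ratio_inside, bf)[0])
        ss_out.append(steady_state_mean(res.series.ratio_outside, bf)[0])
    mean, sd = aggregate_replicates(ss_tot)
    mean_in, sd_in = aggregate_replicates(ss_in)
    mean_out, sd_out = aggregate_replicates(ss_out)
    return ReplicateResult(results=results, ss_means=np.asarray(ss_tot),
                           mean=mean, sd=sd,
                           inside_mean=mean_in, inside_sd=sd_in,
                           outside_mean=mean_out, outside_sd=sd_out)


# ---------------------------------------------------------------------------
# single-molecule traces (for exact-CTMC validation)
# ---------------------------------------------------------------------------

def run_single_molecule_trace(config: SimulationConfig, seed: Optional[int] = None,
                              layout: Optional[AdhesionLayout] = None):
    """Run one molecule for ``config.steps`` events, recording its state
    after every event.

    Returns ``(times, codes)`` including the initial state at t = 0; decode
    with :func:`decode_trace_code`.  Requires ``n_yap == 1`` and no turnover.
    """
    if config.n_yap != 1:
        raise ValueError("trace runs require exactly one molecule")
    if config.lifetime is not None:
        raise ValueError("trace runs do not support adhesion turnover")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    _kernel.seed_kernel(_kernel_seed(seed))
    state = initialize_state(config, rng, layout=layout)
    cfg = config
    geom = cfg.geometry
    init_code = _encode(geom, tuple(int(v) for v in state.pos[0]),
                        int(state.phospho[0]), int(state.bound[0]) >= 0)
    n_steps = cfg.steps
    trace_time = np.empty(n_steps, dtype=np.float64)
    trace_code = np.empty(n_steps, dtype=np.int64)
    done, _ = _kernel.advance(
        state.pos, state.phospho, state.bound, state.times,
        state.grid.array, state.layout.site_map, state.disp, state.counters,
        hop_rate(cfg.D, cfg.l), cfg.Rb, cfg.Rp, cfg.Ru_YAP, cfg.Ru_pYAP,
        cfg.Rdeph, 0, n_steps, math.inf, 0.0,
        True, trace_time, trace_code)
    times = np.concatenate(([0.0], trace_time[:done]))
    codes = np.concatenate(([init_code], trace_code[:done]))
    return times, codes


def _encode(geom: LatticeGeometry, pos0, phospho: int, bound: bool) -> int:
    x, y, z = pos0
    return (((z * geom.ny + y) * geom.nx + x) * 2 + phospho) * 2 + int(bound)


def decode_trace_code(geom: LatticeGeometry, code: int):
    """Decode a trace code to (x, y, z, phospho, bound) with 1-based coords."""
    bound = bool(code & 1)
    code >>= 1
    phospho = int(code & 1)
    code >>= 1
    x = code % geom.nx
    code //= geom.nx
    y = code % geom.ny
    z = code // geom.ny
    return (x + 1, y + 1, z + 1, phospho, bound)
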