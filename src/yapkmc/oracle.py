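"""Exact references for validating the stochastic engine.

For tiny single-molecule problems the model is a finite continuous-time
Markov chain: states are (position, phosphorylation, bound) tuples and the
transition rates are exactly the engine's channel rates (they are read off
:func:`yapkmc.engine.channel_rates`, the shared rate definition).  The
stationary distribution of that chain, obtained by a linear solve, is an
independent prediction of the engine's long-run state frequencies.

Rejected moves (hops off the closed z boundaries) are self-loops that only
stretch the time discretization; they are omitted from the generator, which
leaves the stationary law unchanged.

Also provides the closed-form per-axis mean-squared displacement 2·D·t for
free lattice diffusion, used to calibrate the hop rate d = 6D/l².
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve

from .adhesions import AdhesionFootprint, AdhesionLayout
from .config import SimulationConfig
from .engine import PYAP, YAP, SimulationState, channel_rates
from .lattice import OccupancyGrid, wrap_xy

STATE_CAP = 20_000

#: state tuple: (x, y, z, phospho) 1-based; z == 1 means bound at (x, y)
State = Tuple[int, int, int, int]


@dataclass
class TinyModelSpec:
    """A single-molecule model small enough for exact enumeration."""

    config: SimulationConfig
    layout: AdhesionLayout

    @classmethod
    def single_site(cls, nx: int = 3, ny: int = 3, nz: int = 4,
                    site: Tuple[int, int] = (2, 2), **rate_overrides
                    ) -> "TinyModelSpec":
        """A nx×ny×(nz−1) cytosol over one 1×1 binding site."""
        config = SimulationConfig(
            nx=nx, ny=ny, nz=nz, n_yap=1, n_adhesions=1,
            adhesion_width=1, adhesion_height=1,
            **rate_overrides).validate()
        geom = config.geometry
        fp = AdhesionFootprint(0, site, 1, 1, geom)
        layout = AdhesionLayout(geom, {0: fp})
        return cls(config, layout)


def enumerate_states(spec: TinyModelSpec):
    """All reachable single-molecule states and the CTMC generator.

    Returns ``(states, index, Q)`` with ``Q`` a CSR matrix whose off-diagonal
    entries are the engine's channel rates and whose rows sum to zero.
    """
    cfg = spec.config
    if cfg.n_yap != 1:
        raise ValueError("exact enumeration supports exactly one molecule")
    geom = cfg.geometry
    layout = spec.layout
    binding_sites = layout.binding_sites()

    states: List[State] = []
    for z in range(2, geom.nz + 1):
        for y in range(1, geom.ny + 1):
            for x in range(1, geom.nx + 1):
                for p in (YAP, PYAP):
                    states.append((x, y, z, p))
    for (x, y) in binding_sites:
        for p in (YAP, PYAP):
            states.append((x, y, 1, p))
    if len(states) > STATE_CAP:
        raise ValueError(f"{len(states)} states exceed the cap of {STATE_CAP}")
    index: Dict[State, int] = {s: i for i, s in enumerate(states)}

    # one reusable engine state; molecule 0 is moved through every CTMC state
    from .adhesions import TurnoverSchedule
    sim = SimulationState(cfg, layout, TurnoverSchedule(None))

    rows, cols, vals = [], [], []

    def add(src: State, dst: State, rate: float) -> None:
        if rate > 0:
            rows.append(index[src])
            cols.append(index[dst])
            vals.append(rate)

    for s in states:
        x, y, z, p = s
        sim.grid.array[:] = OccupancyGrid.EMPTY
        sim.grid.array[x - 1, y - 1, z - 1] = 0
        sim.pos[0] = (x - 1, y - 1, z - 1)
        sim.phospho[0] = p
        sim.bound[0] = layout.site_map[x - 1, y - 1] if z == 1 else -1
        b = channel_rates(sim, 0)
        if z == 1:  # bound
            if p == YAP:
                add(s, (x, y, 1, PYAP), b.phosphorylate)
                add(s, (x, y, 2, YAP), b.unbind)
            else:
                add(s, (x, y, 2, PYAP), b.unbind)
            continue
        per_dir = b.diffuse / 6.0
        for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            zt = z + dz
            if zt < 2 or zt > geom.nz:
                continue  # rejected move: omitted self-loop
            xt, yt, _ = wrap_xy(geom, x + dx, y + dy, zt)
            add(s, (xt, yt, zt, p), per_dir)
        if b.bind > 0:
            add(s, (x, y, 1, YAP), b.bind)
        if b.dephosphorylate > 0:
            add(s, (x, y, z, YAP), b.dephosphorylate)

    n = len(states)
    Q = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    Q = Q - sp.diags(np.asarray(Q.sum(axis=1)).ravel())
    return states, index, Q.tocsr()


def stationary_distribution(Q: sp.spmatrix) -> np.ndarray:
    """Solve πQ = 0, Σπ = 1, π ≥ 0.

    The chain must have a single closed communicating class; the stationary
    mass is zero on transient states.  Raises for multiple closed classes.
    """
    n = Q.shape[0]
    off = Q.copy().tolil()
    off.setdiag(0)
    adj = (off.tocsr() > 0).astype(np.int8)
    n_comp, labels = connected_components(adj, directed=True,
                                          connection="strong")
    # a class is closed iff no edge leaves it
    closed = set(range(n_comp))
    coo = adj.tocoo()
    for i, j in zip(coo.row, coo.col):
        if labels[i] != labels[j]:
            closed.discard(labels[i])
    if len(closed) == 0:
        raise ValueError("generator has no closed communicating class")
    if len(closed) > 1:
        raise ValueError(
            f"no unique stationary law: {len(closed)} closed classes "
            f"(labels {sorted(closed)})")
    cls = closed.pop()
    keep = np.where(labels == cls)[0]
    Qc = Q.tocsr()[keep][:, keep]
    m = len(keep)
    # replace the last balance equation with the normalization Σπ = 1
    A = Qc.T.tolil()
    A[m - 1, :] = 1.0
    b = np.zeros(m)
    b[m - 1] = 1.0
    if m <= 1500:
        pi_c = np.linalg.solve(A.toarray(), b)
    else:
        pi_c = spsolve(A.tocsr(), b)
    pi_c = np.clip(pi_c, 0.0, None)
    pi_c /= pi_c.sum()
    resid = np.abs(pi_c @ Qc.toarray() if m <= 1500 else pi_c @ Qc).max()
    if resid > 1e-8:
        raise RuntimeError(f"stationary solve residual {resid:.2e} too large")
    pi = np.zeros(n)
    pi[keep] = pi_c
    return pi


def msd_expectation(D: float, t: float) -> float:
    """Per-axis mean-squared displacement 2·D·t of free lattice diffusion."""
    if t < 0:
        raise ValueError("time must be >= 0")
    return 2.0 * D * t


def simulate_free_diffusion(D: float = 0.8, t: float = 2.0,
                            n_walkers: int = 150, n_runs: int = 100,
                            seed: int = 0, l: float = 0.2) -> dict:
    """Measure the per-axis MSD of reaction-free walkers against 2·D·t.

    Walkers start in a central slab of a tall box (z ∈ [nz/3, 2nz/3]) at low
    density, so the closed z boundaries stay unreached and excluded-volume
    encounters are rare over the measurement window.  Returns the pooled
    per-axis MSDs (μm²), the expectation and the relative errors.
    """
    from . import _kernel
    from .engine import _kernel_seed, hop_rate, initialize_state

    nz = 60
    cfg = SimulationConfig(nx=40, ny=40, nz=nz, l=l, D=D, Rb=0.0, Rp=0.0,
                           Ru_YAP=0.0, Ru_pYAP=0.0, Rdeph=0.0,
                           n_yap=n_walkers, n_adhesions=0,
                           steps=10 ** 9, record_every=10 ** 9)
    d = hop_rate(D, l)
    sq = np.zeros(3)
    total = 0
    for run in range(n_runs):
        run_seed = seed + run
        rng = np.random.default_rng(run_seed)
        _kernel.seed_kernel(_kernel_seed(run_seed))
        state = initialize_state(cfg, rng)
        # relocate every walker to a distinct random site in the central slab
        state.grid.array[:] = OccupancyGrid.EMPTY
        z_lo, z_hi = nz // 3, 2 * nz // 3            # 0-based slab bounds
        slab = cfg.nx * cfg.ny * (z_hi - z_lo)
        flat = rng.choice(slab, size=n_walkers, replace=False)
        for i, f in enumerate(flat):
            x = int(f % cfg.nx)
            y = int((f // cfg.nx) % cfg.ny)
            z = int(f // (cfg.nx * cfg.ny)) + z_lo
            state.grid.array[x, y, z] = i
            state.pos[i] = (x, y, z)
        state.times[:] = rng.exponential(1.0 / d, size=n_walkers)
        state.disp[:] = 0
        _kernel.advance(
            state.pos, state.phospho, state.bound, state.times,
            state.grid.array, state.layout.site_map, state.disp,
            state.counters, d, 0.0, 0.0, 0.0, 0.0, 0.0,
            0, 10 ** 9, t, 0.0,
            False, np.zeros(0), np.zeros(0, dtype=np.int64))
        sq += ((state.disp.astype(float) * l) ** 2).sum(axis=0)
        total += n_walkers
    msd = sq / total
    expected = msd_expectation(D, t)
    return {
        "msd_x": float(msd[0]), "msd_y": float(msd[1]), "msd_z": float(msd[2]),
        "expected": expected, "t": t, "n_walkers": total,
        "rel_err": [float(abs(m - expected) / expected) for m in msd],
    }


def occupancy_from_trace(times: np.ndarray, codes: np.ndarray,
                         burn_in_time: float = 0.0) -> Dict[int, float]:
    """Time-weighted state frequencies from an event trace.

    The state after event k holds from ``times[k]`` to ``times[k+1]``; the
    last state's holding time is unknown and dropped.  States are keyed by
    their trace code.
    """
    times = np.asarray(times, dtype=float)
    codes = np.asarray(codes)
    hold = np.diff(times)
    mask = times[:-1] >= burn_in_time
    total = hold[mask].sum()
    if total <= 0:
        raise ValueError("trace too short after burn-in")
    out: Dict[int, float] = {}
    for c, h in zip(codes[:-1][mask], hold[mask]):
        out[int(c)] = out.get(int(c), 0.0) + float(h)
    return {c: h / total for c, h in out.items()}
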