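"""Compiled inner event loop of the next-event stochastic algorithm.

The kernel advances molecule events only; adhesion turnover, recording and
placement stay in :mod:`yapkmc.engine`, which re-enters the kernel between
checkpoints.  All arrays use 0-based indices; z = 0 is the membrane plane and
the cytosol is z ∈ [1, nz-1].

Per event: the molecule with the globally smallest next-event time wins, its
channel rates are recomputed from the *current* grid (lazy re-evaluation, so a
binding opportunity that appeared or vanished since its clock was drawn is
honoured), a reaction is chosen with probability ri/(ri+di) and otherwise a
diffusion hop, and its clock is redrawn from the post-event rates.  Rejected
attempts (hops into occupied/forbidden sites, release under an occupied z=2
site) consume the event: time advances and the clock is redrawn.
"""

import numpy as np
from numba import njit

# counter indices
C_DIFFUSE = 0
C_DIFFUSE_REJ = 1
C_BIND = 2
C_PHOS = 3
C_UNBIND_YAP = 4
C_UNBIND_YAP_REJ = 5
C_UNBIND_PYAP = 6
C_UNBIND_PYAP_REJ = 7
C_DEPH = 8
N_COUNTERS = 9

COUNTER_NAMES = (
    "diffuse", "diffuse_rejected", "bind", "phosphorylate",
    "unbind_yap", "unbind_yap_rejected", "unbind_pyap",
    "unbind_pyap_rejected", "dephosphorylate",
)


@njit(cache=False)
def seed_kernel(seed):
    np.random.seed(seed)


@njit(cache=False, inline="always")
def _rates(i, pos, phospho, bound, grid, adh_map, d, rb, rp, ru_yap, ru_pyap,
           rdeph):
    """(ri, di) for molecule i under the current grid."""
    if bound[i] >= 0:
        if phospho[i] == 0:
            return rp + ru_yap, 0.0
        return ru_pyap, 0.0
    ri = 0.0
    if phospho[i] == 1:
        ri += rdeph
    elif pos[i, 2] == 1:
        x, y = pos[i, 0], pos[i, 1]
        if adh_map[x, y] >= 0 and grid[x, y, 0] == -1:
            ri += rb
    return ri, d


@njit(cache=False)
def advance(pos, phospho, bound, times, grid, adh_map, disp, counters,
            d, rb, rp, ru_yap, ru_pyap, rdeph,
            step, stop_step, t_stop, t_start,
            trace_on, trace_time, trace_code):
    """Run molecule events until the step budget or an event time >= t_stop.

    Returns (step, current_time).  ``t_stop`` is the next scheduled adhesion
    disassembly (or +inf); an event scheduled at or after it is left pending
    so the caller can fire the turnover first.
    """
    n = pos.shape[0]
    nx, ny, nz = grid.shape
    t_cur = t_start
    while step < stop_step:
        # earliest pending molecule event; ties go to the lowest id
        win = 0
        tmin = times[0]
        for j in range(1, n):
            if times[j] < tmin:
                tmin = times[j]
                win = j
        if tmin >= t_stop or tmin == np.inf:
            break
        i = win
        t_cur = tmin
        x, y, z = pos[i, 0], pos[i, 1], pos[i, 2]
        ri, di = _rates(i, pos, phospho, bound, grid, adh_map,
                        d, rb, rp, ru_yap, ru_pyap, rdeph)
        total = ri + di
        if total <= 0.0:
            times[i] = np.inf
            continue
        if np.random.random() * total < ri:
            # a reaction fires; channels are picked proportionally to rate
            if bound[i] >= 0:
                if phospho[i] == 0:
                    if np.random.random() * ri < rp:
                        phospho[i] = 1
                        counters[C_PHOS] += 1
                    else:  # release without phosphorylation, to z=2 above
                        if grid[x, y, 1] == -1:
                            grid[x, y, 0] = -1
                            grid[x, y, 1] = i
                            pos[i, 2] = 1
                            bound[i] = -1
                            counters[C_UNBIND_YAP] += 1
                        else:
                            counters[C_UNBIND_YAP_REJ] += 1
                else:  # bound pYAP: only release
                    if grid[x, y, 1] == -1:
                        grid[x, y, 0] = -1
                        grid[x, y, 1] = i
                        pos[i, 2] = 1
                        bound[i] = -1
                        counters[C_UNBIND_PYAP] += 1
                    else:
                        counters[C_UNBIND_PYAP_REJ] += 1
            else:
                if phospho[i] == 1:  # cytosolic dephosphorylation
                    phospho[i] = 0
                    counters[C_DEPH] += 1
                else:  # binding: z=2 -> free adhesion site directly below
                    grid[x, y, 1] = -1
                    grid[x, y, 0] = i
                    pos[i, 2] = 0
                    bound[i] = adh_map[x, y]
                    counters[C_BIND] += 1
        else:
            # diffusion hop: one of the six directions, uniformly
            k = int(np.random.random() * 6.0)
            dx = dy = dz = 0
            if k == 0:
                dx = 1
            elif k == 1:
                dx = -1
            elif k == 2:
                dy = 1
            elif k == 3:
                dy = -1
            elif k == 4:
                dz = 1
            else:
                dz = -1
            zt = z + dz
            if zt < 1 or zt > nz - 1:
                counters[C_DIFFUSE_REJ] += 1  # closed top / membrane plane
            else:
                xt = (x + dx) % nx
                yt = (y + dy) % ny
                if grid[xt, yt, zt] != -1:
                    counters[C_DIFFUSE_REJ] += 1  # excluded volume
                else:
                    grid[x, y, z] = -1
                    grid[xt, yt, zt] = i
                    pos[i, 0] = xt
                    pos[i, 1] = yt
                    pos[i, 2] = zt
                    disp[i, 0] += dx
                    disp[i, 1] += dy
                    disp[i, 2] += dz
                    counters[C_DIFFUSE] += 1
        # redraw this molecule's clock from its post-event rates
        ri2, di2 = _rates(i, pos, phospho, bound, grid, adh_map,
                          d, rb, rp, ru_yap, ru_pyap, rdeph)
        total2 = ri2 + di2
        if total2 <= 0.0:
            times[i] = np.inf
        else:
            times[i] = t_cur - np.log(1.0 - np.random.random()) / total2
        if trace_on and step < trace_time.shape[0]:
            trace_time[step] = t_cur
            trace_code[step] = (
                (((pos[0, 2] * ny + pos[0, 1]) * nx + pos[0, 0]) * 2
                 + phospho[0]) * 2 + (1 if bound[0] >= 0 else 0))
        step += 1
    return step, t_cur
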