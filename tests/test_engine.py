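import math

import numpy as np
import pytest

from yapkmc import (AdhesionFootprint, AdhesionLayout, ConsistencyError,
                    RateBundle, SimulationConfig, attempt_diffusion,
                    channel_rates, choose_and_execute, draw_event_time,
                    execute_binding, execute_dephosphorylation,
                    execute_phosphorylation, execute_turnover,
                    execute_unbinding, hop_rate, initialize_state, next_event,
                    run_replicates, run_simulation, run_single_molecule_trace)
from yapkmc.engine import PYAP, YAP, decode_trace_code


def build_state(molecules, footprint=None, lifetime=None, **cfg_kw):
    """State with molecules at explicit (x, y, z, phospho, bound) 1-based."""
    cfg = SimulationConfig(n_yap=len(molecules), lifetime=lifetime,
                           **cfg_kw).validate()
    geom = cfg.geometry
    fps = {}
    if footprint is not None:
        origin, w, h = footprint
        fps[0] = AdhesionFootprint(0, origin, w, h, geom)
    layout = AdhesionLayout(geom, fps)
    rng = np.random.default_rng(0)
    state = initialize_state(cfg, rng, layout=layout)
    state.grid.array[:] = -1
    for i, (x, y, z, p, b) in enumerate(molecules):
        state.pos[i] = (x - 1, y - 1, z - 1)
        state.phospho[i] = p
        state.bound[i] = b
        state.grid.array[x - 1, y - 1, z - 1] = i
    state.times[:] = 0.0
    return state


class FakeRng:
    """Deterministic stand-in exposing the Generator.random() interface."""

    def __init__(self, values):
        self.values = list(values)

    def random(self):
        return self.values.pop(0)


class TestHopRate:
    @pytest.mark.parametrize("D,expected", [(0.8, 120.0), (19.0, 2850.0),
                                            (0.0, 0.0)])
    def test_six_directions_over_l_squared(self, D, expected):
        assert hop_rate(D, 0.2) == pytest.approx(expected)

    def test_invalid(self):
        with pytest.raises(ValueError):
            hop_rate(-1.0, 0.2)
        with pytest.raises(ValueError):
            hop_rate(1.0, 0.0)


class TestChannelRates:
    def test_bulk_pyap_diffuses_and_dephosphorylates(self):
        state = build_state([(5, 5, 5, PYAP, -1)], footprint=((10, 10), 3, 3))
        b = channel_rates(state, 0)
        assert b.di == pytest.approx(120.0)
        assert b.ri == pytest.approx(state.config.Rdeph)
        assert b.dephosphorylate == state.config.Rdeph

    def test_yap_above_free_binding_site_can_bind(self):
        state = build_state([(10, 10, 2, YAP, -1)], footprint=((10, 10), 3, 3))
        b = channel_rates(state, 0)
        assert b.bind == state.config.Rb
        assert b.di == pytest.approx(120.0)

    def test_yap_above_occupied_site_cannot_bind(self):
        state = build_state([(10, 10, 2, YAP, -1), (10, 10, 1, YAP, 0)],
                            footprint=((10, 10), 3, 3))
        assert channel_rates(state, 0).bind == 0.0

    def test_bound_yap(self):
        state = build_state([(10, 10, 1, YAP, 0)], footprint=((10, 10), 3, 3))
        b = channel_rates(state, 0)
        assert b.di == 0.0
        assert b.ri == pytest.approx(state.config.Rp + state.config.Ru_YAP)

    def test_bound_pyap(self):
        state = build_state([(10, 10, 1, PYAP, 0)], footprint=((10, 10), 3, 3))
        b = channel_rates(state, 0)
        assert (b.di, b.ri) == (0.0, state.config.Ru_pYAP)

    def test_forbidden_region_is_inconsistent(self):
        state = build_state([(5, 5, 1, YAP, -1)], footprint=((10, 10), 3, 3))
        with pytest.raises(ConsistencyError):
            channel_rates(state, 0)


class TestDrawEventTime:
    def test_closed_form(self):
        rates = RateBundle(diffuse=120.0)
        # rand = 1 - e^-1 makes the increment exactly 1/(ri+di)
        t = draw_event_time(rates, 2.0, FakeRng([1 - math.exp(-1)]))
        assert t == pytest.approx(2.0 + 1 / 120.0)

    def test_inert_molecule_never_fires(self):
        assert draw_event_time(RateBundle(), 0.0,
                               FakeRng([0.5])) == math.inf

    def test_exponential_mean(self, rng):
        rates = RateBundle(diffuse=120.0)
        n = 100_000
        draws = np.array([draw_event_time(rates, 0.0, rng) for _ in range(n)])
        se = (1 / 120.0) / math.sqrt(n)
        assert abs(draws.mean() - 1 / 120.0) < 3 * se


class TestNextEvent:
    def test_minimum_molecule_wins(self):
        state = build_state([(5, 5, 5, YAP, -1), (6, 6, 6, YAP, -1),
                             (7, 7, 7, YAP, -1)])
        state.times[:] = (0.5, 0.2, 0.9)
        assert next_event(state) == ("molecule", 1, 0.2)

    def test_turnover_precedes_molecules(self):
        state = build_state([(5, 5, 5, YAP, -1)], footprint=((10, 10), 3, 3),
                            lifetime=60.0)
        state.times[:] = 0.5
        state.schedule.next_disassembly[0] = 0.4
        assert next_event(state) == ("turnover", 0, 0.4)
        state.schedule.next_disassembly[0] = 0.5  # exact tie -> turnover
        assert next_event(state) == ("turnover", 0, 0.5)

    def test_molecule_tie_breaks_to_lowest_id(self):
        state = build_state([(5, 5, 5, YAP, -1), (6, 6, 6, YAP, -1)])
        state.times[:] = (0.3, 0.3)
        assert next_event(state)[1] == 0


class TestDiffusion:
    def test_accept_into_empty_site(self):
        state = build_state([(5, 5, 5, YAP, -1)])
        assert attempt_diffusion(state, 0, (1, 0, 0))
        assert tuple(state.pos[0]) == (5, 4, 4)  # 0-based
        assert state.grid.array[5, 4, 4] == 0

    def test_reject_occupied_site(self):
        state = build_state([(5, 5, 5, YAP, -1), (6, 5, 5, YAP, -1)])
        assert not attempt_diffusion(state, 0, (1, 0, 0))
        assert tuple(state.pos[0]) == (4, 4, 4)

    def test_closed_boundaries(self):
        state = build_state([(5, 5, 2, YAP, -1)])
        assert not attempt_diffusion(state, 0, (0, 0, -1))  # z=2 -> membrane
        top = build_state([(5, 5, 20, YAP, -1)])
        assert not attempt_diffusion(top, 0, (0, 0, 1))     # z=nz -> closed

    def test_periodic_wrap(self):
        state = build_state([(40, 1, 5, YAP, -1)])
        assert attempt_diffusion(state, 0, (1, 0, 0))
        assert tuple(state.pos[0] + 1) == (1, 1, 5)
        assert attempt_diffusion(state, 0, (0, -1, 0))
        assert tuple(state.pos[0] + 1) == (1, 40, 5)

    def test_bound_molecule_cannot_diffuse(self):
        state = build_state([(10, 10, 1, YAP, 0)], footprint=((10, 10), 3, 3))
        with pytest.raises(ConsistencyError):
            attempt_diffusion(state, 0, (1, 0, 0))


class TestReactionExecution:
    def test_bind_then_phosphorylate(self):
        state = build_state([(10, 10, 2, YAP, -1)], footprint=((10, 10), 3, 3))
        assert execute_binding(state, 0)
        assert state.bound[0] == 0 and state.pos[0, 2] == 0
        execute_phosphorylation(state, 0)
        assert state.phospho[0] == PYAP
        assert state.n_pyap_inside() == 1
        state.check_invariants()

    def test_binding_race_is_rejected(self):
        state = build_state([(10, 10, 2, YAP, -1)], footprint=((10, 10), 3, 3))
        state.grid.array[9, 9, 0] = 99  # site taken since rates were drawn
        assert not execute_binding(state, 0)
        assert state.bound[0] == -1

    def test_binding_ineligible_raises(self):
        state = build_state([(5, 5, 2, YAP, -1)], footprint=((10, 10), 3, 3))
        with pytest.raises(ConsistencyError):
            execute_binding(state, 0)  # no adhesion below
        pyap = build_state([(10, 10, 2, PYAP, -1)], footprint=((10, 10), 3, 3))
        with pytest.raises(ConsistencyError):
            execute_binding(pyap, 0)   # pYAP never rebinds

    def test_unbind_preserves_phospho_state(self):
        state = build_state([(10, 10, 1, PYAP, 0)], footprint=((10, 10), 3, 3))
        assert execute_unbinding(state, 0)
        assert state.bound[0] == -1 and state.pos[0, 2] == 1
        assert state.phospho[0] == PYAP
        state.check_invariants()

    def test_unbind_into_occupied_site_rejected(self):
        state = build_state([(10, 10, 1, PYAP, 0), (10, 10, 2, YAP, -1)],
                            footprint=((10, 10), 3, 3))
        assert not execute_unbinding(state, 0)
        assert state.bound[0] == 0

    def test_dephosphorylation_rules(self):
        state = build_state([(5, 5, 5, PYAP, -1)])
        execute_dephosphorylation(state, 0)
        assert state.phospho[0] == YAP
        with pytest.raises(ConsistencyError):
            execute_dephosphorylation(state, 0)  # already YAP
        bound = build_state([(10, 10, 1, PYAP, 0)], footprint=((10, 10), 3, 3))
        with pytest.raises(ConsistencyError):
            execute_dephosphorylation(bound, 0)  # protected inside adhesion


class TestChooseAndExecute:
    def test_no_reactions_means_diffusion(self, rng):
        state = build_state([(5, 5, 5, YAP, -1)])
        for _ in range(50):
            out = choose_and_execute(state, 0, rng)
            assert out in ("diffuse", "diffuse_rejected")

    def test_bound_molecule_always_reacts(self, rng):
        outcomes = set()
        for _ in range(200):
            state = build_state([(10, 10, 1, YAP, 0)],
                                footprint=((10, 10), 3, 3))
            outcomes.add(choose_and_execute(state, 0, rng))
        assert outcomes <= {"phosphorylate", "unbind"}

    def test_channel_frequencies_match_rates(self, rng):
        # bound YAP with Rp = 2 Ru_YAP: phosphorylation picked 2/3 of the time
        n = 30_000
        phos = 0
        for _ in range(n):
            state = build_state([(10, 10, 1, YAP, 0)],
                                footprint=((10, 10), 3, 3), Rp=2.0, Ru_YAP=1.0)
            if choose_and_execute(state, 0, rng) == "phosphorylate":
                phos += 1
        p = 2 / 3
        se = math.sqrt(p * (1 - p) / n)
        assert abs(phos / n - p) < 3 * se


class TestTurnover:
    def test_release_conserves_molecules(self):
        state = build_state(
            [(10, 10, 1, PYAP, 0), (11, 10, 1, PYAP, 0), (11, 11, 1, PYAP, 0),
             (12, 12, 1, YAP, 0), (5, 5, 5, YAP, -1)],
            footprint=((10, 10), 3, 3), lifetime=60.0)
        state.time = 42.0
        rng = np.random.default_rng(3)
        released = execute_turnover(state, 0, rng)
        assert sorted(released) == [0, 1, 2, 3]
        assert (state.bound == -1).all()
        assert (state.pos[:, 2] >= 1).all()          # everyone in the cytosol
        assert state.n_pyap_total() == 3             # states preserved
        assert state.grid.n_occupied == 5
        new_fp = state.layout.footprints[0]
        assert new_fp.n_binding_sites == 9           # same size
        assert state.schedule.next_disassembly[0] == pytest.approx(102.0)
        state.check_invariants()

    def test_full_run_with_turnover(self):
        cfg = SimulationConfig(lifetime=5.0, steps=200_000, record_every=20_000,
                               seed=11)
        res = run_simulation(cfg, check_invariants=True)
        assert res.n_turnovers > 0
        assert all(fp.n_binding_sites == 9
                   for fp in res.state.layout.footprints.values())


class TestRunSimulation:
    def test_no_binding_means_no_pyap(self):
        cfg = SimulationConfig(Rb=0.0, steps=100_000, record_every=10_000,
                               seed=5)
        res = run_simulation(cfg)
        assert (res.series.n_pyap_total == 0).all()

    def test_mass_conservation_and_exclusion(self, baseline):
        res = run_simulation(baseline, check_invariants=True)
        assert res.series.n_pyap_total.max() <= baseline.n_yap
        assert res.state.grid.n_occupied == baseline.n_yap

    def test_absorbing_phosphorylation_without_back_flux(self):
        cfg = SimulationConfig(Rdeph=0.0, Ru_pYAP=0.0, steps=300_000,
                               record_every=10_000, seed=2)
        res = run_simulation(cfg)
        assert (np.diff(res.series.n_pyap_total) >= 0).all()

    def test_determinism_same_seed(self, baseline):
        a = run_simulation(baseline)
        b = run_simulation(baseline)
        assert np.array_equal(a.series.n_pyap_total, b.series.n_pyap_total)
        assert np.array_equal(a.series.times, b.series.times)
        assert a.counters == b.counters

    def test_different_seed_differs(self, baseline):
        a = run_simulation(baseline)
        b = run_simulation(baseline, seed=baseline.seed + 1)
        assert not np.array_equal(a.series.n_pyap_total, b.series.n_pyap_total)


class TestRunReplicates:
    def test_three_replicates(self, baseline):
        rep = run_replicates(baseline, k=3)
        assert len(rep.results) == 3
        assert [r.seed for r in rep.results] == [7, 8, 9]
        assert rep.sd >= 0

    def test_single_replicate_warns(self, baseline):
        with pytest.warns(UserWarning):
            rep = run_replicates(baseline, k=1)
        assert rep.sd == 0.0


class TestTrace:
    def test_requires_single_molecule(self, baseline):
        with pytest.raises(ValueError):
            run_single_molecule_trace(baseline)

    def test_trace_is_monotone_and_decodable(self):
        cfg = SimulationConfig(nx=4, ny=4, nz=4, n_yap=1, n_adhesions=1,
                               adhesion_width=1, adhesion_height=1,
                               steps=5_000, record_every=1000, seed=9)
        times, codes = run_single_molecule_trace(cfg)
        assert (np.diff(times) >= 0).all()
        geom = cfg.geometry
        for c in codes[:100]:
            x, y, z, p, b = decode_trace_code(geom, int(c))
            assert 1 <= x <= 4 and 1 <= y <= 4 and 1 <= z <= 4
            assert b == (z == 1)
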