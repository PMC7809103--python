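"""Flow equations, seasonal switching and the Euler integrator."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pestdyn import (CANONICAL_ORDER, SystemState, build_scenario, simulate)
from pestdyn.dynamics import (SeasonTransitionError, active_parasitism_fraction,
                              apply_season_transition, carrying_capacity,
                              growth_flow, parasitism_flow, parasitoid_flows,
                              step)
from pestdyn.parameters import SeasonCalendar

DELAYED_CALENDAR = SeasonCalendar(pest_entry_delay=1.0)


def constant_k_overrides(**extra):
    """Parasitism-free, season-free configuration: pure logistic growth."""
    ov = {
        "calendar": {"capacity_wild": 62_500.0, "carryover_fraction": 1.0},
        "initial_pest_stocks": {"Cp": 156.25},
        "initial_parasitoid_stocks": {"Cp": 0.0},
    }
    ov.update(extra)
    return ov


class TestSeasonalForcing:
    def test_capacity_in_cropping_season(self):
        assert carrying_capacity(1.5, DELAYED_CALENDAR) == 62_500

    def test_capacity_in_non_cropping_season(self):
        assert carrying_capacity(4.0, DELAYED_CALENDAR) == 625

    def test_capacity_before_pest_entry(self):
        # with a 1-month field-entry delay the refuge capacity still applies
        # at the start of each cropping block
        assert carrying_capacity(0.25, DELAYED_CALENDAR) == 625
        assert carrying_capacity(6.5, DELAYED_CALENDAR) == 625

    def test_default_capacity_from_planting(self):
        assert carrying_capacity(0.25, SeasonCalendar()) == 62_500

    def test_second_year_repeats(self):
        cal = SeasonCalendar()
        for t in (0.5, 4.0, 7.0, 10.0):
            assert carrying_capacity(t, cal) == carrying_capacity(t + 12, cal)

    def test_parasitism_fraction_schedule(self):
        cfg = build_scenario({"Cp", "Bf"})
        assert active_parasitism_fraction(2.5, "Cp", cfg) == 0.3
        assert active_parasitism_fraction(1.0, "Cp", cfg) == 0.0
        assert active_parasitism_fraction(4.5, "Bf", cfg) == 0.05
        # onset boundary is inclusive; block end reverts to wild level
        assert active_parasitism_fraction(2.0, "Cp", cfg) == 0.3
        assert active_parasitism_fraction(3.0, "Cp", cfg) == 0.05


class TestFlows:
    def test_logistic_growth_hand_value(self):
        cfg = build_scenario({"Cp"}, constant_k_overrides())
        state = SystemState(1.5, [1000.0], [0.0])
        assert growth_flow(state, cfg) == pytest.approx([816.72], abs=1e-9)

    def test_growth_zero_at_capacity(self):
        cfg = build_scenario({"Cp"}, constant_k_overrides())
        state = SystemState(1.5, [62_500.0], [0.0])
        assert growth_flow(state, cfg) == pytest.approx([0.0], abs=1e-9)

    def test_equilibrium_states_are_growth_nullclines(self):
        # abundances solving K_i = N_i + sum a_ij N_j zero the growth flow
        # under the absolute-units competition convention
        from pestdyn.estimation import solve_equilibrium
        cfg = build_scenario({"Bf", "Cp"}, constant_k_overrides(
            competition_units="absolute"))
        cfg = dataclasses.replace(cfg, initial_parasitoid_stocks={
            "Bf": 0.0, "Cp": 0.0})
        K = np.full(2, 62_500.0)
        N = solve_equilibrium(cfg.matrix, K)
        G = growth_flow(SystemState(1.5, N, np.zeros(2)), cfg)
        assert np.max(np.abs(G)) / 62_500 < 1e-9

    def test_bilinear_parasitism_hand_value(self):
        cfg = build_scenario({"Cp"}, {"parasitism_model": "bilinear"})
        state = SystemState(2.5, [1000.0], [1000.0])
        assert parasitism_flow(state, cfg) == pytest.approx([0.168], abs=1e-12)

    def test_parasitism_zero_without_parasitoids(self):
        cfg = build_scenario({"Cp"})
        assert parasitism_flow(SystemState(2.5, [1000.0], [0.0]), cfg) == \
            pytest.approx([0.0])

    def test_parasitism_zero_inside_onset_window(self):
        cfg = build_scenario({"Cp"})
        assert parasitism_flow(SystemState(1.0, [1000.0], [1000.0]), cfg) == \
            pytest.approx([0.0])

    def test_saturating_parasitism_bounded_by_phi(self):
        cfg = build_scenario({"Cp"})
        L = parasitism_flow(SystemState(2.5, [1000.0], [1e9]), cfg)
        assert L[0] <= 0.3 * 1000.0 + 1e-9

    def test_parasitoid_flow_constants(self):
        cfg = build_scenario({"Cp"})
        state = SystemState(2.5, [1000.0], [100.0])
        R, D = parasitoid_flows(state, cfg, L=np.array([1.0]))
        assert R == pytest.approx([2.3])
        assert D == pytest.approx([70.0])

    def test_empty_system_has_no_flows(self):
        cfg = build_scenario({"Cp"})
        state = SystemState(2.5, [0.0], [0.0])
        R, D = parasitoid_flows(state, cfg)
        assert R == pytest.approx([0.0]) and D == pytest.approx([0.0])


class TestStep:
    def test_euler_logistic_step(self):
        cfg = build_scenario({"Cp"}, constant_k_overrides(
            initial_pest_stocks={"Cp": 1000.0}))
        state = SystemState(1.5, [1000.0], [0.0])
        new, flows, events = step(state, cfg)
        assert new.N == pytest.approx([1204.18], abs=1e-9)
        assert new.t == 1.75
        assert events == []

    def test_empty_state_absorbing(self):
        cfg = build_scenario({"Cp"})
        new, _, _ = step(SystemState(0.0, [0.0], [0.0]), cfg)
        assert new.N == pytest.approx([0.0]) and new.P == pytest.approx([0.0])

    def test_parasitoid_inflow_tracks_parasitism_loss(self, single_trajectories):
        traj = single_trajectories["Bf"]
        pp = traj.config.parasitoid
        conversion = pp.per_host_emergence * pp.sex_ratio  # 2.3 females/host
        assert np.array_equal(traj.R, conversion * traj.L)

    def test_flow_bookkeeping_exact(self, single_trajectories):
        # each stock change equals dt x net flow, except at logged events
        traj = single_trajectories["Sc"]
        dt = traj.config.dt
        event_times = {e["t"] for e in traj.events}
        for k in range(len(traj.times) - 1):
            if traj.times[k + 1] in event_times:
                continue
            assert np.array_equal(traj.N[k + 1],
                                  traj.N[k] + dt * (traj.G[k] - traj.L[k]))
            assert np.array_equal(traj.P[k + 1],
                                  traj.P[k] + dt * (traj.R[k] - traj.D[k]))


class TestSeasonTransition:
    def test_carryover_haircut(self):
        cfg = build_scenario({"Cp"})
        state = SystemState(3.0, [1000.0], [50.0])
        new = apply_season_transition(state, cfg)
        assert new.N == pytest.approx([100.0])
        assert new.P == pytest.approx([50.0])  # parasitoids keep their stock

    def test_identity_when_carryover_is_one(self):
        cfg = build_scenario({"Cp"}, {"calendar": {"carryover_fraction": 1.0}})
        new = apply_season_transition(SystemState(3.0, [1000.0], [0.0]), cfg)
        assert new.N == pytest.approx([1000.0])

    def test_double_application_rejected(self):
        cfg = build_scenario({"Cp"})
        once = apply_season_transition(SystemState(3.0, [1000.0], [0.0]), cfg)
        with pytest.raises(SeasonTransitionError):
            apply_season_transition(once, cfg)

    def test_off_boundary_rejected(self):
        cfg = build_scenario({"Cp"})
        with pytest.raises(SeasonTransitionError):
            apply_season_transition(SystemState(2.0, [1000.0], [0.0]), cfg)


class TestSimulate:
    def test_zero_initial_stocks_stay_flat(self):
        cfg = build_scenario({"Cp", "Sf"}, {
            "initial_pest_stocks": {"Cp": 0.0, "Sf": 0.0},
            "initial_parasitoid_stocks": {"Cp": 0.0, "Sf": 0.0}})
        traj = simulate(cfg)
        assert np.all(traj.N == 0.0) and np.all(traj.P == 0.0)

    def test_grid_and_labels(self, single_trajectories):
        traj = single_trajectories["Cp"]
        assert len(traj.times) == 97
        assert np.allclose(np.diff(traj.times), 0.25)
        assert traj.season_labels[0] == "cropping"
        assert traj.season_labels[traj.at_time(4.0)] == "non-cropping"

    def test_matches_closed_form_logistic_within_euler_error(self):
        cfg = build_scenario({"Cp"}, constant_k_overrides())
        traj = simulate(cfg)
        r, K, n0 = 0.83, 62_500.0, 156.25
        exact = K / (1 + (K - n0) / n0 * np.exp(-r * traj.times))
        err = np.max(np.abs(traj.N[:, 0] - exact) / exact)
        # forward Euler at r*dt ~ 0.21 lags the true exponential phase; the
        # bound here is the expected first-order discretization error
        assert err < 0.5
        assert traj.N[-1, 0] == pytest.approx(K, rel=1e-3)

    def test_convergence_monotone_as_dt_halves(self):
        errs = []
        for dt in (0.25, 0.125, 0.0625):
            cfg = build_scenario({"Cp"}, constant_k_overrides(dt=dt))
            traj = simulate(cfg)
            r, K, n0 = 0.83, 62_500.0, 156.25
            exact = K / (1 + (K - n0) / n0 * np.exp(-r * traj.times))
            errs.append(np.max(np.abs(traj.N[:, 0] - exact) / exact))
        assert errs[0] > errs[1] > errs[2]

    def test_decoupled_runs_match_single_species(self, single_trajectories):
        zero = {a: {b: 0.0 for b in CANONICAL_ORDER if b != a}
                for a in CANONICAL_ORDER}
        quad = simulate(build_scenario(set(CANONICAL_ORDER), {"matrix": zero}))
        for sid in CANONICAL_ORDER:
            j = quad.index_of(sid)
            assert np.array_equal(quad.N[:, j],
                                  single_trajectories[sid].N[:, 0])
            assert np.array_equal(quad.P[:, j],
                                  single_trajectories[sid].P[:, 0])

    def test_invalid_config_rejected(self):
        cfg = build_scenario({"Cp"})
        bad = dataclasses.replace(cfg, dt=-1.0)
        with pytest.raises(ValueError):
            simulate(bad)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        subset=st.sets(st.sampled_from(CANONICAL_ORDER), min_size=1,
                       max_size=4),
        n0=st.floats(0.0, 5000.0),
        p0=st.floats(0.0, 5000.0),
        model=st.sampled_from(["saturating", "bilinear"]),
    )
    def test_stocks_never_negative(self, subset, n0, p0, model):
        cfg = build_scenario(subset, {
            "horizon": 12.0,
            "parasitism_model": model,
            "initial_pest_stocks": {s: n0 for s in subset},
            "initial_parasitoid_stocks": {s: p0 for s in subset}})
        traj = simulate(cfg)
        assert np.all(traj.N >= 0.0) and np.all(traj.P >= 0.0)
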