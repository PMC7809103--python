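"""Dominance shares, peaks, ratios, cycle detection and phase portraits."""

import numpy as np
import pytest

from pestdyn import (build_aggregate_scenario, build_scenario,
                     cross_system_ratio, detect_cycles, dominance_shares,
                     mean_total_pests, peak_summary, phase_diagram, simulate)
from pestdyn.parameters import CompetitionMatrix, SpeciesParameters
from pestdyn.synth import generate_trajectory_fixture


def _twin_species_config():
    """Two species with identical biology and a symmetric matrix."""
    twin = [SpeciesParameters("a1", 0.8, 0.25, "twin 1"),
            SpeciesParameters("a2", 0.8, 0.25, "twin 2")]
    base = build_scenario({"Bf", "Cp"})
    import dataclasses
    return dataclasses.replace(
        base,
        species=tuple(twin),
        matrix=CompetitionMatrix(("a1", "a2"),
                                 np.array([[1.0, 2e-4], [2e-4, 1.0]])),
        initial_pest_stocks={"a1": 156.25, "a2": 156.25},
        initial_parasitoid_stocks={"a1": 15.625, "a2": 15.625})


class TestDominanceShares:
    def test_single_species_share_is_one(self, single_trajectories):
        rep = dominance_shares(single_trajectories["Cp"])
        assert rep.averaged["Cp"] == pytest.approx(1.0, abs=1e-12)
        assert rep.instantaneous["Cp"] == pytest.approx(1.0, abs=1e-12)

    def test_identical_twins_split_evenly(self):
        rep = dominance_shares(simulate(_twin_species_config()))
        assert rep.averaged["a1"] == pytest.approx(0.5, abs=1e-9)
        assert rep.instantaneous["a2"] == pytest.approx(0.5, abs=1e-9)

    def test_cp_dominates_bf_at_month_six(self, pair_trajectory_cp_bf):
        rep = dominance_shares(pair_trajectory_cp_bf)
        assert rep.instantaneous["Cp"] > rep.instantaneous["Bf"]

    def test_shares_sum_to_one(self, pair_trajectory_cp_bf):
        rep = dominance_shares(pair_trajectory_cp_bf)
        assert sum(rep.averaged.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(rep.instantaneous.values()) == pytest.approx(1.0, abs=1e-9)

    def test_invariant_under_uniform_rescaling(self, pair_trajectory_cp_bf):
        import dataclasses
        traj = pair_trajectory_cp_bf
        scaled = dataclasses.replace(traj, N=traj.N * 7.5)
        a = dominance_shares(traj).averaged
        b = dominance_shares(scaled).averaged
        assert a["Cp"] == pytest.approx(b["Cp"], abs=1e-12)

    def test_all_zero_window_rejected(self):
        flat = generate_trajectory_fixture("flat")
        with pytest.raises(ValueError):
            dominance_shares(flat)


class TestPeakSummary:
    def test_monotone_series_has_no_interior_maxima(self):
        traj = generate_trajectory_fixture("logistic")
        pk = peak_summary(traj).stocks["N_Cp"]
        assert pk.interior_maxima == ()
        assert pk.time_of_max == traj.times[-1]

    def test_single_bump(self):
        traj = generate_trajectory_fixture("flat", {"dt": 1.0, "horizon": 2.0})
        traj.N[:, 0] = [0.0, 1.0, 0.0]
        pk = peak_summary(traj).stocks["N_Cp"]
        assert pk.interior_maxima == ((1.0, 1.0),)

    def test_first_seasonal_peak_follows_six_month_crop_cycle(
            self, single_trajectories):
        # the first post-establishment pest peak forms late in the second
        # cropping season, between months 4 and 9
        cyc = detect_cycles(single_trajectories["Cp"], "Cp")
        assert 4.0 < cyc.pest_peaks[0][0] < 9.0

    def test_invariant_to_trailing_zeros_below_max(self, single_trajectories):
        import dataclasses
        traj = single_trajectories["Cp"]
        n_extra = 8
        dt = 0.25
        extra_times = traj.times[-1] + dt * np.arange(1, n_extra + 1)
        ext = dataclasses.replace(
            traj,
            times=np.concatenate([traj.times, extra_times]),
            N=np.vstack([traj.N, np.zeros((n_extra, 1))]),
            P=np.vstack([traj.P, np.zeros((n_extra, 1))]),
            G=np.vstack([traj.G, np.zeros((n_extra, 1))]),
            L=np.vstack([traj.L, np.zeros((n_extra, 1))]),
            R=np.vstack([traj.R, np.zeros((n_extra, 1))]),
            D=np.vstack([traj.D, np.zeros((n_extra, 1))]),
            season_labels=traj.season_labels + ["non-cropping"] * n_extra)
        a = peak_summary(traj).stocks["N_Cp"]
        b = peak_summary(ext).stocks["N_Cp"]
        assert a.max_value == b.max_value and a.time_of_max == b.time_of_max


class TestMeanAndRatios:
    def test_flat_zero_mean(self):
        assert mean_total_pests(generate_trajectory_fixture("flat")) == 0.0

    def test_constant_mean(self):
        traj = generate_trajectory_fixture("flat", {"value": 42.0})
        assert mean_total_pests(traj) == pytest.approx(42.0)

    def test_linear_ramp_mean_is_half(self):
        traj = generate_trajectory_fixture("flat", {"horizon": 10.0, "dt": 1.0})
        traj.N[:, 0] = np.linspace(0.0, 100.0, len(traj.times))
        assert mean_total_pests(traj) == pytest.approx(50.0)

    def test_ratio_identity(self, single_trajectories):
        a = [single_trajectories["Cp"]]
        assert cross_system_ratio(a, a) == pytest.approx(100.0)

    def test_ratio_antisymmetry(self, single_trajectories):
        a = [single_trajectories["Cp"], single_trajectories["Bf"]]
        b = [single_trajectories["Sc"], single_trajectories["Sf"]]
        prod = cross_system_ratio(a, b) * cross_system_ratio(b, a)
        assert prod == pytest.approx(10_000.0, rel=1e-6)

    def test_zero_numerator_and_denominator(self):
        flat = generate_trajectory_fixture("flat")
        live = generate_trajectory_fixture("flat", {"value": 10.0})
        assert cross_system_ratio([flat], [live]) == 0.0
        with pytest.raises(ValueError):
            cross_system_ratio([live], [flat])


class TestDetectCycles:
    def test_pure_logistic_has_no_parasitoid_peaks(self):
        cfg = build_scenario({"Cp"}, {
            "initial_parasitoid_stocks": {"Cp": 0.0}})
        cyc = detect_cycles(simulate(cfg), "Cp")
        assert cyc.parasitoid_peaks == ()

    def test_sine_pair_recovers_half_month_lag(self):
        traj = generate_trajectory_fixture(
            "sine_pair", {"lag": 0.5, "dt": 0.25, "period": 6.0})
        cyc = detect_cycles(traj, "Cp")
        assert len(cyc.lags) >= 2
        for _, lag in cyc.lags:
            assert lag == pytest.approx(0.5, abs=0.25)

    def test_parasitoid_tracks_host_in_default_run(self, single_trajectories):
        cyc = detect_cycles(single_trajectories["Bf"], "Bf")
        assert len(cyc.lags) >= 2
        assert all(lag > 0 for _, lag in cyc.lags)


class TestPhaseDiagram:
    def test_flat_orbit_closure_zero(self):
        portrait = phase_diagram(generate_trajectory_fixture("flat",
                                                             {"value": 5.0}))
        assert portrait.closure_gap == 0.0
        assert portrait.closure_gap_relative == 0.0
        assert len(portrait.host_total) == 97

    def test_synthetic_circle_closes(self):
        portrait = phase_diagram(generate_trajectory_fixture("circle"))
        assert portrait.closure_gap < 1e-9
        assert portrait.loop_diameter == pytest.approx(1000.0, rel=1e-6)

    def test_aggregate_run_orbit_closes(self):
        traj = simulate(build_aggregate_scenario())
        portrait = phase_diagram(traj)
        assert portrait.closure_gap_relative < 0.25
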