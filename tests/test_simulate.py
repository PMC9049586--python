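"""Integrator correctness: closed-form limits, conservation, continuity,
grid-refinement stability and the observable-extraction operations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pkclife import default_parameterization
from pkclife.assays import isolated_decay_rate
from pkclife.network import (
    MOIETY_COUNTS,
    Parameterization,
    SPECIES_NAMES,
    build_default_network,
    conserved_moiety_total,
)
from pkclife.protocols import Protocol, Pulse
from pkclife.simulate import (
    NotStabilizedError,
    drop_after_pulse,
    half_time,
    plateau_value,
    simulate,
    species_series,
    total_pkc_series,
)

IDX = {n: i for i, n in enumerate(SPECIES_NAMES)}


def _series(t, y):
    return pd.Series(y, index=pd.Index(t, name="time_min"))


class TestBasalState:
    def test_no_synthesis_pulse_stays_basal(self, network, params):
        traj = simulate(network, params, Protocol(t_end=120.0))
        tot = total_pkc_series(traj)
        assert np.all(np.abs(tot.to_numpy()) < 1e-9)

    def test_all_zero_state_is_stationary(self, network, params):
        traj = simulate(network, params, Protocol(t_end=60.0),
                        y0=np.zeros(12))
        assert np.all(np.abs(traj.states) < 1e-12)


class TestClosedFormDecay:
    def test_exponential_decay_and_half_life(self, network, params):
        """With only the naive-degradation reaction active the trajectory
        is P0*exp(-lam1*t); half-life ln2/0.001 ~ 693.1 s."""
        zero = {k: 0.0 for k in params.to_dict()}
        zero.update(lam1=params.lam1, mRNA0=0.0)
        p = Parameterization.from_dict(zero)
        y0 = np.zeros(12)
        y0[IDX["PKC"]] = 10.0
        traj = simulate(network, p, Protocol(t_end=40.0), y0=y0,
                        output_dt=0.25)
        got = species_series(traj, "PKC").to_numpy()
        want = 10.0 * np.exp(-p.lam1 * traj.times * 60.0)
        np.testing.assert_allclose(got, want, rtol=1e-6)
        t_half = half_time(_series(traj.times, 10.0 - got), 0.5,
                           plateau=10.0)
        assert t_half * 60.0 == pytest.approx(np.log(2) / 0.001, rel=1e-4)

    @pytest.mark.parametrize("which,expected", [
        ("naive", 0.001), ("mature", 1.3333333333e-6)])
    def test_log_linear_fit_recovers_rate(self, params, which, expected):
        fitted = isolated_decay_rate(params, which)
        assert fitted == pytest.approx(params.get(
            {"naive": "lam1", "mature": "lam4"}[which]), rel=1e-4)
        assert fitted == pytest.approx(expected, rel=1e-4)

    def test_fit_tracks_modified_rate(self, params):
        """The assay measures the simulation, not the input constant."""
        fitted = isolated_decay_rate(params.with_(lam1=0.002), "naive")
        assert fitted == pytest.approx(0.002, rel=1e-4)


class TestMoietyConservation:
    @pytest.mark.parametrize("variant", [False, True])
    def test_conserved_without_sources_and_sinks(self, rng, variant):
        """With synthesis and all degradation rates zeroed the
        moiety-weighted total is invariant along any trajectory."""
        net = build_default_network(variant=variant)
        base = default_parameterization().to_dict()
        base.update(k3=0.0, lam1=0.0, lam2=0.0, lam3=0.0, lam4=0.0,
                    lam5=0.0)
        p = Parameterization.from_dict(base)
        y0 = rng.uniform(0.0, 10.0, size=12)
        proto = Protocol(t_end=200.0,
                         activator_pulses=(Pulse(20.0, 30.0, 0.05),))
        traj = simulate(net, p, proto, y0=y0)
        totals = traj.states @ MOIETY_COUNTS
        assert np.max(np.abs(totals - totals[0])) / totals[0] < 1e-6


class TestNumericalBehaviour:
    def test_grid_refinement_stability(self, network, params):
        """Halving output_dt and tightening rtol tenfold leaves the
        total-PKC series unchanged to 1e-4 relative."""
        proto = Protocol(t_end=100.0,
                         synthesis_pulses=(Pulse(0.0, 10.0),),
                         activator_pulses=(Pulse(50.0, 15.0, 0.005),))
        a = simulate(network, params, proto, output_dt=0.5, rtol=1e-8)
        b = simulate(network, params, proto, output_dt=0.25, rtol=1e-9)
        ta = total_pkc_series(a)
        tb = total_pkc_series(b).loc[ta.index]
        scale = float(ta.max())
        assert np.max(np.abs(ta.to_numpy() - tb.to_numpy())) / scale < 1e-4

    def test_continuity_across_pulse_edges(self, fig5_result):
        """Concentrations are continuous at protocol discontinuities: the
        per-step change in total PKC is bounded by the largest observed
        rate of change times the grid spacing."""
        traj = fig5_result.trajectories["stimulated"]
        tot = total_pkc_series(traj).to_numpy()
        t = traj.times
        rates = np.abs(np.diff(tot) / np.diff(t))
        dt = np.diff(t)
        jumps = np.abs(np.diff(tot))
        assert np.all(jumps <= np.max(rates) * dt + 1e-9)

    def test_trajectory_nonnegative(self, fig2_result, fig5_result):
        for res in (fig2_result, fig5_result):
            for traj in res.trajectories.values():
                assert traj.states.min() > -1e-8

    def test_grid_includes_discontinuities(self, network, params):
        proto = Protocol(t_end=30.0, synthesis_pulses=(Pulse(0.0, 10.0),),
                         activator_pulses=(Pulse(12.3, 4.2, 0.01),))
        traj = simulate(network, params, proto)
        for edge in (10.0, 12.3, 16.5):
            assert np.any(np.isclose(traj.times, edge))

    def test_invalid_output_dt(self, network, params):
        with pytest.raises(ValueError):
            simulate(network, params, Protocol(t_end=10.0), output_dt=0.0)


class TestObservables:
    def test_plateau_of_constant_series(self):
        s = _series(np.arange(0, 50.0, 0.5), np.full(100, 73.0))
        assert plateau_value(s, (10, 40)) == 73.0

    def test_rising_series_not_stabilized(self):
        t = np.arange(0, 50.0, 0.5)
        with pytest.raises(NotStabilizedError):
            plateau_value(_series(t, 2.0 * t), (10, 40), slope_tol=1e-3)

    def test_window_outside_support(self):
        s = _series(np.arange(0, 10.0, 0.5), np.zeros(20))
        with pytest.raises(ValueError):
            plateau_value(s, (5, 15))

    def test_half_time_closed_form(self):
        tau = 12.0
        t = np.arange(0, 200.0, 0.05)
        s = _series(t, 80.0 * (1 - np.exp(-t / tau)))
        got = half_time(s, 0.5, plateau=80.0)
        assert got == pytest.approx(tau * np.log(2), rel=1e-4)

    def test_half_time_requires_crossing(self):
        t = np.arange(0, 10.0, 0.5)
        with pytest.raises(ValueError):
            half_time(_series(t, 100.0 - t), 0.5, plateau=100.0)
        with pytest.raises(ValueError):
            half_time(_series(t, np.full_like(t, 0.1)), 0.5, plateau=100.0)

    def test_drop_of_flat_series_is_zero(self):
        t = np.arange(0, 300.0, 0.5)
        s = _series(t, np.full_like(t, 50.0))
        assert drop_after_pulse(s, Pulse(100.0, 15.0, 0.1)) == 0.0

    def test_tidy_frame_layout(self, fig2_result):
        traj = fig2_result.trajectories["control"]
        frame = traj.to_frame()
        assert list(frame.columns) == ["time_min", "species", "concentration"]
        assert set(frame["species"]) == set(SPECIES_NAMES)
        assert len(frame) == len(traj.times) * 12
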