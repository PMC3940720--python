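"""Tests of the four-channel T-cell model and its integrator."""

import numpy as np
import pytest

from kv13tcell import (
    CaParams,
    CellParams,
    ChannelPopulation,
    DomainError,
    apply_block,
    ca_local_step,
    channel_currents,
    global_from_local,
    ik_open_probability,
    replay_voltage_command,
    simulate_current_clamp,
)


class TestChannelCurrents:
    def test_rest_currents_from_stated_conductances(self):
        # V=-55, closed Kv1.3, no Ca: only the ohmic TASK/CRAC terms
        cp, ca = CellParams(), CaParams()
        i_task, i_crac, i_kv, i_ik = channel_currents(-55.0, 0.0, 0.0, cp, ca)
        assert i_task == pytest.approx(0.13 * 45.0)    # 5.85 pA
        assert i_crac == pytest.approx(0.09 * -135.0)  # -12.15 pA
        assert i_kv == 0.0
        assert i_ik == 0.0

    def test_crac_reversal(self):
        i_crac = channel_currents(80.0, 0.0, 0.0, CellParams(), CaParams())[1]
        assert i_crac == 0.0

    def test_activated_tem_channel_count(self):
        cp = CellParams().with_kv_conductance(22.5)
        assert cp.kv_pop.n_channels == 1500
        assert cp.kv_pop.total_conductance_nS == pytest.approx(22.5)

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(DomainError):
            channel_currents(float("inf"), 0.0, 0.0, CellParams(), CaParams())


class TestIkOpenProbability:
    def test_hill_curve_anchors(self):
        ca = CaParams()
        assert ik_open_probability(0.0, ca) == 0.0
        assert ik_open_probability(ca.ik_k50_uM, ca) == pytest.approx(0.5)
        assert ik_open_probability(2 * ca.ik_k50_uM, ca) > ik_open_probability(ca.ik_k50_uM, ca)

    def test_negative_calcium_rejected(self):
        with pytest.raises(DomainError):
            ik_open_probability(-0.1, CaParams())


class TestCaDynamics:
    def test_no_influx_no_calcium(self):
        assert ca_local_step(0.0, 0.0, 1.0, CaParams()) == 0.0

    def test_fixed_point_of_constant_influx(self):
        # d[Ca]/dt = -e_trans*I - e_diff*[Ca]: fixed point (e_trans/e_diff)*|I|
        ca = CaParams()
        level = 0.0
        for _ in range(20):
            level = ca_local_step(level, -5.0, 10_000.0, ca)
        assert level == pytest.approx((ca.e_trans / ca.e_diff) * 5.0, rel=1e-9)

    def test_decay_time_constant(self):
        ca = CaParams()
        tau = 1.0 / ca.e_diff
        assert ca_local_step(10.0, 0.0, tau, ca) == pytest.approx(10.0 / np.e, rel=1e-12)

    def test_analytic_fixed_point_matches_stepwise_integration(self):
        """Clamped-V steady state agrees with fine integration to 0.1%."""
        cp, ca = CellParams(), CaParams()
        v = -40.0
        i_crac = cp.g_crac_nS * (v - cp.e_crac_mV)
        level = 0.0
        for _ in range(200_000):  # 10 s at dt = 0.05 ms
            level = ca_local_step(level, i_crac, 0.05, ca)
        assert level == pytest.approx((ca.e_trans / ca.e_diff) * abs(i_crac), rel=1e-3)

    def test_global_is_proportional_to_local(self):
        ca = CaParams()
        assert global_from_local(0.0, ca) == 0.0
        assert global_from_local(4.0, ca) == pytest.approx(2 * global_from_local(2.0, ca))


@pytest.fixture(scope="module")
def cell_v_readouts():
    """V and Ca at 10 s across the five Kv1.3 expression levels."""
    cp = CellParams(i_inj_pA=15.0)
    ca = CaParams.calibrated()
    out = {}
    for g in (0.4, 2.0, 4.5, 9.0, 22.5):
        traj = simulate_current_clamp(cp.with_kv_conductance(g), ca, 10_000.0, 0.1)
        out[g] = traj.at_time(10_000.0)
    return out


class TestCurrentClamp:
    def test_isolated_cell_holds_rest_potential(self):
        cp = CellParams(g_task_nS=0.0, g_crac_nS=0.0, g_ik_nS=0.0,
                        kv_pop=ChannelPopulation(0), i_inj_pA=0.0)
        traj = simulate_current_clamp(cp, CaParams(), 100.0, 0.05)
        assert np.max(np.abs(traj.v_mV - cp.v_rest_mV)) == 0.0

    def test_occupancy_and_calcium_stay_physical(self):
        cp = CellParams(i_inj_pA=15.0).with_kv_conductance(4.5)
        traj = simulate_current_clamp(cp, CaParams.calibrated(), 2000.0, 0.1)
        assert np.max(np.abs(traj.kv_occupancy.sum(axis=1) - 1.0)) < 1e-9
        assert np.all(traj.ca_local_uM >= 0.0)
        assert np.all(np.isfinite(traj.v_mV))

    def test_more_kv13_means_lower_voltage_and_more_calcium(self, cell_v_readouts):
        gs = sorted(cell_v_readouts)
        vs = [cell_v_readouts[g]["v_mV"] for g in gs]
        cas = [cell_v_readouts[g]["ca_local_uM"] for g in gs]
        assert all(a > b for a, b in zip(vs, vs[1:]))
        assert all(a < b for a, b in zip(cas, cas[1:]))

    def test_dt_convergence(self):
        cp = CellParams(i_inj_pA=15.0).with_kv_conductance(4.5)
        ca = CaParams.calibrated()
        v = {}
        for dt in (0.2, 0.1):
            v[dt] = simulate_current_clamp(cp, ca, 10_000.0, dt).at_time(10_000.0)["v_mV"]
        assert abs(v[0.2] - v[0.1]) < 0.05

    def test_invalid_arguments_rejected(self):
        with pytest.raises(DomainError):
            simulate_current_clamp(CellParams(), CaParams(), -1.0, 0.05)
        with pytest.raises(DomainError):
            simulate_current_clamp(CellParams(), CaParams(), 100.0, 0.0)


class TestReplay:
    def test_constant_command_at_reversal_gives_zero_current(self, model):
        t = np.arange(0.0, 50.0, 0.5)
        v = np.full_like(t, -73.0)
        tr = replay_voltage_command(t, v, ChannelPopulation(330), model)
        assert np.max(np.abs(tr.i_pA)) < 1e-9

    def test_slow_ramp_produces_hump(self, model):
        # depolarizing ramp: current turns on near -40 mV, peaks, declines
        t = np.arange(0.0, 4000.0, 1.0)
        v = -55.0 + (50.0 - -55.0) * t / t[-1]
        tr = replay_voltage_command(t, v, ChannelPopulation(330), model)
        i_peak = int(np.argmax(tr.i_pA))
        assert 0 < i_peak < t.size - 1
        assert -40.0 < v[i_peak] < 50.0
        assert tr.i_pA[-1] < 0.8 * tr.i_pA[i_peak]
        onset = v[tr.i_pA > 0.05 * tr.i_pA[i_peak]][0]
        assert -50.0 < onset < -25.0

    def test_replayed_current_linear_in_channel_count(self, model):
        t = np.arange(0.0, 200.0, 0.5)
        v = -55.0 + 0.5 * t
        a = replay_voltage_command(t, v, ChannelPopulation(330), model)
        b = replay_voltage_command(t, v, ChannelPopulation(165), model)
        assert np.allclose(a.i_pA, 2.0 * b.i_pA, atol=1e-12)

    def test_malformed_command_rejected(self, model):
        with pytest.raises(DomainError):
            replay_voltage_command([0.0, 1.0], [0.0], ChannelPopulation(10), model)
        with pytest.raises(DomainError):
            replay_voltage_command([0.0, 0.0], [0.0, 1.0], ChannelPopulation(10), model)


class TestBlock:
    def test_zero_fraction_is_identity(self):
        cp = CellParams()
        assert apply_block(cp, 0.0).kv_pop.n_channels == cp.kv_pop.n_channels

    def test_full_block_silences_kv13(self):
        cp = apply_block(CellParams(), 1.0)
        assert cp.kv_pop.n_channels == 0
        assert channel_currents(50.0, 1.0, 0.0, cp, CaParams())[2] == 0.0

    def test_published_block_levels(self):
        # control 4.5 nS (N=300) reduced to 2.0 nS is N~133
        cp = CellParams().with_kv_conductance(4.5)
        blocked = apply_block(cp, 1.0 - 2.0 / 4.5)
        assert blocked.kv_pop.n_channels == 133

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(DomainError):
            apply_block(CellParams(), 1.5)
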