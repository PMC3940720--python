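"""Unit and property tests of the sequential Kv1.3 gating model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kv13tcell import (
    DomainError,
    KineticScheme,
    Kv13Model,
    RateConstants,
    RateSet,
    SignConvention,
    activation_protocol,
    build_generator,
    evolve,
    fit_boltzmann,
    open_probability_trace,
    steady_state,
    voltage_rates,
)
from kv13tcell.errors import ConfigurationError
from kv13tcell.protocols import Segment, VoltageProtocol

from conftest import euler_propagate


class TestVoltageRates:
    def test_zero_voltage_returns_prefactors(self):
        r = voltage_rates(RateConstants(), 0.0)
        assert (r.alpha, r.beta, r.eta, r.phi) == (0.448, 0.043, 0.003, 0.00008)
        assert (r.A, r.B) == (280.035, 1.648)

    def test_one_voltage_scale_gives_factor_e(self):
        # V = m exactly: alpha = a * e^1
        r = voltage_rates(RateConstants(), 27.530)
        assert r.alpha == pytest.approx(0.448 * math.e, rel=1e-12)

    def test_recovery_rate_at_hyperpolarized_holding(self):
        # phi at -90 mV sets the ~10-s recovery scale; check both sign variants
        p = RateConstants()
        r_plus = voltage_rates(p, -90.0, SignConvention(phi=+1))
        r_minus = voltage_rates(p, -90.0, SignConvention(phi=-1))
        assert r_plus.phi == pytest.approx(0.00008 * math.exp(-90.0 / 1016.330), rel=1e-12)
        assert r_minus.phi == pytest.approx(0.00008 * math.exp(90.0 / 1016.330), rel=1e-12)

    def test_non_finite_voltage_rejected(self):
        with pytest.raises(DomainError):
            voltage_rates(RateConstants(), float("nan"))

    def test_rate_constants_must_be_positive(self):
        with pytest.raises(DomainError):
            RateConstants(a=-1.0)


class TestSchemeAndGenerator:
    def test_rows_sum_to_zero(self, model):
        for v in (-90.0, 0.0, 50.0):
            Q = model.generator(v)
            assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
            off = Q - np.diag(Q.diagonal())
            assert np.all(off >= 0)

    def test_multiplicity_scales_edge_rate(self):
        scheme = KineticScheme.linear(4, closed_fwd_mults=(4, 1, 1))
        rates = voltage_rates(RateConstants(), 0.0)
        Q = build_generator(scheme, rates)
        assert Q[0, 1] == pytest.approx(4 * rates.alpha)

    def test_minimal_chain_is_valid(self):
        scheme = KineticScheme.linear(1)  # C - O - I
        Q = build_generator(scheme, voltage_rates(RateConstants(), 0.0))
        assert Q.shape == (3, 3)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_invalid_topologies_rejected(self):
        with pytest.raises(ConfigurationError):
            KineticScheme.linear(0)
        with pytest.raises(ConfigurationError):
            KineticScheme.linear(3, closed_bwd_mults=(1, 2, 3))  # wrong count
        from kv13tcell.markov import Edge

        edges = KineticScheme.linear(2).edges
        with pytest.raises(ConfigurationError):  # drop one reverse edge
            KineticScheme(2, tuple(e for e in edges if not (e.source == 1 and e.target == 0)))


class TestEvolve:
    def test_zero_time_is_identity(self, model):
        p0 = model.steady_state(-90.0)
        assert np.allclose(evolve(model.generator(-90.0), p0, 0.0), p0)

    def test_negative_time_rejected(self, model):
        with pytest.raises(DomainError):
            evolve(model.generator(0.0), model.steady_state(0.0), -1.0)

    @pytest.mark.parametrize("v", [-90.0, -45.0, 0.0, 50.0])
    def test_matches_fine_euler_oracle(self, model, v):
        """Matrix exponential vs dt=1e-3 ms explicit Euler on 100-ms segments."""
        Q = model.generator(v)
        p0 = np.zeros(model.scheme.n_states)
        p0[0] = 1.0
        p_expm = evolve(Q, p0, 100.0)
        p_euler = euler_propagate(Q, p0, 100.0)
        assert np.max(np.abs(p_expm - p_euler)) < 1e-6

    def test_semigroup_property(self, model):
        Q = model.generator(50.0)
        p0 = model.steady_state(-90.0)
        p_once = evolve(Q, p0, 200.0)
        p_twice = evolve(Q, evolve(Q, p0, 100.0), 100.0)
        assert np.max(np.abs(p_once - p_twice)) < 1e-9

    def test_long_depolarization_ends_mostly_inactivated(self, model):
        # 1 s at +50 mV from rest: little open occupancy left, I dominates
        p0 = np.zeros(model.scheme.n_states)
        p0[0] = 1.0
        p = evolve(model.generator(50.0), p0, 1000.0)
        assert p[model.scheme.inactivated_index] > 0.5
        assert p[model.scheme.inactivated_index] > p[model.scheme.open_index]


class TestSteadyState:
    def test_nullvector_property(self, model):
        for v in (-90.0, -45.0, 10.0):
            pi = model.steady_state(v)
            assert np.max(np.abs(pi @ model.generator(v))) < 1e-12
            assert pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_long_time_evolution(self, model):
        for v in (-60.0, 0.0):
            Q = model.generator(v)
            p0 = np.zeros(model.scheme.n_states)
            p0[0] = 1.0
            assert np.max(np.abs(steady_state(Q) - evolve(Q, p0, 1e7))) < 1e-6

    def test_detailed_balance_on_linear_chain(self, model):
        # net flux across every edge vanishes at stationarity
        v = -40.0
        pi = model.steady_state(v)
        Q = model.generator(v)
        for i in range(model.scheme.n_states - 1):
            flux = pi[i] * Q[i, i + 1] - pi[i + 1] * Q[i + 1, i]
            assert abs(flux) < 1e-12

    def test_hyperpolarized_rest_is_closed(self, model):
        pi = model.steady_state(-120.0)
        assert pi[: model.scheme.n_closed].sum() > 0.999
        assert pi[model.scheme.open_index] < 1e-4


class TestOpenProbabilityTrace:
    def test_flat_at_holding(self, model):
        proto = VoltageProtocol(holding_mV=-90.0, segments=(Segment(100.0, -90.0),))
        tr = model.trace(proto, 0.1)
        assert np.max(np.abs(tr.po - tr.po[0])) < 1e-12
        assert tr.po.max() < 1e-3

    def test_step_shows_fast_rise_slow_decay(self, model):
        proto = VoltageProtocol(holding_mV=-90.0, segments=(Segment(1000.0, 50.0),))
        tr = model.trace(proto, 0.05)
        i_peak = int(np.argmax(tr.po))
        assert tr.t_ms[i_peak] < 20.0  # ms-scale activation
        assert tr.po[i_peak] > 0.9
        # slow C-type decline afterwards: still >25% left at 200 ms
        assert 0.25 < tr.po[np.searchsorted(tr.t_ms, 200.0)] < tr.po[i_peak]

    def test_probability_conserved_along_protocol(self, model):
        proto = VoltageProtocol(
            holding_mV=-90.0,
            segments=(Segment(7.0, 50.0), Segment(30.0, -100.0), Segment(500.0, -45.0)),
        )
        tr = model.trace(proto, 0.05)
        assert np.max(np.abs(tr.occupancy.sum(axis=1) - 1.0)) < 1e-9
        assert tr.occupancy.min() >= 0.0

    def test_halving_dt_only_refines_sampling(self, model):
        proto = VoltageProtocol(holding_mV=-90.0, segments=(Segment(100.0, 0.0),))
        coarse = model.trace(proto, 0.2)
        fine = model.trace(proto, 0.1)
        assert np.allclose(fine.t_ms[::2], coarse.t_ms, atol=1e-12)
        assert np.max(np.abs(fine.po[::2] - coarse.po)) < 1e-6

    def test_peak_open_probability_monotone_in_step_voltage(self, model):
        peaks = [model.trace(p, 0.2).po.max() for p in activation_protocol()]
        assert all(b >= a - 1e-12 for a, b in zip(peaks, peaks[1:]))

    def test_empty_protocol_rejected(self, model):
        with pytest.raises(DomainError):
            VoltageProtocol(holding_mV=-90.0, segments=())

    def test_pure_activation_chain_is_boltzmann_like(self):
        """With eta = phi = 0 the steady-state P_o is sigmoidal in V."""
        scheme = KineticScheme.default()
        params = RateConstants()
        vs = np.arange(-70.0, 50.1, 10.0)
        pos = []
        for v in vs:
            r = voltage_rates(params, v)
            r0 = RateSet(alpha=r.alpha, beta=r.beta, eta=0.0, phi=0.0, A=r.A, B=r.B)
            # with eta=phi=0 the I state is unreachable; restrict to the live block
            Q = build_generator(scheme, r0)[:-1, :-1]
            pos.append(steady_state(Q)[scheme.open_index])
        fit = fit_boltzmann(vs, np.asarray(pos), "activation")
        assert math.isfinite(fit.v50_mV)
        assert -70.0 < fit.v50_mV < 50.0
        assert all(b >= a - 1e-12 for a, b in zip(pos, pos[1:]))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    v=st.floats(min_value=-120.0, max_value=60.0),
    t=st.floats(min_value=0.0, max_value=5000.0),
)
def test_probability_conservation_property(v, t):
    """Occupancy stays a distribution under any (V, t) propagation."""
    model = Kv13Model()
    p = evolve(model.generator(v), model.steady_state(-90.0), t)
    assert abs(p.sum() - 1.0) < 1e-9
    assert np.all(p >= 0.0) and np.all(p <= 1.0 + 1e-12)
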