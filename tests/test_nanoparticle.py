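"""NP adhesion law and conservative network advection-deposition."""

import numpy as np
import pytest
import sympy

from nanovasc.fixtures import make_toy_network
from nanovasc.nanoparticle import (NPFormulation, NPTransportSystem,
                                   adhesion_fraction, adhesion_fractions,
                                   advect_deposit_step, run_injection)
from nanovasc.vasculature import NEOVESSEL, PREEXISTING, solve_flow

VISC = 3e-3


def perfused(kind, p_in=1.0, p_out=0.0):
    net = make_toy_network(kind)
    return solve_flow(net, p_in, p_out, VISC)


class TestAdhesionFraction:
    def test_zero_affinity_gives_zero(self):
        f = NPFormulation(alpha_neo=0.0)
        assert adhesion_fraction(f, 1e-9, 100.0) == 0.0

    def test_extreme_shear_kills_adhesion(self):
        f = NPFormulation(alpha_neo=1e12)
        assert adhesion_fraction(f, 1e-9, 1e9) < 1e-12

    def test_matches_high_precision_formula(self):
        """Oracle: arbitrary-precision sympy evaluation of the adhesion law."""
        f = NPFormulation(diameter_m=1e-7, alpha_neo=1e12, beta=1e-4,
                          gamma=1e4, delta1=0.45, delta2=1.57, n0=1.0)
        S_u, srt = 3.7e-10, 412.0
        d, a, b, g, d1, d2 = [sympy.Float(x, 50) for x in
                              (1e-7, 1e12, 1e-4, 1e4, 0.45, 1.57)]
        expected = sympy.Float(S_u, 50) * a * d**d1 * sympy.exp(
            -b * (1 + g * d**d2) * sympy.Float(srt, 50))
        got = adhesion_fraction(f, S_u, srt)
        assert got == pytest.approx(float(expected), rel=1e-12)

    def test_clamped_to_unit_interval(self):
        f = NPFormulation(alpha_neo=1e20)
        assert adhesion_fraction(f, 1e-9, 0.0) == 1.0

    def test_preexisting_affinity_100x_smaller(self):
        f = NPFormulation(alpha_neo=1e10)
        hi = adhesion_fraction(f, 1e-10, 100.0, origin=NEOVESSEL)
        lo = adhesion_fraction(f, 1e-10, 100.0, origin=PREEXISTING)
        assert hi == pytest.approx(100.0 * lo, rel=1e-12)

    def test_activated_segments_use_neo_affinity(self):
        net = perfused("single_segment")
        f = NPFormulation(alpha_neo=1e10)
        base, _ = adhesion_fractions(net, f)
        act, _ = adhesion_fractions(net, f, activated=np.array([True]))
        assert act[0] == pytest.approx(100.0 * base[0], rel=1e-12)


class TestAdvectDeposit:
    def test_zero_adhesion_pure_advection_reaches_inlet_value(self):
        net = perfused("y_branch")
        f = NPFormulation(alpha_neo=0.0)
        system = NPTransportSystem(net, f, dt_s=5.0)  # >> segment transit time
        state = system.fresh_state()
        for _ in range(500):
            system.step(state, 1.0)
        perfused_nodes = ~system.dirichlet
        assert np.allclose(state.C_p[perfused_nodes], 1.0, atol=1e-6)
        assert np.all(state.C_pS == 0)

    def test_full_capture_on_first_segment_starves_downstream(self):
        net = perfused("y_branch")
        f = NPFormulation(alpha_neo=1e30)  # clamps trunk capture to 1
        system = NPTransportSystem(net, f, dt_s=0.05)
        assert system.N_seg[0] == 1.0
        state = system.fresh_state()
        for _ in range(100):
            system.step(state, 1.0)
        assert state.C_pS[0] > 0
        assert np.allclose(state.C_pS[1:], 0.0)
        assert state.C_p[2] == pytest.approx(0.0, abs=1e-12)

    def test_two_segment_chain_steady_deposition_rates(self):
        """Hand recurrence: with capture f per segment and inlet c0, the
        steady deposition rates are Q c0 f and Q c0 (1-f) f."""
        net = make_toy_network("single_segment")
        c = net.add_node(0.2, 0.0)
        net.is_outlet[1] = False
        net.is_outlet = [False, False, True]
        net.add_segment(1, c, 10e-6, 1e-4, PREEXISTING)
        solve_flow(net, 1.0, 0.0, VISC)
        f_np = NPFormulation(alpha_neo=5e9)
        system = NPTransportSystem(net, f_np, dt_s=0.02)
        f1, f2 = system.N_seg
        assert f1 == pytest.approx(f2, rel=1e-9)  # identical segments
        assert 0 < f1 < 1
        state = system.fresh_state()
        for _ in range(400):
            system.step(state, 1.0)
        before = state.C_pS.copy()
        system.step(state, 1.0)
        rate = (state.C_pS - before) / system.dt * system.seg_area
        Q = abs(net.seg_flow[0])
        assert rate[0] == pytest.approx(Q * f1, rel=1e-6)
        assert rate[1] == pytest.approx(Q * (1 - f1) * f1, rel=1e-6)

    def test_global_balance_every_step(self):
        net = perfused("ladder", p_in=2.0, p_out=0.0)
        f = NPFormulation(alpha_neo=3e10)
        system = NPTransportSystem(net, f, dt_s=0.05)
        state = system.fresh_state()
        for k in range(50):
            free0 = state.free_total(system.node_volume)
            bound0 = state.bound_counts(net).sum()
            in0, out0 = state.influx_total, state.outflux_total
            system.step(state, 1.0 if k < 30 else 0.0)
            dfree = state.free_total(system.node_volume) - free0
            dbound = state.bound_counts(net).sum() - bound0
            dflux = (state.influx_total - in0) - (state.outflux_total - out0)
            assert dfree + dbound == pytest.approx(dflux, rel=1e-6, abs=1e-30)

    def test_higher_shear_means_less_binding(self):
        """Scaling all flows up (higher shear) reduces total bound NPs."""
        totals = []
        for p_in in (1.0, 10.0):
            net = perfused("ladder", p_in=p_in)
            f = NPFormulation(alpha_neo=1e10, beta=1e-2)
            state = run_injection(net, f, duration_s=50.0, dt_s=0.5)
            # compare bound per unit supplied concentration-volume
            totals.append(state.bound_counts(net).sum() / state.influx_total)
        assert totals[1] < totals[0]


class TestRunInjection:
    def test_zero_duration_leaves_nothing(self):
        net = perfused("y_branch")
        state = run_injection(net, NPFormulation(), duration_s=0.0)
        assert np.all(state.C_pS == 0) and np.all(state.C_p == 0)

    def test_washout_empties_free_compartment(self):
        net = perfused("ladder")
        f = NPFormulation(alpha_neo=1e9)
        state = run_injection(net, f, duration_s=60.0, dt_s=1.0)
        system = NPTransportSystem(net, f, 1.0)
        assert state.free_total(system.node_volume) < 1e-5 * state.influx_total

    def test_doubling_affinity_doubles_binding_in_linear_regime(self):
        net = perfused("ladder")
        totals = []
        for alpha in (1e8, 2e8):
            state = run_injection(net, NPFormulation(alpha_neo=alpha),
                                  duration_s=60.0, dt_s=1.0)
            totals.append(state.bound_counts(net).sum())
        assert totals[1] == pytest.approx(2.0 * totals[0], rel=0.05)

    def test_bound_nonnegative_and_finite(self):
        net = perfused("grid3x3" if True else "ladder")
        solve_flow(net, 500.0, 0.0, VISC)
        state = run_injection(net, NPFormulation(alpha_neo=1e12),
                              duration_s=120.0, dt_s=2.0)
        M = state.bound_counts(net)
        assert np.all(M >= 0) and np.all(np.isfinite(M))
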