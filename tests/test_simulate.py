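"""Gating kinetics and voltage-clamp integration against closed forms."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import rc_impedance
from mprfit.params import FixedConstants, ModelParams
from mprfit.simulate import gate_steady_state, simulate_clamp, sine_probe, tau_mH_of_V
from mprfit.stimulus import ZapConfig, zap_derivative, zap_voltage


class TestGateSteadyState:
    @pytest.mark.parametrize(
        "V,V_half,k,expected",
        [
            (-51.0, -51.0, -8.0, 0.5),
            (-43.0, -51.0, -8.0, 1.0 / (1.0 + np.exp(-1.0))),
            (-61.0, -67.0, 6.0, 1.0 / (1.0 + np.e)),
        ],
    )
    def test_closed_form(self, V, V_half, k, expected):
        assert gate_steady_state(V, V_half, k) == pytest.approx(expected, rel=1e-12)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            gate_steady_state(-50.0, -51.0, 0.0)

    @given(
        v=st.floats(-95, -5),
        dv=st.floats(0.1, 30),
        v_half=st.floats(-80, -40),
        k=st.floats(4, 15),
    )
    def test_bounded_and_monotone(self, v, dv, v_half, k):
        lo, hi = gate_steady_state(v, v_half, -k), gate_steady_state(v + dv, v_half, -k)
        assert 0.0 < lo < hi < 1.0  # negative slope: opens with depolarization
        lo2, hi2 = gate_steady_state(v, v_half, k), gate_steady_state(v + dv, v_half, k)
        assert 0.0 < hi2 < lo2 < 1.0  # positive slope: closes with depolarization


class TestTauMH:
    @pytest.mark.parametrize(
        "V,tau_max,expected",
        [
            (-110.0, 2179.0, 1089.5),
            (-123.0, 1000.0, 1000.0 / (1.0 + np.e)),
            (-45.0, 1000.0, 1000.0 / (1.0 + np.exp(-5.0))),
        ],
    )
    def test_closed_form(self, V, tau_max, expected):
        assert tau_mH_of_V(V, tau_max) == pytest.approx(expected, rel=1e-12)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            tau_mH_of_V(-60.0, -5.0)


class TestPassiveOracle:
    def test_sine_probe_matches_rc_amplitude(self, passive_params, consts):
        f = 0.1
        tr = sine_probe(passive_params, consts, f=f, n_cycles=3)
        sl = tr.steady
        Z = (tr.V[sl].max() - tr.V[sl].min()) / (tr.I_total[sl].max() - tr.I_total[sl].min())
        Z_ref, _ = rc_impedance(f, passive_params.g_L, consts.C_m)
        assert Z == pytest.approx(Z_ref, rel=0.01)

    def test_current_decomposition_sums(self, median_params, consts):
        tr = sine_probe(median_params, consts, f=1.0, n_cycles=2)
        total = tr.I_Cm + tr.I_L + tr.I_Ca + tr.I_H
        np.testing.assert_allclose(tr.I_total, total, rtol=0, atol=1e-12)

    def test_equilibrium_at_constant_command(self, median_params, consts):
        V0 = -45.0
        t = np.arange(0, 30_000.0, 0.2)  # 30 s >> all time constants
        tr = simulate_clamp(median_params, consts, t, np.full_like(t, V0))
        p, c = median_params, consts
        m = gate_steady_state(V0, c.V_half_mH, c.k_mH)
        mca = gate_steady_state(V0, p.V_half_mCa, c.k_mCa)
        hca = gate_steady_state(V0, p.V_half_hCa, c.k_hCa)
        expected = (
            p.g_L * (V0 - c.E_L)
            + p.g_Ca * mca**3 * hca * (V0 - c.E_Ca)
            + p.g_H * m * (V0 - c.E_H)
        )
        assert tr.I_total[-1] == pytest.approx(expected, rel=1e-9)


class TestIntegration:
    def test_step_refinement_converges(self, median_params, consts):
        """Halving dt changes the current by far less than its range."""
        ref = sine_probe(median_params, consts, f=1.0, n_cycles=3, dt=0.02)
        coarse = sine_probe(median_params, consts, f=1.0, n_cycles=3, dt=0.2)
        ref_sub = ref.I_total[::10]
        n = min(ref_sub.size, coarse.I_total.size)
        err = np.abs(coarse.I_total[:n] - ref_sub[:n]).max()
        assert err < 0.005 * np.ptp(ref.I_total)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_gates_stay_in_unit_interval(self, consts, seed):
        rng = np.random.default_rng(seed)
        from mprfit.params import DEFAULT_BOUNDS

        x = rng.uniform(DEFAULT_BOUNDS.low, DEFAULT_BOUNDS.high)
        params = ModelParams.from_array(x)
        # smooth random command within a generous clamp range
        t = np.arange(0, 5000.0, 0.2)
        knots = rng.uniform(-90, -10, size=12)
        V = np.interp(t, np.linspace(0, t[-1], 12), knots)
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                tr = simulate_clamp(params, consts, t, V)
        for g in (tr.m_H, tr.m_Ca, tr.h_Ca):
            assert (g >= 0.0).all() and (g <= 1.0).all()

    def test_nonuniform_grid_rejected(self, passive_params, consts):
        t = np.array([0.0, 0.2, 0.5, 0.7])
        with pytest.raises(ValueError):
            simulate_clamp(passive_params, consts, t, np.full(4, -45.0))

    def test_large_step_warns(self, consts):
        fast = ModelParams(
            g_L=0.1, g_H=0.0, g_Ca=0.1, tau_mH_max=1000.0,
            V_half_mCa=-51.0, tau_mCa=0.05, V_half_hCa=-67.0, tau_hCa=458.0,
        )
        t = np.arange(0, 100.0, 0.2)
        with pytest.warns(RuntimeWarning):
            simulate_clamp(fast, consts, t, -45.0 + 5 * np.sin(t / 20))


class TestSineProbe:
    def test_capacitive_current_leads_by_quarter_cycle(self, passive_params, consts):
        f = 1.0
        tr = sine_probe(passive_params, consts, f=f, n_cycles=3)
        sl = tr.steady
        phase = (tr.t[sl] - tr.t[sl][0]) * f / 1000.0
        assert phase[np.argmax(tr.V[sl])] == pytest.approx(0.5, abs=0.01)
        assert phase[np.argmax(tr.I_Cm[sl])] == pytest.approx(0.25, abs=0.01)

    @pytest.mark.parametrize("f", [0.1, 1.0, 4.0])
    def test_leak_peaks_at_voltage_peak_any_frequency(self, median_params, consts, f):
        tr = sine_probe(median_params, consts, f=f, n_cycles=3)
        sl = tr.steady
        phase = (tr.t[sl] - tr.t[sl][0]) * f / 1000.0
        assert phase[np.argmax(tr.I_L[sl])] == pytest.approx(0.5, abs=0.01)

    def test_invalid_probe_rejected(self, passive_params, consts):
        with pytest.raises(ValueError):
            sine_probe(passive_params, consts, f=0.0)
        with pytest.raises(ValueError):
            sine_probe(passive_params, consts, f=1.0, n_cycles=1)


class TestLinearLimit:
    def test_zap_impedance_matches_rc_closed_form(self, passive_params, consts):
        """Passive-model |Z| and phase track the analytic RC values to <1%
        across the whole 0.1-4 Hz sweep."""
        from mprfit.impedance import build_profile

        cfg = ZapConfig(dt=0.2)
        t, V = zap_voltage(cfg)
        _, dVdt = zap_derivative(cfg)
        tr = simulate_clamp(passive_params, consts, t, V, dVdt=dVdt)
        prof = build_profile(tr, config=cfg)
        band = prof.f <= 4.0
        Z_ref, phi_ref = rc_impedance(prof.f[band], passive_params.g_L, consts.C_m)
        np.testing.assert_allclose(prof.Z[band], Z_ref, rtol=0.01)
        # phase error relative to the quarter-cycle scale
        assert np.abs(prof.phi[band] - phi_ref).max() < 0.01 * (np.pi / 2)
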