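"""Cycle segmentation, per-cycle impedance, attribute extraction, objectives."""

import numpy as np
import pytest

from conftest import rc_impedance
from mprfit.impedance import (
    AttributeSet,
    ImpedanceProfile,
    attribute_errors,
    build_profile,
    cycle_impedance,
    extract_attributes,
    is_acceptable,
    objective_vector,
    reference_target,
    segment_cycles,
)
from mprfit.simulate import simulate_clamp, sine_probe
from mprfit.stimulus import ZapConfig, zap_derivative, zap_voltage


def _trace_like(t, V):
    class T:
        pass

    tr = T()
    tr.t, tr.V = t, V
    return tr


class TestSegmentation:
    def test_pure_sine_gives_exact_periods(self):
        f, dt = 1.0, 0.2
        t = np.arange(0, 7000.0, dt)
        V = -45.0 + 15.0 * np.sin(2 * np.pi * f * t / 1000.0)
        pairs = segment_cycles(_trace_like(t, V))
        periods = [t[b] - t[a] for a, b in pairs]
        assert len(periods) >= 5
        np.testing.assert_allclose(periods, 1000.0, rtol=1e-3)

    def test_constant_voltage_rejected(self):
        t = np.arange(0, 1000.0, 0.2)
        with pytest.raises(ValueError):
            segment_cycles(_trace_like(t, np.full_like(t, -45.0)))

    def test_too_few_cycles_rejected(self):
        t = np.arange(0, 1500.0, 0.2)
        V = -45.0 + 15.0 * np.sin(2 * np.pi * t / 1000.0)
        with pytest.raises(ValueError):
            segment_cycles(_trace_like(t, V))

    def test_default_zap_frequencies_increase_within_band(self, evaluator):
        f = evaluator.freqs
        assert (np.diff(f) > 0).all()
        assert f.min() >= 0.095 and f.max() <= 4.6


class TestCycleImpedance:
    def test_passive_cycle_matches_rc(self, passive_params, consts):
        f = 0.1
        tr = sine_probe(passive_params, consts, f=f, n_cycles=3)
        sl = tr.steady
        m = cycle_impedance(tr.t[sl], tr.V[sl], tr.I_total[sl])
        Z_ref, phi_ref = rc_impedance(f, passive_params.g_L, consts.C_m)
        assert m.f == pytest.approx(f, rel=1e-3)
        assert m.Z == pytest.approx(Z_ref, rel=0.01)
        assert m.phi == pytest.approx(phi_ref, abs=0.01)

    def test_high_frequency_phase_approaches_quarter_cycle_delay(self, consts):
        from mprfit.params import ModelParams

        small_leak = ModelParams(
            g_L=0.01, g_H=0.0, g_Ca=0.0, tau_mH_max=1000.0,
            V_half_mCa=-51.0, tau_mCa=70.0, V_half_hCa=-67.0, tau_hCa=458.0,
        )
        tr = sine_probe(small_leak, consts, f=20.0, n_cycles=3, dt=0.05)
        sl = tr.steady
        m = cycle_impedance(tr.t[sl], tr.V[sl], tr.I_total[sl])
        assert m.phi < -1.4  # capacitive limit is -pi/2

    def test_zero_current_amplitude_rejected(self):
        t = np.arange(0, 1000.2, 0.2)
        V = -45.0 + 15.0 * np.sin(2 * np.pi * t / 1000.0)
        with pytest.raises(ValueError):
            cycle_impedance(t, V, np.zeros_like(t))

    def test_amplitude_invariant_to_time_reversal(self):
        t = np.arange(0, 1000.2, 0.2)
        V = -45.0 + 15.0 * np.sin(2 * np.pi * t / 1000.0)
        I = 2.0 + 1.3 * np.sin(2 * np.pi * t / 1000.0 + 0.4)
        assert cycle_impedance(t, V, I).Z == pytest.approx(cycle_impedance(t, V[::-1], I[::-1]).Z, rel=1e-9)


class TestProfile:
    def test_passive_profile_matches_analytic_curve(self, passive_params, consts, fast_zap):
        t, V = zap_voltage(fast_zap)
        _, dVdt = zap_derivative(fast_zap)
        tr = simulate_clamp(passive_params, consts, t, V, dVdt=dVdt)
        prof = build_profile(tr, config=fast_zap)
        Z_ref, _ = rc_impedance(prof.f, passive_params.g_L, consts.C_m)
        np.testing.assert_allclose(prof.Z, Z_ref, rtol=0.01)

    def test_resonant_profile_is_unimodal_with_interior_peak(self, evaluator, median_params):
        prof = evaluator.profile_of(median_params.to_array())
        k = int(np.argmax(prof.Z))
        assert 0 < k < prof.f.size - 1
        # rises to the peak, falls after it (allowing tiny sampling wiggle)
        assert prof.Z[0] < prof.Z[k] > prof.Z[-1]

    def test_csv_round_trip(self, tmp_path, evaluator, median_params):
        import pandas as pd

        prof = evaluator.profile_of(median_params.to_array())
        path = tmp_path / "profile.csv"
        prof.to_csv(path)
        back = pd.read_csv(path)
        np.testing.assert_allclose(back["Z_MOhm"].to_numpy(), prof.Z)


class TestAttributeExtraction:
    def _parabola_profile(self, evaluator):
        f = evaluator.freqs
        Z = 13.7 - 5.5 * (f - 1.0) ** 2
        phi = 0.5 - 0.5 * (f / 1.05)  # zero crossing exactly at 1.05 Hz
        return ImpedanceProfile(f, Z, phi)

    def test_known_parabolic_peak_recovered(self, evaluator):
        attrs = extract_attributes(self._parabola_profile(evaluator))
        assert attrs.f_res == pytest.approx(1.0, abs=0.01)
        assert attrs.Z_max == pytest.approx(13.7, abs=0.01)
        assert attrs.f_phi0 == pytest.approx(1.05, abs=0.01)

    def test_monotone_profile_flagged_nonresonant(self):
        f = np.linspace(0.1, 4.0, 40)
        prof = ImpedanceProfile(f, 10.0 - f, -0.1 * f)
        attrs = extract_attributes(prof)
        assert not attrs.has_resonance
        assert attrs.f_res == attrs.f0
        assert attrs.Q_Z == pytest.approx(0.0)
        assert np.isnan(attrs.f_cross_lo)

    def test_json_round_trip_preserves_nan_flags(self):
        f = np.linspace(0.1, 4.0, 40)
        attrs = extract_attributes(ImpedanceProfile(f, 10.0 - f, -0.1 * f))
        back = AttributeSet.from_json(attrs.to_json())
        assert back.has_resonance == attrs.has_resonance
        assert np.isnan(back.f_cross_lo)
        assert back.Z0 == pytest.approx(attrs.Z0)


class TestObjectives:
    def test_identity_gives_all_zeros(self, target):
        np.testing.assert_allclose(objective_vector(target, target), 0.0, atol=1e-12)

    def test_single_attribute_offset_scores_proportionally(self, target):
        attrs = target.replace(Z_max=1.05 * target.Z_max)
        obj = objective_vector(attrs, target)
        assert obj[1] == pytest.approx(0.05, rel=1e-9)
        assert np.delete(obj, 1).max() == pytest.approx(0.0, abs=1e-12)

    def test_missing_attribute_penalized(self, target):
        attrs = target.replace(f_phi0=np.nan, has_phasonance=False)
        obj = objective_vector(attrs, target)
        assert obj[7] == pytest.approx(1e3)

    def test_acceptance_threshold_is_sharp(self, target):
        assert is_acceptable(target, target)
        assert is_acceptable(target.replace(Z0=target.Z0 * 1.049), target)
        assert not is_acceptable(target.replace(Z0=target.Z0 * 1.06), target)

    def test_errors_track_pinned_half_points(self, target):
        attrs = target.replace(Z_half_hi=target.Z_half_hi * 1.1)
        err = attribute_errors(attrs, target)
        assert err["Z_half_hi"] == pytest.approx(0.1, rel=1e-9)

    def test_reference_target_prints(self, target):
        assert (target.f_res, target.Z_max) == (1.0, 13.7)
        assert target.Q_Z == pytest.approx(5.5)
        assert (target.f_half_lo, target.Z_half_lo) == (0.4, 11.65)
        assert (target.f_half_hi, target.Z_half_hi) == (2.5, 11.65)
        assert target.phi_min == -0.4


class TestDtInvariance:
    def test_attributes_stable_under_step_refinement(self, target, median_params):
        from mprfit.evaluator import AttributeEvaluator

        vals = {}
        for dt in (0.5, 0.2):
            ev = AttributeEvaluator(target, zap=ZapConfig(dt=dt))
            a = ev.attributes_of(median_params.to_array())
            vals[dt] = np.array([a.f_res, a.Z_max, a.Z0, a.f_phi0])
        np.testing.assert_allclose(vals[0.5], vals[0.2], rtol=0.005)
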