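import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gramlattice.phasor import (
    PPO_LIFETIME_NS,
    STANDARD_FREQUENCIES_MHZ,
    DecayModel,
    FrequencySweep,
    PhasorPoint,
    average_phasors,
    biphasic_scan,
    decay_to_phasor,
    fit_lifetimes,
    phasor_uncertainty,
    reference_calibration,
    to_phasor,
    _decay_phase_mod,
)

FREQS = np.array(STANDARD_FREQUENCIES_MHZ)


class TestToPhasor:
    @pytest.mark.parametrize(
        "phase, mod, expected",
        [
            (0.0, 1.0, (1.0, 0.0)),
            (90.0, 1.0, (0.0, 1.0)),
            (45.0, 0.8, (0.56569, 0.56569)),
        ],
    )
    def test_examples(self, phase, mod, expected):
        pt = to_phasor(phase, mod)
        assert pt.g == pytest.approx(expected[0], abs=1e-5)
        assert pt.s == pytest.approx(expected[1], abs=1e-5)

    @given(
        phase=st.floats(min_value=1.0, max_value=89.0),
        mod=st.floats(min_value=0.01, max_value=1.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_exact_inversion(self, phase, mod):
        pt = to_phasor(phase, mod)
        assert math.hypot(pt.g, pt.s) == pytest.approx(mod, rel=1e-12)
        assert math.degrees(math.atan2(pt.s, pt.g)) == pytest.approx(phase, rel=1e-10)

    @pytest.mark.parametrize("phase, mod", [(-1.0, 0.5), (91.0, 0.5), (45.0, 0.0), (45.0, 1.5)])
    def test_validation(self, phase, mod):
        with pytest.raises(ValueError):
            to_phasor(phase, mod)


class TestPhasorUncertainty:
    def test_zero_errors_give_zero(self):
        pt = to_phasor(40.0, 0.7)
        assert phasor_uncertainty(pt, math.radians(40.0), 0.0, 0.0) == (0.0, 0.0)

    def test_symmetry_at_45_degrees(self):
        pt = to_phasor(45.0, 0.8)
        dg, ds = phasor_uncertainty(pt, math.radians(45.0), 0.002, 0.002)
        assert dg / pt.g == pytest.approx(ds / pt.s, rel=1e-12)

    @pytest.mark.parametrize("phase_deg", [20.0, 45.0, 70.0])
    def test_matches_monte_carlo_propagation(self, phase_deg):
        # independent multiplicative Gaussian errors on M and phi
        rel_m, rel_p = 0.002, 0.002
        phi = math.radians(phase_deg)
        mod = 0.8
        pt = to_phasor(phase_deg, mod)
        dg, ds = phasor_uncertainty(pt, phi, rel_m, rel_p)
        rng = np.random.default_rng(7)
        n = 100_000
        m_draw = mod * (1 + rel_m * rng.standard_normal(n))
        p_draw = phi * (1 + rel_p * rng.standard_normal(n))
        g_draw = m_draw * np.cos(p_draw)
        s_draw = m_draw * np.sin(p_draw)
        assert dg == pytest.approx(g_draw.std(), rel=0.05)
        assert ds == pytest.approx(s_draw.std(), rel=0.05)

    def test_singular_phases_rejected(self):
        pt = to_phasor(45.0, 0.8)
        for phi in (0.0, math.pi / 2):
            with pytest.raises(ValueError):
                phasor_uncertainty(pt, phi, 0.002, 0.002)


class TestDecayToPhasor:
    @pytest.mark.parametrize("tau", [0.5, 1.46, 4.0, 10.0])
    @pytest.mark.parametrize("freq", [200.0, 53.65, 2.0])
    def test_single_exponential_on_universal_circle(self, tau, freq):
        pt = decay_to_phasor(DecayModel(((tau, 1.0),)), freq)
        assert (pt.g - 0.5) ** 2 + pt.s**2 == pytest.approx(0.25, abs=1e-12)

    def test_ppo_reference_hand_value(self):
        pt = decay_to_phasor(DecayModel(((PPO_LIFETIME_NS, 1.0),)), 200.0)
        assert pt.g == pytest.approx(0.22903, abs=1e-5)
        assert pt.s == pytest.approx(0.42021, abs=1e-5)

    @given(
        tau1=st.floats(min_value=0.2, max_value=3.0),
        tau2=st.floats(min_value=3.5, max_value=15.0),
        f1=st.floats(min_value=0.05, max_value=0.95),
    )
    @settings(derandomize=True, max_examples=60)
    def test_mixtures_lie_strictly_inside_circle(self, tau1, tau2, f1):
        model = DecayModel(((tau1, f1), (tau2, 1.0 - f1)))
        pt = decay_to_phasor(model, 80.0)
        assert (pt.g - 0.5) ** 2 + pt.s**2 < 0.25


class TestReferenceCalibration:
    def test_self_calibration_yields_reference_phasor(self):
        phase, mod = _decay_phase_mod(DecayModel(((2.2, 0.3), (6.0, 0.7))), FREQS)
        raw = FrequencySweep(FREQS, phase, mod)
        cal = reference_calibration(raw, raw, tau_ref=PPO_LIFETIME_NS)
        expected = decay_to_phasor(DecayModel(((PPO_LIFETIME_NS, 1.0),)), FREQS[0])
        pt = to_phasor(cal.phase_deg[0], cal.modulation[0])
        assert pt.g == pytest.approx(expected.g, abs=1e-12)
        assert pt.s == pytest.approx(expected.s, abs=1e-12)

    def test_simulated_instrument_roundtrip(self):
        from gramlattice.synthetic_data import SimConfig, simulate_raw_with_reference

        model = DecayModel(((1.2, 0.45), (4.5, 0.55)))
        raw, ref = simulate_raw_with_reference(model, SimConfig(seed=3))
        cal = reference_calibration(raw, ref)
        phase_true, mod_true = _decay_phase_mod(model, cal.frequency_mhz)
        assert np.allclose(cal.phase_deg, phase_true, atol=1e-10)
        assert np.allclose(cal.modulation, mod_true, atol=1e-10)

    def test_frequency_mismatch_raises(self):
        phase, mod = _decay_phase_mod(DecayModel(((2.0, 1.0),)), FREQS)
        raw = FrequencySweep(FREQS, phase, mod)
        other = FrequencySweep(FREQS[:-1], phase[:-1], mod[:-1])
        with pytest.raises(ValueError, match="grids"):
            reference_calibration(raw, other)


class TestFitLifetimes:
    def test_exact_single_exponential_recovery(self):
        phase, mod = _decay_phase_mod(DecayModel(((2.5, 1.0),)), FREQS)
        sweep = FrequencySweep(FREQS, phase, mod)
        fit = fit_lifetimes(sweep, 1)
        assert fit.components[0][0] == pytest.approx(2.5, abs=1e-6)

    def test_noiseless_two_component_residual_near_zero(self):
        model = DecayModel(((1.0, 0.4), (4.0, 0.6)))
        phase, mod = _decay_phase_mod(model, FREQS)
        sweep = FrequencySweep(FREQS, phase, mod)
        fit = fit_lifetimes(sweep, 2)
        phase_fit, mod_fit = _decay_phase_mod(fit, FREQS)
        assert np.allclose(phase_fit, phase, atol=1e-6)
        assert np.allclose(mod_fit, mod, atol=1e-8)

    def test_noisy_two_component_lifetime_recovery(self):
        model = DecayModel(((1.0, 0.4), (4.0, 0.6)))
        phase, mod = _decay_phase_mod(model, FREQS)
        rng = np.random.default_rng(11)
        sweep = FrequencySweep(
            FREQS,
            np.clip(phase * (1 + 0.002 * rng.standard_normal(FREQS.size)), 0, 90),
            np.clip(mod * (1 + 0.002 * rng.standard_normal(FREQS.size)), 1e-9, 1.0),
            rel_err_phase=np.full(FREQS.size, 0.002),
            rel_err_mod=np.full(FREQS.size, 0.002),
        )
        fit = fit_lifetimes(sweep, 2)
        taus = sorted(t for t, _ in fit.components)
        assert taus[0] == pytest.approx(1.0, rel=0.10)
        assert taus[1] == pytest.approx(4.0, rel=0.10)

    def test_too_few_frequencies(self):
        phase, mod = _decay_phase_mod(DecayModel(((2.0, 1.0),)), FREQS[:3])
        sweep = FrequencySweep(FREQS[:3], phase, mod)
        with pytest.raises(ValueError):
            fit_lifetimes(sweep, 2)


class TestBiphasicScan:
    @staticmethod
    def _series(shift_g=0.0, shift_s=0.0):
        base = PhasorPoint(0.30, 0.45)
        series = {x: base for x in (0.139, 0.141, 0.145, 0.147)}
        series[0.143] = PhasorPoint(0.30 + shift_g, 0.45 + shift_s)
        return series

    def test_planted_leftward_shift_is_flagged(self):
        report = biphasic_scan(self._series(shift_g=-0.015), 0.143)
        assert report.significant and report.leftward and report.biphasic
        assert report.displacement == pytest.approx(0.015, abs=1e-12)

    def test_identical_points_not_flagged(self):
        report = biphasic_scan(self._series(), 0.143)
        assert not report.significant and not report.biphasic

    def test_subthreshold_displacement_not_significant(self):
        report = biphasic_scan(self._series(shift_g=-0.009), 0.143)
        assert not report.significant

    def test_rightward_shift_not_biphasic(self):
        report = biphasic_scan(self._series(shift_g=+0.02), 0.143)
        assert report.significant and not report.leftward and not report.biphasic

    def test_missing_candidate(self):
        with pytest.raises(KeyError):
            biphasic_scan(self._series(), 0.5)


class TestReplicateAveraging:
    def test_triplicate_mean_shrinks_scatter_by_sqrt3(self):
        rng = np.random.default_rng(5)
        g0, s0, sd = 0.3, 0.45, 0.002
        singles, triples = [], []
        for _ in range(2000):
            pts = [
                PhasorPoint(g0 + sd * rng.standard_normal(), s0 + sd * rng.standard_normal())
                for _ in range(3)
            ]
            singles.append(pts[0].g)
            triples.append(average_phasors(pts).g)
        ratio = np.std(singles) / np.std(triples)
        assert ratio == pytest.approx(math.sqrt(3), rel=0.10)


def test_sweep_warns_on_unphysical_ordering():
    with pytest.warns(UserWarning, match="unphysical"):
        FrequencySweep(
            np.array([10.0, 50.0, 200.0]),
            np.array([60.0, 30.0, 10.0]),  # phase falling with frequency
            np.array([0.3, 0.6, 0.9]),
        )
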