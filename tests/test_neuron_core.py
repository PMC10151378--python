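"""Unit tests for the Hodgkin-Huxley reference implementation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from lcne import neuron_core as nc


class TestRateFunctions:
    def test_sodium_activation_midpoint(self):
        assert nc.rate_functions(-34.0).mNa_inf == pytest.approx(0.5)

    def test_sodium_inactivation_midpoint(self):
        assert nc.rate_functions(-55.0).hNa_inf == pytest.approx(0.5)

    def test_potassium_rate_singularity_is_removable(self):
        # limit of 0.01 x / (1 - exp(-x/5)) as x -> 0 is 0.05
        at = nc.rate_functions(-44.0).alphaK
        assert at == pytest.approx(0.05, abs=1e-9)
        lo = nc.rate_functions(-44.0 - 1e-6).alphaK
        hi = nc.rate_functions(-44.0 + 1e-6).alphaK
        assert lo == pytest.approx(0.05, rel=1e-5)
        assert hi == pytest.approx(0.05, rel=1e-5)

    def test_rejects_non_finite_voltage(self):
        with pytest.raises(ValueError):
            nc.rate_functions(np.nan)

    @given(st.floats(min_value=-120.0, max_value=60.0))
    @settings(max_examples=200, deadline=None)
    def test_steady_states_bounded(self, v):
        rf = nc.rate_functions(v)
        for x in (rf.mK_inf, rf.mNa_inf, rf.hNa_inf):
            assert 0.0 <= float(x) <= 1.0
        assert float(rf.alphaK) >= 0.0
        assert float(rf.betaK) >= 0.0


class TestTimeConstants:
    def test_potassium_peak(self):
        tc = nc.time_constants(-40.0)
        assert tc.tau_mK == pytest.approx(3.5)

    def test_sodium_peak(self):
        tc = nc.time_constants(-67.5)
        assert tc.tau_hNa == pytest.approx(8.456)

    def test_direct_evaluation_away_from_peak(self):
        tc = nc.time_constants(0.0)
        assert tc.tau_mK == pytest.approx(3.5 / np.cosh(1.0), rel=1e-12)

    def test_maxima_location(self):
        v = np.linspace(-120, 40, 3201)
        tc = nc.time_constants(v)
        assert v[np.argmax(tc.tau_mK)] == pytest.approx(-40.0, abs=0.1)
        assert v[np.argmax(tc.tau_hNa)] == pytest.approx(-67.5, abs=0.1)


class TestGatingStep:
    def test_zero_dt_is_identity(self):
        assert nc.gating_step(0.3, 5.0, 0.9, 0.0) == pytest.approx(0.3)

    def test_single_euler_step_from_zero(self):
        dt = 1e-4
        out = nc.gating_step(0.0, 5.0, 0.8, dt)
        assert out == pytest.approx((dt * 1e3 / 5.0) * 0.8)

    def test_relaxation_converges(self):
        x, dt = 0.0, 1e-4
        for _ in range(int(10 * 5.0 / (dt * 1e3))):   # 10 time constants
            x = nc.gating_step(x, 5.0, 0.8, dt)
        assert abs(x - 0.8) < 1e-3

    def test_unstable_step_flagged(self):
        with pytest.warns(RuntimeWarning):
            nc.gating_step(0.5, 2.0, 0.5, 0.01)

    @given(st.floats(min_value=0.0, max_value=1.0),
           st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=100, deadline=None)
    def test_stays_in_unit_interval(self, x, x_inf):
        out = nc.gating_step(x, 3.0, x_inf, 1e-4)
        assert 0.0 <= float(out) <= 1.0


@pytest.fixture
def quiet_params():
    return nc.HHParams(D=0.0, EL_sd=0.0)


class TestMembraneStep:
    def test_rest_matches_root_find(self, quiet_params):
        """With noise off the group settles at the fixed point of the
        membrane equation, which an independent root-find locates."""
        p = quiet_params
        rng = np.random.default_rng(0)
        state = nc.HHGroupState.at_rest(4, p, rng)
        for _ in range(int(1.0 / p.dt)):
            nc.membrane_step(state, 0.0, p)
        dv = np.abs(np.diff(state.V))

        def rhs(v):
            rf = nc.rate_functions(v)
            return -(p.gK_bar * rf.mK_inf ** 4 * (v - p.EK)
                     + p.gNa_bar * rf.mNa_inf ** 3 * rf.hNa_inf
                     * (v - p.ENa) + p.gL * (v - p.EL))

        v_star = brentq(rhs, -80.0, -50.0)
        assert np.allclose(state.V, v_star, atol=0.05)
        # and it is stationary
        v_before = state.V.copy()
        nc.membrane_step(state, 0.0, p)
        assert np.allclose(state.V, v_before, atol=1e-6)

    def test_firing_rate_monotone_in_current(self, quiet_params):
        p = quiet_params
        rates = []
        for i_depol in (150.0, 300.0, 600.0):
            rng = np.random.default_rng(1)
            state = nc.HHGroupState.at_rest(1, p, rng)
            spikes = 0
            for _ in range(int(2.0 / p.dt)):
                nc.membrane_step(state, -i_depol, p)
                spikes += int(state.spiked.sum())
            rates.append(spikes / 2.0)
        assert rates[0] > 0, "above-rheobase current must elicit spikes"
        assert rates == sorted(rates)

    def test_no_spikes_at_rest_without_noise(self, quiet_params):
        p = quiet_params
        state = nc.HHGroupState.at_rest(8, p, np.random.default_rng(2))
        total = 0
        for _ in range(int(1.0 / p.dt)):
            nc.membrane_step(state, 0.0, p)
            total += int(state.spiked.sum())
        assert total == 0

    def test_pure_leak_noise_matches_ou_variance(self):
        """With the active conductances removed the membrane is an
        Ornstein-Uhlenbeck process whose stationary variance is known in
        closed form for the chosen discretization."""
        p = nc.HHParams(gK_bar=0.0, gNa_bar=0.0, EL_sd=0.0)
        rng = np.random.default_rng(3)
        state = nc.HHGroupState.at_rest(64, p, rng)
        n_steps = int(3.0 / p.dt)
        samples = []
        for k in range(n_steps):
            nc.membrane_step(state, 0.0, p, rng=rng)
            if k > n_steps // 3 and k % 50 == 0:
                samples.append(state.V.copy())
        var = np.var(np.concatenate(samples))
        s = nc.noise_sigma(p) * (p.dt * 1e3) / p.C      # per-step kick [mV]
        tau_ms = p.C / p.gL
        var_exact = s ** 2 * tau_ms / (2 * p.dt * 1e3)
        assert var == pytest.approx(var_exact, rel=0.15)

    def test_overflow_aborts(self, quiet_params):
        p = quiet_params
        state = nc.HHGroupState.at_rest(1, p, np.random.default_rng(4))
        with pytest.raises(FloatingPointError):
            for _ in range(1000):
                nc.membrane_step(state, -1e7, p)

    def test_gating_variables_stay_bounded(self, quiet_params):
        p = nc.HHParams(EL_sd=0.0)
        rng = np.random.default_rng(5)
        state = nc.HHGroupState.at_rest(16, p, rng)
        for _ in range(2000):
            nc.membrane_step(state, -200.0, p, rng=rng)
            assert np.all((state.mK >= 0) & (state.mK <= 1))
            assert np.all((state.hNa >= 0) & (state.hNa <= 1))

    def test_step_halving_changes_rate_mildly(self, quiet_params):
        """Euler at dt = 1e-4 and 0.5e-4 s give driven firing rates
        within 10% of each other."""
        rates = {}
        for dt in (1e-4, 0.5e-4):
            p = nc.HHParams(D=0.0, EL_sd=0.0, dt=dt)
            state = nc.HHGroupState.at_rest(1, p, np.random.default_rng(6))
            spikes = 0
            for _ in range(int(2.0 / dt)):
                nc.membrane_step(state, -300.0, p)
                spikes += int(state.spiked.sum())
            rates[dt] = spikes / 2.0
        assert rates[1e-4] == pytest.approx(rates[0.5e-4], rel=0.10)


class TestSynapses:
    def test_zero_current_at_reversal(self):
        proj = nc.SynapticProjection("a", "b", weight=2.0)
        proj.gate = 0.7
        assert nc.synaptic_current(proj, 0.0) == pytest.approx(0.0)

    def test_polarity_sign_convention(self):
        exc = nc.SynapticProjection("a", "b", weight=1.0)
        inh = nc.SynapticProjection("a", "b", weight=1.0,
                                    polarity="inhibitory")
        exc.gate = inh.gate = 0.5
        # with the global -I convention: excitatory current negative at
        # rest (depolarizing), inhibitory positive below -75 impossible ->
        # at -60 the inhibitory term is positive (hyperpolarizing)
        assert nc.synaptic_current(exc, -60.0) < 0
        assert nc.synaptic_current(inh, -60.0) > 0

    def test_gate_decays_exponentially(self):
        proj = nc.SynapticProjection("a", "b", weight=1.0, tau=5.0)
        nc.decay_gate(proj, n_source_spikes=10, n_source=10, dt=1e-4)
        g0 = proj.gate
        assert g0 == pytest.approx(1.0, rel=1e-3)
        for _ in range(int(0.005 / 1e-4)):        # one time constant
            nc.decay_gate(proj, 0, 10, 1e-4)
        assert proj.gate == pytest.approx(g0 * np.exp(-1.0), rel=1e-3)

    def test_inconsistent_reversal_rejected(self):
        with pytest.raises(ValueError):
            nc.SynapticProjection("a", "b", weight=1.0,
                                  polarity="excitatory", E_rev=-75.0)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            nc.SynapticProjection("a", "b", weight=-1.0)


class TestParams:
    def test_printed_defaults(self):
        p = nc.HHParams()
        assert (p.C, p.gK_bar, p.gNa_bar, p.gL) == (36.0, 250.0, 400.0, 6.0)
        assert (p.EK, p.ENa, p.EL) == (-94.0, 55.0, -60.0)
        assert p.D == 20.0 and p.dt == 1e-4

    def test_validation(self):
        with pytest.raises(ValueError):
            nc.HHParams(C=-1.0)
        with pytest.raises(ValueError):
            nc.HHParams(dt=0.0)
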