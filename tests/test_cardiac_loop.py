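"""Unit tests for the cardiac readout chain and FHN tissue."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lcne import cardiac_loop as cl
from lcne.params import CardiacParams


class TestHillGains:
    def test_ne_midpoint(self):
        assert cl.hill_ne(350.0) == pytest.approx(0.5)

    def test_ne_saturation(self):
        assert cl.hill_ne(1e6) == pytest.approx(1.0, abs=1e-6)

    def test_ne_direct_evaluation(self):
        # 1/(1 + 0.5^10) at twice the midpoint
        assert cl.hill_ne(700.0) == pytest.approx(1.0 / (1.0 + 0.5 ** 10),
                                                  rel=1e-9)

    def test_ach_midpoint(self):
        assert cl.hill_ach(20.0) == pytest.approx(0.5)

    def test_ach_saturation(self):
        assert cl.hill_ach(1e6) == pytest.approx(0.0, abs=1e-6)

    def test_ach_direct_evaluation(self):
        # 1 - 1/(1 + 0.5^5) at twice the midpoint
        assert cl.hill_ach(40.0) == pytest.approx(
            1.0 - 1.0 / (1.0 + 0.5 ** 5), rel=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            cl.hill_ne(0.0)
        with pytest.raises(ValueError):
            cl.hill_ach(-1.0)

    @given(st.floats(min_value=1.0, max_value=5000.0),
           st.floats(min_value=1.0, max_value=5000.0))
    @settings(max_examples=100, deadline=None)
    def test_monotonicity(self, a, b):
        lo, hi = sorted((a, b))
        assert cl.hill_ne(lo) <= cl.hill_ne(hi)
        assert cl.hill_ach(lo) >= cl.hill_ach(hi)


class TestModulatedParams:
    def test_bounds_at_extremes(self):
        p = CardiacParams()
        assert cl.modulated_fhn_params(0.0, 0.0, p) == (p.c_min, p.b_min)
        assert cl.modulated_fhn_params(1.0, 1.0, p) == (p.c_max, p.b_max)

    def test_midpoint_affine(self):
        p = CardiacParams()
        gc, b = cl.modulated_fhn_params(0.5, 0.5, p)
        assert gc == pytest.approx((p.c_min + p.c_max) / 2)
        assert b == pytest.approx((p.b_min + p.b_max) / 2)

    def test_misordered_bounds_rejected(self):
        p = CardiacParams(c_min=40.0, c_max=20.0)
        with pytest.raises(ValueError):
            cl.modulated_fhn_params(0.5, 0.5, p)


def _run_cable(gc, b, params=None, dur=18.0, dt=1e-3):
    p = params or CardiacParams()
    st_ = cl.FHNTissueState.resting(p)
    n = int(dur / dt)
    rec = np.empty(n)
    for k in range(n):
        cl.fhn_tissue_step(st_, gc, b, dt)
        rec[k] = st_.v[-1]
    t = (np.arange(n) + 1) * dt
    return t, rec


class TestFHNTissue:
    def test_uniform_field_has_zero_diffusion(self):
        """From a uniform field, one step is independent of the diffusion
        coefficient (the discrete Laplacian vanishes)."""
        p_hi = CardiacParams(d_diff=200.0)
        p_lo = CardiacParams(d_diff=0.0)
        s1 = cl.FHNTissueState.resting(p_hi)
        s2 = cl.FHNTissueState.resting(p_lo)
        s1.v[:] = 0.37
        s2.v[:] = 0.37
        s1.w[:] = 0.05
        s2.w[:] = 0.05
        cl.fhn_tissue_step(s1, 30.0, 4.0, 1e-4)
        cl.fhn_tissue_step(s2, 30.0, 4.0, 1e-4)
        assert np.allclose(s1.v, s2.v)

    def test_diffusion_operator_conserves(self):
        """The no-flux Laplacian sums to zero for any field, so diffusion
        does not change the cable total of v."""
        rng = np.random.default_rng(0)
        v = rng.uniform(-0.5, 1.0, 32)
        lap = np.zeros_like(v)
        lap[1:-1] = v[:-2] + v[2:] - 2 * v[1:-1]
        lap[0] = v[1] - v[0]
        lap[-1] = v[-2] - v[-1]
        assert lap.sum() == pytest.approx(0.0, abs=1e-12)

    def test_distal_cell_beats(self):
        p = CardiacParams()
        gc = (p.c_min + p.c_max) / 2
        b = (p.b_min + p.b_max) / 2
        t, rec = _run_cable(gc, b)
        hr = cl.heart_rate(t, rec, 8.0, 18.0)
        assert 40.0 < hr < 110.0

    def test_rate_increases_with_b(self):
        """Chronotropic contract: the recovery rate b (vagal withdrawal)
        raises the heart rate."""
        p = CardiacParams()
        gc = (p.c_min + p.c_max) / 2
        hrs = []
        for b in (p.b_min + 0.5, (p.b_min + p.b_max) / 2, p.b_max):
            t, rec = _run_cable(gc, b)
            hrs.append(cl.heart_rate(t, rec, 8.0, 18.0))
        assert hrs[0] < hrs[1] < hrs[2]

    def test_membrane_potential_continuous_at_c_switch(self):
        """The excitation-rate switch changes dv/dt, never v itself."""
        p = CardiacParams()
        st_ = cl.FHNTissueState.resting(p)
        dt = 1e-3
        prev = st_.v.copy()
        max_jump = 0.0
        for _ in range(int(10.0 / dt)):
            cl.fhn_tissue_step(st_, 34.0, 4.0, dt)
            max_jump = max(max_jump, float(np.max(np.abs(st_.v - prev))))
            prev = st_.v.copy()
        # one Euler step cannot move v by more than dt * max|dv| ~ 0.05
        assert max_jump < 0.06

    def test_period_refinement_oracle(self):
        """The limit-cycle period at dt = 1e-3 matches an independent
        fine-step (dt = 1e-4) integration within 1%."""
        p = CardiacParams()
        gc, b = 34.0, 4.0
        periods = {}
        for dt in (1e-3, 1e-4):
            t, rec = _run_cable(gc, b, dur=14.0, dt=dt)
            hr = cl.heart_rate(t, rec, 6.0, 14.0)
            periods[dt] = 60.0 / hr
        assert periods[1e-3] == pytest.approx(periods[1e-4], rel=0.01)

    def test_blow_up_detected(self):
        st_ = cl.FHNTissueState.resting()
        with pytest.raises(FloatingPointError):
            for _ in range(500):
                cl.fhn_tissue_step(st_, 1e5, 1e4, 1.0)


class TestAutonomicOutflow:
    def test_decay_to_zero_without_firing(self):
        s = cl.NeuromodulatorState(p_ne=100.0, q_ach=10.0)
        for _ in range(int(20 * CardiacParams().tau_mod / 1e-3)):
            cl.autonomic_outflow_step(s, 0.0, 0.0, 1e-3)
        assert s.p_ne < 1e-3 and s.q_ach < 1e-3

    def test_steady_level_is_gain_times_rate(self):
        p = CardiacParams()
        s = cl.NeuromodulatorState(p_ne=0.0, q_ach=0.0)
        for _ in range(int(20 * p.tau_mod / 1e-3)):
            cl.autonomic_outflow_step(s, 5.0, 3.0, 1e-3, p)
        assert s.p_ne == pytest.approx(p.k_ne * 5.0, rel=1e-3)
        assert s.q_ach == pytest.approx(p.k_ach * 3.0, rel=1e-3)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            cl.autonomic_outflow_step(cl.NeuromodulatorState(), -1.0, 0.0,
                                      1e-3)


class TestHeartRate:
    def test_synthetic_one_hertz(self):
        t = np.arange(0, 30, 1e-3)
        v = (np.sin(2 * np.pi * 1.0 * t) > 0.95).astype(float)
        assert cl.heart_rate(t, v, 0, 30) == pytest.approx(60.0, abs=2.0)

    def test_no_beats_raises(self):
        t = np.arange(0, 10, 1e-3)
        with pytest.raises(ValueError):
            cl.heart_rate(t, np.zeros_like(t), 0, 10)
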