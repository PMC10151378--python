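"""Unit tests for lung mechanics, gas exchange and breathing-rate readout."""

import numpy as np
import pytest

from lcne import respiratory_loop as rl
from lcne.params import LungGasParams


class TestLungStep:
    def test_relaxes_to_rest_volume(self):
        p = LungGasParams()
        v = p.v_rest + 0.8
        for _ in range(int(20.0 / 1e-3)):
            v = rl.lung_step(v, 0.0, 0.0, 1e-3, p)
        assert v == pytest.approx(p.v_rest, abs=1e-6)

    def test_tidal_volume_monotone_in_drive(self):
        p = LungGasParams()
        finals = []
        for drive in (0.4, 0.8):
            v = p.v_rest
            for _ in range(int(10.0 / 1e-3)):
                v = rl.lung_step(v, drive, 0.0, 1e-3, p)
            finals.append(v - p.v_rest)
        assert 0 < finals[0] < finals[1]

    def test_periodic_drive_gives_periodic_volume(self):
        """A 0.25 Hz inspiratory drive forces a 0.25 Hz volume rhythm."""
        p = LungGasParams()
        dt = 1e-3
        v = p.v_rest
        trace = []
        t = np.arange(0, 40, dt)
        drive = 0.5 * (1 + np.sin(2 * np.pi * 0.25 * t)) / 2
        for d in drive:
            v = rl.lung_step(v, d, 0.0, dt, p)
            trace.append(v)
        x = np.asarray(trace[int(8 / dt):]) - np.mean(trace[int(8 / dt):])
        spec = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(len(x), dt)
        assert freqs[np.argmax(spec[1:]) + 1] == pytest.approx(0.25,
                                                               abs=0.02)

    def test_activity_range_enforced(self):
        with pytest.raises(ValueError):
            rl.lung_step(2.0, 1.5, 0.0, 1e-3)


class TestGasExchange:
    def test_zero_flux_at_equilibrium(self):
        p = LungGasParams()
        s = rl.LungGasState(v_lung=p.v_rest, pco2_alv=40.0, pco2_art=40.0,
                            po2_alv=100.0, po2_art=100.0, params=p)
        before = (s.pco2_alv, s.pco2_art)
        # no ventilation, no gradient, no metabolism
        p2 = LungGasParams(m_co2=0.0, m_o2=0.0)
        s.params = p2
        rl.gas_exchange_step(s, 0.0, 1e-3)
        assert s.pco2_alv == pytest.approx(before[0])
        assert s.pco2_art == pytest.approx(before[1])

    def test_apnea_raises_arterial_co2(self):
        """With ventilation stopped, metabolism makes arterial pCO2
        strictly increase."""
        s = rl.LungGasState(v_lung=2.0)
        prev = s.pco2_art
        for _ in range(int(30.0 / 1e-3)):
            rl.gas_exchange_step(s, 0.0, 1e-3)
            assert s.pco2_art >= prev
            prev = s.pco2_art
        assert s.pco2_art > 40.5

    def test_ventilation_clears_co2(self):
        s1 = rl.LungGasState(v_lung=2.5, pco2_alv=45.0)
        s2 = rl.LungGasState(v_lung=2.5, pco2_alv=45.0)
        for _ in range(int(20.0 / 1e-3)):
            rl.gas_exchange_step(s1, 0.0, 1e-3)
            rl.gas_exchange_step(s2, 0.2, 1e-3)   # steady inflow
        assert s2.pco2_alv < s1.pco2_alv

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            rl.LungGasState(v_lung=-1.0)
        with pytest.raises(ValueError):
            rl.LungGasState(v_lung=2.0, pco2_art=-5.0)


class TestPSRDrive:
    def test_zero_at_and_below_rest(self):
        p = LungGasParams()
        assert rl.psr_drive(p.v_rest, p) == 0.0
        assert rl.psr_drive(p.v_rest - 0.5, p) == 0.0

    def test_monotone_in_volume(self):
        p = LungGasParams()
        vols = p.v_rest + np.linspace(0, 1.0, 11)
        drives = rl.psr_drive(vols, p)
        assert np.all(np.diff(drives) >= 0)

    def test_memoryless_periodicity(self):
        """A sinusoidal volume yields a drive periodic at the same
        frequency (the map has no memory)."""
        p = LungGasParams()
        t = np.arange(0, 20, 1e-2)
        v = p.v_rest + 0.3 + 0.25 * np.sin(2 * np.pi * 0.25 * t)
        d = rl.psr_drive(v, p)
        period = int(4.0 / 1e-2)
        assert np.allclose(d[:period], d[period:2 * period], atol=1e-12)

    def test_positive_volume_required(self):
        with pytest.raises(ValueError):
            rl.psr_drive(0.0)


class TestBreathingRate:
    def test_square_wave_quarter_hertz(self):
        t = np.arange(0, 60, 1e-3)
        insp = (np.sin(2 * np.pi * 0.25 * t) > 0).astype(float)
        assert rl.breathing_rate(t, insp, 0, 60) == pytest.approx(15.0,
                                                                  abs=1.0)

    def test_no_bursts_warns_and_returns_zero(self):
        t = np.arange(0, 30, 1e-3)
        with pytest.warns(RuntimeWarning):
            br = rl.breathing_rate(t, np.zeros_like(t), 0, 30)
        assert br == 0.0

    def test_empty_window_rejected(self):
        t = np.arange(0, 30, 1e-3)
        with pytest.raises(ValueError):
            rl.breathing_rate(t, np.ones_like(t), 10, 10)


@pytest.fixture(scope="module")
def resp_run():
    m = rl.respiratory_model()
    return m, m.run(40.0, seed=7)


class TestClosedLoopRhythm:
    """The reconstructed CPG in closed loop with the lung and gas
    exchange (simulated via the fused integrator)."""

    def test_baseline_rhythm_in_normal_range(self, resp_run):
        _, r = resp_run
        br = rl.breathing_rate(r.t, r.trace("insp_act"), 15.0, 40.0)
        assert 12.0 <= br <= 20.0

    def test_motor_outputs_bounded(self, resp_run):
        _, r = resp_run
        assert np.all((r.trace("insp_act") >= 0)
                      & (r.trace("insp_act") <= 1))
        assert np.all((r.trace("exp_act") >= 0) & (r.trace("exp_act") <= 1))

    def test_no_active_expiration_at_normocapnia(self, resp_run):
        _, r = resp_run
        i0 = int(15.0 / r.dt_rec)
        assert r.trace("exp_act")[i0:].mean() < 0.05

    def test_arterial_co2_near_40(self, resp_run):
        _, r = resp_run
        i0 = int(15.0 / r.dt_rec)
        assert r.trace("pco2")[i0:].mean() == pytest.approx(40.0, abs=4.0)

    def test_hypercapnia_recruits_expiration(self, resp_run):
        """Clamping arterial pCO2 at a hypercapnic level recruits the
        late-E/abdominal pathway that is silent at normocapnia."""
        m, r_norm = resp_run
        r_hyp = m.run(40.0, seed=7, clamp_pco2=60.0)
        i0 = int(15.0 / r_norm.dt_rec)
        idx = r_norm.pop_names.index("LATEE")
        latee_norm = r_norm.pop_counts[i0:, idx].sum()
        latee_hyp = r_hyp.pop_counts[i0:, idx].sum()
        assert latee_hyp > 3.0 * max(latee_norm, 1.0)
        assert r_hyp.trace("exp_act")[i0:].max() \
            > 2.0 * r_norm.trace("exp_act")[i0:].max()

    def test_chemoreflex_sign(self, resp_run):
        """Raising imposed pCO2 never slows the inspiratory rhythm."""
        m, r_norm = resp_run
        r_hyp = m.run(40.0, seed=7, clamp_pco2=55.0)
        br_n = rl.breathing_rate(r_norm.t, r_norm.trace("insp_act"),
                                 15.0, 40.0)
        br_h = rl.breathing_rate(r_hyp.t, r_hyp.trace("insp_act"),
                                 15.0, 40.0)
        assert br_h >= br_n - 1.0
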