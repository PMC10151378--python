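"""Closed-loop respiratory control: CPG, lung mechanics, gas exchange.

The rhythm is generated by the preI/I (pre-Boetzinger) population -- a
noisy HH group with slow recurrent excitation and spike-triggered
adaptation that produces inspiratory population bursts -- switched by the
post-I inhibitory companion, relayed by ramp-I to the inspiratory motor
output, with late-E providing the abdominal (active expiration) output via
the cVRG under hypercapnic drive from the RTN.  Feedback closes two loops:
pulmonary stretch receptors report lung volume to the NTS, and blood-gas
chemoreception (peripheral at the NTS, central at the RTN) reports CO2.

The lumped human lung carries the published elastance and diffusion
constants; motor outputs are normalized low-pass filtered population rates
in [0, 1].

Scalar-step functions here are the reference/oracle path; population
dynamics run inside the fused integrator (build the subnetwork with
:func:`respiratory_model`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._dynamics import lung_volume_step, psr_drive_scalar
from .params import LungGasParams, NetworkConfig
from .signal_analysis import events_from_trace

__all__ = [
    "LungGasState", "LungGasParams", "RESPIRATORY_POPULATIONS",
    "respiratory_model", "lung_step", "gas_exchange_step", "psr_drive",
    "breathing_rate",
]

#: populations forming the stand-alone respiratory loop (with the LC and
#: its chemo afferents, which the rhythm is entrained through)
RESPIRATORY_POPULATIONS = ("LC", "NTS_CHEMO_B", "RTN", "PREI", "RAMPI",
                           "POSTI", "LATEE", "CVRG")


@dataclass
class LungGasState:
    """Lung volume [L] and alveolar/arterial gas tensions [mmHg]."""

    v_lung: float
    pco2_alv: float = 32.0
    pco2_art: float = 40.0
    po2_alv: float = 110.0
    po2_art: float = 100.0
    params: LungGasParams = field(default_factory=LungGasParams)

    def __post_init__(self) -> None:
        if self.v_lung <= 0:
            raise ValueError("lung volume must be positive")
        for name in ("pco2_alv", "pco2_art", "po2_alv", "po2_art"):
            if getattr(self, name) <= 0:
                raise ValueError("partial pressures must be positive")


def respiratory_model(config: NetworkConfig | None = None, **kw):
    """A CoupledModel containing only the respiratory loop populations."""
    from .model import CoupledModel

    cfg = (config or NetworkConfig()).with_(
        include=RESPIRATORY_POPULATIONS, **kw)
    return CoupledModel(cfg)


def lung_step(v_lung: float, insp_act: float, exp_act: float, dt: float,
              params: LungGasParams | None = None) -> float:
    """One Euler step of lung volume under the motor outputs.

    Inspiratory drive inflates against the elastance recoil, the abdominal
    output actively deflates, and with both at zero the volume relaxes to
    the rest (functional residual) volume.
    """
    p = params or LungGasParams()
    if not (0.0 <= insp_act <= 1.0 and 0.0 <= exp_act <= 1.0):
        raise ValueError("motor activities must lie in [0, 1]")
    v_new, _ = lung_volume_step(v_lung, insp_act, exp_act, p.v_rest,
                                p.elastance, p.resistance, p.p_insp,
                                p.p_exp, dt)
    if v_new <= 0:
        raise FloatingPointError("lung volume collapsed")
    return v_new


def gas_exchange_step(state: LungGasState, flow: float, dt: float
                      ) -> LungGasState:
    """One Euler step of alveolar/arterial CO2 and O2 exchange.

    The blood-alveolar flux is proportional to the tension gradient
    through the serial diffusion (delta * D) and capillary perfusion
    (V_c / T_L) conductances; inspiratory airflow dilutes the alveolar gas
    with ambient air; metabolism loads the arterial pools.  Flux is zero
    exactly at gradient equilibrium.
    """
    p = state.params
    v_in = max(flow, 0.0)
    flux_c = p.g_co2 * (state.pco2_art - state.pco2_alv)
    flux_o = p.g_o2 * (state.po2_alv - state.po2_art)
    state.pco2_alv += dt * (flux_c * 760.0 - v_in * state.pco2_alv) \
        / state.v_lung
    state.po2_alv += dt * (-flux_o * 760.0
                           + v_in * (p.po2_air - state.po2_alv)) \
        / state.v_lung
    state.pco2_art += dt * (p.m_co2 - flux_c) / p.beta_co2
    state.po2_art += dt * (flux_o - p.m_o2) / p.beta_o2
    if min(state.pco2_alv, state.po2_alv, state.pco2_art,
           state.po2_art) <= 0:
        raise FloatingPointError("gas tension became non-positive")
    return state


def psr_drive(v_lung, params: LungGasParams | None = None):
    """Pulmonary stretch-receptor signal: rectified-linear in lung volume
    above the rest volume (0 at or below it), normalized by the tidal
    scale so a full tidal breath gives a drive of order 1."""
    p = params or LungGasParams()
    v = np.asarray(v_lung, dtype=float)
    if np.any(v <= 0):
        raise ValueError("lung volume must be positive")
    out = np.vectorize(psr_drive_scalar)(v, p.v_rest, 1.0 / p.psr_scale)
    return float(out) if np.isscalar(v_lung) else out


def breathing_rate(t: np.ndarray, insp_act: np.ndarray, t0: float,
                   t1: float, threshold: float = 0.5,
                   refractory: float = 0.3) -> float:
    """Breathing rate [bpm] from inspiratory burst onsets in [t0, t1].

    An onset is an upward crossing of ``threshold`` on the normalized
    inspiratory motor output, with a refractory lockout against ripple.
    A window without any burst returns 0 with a warning.
    """
    if t1 <= t0:
        raise ValueError("empty analysis window")
    onsets = events_from_trace(t, insp_act, threshold, refractory)
    onsets = onsets[(onsets >= t0) & (onsets <= t1)]
    if len(onsets) == 0:
        warnings.warn("no inspiratory bursts in the analysis window",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    return 60.0 * len(onsets) / (t1 - t0)
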