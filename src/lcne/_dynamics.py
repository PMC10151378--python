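"""Shared elementary dynamics, numba-compiled.

Every function here is a small, pure piece of the model's right-hand side:
Hodgkin-Huxley channel kinetics, the CO2 gate on the locus-coeruleus leak,
Hill-type neuromodulator gains, lung/gas-exchange increments and the
FitzHugh-Nagumo cardiac cell.  They are compiled with numba so the fused
network integrator in :mod:`lcne._kernel` can call them in its inner loop,
and they are equally callable from Python, which is how the public module
surfaces (:mod:`lcne.neuron_core`, :mod:`lcne.lc_ne`, ...) and the test
suite exercise them.

Units: membrane potential mV, conductance nS, capacitance pF, current pA,
channel time constants ms, partial pressures mmHg, volumes L.  Simulation
time is tracked in seconds outside the membrane equations.
"""

import math

from numba import njit

__all__ = [
    "alpha_k",
    "beta_k",
    "mk_inf",
    "mna_inf",
    "hna_inf",
    "tau_mk",
    "tau_hna",
    "co2_gate_scalar",
    "hill_ne_scalar",
    "hill_ach_scalar",
    "lung_volume_step",
    "psr_drive_scalar",
    "fhn_cell_rhs",
]

_JIT = dict(cache=True, fastmath=True)


@njit(**_JIT)
def alpha_k(v):
    """Potassium activation forward rate; the removable singularity at
    V = -44 mV is evaluated by its analytic limit 0.05."""
    x = v + 44.0
    if abs(x) < 1e-7:
        return 0.05
    return 0.01 * x / (1.0 - math.exp(-x / 5.0))


@njit(**_JIT)
def beta_k(v):
    return 0.17 * math.exp(-(v + 49.0) / 40.0)


@njit(**_JIT)
def mk_inf(v):
    a = alpha_k(v)
    return a / (a + beta_k(v))


@njit(**_JIT)
def mna_inf(v):
    return 1.0 / (1.0 + math.exp(-(v + 34.0) / 7.8))


@njit(**_JIT)
def hna_inf(v):
    return 1.0 / (1.0 + math.exp((v + 55.0) / 7.0))


@njit(**_JIT)
def tau_mk(v):
    """Potassium activation time constant [ms]; peak 3.5 ms at V = -40."""
    return 3.5 / math.cosh((v + 40.0) / 40.0)


@njit(**_JIT)
def tau_hna(v):
    """Sodium inactivation time constant [ms]; peak 8.456 ms at V = -67.5."""
    return 8.456 / math.cosh((v + 67.5) / 12.8)


@njit(**_JIT)
def co2_gate_scalar(pco2, s_scale):
    """CO2 gate phi in (0, 1), strictly decreasing in pCO2.

    phi = 1 - 1 / (1 + (s_half / s)**h_s) with s_half = 10, h_s = 5 and
    s = pco2 / s_scale.  ``s_scale`` fixes the adopted scaling convention
    (default 7.6, i.e. s = pCO2/760 x 100, which keeps chemosensitivity
    alive around the 40 mmHg operating point).
    """
    s = pco2 / s_scale
    return 1.0 - 1.0 / (1.0 + (10.0 / s) ** 5.0)


@njit(**_JIT)
def hill_ne_scalar(p_ne, p_mid, alpha):
    """Sympathetic Hill gain, increasing in the NE pool, 0.5 at p_mid."""
    return 1.0 / (1.0 + (p_mid / p_ne) ** alpha)


@njit(**_JIT)
def hill_ach_scalar(q_ach, q_mid, alpha):
    """Parasympathetic Hill gain, decreasing in the ACh pool, 0.5 at q_mid."""
    return 1.0 - 1.0 / (1.0 + (q_mid / q_ach) ** alpha)


@njit(**_JIT)
def lung_volume_step(v_l, insp_act, exp_act, v_rest, elastance, resistance,
                     p_insp, p_exp, dt):
    """One Euler step of the lumped lung/chest-wall mechanics.

    dV/dt = (P_insp*insp - P_exp*exp - E*(V - V_rest)) / R with pressures
    in mmHg, elastance in mmHg/L and resistance in mmHg/(L/s); passive
    recoil relaxes V toward the rest (functional residual) volume.
    Returns (new volume, flow L/s).
    """
    flow = (p_insp * insp_act - p_exp * exp_act
            - elastance * (v_l - v_rest)) / resistance
    return v_l + dt * flow, flow


@njit(**_JIT)
def psr_drive_scalar(v_l, v_rest, gain):
    """Pulmonary stretch-receptor drive: rectified-linear in lung volume
    above rest, zero at or below the rest volume."""
    x = v_l - v_rest
    if x <= 0.0:
        return 0.0
    return gain * x


@njit(**_JIT)
def fhn_cell_rhs(v, w, gc, b, alpha, d, i_ext):
    """FitzHugh-Nagumo cardiac cell right-hand side with the switched
    excitation rate: c = Gc*1 on the upstroke (dv/dt >= 0), Gc*0.22 on the
    downstroke, evaluated self-consistently from the sign of the cubic
    part.  Returns (dv/dt, dw/dt) excluding diffusion."""
    f = v * (v - alpha) * (1.0 - v) - w
    # the switch depends on sign(dv); evaluate the upstroke branch first
    # (c = Gc*1) and keep it only if it is indeed non-negative, otherwise
    # take the downstroke branch (c = Gc*0.22).
    dv = gc * f + i_ext
    if dv < 0.0:
        dv = gc * 0.22 * f + i_ext
    dw = b * (v - d * w)
    return dv, dw
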