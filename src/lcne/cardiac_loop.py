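"""Cardiac centre, autonomic neuromodulation and FitzHugh-Nagumo heart.

The cardiac centre populations (NTS baroreceptive sets -> CVLM/AMB, CVLM
inhibiting RVLM, the pontine IE bridge from the respiratory CPG, and the
amygdala's inhibition of the baroreceptive NTS) run inside the fused
network integrator.  This module holds the readout chain they drive:

* first-order transmitter pools p_NE (sympathetic, from RVLM firing) and
  q_ACh (parasympathetic, from AMB firing);
* Hill gains H(p_NE) (increasing, midpoint 350, exponent 10) and H(q_ACh)
  (decreasing, midpoint 20, exponent 5);
* the affine maps onto the FHN tissue excitation scale G_c and recovery
  rate b, and the 1-D cardiac cable itself (32 cells, no-flux boundaries,
  pacemaker at cell 0 -- an intrinsically oscillatory cell with a negative
  excitation threshold -- and heart rate read at the distal cell).

The switched excitation rate c = G_c * {1 on the upstroke, 0.22 on the
downstroke} keeps the ratio c2/c1 = 0.22 at every instant by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._dynamics import fhn_cell_rhs, hill_ach_scalar, hill_ne_scalar
from .params import CardiacParams
from .signal_analysis import events_from_trace

__all__ = [
    "CardiacParams", "FHNTissueState", "NeuromodulatorState", "hill_ne",
    "hill_ach", "modulated_fhn_params", "fhn_tissue_step",
    "autonomic_outflow_step", "heart_rate",
]


@dataclass
class NeuromodulatorState:
    """Sympathetic / parasympathetic transmitter pool levels (Hill-scaled,
    dimensionless)."""

    p_ne: float = 350.0
    q_ach: float = 20.0

    def __post_init__(self) -> None:
        if self.p_ne < 0 or self.q_ach < 0:
            raise ValueError("transmitter levels must be non-negative")


@dataclass
class FHNTissueState:
    """FHN cardiac cable state: v (membrane), w (recovery) per cell."""

    v: np.ndarray
    w: np.ndarray
    params: CardiacParams = field(default_factory=CardiacParams)

    @classmethod
    def resting(cls, params: CardiacParams | None = None) -> "FHNTissueState":
        p = params or CardiacParams()
        return cls(v=np.zeros(p.n_cable), w=np.zeros(p.n_cable), params=p)

    def __post_init__(self) -> None:
        if self.v.shape != self.w.shape:
            raise ValueError("v and w must share the cable shape")


def hill_ne(p_ne, p_mid: float = 350.0, alpha: float = 10.0):
    """Sympathetic Hill gain in (0, 1), increasing, H(p_mid) = 0.5."""
    p = np.asarray(p_ne, dtype=float)
    if np.any(p <= 0):
        raise ValueError("p_NE must be positive")
    out = np.vectorize(hill_ne_scalar)(p, p_mid, alpha)
    return float(out) if np.isscalar(p_ne) else out


def hill_ach(q_ach, q_mid: float = 20.0, alpha: float = 5.0):
    """Parasympathetic Hill gain in (0, 1), decreasing, H(q_mid) = 0.5."""
    q = np.asarray(q_ach, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q_ACh must be positive")
    out = np.vectorize(hill_ach_scalar)(q, q_mid, alpha)
    return float(out) if np.isscalar(q_ach) else out


def modulated_fhn_params(h_ne: float, h_ach: float,
                         params: CardiacParams | None = None
                         ) -> tuple[float, float]:
    """Affine neuromodulation of the tissue: G_c = (c_max - c_min) H_NE +
    c_min and b = (b_max - b_min) H_ACh + b_min."""
    p = params or CardiacParams()
    if not (0.0 <= h_ne <= 1.0 and 0.0 <= h_ach <= 1.0):
        raise ValueError("Hill gains must lie in [0, 1]")
    if p.c_min >= p.c_max or p.b_min >= p.b_max:
        raise ValueError("FHN bounds misordered")
    gc = (p.c_max - p.c_min) * h_ne + p.c_min
    b = (p.b_max - p.b_min) * h_ach + p.b_min
    return gc, b


def fhn_tissue_step(state: FHNTissueState, gc: float, b: float,
                    dt: float) -> FHNTissueState:
    """One Euler step of the cable (reference path).

    No-flux boundaries; the pacemaker bias drives cell 0; diffusion is the
    discrete Laplacian, which sums to zero over the cable for any field.
    """
    p = state.params
    v, w = state.v, state.w
    n = len(v)
    v_new = np.empty_like(v)
    w_new = np.empty_like(w)
    for j in range(n):
        lap = 0.0
        if j > 0:
            lap += v[j - 1] - v[j]
        if j < n - 1:
            lap += v[j + 1] - v[j]
        i_ext = p.d_diff * lap
        dv, dw = fhn_cell_rhs(v[j], w[j], gc, b, p.alpha, p.d, i_ext)
        # every cell's recovery nullcline is offset by a graded w_pace, so
        # each is intrinsically oscillatory with the intrinsic rate
        # decreasing along the cable; diffusion entrains the strand to the
        # fastest (pacemaker) end and the excitation propagates with a
        # measurable node-to-distal lag
        woff = p.w_pace * (1.0 - p.pace_grad * j / (n - 1))
        dw = b * (v[j] - p.d * w[j] - woff)
        v_new[j] = v[j] + dt * dv
        w_new[j] = w[j] + dt * dw
    if not np.all(np.isfinite(v_new)) or np.any(np.abs(v_new) > 1e3):
        raise FloatingPointError("cardiac tissue integration blew up")
    state.v, state.w = v_new, w_new
    return state


def autonomic_outflow_step(state: NeuromodulatorState, rvlm_rate: float,
                           amb_rate: float, dt: float,
                           params: CardiacParams | None = None
                           ) -> NeuromodulatorState:
    """First-order transmitter accumulation from population firing.

    d p/dt = (k_NE * r_RVLM - p)/tau; steady level = gain x rate, decay to
    zero without input.  Firing rates are per-neuron averages [Hz].
    """
    p = params or CardiacParams()
    if rvlm_rate < 0 or amb_rate < 0:
        raise ValueError("firing rates must be non-negative")
    state.p_ne += dt * (p.k_ne * rvlm_rate - state.p_ne) / p.tau_mod
    state.q_ach += dt * (p.k_ach * amb_rate - state.q_ach) / p.tau_mod
    return state


def heart_rate(t: np.ndarray, v_sense: np.ndarray, t0: float, t1: float,
               threshold: float = 0.5) -> float:
    """Heart rate [bpm] from upward threshold crossings of the sensing
    cell's membrane potential over [t0, t1]."""
    if t1 <= t0:
        raise ValueError("empty analysis window")
    beats = events_from_trace(t, v_sense, threshold, refractory=0.15)
    beats = beats[(beats >= t0) & (beats <= t1)]
    if len(beats) == 0:
        raise ValueError("no cardiac beats detected in the window")
    return 60.0 * len(beats) / (t1 - t0)
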