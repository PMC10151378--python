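"""Locus coeruleus grid, CO2 gating and norepinephrine release.

The LC is a 15 x 15 grid of excitatory HH neurons coupled by gap junctions
to their 8-neighbourhood (boundary cells keep their existing neighbours; no
wrap-around).  Its leak conductance and excitatory synaptic input are
scaled by the CO2 gate phi (hypercapnia disinhibits the LC), and its pooled
spiking drives a second-order linear cascade

    tau0 dy/dt   = -y + kappa * sum_j delta(t - t_j)
    tau1 dg/dt   = -g_NE + y

whose output g_NE -- the NE-modulated conductance [nS] -- is the model's
scalar arousal readout.  ``kappa`` is the quantal release gain calibrated
once against the resting arousal anchor.

These are the reference implementations; the production integrator fuses
the same arithmetic (see ``lcne._kernel``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._dynamics import co2_gate_scalar
from .neuron_core import HHParams, HHGroupState, membrane_step
from .params import NEParams

__all__ = [
    "LCState", "CO2Gate", "NEParams", "lc_params", "co2_gate",
    "gap_current", "lc_membrane_step", "ne_release_step", "ne_current",
]


@dataclass
class CO2Gate:
    """Sigmoid CO2 gate: phi = 1 - 1/(1 + (s_half/s)^h_s), s = pCO2/scale.

    phi is strictly decreasing in pCO2 with phi = 0.5 at s = s_half.  The
    scaling convention s = pCO2/760 x 100 (scale 7.6) is adopted; it keeps
    phi responsive around the physiological 40 mmHg operating point.
    """

    s_half: float = 10.0
    h_s: float = 5.0
    scale: float = 7.6

    def __call__(self, pco2) -> np.ndarray | float:
        return co2_gate(pco2, self.scale)


def co2_gate(pco2, scale: float = 7.6):
    """CO2 gate phi in (0, 1); rejects non-positive pressures."""
    p = np.asarray(pco2, dtype=float)
    if np.any(p <= 0):
        raise ValueError("pCO2 must be positive")
    out = np.vectorize(co2_gate_scalar)(p, scale)
    return float(out) if np.isscalar(pco2) else out


@dataclass
class LCState:
    """15 x 15 LC grid membrane state plus the NE release cascade."""

    hh: HHGroupState
    side: int = 15
    y: float = 0.0
    g_ne: float = 0.0

    def __post_init__(self) -> None:
        if self.hh.n != self.side * self.side:
            raise ValueError("LC state must be a full grid")
        if self.y < 0 or self.g_ne < 0:
            raise ValueError("NE release variables must be non-negative")

    @property
    def V_grid(self) -> np.ndarray:
        return self.hh.V.reshape(self.side, self.side)


def lc_params(ne: NEParams | None = None, **overrides) -> HHParams:
    """HH constants with the LC overrides (C = 25 pF, tau_mK halved)."""
    ne = ne or NEParams()
    kw = dict(C=ne.lc_C, tau_mK_scale=ne.lc_tau_mk_scale)
    kw.update(overrides)
    return HHParams(**kw)


def gap_current(V_grid: np.ndarray, g_gap: float) -> np.ndarray:
    """Gap-junction current grid [pA]: I_i = sum_j g_gap (V_i - V_j) over
    the 8-neighbourhood.  Pairwise antisymmetric, so the grid total is 0."""
    V = np.asarray(V_grid, dtype=float)
    if V.ndim != 2:
        raise ValueError("expected a rectangular grid")
    padded = np.pad(V, 1, mode="constant")
    acc = np.zeros_like(V)
    cnt = np.zeros_like(V)
    mask = np.pad(np.ones_like(V), 1, mode="constant")
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            nb = padded[1 + dr:1 + dr + V.shape[0], 1 + dc:1 + dc + V.shape[1]]
            m = mask[1 + dr:1 + dr + V.shape[0], 1 + dc:1 + dc + V.shape[1]]
            acc += nb * m
            cnt += m
    return g_gap * (cnt * V - acc)


def lc_membrane_step(state: LCState, phi: float, I_syn_E, I_vib,
                     params: HHParams, ne: NEParams,
                     rng: np.random.Generator | None = None,
                     dt: float | None = None) -> LCState:
    """One Euler-Maruyama step of the LC grid (reference path).

    phi scales both the leak and the excitatory synaptic input; the
    vibration current enters through the -I slot (negative printed
    amplitudes depolarize); gap-junction and NE self-inhibition currents
    are evaluated from the current state.
    """
    if not (0.0 < phi <= 1.0):
        raise ValueError("phi must be in (0, 1]")
    side = state.side
    I_gap = gap_current(state.hh.V.reshape(side, side), ne.g_gap).ravel()
    I_ne = ne_current(state.g_ne, state.hh.V, ne)
    I_ext = phi * np.asarray(I_syn_E) + I_ne + I_gap + np.asarray(I_vib)
    membrane_step(state.hh, I_ext, params, rng=rng, dt=dt, phi=phi)
    return state


def ne_release_step(y: float, g_ne: float, n_spikes: int, dt: float,
                    ne: NEParams | None = None) -> tuple[float, float]:
    """One Euler step of the NE cascade.

    Each LC spike contributes a unit-area impulse scaled by the release
    gain kappa, so the long-run mean of g_NE equals kappa times the pooled
    LC spike rate [Hz].
    """
    ne = ne or NEParams()
    if n_spikes < 0:
        raise ValueError("spike count must be non-negative")
    y_new = y + dt * (-y) / ne.tau0 + ne.kappa * n_spikes / ne.tau0
    g_new = g_ne + dt * (y - g_ne) / ne.tau1
    return y_new, g_new


def ne_current(g_ne: float, V, ne: NEParams | None = None):
    """NE self-inhibition current [pA]: g_NE0 * g_NE * (V - V_syn_I);
    zero at the inhibitory reversal (-75 mV) and linear in g_NE."""
    ne = ne or NEParams()
    if g_ne < 0:
        raise ValueError("g_NE must be non-negative")
    return ne.g_ne0 * g_ne * (np.asarray(V, dtype=float) - ne.v_syn_i)
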