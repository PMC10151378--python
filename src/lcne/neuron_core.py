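"""Noisy Hodgkin-Huxley population dynamics and conductance synapses.

This module is the *reference* implementation of the membrane model every
brainstem population in the package shares: a single-compartment HH neuron
with a potassium current g_K*mK^4*(V-EK), a sodium current with
instantaneous activation g_Na*mNa_inf(V)^3*hNa*(V-ENa), an ohmic leak and
an additive Gaussian current noise, integrated with the Euler /
Euler-Maruyama method.  The production integrator in ``lcne._kernel``
re-implements the same equations in a fused numba loop for speed; the two
are held together by an exact-equivalence test in the suite.

Sign convention: every ionic, synaptic or injected term enters the voltage
equation as ``C dV/dt = -(sum of currents)``, so a *negative* injected
current depolarizes.

Default constants (capacitance 36 pF, peak conductances 250/400/6 nS,
reversals -94/55/-60 mV, noise strength D = 20, step 1e-4 s) describe the
generic brainstem neuron; individual populations override them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

__all__ = [
    "HHParams",
    "HHGroupState",
    "SynapticProjection",
    "RateFunctions",
    "TimeConstants",
    "rate_functions",
    "time_constants",
    "gating_step",
    "membrane_step",
    "synaptic_current",
    "noise_sigma",
    "SPIKE_THRESHOLD_MV",
    "REFRACTORY_S",
]

#: Upward-crossing voltage that registers a spike [mV].
SPIKE_THRESHOLD_MV = -20.0
#: Dead time after a registered spike during which crossings are ignored [s].
REFRACTORY_S = 2e-3


@dataclass
class HHParams:
    """Biophysical constants of one HH population.

    ``D`` is the printed noise strength; the per-step current deviate is
    ``sqrt(2 D / noise_dt_eff) * N(0, 1)`` pA (an Euler-Maruyama reading of
    the white-noise term in which ``noise_dt_eff`` [s] sets the effective
    bandwidth of the noise; it was fixed once, against the baseline firing
    targets, and is not a per-run tuning knob).
    """

    C: float = 36.0          # membrane capacitance [pF]
    gK_bar: float = 250.0    # peak potassium conductance [nS]
    gNa_bar: float = 400.0   # peak sodium conductance [nS]
    gL: float = 6.0          # leak conductance [nS]
    EK: float = -94.0        # [mV]
    ENa: float = 55.0        # [mV]
    EL: float = -60.0        # leak reversal mean [mV]
    EL_sd: float = 1.2       # per-neuron leak-reversal spread [mV]
    D: float = 20.0          # noise strength as printed
    dt: float = 1.0e-4       # integration step [s]
    noise_dt_eff: float = 5.0e-4   # noise discretization window [s]
    tau_mK_scale: float = 1.0      # population tau_mK multiplier (LC: 0.5)

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("capacitance must be positive")
        if min(self.gK_bar, self.gNa_bar, self.gL) < 0:
            raise ValueError("conductances must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def with_(self, **kw) -> "HHParams":
        return replace(self, **kw)


def noise_sigma(params: HHParams) -> float:
    """Per-step Gaussian current deviate amplitude [pA]."""
    if params.D <= 0:
        return 0.0
    return float(np.sqrt(2.0 * params.D / params.noise_dt_eff))


@dataclass
class HHGroupState:
    """Membrane state of one population (vectors of length group size)."""

    V: np.ndarray
    mK: np.ndarray
    hNa: np.ndarray
    EL: np.ndarray
    spiked: np.ndarray = field(default=None)          # bool, this step
    refrac: np.ndarray = field(default=None)          # steps left refractory

    def __post_init__(self) -> None:
        n = self.V.shape[0]
        for name in ("mK", "hNa", "EL"):
            if getattr(self, name).shape[0] != n:
                raise ValueError("state vectors must share the group size")
        if self.spiked is None:
            self.spiked = np.zeros(n, dtype=bool)
        if self.refrac is None:
            self.refrac = np.zeros(n, dtype=np.int64)

    @property
    def n(self) -> int:
        return self.V.shape[0]

    @classmethod
    def at_rest(cls, n: int, params: HHParams, rng: np.random.Generator
                ) -> "HHGroupState":
        """Group initialized at its leak reversal with per-neuron EL jitter
        drawn from N(EL, EL_sd)."""
        el = params.EL + params.EL_sd * rng.standard_normal(n)
        v = el.copy()
        return cls(V=v, mK=rate_functions(v).mK_inf.copy(),
                   hNa=rate_functions(v).hNa_inf.copy(), EL=el)


@dataclass
class SynapticProjection:
    """A pooled conductance synapse between two named populations.

    The gate ``g`` is a single exponential driven by presynaptic spikes
    (increment 1/N_source per spike so the weight is a per-source-rate
    conductance) and the postsynaptic current is
    ``weight * g * (V_post - E_rev)``, entering the voltage equation with
    the global minus sign, so E_rev = 0 mV depolarizes from rest and
    E_rev = -75 mV hyperpolarizes.
    """

    source: str
    target: str
    weight: float                 # [nS]
    polarity: str = "excitatory"  # or "inhibitory"
    E_rev: float | None = None    # [mV]; default by polarity
    tau: float | None = None      # [ms]; default 5 exc / 10 inh
    gate: float = 0.0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("synaptic weight must be non-negative")
        if self.polarity not in ("excitatory", "inhibitory"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.E_rev is None:
            self.E_rev = 0.0 if self.polarity == "excitatory" else -75.0
        if self.tau is None:
            self.tau = 5.0 if self.polarity == "excitatory" else 10.0
        depol = self.E_rev > -55.0
        if depol != (self.polarity == "excitatory"):
            raise ValueError("reversal potential inconsistent with polarity")


class RateFunctions(NamedTuple):
    alphaK: np.ndarray
    betaK: np.ndarray
    mK_inf: np.ndarray
    mNa_inf: np.ndarray
    hNa_inf: np.ndarray


class TimeConstants(NamedTuple):
    tau_mK: np.ndarray   # [ms]
    tau_hNa: np.ndarray  # [ms]


def _check_finite(V) -> np.ndarray:
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane potential must be finite")
    return V


def rate_functions(V) -> RateFunctions:
    """Steady-state channel variables and potassium rates at voltage V.

    The potassium forward rate 0.01(V+44)/(1-exp(-(V+44)/5)) has a
    removable singularity at V = -44 mV which is evaluated by its limit
    0.05, keeping alphaK continuous.
    """
    V = _check_finite(V)
    x = V + 44.0
    with np.errstate(over="ignore"):
        den = 1.0 - np.exp(-x / 5.0)
    aK = np.where(np.abs(x) < 1e-7, 0.05,
                  0.01 * x / np.where(den == 0.0, np.inf, den))
    bK = 0.17 * np.exp(-(V + 49.0) / 40.0)
    return RateFunctions(
        alphaK=aK,
        betaK=bK,
        mK_inf=aK / (aK + bK),
        mNa_inf=1.0 / (1.0 + np.exp(-(V + 34.0) / 7.8)),
        hNa_inf=1.0 / (1.0 + np.exp((V + 55.0) / 7.0)),
    )


def time_constants(V, tau_mK_scale: float = 1.0) -> TimeConstants:
    """Channel time constants [ms]; maxima 3.5 ms at V = -40 (tau_mK) and
    8.456 ms at V = -67.5 (tau_hNa)."""
    V = _check_finite(V)
    return TimeConstants(
        tau_mK=tau_mK_scale * 3.5 / np.cosh((V + 40.0) / 40.0),
        tau_hNa=8.456 / np.cosh((V + 67.5) / 12.8),
    )


def gating_step(x, tau_ms, x_inf, dt: float):
    """First-order relaxation of a gating variable over one step.

    ``x' = x + (dt/tau) (x_inf - x)``, clamped to [0, 1] to guard Euler
    overshoot.  dt is in seconds, tau in ms.  A step larger than the time
    constant is flagged as an unstable configuration.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    dt_ms = dt * 1e3
    if np.any(dt_ms >= np.asarray(tau_ms)):
        warnings.warn("integration step exceeds a gating time constant; "
                      "the Euler update is unstable", RuntimeWarning,
                      stacklevel=2)
    x = np.asarray(x, dtype=float)
    return np.clip(x + (dt_ms / np.asarray(tau_ms)) * (np.asarray(x_inf) - x),
                   0.0, 1.0)


def membrane_step(state: HHGroupState, I_ext, params: HHParams,
                  rng: np.random.Generator | None = None,
                  dt: float | None = None, phi: float = 1.0) -> HHGroupState:
    """Advance a population one Euler-Maruyama step (in place).

    ``I_ext`` [pA] is the total extra current per neuron (synaptic, gap,
    injected), entering with the -I convention.  ``phi`` scales the leak
    conductance (the CO2 gate of the LC; 1 elsewhere).  Spikes are upward
    crossings of -20 mV with a 2 ms refractory lockout.
    """
    if dt is None:
        dt = params.dt
    dt_ms = dt * 1e3
    V = state.V
    rf = rate_functions(V)
    tc = time_constants(V, params.tau_mK_scale)

    I_ion = (params.gK_bar * state.mK ** 4 * (V - params.EK)
             + params.gNa_bar * rf.mNa_inf ** 3 * state.hNa * (V - params.ENa)
             + phi * params.gL * (V - state.EL))
    I_noise = 0.0
    sig = noise_sigma(params)
    if sig > 0.0 and rng is not None:
        I_noise = sig * rng.standard_normal(state.n)
    v_new = V + dt_ms * (-(I_ion + np.asarray(I_ext) + I_noise) / params.C)
    if not np.all(np.isfinite(v_new)) or np.any(np.abs(v_new) > 500.0):
        raise FloatingPointError("membrane potential overflow; aborting run")

    state.mK = np.clip(state.mK + (dt_ms / tc.tau_mK) * (rf.mK_inf - state.mK),
                       0.0, 1.0)
    state.hNa = np.clip(
        state.hNa + (dt_ms / tc.tau_hNa) * (rf.hNa_inf - state.hNa), 0.0, 1.0)

    crossed = (V < SPIKE_THRESHOLD_MV) & (v_new >= SPIKE_THRESHOLD_MV)
    state.spiked = crossed & (state.refrac <= 0)
    refrac_steps = max(1, int(round(REFRACTORY_S / dt)))
    state.refrac = np.where(state.spiked, refrac_steps,
                            np.maximum(state.refrac - 1, 0))
    state.V = v_new
    return state


def synaptic_current(proj: SynapticProjection, V_post) -> np.ndarray:
    """Postsynaptic current vector [pA] for the projection's current gate:
    ``weight * gate * (V_post - E_rev)`` (zero exactly at the reversal)."""
    V_post = np.asarray(V_post, dtype=float)
    return proj.weight * proj.gate * (V_post - proj.E_rev)


def decay_gate(proj: SynapticProjection, n_source_spikes: int,
               n_source: int, dt: float) -> None:
    """Exponential gate update for one step: decay with tau then add
    1/N_source per presynaptic spike."""
    if n_source <= 0:
        raise ValueError("projection source group is empty")
    proj.gate *= np.exp(-dt * 1e3 / proj.tau)
    proj.gate += n_source_spikes / n_source
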