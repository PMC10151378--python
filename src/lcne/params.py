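"""Network configuration: populations, wiring and calibrated constants.

The printed biophysics (HH constants, LC grid and gap junctions, NE release
time constants, Hill midpoints/exponents, the human lung/gas constants) are
fixed here at their published values.  Everything the source architecture
leaves open -- synaptic weights, tonic biases, adaptation constants of the
bursting populations, the FitzHugh-Nagumo shape/bound parameters and the
autonomic gain constants -- is a calibration parameter.  Those were tuned
once, against the resting-state anchors (breathing rate 16 bpm, heart rate
68 bpm, NE-modulated conductance 60 nS) and the entrainment phenomenology,
and then frozen; see docs/methods.md for the procedure.  They are plain
dataclass fields so a study can still override any of them explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["NetworkConfig", "POPULATIONS", "SCALED_POPULATIONS",
           "PROJECTIONS", "default_weights", "default_biases",
           "default_field_gains", "LC_GRID_SIDE"]

LC_GRID_SIDE = 15

#: Population name -> default size.  The LC is a 15 x 15 grid; the eight
#: medullary/pontine groups carry the printed counts (amygdala 20, RTN 40,
#: RVLM/CVLM/AMB 30, NTS Baro 20+20, NTS Chemo 30+30, IE 30+30); the four
#: respiratory CPG populations are reconstructed at 20 neurons each.
POPULATIONS: tuple[tuple[str, int], ...] = (
    ("LC", LC_GRID_SIDE * LC_GRID_SIDE),
    ("AMY", 20),
    ("NTS_CHEMO_A", 30),   # lung CO2 signal -> amygdala
    ("NTS_CHEMO_B", 30),   # peripheral chemoreceptors -> RTN, preI/I, RVLM
    ("RTN", 40),
    ("PREI", 20),          # preI/I (pre-Boetzinger) inspiratory burster
    ("RAMPI", 20),         # ramp-I inspiratory premotor
    ("POSTI", 20),         # post-I inhibitory (phase-switch companion)
    ("LATEE", 20),         # late-E expiratory
    ("CVRG", 20),          # caudal ventral respiratory group relay
    ("NTSB_E", 20),
    ("NTSB_I", 20),
    ("IE_E", 30),
    ("IE_I", 30),
    ("CVLM", 30),
    ("RVLM", 30),
    ("AMB", 30),
)

POP_INDEX = {name: i for i, (name, _) in enumerate(POPULATIONS)}

#: Populations whose size follows the neuron-count multiplier in the
#: parametric scan (the eight groups the scan enumerates; exc/inh sets
#: scale together).
SCALED_POPULATIONS = ("AMY", "RTN", "RVLM", "CVLM", "AMB",
                      "NTSB_E", "NTSB_I", "NTS_CHEMO_A", "NTS_CHEMO_B",
                      "IE_E", "IE_I")

#: (name, source, target, polarity).  Reversal 0 mV / tau 5 ms for
#: excitatory, -75 mV / 10 ms for inhibitory projections; excitatory
#: projections onto the LC are additionally scaled by the CO2 gate phi.
PROJECTIONS: tuple[tuple[str, str, str, str], ...] = (
    ("prei_rec",    "PREI",        "PREI",   "excitatory"),
    ("prei_rampi",  "PREI",        "RAMPI",  "excitatory"),
    ("prei_posti",  "PREI",        "POSTI",  "excitatory"),
    ("posti_prei",  "POSTI",       "PREI",   "inhibitory"),
    ("posti_rampi", "POSTI",       "RAMPI",  "inhibitory"),
    ("posti_latee", "POSTI",       "LATEE",  "inhibitory"),
    ("posti_rtn",   "POSTI",       "RTN",    "inhibitory"),
    ("prei_lc",     "PREI",        "LC",     "excitatory"),
    ("rampi_latee", "RAMPI",       "LATEE",  "inhibitory"),
    ("latee_cvrg",  "LATEE",       "CVRG",   "excitatory"),
    ("rtn_prei",    "RTN",         "PREI",   "excitatory"),
    ("rtn_prei_s",  "RTN",         "PREI",   "excitatory"),
    ("rtn_latee",   "RTN",         "LATEE",  "excitatory"),
    ("lc_rtn",      "LC",          "RTN",    "excitatory"),
    ("lc_amy",      "LC",          "AMY",    "excitatory"),
    ("amy_lc",      "AMY",         "LC",     "excitatory"),
    ("chemoa_amy",  "NTS_CHEMO_A", "AMY",    "excitatory"),
    ("chemob_rtn",  "NTS_CHEMO_B", "RTN",    "excitatory"),
    ("chemob_prei", "NTS_CHEMO_B", "PREI",   "excitatory"),
    ("chemob_rvlm", "NTS_CHEMO_B", "RVLM",   "excitatory"),
    ("rampi_iee",   "RAMPI",       "IE_E",   "excitatory"),
    ("rampi_iei",   "RAMPI",       "IE_I",   "excitatory"),
    ("latee_iei",   "LATEE",       "IE_I",   "excitatory"),
    ("ntsbe_cvlm",  "NTSB_E",      "CVLM",   "excitatory"),
    ("ntsbe_amb",   "NTSB_E",      "AMB",    "excitatory"),
    ("amy_ntsbi",   "AMY",         "NTSB_I", "excitatory"),
    ("ntsbi_ntsbe", "NTSB_I",      "NTSB_E", "inhibitory"),
    ("cvlm_rvlm",   "CVLM",        "RVLM",   "inhibitory"),
    ("iee_rvlm",    "IE_E",        "RVLM",   "excitatory"),
    ("iei_amb",     "IE_I",        "AMB",    "inhibitory"),
)

#: One global conductance unit [nS] for the dimensionless weight table
#: below; the preI/I -> LC strength is the literature's 0.1 in these units.
SYN_UNIT_NS = 30.0


def default_weights() -> dict[str, float]:
    """Dimensionless synaptic weights (multiplied by SYN_UNIT_NS)."""
    return {
        "prei_rec":    0.22,
        "prei_rampi":  0.35,
        "prei_posti":  0.20,
        "posti_prei":  0.25,
        "posti_rampi": 0.20,
        "posti_latee": 0.10,
        "posti_rtn":   0.10,
        "prei_lc":     0.10,   # printed relative strength
        "rampi_latee": 0.20,
        "latee_cvrg":  1.00,
        "rtn_prei":    2.20,
        "rtn_prei_s":  0.0008,
        "rtn_latee":   0.10,
        "lc_rtn":      0.55,
        "lc_amy":      0.04,
        "amy_lc":      0.01,
        "chemoa_amy":  0.06,
        "chemob_rtn":  0.10,
        "chemob_prei": 0.05,
        "chemob_rvlm": 0.08,
        "rampi_iee":   0.50,
        "rampi_iei":   0.50,
        "latee_iei":   0.13,
        "ntsbe_cvlm":  0.60,
        "ntsbe_amb":   0.80,
        "amy_ntsbi":   3.00,
        "ntsbi_ntsbe": 1.20,
        "cvlm_rvlm":   0.50,
        "iee_rvlm":    0.35,
        "iei_amb":     0.05,
    }


def default_biases() -> dict[str, float]:
    """Tonic depolarizing bias current per population [pA]."""
    return {
        "LC": -30.0,
        "AMY": -58.0,
        "NTS_CHEMO_A": -18.0,  # cancels the resting chemo-field drive
        "NTS_CHEMO_B": -18.0,
        "RTN": -85.0,
        "PREI": -37.0,
        "RAMPI": -10.0,
        "POSTI": -35.0,
        "LATEE": -70.0,
        "CVRG": -10.0,
        "NTSB_E": 1.0,
        "NTSB_I": -20.0,
        "IE_E": -20.0,
        "IE_I": -20.0,
        "CVLM": -6.0,
        "RVLM": 6.0,
        "AMB": 0.0,
    }


def default_field_gains() -> dict[str, dict[str, float]]:
    """Scalar-signal current gains [pA per unit signal] per population.

    ``chem``  peripheral chemoreceptor signal (sigmoid of arterial pCO2),
    ``cchem`` central chemoreceptor signal (sigmoid of brain pCO2),
    ``psr``   pulmonary stretch-receptor signal (normalized lung stretch).
    """
    return {
        "chem":  {"NTS_CHEMO_A": 36.0, "NTS_CHEMO_B": 36.0},
        "cchem": {"RTN": 30.0, "LATEE": 60.0},
        "psr":   {"NTSB_E": 60.0},
    }


def default_adaptation() -> dict[str, tuple[float, float]]:
    """Spike-triggered adaptation (increment nS, time constant s) for the
    bursting/burst-shaping populations; unlisted populations have none."""
    return {
        "PREI":  (1.4, 2.2),
        "RAMPI": (0.30, 0.8),
        "LATEE": (0.30, 1.5),
        "AMY":   (0.15, 1.0),
    }


@dataclass
class LungGasParams:
    """Human lung mechanics and alveolar/arterial gas exchange.

    Elastance, capillary volume, diffusion capacities, the reaction
    acceleration factor and the heart period are the published adult-human
    values; the mechanical resistance, rest volume, muscle pressure gains
    and the blood CO2/O2 capacitances close the loop and are this
    package's own constants.
    """

    elastance: float = 3.659       # [mmHg/L]
    heart_period: float = 0.833    # capillary transit time T_L [s]
    v_cap: float = 0.070           # lung capillary volume [L]
    delta: float = 10 ** 1.9       # chemical reaction acceleration [-]
    d_co2: float = 7.08e-3         # CO2 diffusion capacity [L/mmHg/s]
    d_o2: float = 3.5e-4           # O2 diffusion capacity [L/mmHg/s]
    tau_m2: float = 2.0            # pump-muscle gating time constants [s]
    tau_m3: float = 2.0
    v_rest: float = 2.0            # functional residual capacity [L]
    resistance: float = 1.2        # airway+tissue resistance [mmHg/(L/s)]
    p_insp: float = 3.2            # inspiratory muscle pressure gain [mmHg]
    p_exp: float = 2.0             # abdominal (active expiration) gain
    s_co2_blood: float = 0.0057    # blood CO2 content slope [L/L/mmHg]
    s_o2_blood: float = 0.0031
    beta_co2: float = 0.08         # body CO2 store capacitance [L/mmHg]
    beta_o2: float = 0.012
    m_co2: float = 4.2e-3          # metabolic CO2 production [L/s]
    m_o2: float = 4.5e-3           # metabolic O2 consumption [L/s]
    po2_air: float = 149.0         # inspired pO2 [mmHg]
    chem_mid: float = 40.0         # peripheral chemo sigmoid midpoint [mmHg]
    chem_width: float = 2.5        # [mmHg]
    tau_brain: float = 10.0        # brain pCO2 lag [s]
    tau_motor: float = 0.05        # motor-output low-pass [s]
    r_norm_insp: float = 12.0      # filtered rate mapping to insp_act = 1 [Hz]
    r_norm_exp: float = 25.0
    psr_scale: float = 0.5         # lung stretch [L] mapping to psr = 1

    @property
    def g_co2(self) -> float:
        """Serial diffusion+perfusion CO2 transfer conductance [L/s/mmHg]."""
        perf = self.v_cap * self.s_co2_blood / self.heart_period
        diff = self.delta * self.d_co2
        return 1.0 / (1.0 / diff + 1.0 / perf)

    @property
    def g_o2(self) -> float:
        perf = self.v_cap * self.s_o2_blood / self.heart_period
        diff = self.delta * self.d_o2
        return 1.0 / (1.0 / diff + 1.0 / perf)


@dataclass
class CardiacParams:
    """FitzHugh-Nagumo tissue, Hill gains and autonomic transmitter pools.

    The Hill midpoints and exponents are the published values; the tissue
    shape constants, conduction/recovery bounds and the transmitter gains
    are calibration parameters frozen against the 68 bpm resting anchor.
    """

    n_cable: int = 32
    d_diff: float = 15.0          # cable diffusion [1/s]
    alpha: float = 0.15           # excitation threshold shape
    w_pace: float = 0.3           # recovery offset of the pacemaker end
    pace_grad: float = 0.3        # intrinsic-rate gradient along the cable
    d: float = 0.4                # recovery coupling shape
    c_min: float = 24.0           # G_c bounds [1/s]
    c_max: float = 49.0
    b_min: float = 1.2            # recovery-rate bounds [1/s]
    b_max: float = 8.2
    p_ne_mid: float = 350.0
    q_ach_mid: float = 20.0
    alpha_ne: float = 10.0
    alpha_ach: float = 5.0
    tau_mod: float = 5.0          # transmitter pool time constant [s]
    tau_rate: float = 0.5         # firing-rate estimator time constant [s]
    k_ne: float = 188.0           # pool units per Hz of RVLM rate (overridden
    k_ach: float = 1.68           # by the set-point normalization below)
    #: resting-state pool set-points: on assembly the gains k_ne/k_ach are
    #: normalized per network instance so the no-stimulation pools settle
    #: at these values (the counterpart of adjusting the Hill constants to
    #: reproduce the resting rates); disable with auto_setpoint=False.
    p_ne_set: float = 312.0
    q_ach_set: float = 22.5
    auto_setpoint: bool = True
    beat_threshold: float = 0.5   # upward v crossing at the sensing cell


@dataclass
class NEParams:
    """LC NE release cascade and its postsynaptic constants."""

    tau0: float = 0.100           # release rise time constant [s]
    tau1: float = 0.300           # conductance decay time constant [s]
    g_ne0: float = 0.03e-3        # NE->LC self-inhibition unit [nS]
    v_syn_i: float = -75.0        # inhibitory reversal [mV]
    kappa: float = 0.229           # quantal release gain per spike [-]
    g_gap: float = 0.005          # LC gap-junction conductance [nS]
    lc_C: float = 25.0            # LC capacitance [pF]
    lc_tau_mk_scale: float = 0.5  # tau_mK numerator 1.75 instead of 3.5
    s_scale: float = 7.6          # CO2 gate scaling: s = pCO2 / 7.6


@dataclass
class NetworkConfig:
    """Full assembly configuration for the coupled model."""

    size_multiplier: float = 1.0
    dt: float = 1.0e-4                  # [s]
    noise_dt_eff: float = 5.0e-4        # noise discretization window [s]
    noise_D: float = 20.0               # noise strength (0 disables)
    el_mean: float = -60.0
    el_sd: float = 1.2
    weights: dict = field(default_factory=default_weights)
    #: per-projection synaptic time-constant overrides [ms] (defaults:
    #: 5 ms excitatory / 10 ms inhibitory); the preI/I recurrent
    #: excitation is slow (NMDA-like) to sustain inspiratory bursts.
    syn_tau: dict = field(default_factory=lambda: {
        "prei_rec": 120.0, "posti_prei": 500.0, "posti_rampi": 400.0,
        "posti_rtn": 400.0, "rtn_prei": 25.0, "rtn_prei_s": 1500.0,
        "lc_rtn": 50.0, "lc_amy": 300.0})
    #: per-projection short-term depression (U per presynaptic spike,
    #: recovery time constant s); the phasic RTN -> preI/I kick pathway is
    #: strongly depressing, which makes it transmit discrete vibration
    #: kicks but not sustained high-frequency drive.
    depression: dict = field(default_factory=lambda: {"rtn_prei": (0.85, 2.0)})
    biases: dict = field(default_factory=default_biases)
    field_gains: dict = field(default_factory=default_field_gains)
    adaptation: dict = field(default_factory=default_adaptation)
    lung: LungGasParams = field(default_factory=LungGasParams)
    cardiac: CardiacParams = field(default_factory=CardiacParams)
    ne: NEParams = field(default_factory=NEParams)
    include: tuple[str, ...] = tuple(name for name, _ in POPULATIONS)
    lc_grid_side: int = LC_GRID_SIDE
    record_stride: int = 10             # record every N steps (1 ms)

    def sizes(self) -> dict[str, int]:
        out = {}
        for name, n in POPULATIONS:
            if name not in self.include:
                continue
            if name == "LC":
                out[name] = self.lc_grid_side * self.lc_grid_side
            elif name in SCALED_POPULATIONS:
                out[name] = max(1, int(round(n * self.size_multiplier)))
            else:
                out[name] = n
        return out

    def with_(self, **kw) -> "NetworkConfig":
        return replace(self, **kw)

    def validate(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.size_multiplier <= 0:
            raise ValueError("size multiplier must be positive")
        known = {name for name, _ in POPULATIONS}
        unknown = set(self.include) - known
        if unknown:
            raise ValueError(f"unknown populations in include: {unknown}")
        for name, src, tgt, _pol in PROJECTIONS:
            if name not in self.weights:
                raise ValueError(f"projection {name} has no weight entry")
        if self.cardiac.c_min >= self.cardiac.c_max:
            raise ValueError("FHN conduction bounds misordered")
        if self.cardiac.b_min >= self.cardiac.b_max:
            raise ValueError("FHN recovery bounds misordered")
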