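# Methods

`lcne` simulates the coupling between the locus coeruleus–norepinephrine
(LC–NE) arousal system and the cardio-respiratory system, and predicts how
sinusoidal vibration input to the LC changes arousal level, breathing rate
(BR) and heart rate (HR). This note documents the model equations, the
reconstruction choices the package had to make, the one-time calibration,
and what the simulations do and do not show.

## Membrane model

Every brainstem population is a group of single-compartment
Hodgkin–Huxley neurons

    C dV/dt = −ḡ_K mK⁴ (V−E_K) − ḡ_Na mNa³ hNa (V−E_Na)
              − g_L (V−E_L) − I − √(2D) ξ(t)

with C = 36 pF, ḡ_K = 250 nS, ḡ_Na = 400 nS, g_L = 6 nS, E_K = −94 mV,
E_Na = 55 mV and E_L drawn per neuron from N(−60, 1.2) mV. Sodium
activation is instantaneous (mNa = mNa∞(V)); the potassium activation and
sodium inactivation relax with the voltage-dependent time constants
τ_mK = 3.5/cosh((V+40)/40) ms and τ_hNa = 8.456/cosh((V+67.5)/12.8) ms.
The steady-state curves are the standard Boltzmann/ratio forms with the
removable singularity of the potassium forward rate at V = −44 mV
evaluated by its analytic limit (0.05). Integration is forward Euler at
dt = 1e−4 s; gating variables are clamped to [0,1] after each step to
guard Euler overshoot.

**Noise.** The printed noise strength D = 20 "pA" is dimensionally
incomplete for a white-noise current. We read the noise term
Euler–Maruyama style: each step adds a current deviate
σ_I·N(0,1) with σ_I = √(2D/dt_eff) and an effective discretization
window dt_eff = 5e−4 s (σ_I ≈ 283 pA, stationary membrane-potential
s.d. ≈ 4–7 mV depending on capacitance). dt_eff was fixed once so that an
isolated neuron at its default bias fires irregularly at ~0.5–2 Hz and an
isolated LC cell at ~1 Hz, and is not a per-run tuning knob.

**Spikes** are upward crossings of −20 mV with a 2 ms refractory lockout.

**Synapses.** Projections are population-pooled conductances: a single
gate per projection decays exponentially (5 ms excitatory / 10 ms
inhibitory unless stated) and increments by 1/N_source per presynaptic
spike; the postsynaptic current is w·g·(V−E_rev) with E_rev = 0 mV
(excitatory) or −75 mV (inhibitory). Weights are dimensionless multiples
of one global conductance unit (30 nS). Two projections deviate from the
default kinetics on purpose (see *Entrainment mechanism*).

## LC grid and arousal readout

The LC is a 15×15 grid of excitatory HH cells (C = 25 pF, τ_mK numerator
1.75 ms) coupled by gap junctions (g_gap = 0.005 nS) to their
8-neighbourhood; boundary cells keep their existing neighbours (no
wrap-around). The CO₂ gate φ = 1 − 1/(1+(10/s)⁵) with s = pCO₂/7.6
scales both the LC leak and its excitatory synaptic input; of the two
readings of the printed scaling we adopted the one that keeps φ responsive
near the 40 mmHg operating point (φ(40) ≈ 0.961).

Pooled LC spikes drive the NE release cascade
τ₀ ẏ = −y + κ Σδ(t−t_j), τ₁ ġ_NE = −g_NE + y with τ₀ = 100 ms,
τ₁ = 300 ms. The long-run mean of g_NE is κ × (pooled LC rate in Hz);
the quantal gain κ = 0.229 was calibrated once against the resting arousal
anchor g_NE ≈ 60 nS and frozen. g_NE feeds back onto the LC itself as a
weak inhibitory conductance g_NE⁰·g_NE·(V+75) with g_NE⁰ = 3e−5 nS.

The vibration input I_vib = A·sin(2πf t) is injected identically into
every LC cell through the −I slot of the membrane equation, so the
printed negative amplitudes are depolarizing ("excitatory stimulation").

## Respiratory loop

The respiratory central pattern generator is reconstructed, not copied:
the source architecture fixes the closed-loop topology (RTN
chemoreception, preI/I and ramp-I inspiratory populations, late-E
expiration, pulmonary stretch and blood-gas feedback) but not the cellular
parameters. Our reconstruction:

* **preI/I (20 cells)** is the inspiratory burster: slow recurrent
  excitation (NMDA-like, τ = 120 ms) plus spike-triggered adaptation (an
  outward conductance incremented 1.4 nS per spike, decaying with
  τ_a = 2.2 s) produces all-or-none population bursts; the burst
  frequency rises with tonic drive, which is what lets the rhythm be
  pushed from its resting ~0.27 Hz to ~0.5 Hz by strong stimulation.
* **post-I (20 cells)** is the inhibitory phase switch: silent unless
  driven by preI/I, it inhibits preI/I, ramp-I, late-E and the RTN with
  slow gates (0.4–0.5 s), suppressing echo bursts and giving the rhythm
  its low cycle-to-cycle variability (CV ≈ 0.1).
* **ramp-I (20 cells)** relays preI/I bursts to the inspiratory motor
  output; **late-E (20 cells)** is kept subthreshold at normocapnia and
  recruited by RTN drive under hypercapnia, relayed by the cVRG to the
  abdominal (active expiration) output.
* Motor outputs are low-pass filtered (80 ms) normalized pooled rates,
  clipped to [0, 1].

**Lung and gas exchange.** Lung volume follows
dV_L/dt = (P_i·insp − P_e·exp − E·(V_L−V_rest))/R with the published
human elastance E = 3.659 mmHg/L, V_rest = 2.0 L, R = 1.2 mmHg/(L/s).
Alveolar and arterial CO₂/O₂ tensions exchange through a serial
diffusion–perfusion conductance built from the published constants
(δ = 10^1.9, D_CO₂ = 7.08e−3 and D_O₂ = 3.5e−4 L/mmHg/s, capillary
volume 0.070 L, transit time 0.833 s); inspiratory airflow dilutes the
alveolar gas, metabolism loads the arterial pools, and the loop settles
near 40 mmHg arterial pCO₂. Central chemoreception sees arterial pCO₂
through a 10 s first-order lag. The τ_m2 = τ_m3 = 2.0 s pump-muscle
gating constants of the source lung model are carried in the parameter
set for completeness; the lumped first-order mechanics above does not
expose separate pump-muscle gates.

**Readouts.** BR = 60 × (inspiratory onsets)/(window), an onset being an
upward crossing of 0.5 on insp_act with a 0.3 s lockout.

## Entrainment mechanism

The LC excites the RTN, the RTN drives preI/I, and preI/I excites the LC
back (relative strength 0.1, the printed value). Three deliberate
filter choices shape how vibration frequency maps onto the rhythm — these
are the package's mechanistic account of the 1:1 → 2:1 → 4:1 → PAC mode
cascade:

1. **LC→RTN is slow (τ = 50 ms) and the RTN is a threshold detector**
   (deep tonic hyperpolarization). Vibration synchronizes LC spikes into
   per-cycle pulses; the 50 ms synapse passes ≤2 Hz pulses intact but
   smears ≥10 Hz pulses into near-tonic drive, so the RTN's rectified
   response — and with it the phasic "kick" delivered to preI/I — falls
   steeply with stimulus frequency.
2. **RTN→preI/I has two components:** a fast kick synapse (25 ms) with
   strong short-term depression (recovery ≈ 2 s), which transmits
   discrete kicks after sufficient silent gaps but depresses under rapid
   firing; and a weak slow synapse (1.5 s) that integrates the RTN mean
   rate and carries the tonic, frequency-independent part of the drive.
3. **The burster's recovery clock** (adaptation τ_a plus the post-I
   gate) sets which kicks can re-ignite a burst: wide low-frequency kicks
   capture the rhythm 1:1 up to ~1.3 Hz; at 1.7–3 Hz only every second
   to fourth kick finds a recovered oscillator (2:1, 4:1); at ≥5 Hz the
   kicks vanish into tonic drive and the rhythm free-runs at a
   drive-elevated rate, phase–amplitude coupled to the LC (PAC).

## Cardiac loop

Scalar feedback signals (peripheral and central chemoreceptor sigmoids of
arterial/brain pCO2, and the pulmonary stretch signal) enter their target
populations as field currents; the resting-state contribution of each
field is cancelled by the population bias, so the fields act as
*deviations* around the calibrated operating point (hypercapnia recruits
late-E through exactly this mechanism).

NTS baroreceptive cells (20 excitatory + 20 inhibitory) receive the
stretch-receptor signal; the excitatory set drives both the CVLM (which
inhibits the RVLM — the baroreflex sign) and the AMB. The amygdala
(driven by the LC and the CO₂-sensing NTS group, with a slow 300 ms
input synapse so that it responds preferentially to long low-frequency
LC bursts) excites the inhibitory NTS set, implementing the
stress-induced inhibition of baroreceptive NTS neurons. Pontine IE
neurons bridge the loops: excitatory IE (ramp-I → RVLM) adds
inspiration-locked sympathetic drive; inhibitory IE (ramp-I and late-E →
AMB) withdraws parasympathetic drive during inspiration and active
expiration.

RVLM and AMB pooled rates accumulate into transmitter pools
(τ = 2 s): p_NE = k_NE·r_RVLM, q_ACh = k_ACh·r_AMB at steady state, with
gains placing the resting state near the printed Hill midpoints. The
Hill gains H(p_NE) = 1/(1+(350/p_NE)¹⁰) and
H(q_ACh) = 1 − 1/(1+(20/q_ACh)⁵) set the FitzHugh–Nagumo tissue
parameters affinely: G_c ∈ [c_min, c_max], b ∈ [b_min, b_max].

**Cardiac tissue.** A 1-D cable of 32 FHN cells,
v̇ = D∇²v + c(v(v−α)(1−v) − w), ẇ = b(v − d·w), with the excitation
rate switched by the sign of v̇ (c = G_c·1 on the upstroke, G_c·0.22 on
the downstroke, so c₂/c₁ = 0.22 always). The shape and bound constants
(α = 0.15, d = 0.4, D = 15/s, c ∈ [24, 49]/s, b ∈ [1.2, 8.2]/s) are
calibration parameters: they were tuned once so the modulation plane
spans ≈30–115 bpm with the resting operating point near 68 bpm. Every cell
carries a graded recovery offset (0.3 at the pacemaker end, falling 30%
along the cable), which makes each cell intrinsically oscillatory with
the fastest intrinsic rate at the pacemaker end; diffusion entrains the
strand to that end and the excitation travels with a node-to-distal lag.
(A purely excitable strand driven by one pacemaker cell does not
propagate robustly across the whole (G_c, b) plane with this cubic — its
recovery is too fast relative to the weak regenerative current — so the
graded-oscillator cable is the package's design choice for the printed
"diffusion equation" tissue.) HR is read as upward 0.5-crossings of v at
the distal cell. The printed chronotropic sentence for b is
self-contradictory ("increases … and decreases with b"); we implement
HR increasing with b, consistent with b being driven by vagal withdrawal
through H(q_ACh).

## Calibration, in one pass

Free parameters (synaptic weights, biases, adaptation constants, FHN
bounds, autonomic gains, κ) were tuned once, stage-wise — isolated
neuron → LC grid → respiratory loop → cardiac chain — against the
resting anchors (BR 16 bpm, HR 68 bpm, g_NE 60 nS) and the entrainment
phenomenology at −12 pA (BR 66/51/45/32 bpm at 1.1/1.7/3/10 Hz), then
frozen in `lcne.params`. No parameter is re-tuned per run or per seed.
The calibration sweeps live outside the package; the frozen values are
the package defaults.

## Entrainment analysis

Run labels are mutually exclusive, mirroring the study's usage:

* **n:m locking** between the vibration cycle train and the inspiratory
  onset train: the smallest-order coprime ratio (n, m ≤ 8) whose cyclic
  relative phase m·φ_vib − n·φ_insp has mean resultant length above 0.6
  (threshold chosen by ROC on labelled synthetic fixtures).
* **PAC** (tested when no lock is found, or at baseline): Tort-style
  modulation index of the pooled LC rate binned by the Hilbert phase of
  the inspiratory output, thresholded against block-shuffle surrogates
  (plain circular shifts do not work: the MI of a periodic AM signal is
  shift-invariant).
* **Beat frequency**: the two dominant close spectral components of the
  arousal trace (Hann window, zero-padding, parabolic peak
  interpolation), ω₃ = |ω₁ − ω₂|; resolving the study's full-duration
  ω₃ ≈ 3.7e−4 Hz requires the hour-long condition-2 run.

The synthetic fixture generator (`signal_analysis.make_fixture`) produces
jittered n:m event trains, amplitude-modulated carriers, two-tone beats
and independent Poisson trains with known ground truth; the classifier
suite holds ≥95% category accuracy over 200 draws. The fixtures emulate
the *structure* of simulator output (burst trains, slow envelopes), not
its biophysics; passing them shows the analysis layer is sound, not that
the simulator is right — that is what the coupled-model tests are for.

## Problem sizes and defaults

Production runs integrate ~620 neurons for 80 s at dt = 1e−4 s and
summarize the 60–80 s window (condition 1) or the 20 s before each
extraction point (condition 2). The acceptance script uses 5 seeds for
the baseline anchors and one seed per stimulated protocol; the test
suite uses shorter desk-scale runs (10–45 s) for everything except the
acceptance criteria themselves. Condition 2 at its printed one-hour
duration is supported but long (~45 min per run on one core); the scaled
mode rescales the extraction points and flags the rows.

## Known limitations

* The CPG internals, all synaptic weights and the FHN constants are
  reconstructions; only the architecture, the printed HH/NE/Hill/lung
  constants and the preI/I→LC strength are sourced. Quantities that
  depend on unprinted internals (e.g. the exact Arnold-tongue widths)
  carry that uncertainty.
* The frequency profile of the heart-rate response under strong
  stimulation is compressed relative to the modelled system's published
  behaviour: in this reconstruction every measurable sympathetic /
  vagal-withdrawal driver (amygdala activity, pontine IE rates, stretch
  feedback, blood gases) is weaker at 0.3 Hz than at 0.5–1.1 Hz, so the
  strong tachycardia specific to ~0.3 Hz stimulation is not reproduced;
  the reconstruction yields a near-uniform stimulated tachycardia
  instead. The drivers involved are documented above; resolving it would
  need the unprinted internals of the source cardiac centre.
* The vibration amplitude → pA mapping at the LC is taken as printed
  current values; no physical vibration transduction is modelled.
* One noise stream drives the whole network per run; population-size
  changes therefore reshuffle the noise realisation (determinism for a
  fixed configuration and seed is exact).
* The lumped lung has no airway-resistance dynamics or separate
  pump-muscle gating; O₂ transport exists only as the single published
  diffusion pathway.
* Blood pressure is not modelled mechanically: baroreceptive NTS input
  is the pulmonary stretch signal, per the modelled architecture.
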