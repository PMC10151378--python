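"""Entrainment analysis of simulator traces.

The classifiers here answer the questions the study asks of every run: is
the respiratory rhythm n:m phase-locked to the vibration input (m
inspiratory bursts per n vibration cycles), is there phase-amplitude
coupling (PAC) between the slow respiratory rhythm and the fast LC/NE
activity, and does a slowly beating arousal level reflect two close
frequencies (beat oscillation, omega3 = |omega1 - omega2|)?

Everything is event- or spectrum-based and independent of the simulator:
``make_fixture`` generates synthetic ground-truth data so the whole module
is testable stand-alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "EntrainmentLabel", "BeatEstimate", "windowed_mean", "events_from_trace",
    "classify_locking", "pac_index", "beat_frequency", "make_fixture",
    "label_run",
]

#: minimum phase-locking strength counted as entrainment (chosen by ROC on
#: labelled fixtures; see docs/methods.md)
LOCKING_THRESHOLD = 0.6
PAC_BINS = 18
PAC_SURROGATES = 19


@dataclass
class EntrainmentLabel:
    """Mutually exclusive entrainment category of one run.

    ``category`` is one of ``"none"``, ``"lock"`` (with the oriented ratio
    ``n:m`` = n vibration cycles per m inspiratory bursts) or ``"PAC"``.
    """

    category: str
    n: int = 0
    m: int = 0
    strength: float = 0.0          # 1 - circular variance of n:m phase
    pac_mi: float = 0.0            # modulation index in [0, 1]
    slow_freq: float = 0.0         # dominant slow rhythm [Hz]

    def __post_init__(self) -> None:
        if self.category not in ("none", "lock", "PAC"):
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def is_locked(self) -> bool:
        return self.category == "lock"

    @property
    def is_pac(self) -> bool:
        return self.category == "PAC"

    def __str__(self) -> str:
        if self.category == "lock":
            return f"{self.n}:{self.m} (strength {self.strength:.2f})"
        if self.category == "PAC":
            return f"PAC (MI {self.pac_mi:.3f} @ {self.slow_freq:.2f} Hz)"
        return "none"


@dataclass
class BeatEstimate:
    """Two close spectral components and their beat frequency [Hz]."""

    omega1: float
    omega2: float
    single_tone: bool = False

    @property
    def omega3(self) -> float:
        return abs(self.omega1 - self.omega2)


def windowed_mean(t: np.ndarray, x: np.ndarray, t0: float, t1: float) -> float:
    """Time-average of ``x`` over ``[t0, t1]``."""
    if t1 <= t0:
        raise ValueError("empty averaging window")
    sel = (t >= t0) & (t <= t1)
    if not np.any(sel):
        raise ValueError("window outside the trace")
    return float(np.mean(np.asarray(x)[sel]))


def events_from_trace(t: np.ndarray, x: np.ndarray, threshold: float,
                      refractory: float = 0.3) -> np.ndarray:
    """Upward threshold-crossing times with a refractory lockout [s]."""
    x = np.asarray(x)
    up = np.flatnonzero((x[1:] >= threshold) & (x[:-1] < threshold))
    if len(up) == 0:
        return np.empty(0)
    times = t[up + 1]
    keep = [times[0]]
    for ev in times[1:]:
        if ev - keep[-1] >= refractory:
            keep.append(ev)
    return np.asarray(keep)


def _event_phase(events: np.ndarray, tgrid: np.ndarray) -> np.ndarray:
    """Unwrapped phase increasing by 2*pi per event, linearly interpolated
    between events (extrapolated at the edges with the mean rate)."""
    idx = np.arange(len(events), dtype=float)
    rate = (len(events) - 1) / (events[-1] - events[0])
    phase = np.interp(tgrid, events, idx,
                      left=idx[0] + (tgrid[0] - events[0]) * rate,
                      right=idx[-1] + (tgrid[-1] - events[-1]) * rate)
    # proper linear extrapolation outside the event span
    before = tgrid < events[0]
    after = tgrid > events[-1]
    phase[before] = (tgrid[before] - events[0]) * rate
    phase[after] = idx[-1] + (tgrid[after] - events[-1]) * rate
    return 2.0 * np.pi * phase


def _coprime_pairs(n_max: int):
    from math import gcd

    pairs = []
    for n in range(1, n_max + 1):
        for m in range(1, n_max + 1):
            if gcd(n, m) == 1:
                pairs.append((n, m))
    pairs.sort(key=lambda p: (p[0] + p[1], p[0]))
    return pairs


def classify_locking(events_a: np.ndarray, events_b: np.ndarray,
                     n_max: int = 8,
                     threshold: float = LOCKING_THRESHOLD
                     ) -> tuple[int, int, float]:
    """n:m phase locking between two event series.

    Returns the smallest-order coprime ratio ``(n, m)`` (n events of series
    a per m events of series b) whose cyclic relative phase
    ``n*phi_b - m*phi_a`` is concentrated above ``threshold``, together
    with the locking strength (1 - circular variance).  ``(0, 0, s)`` means
    no locking.  Fewer than 5 events on either side classifies as none.
    """
    a = np.sort(np.asarray(events_a, dtype=float))
    b = np.sort(np.asarray(events_b, dtype=float))
    if len(a) < 5 or len(b) < 5:
        return 0, 0, 0.0
    t0 = max(a[0], b[0])
    t1 = min(a[-1], b[-1])
    if t1 <= t0:
        return 0, 0, 0.0
    tgrid = np.linspace(t0, t1, 2048)
    pa = _event_phase(a, tgrid)
    pb = _event_phase(b, tgrid)
    # mean rates bound the plausible ratios
    ra = (len(a) - 1) / (a[-1] - a[0])
    rb = (len(b) - 1) / (b[-1] - b[0])
    best = (0, 0, 0.0)
    for n, m in _coprime_pairs(n_max):
        # n:m means n cycles of a per m cycles of b -> m*pa ~ n*pb... the
        # oriented convention: ratio of rates ra/rb ~ n/m.
        if not (0.6 < (ra / rb) / (n / m) < 1.67):
            continue
        z = np.exp(1j * (m * pa - n * pb))
        strength = float(np.abs(np.mean(z)))
        if strength >= threshold:
            return n, m, strength
        if strength > best[2]:
            best = (0, 0, strength)
    return best


def pac_index(fast: np.ndarray, slow: np.ndarray, fs: float,
              n_bins: int = PAC_BINS, n_surrogates: int = PAC_SURROGATES,
              seed: int = 0) -> tuple[float, float, bool]:
    """Phase-amplitude coupling between a fast signal and a slow rhythm.

    The fast signal's amplitude (the signal itself; rates and conductances
    are non-negative envelopes already) is binned by the Hilbert phase of
    the mean-removed slow signal; the modulation index is the
    Kullback-Leibler divergence of the binned amplitude distribution from
    uniform, normalized by log(n_bins) (Tort-style).  ``is_PAC`` requires
    the MI to exceed the 95th percentile of circular-shift surrogates.

    Returns ``(MI, slow_freq, is_PAC)`` with ``slow_freq`` the dominant
    rhythm of the slow signal [Hz].
    """
    fast = np.asarray(fast, dtype=float)
    slow = np.asarray(slow, dtype=float)
    if len(fast) != len(slow):
        raise ValueError("fast and slow signals must share a time base")
    n = len(fast)
    if n < 16 or np.ptp(slow) < 1e-12 or np.ptp(fast) < 1e-12:
        return 0.0, 0.0, False

    slow0 = slow - slow.mean()
    phase = np.angle(hilbert(slow0))
    amp = fast - fast.min()
    if amp.max() <= 0:
        return 0.0, 0.0, False

    spec = np.abs(np.fft.rfft(slow0 * np.hanning(n))) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    slow_freq = float(freqs[1:][np.argmax(spec[1:])]) if len(freqs) > 1 else 0.0

    def mi_of(a):
        bins = ((phase + np.pi) / (2 * np.pi) * n_bins).astype(int) % n_bins
        dist = np.zeros(n_bins)
        for k in range(n_bins):
            sel = bins == k
            dist[k] = a[sel].mean() if np.any(sel) else 0.0
        if dist.sum() <= 0:
            return 0.0
        p = dist / dist.sum()
        nz = p > 0
        return float(np.sum(p[nz] * np.log(p[nz] * n_bins)) / np.log(n_bins))

    mi = mi_of(amp)
    # block-shuffle surrogates: permuting ~half-cycle blocks of the
    # amplitude destroys any systematic phase-amplitude alignment (a plain
    # circular shift would not -- the MI of a periodic AM signal is
    # shift-invariant) while preserving the amplitude distribution.
    rng = np.random.default_rng(seed)
    if slow_freq > 0:
        block = max(2, int(round(0.5 * fs / slow_freq)))
    else:
        block = max(2, n // 32)
    block = min(block, max(2, n // 8))
    n_blocks = n // block
    surr = []
    for _ in range(n_surrogates):
        order = rng.permutation(n_blocks)
        shuffled = np.concatenate(
            [amp[k * block:(k + 1) * block] for k in order])
        surr.append(mi_of(np.concatenate([shuffled, amp[n_blocks * block:]])))
    thr = float(np.quantile(surr, 0.95))
    is_pac = bool(mi > thr and mi > 0.005)
    return mi, slow_freq, is_pac


def beat_frequency(t: np.ndarray, x: np.ndarray,
                   min_rel_power: float = 0.05) -> BeatEstimate:
    """Identify the two dominant close spectral components of a trace.

    The spectrum (Hann-windowed, zero-padded, parabolically interpolated
    around peaks) is searched for the strongest component omega1 and the
    strongest other local maximum omega2 with at least ``min_rel_power``
    of its power; a trace with a single dominant tone returns omega3 = 0
    with the ``single_tone`` flag set.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 16:
        raise ValueError("trace too short for spectral analysis")
    dt = float(t[1] - t[0])
    xw = (x - x.mean()) * np.hanning(n)
    nfft = int(2 ** np.ceil(np.log2(n * 8)))
    spec = np.abs(np.fft.rfft(xw, nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=dt)

    def refine(i):
        if 0 < i < len(spec) - 1:
            y0, y1, y2 = np.log(spec[i - 1] + 1e-300), np.log(spec[i] + 1e-300), \
                np.log(spec[i + 1] + 1e-300)
            denom = y0 - 2 * y1 + y2
            if denom != 0:
                return freqs[i] + 0.5 * (y0 - y2) / denom * (freqs[1] - freqs[0]) * -1.0
        return freqs[i]

    i1 = int(np.argmax(spec[1:]) + 1)
    f1 = refine(i1)
    # exclude the main peak's lobe: three Hann main-lobe widths on the
    # 8x zero-padded grid
    lobe = 3 * 8
    cand = []
    for i in range(2, len(spec) - 1):
        if abs(i - i1) <= lobe:
            continue
        if spec[i] >= spec[i - 1] and spec[i] >= spec[i + 1] \
                and spec[i] >= min_rel_power * spec[i1]:
            cand.append(i)
    if not cand:
        return BeatEstimate(omega1=f1, omega2=f1, single_tone=True)
    i2 = max(cand, key=lambda i: spec[i])
    return BeatEstimate(omega1=f1, omega2=refine(i2))


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------

def make_fixture(kind: str, params: dict | None = None, seed: int = 0):
    """Reproducible synthetic data with known entrainment structure.

    Kinds: ``nm_locked`` (two jittered periodic event series at rates
    n*f0 and m*f0), ``pac`` (a fast carrier amplitude-modulated by a slow
    phase), ``beat`` (two close tones), ``independent`` (two Poisson
    trains).  Returns a dict with the relevant arrays plus the ground
    truth used to build them.
    """
    p = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "nm_locked":
        n, m = int(p.get("n", 1)), int(p.get("m", 1))
        f0 = float(p.get("f0", 0.25))
        dur = float(p.get("duration", 120.0))
        jit = float(p.get("jitter", 0.02))
        ev_a = np.arange(0.0, dur, 1.0 / (n * f0))
        ev_b = np.arange(0.0, dur, 1.0 / (m * f0)) + p.get("offset", 0.13)
        ev_a = np.sort(ev_a + jit / (n * f0) * rng.standard_normal(len(ev_a)))
        ev_b = np.sort(ev_b + jit / (m * f0) * rng.standard_normal(len(ev_b)))
        return {"events_a": ev_a, "events_b": ev_b, "n": n, "m": m}
    if kind == "pac":
        fs = float(p.get("fs", 100.0))
        dur = float(p.get("duration", 60.0))
        f_slow = float(p.get("f_slow", 0.5))
        f_fast = float(p.get("f_fast", 8.0))
        depth = float(p.get("mod_depth", 0.8))
        noise = float(p.get("noise", 0.05))
        t = np.arange(0.0, dur, 1.0 / fs)
        slow = np.sin(2 * np.pi * f_slow * t)
        env = 1.0 + depth * np.cos(2 * np.pi * f_slow * t)
        fast = env * (1.0 + np.sin(2 * np.pi * f_fast * t)) / 2.0
        fast = fast + noise * rng.standard_normal(len(t))
        return {"t": t, "fast": fast, "slow": slow, "f_slow": f_slow,
                "mod_depth": depth}
    if kind == "beat":
        fs = float(p.get("fs", 10.0))
        dur = float(p.get("duration", 600.0))
        f1 = float(p.get("f1", 0.3))
        f2 = float(p.get("f2", 0.31))
        noise = float(p.get("noise", 0.02))
        t = np.arange(0.0, dur, 1.0 / fs)
        x = np.sin(2 * np.pi * f1 * t) + float(p.get("a2", 0.8)) * \
            np.sin(2 * np.pi * f2 * t + 0.4)
        x = x + noise * rng.standard_normal(len(t))
        return {"t": t, "x": x, "f1": f1, "f2": f2, "omega3": abs(f1 - f2)}
    if kind == "independent":
        dur = float(p.get("duration", 120.0))
        ra = float(p.get("rate_a", 0.5))
        rb = float(p.get("rate_b", 0.3))
        ev_a = np.cumsum(rng.exponential(1.0 / ra, int(3 * dur * ra) + 10))
        ev_b = np.cumsum(rng.exponential(1.0 / rb, int(3 * dur * rb) + 10))
        return {"events_a": ev_a[ev_a < dur], "events_b": ev_b[ev_b < dur]}
    raise ValueError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# run-level labelling
# ---------------------------------------------------------------------------

def label_run(result, t0: float, t1: float) -> EntrainmentLabel:
    """Entrainment label of one simulation run over the window [t0, t1].

    With a vibration input, locking is judged between the vibration cycle
    markers (known from the protocol) and the inspiratory burst onsets;
    without one, or when no n:m lock is found, LC-respiratory PAC is tested
    between the pooled LC firing rate and the inspiratory motor output
    (mirrors the mutually exclusive run labels of the study).
    """
    t = result.t
    insp = result.trace("insp_act")
    insp_on = events_from_trace(t, insp, 0.5, refractory=0.3)
    insp_on = insp_on[(insp_on >= t0) & (insp_on <= t1)]

    n = m = 0
    strength = 0.0
    if result.amplitude != 0.0 and result.frequency > 0.0:
        k0 = int(np.ceil((t0 - result.onset) * result.frequency))
        k1 = int(np.floor((t1 - result.onset) * result.frequency))
        vib = result.onset + np.arange(k0, k1 + 1) / result.frequency
        n, m, strength = classify_locking(vib, insp_on)
        if n > 0:
            return EntrainmentLabel("lock", n=n, m=m, strength=strength)

    sel = (t >= t0) & (t <= t1)
    fs = 1.0 / result.dt_rec
    lc_rate = result.pop_rate("LC", smooth_s=0.1)[sel]
    mi, slow_freq, is_pac = pac_index(lc_rate, insp[sel], fs,
                                      seed=result.seed + 7)
    if is_pac:
        return EntrainmentLabel("PAC", pac_mi=mi, slow_freq=slow_freq,
                                strength=strength)
    return EntrainmentLabel("none", pac_mi=mi, slow_freq=slow_freq,
                            strength=strength)
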