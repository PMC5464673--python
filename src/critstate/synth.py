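"""Synthetic labeled spike + LFP data and surrogate controls.

The generator emulates the phenomenology the state-resolved analysis assumes:
within each cortical state, channels fire as doubly stochastic (Cox) processes
sharing one band-limited rate envelope whose depth and frequency band depend
on the state.  Synchronized states carry a strong quasi-oscillatory 1-5 Hz (or
5-15 Hz) common modulation with near-silent gaps between population bursts;
desynchronized states have weak modulation and near-independent,
near-homogeneous firing.  The LFP proxy is the negative of the smoothed
population spike count (population bursts produce negative deflections) plus
independent 1/f background noise per channel.

Two surrogate controls are provided: within-window spike-time randomization
(destroys sub-second temporal structure, preserves per-window counts) and a
rate-matched homogeneous Poisson surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .io import LfpMatrix, SpikeRecording

__all__ = [
    "StateSpec",
    "SynthStateParams",
    "generate_labeled_recording",
    "segment_shuffle_surrogate",
    "homogeneous_poisson_surrogate",
]


@dataclass(frozen=True)
class StateSpec:
    """One cortical state of the generator.

    Parameters
    ----------
    rate_hz
        Mean firing rate per channel in this state.
    band_hz
        Frequency band (low, high) of the shared rate envelope.
    depth
        Modulation depth in [0, 1).  The envelope is a pulse train
        ``w = exp(kappa (sin(phase) - 1))`` (mean-normalized) with
        ``kappa = 2 atanh(depth)``: depth 0 is homogeneous Poisson firing,
        shallow depths give near-sinusoidal modulation, and deep modulation
        gives sharp population bursts separated by near-silent gaps with the
        harmonic-rich spectrum characteristic of cortical up-down states.
    """

    rate_hz: float
    band_hz: tuple[float, float]
    depth: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.depth < 1.0):
            raise ValueError(
                f"modulation depth {self.depth} implies a negative or "
                "non-finite intensity; require 0 <= depth < 1"
            )
        if self.rate_hz <= 0:
            raise ValueError("rate must be positive")
        lo, hi = self.band_hz
        if not (0 < lo < hi):
            raise ValueError("band must satisfy 0 < lo < hi")


def five_state_defaults() -> dict[str, StateSpec]:
    """Default five-state repertoire mirroring the canonical cortical states.

    Two desynchronized states (weak/moderate slow modulation), one fast
    synchronized state (5-15 Hz band) and two slow synchronized states with
    deep 1-5 Hz modulation.
    """
    return {
        "desyn_i": StateSpec(5.0, (2.0, 5.0), 0.05),
        "desyn_ii": StateSpec(5.0, (6.5, 7.5), 0.75),
        "syn_fast": StateSpec(5.0, (10.5, 11.5), 0.88),
        "syn_slow_i": StateSpec(5.0, (2.6, 3.4), 0.80),
        "syn_slow_ii": StateSpec(6.0, (4.1, 4.9), 0.88),
    }


@dataclass
class SynthStateParams:
    """Parameters of the labeled-recording generator."""

    states: dict[str, StateSpec] = field(default_factory=five_state_defaults)
    n_channels: int = 10
    mean_dwell_s: float = 20.0
    fs: float = 1000.0
    envelope_freq_tau_s: float = 0.05  # correlation time of the wandering frequency
    lfp_smooth_ms: float = 20.0
    lfp_spike_coupling: float = 0.05
    lfp_background_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if self.mean_dwell_s <= 0:
            raise ValueError("dwell time must be positive")


def _markov_state_sequence(
    names: list[str], n_seg: int, mean_dwell: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-second state labels from a symmetric Markov chain on segments."""
    p_switch = min(1.0, 1.0 / mean_dwell)
    labels = np.empty(n_seg, dtype=object)
    current = names[rng.integers(len(names))]
    for k in range(n_seg):
        labels[k] = current
        if rng.random() < p_switch and len(names) > 1:
            others = [s for s in names if s != current]
            current = others[rng.integers(len(others))]
    return labels


def _wandering_phase(
    band: tuple[float, float], n: int, dt: float, tau: float, rng: np.random.Generator
) -> np.ndarray:
    """Phase of a quasi-oscillation whose frequency wanders within ``band``.

    The instantaneous frequency follows an Ornstein-Uhlenbeck walk around the
    band center, reflected at the band edges, so a 1 s stretch spreads its
    power across the band rather than a single 1 Hz bin.
    """
    from scipy.signal import lfilter

    lo, hi = band
    mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
    theta = dt / tau
    # AR(1) walk around the band center (vectorized), then folded into the
    # band by reflection
    noise = rng.standard_normal(n) * half * np.sqrt(2 * theta)
    noise[0] = half * (2 * rng.random() - 1)  # initial deviation from center
    dev = lfilter([1.0], [1.0, -(1.0 - theta)], noise)
    g = np.mod(dev + half, 4 * half)  # reflect into [-half, half]
    f = mid + half - np.abs(g - 2 * half)
    phase = 2 * np.pi * np.cumsum(f) * dt
    phase += 2 * np.pi * rng.random()
    return phase


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with power spectral density proportional to 1/f."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** -0.5
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_labeled_recording(
    params: SynthStateParams, duration: float, seed: int
) -> tuple[SpikeRecording, LfpMatrix, np.ndarray]:
    """Generate a labeled recording: spikes, LFP proxy and true state labels.

    Returns
    -------
    rec : SpikeRecording
        Spikes of ``n_channels`` electrodes over ``duration`` seconds, with
        ``segment_labels`` set to the true per-second state sequence.
    lfp : LfpMatrix
        Per-channel LFP proxy at ``params.fs``.
    labels : ndarray
        The true label per 1 s segment (identical to ``rec.segment_labels``).
    """
    if duration < params.mean_dwell_s:
        raise ValueError("duration must be at least one mean dwell time")
    rng = np.random.default_rng(seed)
    fs, dt = params.fs, 1.0 / params.fs
    n_seg = int(np.floor(duration))
    n_samp = int(round(duration * fs))
    names = sorted(params.states)
    labels = _markov_state_sequence(names, n_seg, params.mean_dwell_s, rng)

    # shared envelope: one wandering-frequency pulse train per state,
    # composed piecewise over segments
    intensity = np.zeros(n_samp)   # Hz
    lfp_env = np.zeros(n_samp)     # deterministic LFP component
    sample_seg = np.minimum((np.arange(n_samp) * dt).astype(np.int64), n_seg - 1)
    for name in names:
        spec = params.states[name]
        mask = np.isin(sample_seg, np.flatnonzero(labels == name))
        if not mask.any():
            continue
        phase = _wandering_phase(
            spec.band_hz, n_samp, dt, params.envelope_freq_tau_s, rng
        )
        kappa = 2.0 * np.arctanh(spec.depth)
        w = np.exp(kappa * (np.sin(phase[mask]) - 1.0))
        w /= max(w.mean(), 1e-12)
        intensity[mask] = spec.rate_hz * w
        dev = w - w.mean()
        sd = dev.std()
        # LFP deflects negatively during bursts; amplitude scales with depth
        lfp_env[mask] = spec.depth * (dev / sd if sd > 0 else dev)

    # spikes: inhomogeneous Poisson per channel, piecewise constant per sample
    lam = intensity * dt
    times, elecs = [], []
    for ch in range(params.n_channels):
        counts = rng.poisson(lam)
        idx = np.repeat(np.arange(n_samp), counts)
        t = (idx + rng.random(idx.size)) * dt
        times.append(t)
        elecs.append(np.full(t.size, ch, dtype=np.int64))
    time = np.concatenate(times)
    elec = np.concatenate(elecs)
    time = np.clip(time, 0, np.nextafter(duration, 0))

    # LFP proxy: the field integrates the synaptic activity of far more
    # neurons than are recorded, so its deterministic part is the common rate
    # envelope itself (negative during population bursts), plus a small
    # spike-coupled term and 1/f background noise per channel.
    pop_counts = np.bincount(
        np.minimum((time * fs).astype(np.int64), n_samp - 1), minlength=n_samp
    ).astype(np.float64)
    smooth = gaussian_filter1d(pop_counts, sigma=params.lfp_smooth_ms * fs / 1000.0)
    smooth -= smooth.mean()
    sd = smooth.std()
    if sd > 0:
        smooth /= sd
    lfp = np.empty((params.n_channels, n_samp))
    for ch in range(params.n_channels):
        lfp[ch] = (
            -lfp_env
            - params.lfp_spike_coupling * smooth
            + params.lfp_background_scale * _pink_noise(n_samp, rng)
        )

    rec = SpikeRecording(elec, time, duration=float(duration), segment_labels=labels)
    return rec, LfpMatrix(lfp, fs=fs), labels


def segment_shuffle_surrogate(
    rec: SpikeRecording, window: float = 1.0, seed: int = 0
) -> SpikeRecording:
    """Randomize spike times uniformly within their own window, per electrode.

    Counts per (electrode, window) are preserved exactly; all structure at
    time scales finer than ``window`` is destroyed.  A window longer than the
    recording reduces to a whole-recording homogeneous shuffle.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rng = np.random.default_rng(seed)
    seg = np.floor(rec.time / window)
    lo = seg * window
    hi = np.minimum(lo + window, rec.duration)
    new_t = lo + rng.random(rec.n_spikes) * (hi - lo)
    new_t = np.clip(new_t, 0, np.nextafter(rec.duration, 0))
    return SpikeRecording(
        rec.electrode_id.copy(),
        new_t,
        duration=rec.duration,
        segment_labels=None if rec.segment_labels is None else rec.segment_labels.copy(),
    )


def homogeneous_poisson_surrogate(rec: SpikeRecording, seed: int = 0) -> SpikeRecording:
    """Homogeneous Poisson train per electrode with matched mean rate."""
    if rec.n_spikes == 0:
        raise ValueError("cannot build a Poisson surrogate of an empty recording")
    rng = np.random.default_rng(seed)
    times, elecs = [], []
    for e in rec.sites:
        n = rng.poisson((rec.electrode_id == e).sum())
        t = rng.random(n) * rec.duration
        times.append(t)
        elecs.append(np.full(n, e, dtype=np.int64))
    time = np.clip(np.concatenate(times), 0, np.nextafter(rec.duration, 0))
    return SpikeRecording(
        np.concatenate(elecs),
        time,
        duration=rec.duration,
        segment_labels=None if rec.segment_labels is None else rec.segment_labels.copy(),
    )
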