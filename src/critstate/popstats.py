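"""Per-state descriptive statistics linking spikes and LFP.

The central object is the *population spike train*: spikes of all electrodes
collated into one train.  When restricted to a cortical state, the train is a
set of contiguous runs of same-state 1 s segments; inter-spike intervals are
computed within runs only, so no ISI spans a state gap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .io import LfpMatrix, SpikeRecording

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationTrain",
    "population_train",
    "population_ach",
    "spike_triggered_average",
    "firing_rates",
    "fano_factor",
    "AchResult",
    "StaResult",
]


@dataclass
class PopulationTrain:
    """Pooled spike train over a set of contiguous time runs.

    ``runs`` are half-open intervals on the original recording clock; spikes
    lie within the runs.  ISIs are successive differences within each run.
    """

    times: np.ndarray
    runs: list[tuple[float, float]]

    def __post_init__(self) -> None:
        self.times = np.sort(np.asarray(self.times, dtype=np.float64))

    @property
    def n_spikes(self) -> int:
        return self.times.size

    @property
    def total_time(self) -> float:
        return float(sum(t1 - t0 for t0, t1 in self.runs))

    @property
    def isis(self) -> np.ndarray:
        """ISIs in seconds, computed within runs (never across a gap)."""
        out = []
        for t0, t1 in self.runs:
            t = self.times[(self.times >= t0) & (self.times < t1)]
            if t.size >= 2:
                out.append(np.diff(t))
        return np.concatenate(out) if out else np.empty(0)

    @property
    def mean_isi(self) -> float:
        """Mean ISI in seconds."""
        isis = self.isis
        if isis.size == 0:
            raise ValueError("train has no ISIs")
        return float(isis.mean())

    @property
    def mean_isi_ms(self) -> float:
        return 1000.0 * self.mean_isi

    @property
    def cv(self) -> float:
        """Coefficient of variation of the population ISI distribution."""
        isis = self.isis
        if isis.size == 0:
            raise ValueError("train has no ISIs")
        return float(isis.std() / isis.mean())

    @property
    def rate(self) -> float:
        """Pooled firing rate in Hz."""
        return self.n_spikes / self.total_time


def _state_runs(rec: SpikeRecording, state) -> list[tuple[float, float]]:
    """Contiguous runs of same-state 1 s segments as (t0, t1) intervals."""
    segs = rec.state_segments(state)
    if segs.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(segs) > 1)
    starts = np.r_[segs[0], segs[breaks + 1]]
    ends = np.r_[segs[breaks], segs[-1]] + 1
    return [(float(a), float(b)) for a, b in zip(starts, ends)]


def population_train(rec: SpikeRecording, state=None) -> PopulationTrain:
    """Collate all electrodes into one population train, optionally per state."""
    if state is None:
        runs = [(0.0, float(rec.duration))]
        times = rec.time
    else:
        runs = _state_runs(rec, state)
        if not runs:
            raise ValueError(f"state {state!r} has no segments")
        mask = np.zeros(rec.n_spikes, dtype=bool)
        for t0, t1 in runs:
            mask |= (rec.time >= t0) & (rec.time < t1)
        times = rec.time[mask]
    if times.size < 2:
        raise ValueError("fewer than 2 spikes in scope")
    return PopulationTrain(times.copy(), runs)


@dataclass
class AchResult:
    """Shift-predictor-corrected population autocorrelation histogram."""

    lags_ms: np.ndarray
    curve: np.ndarray          # corrected, normalized to center peak 1
    peak_amplitude: float      # max after removing the zero-lag bin
    area: float                # enclosed area |curve - baseline|, zero lag excluded
    n_segments_used: int


def population_ach(
    rec: SpikeRecording,
    state_segments: np.ndarray,
    max_lag_ms: int = 250,
    n_shuffles: int = 100,
    seed: int = 0,
    bin_ms: float = 1.0,
) -> AchResult:
    """Population ACH per 1 s segment, averaged, shift-predictor corrected.

    For every segment the pooled train is binned at ``bin_ms``; its
    autocorrelation is averaged over segments.  Both the data ACH and the
    shift predictor (mean ACH of ``n_shuffles`` rate-matched within-segment
    shuffles) are normalized to a center peak of one; the predictor is then
    subtracted, so the curve reads in units of the center peak with the
    shuffle baseline at zero.  The peak amplitude is measured after removing
    the zero-lag bin and the area is the integral between curve and baseline
    over +-``max_lag_ms``.
    """
    rng = np.random.default_rng(seed)
    n_bins = int(round(1000.0 / bin_ms))
    n_lag = int(round(max_lag_ms / bin_ms))
    acc_data = np.zeros(2 * n_bins - 1)
    acc_shift = np.zeros(2 * n_bins - 1)
    used = 0
    for k in np.asarray(state_segments, dtype=int):
        t = rec.time[(rec.time >= k) & (rec.time < k + 1)] - k
        n = t.size
        if n == 0:
            logger.info("segment %d has no spikes; skipped", k)
            continue
        x = np.bincount(
            np.minimum((t / (bin_ms / 1000.0)).astype(int), n_bins - 1),
            minlength=n_bins,
        ).astype(float)
        acc_data += fftconvolve(x, x[::-1])
        surr = rng.random((n_shuffles, n))
        xs = np.zeros((n_shuffles, n_bins))
        idx = np.minimum((surr * n_bins).astype(int), n_bins - 1)
        for row in range(n_shuffles):
            xs[row] = np.bincount(idx[row], minlength=n_bins)
        acc_shift += fftconvolve(xs, xs[:, ::-1], axes=1).mean(axis=0)
        used += 1
    if used == 0:
        raise ValueError("no segment contained spikes")
    center = n_bins - 1
    if acc_data[center] > 0:
        acc_data = acc_data / acc_data[center]
    if acc_shift[center] > 0:
        acc_shift = acc_shift / acc_shift[center]
    corrected = acc_data - acc_shift
    sl = slice(center - n_lag, center + n_lag + 1)
    lags = (np.arange(-n_lag, n_lag + 1)) * bin_ms
    curve = corrected[sl].copy()
    off = np.r_[curve[:n_lag], curve[n_lag + 1:]]
    peak = float(off.max()) if off.size else 0.0
    # enclosed area between curve and the (zero) shuffle baseline
    area = float(np.abs(off).sum() * (bin_ms / 1000.0))
    return AchResult(lags, curve, peak, area, used)


@dataclass
class StaResult:
    """Spike-triggered average of the z-scored LFP."""

    lags_ms: np.ndarray
    curve: np.ndarray             # channel-averaged STA
    negative_peak: float          # amplitude of the trough (negative number)
    area: float                   # |integral| of the negative deflection
    n_spikes_used: int
    n_spikes_dropped: int


def _negative_deflection_area(curve: np.ndarray, dt: float) -> float:
    """|Area| of the trough between its flanking zero crossings."""
    i_min = int(np.argmin(curve))
    if curve[i_min] >= 0:
        return 0.0
    lo = i_min
    while lo > 0 and curve[lo - 1] < 0:
        lo -= 1
    hi = i_min
    while hi < curve.size - 1 and curve[hi + 1] < 0:
        hi += 1
    return float(-curve[lo : hi + 1].sum() * dt)


def spike_triggered_average(
    rec: SpikeRecording,
    lfp: LfpMatrix,
    window_ms: int = 250,
    state_segments: np.ndarray | None = None,
) -> StaResult:
    """STA of the z-scored LFP around each spike (same-electrode channel).

    The summary curve is the unweighted mean over channels with at least one
    usable spike.  Spikes too close to the recording edge are dropped and
    counted.
    """
    z = lfp.zscored().samples
    fs = lfp.fs
    w = int(round(window_ms * fs / 1000.0))
    chan_of = {int(c): i for i, c in enumerate(lfp.channel_ids)}
    offsets = np.arange(-w, w + 1)
    per_channel = []
    used = dropped = 0
    seg_mask = None
    if state_segments is not None:
        seg_mask = np.zeros(int(np.floor(rec.duration)) + 1, dtype=bool)
        seg_mask[np.asarray(state_segments, dtype=int)] = True
    for e in rec.sites:
        if int(e) not in chan_of:
            continue
        t = rec.spikes_of(int(e))
        if seg_mask is not None:
            t = t[seg_mask[np.minimum(t.astype(int), seg_mask.size - 1)]]
        idx = np.round(t * fs).astype(np.int64)
        ok = (idx - w >= 0) & (idx + w < lfp.n_samples)
        dropped += int((~ok).sum())
        idx = idx[ok]
        if idx.size == 0:
            continue
        used += idx.size
        row = z[chan_of[int(e)]]
        acc = np.zeros(2 * w + 1)
        for start in range(0, idx.size, 8192):
            chunk = idx[start : start + 8192]
            acc += row[chunk[:, None] + offsets[None, :]].sum(axis=0)
        per_channel.append(acc / idx.size)
    if used < 1:
        raise ValueError("no usable spikes for STA")
    curve = np.mean(per_channel, axis=0)
    lags = offsets * 1000.0 / fs
    return StaResult(
        lags_ms=lags,
        curve=curve,
        negative_peak=float(curve.min()),
        area=_negative_deflection_area(curve, 1.0 / fs),
        n_spikes_used=used,
        n_spikes_dropped=dropped,
    )


def firing_rates(rec: SpikeRecording, labels: np.ndarray | None = None) -> dict:
    """Per-state mean channel firing rate in Hz.

    For each state: per electrode, spikes inside the state's segments divided
    by the state's total duration; averaged over all electrodes present in
    the recording.  With ``labels=None`` the whole recording is one state
    called ``"all"``.
    """
    if labels is None:
        labels = np.full(int(np.floor(rec.duration)), "all", dtype=object)
    labels = np.asarray(labels)
    seg = np.minimum(rec.time.astype(np.int64), labels.size - 1)
    out = {}
    sites = rec.sites
    for state in np.unique(labels):
        dur = float((labels == state).sum())
        if dur == 0:
            warnings.warn(f"state {state} has zero duration; excluded")
            continue
        in_state = labels[seg] == state
        rates = [
            ((rec.electrode_id == e) & in_state).sum() / dur for e in sites
        ]
        out[state] = float(np.mean(rates))
    return out


def fano_factor(train: PopulationTrain, binsize_ms: float) -> float:
    """Variance-to-mean ratio of pooled spike counts in ``binsize_ms`` bins.

    Only complete bins inside the train's runs are counted.
    """
    b = binsize_ms / 1000.0
    if train.total_time < 10 * b:
        raise ValueError("duration must be at least 10 bins")
    counts = []
    for t0, t1 in train.runs:
        n_bins = int(np.floor((t1 - t0) / b + 1e-9))
        if n_bins == 0:
            continue
        t = train.times[(train.times >= t0) & (train.times < t0 + n_bins * b)]
        counts.append(
            np.bincount(
                np.minimum(((t - t0) / b).astype(int), n_bins - 1),
                minlength=n_bins,
            )
        )
    c = np.concatenate(counts).astype(float)
    if c.mean() == 0:
        warnings.warn("zero mean count: Fano factor undefined")
        return np.nan
    return float(c.var() / c.mean())
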