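"""Cortical-state classification from LFP spectra and state dynamics.

One-second epochs are represented by their channel-averaged multitaper power
spectrum binned at 1 Hz between 1 and 100 Hz, embedded with PCA (first three
components, each score dimension rescaled to unit maximum absolute value) and
clustered with k-means.  The number of clusters is selected by the Dunn
index.  Clusters are given semantic state names from their band-power
composition: low 1-5 Hz power -> desynchronized, high 1-5 Hz power -> slow
synchronized, high 5-15/1-5 Hz power ratio -> fast synchronized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .io import LfpMatrix

__all__ = [
    "SegmentSpectra",
    "StateModel",
    "segment_power_spectra",
    "embed_and_cluster",
    "dunn_index",
    "semantic_names",
    "state_timecourse",
    "correlate_timecourses",
]

FREQ_BINS = np.arange(1, 101)  # 1 Hz bins, 1-100 Hz


@dataclass
class SegmentSpectra:
    """Per-segment channel-averaged power in 1 Hz bins (segments x 100)."""

    power: np.ndarray

    def __post_init__(self) -> None:
        self.power = np.atleast_2d(np.asarray(self.power, dtype=np.float64))
        if self.power.shape[1] != FREQ_BINS.size:
            raise ValueError("expected 100 frequency bins (1-100 Hz)")
        if (self.power < 0).any():
            raise ValueError("power must be non-negative")

    @property
    def n_segments(self) -> int:
        return self.power.shape[0]

    def band_power(self, lo: float, hi: float) -> np.ndarray:
        """Mean power in [lo, hi] Hz (inclusive) per segment."""
        m = (FREQ_BINS >= lo) & (FREQ_BINS <= hi)
        return self.power[:, m].mean(axis=1)


@dataclass
class StateModel:
    """PCA + k-means state model over segment spectra."""

    loadings: np.ndarray          # 3 x 100
    scores: np.ndarray            # segments x 3, normalized
    score_norms: np.ndarray       # per-dimension normalization constants
    centers: np.ndarray           # k x 3
    labels: np.ndarray            # cluster index per segment, in {0..k-1}
    dunn_by_k: dict[int, float]
    k: int
    cluster_names: list[str] = field(default_factory=list)

    @property
    def segment_states(self) -> np.ndarray:
        """Semantic state name per segment."""
        return np.asarray([self.cluster_names[c] for c in self.labels], dtype=object)


def segment_power_spectra(
    lfp: LfpMatrix,
    window: float = 1.0,
    n_tapers: int = 5,
    time_bandwidth: float = 3.0,
) -> SegmentSpectra:
    """Multitaper power spectra of non-overlapping windows, channel-averaged.

    Each window is tapered with ``n_tapers`` DPSS tapers (time-bandwidth
    product ``time_bandwidth``); the per-taper periodograms are averaged over
    tapers and channels and integrated into 1 Hz bins spanning 1-100 Hz.
    """
    if lfp.fs < 200:
        raise ValueError("sampling rate too low for 100 Hz spectral content")
    n_win = int(round(window * lfp.fs))
    n_seg = lfp.n_samples // n_win
    if n_seg < 1:
        raise ValueError("LFP shorter than one window")
    tapers = signal.windows.dpss(n_win, time_bandwidth, Kmax=n_tapers)
    freqs = np.fft.rfftfreq(n_win, d=1.0 / lfp.fs)
    # assignment of rfft bins to 1 Hz bins [k-0.5, k+0.5)
    bin_idx = np.round(freqs).astype(int)
    keep = (bin_idx >= 1) & (bin_idx <= 100)
    out = np.zeros((n_seg, FREQ_BINS.size))
    for ch in range(lfp.n_channels):
        segs = lfp.samples[ch, : n_seg * n_win].reshape(n_seg, n_win)
        segs = segs - segs.mean(axis=1, keepdims=True)
        tapered = segs[:, None, :] * tapers[None, :, :]
        spec = np.abs(np.fft.rfft(tapered, axis=-1)) ** 2
        spec = spec.mean(axis=1)  # average over tapers
        for k in range(1, 101):
            out[:, k - 1] += spec[:, keep & (bin_idx == k)].sum(axis=1)
    out /= lfp.n_channels
    return SegmentSpectra(out)


def dunn_index(points: np.ndarray, labels: np.ndarray) -> float:
    """Dunn index: min pairwise center distance / max within-cluster radius.

    The radius of a cluster is the maximum distance from its center to its
    members.  A clustering in which every cluster is a single point has zero
    radius and returns ``inf`` (degenerate).
    """
    points = np.asarray(points, dtype=np.float64)
    labs = np.asarray(labels)
    uniq = np.unique(labs)
    if uniq.size < 2:
        raise ValueError("need at least 2 clusters")
    centers = np.stack([points[labs == u].mean(axis=0) for u in uniq])
    radii = np.array(
        [
            np.linalg.norm(points[labs == u] - c, axis=1).max()
            for u, c in zip(uniq, centers)
        ]
    )
    dc = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
    min_between = dc[np.triu_indices(uniq.size, k=1)].min()
    max_radius = radii.max()
    if max_radius == 0:
        return np.inf
    return float(min_between / max_radius)


def semantic_names(spectra: SegmentSpectra, labels: np.ndarray, k: int) -> list[str]:
    """Name clusters from their mean band powers.

    The cluster with the maximal 5-15 Hz to 1-5 Hz power ratio is the fast
    synchronized state; of the rest, the lowest 1-5 Hz power is Desyn I
    (followed by Desyn II when five clusters are present) and the remaining
    clusters are slow synchronized states in ascending 1-5 Hz power.
    """
    slow = spectra.band_power(1, 5)
    fast = spectra.band_power(5, 15)
    slow_c = np.array([slow[labels == c].mean() for c in range(k)])
    fast_c = np.array([fast[labels == c].mean() for c in range(k)])
    names = [""] * k
    order_pool = list(range(k))
    if k >= 3:
        syn_fast = int(np.argmax(fast_c / np.maximum(slow_c, 1e-300)))
        names[syn_fast] = "syn_fast"
        order_pool.remove(syn_fast)
    by_slow = sorted(order_pool, key=lambda c: slow_c[c])
    desyn = ["desyn_i", "desyn_ii"] if k >= 5 else ["desyn_i"]
    for name, c in zip(desyn, by_slow):
        names[c] = name
    rest = by_slow[len(desyn):]
    for i, c in enumerate(rest):
        names[c] = f"syn_slow_{'i' * (i + 1)}" if i < 3 else f"syn_slow_{i + 1}"
    return names


def embed_and_cluster(
    spectra: SegmentSpectra,
    k_range: range = range(2, 11),
    n_pc: int = 3,
    seed: int = 0,
    n_init: int = 50,
) -> StateModel:
    """PCA-embed segment spectra and k-means cluster them; pick k by Dunn index.

    Scores on the first ``n_pc`` components are each rescaled to unit maximum
    absolute value before clustering.  Ties in the Dunn index break toward
    smaller k.
    """
    X = spectra.power
    if spectra.n_segments < 10 * max(k_range):
        raise ValueError("need at least 10*max(k_range) segments")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("degenerate spectra: zero variance")
    pca = PCA(n_components=n_pc, random_state=seed)
    scores = pca.fit_transform(X)
    loadings = pca.components_.copy()
    # sign convention: largest-magnitude coefficient of each loading positive
    for i in range(n_pc):
        if loadings[i, np.argmax(np.abs(loadings[i]))] < 0:
            loadings[i] *= -1
            scores[:, i] *= -1
    norms = np.abs(scores).max(axis=0)
    norms[norms == 0] = 1.0
    scores = scores / norms

    best = None
    dunn_by_k: dict[int, float] = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labs = km.fit_predict(scores)
        di = dunn_index(scores, labs)
        dunn_by_k[k] = di
        if best is None or di > dunn_by_k[best[0]]:
            best = (k, labs, km.cluster_centers_)
    k, labs, centers = best
    names = semantic_names(spectra, labs, k)
    return StateModel(
        loadings=loadings,
        scores=scores,
        score_norms=norms,
        centers=centers,
        labels=labs,
        dunn_by_k=dunn_by_k,
        k=k,
        cluster_names=names,
    )


def state_timecourse(
    labels: np.ndarray,
    which: set,
    window: int = 100,
    step: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sliding-window probability of a set of states and its power spectrum.

    Returns ``(series, freqs, power)`` where ``series[i]`` is the fraction of
    segments in ``labels[i*step : i*step+window]`` whose label is in
    ``which`` and the spectrum is the periodogram of the mean-removed series
    (sampling interval = ``step`` seconds).
    """
    labels = np.asarray(labels)
    if window > labels.size:
        raise ValueError("window exceeds series length")
    ind = np.isin(labels, list(which)).astype(float)
    kernel = np.ones(window) / window
    series = np.convolve(ind, kernel, mode="valid")[::step]
    freqs, power = signal.periodogram(series - series.mean(), fs=1.0 / step)
    return series, freqs, power


def correlate_timecourses(
    a: np.ndarray, b: np.ndarray, n_shifts: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Pearson r between two series with a circular-shift permutation p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("series must have equal length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance input: correlation undefined")
    r = float(stats.pearsonr(a, b).statistic)
    rng = np.random.default_rng(seed)
    shifts = rng.integers(1, a.size, size=n_shifts)
    az = (a - a.mean()) / a.std()
    bz = (b - b.mean()) / b.std()
    null = np.array([np.mean(az * np.roll(bz, s)) for s in shifts])
    p = float((np.sum(np.abs(null) >= abs(r)) + 1) / (n_shifts + 1))
    return r, p
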