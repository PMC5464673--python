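"""Neuronal avalanche detection, heavy-tail model comparison, shape collapse.

An avalanche (spike cluster) is a maximal run of consecutive time bins whose
pooled spike count meets a threshold.  Its *size* is the total spike count in
the run and its *lifetime* the number of bins.  Clusters touching the edge of
an analyzed window without a flanking sub-threshold bin are discarded.  The
bin size defaults to the mean ISI of the population spike train.

Size and lifetime distributions are compared between a discrete power law
(zeta-normalized, xmin fixed at the sample minimum) and a lognormal fitted as
a continuous density on the same support; the comparison statistic is the
loglikelihood ratio (positive favoring the power law) with a Vuong-type
normalized ratio and two-sided p-value.

Self-similarity is tested by shape collapse: mean avalanche profiles per
lifetime are rescaled in time to (0, 1] and in amplitude by
``lifetime**(1 - gamma)``; the scaling exponent is the grid argmin of the
collapse index (residual variance across rescaled profiles, normalized by the
squared range of the mean rescaled profile).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .popstats import PopulationTrain

logger = logging.getLogger(__name__)

__all__ = [
    "AvalancheSet",
    "TailFit",
    "CollapseResult",
    "default_bin_size",
    "detect_avalanches",
    "fit_tail",
    "threshold_sweep",
    "shape_collapse",
    "sample_discrete_powerlaw",
]


@dataclass
class AvalancheSet:
    """Sizes, lifetimes and binned profiles of detected spike clusters."""

    sizes: np.ndarray
    lifetimes: np.ndarray
    profiles: list[np.ndarray]
    delta_t_ms: float
    threshold: int
    n_spikes_binned: int = 0       # spikes falling into complete bins
    n_spikes_subthreshold: int = 0
    n_spikes_discarded: int = 0    # spikes in discarded boundary clusters

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        self.lifetimes = np.asarray(self.lifetimes, dtype=np.int64)
        if (self.sizes < self.lifetimes * self.threshold).any():
            raise ValueError("size must be >= lifetime * threshold")

    @property
    def n(self) -> int:
        return self.sizes.size


def default_bin_size(train: PopulationTrain) -> float:
    """Mean ISI of the population train, rounded to the nearest ms (>= 1 ms).

    Intended for millisecond-resolution empirical-style data; for model data
    with sub-millisecond mean ISIs pass the exact mean ISI instead.
    """
    return max(1.0, float(np.round(train.mean_isi_ms)))


def _clusters_in_counts(counts: np.ndarray, threshold: int):
    """Maximal runs of bins with count >= threshold, with boundary discards.

    Returns ``(kept, discarded)`` where each element is a list of
    ``(start, stop)`` index pairs (half-open).  A run touching the window
    start or end (no flanking sub-threshold bin) is discarded.
    """
    above = counts >= threshold
    if not above.any():
        return [], []
    d = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(above.size)
    kept, discarded = [], []
    for s, e in zip(starts, stops):
        if s == 0 or e == above.size:
            discarded.append((s, e))
        else:
            kept.append((s, e))
    return kept, discarded


def detect_avalanches(
    train: PopulationTrain, delta_t_ms: float, threshold: int = 1
) -> AvalancheSet:
    """Detect avalanches in the pooled train at bin size ``delta_t_ms``.

    Each contiguous run of the train is binned independently (only complete
    bins); boundary clusters touching a run edge are discarded per the
    detection rule.  An empty result is not an error.
    """
    if delta_t_ms <= 0:
        raise ValueError("delta_t must be positive")
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    b = delta_t_ms / 1000.0
    sizes, lifetimes, profiles = [], [], []
    n_binned = n_sub = n_disc = 0
    for t0, t1 in train.runs:
        n_bins = int(np.floor((t1 - t0) / b + 1e-9))
        if n_bins == 0:
            continue
        t = train.times[(train.times >= t0) & (train.times < t0 + n_bins * b)]
        counts = np.bincount(
            np.minimum(((t - t0) / b).astype(np.int64), n_bins - 1),
            minlength=n_bins,
        )
        counts = counts[:n_bins]
        n_binned += int(counts.sum())
        kept, discarded = _clusters_in_counts(counts, threshold)
        for s, e in kept:
            run = counts[s:e]
            sizes.append(int(run.sum()))
            lifetimes.append(e - s)
            profiles.append(run.astype(np.int64))
        n_disc += int(sum(counts[s:e].sum() for s, e in discarded))
        n_sub += int(counts[counts < threshold].sum())
    return AvalancheSet(
        np.asarray(sizes, dtype=np.int64),
        np.asarray(lifetimes, dtype=np.int64),
        profiles,
        delta_t_ms=delta_t_ms,
        threshold=threshold,
        n_spikes_binned=n_binned,
        n_spikes_subthreshold=n_sub,
        n_spikes_discarded=n_disc,
    )


# ---------------------------------------------------------------------------
# heavy-tail model comparison


@dataclass
class TailFit:
    """Discrete power law vs lognormal comparison on one sample.

    ``alpha`` is reported with the conventional negative sign (the fitted
    density decays as ``x**alpha``).  ``llr`` is the summed loglikelihood
    difference (power law minus lognormal; positive favors the power law),
    ``llr_normalized`` the Vuong-type normalized ratio and ``p`` its
    two-sided significance.
    """

    alpha: float
    mu: float
    sigma: float
    llr: float
    llr_normalized: float
    p: float
    n: int
    xmin: int


def _powerlaw_mle(x: np.ndarray, xmin: int) -> float:
    """MLE exponent (positive magnitude) of the discrete power law."""
    vals, cnts = np.unique(x, return_counts=True)
    sum_log = float(np.sum(cnts * np.log(vals)))
    n = x.size

    def nll(a: float) -> float:
        return a * sum_log + n * np.log(special.zeta(a, xmin))

    res = optimize.minimize_scalar(nll, bounds=(1.01, 12.0), method="bounded")
    return float(res.x)


def _loglik_lognormal(x: np.ndarray, mu: float, sig: float, xmin: int) -> np.ndarray:
    """Log pmf of the discretized truncated lognormal at integer x >= xmin.

    The continuous lognormal is discretized by integrating the density over
    [x - 0.5, x + 0.5] and renormalizing on the support x >= xmin, so both
    models are compared as probability masses on the same discrete support.
    """
    hi = stats.norm.logcdf((np.log(x + 0.5) - mu) / sig)
    lo = stats.norm.logcdf((np.log(np.maximum(x - 0.5, 1e-12)) - mu) / sig)
    with np.errstate(divide="ignore"):
        mass = hi + np.log1p(-np.exp(np.minimum(lo - hi, -1e-12)))
    norm = stats.norm.logsf((np.log(xmin - 0.5) - mu) / sig) if xmin > 0.5 else 0.0
    return mass - norm


def _lognormal_mle(x: np.ndarray, xmin: int) -> tuple[float, float]:
    """MLE of the discretized truncated lognormal (mu >= 0, sigma > 0)."""
    vals, cnts = np.unique(x, return_counts=True)
    logx = np.log(x)
    mu0 = max(float(logx.mean()), 0.0)
    s0 = max(float(logx.std()), 0.05)

    def nll(theta):
        mu, sig = theta
        return -float(cnts @ _loglik_lognormal(vals, mu, sig, xmin))

    res = optimize.minimize(
        nll,
        x0=[mu0, s0],
        method="Nelder-Mead",
        bounds=[(0.0, None), (1e-3, None)],
    )
    return float(res.x[0]), float(res.x[1])


def _loglik_powerlaw(x: np.ndarray, alpha: float, xmin: int) -> np.ndarray:
    return -alpha * np.log(x) - np.log(special.zeta(alpha, xmin))


def fit_tail(samples: np.ndarray, min_samples: int = 50) -> TailFit:
    """Fit and compare power-law and lognormal models of a discrete sample.

    xmin is fixed at the sample minimum (the entire distribution is fitted,
    never a truncated tail).
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.size < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {x.size}")
    if np.unique(x).size == 1:
        raise ValueError("degenerate sample: all values equal")
    xmin = int(x.min())
    a = _powerlaw_mle(x, xmin)
    mu, sig = _lognormal_mle(x, xmin)
    li = _loglik_powerlaw(x, a, xmin) - _loglik_lognormal(x, mu, sig, xmin)
    llr = float(li.sum())
    sd = float(li.std())
    if sd == 0:
        norm, p = 0.0, 1.0
    else:
        norm = llr / (sd * np.sqrt(x.size))
        p = float(special.erfc(abs(norm) / np.sqrt(2)))
    return TailFit(
        alpha=-a, mu=mu, sigma=sig, llr=llr, llr_normalized=float(norm),
        p=p, n=int(x.size), xmin=xmin,
    )


def threshold_sweep(
    train: PopulationTrain,
    delta_t_ms: float,
    thresholds,
    min_avalanches: int = 50,
) -> list[dict]:
    """Detect and fit at each threshold; rows with too few avalanches are skipped."""
    rows = []
    for thr in thresholds:
        av = detect_avalanches(train, delta_t_ms, threshold=int(thr))
        row = {"threshold": int(thr), "n_avalanches": av.n}
        if av.n < min_avalanches:
            logger.warning(
                "threshold %d yielded %d avalanches (<%d); fit skipped",
                thr, av.n, min_avalanches,
            )
            rows.append(row)
            continue
        for kind, sample in (("size", av.sizes), ("lifetime", av.lifetimes)):
            try:
                fit = fit_tail(sample, min_samples=min_avalanches)
            except ValueError:
                continue
            row[f"{kind}_alpha"] = fit.alpha
            row[f"{kind}_llr"] = fit.llr
            row[f"{kind}_llr_normalized"] = fit.llr_normalized
            row[f"{kind}_p"] = fit.p
        rows.append(row)
    return rows


def sample_discrete_powerlaw(
    alpha: float, n: int, xmin: int = 1, rng=None, table_max: int = 1_000_000
) -> np.ndarray:
    """Draw from the zeta-normalized discrete power law p(x) ~ x**-alpha.

    Exact inverse-CDF sampling over a table up to ``table_max``; the far tail
    beyond the table (survival mass typically < 1e-3) falls back to the
    continuous Pareto approximation of the discrete survival function.
    """
    rng = np.random.default_rng(rng)
    xs = np.arange(xmin, table_max + 1, dtype=np.float64)
    pmf = xs**-alpha / special.zeta(alpha, xmin)
    cdf = np.cumsum(pmf)
    u = rng.random(n)
    idx = np.searchsorted(cdf, u)
    out = xmin + idx
    over = idx >= xs.size
    if over.any():
        tail_u = (1.0 - u[over]) * special.zeta(alpha, xmin)
        # invert zeta(alpha, x) ~ x**(1-alpha)/(alpha-1)
        out[over] = np.floor((tail_u * (alpha - 1)) ** (1.0 / (1.0 - alpha)))
    return out.astype(np.int64)


# ---------------------------------------------------------------------------
# shape collapse


@dataclass
class CollapseResult:
    """Scaling exponent and collapse index of mean avalanche profiles."""

    gamma: float                    # best scaling exponent (sigma-nu-z)
    ci: float                       # collapse index at gamma
    gamma_grid: np.ndarray
    ci_curve: np.ndarray
    durations: np.ndarray
    mean_profiles: dict = field(default_factory=dict)    # duration -> raw profile
    rescaled: np.ndarray | None = None                   # durations x grid, at gamma


def _interp_profile(profile: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Linear interpolation of a binned profile onto the common (0, 1] grid.

    Bin i of a lifetime-T profile is placed at scaled time (i+1)/T, with an
    implicit (0, 0) anchor at scaled time zero.
    """
    T = profile.size
    x = np.r_[0.0, (np.arange(T) + 1.0) / T]
    y = np.r_[0.0, profile]
    return np.interp(grid, x, y)


def shape_collapse(
    av: AvalancheSet,
    min_per_duration: int = 20,
    gamma_grid: np.ndarray | None = None,
    n_grid: int = 100,
    min_duration: int = 2,
) -> CollapseResult:
    """Test self-similarity of avalanche temporal profiles.

    The mean profile of each lifetime (with at least ``min_per_duration``
    avalanches) is rescaled in time onto a common grid and in amplitude by
    ``lifetime**(1 - gamma)``; the collapse index is the grid-mean variance
    across rescaled profiles divided by the squared range of their mean.
    """
    if gamma_grid is None:
        gamma_grid = np.arange(0.5, 2.5 + 1e-9, 0.01)
    durations, counts = np.unique(av.lifetimes, return_counts=True)
    ok = (counts >= min_per_duration) & (durations >= min_duration)
    durations = durations[ok]
    if durations.size < 3:
        raise ValueError(
            f"need >= 3 distinct lifetimes with >= {min_per_duration} "
            f"avalanches each; found {durations.size}"
        )
    grid = (np.arange(n_grid) + 1.0) / n_grid
    mean_profiles = {}
    interp = np.empty((durations.size, n_grid))
    for i, d in enumerate(durations):
        profs = [p for p, L in zip(av.profiles, av.lifetimes) if L == d]
        mp = np.mean(profs, axis=0)
        mean_profiles[int(d)] = mp
        interp[i] = _interp_profile(mp, grid)

    dur = durations.astype(np.float64)
    ci_curve = np.empty(gamma_grid.size)
    for gi, g in enumerate(gamma_grid):
        scaled = interp * dur[:, None] ** (1.0 - g)
        mean_curve = scaled.mean(axis=0)
        rng_ = mean_curve.max() - mean_curve.min()
        var = scaled.var(axis=0).mean()
        ci_curve[gi] = var / rng_**2 if rng_ > 0 else np.inf
    best = int(np.argmin(ci_curve))
    g = float(gamma_grid[best])
    rescaled = interp * dur[:, None] ** (1.0 - g)
    return CollapseResult(
        gamma=g,
        ci=float(ci_curve[best]),
        gamma_grid=gamma_grid,
        ci_curve=ci_curve,
        durations=durations,
        mean_profiles=mean_profiles,
        rescaled=rescaled,
    )
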