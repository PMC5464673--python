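"""Pairwise maximum-entropy (Ising) modeling of binarized ensemble activity.

Ensemble activity is binarized into +-1 patterns (sigma_i = +1 iff site i
spiked in the bin).  The pairwise maximum-entropy model is the Boltzmann
distribution P(sigma) ~ exp(-E), E = -sum_i h_i sigma_i
- 1/2 sum_ij J_ij sigma_i sigma_j, matching the empirical activation rates
<sigma_i> and pairwise correlations <sigma_i sigma_j>.  Parameters are fitted
by gradient descent on the moment mismatch; model moments come from exact
enumeration (N <= 20) or single-spin-flip Metropolis sampling.

Thermodynamics: a temperature T rescales all parameters (Omega -> Omega/T);
the heat capacity is C(T) = var[E]/T^2 with E the unscaled-parameter energy
of patterns drawn at temperature T.  A peak of C near T = 1 (the operating
point) is the criticality marker.  The entropy follows from the
thermodynamic identity S = S(T->0) + integral_0^1 C(T)/T dT, where the
boundary term is the log ground-state degeneracy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from numba import njit
from scipy import stats

from .io import SpikeRecording

logger = logging.getLogger(__name__)

__all__ = [
    "PatternData",
    "MemModel",
    "ThermoCurve",
    "binarize",
    "bin_size_for_emission",
    "fit_independent",
    "fit_pairwise",
    "model_distribution",
    "metropolis_moments",
    "sample_patterns",
    "empirical_distribution",
    "js_goodness",
    "decode_states",
    "binomial_chance_bound",
    "heat_capacity",
    "entropy",
    "ensemble_scan",
    "least_squares_slope_ci",
]

EXACT_MAX_N = 20


@dataclass
class PatternData:
    """L x N matrix of +-1 ensemble patterns with provenance."""

    patterns: np.ndarray
    bin_ms: float
    site_ids: np.ndarray | None = None
    state: object = None

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=np.int8)
        if not np.isin(self.patterns, (-1, 1)).all():
            raise ValueError("patterns must be over {-1, +1}")

    @property
    def L(self) -> int:
        return self.patterns.shape[0]

    @property
    def N(self) -> int:
        return self.patterns.shape[1]

    @property
    def emission_probability(self) -> np.ndarray:
        """Fraction of bins in which each site is active."""
        return (self.patterns == 1).mean(axis=0)

    def moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Empirical <sigma_i> and <sigma_i sigma_j>."""
        s = self.patterns.astype(np.float64)
        return s.mean(axis=0), (s.T @ s) / self.L

    def subset(self, cols) -> "PatternData":
        return PatternData(
            self.patterns[:, cols],
            bin_ms=self.bin_ms,
            site_ids=None if self.site_ids is None else self.site_ids[cols],
            state=self.state,
        )


@dataclass
class MemModel:
    """Fitted Boltzmann model: biases h, symmetric zero-diagonal couplings J."""

    h: np.ndarray
    J: np.ndarray
    converged: bool = True
    n_iter: int = 0
    max_mismatch: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=np.float64)
        self.J = np.asarray(self.J, dtype=np.float64)
        if self.J.shape != (self.h.size, self.h.size):
            raise ValueError("J must be N x N")
        if not np.allclose(self.J, self.J.T):
            raise ValueError("J must be symmetric")
        if not np.allclose(np.diag(self.J), 0):
            raise ValueError("J must have zero diagonal")

    @property
    def N(self) -> int:
        return self.h.size

    def energies(self, patterns: np.ndarray) -> np.ndarray:
        """E(sigma) = -h.sigma - 1/2 sigma.J.sigma per pattern row."""
        s = np.asarray(patterns, dtype=np.float64)
        return -(s @ self.h) - 0.5 * np.einsum("pi,ij,pj->p", s, self.J, s)


@lru_cache(maxsize=8)
def _all_patterns(n: int) -> np.ndarray:
    """All 2^n patterns over {-1,+1}; bit i of the row index maps to site i."""
    idx = np.arange(2**n, dtype=np.uint32)
    bits = (idx[:, None] >> np.arange(n)[None, :]) & 1
    return (2 * bits.astype(np.int8) - 1).copy()


def pattern_index(patterns: np.ndarray) -> np.ndarray:
    """Row index of each +-1 pattern in the :func:`_all_patterns` enumeration."""
    bits = (np.asarray(patterns) == 1).astype(np.uint32)
    return bits @ (1 << np.arange(patterns.shape[1], dtype=np.uint32))


# ---------------------------------------------------------------------------
# binarization


def binarize(
    rec: SpikeRecording, sites, b_ms: float, state=None
) -> PatternData:
    """Binarize ensemble activity of ``sites`` in non-overlapping b_ms bins.

    With a state label, only bins inside that state's 1 s segments are kept
    (bins never straddle a segment edge).
    """
    sites = np.asarray(sites)
    if sites.size < 2:
        raise ValueError("need at least 2 sites")
    if b_ms <= 0:
        raise ValueError("bin size must be positive")
    missing = np.setdiff1d(sites, rec.sites)
    if missing.size:
        raise ValueError(f"sites not present in recording: {missing.tolist()}")
    b = b_ms / 1000.0
    if state is None:
        segs = np.arange(int(np.floor(rec.duration)))
    else:
        segs = rec.state_segments(state)
        if segs.size == 0:
            raise ValueError(f"state {state!r} absent from recording")
    per_seg = int(np.floor(1.0 / b))
    if per_seg == 0:
        raise ValueError("bin size exceeds the 1 s segment length")
    seg_rank = -np.ones(int(np.floor(rec.duration)) + 1, dtype=np.int64)
    seg_rank[segs] = np.arange(segs.size)
    L = segs.size * per_seg
    patterns = -np.ones((L, sites.size), dtype=np.int8)
    for j, e in enumerate(sites):
        t = rec.spikes_of(int(e))
        s = np.minimum(t.astype(np.int64), seg_rank.size - 1)
        r = seg_rank[s]
        ok = r >= 0
        within = ((t[ok] - s[ok]) / b).astype(np.int64)
        ok2 = within < per_seg  # drop the partial bin at each segment end
        rows = r[ok][ok2] * per_seg + within[ok2]
        patterns[rows, j] = 1
    return PatternData(patterns, bin_ms=b_ms, site_ids=sites, state=state)


def bin_size_for_emission(
    rec: SpikeRecording,
    sites,
    target: float = 0.048,
    state=None,
    b_range_ms: tuple[float, float] = (0.5, 200.0),
) -> float:
    """Bin size (ms) whose mean emission probability best matches ``target``.

    Bisection on the monotone emission(b) relationship.
    """
    lo, hi = b_range_ms

    def emission(b: float) -> float:
        return float(binarize(rec, sites, b, state=state).emission_probability.mean())

    for _ in range(30):
        mid = np.sqrt(lo * hi)
        if emission(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1.01:
            break
    return float(np.sqrt(lo * hi))


# ---------------------------------------------------------------------------
# fitting


def fit_independent(data: PatternData) -> MemModel:
    """Independent model: J = 0, h_i = atanh(<sigma_i>) (closed form)."""
    m, _ = data.moments()
    m = np.clip(m, -1 + 1e-6, 1 - 1e-6)
    h = np.arctanh(m)
    return MemModel(h, np.zeros((data.N, data.N)), meta={"kind": "independent"})


def _exact_moments(model: MemModel) -> tuple[np.ndarray, np.ndarray]:
    M = _all_patterns(model.N).astype(np.float64)
    E = model.energies(M)
    E -= E.min()
    w = np.exp(-E)
    P = w / w.sum()
    mean = M.T @ P
    corr = (M * P[:, None]).T @ M
    return mean, corr


def fit_pairwise(
    data: PatternData,
    learning_rate: float = 0.1,
    tol: float = 0.005,
    max_iter: int = 100,
    method: str = "exact",
    seed: int = 0,
    mc_steps: int = 500_000,
) -> MemModel:
    """Fit the pairwise model by gradient descent on the moment mismatch.

    ``method='exact'`` computes model moments by enumeration (N <= 20);
    ``method='mc'`` uses Metropolis sampling with ``mc_steps`` steps.
    Convergence is max absolute mismatch over all first and second moments
    below ``tol``; non-convergence returns the model with a warning flag.
    """
    if data.L < 10 * data.N:
        raise ValueError("need at least 10*N patterns")
    if method == "exact" and data.N > EXACT_MAX_N:
        raise ValueError(f"exact mode limited to N <= {EXACT_MAX_N}")
    m_emp, c_emp = data.moments()
    model = fit_independent(data)
    h, J = model.h.copy(), model.J.copy()
    off = ~np.eye(data.N, dtype=bool)
    mismatch = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        m = MemModel(h, J)
        if method == "exact":
            mean, corr = _exact_moments(m)
        else:
            mean, corr, _, _ = metropolis_moments(
                m, T=1.0, n_steps=mc_steps, seed=seed + it
            )
        dm = mean - m_emp
        dc = (corr - c_emp) * off
        mismatch = max(np.abs(dm).max(), np.abs(dc).max())
        if mismatch < tol:
            break
        h -= learning_rate * dm
        J -= learning_rate * dc
        J = 0.5 * (J + J.T)
        np.fill_diagonal(J, 0.0)
    converged = mismatch < tol
    if not converged:
        warnings.warn(
            f"pairwise fit did not converge in {max_iter} iterations "
            f"(max mismatch {mismatch:.4f})"
        )
    return MemModel(
        h, J, converged=converged, n_iter=it, max_mismatch=float(mismatch),
        meta={"kind": "pairwise", "method": method},
    )


# ---------------------------------------------------------------------------
# model distribution, sampling


def model_distribution(model: MemModel, T: float = 1.0):
    """Exact energies, probabilities and partition function (N <= 20).

    Energies are computed with unscaled parameters; the Boltzmann weights use
    E/T (parameter rescaling Omega -> Omega/T).
    """
    if model.N > EXACT_MAX_N:
        raise ValueError(
            f"exact enumeration limited to N <= {EXACT_MAX_N}; "
            "use metropolis_moments / sample_patterns"
        )
    M = _all_patterns(model.N).astype(np.float64)
    E = model.energies(M)
    shift = E.min()
    w = np.exp(-(E - shift) / T)
    Z = w.sum()  # relative to the shifted energies
    P = w / Z
    return M, E, P


@njit(cache=True)
def _metropolis(h, J, T, n_steps, burn_in, seed):  # pragma: no cover - numba
    np.random.seed(seed)
    N = h.size
    s = np.empty(N)
    for i in range(N):
        s[i] = 1.0 if np.random.random() < 0.5 else -1.0
    E = 0.0
    for i in range(N):
        E -= h[i] * s[i]
        for j in range(i + 1, N):
            E -= J[i, j] * s[i] * s[j]
    m = np.zeros(N)
    c = np.zeros((N, N))
    e_sum = 0.0
    e2_sum = 0.0
    kept = 0
    for step in range(n_steps + burn_in):
        i = np.random.randint(N)
        dE = 2.0 * s[i] * h[i]
        for j in range(N):
            dE += 2.0 * s[i] * J[i, j] * s[j]
        if dE <= 0.0 or np.random.random() < np.exp(-dE / T):
            s[i] = -s[i]
            E += dE
        if step >= burn_in:
            kept += 1
            e_sum += E
            e2_sum += E * E
            for a in range(N):
                m[a] += s[a]
                for b in range(N):
                    c[a, b] += s[a] * s[b]
    m /= kept
    c /= kept
    e_mean = e_sum / kept
    e_var = e2_sum / kept - e_mean * e_mean
    return m, c, e_mean, e_var


def metropolis_moments(
    model: MemModel,
    T: float = 1.0,
    n_steps: int = 500_000,
    burn_in: int = 10_000,
    seed: int = 0,
):
    """Single-spin-flip Metropolis estimate of model moments and energy stats.

    Returns ``(mean, corr, e_mean, e_var)``; energies are unscaled-parameter
    energies of patterns drawn at temperature ``T``.
    """
    return _metropolis(
        model.h, model.J, float(T), int(n_steps), int(burn_in), int(seed) & 0x7FFFFFFF
    )


def sample_patterns(model: MemModel, L: int, seed: int = 0) -> PatternData:
    """Draw L i.i.d. patterns from the exact model distribution (N <= 20)."""
    M, _, P = model_distribution(model)
    rng = np.random.default_rng(seed)
    idx = rng.choice(M.shape[0], size=L, p=P)
    return PatternData(M[idx].astype(np.int8), bin_ms=np.nan)


# ---------------------------------------------------------------------------
# goodness of fit, decoding


def empirical_distribution(data: PatternData) -> np.ndarray:
    """Empirical probability over the full 2^N pattern support."""
    idx = pattern_index(data.patterns)
    return np.bincount(idx, minlength=2**data.N) / data.L


def js_goodness(p_emp: np.ndarray, p_model: np.ndarray) -> tuple[float, float]:
    """Jensen-Shannon divergence (natural log) and goodness 1/D_JS."""
    p = np.asarray(p_emp, dtype=np.float64)
    q = np.asarray(p_model, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError("distributions must share one support")
    if abs(p.sum() - 1) > 1e-6 or abs(q.sum() - 1) > 1e-6:
        raise ValueError("inputs must be normalized")
    if (q <= 0).any():
        raise ValueError("model distribution must be positive everywhere")
    m = 0.5 * (p + q)

    def kl(a, b):
        nz = a > 0
        return float(np.sum(a[nz] * np.log(a[nz] / b[nz])))

    djs = 0.5 * kl(p, m) + 0.5 * kl(q, m)
    djs = max(djs, 0.0)
    return djs, (np.inf if djs == 0 else 1.0 / djs)


def binomial_chance_bound(n: int, p: float, quantile: float = 0.95) -> int:
    """Smallest k with P(Binomial(n, p) <= k) >= quantile (exact cumsum)."""
    k = np.arange(n + 1)
    cdf = np.cumsum(stats.binom.pmf(k, n, p))
    return int(k[np.searchsorted(cdf, quantile)])


def decode_states(
    data_by_state: dict,
    N: int,
    Q: int = 10,
    train_frac: float = 0.7,
    repeats: int = 30,
    seed: int = 0,
    independent: bool = False,
    fit_kwargs: dict | None = None,
) -> dict:
    """Cross-validated cortical-state decoding from ensemble activity.

    For each of ``Q`` random N-site ensembles and each state, a model is
    fitted on a contiguous ``train_frac`` block (random offset per repeat)
    and every test block is assigned to the state whose model maximizes
    1/D_JS against the test pattern distribution.  Returns the median and
    5-95th percentile accuracy (percent over n = Q * n_states tests per
    repeat) and the 95% binomial chance bound.
    """
    fit_kwargs = fit_kwargs or {}
    states = sorted(data_by_state, key=str)
    n_states = len(states)
    first = data_by_state[states[0]]
    n_sites = first.N
    if N > n_sites:
        raise ValueError("ensemble size exceeds available sites")
    for s in states:
        if data_by_state[s].L < 100:
            raise ValueError(f"state {s!r} has fewer than 100 bins")
    rng = np.random.default_rng(seed)
    ensembles = [rng.choice(n_sites, size=N, replace=False) for _ in range(Q)]
    accuracies = []
    for _ in range(repeats):
        hits = 0
        total = 0
        for cols in ensembles:
            models = {}
            tests = {}
            for s in states:
                d = data_by_state[s].subset(cols)
                L = d.L
                n_train = int(round(train_frac * L))
                off = int(rng.integers(L))
                idx = (np.arange(L) + off) % L
                train = PatternData(d.patterns[idx[:n_train]], d.bin_ms)
                test = PatternData(d.patterns[idx[n_train:]], d.bin_ms)
                if independent:
                    models[s] = fit_independent(train)
                else:
                    models[s] = fit_pairwise(train, **fit_kwargs)
                tests[s] = empirical_distribution(test)
            model_ps = {s: model_distribution(models[s])[2] for s in states}
            for s_true in states:
                scores = [
                    js_goodness(tests[s_true], model_ps[s])[1] for s in states
                ]
                if states[int(np.argmax(scores))] == s_true:
                    hits += 1
                total += 1
        accuracies.append(100.0 * hits / total)
    acc = np.asarray(accuracies)
    n_tests = Q * n_states
    k_chance = binomial_chance_bound(n_tests, 1.0 / n_states)
    return {
        "accuracy_median": float(np.median(acc)),
        "accuracy_p5": float(np.percentile(acc, 5)),
        "accuracy_p95": float(np.percentile(acc, 95)),
        "chance_bound_hits": k_chance,
        "chance_bound_percent": 100.0 * k_chance / n_tests,
        "n_tests": n_tests,
        "accuracies": acc,
    }


# ---------------------------------------------------------------------------
# thermodynamics


@dataclass
class ThermoCurve:
    """Heat capacity over a temperature grid."""

    T: np.ndarray
    C: np.ndarray
    T_max: float

    def c_at(self, T: float) -> float:
        return float(np.interp(T, self.T, self.C))


def heat_capacity(
    model: MemModel,
    T_grid: np.ndarray | None = None,
    method: str = "exact",
    seed: int = 0,
    mc_steps: int = 500_000,
) -> ThermoCurve:
    """C(T) = var[E]/T^2 under parameter rescaling Omega -> Omega/T."""
    if T_grid is None:
        T_grid = np.arange(0.1, 3.0 + 1e-9, 0.02)
    T_grid = np.asarray(T_grid, dtype=np.float64)
    if (T_grid <= 0).any():
        raise ValueError("temperatures must be positive")
    C = np.empty(T_grid.size)
    if method == "exact":
        M, E, _ = model_distribution(model)
        shift = E.min()
        Es = E - shift
        for i, T in enumerate(T_grid):
            w = np.exp(-Es / T)
            P = w / w.sum()
            mu = float(Es @ P)
            C[i] = float(((Es - mu) ** 2) @ P) / T**2
    else:
        for i, T in enumerate(T_grid):
            _, _, _, e_var = metropolis_moments(
                model, T=T, n_steps=mc_steps, seed=seed + i
            )
            C[i] = max(e_var, 0.0) / T**2
    return ThermoCurve(T_grid, C, T_max=float(T_grid[int(np.argmax(C))]))


def entropy(
    model: MemModel,
    n_grid: int = 200,
    t_low: float = 0.02,
    check_tol: float = 0.02,
) -> float:
    """Entropy in bits via the thermodynamic identity S(1) = S(T0) + int C/T dT.

    The integral runs on ``n_grid`` log-spaced points from ``t_low`` to 1;
    the boundary term S(t_low) is the enumeration entropy at that
    temperature (it reduces to the log ground-state degeneracy as t_low -> 0
    and handles quasi-degenerate low-lying states at any t_low).  The result
    is cross-checked against -sum P log2 P at T = 1; a mismatch beyond
    ``check_tol`` raises a numerical-accuracy error.
    """
    if model.N > EXACT_MAX_N:
        raise ValueError("entropy currently requires exact mode (N <= 20)")
    M, E, P = model_distribution(model)
    _, _, P0 = model_distribution(model, T=t_low)
    s_boundary = float(-np.sum(P0[P0 > 0] * np.log2(P0[P0 > 0])))
    Ts = np.logspace(np.log10(t_low), 0.0, n_grid)
    curve = heat_capacity(model, T_grid=Ts, method="exact")
    s_nats = np.trapezoid(curve.C / Ts, Ts)
    s_bits = s_boundary + s_nats / np.log(2)
    s_direct = float(-np.sum(P[P > 0] * np.log2(P[P > 0])))
    if abs(s_bits - s_direct) > check_tol * max(s_direct, 0.1):
        raise ArithmeticError(
            f"entropy integral ({s_bits:.4f} bits) disagrees with enumeration "
            f"({s_direct:.4f} bits) beyond {100 * check_tol:.0f}%"
        )
    return float(s_bits)


def least_squares_slope_ci(
    x: np.ndarray, y: np.ndarray, level: float = 0.95
) -> dict:
    """Least-squares slope with t-based confidence interval.

    The half-width is t_{n-2}(i) * sqrt(S^2 / Sxx), with S^2 the unbiased
    estimator of the residual variance and Sxx the sum of squared deviations
    of x from its mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    xm = x.mean()
    sxx = float(np.sum((x - xm) ** 2))
    slope = float(np.sum((x - xm) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * xm)
    resid = y - (intercept + slope * x)
    s2 = float(np.sum(resid**2) / (n - 2))
    se = np.sqrt(s2 / sxx)
    tcrit = float(stats.t.ppf(0.5 + level / 2, n - 2))
    tstat = slope / se if se > 0 else np.inf
    p = float(2 * stats.t.sf(abs(tstat), n - 2))
    return {
        "slope": slope,
        "intercept": intercept,
        "ci": (slope - tcrit * se, slope + tcrit * se),
        "se": float(se),
        "p": p,
        "n": n,
    }


def ensemble_scan(
    data: PatternData,
    N_list,
    Q: int = 10,
    seed: int = 0,
    fit_kwargs: dict | None = None,
    T_grid: np.ndarray | None = None,
) -> dict:
    """Heat capacity and entropy versus ensemble size N.

    For each N, ``Q`` random site subsets are fitted and their thermodynamic
    quantities averaged; slopes of C/N and S/N versus N carry t-based 95%
    confidence intervals.
    """
    fit_kwargs = fit_kwargs or {}
    rng = np.random.default_rng(seed)
    rows = []
    for N in N_list:
        if N > data.N:
            logger.warning("N=%d exceeds available sites (%d); skipped", N, data.N)
            continue
        for q in range(Q):
            cols = rng.choice(data.N, size=N, replace=False)
            model = fit_pairwise(data.subset(cols), **fit_kwargs)
            curve = heat_capacity(model, T_grid=T_grid)
            S = entropy(model)
            rows.append(
                {
                    "N": int(N),
                    "q": q,
                    "T_max": curve.T_max,
                    "C_at_1": curve.c_at(1.0),
                    "C_over_N": curve.c_at(1.0) / N,
                    "S_bits": S,
                    "S_over_N": S / N,
                }
            )
    out = {"rows": rows}
    Ns = np.array([r["N"] for r in rows], dtype=float)
    if np.unique(Ns).size >= 3:
        for key in ("C_over_N", "S_over_N"):
            vals = np.array([r[key] for r in rows])
            out[f"slope_{key}"] = least_squares_slope_ci(Ns, vals)
    else:
        out["slope_flagged"] = "fewer than 3 distinct N; no slope fitted"
    return out
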