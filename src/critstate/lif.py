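"""Conductance-based LIF network on a 2D grid with distance-dependent coupling.

2500 neurons (70% excitatory) sit on a 50x50 grid with 25 um spacing; each
ordered pair is connected with probability exp(-d^2 / (2 tau_w^2)),
tau_w = 100 um.  Membranes follow

    dv/dt = (v_rest - v)/tau_m + [g_exc (v_exc - v) + g_inh (v_inh - v)] / C

with exponentially decaying conductances incremented by the peak conductance
one delay (1 ms) after each presynaptic spike; threshold crossing emits a
spike, resets v and clamps it for a 1 ms refractory period.  Each neuron
receives an independent external Poisson drive; every external event adds
g_ext (v_exc - v)/C to the membrane potential directly.  The external event
conductance g_ext (default 0.28 nS, ~0.08 mV per event at rest) is a
calibration constant distinct from the recurrent excitatory peak: it places
the rheobase drive between the two operating input rates, so that low drive
(6 kHz) yields the fluctuation-driven synchronous-irregular (SI) bursting
regime and high drive (9 kHz) the mean-driven asynchronous-irregular (AI)
regime.  (Carrying the recurrent 0.7 nS peak into the external jump makes
6 kHz already mean-driving and both drives asynchronous.)

Integration is exponential Euler at dt = 0.1 ms (exact for conductances held
constant over a step; halving dt moves pooled rates by <5%); the grid is
open (no wrap-around) and self-connections are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .io import SpikeRecording
from .popstats import PopulationTrain, fano_factor, population_train

__all__ = [
    "NetworkParams",
    "Connectivity",
    "build_network",
    "connection_probability",
    "simulate",
    "subsample_to_rate",
    "split_by_fano",
]


@dataclass(frozen=True)
class NetworkParams:
    """Full parameterization of the spiking network (defaults = study values)."""

    n_neurons: int = 2500
    frac_excitatory: float = 0.7
    grid_side: int = 50
    grid_spacing_um: float = 25.0
    tau_w_um: float = 100.0       # connectivity decay constant
    c_m_pf: float = 200.0         # membrane capacitance
    tau_m_ms: float = 20.0
    v_rest_mv: float = -60.0
    v_th_mv: float = -50.0
    tau_exc_ms: float = 5.0
    tau_inh_ms: float = 10.0
    g_exc_peak_ns: float = 0.7
    g_inh_peak_ns: float = 50.0
    v_exc_mv: float = 0.0
    v_inh_mv: float = -70.0
    delay_ms: float = 1.0
    refractory_ms: float = 1.0
    i_ext_rate_hz: float = 6000.0
    g_ext_ns: float = 0.28
    dt_ms: float = 0.1

    def __post_init__(self) -> None:
        if self.grid_side**2 != self.n_neurons:
            raise ValueError("grid_side^2 must equal n_neurons")
        if not (self.v_rest_mv < self.v_th_mv < self.v_exc_mv):
            raise ValueError("require v_rest < v_th < v_exc")
        if self.v_inh_mv > self.v_rest_mv:
            raise ValueError("require v_inh <= v_rest")
        for tau in (self.tau_m_ms, self.tau_exc_ms, self.tau_inh_ms):
            if tau <= 0:
                raise ValueError("time constants must be positive")
        if self.dt_ms > 0.5:
            raise ValueError("dt must be <= 0.5 ms")


def connection_probability(d_um: np.ndarray, tau_w_um: float = 100.0) -> np.ndarray:
    """p(d) = exp(-d^2 / (2 tau_w^2))."""
    d = np.asarray(d_um, dtype=float)
    return np.exp(-(d**2) / (2.0 * tau_w_um**2))


@dataclass
class Connectivity:
    """Directed synapses in CSR-by-source layout; sign follows the source."""

    indptr: np.ndarray           # len n+1
    indices: np.ndarray          # targets, concatenated per source
    exc_mask: np.ndarray         # True where the source neuron is excitatory
    positions_um: np.ndarray     # n x 2

    @property
    def n(self) -> int:
        return self.indptr.size - 1

    def targets_of(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i] : self.indptr[i + 1]]


def build_network(params: NetworkParams, seed: int = 0) -> Connectivity:
    """Place neurons on the grid and draw the distance-dependent connectivity."""
    rng = np.random.default_rng(seed)
    n = params.n_neurons
    side = params.grid_side
    gx, gy = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    pos = np.column_stack([gx.ravel(), gy.ravel()]) * params.grid_spacing_um
    exc = np.zeros(n, dtype=bool)
    exc[rng.choice(n, size=int(round(params.frac_excitatory * n)), replace=False)] = True

    indptr = np.zeros(n + 1, dtype=np.int64)
    chunks = []
    for i in range(n):
        d2 = np.sum((pos - pos[i]) ** 2, axis=1)
        p = np.exp(-d2 / (2.0 * params.tau_w_um**2))
        p[i] = 0.0  # no self-connections
        targets = np.flatnonzero(rng.random(n) < p)
        chunks.append(targets.astype(np.int32))
        indptr[i + 1] = indptr[i] + targets.size
    return Connectivity(
        indptr=indptr,
        indices=np.concatenate(chunks),
        exc_mask=exc,
        positions_um=pos.astype(np.float64),
    )


@njit(cache=True)
def _integrate(
    indptr, indices, exc_mask, n_steps, dt, tau_m, v_rest, v_th, v_exc, v_inh,
    c_m, tau_e, tau_i, ge_peak, gi_peak, g_ext, delay_steps, refrac_steps,
    ext_lambda, v0, seed, out_step, out_idx,
):  # pragma: no cover - numba kernel
    np.random.seed(seed)
    n = indptr.size - 1
    v = v0.copy()
    ge = np.zeros(n)
    gi = np.zeros(n)
    D = delay_steps + 1
    buf_e = np.zeros((D, n))
    buf_i = np.zeros((D, n))
    refrac_until = np.full(n, -1, dtype=np.int64)
    dec_e = np.exp(-dt / tau_e)
    dec_i = np.exp(-dt / tau_i)
    count = 0
    cap = out_step.size
    for step in range(n_steps):
        slot = step % D
        for i in range(n):
            ge[i] += buf_e[slot, i]
            gi[i] += buf_i[slot, i]
            buf_e[slot, i] = 0.0
            buf_i[slot, i] = 0.0
        deliver = (step + delay_steps) % D
        for i in range(n):
            if step < refrac_until[i]:
                v[i] = v_rest
                continue
            k = np.random.poisson(ext_lambda)
            if k > 0:
                # each external event adds g_ext (v_exc - v)/C instantaneously
                q = 1.0 - g_ext / c_m
                v[i] = v_exc + (v[i] - v_exc) * q**k
            # exponential-Euler step: exact for conductances held over dt
            b = 1.0 / tau_m + (ge[i] + gi[i]) / c_m
            v_inf = (
                v_rest / tau_m + (ge[i] * v_exc + gi[i] * v_inh) / c_m
            ) / b
            v[i] = v_inf + (v[i] - v_inf) * np.exp(-b * dt)
            if np.abs(v[i]) > 1e3:
                return count, 2  # numerical divergence
            if v[i] >= v_th:
                if count >= cap:
                    return count, 3  # spike buffer overflow
                out_step[count] = step
                out_idx[count] = i
                count += 1
                v[i] = v_rest
                refrac_until[i] = step + refrac_steps
                peak = ge_peak if exc_mask[i] else gi_peak
                for ptr in range(indptr[i], indptr[i + 1]):
                    j = indices[ptr]
                    if exc_mask[i]:
                        buf_e[deliver, j] += peak
                    else:
                        buf_i[deliver, j] += peak
        for i in range(n):
            ge[i] *= dec_e
            gi[i] *= dec_i
    return count, 0


def simulate(
    params: NetworkParams,
    conn: Connectivity,
    duration: float,
    seed: int = 0,
    max_rate_per_neuron_hz: float = 60.0,
) -> SpikeRecording:
    """Integrate the network for ``duration`` seconds and return its spikes.

    Initial membrane potentials are uniform in [v_rest, v_th).  Raises on
    numerical divergence (advising a smaller dt) or spike-buffer overflow.
    """
    rng = np.random.default_rng(seed)
    n = conn.n
    dt = params.dt_ms
    n_steps = int(round(duration * 1000.0 / dt))
    cap = int(n * duration * max_rate_per_neuron_hz) + 1000
    out_step = np.empty(cap, dtype=np.int64)
    out_idx = np.empty(cap, dtype=np.int32)
    v0 = params.v_rest_mv + rng.random(n) * (params.v_th_mv - params.v_rest_mv)
    count, status = _integrate(
        conn.indptr,
        conn.indices,
        conn.exc_mask,
        n_steps,
        dt,
        params.tau_m_ms,
        params.v_rest_mv,
        params.v_th_mv,
        params.v_exc_mv,
        params.v_inh_mv,
        params.c_m_pf,
        params.tau_exc_ms,
        params.tau_inh_ms,
        params.g_exc_peak_ns,
        params.g_inh_peak_ns,
        params.g_ext_ns,
        int(round(params.delay_ms / dt)),
        int(round(params.refractory_ms / dt)),
        params.i_ext_rate_hz * dt * 1e-3,
        v0,
        int(seed) & 0x7FFFFFFF,
        out_step,
        out_idx,
    )
    if status == 2:
        raise ArithmeticError(
            "membrane potential diverged (|v| > 1000 mV); use a smaller dt"
        )
    if status == 3:
        raise RuntimeError(
            "spike buffer overflow; raise max_rate_per_neuron_hz"
        )
    times = out_step[:count] * dt * 1e-3
    times = np.clip(times, 0, np.nextafter(duration, 0))
    return SpikeRecording(
        out_idx[:count].astype(np.int64), times, duration=float(duration)
    )


def subsample_to_rate(
    rec: SpikeRecording, target_rate_hz: float, n_repeats: int = 1, seed: int = 0
) -> list[SpikeRecording]:
    """Randomly remove whole spike trains until the pooled rate reaches target.

    Neurons are removed uniformly at random; removal stops at the first
    crossing of the target pooled rate.  Returns ``n_repeats`` independent
    draws.
    """
    pooled = rec.n_spikes / rec.duration
    if target_rate_hz >= pooled:
        raise ValueError(
            f"target rate {target_rate_hz} Hz >= current pooled rate {pooled:.1f} Hz"
        )
    rng = np.random.default_rng(seed)
    sites = rec.sites
    counts = np.array([(rec.electrode_id == e).sum() for e in sites])
    out = []
    for _ in range(n_repeats):
        order = rng.permutation(sites.size)
        removed = np.cumsum(counts[order])
        remaining_rate = (rec.n_spikes - removed) / rec.duration
        k = int(np.argmax(remaining_rate <= target_rate_hz)) + 1
        keep = np.ones(sites.size, dtype=bool)
        keep[order[:k]] = False
        mask = np.isin(rec.electrode_id, sites[keep])
        out.append(
            SpikeRecording(
                rec.electrode_id[mask].copy(),
                rec.time[mask].copy(),
                duration=rec.duration,
                segment_labels=None
                if rec.segment_labels is None
                else rec.segment_labels.copy(),
            )
        )
    return out


def split_by_fano(
    rec: SpikeRecording,
    binsize_ms: float = 50.0,
    quantiles=(0.0, 0.25, 0.5, 0.75, 1.0),
) -> tuple[dict[str, SpikeRecording], np.ndarray]:
    """Partition 1 s segments into Fano-factor quantile strata.

    Returns a mapping ``"q1".."qK" -> SpikeRecording`` (each carrying
    segment labels that mark its own stratum, so state-restricted statistics
    apply directly) and the per-segment Fano factors.
    """
    n_seg = int(np.floor(rec.duration))
    if n_seg < 100:
        raise ValueError("need at least 100 one-second segments")
    b = binsize_ms / 1000.0
    per_seg = int(np.floor(1.0 / b))
    seg_idx = np.minimum(rec.time.astype(np.int64), n_seg - 1)
    ff = np.full(n_seg, np.nan)
    for k in range(n_seg):
        t = rec.time[seg_idx == k] - k
        counts = np.bincount(
            np.minimum((t / b).astype(np.int64), per_seg - 1), minlength=per_seg
        ).astype(float)
        if counts.mean() > 0:
            ff[k] = counts.var() / counts.mean()
    valid = ~np.isnan(ff)
    edges = np.nanquantile(ff[valid], quantiles)
    edges[-1] = np.inf
    strata: dict[str, SpikeRecording] = {}
    for i in range(len(quantiles) - 1):
        name = f"q{i + 1}"
        member = valid & (ff >= edges[i]) & (ff < edges[i + 1])
        if not member.any():
            warnings.warn(f"Fano stratum {name} is empty")
        labels = np.where(member, name, "other").astype(object)
        mask = member[seg_idx]
        strata[name] = SpikeRecording(
            rec.electrode_id[mask].copy(),
            rec.time[mask].copy(),
            duration=rec.duration,
            segment_labels=labels,
        )
    return strata, ff
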