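"""Avalanche detection, heavy-tail model comparison and shape collapse."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from critstate.avalanche import (
    AvalancheSet,
    _clusters_in_counts,
    default_bin_size,
    detect_avalanches,
    fit_tail,
    sample_discrete_powerlaw,
    shape_collapse,
    threshold_sweep,
)
from critstate.popstats import PopulationTrain

from conftest import train_from_counts


def brute_force_clusters(counts, threshold):
    """Reference detector: linear scan with explicit boundary discards."""
    kept, discarded, run = [], [], None
    for i, c in enumerate(list(counts) + [-1]):  # sentinel ends any open run
        if c >= threshold and i < len(counts):
            run = [i, i] if run is None else [run[0], i]
        elif run is not None:
            s, e = run[0], run[1] + 1
            if s == 0 or e == len(counts):
                discarded.append((s, e))
            else:
                kept.append((s, e))
            run = None
    return kept, discarded


def test_detector_hand_example():
    """Counts [0,2,1,0,3,0] at threshold 1 give clusters (3,2) and (3,1)."""
    train = train_from_counts([0, 2, 1, 0, 3, 0])
    av = detect_avalanches(train, 10.0, threshold=1)
    assert sorted(zip(av.sizes, av.lifetimes)) == [(3, 1), (3, 2)]


def test_detector_boundary_discard():
    """A supra-threshold run touching the window start is discarded."""
    train = train_from_counts([2, 2, 0, 1, 0])
    av = detect_avalanches(train, 10.0, threshold=1)
    assert list(av.sizes) == [1]
    assert av.n_spikes_discarded == 4


def test_isolated_spikes_give_unit_avalanches():
    times = np.arange(1, 20) * 0.5  # spikes 500 ms apart
    train = PopulationTrain(times, [(0.0, 10.0)])
    av = detect_avalanches(train, 10.0, threshold=1)
    assert (av.sizes == 1).all() and (av.lifetimes == 1).all()


def test_detector_matches_brute_force_oracle():
    """Detector equals the brute-force reference on 1000 random count vectors."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        n = rng.integers(3, 40)
        counts = rng.poisson(rng.uniform(0.2, 3.0), size=n)
        thr = int(rng.integers(1, 4))
        kept, discarded = brute_force_clusters(counts, thr)
        got_kept, got_disc = _clusters_in_counts(np.asarray(counts), thr)
        assert got_kept == kept
        assert got_disc == discarded


@settings(max_examples=200, deadline=None)
@given(
    counts=st.lists(st.integers(0, 6), min_size=3, max_size=50),
    thr=st.integers(1, 3),
)
def test_spike_conservation(counts, thr):
    """Sizes + sub-threshold spikes + discarded boundary spikes = binned total."""
    train = train_from_counts(counts)
    av = detect_avalanches(train, 10.0, threshold=thr)
    assert (
        av.sizes.sum() + av.n_spikes_subthreshold + av.n_spikes_discarded
        == av.n_spikes_binned
        == sum(counts)
    )
    assert (av.sizes >= av.lifetimes * thr).all()


def test_default_bin_size_rounds_to_ms():
    train = PopulationTrain(np.arange(100) * 0.0123, [(0.0, 1.3)])
    assert default_bin_size(train) == 12.0
    fast = PopulationTrain(np.arange(1000) * 0.0002, [(0.0, 0.2)])
    assert default_bin_size(fast) == 1.0  # never below 1 ms


class TestTailFit:
    def test_powerlaw_mle_matches_grid_search(self):
        """MLE equals a dense grid scan of the discrete log-likelihood."""
        from scipy import special

        rng = np.random.default_rng(3)
        x = sample_discrete_powerlaw(1.8, 800, xmin=1, rng=rng)
        fit = fit_tail(x)
        grid = np.arange(1.05, 5.0, 0.001)
        ll = [-a * np.log(x).sum() - x.size * np.log(special.zeta(a, 1)) for a in grid]
        assert abs(-fit.alpha - grid[int(np.argmax(ll))]) < 2e-3

    def test_powerlaw_recovery_and_llr_sign(self):
        x = sample_discrete_powerlaw(1.5, 100_000, xmin=1, rng=1)
        fit = fit_tail(x)
        assert fit.alpha == pytest.approx(-1.5, abs=0.02)
        assert fit.llr > 0

    def test_lognormal_recovery_llr_negative(self):
        rng = np.random.default_rng(5)
        x = np.ceil(rng.lognormal(1.0, 1.0, size=100_000)).astype(int)
        fit = fit_tail(x)
        assert fit.llr < 0 and fit.p < 0.05

    def test_degenerate_sample_raises(self):
        with pytest.raises(ValueError):
            fit_tail(np.full(100, 3))

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError):
            fit_tail(np.arange(1, 20))


def test_threshold_sweep_skips_sparse_rows():
    train = train_from_counts([0, 1, 0, 2, 0, 1, 0])
    rows = threshold_sweep(train, 10.0, [1, 5])
    assert rows[0]["n_avalanches"] >= 1
    assert "size_llr" not in rows[1]  # too few avalanches -> fit skipped


class TestShapeCollapse:
    @staticmethod
    def _selfsimilar_set(durations=range(40, 101, 10), copies=25):
        profiles, sizes, lifetimes = [], [], []
        for T in durations:
            t = np.arange(1, T + 1)
            prof = T * np.sin(np.pi * t / T)
            for _ in range(copies):
                profiles.append(prof)
                lifetimes.append(T)
                sizes.append(int(prof.sum()) + T)  # satisfies size >= T * thr
        return AvalancheSet(
            np.asarray(sizes), np.asarray(lifetimes), profiles,
            delta_t_ms=1.0, threshold=1,
        )

    def test_recovers_selfsimilar_exponent(self):
        """S(t,T) = T sin(pi t / T) collapses at gamma = 2 with tiny CI."""
        res = shape_collapse(self._selfsimilar_set())
        assert res.gamma == pytest.approx(2.0, abs=0.01)
        assert res.ci < 1e-4

    def test_rejects_nonselfsimilar_control(self):
        good = shape_collapse(self._selfsimilar_set())
        profiles, sizes, lifetimes = [], [], []
        for T in range(40, 101, 10):
            t = np.arange(1, T + 1)
            prof = (
                T * np.sin(np.pi * t / T) if T < 70 else np.full(T, float(T))
            )
            for _ in range(25):
                profiles.append(prof)
                lifetimes.append(T)
                sizes.append(int(prof.sum()) + T)
        bad = AvalancheSet(
            np.asarray(sizes), np.asarray(lifetimes), profiles,
            delta_t_ms=1.0, threshold=1,
        )
        res = shape_collapse(bad)
        assert res.ci > 10 * good.ci

    def test_too_few_durations_raises(self):
        a = self._selfsimilar_set(durations=[10, 20], copies=25)
        with pytest.raises(ValueError):
            shape_collapse(a)
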