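"""Population train, ACH, STA, firing rates and Fano factors."""

import numpy as np
import pytest

from critstate.io import LfpMatrix, SpikeRecording
from critstate.popstats import (
    fano_factor,
    firing_rates,
    population_ach,
    population_train,
    spike_triggered_average,
)


class TestPopulationTrain:
    def test_hand_computed_pooled_isis(self):
        """Electrodes at (0.1, 0.3) and (0.2, 0.4) pool to ISIs {0.1,0.1,0.1}."""
        rec = SpikeRecording([0, 0, 1, 1], [0.1, 0.3, 0.2, 0.4], duration=1.0)
        tr = population_train(rec)
        assert np.allclose(tr.isis, 0.1)
        assert tr.cv == pytest.approx(0.0, abs=1e-9)

    def test_poisson_cv_is_one(self, poisson_recording):
        assert population_train(poisson_recording).cv == pytest.approx(1.0, abs=0.05)

    def test_state_restriction_never_spans_gaps(self):
        labels = np.array(["a", "b", "a"], dtype=object)
        rec = SpikeRecording(
            [0, 0, 0, 0], [0.9, 1.5, 2.1, 2.5], duration=3.0, segment_labels=labels
        )
        tr = population_train(rec, state="a")
        # ISI 0.9 -> 2.1 would span the 'b' gap; only 2.1 -> 2.5 counts
        assert np.allclose(tr.isis, [0.4])

    def test_missing_state_raises(self):
        rec = SpikeRecording(
            [0, 0], [0.1, 0.2], duration=1.0, segment_labels=np.array(["a"])
        )
        with pytest.raises(ValueError):
            population_train(rec, state="zzz")

    def test_cv_nonnegative_zero_iff_regular(self):
        regular = SpikeRecording([0] * 10, np.arange(10) * 0.05, duration=1.0)
        assert population_train(regular).cv == pytest.approx(0.0, abs=1e-9)


class TestAch:
    def test_poisson_corrected_ach_near_zero(self, poisson_recording):
        res = population_ach(
            poisson_recording, np.arange(100), n_shuffles=50, seed=0
        )
        off = np.r_[res.curve[:250], res.curve[251:]]
        assert np.abs(off).max() < 0.1  # relative to center peak 1
        assert abs(res.area) < 0.01

    def test_symmetry(self, poisson_recording):
        res = population_ach(poisson_recording, np.arange(40), seed=1)
        assert np.allclose(res.curve, res.curve[::-1])

    def test_common_modulation_oscillates_at_200ms(self):
        """5 Hz co-modulated spikes give ACH peaks at +-200 ms lags."""
        rng = np.random.default_rng(2)
        duration = 120.0
        t_grid = np.arange(0, duration, 0.001)
        lam = 40.0 * np.clip(np.sin(2 * np.pi * 5 * t_grid), 0, None) * 0.001
        times, elecs = [], []
        for ch in range(4):
            counts = rng.poisson(lam)
            idx = np.repeat(np.arange(t_grid.size), counts)
            times.append((idx + rng.random(idx.size)) * 0.001)
            elecs.append(np.full(idx.size, ch))
        rec = SpikeRecording(
            np.concatenate(elecs), np.concatenate(times), duration=duration
        )
        res = population_ach(rec, np.arange(int(duration)), seed=3)
        lag200 = np.flatnonzero(np.isclose(res.lags_ms, 200.0))[0]
        lag100 = np.flatnonzero(np.isclose(res.lags_ms, 100.0))[0]
        assert res.curve[lag200] > res.curve[lag100] + 0.05

    def test_sync_state_has_larger_area_than_desync(self, synth_recording):
        rec, _, labels = synth_recording
        areas = {}
        for st in ("syn_slow_ii", "desyn_i"):
            segs = np.flatnonzero(labels == st)
            areas[st] = population_ach(rec, segs, n_shuffles=30, seed=4).area
        assert areas["syn_slow_ii"] > areas["desyn_i"]


class TestSta:
    def test_unrelated_lfp_sta_near_zero(self, poisson_recording):
        rng = np.random.default_rng(5)
        lfp = LfpMatrix(rng.standard_normal((2, 200_000)))
        res = spike_triggered_average(poisson_recording, lfp)
        assert np.abs(res.curve).max() < 5.0 / np.sqrt(res.n_spikes_used)

    def test_spikes_at_cosine_troughs_give_trough_at_zero_lag(self):
        fs = 1000.0
        duration = 100.0
        t = np.arange(int(duration * fs)) / fs
        lfp_sig = -np.cos(2 * np.pi * 5 * t)
        # spikes exactly at the LFP minima (cos peaks): t = k / 5
        spikes = np.arange(1, duration * 5 - 1) / 5.0
        rec = SpikeRecording(np.zeros(spikes.size, int), spikes, duration=duration)
        res = spike_triggered_average(rec, LfpMatrix(lfp_sig[None, :]))
        mid = res.curve.size // 2
        assert res.curve[mid] == pytest.approx(res.curve.min())
        assert res.negative_peak < -1.0
        assert res.area > 0

    def test_sync_sta_area_exceeds_desync(self, synth_recording):
        rec, lfp, labels = synth_recording
        areas = {}
        for st in ("syn_slow_ii", "desyn_i"):
            segs = np.flatnonzero(labels == st)
            areas[st] = spike_triggered_average(rec, lfp, state_segments=segs).area
        assert areas["syn_slow_ii"] > areas["desyn_i"]

    def test_edge_spikes_dropped_and_counted(self):
        lfp = LfpMatrix(np.random.default_rng(6).standard_normal((1, 1000)))
        rec = SpikeRecording(
            np.zeros(200, int), np.linspace(0.0, 0.999, 200), duration=1.0
        )
        res = spike_triggered_average(rec, lfp, window_ms=250)
        assert res.n_spikes_dropped > 0
        assert res.n_spikes_used + res.n_spikes_dropped == 200


class TestRates:
    def test_single_electrode_rate(self):
        rec = SpikeRecording(np.zeros(10, int), np.arange(10) * 0.95, duration=10.0)
        assert firing_rates(rec)["all"] == pytest.approx(1.0)

    def test_rates_additive_over_electrodes(self, poisson_recording):
        rec = poisson_recording
        per = [
            rec.spikes_of(e).size / rec.duration for e in rec.sites
        ]
        pooled = rec.n_spikes / rec.duration
        assert pooled == pytest.approx(sum(per))
        mean_rate = firing_rates(rec)["all"]
        assert mean_rate == pytest.approx(pooled / rec.n_sites)

    def test_per_state_rates(self):
        labels = np.array(["a", "b"], dtype=object)
        rec = SpikeRecording(
            [0, 0, 0], [0.1, 0.2, 1.5], duration=2.0, segment_labels=labels
        )
        rates = firing_rates(rec, labels)
        assert rates["a"] == pytest.approx(2.0)
        assert rates["b"] == pytest.approx(1.0)


class TestFano:
    def test_poisson_fano_near_one(self, poisson_recording):
        tr = population_train(poisson_recording)
        assert fano_factor(tr, 100.0) == pytest.approx(1.0, abs=0.15)

    def test_regular_train_fano_zero(self):
        # spikes placed mid-bin so float rounding cannot move them across edges
        rec = SpikeRecording(
            np.zeros(100, int), np.arange(100) * 0.1 + 0.05, duration=10.0
        )
        tr = population_train(rec)
        assert fano_factor(tr, 100.0) == 0.0

    def test_too_short_raises(self):
        rec = SpikeRecording([0, 0, 0], [0.1, 0.2, 0.3], duration=0.5)
        tr = population_train(rec)
        with pytest.raises(ValueError):
            fano_factor(tr, 100.0)
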