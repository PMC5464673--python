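"""Pairwise maximum-entropy model: fitting, distribution, thermodynamics."""

import numpy as np
import pytest
from scipy import optimize, stats

from critstate.mem import (
    MemModel,
    PatternData,
    _all_patterns,
    binarize,
    binomial_chance_bound,
    decode_states,
    empirical_distribution,
    entropy,
    fit_independent,
    fit_pairwise,
    heat_capacity,
    js_goodness,
    least_squares_slope_ci,
    metropolis_moments,
    model_distribution,
    sample_patterns,
)


def random_model(N=6, seed=0, scale=0.4):
    rng = np.random.default_rng(seed)
    h = rng.normal(0, scale, N)
    J = rng.normal(0, scale / np.sqrt(N), (N, N))
    J = 0.5 * (J + J.T)
    np.fill_diagonal(J, 0.0)
    return MemModel(h, J)


class TestDistribution:
    def test_uniform_model(self):
        m = MemModel(np.zeros(6), np.zeros((6, 6)))
        _, E, P = model_distribution(m)
        assert np.allclose(E, 0) and np.allclose(P, 1 / 64)

    def test_two_spin_enumeration(self):
        """N=2, h=0, J12=J: P(++)=P(--)=e^J/Z with Z=2e^J+2e^-J."""
        J = 0.8
        m = MemModel(np.zeros(2), np.array([[0.0, J], [J, 0.0]]))
        M, E, P = model_distribution(m)
        Z = 2 * np.exp(J) + 2 * np.exp(-J)
        for row, p in zip(M, P):
            expected = np.exp(J if row[0] == row[1] else -J) / Z
            assert p == pytest.approx(expected, rel=1e-12)

    def test_exact_mode_capacity_error(self):
        m = MemModel(np.zeros(25), np.zeros((25, 25)))
        with pytest.raises(ValueError, match="exact"):
            model_distribution(m)

    def test_sampler_matches_exact_moments(self):
        """Metropolis moments agree with enumeration within 3 standard errors."""
        m = random_model(6, seed=3)
        M, _, P = model_distribution(m)
        mean_exact = M.T @ P
        mean_mc, corr_mc, _, _ = metropolis_moments(m, n_steps=500_000, seed=9)
        # effective samples ~ n_steps / (N * autocorrelation); be conservative
        se = 3.0 * np.sqrt(1.0 / 500_000) * 8
        assert np.abs(mean_mc - mean_exact).max() < max(se, 0.02)


class TestFitting:
    def test_independent_closed_form(self):
        rng = np.random.default_rng(0)
        pat = np.where(rng.random((5000, 4)) < 0.75, 1, -1).astype(np.int8)
        model = fit_independent(PatternData(pat, 10.0))
        m_emp = pat.astype(float).mean(axis=0)
        assert np.allclose(model.h, np.arctanh(m_emp))
        # model reproduces the rates exactly
        M, _, P = model_distribution(model)
        assert np.allclose(M.T @ P, m_emp, atol=1e-9)

    def test_pairwise_reproduces_moments_within_tol(self):
        truth = random_model(5, seed=1)
        data = sample_patterns(truth, 20_000, seed=2)
        model = fit_pairwise(data, max_iter=500)
        assert model.converged
        m_emp, c_emp = data.moments()
        M, _, P = model_distribution(model)
        assert np.abs(M.T @ P - m_emp).max() < 0.005
        c_model = (M * P[:, None]).T @ M
        off = ~np.eye(5, dtype=bool)
        assert np.abs((c_model - c_emp)[off]).max() < 0.005

    def test_parameter_recovery(self):
        """h and J of a known N=6 model recovered within 0.1 RMS at L=5e4."""
        truth = random_model(6, seed=4)
        data = sample_patterns(truth, 50_000, seed=5)
        model = fit_pairwise(data, max_iter=1000)
        rms_h = np.sqrt(np.mean((model.h - truth.h) ** 2))
        off = ~np.eye(6, dtype=bool)
        rms_j = np.sqrt(np.mean((model.J - truth.J)[off] ** 2))
        assert rms_h < 0.1 and rms_j < 0.1

    def test_uncorrelated_data_gives_zero_couplings(self):
        rng = np.random.default_rng(6)
        pat = np.where(rng.random((30_000, 5)) < 0.3, 1, -1).astype(np.int8)
        model = fit_pairwise(PatternData(pat, 10.0), max_iter=300)
        off = ~np.eye(5, dtype=bool)
        assert np.abs(model.J[off]).max() < 0.05

    def test_maximum_entropy_property(self):
        """Fitted P has maximal entropy among distributions matching moments (N=3)."""
        truth = random_model(3, seed=7, scale=0.5)
        data = sample_patterns(truth, 30_000, seed=8)
        model = fit_pairwise(data, max_iter=800, tol=1e-4)
        M, _, P = model_distribution(model)
        m_emp, c_emp = data.moments()
        # oracle: directly maximize entropy under the same moment constraints
        iu = np.triu_indices(3, k=1)

        def neg_entropy(q):
            q = np.abs(q) / np.abs(q).sum()
            return float(np.sum(q * np.log(np.maximum(q, 1e-300))))

        cons = [
            {"type": "eq", "fun": lambda q: np.abs(q).sum() - 1.0},
            {"type": "eq",
             "fun": lambda q: M.T @ (np.abs(q) / np.abs(q).sum()) - M.T @ P},
            {"type": "eq",
             "fun": lambda q: ((M[:, iu[0]] * M[:, iu[1]]).T
                               @ (np.abs(q) / np.abs(q).sum())
                               - (M[:, iu[0]] * M[:, iu[1]]).T @ P)},
        ]
        res = optimize.minimize(
            neg_entropy, x0=np.full(8, 1 / 8), constraints=cons, method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-12},
        )
        s_fit = -np.sum(P * np.log(P))
        s_oracle = -res.fun
        assert s_oracle <= s_fit + 1e-4 / np.log(2)


class TestGoodness:
    def test_js_zero_for_identical(self):
        p = np.full(8, 1 / 8)
        d, g = js_goodness(p, p)
        assert d == 0 and g == np.inf

    def test_js_maximum_for_disjoint(self):
        p = np.r_[np.full(4, 0.25), np.zeros(4)]
        q = np.r_[np.full(4, 1e-12), np.full(4, 0.25 - 1e-12)]
        d, _ = js_goodness(p, q)
        assert d == pytest.approx(np.log(2), rel=1e-3)

    def test_js_symmetry(self):
        rng = np.random.default_rng(1)
        p = rng.random(16)
        p /= p.sum()
        q = rng.random(16) + 0.01
        q /= q.sum()
        assert js_goodness(p, q)[0] == pytest.approx(js_goodness(q, p)[0])

    def test_unnormalized_raises(self):
        with pytest.raises(ValueError):
            js_goodness(np.full(4, 0.3), np.full(4, 0.25))


class TestThermo:
    def test_uniform_model_flat_capacity_and_full_entropy(self):
        m = MemModel(np.zeros(6), np.zeros((6, 6)))
        curve = heat_capacity(m)
        assert np.allclose(curve.C, 0)
        assert entropy(m) == pytest.approx(6.0, abs=1e-9)

    def test_two_spin_closed_form(self):
        """Ferromagnetic pair matches the analytic two-spin C(T) to 1e-6."""
        J = 1.0
        m = MemModel(np.zeros(2), np.array([[0.0, J], [J, 0.0]]))
        T = np.arange(0.1, 3.0, 0.02)
        curve = heat_capacity(m, T_grid=T)
        # states: ++/-- at energy -J (x2), +-/-+ at +J (x2)
        w = np.exp(J / T) + np.exp(-J / T)
        e_mean = (-J * np.exp(J / T) + J * np.exp(-J / T)) / w
        e2_mean = J**2
        expected = (e2_mean - e_mean**2) / T**2
        assert np.abs(curve.C - expected).max() < 1e-6

    def test_deterministic_model_entropy_near_zero(self):
        m = MemModel(np.full(4, 8.0), np.zeros((4, 4)))
        assert entropy(m) < 0.01

    def test_entropy_integral_matches_enumeration(self):
        """Thermodynamic integral agrees with -sum P log2 P within 2%."""
        for seed in range(4):
            m = random_model(6, seed=seed)
            _, _, P = model_distribution(m)
            s_direct = -np.sum(P * np.log2(P))
            assert entropy(m) == pytest.approx(s_direct, rel=0.02)

    def test_sampled_capacity_matches_exact(self):
        m = random_model(6, seed=11)
        T = np.array([0.5, 1.0, 2.0])
        exact = heat_capacity(m, T_grid=T)
        mc = heat_capacity(m, T_grid=T, method="mc", seed=4, mc_steps=500_000)
        assert np.abs(mc.C - exact.C).max() < 0.25 * max(exact.C.max(), 1.0)


class TestDecoding:
    def test_chance_bound_exact_binomial(self):
        """Bound equals the exact binomial quantile (n=50, p=0.2 -> 15 hits)."""
        k = binomial_chance_bound(50, 0.2)
        cdf = 0.0
        for j in range(51):
            cdf += stats.binom.pmf(j, 50, 0.2)
            if cdf >= 0.95:
                break
        assert k == j == 15

    def test_distinct_models_decodable(self):
        data = {
            s: sample_patterns(random_model(4, seed=s, scale=0.8), 4000, seed=10 + s)
            for s in range(3)
        }
        for s, d in data.items():
            d.state = s
        res = decode_states(
            data, N=4, Q=3, repeats=5, seed=0, fit_kwargs={"max_iter": 200}
        )
        assert res["accuracy_median"] > res["chance_bound_percent"]
        assert res["accuracy_median"] > 80.0

    def test_identical_data_decodes_at_chance(self):
        base = sample_patterns(random_model(4, seed=20), 3000, seed=21)
        data = {s: PatternData(base.patterns.copy(), 10.0) for s in range(3)}
        res = decode_states(
            data, N=4, Q=2, repeats=6, seed=1, fit_kwargs={"max_iter": 60}
        )
        assert res["accuracy_median"] < 70.0  # near chance (33%), far from perfect


class TestBinarize:
    def test_silent_and_saturated_sites(self):
        from critstate.io import SpikeRecording

        t = np.arange(0.005, 10.0, 0.01)  # site 1 fires every 10 ms
        rec = SpikeRecording(
            np.r_[np.zeros(1, int), np.ones(t.size, int)],
            np.r_[[0.5], t],
            duration=10.0,
        )
        pat = binarize(rec, [0, 1], 10.0)
        assert pat.emission_probability[1] == 1.0
        assert pat.emission_probability[0] == pytest.approx(1 / 1000)

    def test_state_restriction(self):
        from critstate.io import SpikeRecording

        labels = np.array(["a", "b"] * 5, dtype=object)
        t = np.arange(0.05, 10.0, 0.1)
        rec = SpikeRecording(
            np.zeros(t.size, int) , t, duration=10.0, segment_labels=labels
        )
        rec2 = SpikeRecording(
            np.r_[np.zeros(t.size, int), [1]], np.r_[t, [0.123]],
            duration=10.0, segment_labels=labels,
        )
        pat = binarize(rec2, [0, 1], 50.0, state="b")
        assert pat.L == 5 * 20
        assert pat.emission_probability[1] == 0.0  # site 1 spiked only in 'a'


def test_slope_ci_coverage():
    """95% CI of the least-squares slope covers the truth ~95% of the time."""
    rng = np.random.default_rng(99)
    x = np.arange(10.0)
    hits = 0
    n_sim = 1000
    for _ in range(n_sim):
        y = 2.0 + 0.3 * x + rng.normal(0, 1.0, x.size)
        lo, hi = least_squares_slope_ci(x, y)["ci"]
        hits += lo <= 0.3 <= hi
    assert 0.93 < hits / n_sim < 0.97


def test_ensemble_scan_degenerate_single_n_flagged():
    """A scan with one ensemble size yields rows but no slope fit."""
    from critstate.mem import ensemble_scan

    truth = random_model(6, seed=30)
    data = sample_patterns(truth, 3000, seed=31)
    out = ensemble_scan(data, N_list=[4], Q=1, seed=0,
                        fit_kwargs={"max_iter": 100})
    assert len(out["rows"]) == 1
    assert "slope_C_over_N" not in out
    assert "flagged" in " ".join(out.keys()) or "slope_flagged" in out


def test_ensemble_scan_slopes_over_n():
    """Scan over N returns per-N thermodynamics and slope CIs."""
    from critstate.mem import ensemble_scan

    truth = random_model(8, seed=32, scale=0.5)
    data = sample_patterns(truth, 6000, seed=33)
    out = ensemble_scan(data, N_list=[4, 5, 6], Q=2, seed=1,
                        fit_kwargs={"max_iter": 150, "tol": 0.01})
    assert {r["N"] for r in out["rows"]} == {4, 5, 6}
    assert "slope_S_over_N" in out and "ci" in out["slope_S_over_N"]
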