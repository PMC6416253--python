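"""Simplex projection, S-map, E selection, nonlinearity test.

The simplex and S-map forecasters are checked against independent
brute-force re-implementations written here with plain loops.
"""

import numpy as np
import pytest

from seasonccm.edm import (
    SimplexForecaster,
    pearson_rho,
    phase_randomize,
    select_embedding_dimension,
    simplex_forecast,
    smap_forecast,
    smap_nonlinearity_test,
)
from seasonccm.embedding import embed


def brute_force_simplex(x, E, tp=1, theiler=1):
    """Exhaustive nearest-neighbor forecast of a single series."""
    n = len(x)
    t0 = E - 1
    times = list(range(t0, n))
    vec = {t: np.array([x[t - k] for k in range(E)]) for t in times}
    preds, obs = [], []
    for t in times:
        if t + tp >= n:
            continue
        cands = []
        for s in times:
            if s == t or abs(s - t) <= theiler or s + tp >= n:
                continue
            cands.append((np.linalg.norm(vec[t] - vec[s]), s))
        cands.sort(key=lambda p: (p[0], p[1]))
        if len(cands) < E + 1:
            continue
        nn = cands[: E + 1]
        # keep deterministic ties consistent with distance ordering
        d = np.array([c[0] for c in nn])
        d1 = d.min()
        w = (d == 0).astype(float) if d1 == 0 else np.exp(-d / d1)
        w = w / w.sum()
        preds.append(sum(wi * x[s + tp] for wi, (_, s) in zip(w, nn)))
        obs.append(x[t + tp])
    return np.array(preds), np.array(obs)


def brute_force_smap(x, E, theta, tp=1, theiler=1, ridge=1e-8):
    n = len(x)
    t0 = E - 1
    times = list(range(t0, n))
    vec = {t: np.array([x[t - k] for k in range(E)]) for t in times}
    preds, obs = [], []
    for t in times:
        if t + tp >= n:
            continue
        lib = [s for s in times
               if s != t and abs(s - t) > theiler and s + tp < n]
        if len(lib) < 2:
            continue
        d = np.array([np.linalg.norm(vec[t] - vec[s]) for s in lib])
        dbar = d.mean()
        w = np.ones_like(d) if (theta == 0 or dbar == 0) else np.exp(-theta * d / dbar)
        A = np.column_stack([np.ones(len(lib)),
                             np.array([vec[s] for s in lib])])
        y = np.array([x[s + tp] for s in lib])
        W = np.diag(w)
        lam = ridge * max(1.0, float(np.abs(A * np.sqrt(w)[:, None]).max()) ** 2)
        beta = np.linalg.solve(A.T @ W @ A + lam * np.eye(A.shape[1]),
                               A.T @ W @ y)
        preds.append(beta[0] + vec[t] @ beta[1:])
        obs.append(x[t + tp])
    return np.array(preds), np.array(obs)


def logistic_series(r=3.8, n=100, x0=0.37):
    x = np.empty(n + 100)
    x[0] = x0
    for t in range(len(x) - 1):
        x[t + 1] = r * x[t] * (1 - x[t])
    return x[100:]


class TestSimplex:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        res = simplex_forecast(embed(x, E=2))
        preds, obs = brute_force_simplex(x, E=2)
        np.testing.assert_allclose(res.predicted, preds, atol=1e-10)
        np.testing.assert_allclose(res.observed, obs, atol=1e-10)

    @pytest.mark.parametrize("E", [1, 2, 3])
    def test_matches_brute_force_across_E(self, E):
        rng = np.random.default_rng(E + 10)
        x = rng.normal(size=40)
        res = simplex_forecast(embed(x, E=E))
        preds, _ = brute_force_simplex(x, E=E)
        np.testing.assert_allclose(res.predicted, preds, atol=1e-10)

    def test_chaotic_map_is_one_step_predictable(self):
        res = simplex_forecast(embed(logistic_series(), E=2))
        assert res.rho > 0.95

    def test_iid_noise_is_unpredictable(self):
        rhos = []
        for seed in range(20):
            x = np.random.default_rng(seed).normal(size=100)
            rhos.append(simplex_forecast(embed(x, E=2)).rho)
        assert abs(np.median(rhos)) < 0.3

    def test_affine_invariance_of_skill(self):
        x = logistic_series(n=80)
        r1 = simplex_forecast(embed(x, E=3)).rho
        r2 = simplex_forecast(embed(5.0 * x - 11.0, E=3)).rho
        assert abs(r1 - r2) < 1e-9

    def test_estimator_api(self):
        est = SimplexForecaster(E=2).fit(logistic_series(n=60))
        assert est.rho_ == est.result_.rho
        assert est.get_params()["E"] == 2
        assert len(est.predict()) == est.n_pred_


class TestEmbeddingSelection:
    def test_singleton_range(self):
        x = logistic_series(n=50)
        assert select_embedding_dimension(x, E_range=[3]) == 3

    def test_coupled_logistic_low_dimensional(self):
        n = 300
        x = np.empty(n)
        y = np.empty(n)
        x[0], y[0] = 0.4, 0.2
        for t in range(n - 1):
            x[t + 1] = x[t] * (3.8 - 3.8 * x[t] - 0.1 * y[t])
            y[t + 1] = y[t] * (3.5 - 3.5 * y[t] - 0.05 * x[t])
        # slight observation noise keeps the selection discriminative: the
        # noise-free map is already a function of x_t alone
        obs = x[100:] + np.random.default_rng(0).normal(0, 0.02, size=n - 100)
        E = select_embedding_dimension(obs, E_range=range(1, 8))
        assert E in (2, 3)

    def test_sine_is_planar(self):
        t = np.arange(240)
        x = np.sin(2 * np.pi * t / 12)
        E = select_embedding_dimension(x, E_range=range(1, 6))
        assert E in (2, 3)


class TestSMap:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=35)
        for theta in (0.0, 1.0, 4.0):
            res = smap_forecast(embed(x, E=2), theta=theta)
            preds, _ = brute_force_smap(x, E=2, theta=theta)
            np.testing.assert_allclose(res.predicted, preds, atol=1e-8)

    def test_theta_zero_grid_gives_zero_delta(self):
        res = smap_nonlinearity_test(
            logistic_series(n=80), E=2, theta_grid=[0.0], n_surrogate=5, seed=0
        )
        assert res.delta_rho == 0.0

    def test_theta_grid_must_include_zero(self):
        with pytest.raises(ValueError, match="include 0"):
            smap_nonlinearity_test(logistic_series(n=60), E=2,
                                   theta_grid=[0.5, 1.0])

    def test_linear_series_not_flagged(self):
        flags = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = np.empty(200)
            x[0] = rng.normal()
            for t in range(199):
                x[t + 1] = 0.6 * x[t] + rng.normal()
            res = smap_nonlinearity_test(
                x, E=2, theta_grid=(0.0, 0.5, 2.0, 8.0),
                n_surrogate=40, seed=seed,
            )
            flags.append(res.nonlinear)
        assert sum(flags) <= 1  # <= 10% of seeds

    def test_chaotic_series_flagged(self):
        flags = []
        for seed in range(10):
            x = logistic_series(n=200, x0=0.1 + 0.05 * seed)
            x = x + np.random.default_rng(seed).normal(0, 0.01, size=len(x))
            res = smap_nonlinearity_test(
                x, E=2, theta_grid=(0.0, 0.5, 2.0, 8.0),
                n_surrogate=40, seed=seed,
            )
            flags.append(res.nonlinear)
        assert sum(flags) >= 9  # >= 90% of seeds


class TestHelpers:
    def test_phase_randomize_preserves_amplitudes(self):
        x = np.random.default_rng(0).normal(size=36)
        surr = phase_randomize(x, np.random.default_rng(1))
        np.testing.assert_allclose(
            np.abs(np.fft.rfft(surr)), np.abs(np.fft.rfft(x)), atol=1e-9
        )

    def test_pearson_rho_degenerate_is_zero(self):
        assert pearson_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]) == 0.0
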