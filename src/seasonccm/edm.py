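"""Simplex projection, S-map, and the univariate EDM diagnostics.

These are the first two steps of the analysis protocol: (1) pick the
optimal embedding dimension E for each series by leave-one-out simplex
forecast skill, and (2) test the series for state-dependent (nonlinear)
dynamics by the S-map theta scan against phase-randomized surrogates.

Forecast skill is throughout the Pearson correlation rho between predicted
and observed values, the same scale-free statistic the cross-mapping step
uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

from .embedding import DelayEmbedding, EmbeddingError, embed, exclusion_matrix

DEFAULT_THETA_GRID = (0.0, 0.1, 0.3, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0)


def pearson_rho(pred: np.ndarray, obs: np.ndarray) -> float:
    """Pearson correlation, defined as 0.0 when either side is constant."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if len(pred) < 2:
        return 0.0
    sp, so = pred.std(), obs.std()
    if sp == 0 or so == 0 or not (np.isfinite(sp) and np.isfinite(so)):
        return 0.0
    return float(np.corrcoef(pred, obs)[0, 1])


@dataclass(frozen=True)
class ForecastResult:
    """Leave-one-out forecast of one series."""

    rho: float
    predicted: np.ndarray
    observed: np.ndarray
    target_segments: np.ndarray
    target_times: np.ndarray
    n_pred: int
    n_skipped: int


def _neighbor_weights(d: np.ndarray) -> np.ndarray:
    """Exponential distance weights exp(-d/d1); uniform over exact matches
    when the nearest distance is zero."""
    d1 = d.min()
    if d1 == 0:
        w = (d == 0).astype(float)
    else:
        w = np.exp(-d / d1)
    return w / w.sum()


def simplex_forecast(
    embedding: DelayEmbedding,
    tp: int = 1,
    theiler: int = 1,
) -> ForecastResult:
    """Nearest-neighbor (simplex) leave-one-out forecast at horizon ``tp``.

    Each target's prediction is the weight-normalized average of the
    futures of its E+1 nearest library neighbors, with weights
    ``exp(-d_i/d_1)``.  The target itself and temporally adjacent vectors
    within the Theiler window are excluded from its neighbor search;
    targets with fewer than E+1 eligible neighbors are skipped and counted.
    """
    X = embedding.vectors
    n = embedding.n_vectors
    k = embedding.E + 1
    fut, fut_ok = embedding.future(tp)

    D = cdist(X, X)
    D[exclusion_matrix(embedding, theiler)] = np.inf
    D[:, ~fut_ok] = np.inf  # neighbors must have a known future

    preds = np.full(n, np.nan)
    n_skipped = 0
    eligible = np.isfinite(D).sum(axis=1)
    for i in range(n):
        if not fut_ok[i]:
            continue
        if eligible[i] < k:
            n_skipped += 1
            continue
        idx = np.argpartition(D[i], k - 1)[:k]
        w = _neighbor_weights(D[i, idx])
        preds[i] = w @ fut[idx]

    mask = np.isfinite(preds) & fut_ok
    if mask.sum() == 0:
        raise EmbeddingError("no predictable targets: series too short for E")
    rho = pearson_rho(preds[mask], fut[mask])
    return ForecastResult(
        rho=rho,
        predicted=preds[mask],
        observed=fut[mask],
        target_segments=embedding.segments[mask],
        target_times=embedding.times[mask],
        n_pred=int(mask.sum()),
        n_skipped=n_skipped,
    )


def select_embedding_dimension(
    series,
    E_range=range(1, 6),
    tau: int = 1,
    tp: int = 1,
    theiler: int = 1,
    rho_tolerance: float = 1e-6,
) -> int:
    """Optimal E: argmax of leave-one-out simplex rho, ties toward small E.

    Rhos within ``rho_tolerance`` of the best count as ties (on noise-free
    deterministic series every E reaches rho ~ 1 up to float dust, and the
    smallest sufficient dimension is the meaningful answer).
    """
    rhos: dict[int, float] = {}
    for E in E_range:
        try:
            res = simplex_forecast(embed(series, E=E, tau=tau), tp=tp,
                                   theiler=theiler)
        except EmbeddingError:
            continue
        rhos[E] = res.rho
    if not rhos:
        raise EmbeddingError("no embedding dimension in range gave a defined rho")
    best = max(rhos.values())
    return int(min(E for E, r in rhos.items() if r >= best - rho_tolerance))


def smap_forecast(
    embedding: DelayEmbedding,
    theta: float,
    tp: int = 1,
    theiler: int = 1,
    ridge: float = 1e-8,
) -> ForecastResult:
    """S-map: locally weighted linear forecast with weighting
    ``exp(-theta * d / d_mean)``.

    ``theta = 0`` weights all library points equally (a global linear
    autoregressive map); increasing theta localizes the fit, so a skill
    gain at theta > 0 is evidence of state-dependent dynamics.  The local
    solve is ridge-regularized and never hard-fails on singular designs.
    """
    X = embedding.vectors
    n = embedding.n_vectors
    fut, fut_ok = embedding.future(tp)

    D = cdist(X, X)
    bad = exclusion_matrix(embedding, theiler) | ~fut_ok[None, :]

    preds = np.full(n, np.nan)
    for i in range(n):
        lib = ~bad[i]
        if lib.sum() < 2:
            continue
        d = D[i, lib]
        dbar = d.mean()
        w = np.ones_like(d) if (theta == 0 or dbar == 0) else np.exp(-theta * d / dbar)
        sw = np.sqrt(w)
        A = np.column_stack([np.ones(lib.sum()), X[lib]]) * sw[:, None]
        y = fut[lib] * sw
        # ridge-augmented least squares keeps degenerate local designs solvable
        lam = ridge * max(1.0, float(np.abs(A).max()) ** 2)
        p = A.shape[1]
        A_aug = np.vstack([A, np.sqrt(lam) * np.eye(p)])
        y_aug = np.concatenate([y, np.zeros(p)])
        beta = np.linalg.lstsq(A_aug, y_aug, rcond=None)[0]
        preds[i] = beta[0] + X[i] @ beta[1:]

    mask = np.isfinite(preds) & fut_ok
    if mask.sum() == 0:
        raise EmbeddingError("no predictable targets for S-map")
    rho = pearson_rho(preds[mask], fut[mask])
    return ForecastResult(
        rho=rho,
        predicted=preds[mask],
        observed=fut[mask],
        target_segments=embedding.segments[mask],
        target_times=embedding.times[mask],
        n_pred=int(mask.sum()),
        n_skipped=int(n - mask.sum()),
    )


def phase_randomize(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Amplitude-preserving phase randomization of a real series.

    Keeps the DC and (even-length) Nyquist coefficients, draws uniform
    phases for the remaining positive frequencies, and inverts with
    conjugate symmetry so the output is real with the exact amplitude
    spectrum of the input.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    spec = np.fft.rfft(x)
    n_free = len(spec) - 1 - (1 if n % 2 == 0 else 0)
    if n_free > 0:
        phases = rng.uniform(0, 2 * np.pi, size=n_free)
        spec[1:1 + n_free] = np.abs(spec[1:1 + n_free]) * np.exp(1j * phases)
    return np.fft.irfft(spec, n=n)


@dataclass(frozen=True)
class NonlinearityResult:
    delta_rho: float
    p_value: float
    nonlinear: bool
    rho_by_theta: dict[float, float]


def smap_nonlinearity_test(
    series,
    E: int,
    theta_grid=DEFAULT_THETA_GRID,
    n_surrogate: int = 100,
    seed: int = 0,
    tau: int = 1,
    tp: int = 1,
    theiler: int = 1,
) -> NonlinearityResult:
    """Test for state dependence: does localizing the S-map help?

    The statistic is ``delta_rho = max_theta rho(theta) - rho(0)``; its
    null distribution comes from phase-randomized surrogates of the series
    (linear dynamics with the same power spectrum), randomized per segment.
    """
    theta_grid = tuple(float(t) for t in theta_grid)
    if 0.0 not in theta_grid:
        raise ValueError("theta_grid must include 0 (the linear baseline)")
    if isinstance(series, dict):
        segs = [np.asarray(series[k], dtype=float) for k in sorted(series)]
    elif isinstance(series, (list, tuple)) and np.ndim(series[0]) == 1:
        segs = [np.asarray(s, dtype=float) for s in series]
    else:
        segs = [np.asarray(series, dtype=float)]
    if all(np.std(s) == 0 for s in segs):
        raise EmbeddingError("degenerate (constant) series: nonlinearity undefined")

    def delta_of(seg_list) -> tuple[float, dict[float, float]]:
        emb = embed(seg_list, E=E, tau=tau)
        rhos = {
            th: smap_forecast(emb, theta=th, tp=tp, theiler=theiler).rho
            for th in theta_grid
        }
        return max(rhos.values()) - rhos[0.0], rhos

    delta_obs, rho_by_theta = delta_of(segs)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_surrogate):
        surr = [phase_randomize(s, rng) for s in segs]
        d, _ = delta_of(surr)
        if d >= delta_obs:
            exceed += 1
    p = (1 + exceed) / (n_surrogate + 1)
    return NonlinearityResult(
        delta_rho=float(delta_obs),
        p_value=float(p),
        nonlinear=bool(p < 0.05),
        rho_by_theta=rho_by_theta,
    )


class SimplexForecaster(BaseEstimator):
    """Nearest-neighbor forecaster over a delay embedding.

    Parameters follow the EDM conventions: embedding dimension ``E``, lag
    ``tau``, prediction horizon ``tp``, and Theiler exclusion window.
    ``fit`` accepts a 1-D series, a list of per-segment series, or a dict
    of named segments, and performs the leave-one-out forecast.
    """

    def __init__(self, E: int = 2, tau: int = 1, tp: int = 1, theiler: int = 1):
        self.E = E
        self.tau = tau
        self.tp = tp
        self.theiler = theiler

    def fit(self, X, y=None):
        self.embedding_ = embed(X, E=self.E, tau=self.tau)
        res = simplex_forecast(self.embedding_, tp=self.tp, theiler=self.theiler)
        self.result_ = res
        self.rho_ = res.rho
        self.n_pred_ = res.n_pred
        return self

    def predict(self):
        """Fitted leave-one-out predictions (aligned with ``result_``)."""
        return self.result_.predicted

    def score(self, X=None, y=None) -> float:
        return self.rho_


class SMapForecaster(BaseEstimator):
    """Locally weighted linear (S-map) forecaster; ``theta`` localizes."""

    def __init__(self, E: int = 2, theta: float = 0.0, tau: int = 1,
                 tp: int = 1, theiler: int = 1, ridge: float = 1e-8):
        self.E = E
        self.theta = theta
        self.tau = tau
        self.tp = tp
        self.theiler = theiler
        self.ridge = ridge

    def fit(self, X, y=None):
        self.embedding_ = embed(X, E=self.E, tau=self.tau)
        res = smap_forecast(self.embedding_, theta=self.theta, tp=self.tp,
                            theiler=self.theiler, ridge=self.ridge)
        self.result_ = res
        self.rho_ = res.rho
        return self

    def score(self, X=None, y=None) -> float:
        return self.rho_


__all__ = [
    "DEFAULT_THETA_GRID",
    "ForecastResult",
    "NonlinearityResult",
    "SimplexForecaster",
    "SMapForecaster",
    "pearson_rho",
    "phase_randomize",
    "simplex_forecast",
    "smap_forecast",
    "select_embedding_dimension",
    "smap_nonlinearity_test",
]
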