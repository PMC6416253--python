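"""Seasonal surrogate null series and the surrogate skill distribution.

Strong shared seasonality can make two causally unrelated genes highly
cross-predictable.  The null model therefore keeps everything seasonal and
spectral about the putative cause while destroying its specific temporal
alignment with the effect: per individual, the series is split into a
calendar-month mean profile plus a residual; the residual's Fourier phases
are randomized (amplitudes kept — an Ebisuzaki surrogate); profile and
randomized residual are recombined and the winter zeros re-imposed.

The calendar-month profile is precisely the projection of the series onto
the annual DFT harmonics, whose coefficients are zero in the residual and
stay zero under phase randomization — so every surrogate reproduces the
original per-month means to machine precision while its residual keeps the
exact amplitude spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ccm import CrossMapProblem
from .edm import phase_randomize
from .panel import WINTER_MONTHS, ExpressionPanel


class SurrogateError(ValueError):
    """Series not usable for seasonal surrogates (partial years, etc.)."""


def _months_for(length: int, months=None) -> np.ndarray:
    if months is not None:
        months = np.asarray(months, dtype=int)
        if len(months) != length:
            raise SurrogateError("months axis length mismatch")
        return months
    return np.tile(np.arange(1, 13), length // 12)


def seasonal_surrogate_series(
    x: np.ndarray,
    rng: np.random.Generator,
    months=None,
    mask_winter: bool = True,
) -> np.ndarray:
    """One seasonal surrogate of a single whole-years monthly series."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n % 12 != 0:
        raise SurrogateError(
            f"segment length {n} is not a whole number of years"
        )
    months = _months_for(n, months)
    profile = np.zeros(n)
    for m in np.unique(months):
        sel = months == m
        profile[sel] = x[sel].mean()
    residual = x - profile
    surr = profile + phase_randomize(residual, rng)
    if mask_winter:
        surr[np.isin(months, list(WINTER_MONTHS))] = 0.0
    return surr


def seasonal_surrogate(
    series,
    n: int,
    seed: int = 0,
    months=None,
    mask_winter: bool = True,
) -> list:
    """Generate ``n`` seasonal surrogates of a (possibly segmented) series.

    ``series`` may be a 1-D array, a list of per-segment arrays, or a dict
    of named segments; the return value mirrors that structure per
    surrogate.  Segments are randomized independently (they are physically
    distinct trees) but from one seeded stream.
    """
    rng = np.random.default_rng(seed)
    if isinstance(series, dict):
        keys = sorted(series)
        return [
            {k: seasonal_surrogate_series(series[k], rng, months, mask_winter)
             for k in keys}
            for _ in range(n)
        ]
    if isinstance(series, (list, tuple)) and np.ndim(series[0]) == 1:
        return [
            [seasonal_surrogate_series(s, rng, months, mask_winter)
             for s in series]
            for _ in range(n)
        ]
    x = np.asarray(series, dtype=float)
    return [seasonal_surrogate_series(x, rng, months, mask_winter)
            for _ in range(n)]


@dataclass(frozen=True)
class SurrogateEnsemble:
    """Null cross-map skill distribution for one ordered pair."""

    base_gene: str
    n_surrogates: int
    surrogate_series: list
    rho_surr_samples: np.ndarray

    @property
    def ucl95(self) -> float:
        return float(np.percentile(self.rho_surr_samples, 95))


def surrogate_rho_distribution(
    panel: ExpressionPanel,
    cause: str,
    effect: str,
    E: int,
    n_surrogates: int = 1000,
    n_boot_per_surrogate: int = 1,
    seed: int = 0,
    tau: int = 1,
    theiler: int = 1,
    keep_series: bool = False,
) -> SurrogateEnsemble:
    """Cross-map skill of the effect's embedding onto surrogate causes.

    For each seasonal surrogate of the cause gene, the (real) effect
    variable's full-library embedding cross-maps the surrogate; one
    deterministic full-library pass per surrogate by default, or the mean
    of ``n_boot_per_surrogate`` bootstrap replicates when > 1.
    """
    if not panel.winter_masked:
        raise SurrogateError("panel must be winter-masked (whole-year series)")
    prob = CrossMapProblem(panel, cause, effect, E, tau=tau, theiler=theiler)
    cause_segments = panel.segments(cause)
    months = {ind: None for ind in cause_segments}
    # month axis per individual comes from the panel itself
    for ind in cause_segments:
        months[ind] = panel.month_axis(ind)

    rng = np.random.default_rng(seed)
    rhos = np.empty(n_surrogates)
    kept = []
    for s in range(n_surrogates):
        surr = {
            ind: seasonal_surrogate_series(vals, rng, months[ind])
            for ind, vals in sorted(cause_segments.items())
        }
        x_surr, ok = prob.embedding.values_at(surr, tp=0)
        assert ok.all()
        if n_boot_per_surrogate <= 1:
            rhos[s] = prob.evaluate_full(x=x_surr)
        else:
            samples = np.empty(n_boot_per_surrogate)
            for b in range(n_boot_per_surrogate):
                lib = rng.integers(0, prob.n_vectors, size=prob.n_vectors)
                samples[b] = prob.evaluate_library(lib, x=x_surr)
            rhos[s] = samples.mean()
        if keep_series:
            kept.append(surr)
    return SurrogateEnsemble(
        base_gene=cause,
        n_surrogates=n_surrogates,
        surrogate_series=kept,
        rho_surr_samples=rhos,
    )


__all__ = [
    "SurrogateError",
    "SurrogateEnsemble",
    "seasonal_surrogate",
    "seasonal_surrogate_series",
    "surrogate_rho_distribution",
]
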