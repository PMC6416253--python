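"""Convergent cross mapping with bootstrap libraries.

To test whether gene X causally influences gene Y, the *effect* variable Y
is delay-embedded (Y's history carries the signature of its drivers) and
Y's nearest neighbors are used to estimate the contemporaneous value of X
(cross-map prediction at lag 0).  Skill is Pearson's rho between estimated
and observed X.  Convergence — skill rising with library size — separates
causal influence from mere correlation, so skill distributions are sampled
by bootstrap at the minimum informative library size (E + 1) and at the
maximum (all pooled vectors), 1,000 replicates each by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

from .edm import pearson_rho, select_embedding_dimension
from .embedding import exclusion_matrix
from .panel import ExpressionPanel
from .pool import pool_individuals

DEFAULT_N_BOOT = 1000


@dataclass(frozen=True)
class CcmRho:
    """Bootstrap cross-map skill distributions for one ordered pair."""

    cause: str
    effect: str
    E: int
    rho_min_samples: np.ndarray
    rho_max_samples: np.ndarray
    library_sizes: tuple[int, ...]
    rho_curve: np.ndarray

    @property
    def mean_rho_max(self) -> float:
        return float(np.mean(self.rho_max_samples))

    @property
    def ucl95_rho_min(self) -> float:
        return float(np.percentile(self.rho_min_samples, 95))


class CrossMapProblem:
    """Precomputed geometry for one (cause, effect) direction.

    Holds the pooled embedding of the effect (library) variable, the full
    pairwise distance matrix with self/Theiler exclusions, and the cause
    values aligned to every vector time.  All library evaluations —
    bootstraps and surrogates alike — reuse this object.
    """

    def __init__(
        self,
        panel: ExpressionPanel,
        cause: str,
        effect: str,
        E: int,
        tau: int = 1,
        theiler: int = 1,
    ):
        self.cause = cause
        self.effect = effect
        self.E = E
        self.tau = tau
        self.theiler = theiler
        lib = pool_individuals(panel, effect, E=E, tau=tau)
        self.embedding = lib.embedding
        self.n_vectors = self.embedding.n_vectors
        x, ok = self.embedding.values_at(panel.segments(cause), tp=0)
        assert ok.all()  # tp=0 always lands inside the segment
        self.x = x
        D = cdist(self.embedding.vectors, self.embedding.vectors)
        D[exclusion_matrix(self.embedding, theiler)] = np.inf
        self.D = D
        self.cause_segments = panel.segments(cause)

    # ------------------------------------------------------------------
    def evaluate_library(self, lib: np.ndarray, x: np.ndarray | None = None) -> float:
        """Cross-map skill using the (multiset) library ``lib`` of vector
        indices; duplicates from bootstrap resampling occupy neighbor
        slots independently.  Targets with fewer than E+1 eligible
        neighbors are skipped."""
        x = self.x if x is None else x
        k = self.E + 1
        Dsub = self.D[:, lib]
        elig = np.isfinite(Dsub).sum(axis=1)
        ok = elig >= k
        if ok.sum() < 2:
            return 0.0
        Dok = Dsub[ok]
        part = np.argpartition(Dok, k - 1, axis=1)[:, :k]
        rows = np.arange(Dok.shape[0])[:, None]
        d = Dok[rows, part]
        d1 = d.min(axis=1, keepdims=True)
        w = np.exp(-d / np.where(d1 > 0, d1, 1.0))
        zero = d1[:, 0] == 0
        if zero.any():
            w[zero] = (d[zero] == 0).astype(float)
        w /= w.sum(axis=1, keepdims=True)
        xv = x[lib]
        pred = (w * xv[part]).sum(axis=1)
        return pearson_rho(pred, x[ok])

    def full_library(self) -> np.ndarray:
        return np.arange(self.n_vectors)

    def evaluate_full(self, x: np.ndarray | None = None) -> float:
        """Single deterministic pass with the full library.

        Neighbor indices and weights depend only on the effect embedding,
        so they are computed once and reused — evaluating many surrogate
        cause series against the same library is then just a weighted sum.
        """
        if not hasattr(self, "_full_cache"):
            k = self.E + 1
            elig = np.isfinite(self.D).sum(axis=1)
            ok = elig >= k
            Dok = self.D[ok]
            part = np.argpartition(Dok, k - 1, axis=1)[:, :k]
            rows = np.arange(Dok.shape[0])[:, None]
            d = Dok[rows, part]
            d1 = d.min(axis=1, keepdims=True)
            w = np.exp(-d / np.where(d1 > 0, d1, 1.0))
            zero = d1[:, 0] == 0
            if zero.any():
                w[zero] = (d[zero] == 0).astype(float)
            w /= w.sum(axis=1, keepdims=True)
            self._full_cache = (ok, part, w)
        ok, part, w = self._full_cache
        x = self.x if x is None else x
        pred = (w * x[part]).sum(axis=1)
        return pearson_rho(pred, x[ok])

    def bootstrap(
        self,
        library_size: int,
        n_boot: int,
        rng: np.random.Generator,
        replace: bool = True,
    ) -> np.ndarray:
        if library_size < self.E + 1:
            raise ValueError(
                f"library_size {library_size} < E+1 = {self.E + 1}"
            )
        if library_size > self.n_vectors and not replace:
            raise ValueError(
                f"library_size {library_size} exceeds the {self.n_vectors} "
                "available vectors (without replacement)"
            )
        out = np.empty(n_boot)
        for b in range(n_boot):
            if replace:
                lib = rng.integers(0, self.n_vectors, size=library_size)
            else:
                lib = rng.choice(self.n_vectors, size=library_size, replace=False)
            out[b] = self.evaluate_library(lib)
        return out


def resolve_embedding_dimension(
    panel: ExpressionPanel,
    gene: str,
    E_range=range(1, 6),
    tau: int = 1,
    theiler: int = 1,
) -> int:
    """Optimal E of a gene's pooled series (the library variable's E is
    what each cross-map direction uses)."""
    return select_embedding_dimension(
        panel.segments(gene), E_range=E_range, tau=tau, theiler=theiler
    )


def cross_map(
    panel: ExpressionPanel,
    cause: str,
    effect: str,
    E: int,
    library_size: int,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    tau: int = 1,
    theiler: int = 1,
    replace: bool = True,
) -> np.ndarray:
    """Bootstrap cross-map skill for cause -> effect at one library size."""
    prob = CrossMapProblem(panel, cause, effect, E, tau=tau, theiler=theiler)
    rng = np.random.default_rng(seed)
    return prob.bootstrap(library_size, n_boot, rng, replace=replace)


def convergence_curve(
    panel: ExpressionPanel,
    cause: str,
    effect: str,
    E: int,
    sizes=None,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    tau: int = 1,
    theiler: int = 1,
) -> CcmRho:
    """Bootstrap rho across a library-size grid.

    ``sizes`` defaults to ``[E+1, ..., n_vectors]`` endpoints only.  The
    returned :class:`CcmRho` carries the full samples at the smallest
    (rho_min) and largest (rho_max) sizes.
    """
    prob = CrossMapProblem(panel, cause, effect, E, tau=tau, theiler=theiler)
    if sizes is None:
        sizes = [E + 1, prob.n_vectors]
    sizes = sorted(int(s) for s in sizes)
    if sizes[0] < E + 1:
        raise ValueError(f"minimum library size {sizes[0]} < E+1 = {E + 1}")
    rng = np.random.default_rng(seed)
    samples = {L: prob.bootstrap(L, n_boot, rng) for L in dict.fromkeys(sizes)}
    curve = np.array([samples[L].mean() for L in sizes])
    return CcmRho(
        cause=cause,
        effect=effect,
        E=E,
        rho_min_samples=samples[sizes[0]] if sizes[0] == E + 1
        else prob.bootstrap(E + 1, n_boot, rng),
        rho_max_samples=samples[sizes[-1]],
        library_sizes=tuple(sizes),
        rho_curve=curve,
    )


class ConvergentCrossMap(BaseEstimator):
    """CCM for one ordered gene pair, sklearn-estimator style.

    ``fit(panel)`` selects E for the effect (library) variable if not
    given, then samples bootstrap skill at the minimum (E+1) and maximum
    library sizes.  Fitted attributes: ``E_``, ``rho_min_samples_``,
    ``rho_max_samples_``, ``rho_curve_``, ``mean_rho_max_``.
    """

    def __init__(
        self,
        cause: str = "X",
        effect: str = "Y",
        E: int | None = None,
        sizes=None,
        n_boot: int = DEFAULT_N_BOOT,
        tau: int = 1,
        theiler: int = 1,
        seed: int = 0,
    ):
        self.cause = cause
        self.effect = effect
        self.E = E
        self.sizes = sizes
        self.n_boot = n_boot
        self.tau = tau
        self.theiler = theiler
        self.seed = seed

    def fit(self, X: ExpressionPanel, y=None):
        panel = X
        E = self.E if self.E is not None else resolve_embedding_dimension(
            panel, self.effect, tau=self.tau, theiler=self.theiler
        )
        res = convergence_curve(
            panel, self.cause, self.effect, E,
            sizes=self.sizes, n_boot=self.n_boot, seed=self.seed,
            tau=self.tau, theiler=self.theiler,
        )
        self.E_ = E
        self.result_ = res
        self.rho_min_samples_ = res.rho_min_samples
        self.rho_max_samples_ = res.rho_max_samples
        self.rho_curve_ = res.rho_curve
        self.library_sizes_ = res.library_sizes
        self.mean_rho_max_ = res.mean_rho_max
        return self


__all__ = [
    "DEFAULT_N_BOOT",
    "CcmRho",
    "CrossMapProblem",
    "ConvergentCrossMap",
    "cross_map",
    "convergence_curve",
    "resolve_embedding_dimension",
]
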