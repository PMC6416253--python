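"""Two-criterion causality decision per ordered gene pair, and the network.

A directed influence cause -> effect is called significant when

1. the mean bootstrap skill at the maximum library size (mean rho_max)
   exceeds both zero and the 95% upper confidence limit of the skill at
   the minimum library size (convergence: more data genuinely helps), and
2. mean rho_max minus the 95% upper confidence limit of the seasonal
   surrogate skill exceeds a margin epsilon (skill is not explained by
   shared seasonality plus spectrum).

Epsilon tightens for shorter panels because type-one errors are more
likely there: 0.02 for 24 points per individual, 0.01 for 36, linearly
interpolated in between.  "95% upper confidence limit" is the 95th
percentile of the respective sample distribution (one-sided).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .ccm import DEFAULT_N_BOOT, CcmRho, convergence_curve, resolve_embedding_dimension
from .panel import ExpressionPanel
from .surrogate import SurrogateEnsemble, surrogate_rho_distribution


def _seed_key(seed) -> list[int]:
    """Normalize an int-or-sequence seed into a list usable as an RNG key."""
    if isinstance(seed, (list, tuple)):
        return [int(s) for s in seed]
    return [int(seed)]


def epsilon_for_length(n_points_per_individual: int) -> float:
    """Decision margin epsilon as a function of series length.

    0.02 at <= 24 monthly points per individual, 0.01 at >= 36, linear in
    between.
    """
    n = int(n_points_per_individual)
    if n < 12:
        raise ValueError("need at least 12 points per individual")
    if n <= 24:
        return 0.02
    if n >= 36:
        return 0.01
    return 0.02 + (n - 24) * (0.01 - 0.02) / 12.0


@dataclass(frozen=True)
class CausalVerdict:
    """Decision record for one ordered pair, with full audit statistics."""

    cause: str
    effect: str
    E: int
    mean_rho_max: float
    ucl95_rho_min: float
    ucl95_rho_surr: float
    epsilon: float
    criterion1: bool
    criterion2: bool
    causal: bool

    @classmethod
    def from_stats(
        cls,
        cause: str,
        effect: str,
        E: int,
        mean_rho_max: float,
        ucl95_rho_min: float,
        ucl95_rho_surr: float,
        epsilon: float,
    ) -> "CausalVerdict":
        c1 = (mean_rho_max > 0) and (mean_rho_max > ucl95_rho_min)
        c2 = (mean_rho_max - ucl95_rho_surr) > epsilon
        return cls(
            cause=cause,
            effect=effect,
            E=E,
            mean_rho_max=float(mean_rho_max),
            ucl95_rho_min=float(ucl95_rho_min),
            ucl95_rho_surr=float(ucl95_rho_surr),
            epsilon=float(epsilon),
            criterion1=bool(c1),
            criterion2=bool(c2),
            causal=bool(c1 and c2),
        )


class CcmCausalityTest(BaseEstimator):
    """Full causality test for one ordered pair (cause -> effect).

    ``fit(panel)`` runs embedding-dimension selection for the effect
    (library) variable unless ``E`` is given, bootstrap CCM at minimum and
    maximum library sizes, the seasonal-surrogate null, and the
    two-criterion decision.  Fitted attributes: ``verdict_``, ``ccm_``,
    ``surrogates_``, ``E_``.
    """

    def __init__(
        self,
        cause: str = "X",
        effect: str = "Y",
        E: int | None = None,
        n_boot: int = DEFAULT_N_BOOT,
        n_surrogates: int = 1000,
        n_boot_per_surrogate: int = 1,
        epsilon: float | str = "auto",
        tau: int = 1,
        theiler: int = 1,
        seed: int = 0,
    ):
        self.cause = cause
        self.effect = effect
        self.E = E
        self.n_boot = n_boot
        self.n_surrogates = n_surrogates
        self.n_boot_per_surrogate = n_boot_per_surrogate
        self.epsilon = epsilon
        self.tau = tau
        self.theiler = theiler
        self.seed = seed

    def _resolved_epsilon(self, panel: ExpressionPanel) -> float:
        if self.epsilon == "auto":
            return epsilon_for_length(panel.n_points_per_individual())
        return float(self.epsilon)

    def fit(self, X: ExpressionPanel, y=None):
        panel = X
        E = self.E if self.E is not None else resolve_embedding_dimension(
            panel, self.effect, tau=self.tau, theiler=self.theiler
        )
        eps = self._resolved_epsilon(panel)
        # independent seeded substreams for bootstrap and surrogate stages
        base = _seed_key(self.seed)
        ccm_res: CcmRho = convergence_curve(
            panel, self.cause, self.effect, E,
            n_boot=self.n_boot, seed=base + [1],
            tau=self.tau, theiler=self.theiler,
        )
        surr: SurrogateEnsemble = surrogate_rho_distribution(
            panel, self.cause, self.effect, E,
            n_surrogates=self.n_surrogates,
            n_boot_per_surrogate=self.n_boot_per_surrogate,
            seed=base + [2],
            tau=self.tau, theiler=self.theiler,
        )
        self.E_ = E
        self.ccm_ = ccm_res
        self.surrogates_ = surr
        self.verdict_ = CausalVerdict.from_stats(
            self.cause, self.effect, E,
            mean_rho_max=ccm_res.mean_rho_max,
            ucl95_rho_min=ccm_res.ucl95_rho_min,
            ucl95_rho_surr=surr.ucl95,
            epsilon=eps,
        )
        return self


def test_causality(
    panel: ExpressionPanel,
    cause: str,
    effect: str,
    **kwargs,
) -> CausalVerdict:
    """Functional wrapper over :class:`CcmCausalityTest`."""
    est = CcmCausalityTest(cause=cause, effect=effect, **kwargs)
    est.fit(panel)
    return est.verdict_


_EDGE_COLUMNS = [
    "cause", "effect", "E", "mean_rho_max", "ucl95_rho_min",
    "ucl95_rho_surr", "epsilon", "criterion1", "criterion2", "causal",
]


class CcmNetwork(BaseEstimator):
    """Pairwise causal network over a gene set.

    ``fit(panel)`` runs the two-criterion test for every ordered pair of
    ``genes`` (all panel genes when None): n(n-1) tests, no multiplicity
    correction by default (``holm=True`` additionally requires a
    Holm-adjusted empirical surrogate p-value < 0.05).  Fitted attributes:
    ``edges_`` (verdict table, one row per ordered pair), ``verdicts_``,
    ``graph_`` (networkx DiGraph of causal edges), ``failures_``.
    """

    def __init__(
        self,
        genes=None,
        E: int | None = None,
        n_boot: int = DEFAULT_N_BOOT,
        n_surrogates: int = 1000,
        n_boot_per_surrogate: int = 1,
        epsilon: float | str = "auto",
        tau: int = 1,
        theiler: int = 1,
        holm: bool = False,
        seed: int = 0,
    ):
        self.genes = genes
        self.E = E
        self.n_boot = n_boot
        self.n_surrogates = n_surrogates
        self.n_boot_per_surrogate = n_boot_per_surrogate
        self.epsilon = epsilon
        self.tau = tau
        self.theiler = theiler
        self.holm = holm
        self.seed = seed

    def fit(self, X: ExpressionPanel, y=None):
        panel = X
        genes = list(self.genes) if self.genes is not None else panel.genes
        if len(genes) < 2:
            raise ValueError("network inference needs at least 2 genes")
        # E per library (effect) variable, computed once per gene
        E_by_gene = {}
        for g in genes:
            E_by_gene[g] = self.E if self.E is not None else (
                resolve_embedding_dimension(panel, g, tau=self.tau,
                                            theiler=self.theiler)
            )
        verdicts, failures, p_surr = [], [], []
        pairs = [(c, e) for c in genes for e in genes if c != e]
        for ci, (cause, effect) in enumerate(pairs):
            try:
                est = CcmCausalityTest(
                    cause=cause, effect=effect, E=E_by_gene[effect],
                    n_boot=self.n_boot, n_surrogates=self.n_surrogates,
                    n_boot_per_surrogate=self.n_boot_per_surrogate,
                    epsilon=self.epsilon, tau=self.tau, theiler=self.theiler,
                    seed=_seed_key(self.seed) + [ci],
                ).fit(panel)
            except Exception as exc:  # keep the rest of the network
                failures.append((cause, effect, repr(exc)))
                continue
            verdicts.append(est.verdict_)
            s = est.surrogates_.rho_surr_samples
            p_surr.append(
                (1 + np.sum(s >= est.verdict_.mean_rho_max)) / (len(s) + 1)
            )
        causal_flags = [v.causal for v in verdicts]
        if self.holm and verdicts:
            from statsmodels.stats.multitest import multipletests
            reject, *_ = multipletests(p_surr, alpha=0.05, method="holm")
            causal_flags = [c and r for c, r in zip(causal_flags, reject)]
        rows = []
        for v, flag in zip(verdicts, causal_flags):
            rows.append((v.cause, v.effect, v.E, v.mean_rho_max,
                         v.ucl95_rho_min, v.ucl95_rho_surr, v.epsilon,
                         v.criterion1, v.criterion2, flag))
        self.verdicts_ = verdicts
        self.failures_ = failures
        self.edges_ = pd.DataFrame(rows, columns=_EDGE_COLUMNS)
        self.E_by_gene_ = E_by_gene

        import networkx as nx
        g = nx.DiGraph()
        g.add_nodes_from(genes)
        for _, row in self.edges_[self.edges_["causal"]].iterrows():
            g.add_edge(row["cause"], row["effect"],
                       rho=float(row["mean_rho_max"]))
        self.graph_ = g
        return self


def build_network(panel: ExpressionPanel, genes=None, **kwargs) -> pd.DataFrame:
    """Functional wrapper over :class:`CcmNetwork`; returns the edge table."""
    est = CcmNetwork(genes=genes, **kwargs)
    est.fit(panel)
    return est.edges_


def network_metrics(edges: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Precision/recall of called edges against a ground-truth edge list."""
    called = {
        (r.cause, r.effect) for r in edges.itertuples() if r.causal
    }
    true_edges = {(r.cause, r.effect) for r in truth.itertuples()}
    tp = len(called & true_edges)
    precision = tp / len(called) if called else float("nan")
    recall = tp / len(true_edges) if true_edges else float("nan")
    return {
        "tp": tp,
        "n_called": len(called),
        "n_true": len(true_edges),
        "precision": precision,
        "recall": recall,
    }


def edges_to_dot(edges: pd.DataFrame) -> str:
    """Causal edges as a GraphViz DOT digraph."""
    lines = ["digraph ccm {"]
    for r in edges.itertuples():
        if r.causal:
            lines.append(
                f'  "{r.cause}" -> "{r.effect}" '
                f'[label="{r.mean_rho_max:.2f}"];'
            )
    lines.append("}")
    return "\n".join(lines)


__all__ = [
    "CausalVerdict",
    "CcmCausalityTest",
    "CcmNetwork",
    "build_network",
    "edges_to_dot",
    "epsilon_for_length",
    "network_metrics",
    "test_causality",
]
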