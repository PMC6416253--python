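"""Masting-like synthetic expression panels with known causal structure.

Latent gene dynamics follow coupled logistic maps — the canonical benchmark
family for cross-mapping causality, chosen because unidirectional coupling
is provable by construction and the chaotic regime matches the orbital
instability the causality test exploits.  One map iteration corresponds to
one growing-season month (June--October); winter months carry no latent
update, mimicking dormancy.  The observation layer multiplies the latent
state by a seasonal factor peaking in July and adds Gaussian noise, so that
two *uncoupled* genes can still share strong common seasonality — the
failure mode the seasonal surrogate null exists to absorb.

The latent update for gene j is

    x_j(t+1) = x_j(t) * (r_j - r_j * x_j(t) - sum_i c[i, j] * x_i(t))

with growth rate ``r_j`` in the chaotic band (~3.6--4.0) and ``c[i, j]``
the strength of influence of gene i on gene j.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import (
    GROWING_MONTHS,
    ExpressionPanel,
    apply_winter_mask,
    normalize_panel,
)

_BURN_IN = 200


class SimulationError(ValueError):
    """Invalid simulation parameters or divergent trajectory."""


@dataclass(frozen=True)
class NetworkSpec:
    """Full specification of a synthetic coupled-gene system.

    ``coupling[i, j]`` is the influence of gene ``genes[i]`` on
    ``genes[j]``; zero means no edge.  Identical spec + seed reproduces a
    bit-identical panel.
    """

    genes: tuple[str, ...]
    coupling: np.ndarray
    growth_rates: np.ndarray
    seasonal_amplitude: np.ndarray
    noise_sd: float = 0.05
    n_individuals: int = 3
    n_years: int = 2
    start_year: int = 2015
    seed: int = 0

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        if len(set(genes)) != len(genes):
            raise SimulationError("gene ids must be unique")
        n = len(genes)
        c = np.asarray(self.coupling, dtype=float)
        if c.shape != (n, n):
            raise SimulationError(f"coupling must be {n}x{n}, got {c.shape}")
        if np.any(np.diag(c) != 0):
            raise SimulationError("coupling diagonal must be zero")
        r = np.broadcast_to(np.asarray(self.growth_rates, dtype=float), (n,)).copy()
        amp = np.broadcast_to(
            np.asarray(self.seasonal_amplitude, dtype=float), (n,)
        ).copy()
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be >= 0")
        if self.n_individuals < 1:
            raise SimulationError("need at least one individual")
        if self.n_years < 2:
            raise SimulationError(
                "n_years must be >= 2: cross mapping needs at least E+2 "
                "growing-season points"
            )
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "coupling", c)
        object.__setattr__(self, "growth_rates", r)
        object.__setattr__(self, "seasonal_amplitude", amp)

    def truth_adjacency(self) -> pd.DataFrame:
        """Ground-truth directed edges as a (cause, effect, strength) frame."""
        rows = [
            (self.genes[i], self.genes[j], float(self.coupling[i, j]))
            for i in range(len(self.genes))
            for j in range(len(self.genes))
            if self.coupling[i, j] != 0
        ]
        return pd.DataFrame(rows, columns=["cause", "effect", "strength"])


def seasonal_multiplier(month: int | np.ndarray, amplitude) -> np.ndarray:
    """Observation-level seasonal factor, peaking in July."""
    return 1.0 + np.asarray(amplitude) * np.cos(2 * np.pi * (np.asarray(month) - 7) / 12)


def _iterate(state: np.ndarray, r: np.ndarray, coupling: np.ndarray) -> np.ndarray:
    forcing = coupling.T @ state  # forcing[j] = sum_i c[i, j] x_i
    new = state * (r - r * state - forcing)
    if np.any(~np.isfinite(new)) or np.any(np.abs(new) > 10):
        raise SimulationError(
            "trajectory diverged (state left [-10, 10]); reduce coupling or "
            "growth rates"
        )
    return new


def simulate_panel(
    spec: NetworkSpec, *, raw: bool = False
) -> tuple[ExpressionPanel, pd.DataFrame]:
    """Simulate a panel from a :class:`NetworkSpec`.

    Returns ``(panel, truth)`` where *truth* is the ground-truth edge list.
    By default the panel is returned normalized and winter-masked (the form
    every downstream stage consumes); ``raw=True`` returns the bare
    growing-season observations instead.
    """
    n = len(spec.genes)
    records: list[tuple] = []
    seed_key = ([int(s) for s in spec.seed]
                if isinstance(spec.seed, (list, tuple)) else [int(spec.seed)])
    for k in range(spec.n_individuals):
        # one RNG stream per panel, split per individual by a fixed key
        rng = np.random.default_rng(seed_key + [k])
        state = rng.uniform(0.2, 0.8, size=n)
        for _ in range(_BURN_IN):
            state = _iterate(state, spec.growth_rates, spec.coupling)
        ind = f"ind{k + 1}"
        for y in range(spec.n_years):
            year = spec.start_year + y
            for month in GROWING_MONTHS:
                state = _iterate(state, spec.growth_rates, spec.coupling)
                s_m = seasonal_multiplier(month, spec.seasonal_amplitude)
                obs = state * s_m
                if spec.noise_sd > 0:
                    obs = obs + rng.normal(0.0, spec.noise_sd, size=n)
                for g, v in zip(spec.genes, obs):
                    records.append((g, ind, year, month, float(v)))
    panel = ExpressionPanel(
        pd.DataFrame(
            records, columns=["gene_id", "individual_id", "year", "month", "value"]
        )
    )
    if not raw:
        panel = apply_winter_mask(normalize_panel(panel))
    return panel, spec.truth_adjacency()


def two_gene_spec(
    coupling_yx: float = 0.32,
    coupling_xy: float = 0.0,
    *,
    growth_rates=(3.7, 3.6),
    seasonal_amplitude=0.3,
    noise_sd: float = 0.05,
    n_individuals: int = 3,
    n_years: int = 2,
    seed: int = 0,
) -> NetworkSpec:
    """Two-gene benchmark: gene ``Y`` drives gene ``X`` with strength
    ``coupling_yx`` (and optionally back).  Gene order is (X, Y)."""
    c = np.zeros((2, 2))
    c[1, 0] = coupling_yx  # Y -> X
    c[0, 1] = coupling_xy  # X -> Y
    return NetworkSpec(
        genes=("X", "Y"),
        coupling=c,
        growth_rates=np.asarray(growth_rates, dtype=float),
        seasonal_amplitude=np.full(2, float(seasonal_amplitude)),
        noise_sd=noise_sd,
        n_individuals=n_individuals,
        n_years=n_years,
        seed=seed,
    )


#: Gene names of the flowering-induction motif: an upstream flowering-time
#: regulator (FE), four nitrate transporters (NPF1-4), the florigen readout
#: (FT) and an FT-interacting partner (FTIP1).
MOTIF_GENES = ("FE", "NPF1", "NPF2", "NPF3", "NPF4", "FT", "FTIP1")


def motif_spec(
    n_individuals: int = 6,
    n_years: int = 3,
    seed: int = 0,
    *,
    noise_sd: float = 0.05,
    seasonal_amplitude: float = 0.3,
) -> NetworkSpec:
    """Seven-gene chain/fan motif: FE -> {NPF1..NPF4} -> FT, FE -> FT,
    FE -> FTIP1 (10 true directed edges, 32 non-edges)."""
    genes = MOTIF_GENES
    idx = {g: i for i, g in enumerate(genes)}
    c = np.zeros((7, 7))
    for npf in ("NPF1", "NPF2", "NPF3", "NPF4"):
        c[idx["FE"], idx[npf]] = 0.32
        c[idx[npf], idx["FT"]] = 0.12
    c[idx["FE"], idx["FT"]] = 0.12
    c[idx["FE"], idx["FTIP1"]] = 0.32
    # FE: edge-of-chaos driver; driven genes single-band chaotic; FT's
    # five-parent fan-in uses weaker per-edge coupling so its state stays
    # in [0, 1] under the summed forcing
    r = np.array([3.6, 3.7, 3.71, 3.72, 3.69, 3.8, 3.7])
    return NetworkSpec(
        genes=genes,
        coupling=c,
        growth_rates=r,
        seasonal_amplitude=np.full(7, float(seasonal_amplitude)),
        noise_sd=noise_sd,
        n_individuals=n_individuals,
        n_years=n_years,
        seed=seed,
    )


def simulate_motif_fe_npf_ft(
    n_individuals: int = 6, n_years: int = 3, seed: int = 0, **kwargs
) -> tuple[ExpressionPanel, pd.DataFrame]:
    """Simulate the flowering-induction motif panel with known truth."""
    spec = motif_spec(n_individuals, n_years, seed, **kwargs)
    return simulate_panel(spec)


__all__ = [
    "NetworkSpec",
    "SimulationError",
    "MOTIF_GENES",
    "seasonal_multiplier",
    "simulate_panel",
    "simulate_motif_fe_npf_ft",
    "two_gene_spec",
    "motif_spec",
]
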