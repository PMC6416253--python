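import numpy as np
import pandas as pd
import pytest

from seasonccm.panel import ExpressionPanel, apply_winter_mask, normalize_panel
from seasonccm.synthetic import simulate_panel, two_gene_spec

GROWING = (6, 7, 8, 9, 10)


def make_long_frame(n_genes=3, n_individuals=2, years=(2015, 2016), months=GROWING,
                    rng=None):
    """Growing-season long-format frame with random values."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for g in range(n_genes):
        for i in range(n_individuals):
            for y in years:
                for m in months:
                    rows.append(
                        (f"g{g}", f"ind{i}", y, m, float(rng.normal()))
                    )
    return pd.DataFrame(
        rows, columns=["gene_id", "individual_id", "year", "month", "value"]
    )


@pytest.fixture
def raw_panel():
    return ExpressionPanel(make_long_frame())


@pytest.fixture
def masked_panel(raw_panel):
    return apply_winter_mask(normalize_panel(raw_panel))


@pytest.fixture(scope="session")
def coupled_panel():
    """Unidirectional Y -> X benchmark panel (3 individuals x 24 points)."""
    panel, truth = simulate_panel(two_gene_spec(seed=42))
    return panel, truth
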