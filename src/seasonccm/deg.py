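"""Candidate-gene screen: induction labeling and two-way blocked ANOVA.

Floral induction happens one year before anthesis, so a calendar year is
labeled an induction year for a tree when the *following* spring's
proportion of reproductive buds exceeds 0.4 (strictly).  Each gene is then
screened with a two-factor fixed-effects ANOVA — induction status and
season (summer = Jun--Aug, fall = Sep--Oct) — with tree identity as a
blocking term, keeping genes with a factor p-value below 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .panel import ExpressionPanel, InductionLabels

SUMMER_MONTHS = (6, 7, 8)
FALL_MONTHS = (9, 10)

INDUCTION_THRESHOLD = 0.4


@dataclass(frozen=True)
class DegResult:
    gene_id: str
    p_induction: float
    p_season: float
    sig_induction: bool
    sig_season: bool


def label_induction_years(flowering: pd.DataFrame) -> InductionLabels:
    """Derive induction labels from a flowering-intensity table.

    ``flowering`` columns: ``individual_id, year, proportion`` (proportion
    of reproductive buds observed in that spring).  Year y is induced for
    a tree iff proportion(y+1) > 0.4; years with no following-spring
    observation stay unlabeled.
    """
    if not flowering["proportion"].between(0, 1).all():
        bad = flowering.loc[~flowering["proportion"].between(0, 1)].iloc[0]
        raise ValueError(
            f"flowering proportion outside [0, 1] for "
            f"({bad['individual_id']}, {int(bad['year'])}): {bad['proportion']}"
        )
    rows = []
    for ind, sub in flowering.groupby("individual_id"):
        by_year = dict(zip(sub["year"].astype(int), sub["proportion"]))
        for year in sorted(by_year):
            if (year + 1) not in by_year:
                continue  # no following spring observed: unlabeled
            rows.append(
                (str(ind), int(year), bool(by_year[year + 1] > INDUCTION_THRESHOLD),
                 float(by_year[year + 1]))
            )
    entries = pd.DataFrame(
        rows, columns=["individual_id", "year", "induced", "flowering_proportion"]
    )
    return InductionLabels(entries)


def _season_of(month: int) -> str | None:
    if month in SUMMER_MONTHS:
        return "summer"
    if month in FALL_MONTHS:
        return "fall"
    return None


def _gene_frame(panel: ExpressionPanel, gene: str,
                lookup: dict[tuple[str, int], bool]) -> pd.DataFrame:
    sub = panel.data[panel.data["gene_id"] == gene].copy()
    sub["season"] = sub["month"].map(_season_of)
    sub = sub.dropna(subset=["season"])
    sub["induction"] = [
        lookup.get((r.individual_id, int(r.year))) for r in sub.itertuples()
    ]
    return sub.dropna(subset=["induction"]).astype({"induction": bool})


def _check_design(df: pd.DataFrame, gene: str) -> None:
    problems = []
    if df["individual_id"].nunique() < 2:
        problems.append("fewer than 2 individuals (tree block is confounded)")
    if df["induction"].nunique() < 2:
        problems.append("induction factor has a single level")
    if df["season"].nunique() < 2:
        problems.append("season factor has a single level")
    if problems:
        raise ValueError(f"rank-deficient design for gene {gene!r}: "
                         + "; ".join(problems))


def _anova_pvalues(df: pd.DataFrame, interaction: bool) -> tuple[float, float]:
    rhs = "C(induction) + C(season) + C(individual_id)"
    if interaction:
        rhs += " + C(induction):C(season)"
    fit = smf.ols(f"value ~ {rhs}", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    return (
        float(table.loc["C(induction)", "PR(>F)"]),
        float(table.loc["C(season)", "PR(>F)"]),
    )


def _permutation_pvalues(
    df: pd.DataFrame, n_perm: int, seed, interaction: bool
) -> tuple[float, float]:
    """Strata-permutation alternative: F statistics re-computed under
    within-tree permutation of year-level induction labels and global
    permutation of season labels."""
    rhs = "C(induction) + C(season) + C(individual_id)"
    if interaction:
        rhs += " + C(induction):C(season)"

    def fstats(d: pd.DataFrame) -> tuple[float, float]:
        fit = smf.ols(f"value ~ {rhs}", data=d).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        return (float(table.loc["C(induction)", "F"]),
                float(table.loc["C(season)", "F"]))

    f_ind, f_sea = fstats(df)
    rng = np.random.default_rng(seed)
    ge_ind = ge_sea = 0
    years = df[["individual_id", "year", "induction"]].drop_duplicates()
    for _ in range(n_perm):
        perm = df.copy()
        # permute induction year-labels within each tree (strata)
        lab = {}
        for ind, sub in years.groupby("individual_id"):
            vals = rng.permutation(sub["induction"].to_numpy())
            for (y, v) in zip(sub["year"], vals):
                lab[(ind, int(y))] = bool(v)
        perm["induction"] = [
            lab[(r.individual_id, int(r.year))] for r in perm.itertuples()
        ]
        perm["season"] = rng.permutation(perm["season"].to_numpy())
        try:
            fi, fs = fstats(perm)
        except Exception:
            continue
        ge_ind += fi >= f_ind
        ge_sea += fs >= f_sea
    return ((1 + ge_ind) / (n_perm + 1), (1 + ge_sea) / (n_perm + 1))


def anova_screen(
    panel: ExpressionPanel,
    labels: InductionLabels,
    alpha: float = 0.01,
    interaction: bool = False,
    method: str = "anova",
    n_perm: int = 499,
    seed: int = 0,
) -> list[DegResult]:
    """Screen every gene for induction and season effects.

    Only growing-season observations enter (summer Jun--Aug vs fall
    Sep--Oct); tree identity is a fixed blocking factor.  ``method`` is
    ``"anova"`` (F-tests) or ``"permutation"`` (strata-permutation null).
    No correction across genes is applied: the screen keeps raw p < alpha.
    """
    lookup = labels.lookup()
    results = []
    for gene in panel.genes:
        df = _gene_frame(panel, gene, lookup)
        _check_design(df, gene)
        if method == "anova":
            p_ind, p_sea = _anova_pvalues(df, interaction)
        elif method == "permutation":
            p_ind, p_sea = _permutation_pvalues(df, n_perm, seed, interaction)
        else:
            raise ValueError(f"unknown method {method!r}")
        results.append(
            DegResult(
                gene_id=gene,
                p_induction=p_ind,
                p_season=p_sea,
                sig_induction=bool(p_ind < alpha),
                sig_season=bool(p_sea < alpha),
            )
        )
    return results


def overlap_counts(results: list[DegResult]) -> tuple[int, int, int]:
    """Venn counts: (significant for induction, for season, for both)."""
    if not results:
        raise ValueError("no DEG results to count")
    n_ind = sum(r.sig_induction for r in results)
    n_sea = sum(r.sig_season for r in results)
    n_both = sum(r.sig_induction and r.sig_season for r in results)
    return n_ind, n_sea, n_both


def results_frame(results: list[DegResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


__all__ = [
    "SUMMER_MONTHS",
    "FALL_MONTHS",
    "INDUCTION_THRESHOLD",
    "DegResult",
    "anova_screen",
    "label_induction_years",
    "overlap_counts",
    "results_frame",
]
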