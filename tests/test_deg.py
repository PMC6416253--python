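"""Induction-year labeling and the two-way blocked ANOVA screen."""

import numpy as np
import pandas as pd
import pytest

from seasonccm.deg import (
    anova_screen,
    label_induction_years,
    overlap_counts,
    results_frame,
)
from seasonccm.deg import DegResult
from seasonccm.panel import ExpressionPanel, InductionLabels


def flowering_table(props_by_ind):
    rows = []
    for ind, by_year in props_by_ind.items():
        for year, p in by_year.items():
            rows.append((ind, year, p))
    return pd.DataFrame(rows, columns=["individual_id", "year", "proportion"])


def simulated_deg_panel(n_genes, effect_sd=0.0, season_shift=None, seed=0,
                        n_trees=3, years=(2015, 2016), induced_year=2016):
    """Genes with optional induction-year mean shift and/or seasonal spike."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_genes):
        for i in range(n_trees):
            for y in years:
                for m in (6, 7, 8, 9, 10):
                    v = rng.normal()
                    if y == induced_year:
                        v += effect_sd
                    if season_shift and m in (9, 10):
                        v += season_shift
                    rows.append((f"g{g}", f"tree{i}", y, m, v))
    panel = ExpressionPanel(pd.DataFrame(
        rows, columns=["gene_id", "individual_id", "year", "month", "value"]))
    labels = InductionLabels(pd.DataFrame({
        "individual_id": [f"tree{i}" for i in range(n_trees) for _ in years],
        "year": list(years) * n_trees,
        "induced": [y == induced_year for _ in range(n_trees) for y in years],
        "flowering_proportion": 0.5,
    }))
    return panel, labels


class TestLabeling:
    def test_following_spring_above_threshold_labels_prior_year(self):
        labels = label_induction_years(flowering_table(
            {"HG1": {2016: 0.0, 2017: 0.45}}
        ))
        lk = labels.lookup()
        assert lk[("HG1", 2016)] is True

    def test_exactly_threshold_is_not_induced(self):
        labels = label_induction_years(flowering_table(
            {"HG1": {2015: 0.0, 2016: 0.40}}
        ))
        assert labels.lookup()[("HG1", 2015)] is False

    def test_no_flowering_means_no_induction(self):
        labels = label_induction_years(flowering_table(
            {"HG3": {2014: 0.0, 2015: 0.0, 2016: 0.0}}
        ))
        assert not any(labels.lookup().values())

    def test_year_without_following_spring_unlabeled(self):
        labels = label_induction_years(flowering_table(
            {"HG1": {2015: 0.2, 2016: 0.5}}
        ))
        assert ("HG1", 2016) not in labels.lookup()

    def test_proportion_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            label_induction_years(flowering_table({"HG1": {2015: 1.2}}))


class TestAnovaScreen:
    def test_induction_effect_detected_with_high_power(self):
        panel, labels = simulated_deg_panel(100, effect_sd=2.0, seed=1)
        results = anova_screen(panel, labels)
        power = np.mean([r.sig_induction for r in results])
        assert power >= 0.9

    def test_null_genes_false_positive_rate_near_alpha(self):
        panel, labels = simulated_deg_panel(1000, seed=2)
        results = anova_screen(panel, labels)
        fp = np.mean([r.sig_induction for r in results])
        # binomial 99% CI around alpha = 0.01 for n = 1000
        assert 0.002 <= fp <= 0.021

    def test_october_spike_is_seasonal_not_induction(self):
        hits = 0
        for seed in range(10):
            panel, labels = simulated_deg_panel(
                1, season_shift=3.0, seed=seed)
            r = anova_screen(panel, labels)[0]
            hits += r.sig_season and not r.sig_induction
        assert hits >= 9

    def test_single_individual_design_rejected(self):
        panel, labels = simulated_deg_panel(1, n_trees=1)
        with pytest.raises(ValueError, match="rank-deficient"):
            anova_screen(panel, labels)

    def test_pvalues_invariant_to_affine_rescaling(self):
        panel, labels = simulated_deg_panel(3, effect_sd=1.0, seed=3)
        base = anova_screen(panel, labels)
        df = panel.data.copy()
        df["value"] = 7.5 * df["value"] - 2.0
        scaled = anova_screen(ExpressionPanel(df), labels)
        for a, b in zip(base, scaled):
            assert a.p_induction == pytest.approx(b.p_induction, rel=1e-8)
            assert a.p_season == pytest.approx(b.p_season, rel=1e-8)

    def test_permutation_method_agrees_directionally(self):
        # four years give enough within-tree label permutations for the
        # strata-permutation null to resolve small p-values
        years = (2013, 2014, 2015, 2016)
        panel, labels = simulated_deg_panel(2, effect_sd=3.0, seed=4,
                                            years=years, induced_year=2016)
        perm = anova_screen(panel, labels, method="permutation", n_perm=99,
                            seed=0)
        assert all(r.p_induction < 0.1 for r in perm)
        null_panel, null_labels = simulated_deg_panel(
            2, effect_sd=0.0, seed=54, years=years, induced_year=2016)
        null = anova_screen(null_panel, null_labels, method="permutation",
                            n_perm=99, seed=0)
        assert all(r.p_induction > 0.1 for r in null)


class TestOverlap:
    def test_counting(self):
        results = [
            DegResult("a", 0.001, 0.5, True, False),
            DegResult("b", 0.5, 0.001, False, True),
            DegResult("c", 0.001, 0.001, True, True),
        ]
        assert overlap_counts(results) == (2, 2, 1)

    def test_all_nonsignificant(self):
        results = [DegResult("a", 0.5, 0.5, False, False)]
        assert overlap_counts(results) == (0, 0, 0)

    def test_both_bounded_by_each_margin(self):
        panel, labels = simulated_deg_panel(50, effect_sd=1.0, seed=5)
        results = anova_screen(panel, labels, alpha=0.05)
        n_ind, n_sea, n_both = overlap_counts(results)
        assert n_both <= min(n_ind, n_sea)
        assert len(results_frame(results)) == 50

    def test_planted_signals_recovered(self):
        # 10 induction genes, 5 seasonal, at alpha 0.01, strong effects
        panel_i, labels = simulated_deg_panel(10, effect_sd=2.5, seed=6)
        panel_s, _ = simulated_deg_panel(5, season_shift=2.5, seed=7)
        df_s = panel_s.data.copy()
        df_s["gene_id"] = "s" + df_s["gene_id"]
        panel = ExpressionPanel(pd.concat([panel_i.data, df_s],
                                          ignore_index=True))
        results = anova_screen(panel, labels)
        n_ind, n_sea, _ = overlap_counts(results)
        assert abs(n_ind - 10) <= 2
        assert abs(n_sea - 5) <= 2
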