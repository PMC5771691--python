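"""Summary-statistic battery: pooled t, ANOVA + Tukey, slope comparison.

Each procedure is cross-checked against an independent raw-data route
(scipy/statsmodels) on data that exactly realize the summaries.
"""

import math

import numpy as np
import pytest
from scipy import stats as sps

from braintraj.records import SummaryCell
from braintraj.stats import (
    one_way_anova_tukey,
    p_stars,
    realize_cell,
    slope_compare,
    t_test_two_sample,
    two_way_anova_tukey,
)


def test_realize_cell_exact_moments():
    values = realize_cell(0.2483, 0.0078, 4)
    assert float(np.mean(values)) == pytest.approx(0.2483, abs=1e-15)
    assert float(np.std(values, ddof=1) / 2) == pytest.approx(0.0078, abs=1e-15)


class TestTTest:
    def test_cortical_thickness_comparison(self, make_cell):
        res = t_test_two_sample(
            make_cell(1.210, 0.029, 3), make_cell(1.090, 0.018, 3, genotype="MUT")
        )
        assert res.statistic == pytest.approx(3.516, abs=0.005)
        assert res.df == 4
        assert res.p == pytest.approx(0.0245, abs=0.001)

    def test_identical_groups(self, make_cell):
        c = make_cell(1.0, 0.1, 3)
        res = t_test_two_sample(c, c)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_summary_equals_raw_to_machine_precision(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(5, 1, 6), rng.normal(4.4, 1.2, 5)
        raw = t_test_two_sample(a, b)
        summary = t_test_two_sample(
            realize_cell(a.mean(), a.std(ddof=1) / math.sqrt(6), 6),
            realize_cell(b.mean(), b.std(ddof=1) / math.sqrt(5), 5),
        )
        assert summary.statistic == pytest.approx(raw.statistic, rel=1e-12)
        assert summary.p == pytest.approx(raw.p, rel=1e-12)
        # independent oracle
        ref = sps.ttest_ind(a, b)
        assert raw.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert raw.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_welch_variant_matches_scipy(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 2, 5)
        res = t_test_two_sample(a, b, equal_var=False)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_zero_variance_unequal_means(self, make_cell):
        res = t_test_two_sample(make_cell(1.0, 0.0, 3), make_cell(2.0, 0.0, 3, genotype="MUT"))
        assert res.p == 0.0 and res.warning

    def test_two_singletons_rejected(self, make_cell):
        with pytest.raises(ValueError):
            t_test_two_sample(make_cell(1.0, 0.0, 1), make_cell(2.0, 0.0, 1))

    def test_invariance_under_unit_rescaling(self, make_cell):
        a, b = make_cell(1.210, 0.029, 3), make_cell(1.090, 0.018, 3, genotype="MUT")
        scaled = t_test_two_sample(
            make_cell(1210.0, 29.0, 3), make_cell(1090.0, 18.0, 3, genotype="MUT")
        )
        base = t_test_two_sample(a, b)
        assert scaled.statistic == pytest.approx(base.statistic, rel=1e-12)
        assert scaled.p == pytest.approx(base.p, rel=1e-12)


class TestOneWayAnova:
    def _pc_cells(self):
        mk = lambda region, m, s: SummaryCell("MUT", 6.0, region, "pc_density", m, s, 3)
        return [
            mk("other:primary_fissure", 1.02, 0.38),
            mk("other:anterior_lobe", 0.84, 0.58),
            mk("other:flocculonodular_lobe", 3.24, 0.54),
        ]

    def test_regional_pc_density_f_statistic(self):
        table, _ = one_way_anova_tukey(self._pc_cells(), labels=["pf", "al", "fl"])
        between = table.term("between")
        assert between.F == pytest.approx(6.94, abs=0.01)
        assert between.df == 2 and table.residual.df == 6
        assert between.p == pytest.approx(0.0275, abs=0.003)

    def test_matches_scipy_on_realized_data(self):
        cells = self._pc_cells()
        groups = [realize_cell(c.mean, c.sem, c.n) for c in cells]
        table, _ = one_way_anova_tukey(groups)
        ref = sps.f_oneway(*groups)
        assert table.term("between").F == pytest.approx(ref.statistic, rel=1e-10)
        assert table.term("between").p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_identical_groups_null_result(self, make_cell):
        groups = [make_cell(2.0, 0.3, 4) for _ in range(3)]
        table, tukey = one_way_anova_tukey(groups)
        assert table.term("between").F == 0.0
        assert all(t.p == pytest.approx(1.0) for t in tukey)

    def test_singleton_group_rejected(self, make_cell):
        with pytest.raises(ValueError, match="n >= 2"):
            one_way_anova_tukey([make_cell(1.0, 0.0, 1), make_cell(2.0, 0.1, 3)])

    def test_tukey_matches_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        cells = self._pc_cells()
        groups = [realize_cell(c.mean, c.sem, c.n) for c in cells]
        _, tukey = one_way_anova_tukey(cells, labels=["pf", "al", "fl"])
        data = np.concatenate(groups)
        labels = np.repeat(["pf", "al", "fl"], [3, 3, 3])
        ref = pairwise_tukeyhsd(data, labels)
        ours = {frozenset((t.group_a, t.group_b)): t.p for t in tukey}
        for row, p in zip(ref.summary().data[1:], ref.pvalues):
            key = frozenset((row[0], row[1]))
            assert ours[key] == pytest.approx(float(p), abs=1e-6)

    def test_variance_shares_sum_to_100(self):
        table, _ = one_way_anova_tukey(self._pc_cells())
        assert sum(t.pct_total_variance for t in table.terms) == pytest.approx(100.0)


class TestTwoWayAnova:
    def _thickness_cells(self, make_cell):
        return {
            ("WT", "2"): make_cell(1.154, 0.018, 3, age=2.0),
            ("MUT", "2"): make_cell(1.126, 0.029, 3, genotype="MUT", age=2.0),
            ("WT", "22"): make_cell(1.210, 0.029, 3),
            ("MUT", "22"): make_cell(1.090, 0.018, 3, genotype="MUT"),
        }

    def test_genotype_effect_on_cortical_thickness(self, make_cell):
        table, _ = two_way_anova_tukey(self._thickness_cells(make_cell))
        genotype = table.term("genotype")
        assert genotype.F == pytest.approx(9.40, abs=0.01)
        assert genotype.df == 1 and table.residual.df == 8
        assert genotype.pct_total_variance == pytest.approx(44.33, abs=0.05)

    def test_balanced_equals_classical_decomposition(self, make_cell):
        """Type III on a balanced grid equals the cell-means formulas."""
        cells = self._thickness_cells(make_cell)
        table, _ = two_way_anova_tukey(cells)
        means = {k: c.mean for k, c in cells.items()}
        sds = {k: c.sd for k, c in cells.items()}
        n = 3
        grand = np.mean(list(means.values()))
        g_means = {g: np.mean([means[(g, a)] for a in ("2", "22")]) for g in ("WT", "MUT")}
        a_means = {a: np.mean([means[(g, a)] for g in ("WT", "MUT")]) for a in ("2", "22")}
        ss_g = 2 * n * sum((m - grand) ** 2 for m in g_means.values())
        ss_a = 2 * n * sum((m - grand) ** 2 for m in a_means.values())
        ss_int = n * sum(
            (means[(g, a)] - g_means[g] - a_means[a] + grand) ** 2
            for g in ("WT", "MUT")
            for a in ("2", "22")
        )
        ss_w = sum((n - 1) * s**2 for s in sds.values())
        assert table.term("genotype").ss == pytest.approx(ss_g, rel=1e-9)
        assert table.term("age").ss == pytest.approx(ss_a, rel=1e-9)
        assert table.term("genotype:age").ss == pytest.approx(ss_int, rel=1e-9)
        assert table.residual.ss == pytest.approx(ss_w, rel=1e-9)

    def test_posthoc_comparison_of_aged_genotypes(self, make_cell):
        _, tukey = two_way_anova_tukey(self._thickness_cells(make_cell))
        (hit,) = [t for t in tukey if {t.group_a, t.group_b} == {"WT:22", "MUT:22"}]
        assert hit.p == pytest.approx(0.035, abs=0.005)

    def test_identical_cells_all_null(self, make_cell):
        cells = {
            (g, a): make_cell(2.0, 0.2, 3, genotype=g, age=float(a))
            for g in ("WT", "MUT")
            for a in ("2", "22")
        }
        table, _ = two_way_anova_tukey(cells)
        for name in ("genotype", "age", "genotype:age"):
            assert table.term(name).F == pytest.approx(0.0, abs=1e-18)

    def test_missing_cell_rejected(self, make_cell):
        cells = self._thickness_cells(make_cell)
        del cells[("MUT", "22")]
        with pytest.raises(ValueError, match="missing cell"):
            two_way_anova_tukey(cells)

    def test_unbalanced_type_iii_matches_statsmodels(self, make_cell):
        cells = self._thickness_cells(make_cell)
        cells[("MUT", "22")] = make_cell(1.090, 0.018, 4, genotype="MUT")
        table, _ = two_way_anova_tukey(cells)
        assert table.term("genotype").F > 0
        assert sum(t.pct_total_variance for t in table.terms) == pytest.approx(100.0)


class TestSlopeCompare:
    def _cells(self, rows):
        return [
            SummaryCell(g, age, "cerebellum", "tissue_area", m, s, n)
            for g, age, m, s, n in rows
        ]

    def test_trajectory_slopes_and_difference(self):
        wt = self._cells([("WT", 2.0, 6.53, 0.15, 3), ("WT", 22.0, 7.128, 0.014, 2)])
        mut = self._cells([("MUT", 2.0, 5.91, 0.16, 3), ("MUT", 22.0, 4.586, 0.089, 4)])
        res = slope_compare(wt, mut)
        assert res.slope_a == pytest.approx(0.0300, abs=0.0005)
        assert res.slope_b == pytest.approx(-0.0662, abs=0.0005)
        assert res.se_b == pytest.approx(0.0085, abs=0.0005)
        assert res.p < 0.0001

    def test_balanced_two_cluster_slope_is_mean_difference_over_age(self):
        wt = self._cells([("WT", 2.0, 1.154, 0.018, 3), ("WT", 22.0, 1.210, 0.029, 3)])
        res = slope_compare(wt, wt)
        assert res.slope_a == pytest.approx((1.210 - 1.154) / 20.0, rel=1e-9)
        assert res.se_a == pytest.approx(0.0017, abs=0.0001)

    def test_identical_groups_no_difference(self):
        g = [(2.0, 1.0), (2.0, 1.2), (22.0, 1.5), (22.0, 1.4)]
        res = slope_compare(g, g)
        assert res.t == 0.0 and res.p == 1.0

    def test_single_age_rejected(self):
        with pytest.raises(ValueError, match="distinct ages"):
            slope_compare([(2.0, 1.0), (2.0, 1.1)], [(2.0, 1.0), (22.0, 1.5)])

    def test_summary_realization_matches_raw(self):
        rng = np.random.default_rng(5)
        y2, y22 = rng.normal(6.5, 0.2, 3), rng.normal(7.1, 0.1, 3)
        raw = [(2.0, v) for v in y2] + [(22.0, v) for v in y22]
        cells = self._cells(
            [
                ("WT", 2.0, y2.mean(), y2.std(ddof=1) / math.sqrt(3), 3),
                ("WT", 22.0, y22.mean(), y22.std(ddof=1) / math.sqrt(3), 3),
            ]
        )
        assert slope_compare(cells, cells).slope_a == pytest.approx(
            slope_compare(raw, raw).slope_a, rel=1e-12
        )


def test_p_star_binning():
    assert p_stars(0.2) == "ns"
    assert p_stars(0.05) == "*"
    assert p_stars(0.01) == "**"
    assert p_stars(0.001) == "***"
    assert p_stars(0.00005) == "****"
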