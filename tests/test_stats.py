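"""Relative changes and the longitudinal statistical battery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cartt2.stats import (
    LongitudinalStudy,
    UndefinedStatisticError,
    anova_tukey,
    delta_table,
    friedman_dunn,
    friedman_statistic,
    kruskal_wallis,
    relative_change,
    report,
    validate_table,
)


def tidy(rows):
    return pd.DataFrame(rows, columns=["sample_id", "group", "time_point",
                                       "roi", "measure", "value"])


def make_table(values_by_group, roi="whole", measure="t2_mean"):
    """values_by_group: {group: array (n_samples, n_time_points)}."""
    rows = []
    for group, mat in values_by_group.items():
        for i, series in enumerate(np.atleast_2d(mat)):
            for t, v in enumerate(series):
                rows.append((f"{group}{i}", group, f"t{t}", roi, measure, v))
    return tidy(rows)


class TestRelativeChange:
    def test_identity_is_zero(self):
        assert relative_change(42.0, 42.0) == 0.0

    def test_group_mean_example(self):
        # ratio of group means, evaluated directly from the formula
        assert relative_change(40.3, 32.0) == pytest.approx(25.94, abs=0.005)

    def test_halving_is_minus_fifty(self):
        assert relative_change(16.0, 32.0) == -50.0

    def test_scale_invariance(self):
        assert relative_change(7 * 1.3, 7.0) == pytest.approx(
            relative_change(91 * 1.3, 91.0))

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            relative_change(10.0, 0.0)


class TestFriedman:
    def test_constant_blocks_give_null_result(self):
        data = np.full((5, 4), 3.3)
        assert friedman_statistic(data) == (0.0, 1.0)

    def test_matches_scipy_without_ties(self, rng):
        data = rng.normal(size=(8, 4))
        stat, p = friedman_statistic(data)
        ref_stat, ref_p = sps.friedmanchisquare(*data.T)
        assert stat == pytest.approx(ref_stat, rel=1e-12)
        assert p == pytest.approx(ref_p, rel=1e-12)

    def test_matches_rank_oracle_on_toy_table(self):
        """Classic chi-square formula evaluated by explicit ranking."""
        data = np.array([[1.0, 2.0, 3.0, 4.0],
                         [2.0, 1.0, 4.0, 3.0],
                         [1.0, 3.0, 2.0, 4.0],
                         [1.0, 2.0, 4.0, 3.0]])
        n, k = data.shape
        ranks = np.array([sps.rankdata(row) for row in data])
        col = ranks.sum(axis=0)
        oracle = 12.0 / (n * k * (k + 1)) * (col ** 2).sum() - 3 * n * (k + 1)
        stat, _ = friedman_statistic(data)
        assert stat == pytest.approx(oracle, rel=1e-12)

    def test_monotone_transform_invariance(self, rng):
        data = rng.normal(size=(6, 4))
        assert friedman_statistic(data)[0] == pytest.approx(
            friedman_statistic(np.exp(data))[0], rel=1e-12)

    def test_friedman_dunn_on_trending_cohort(self, rng):
        # strong monotone time trend in every sample -> significant, and the
        # extreme pair has the smallest post-hoc p
        base = rng.uniform(30, 40, 8)
        mat = base[:, None] + np.array([0.0, 5.0, 10.0, 20.0])[None, :]
        mat += rng.normal(0, 0.5, mat.shape)
        table = make_table({"HIMP": mat})
        res = friedman_dunn(table, "HIMP", "whole", "t2_mean")
        assert res.significant
        assert res.posthoc[("t0", "t3")] == min(res.posthoc.values())

    def test_incomplete_blocks_excluded_with_warning(self):
        table = make_table({"A": np.arange(16.0).reshape(4, 4)})
        table = table[~((table.sample_id == "A0") & (table.time_point == "t3"))]
        with pytest.warns(UserWarning, match="A0"):
            res = friedman_dunn(table, "A", "whole", "t2_mean")
        assert res.n == 3

    def test_too_few_samples_rejected(self):
        table = make_table({"A": np.arange(8.0).reshape(2, 4)})
        with pytest.raises(UndefinedStatisticError):
            friedman_dunn(table, "A", "whole", "t2_mean")

    def test_dunn_adjustment_never_decreases_p(self, rng):
        mat = rng.normal(size=(6, 4))
        table = make_table({"A": mat})
        plain = friedman_dunn(table, "A", "whole", "t2_mean", adjust="none")
        holm = friedman_dunn(table, "A", "whole", "t2_mean", adjust="holm")
        bonf = friedman_dunn(table, "A", "whole", "t2_mean", adjust="bonferroni")
        for pair in plain.posthoc:
            assert holm.posthoc[pair] >= plain.posthoc[pair] - 1e-15
            assert bonf.posthoc[pair] >= plain.posthoc[pair] - 1e-15


class TestKruskalWallis:
    def test_identical_values_give_h_zero(self):
        table = make_table({g: np.full((3, 1), 5.0) for g in ("A", "B", "C")})
        res = kruskal_wallis(table, "t0", "whole", "t2_mean")
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_hand_rank_formula(self):
        groups = {"A": [1.0, 2.0, 3.0], "B": [4.0, 5.0, 6.0], "C": [7.0, 8.0, 9.0]}
        table = make_table({g: np.array(v)[:, None] for g, v in groups.items()})
        res = kruskal_wallis(table, "t0", "whole", "t2_mean")
        # no ties: H = 12/(N(N+1)) * sum n_i rbar_i^2 - 3(N+1)
        n_tot = 9
        mean_ranks = {"A": 2.0, "B": 5.0, "C": 8.0}
        oracle = (12.0 / (n_tot * (n_tot + 1))
                  * sum(3 * r ** 2 for r in mean_ranks.values())
                  - 3 * (n_tot + 1))
        assert res.statistic == pytest.approx(oracle, rel=1e-12)
        assert res.statistic == pytest.approx(
            sps.kruskal(*groups.values()).statistic, rel=1e-12)

    def test_monotone_transform_invariance(self, rng):
        mats = {g: rng.normal(size=(5, 1)) for g in ("A", "B")}
        a = kruskal_wallis(make_table(mats), "t0", "whole", "t2_mean")
        b = kruskal_wallis(
            make_table({g: np.exp(m) for g, m in mats.items()}),
            "t0", "whole", "t2_mean")
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    def test_separated_groups_post_hoc(self, rng):
        mats = {"CONT": rng.normal(30, 1, (7, 1)),
                "HIMP": rng.normal(60, 1, (7, 1))}
        res = kruskal_wallis(make_table(mats), "t0", "whole", "t2_mean")
        assert res.significant
        assert res.posthoc[("CONT", "HIMP")] < 0.01

    def test_degenerate_groups_rejected(self):
        table = make_table({"A": np.array([[1.0]]), "B": np.array([[2.0]])})
        with pytest.raises(UndefinedStatisticError):
            kruskal_wallis(table, "t0", "whole", "t2_mean")


class TestAnovaTukey:
    def test_equal_group_distributions_give_f_zero(self):
        res = anova_tukey({"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0]})
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_computed_sums_of_squares(self):
        groups = {"A": np.array([1.0, 2.0, 3.0]), "B": np.array([4.0, 6.0, 8.0])}
        grand = np.concatenate(list(groups.values())).mean()
        ss_b = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
        ss_w = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        oracle = (ss_b / 1) / (ss_w / 4)
        res = anova_tukey(groups)
        assert res.statistic == pytest.approx(oracle, abs=1e-10)

    def test_zero_variance_everywhere_flagged_undefined(self):
        res = anova_tukey({"A": [5.0, 5.0], "B": [5.0, 5.0]})
        assert not res.defined and not res.significant

    def test_tukey_pairs_reported(self, rng):
        groups = {"CONT": rng.normal(0, 1, 7), "LIMP": rng.normal(1, 1, 14),
                  "HIMP": rng.normal(5, 1, 14)}
        res = anova_tukey(groups)
        assert set(res.posthoc) == {("CONT", "LIMP"), ("CONT", "HIMP"),
                                    ("LIMP", "HIMP")}
        assert res.posthoc[("CONT", "HIMP")] < 0.01

    def test_small_groups_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            anova_tukey({"A": [1.0], "B": [2.0, 3.0]})


class TestDeltaTable:
    def test_per_sample_deltas(self):
        table = make_table({"A": np.array([[20.0, 25.0, 30.0, 10.0]])})
        d = delta_table(table)
        vals = d.set_index("delta")["value"]
        assert vals["t1"] == pytest.approx(25.0)
        assert vals["t2"] == pytest.approx(50.0)
        assert vals["t3"] == pytest.approx(-50.0)

    def test_mean_of_ratios_not_ratio_of_means(self):
        # two samples with equal mean change but different baselines
        table = make_table({"A": np.array([[10.0, 20.0, 10.0, 10.0],
                                           [40.0, 44.0, 40.0, 40.0]])})
        d = delta_table(table)
        t1 = d[d.delta == "t1"]["value"]
        assert sorted(np.round(t1, 6)) == [10.0, 100.0]
        assert t1.mean() == pytest.approx(55.0)  # mean of per-sample deltas

    def test_nonpositive_baseline_skipped_with_warning(self):
        table = make_table({"A": np.array([[0.0, 1.0, 2.0, 3.0]])})
        with pytest.warns(UserWarning):
            d = delta_table(table)
        assert len(d) == 0


class TestStudyModel:
    def test_duplicate_rows_rejected(self):
        table = make_table({"A": np.ones((3, 4))})
        bad = pd.concat([table, table.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            validate_table(bad)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="lacks"):
            validate_table(pd.DataFrame({"sample_id": [], "value": []}))

    def test_empty_table_produces_empty_report(self):
        res = LongitudinalStudy(tidy([])).fit()
        assert res.friedman == {} and res.kruskal == {} and res.anova == {}
        assert len(res.measure_table("t2_mean")) == 0
        assert "(none)" in res.summary()

    def test_report_shapes_and_flags(self, rng, tmp_path):
        mats = {
            "CONT": rng.normal(33, 2, (4, 4)),
            "LIMP": rng.normal(33, 2, (4, 4)) + np.array([0, 3, 6, 8.0]),
            "HIMP": rng.normal(33, 2, (4, 4)) + np.array([0, 8, 15, 22.0]),
        }
        table = pd.concat([
            make_table(mats, roi=roi) for roi in ("whole", "superficial", "deep")
        ], ignore_index=True)
        res = report(table, out_dir=tmp_path)
        grid = res.measure_table("t2_mean")
        # 3 groups + 1 between-group p row, for each of the 3 ROIs
        assert len(grid) == 12
        assert set(grid.columns) >= {"roi", "group", "t0", "t1", "t2", "t3",
                                     "friedman_p", "significant"}
        # significance flag means p <= 0.01 exactly
        for (grp, roi, measure), r in res.friedman.items():
            assert r.significant == (r.p_value <= 0.01)
        d = res.delta_summary("t2_mean")
        assert len(d) == 12  # 3 groups + ANOVA row per ROI
        assert (tmp_path / "summary_t2_mean.csv").exists()
        assert (tmp_path / "results.json").exists()

    def test_alpha_threshold_is_inclusive(self):
        from cartt2.stats import TestResult

        assert TestResult("t", 1.0, 0.01).significant
        assert not TestResult("t", 1.0, 0.010001).significant
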