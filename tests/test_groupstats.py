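"""Tests of test selection, effect sizes, BH control, post hoc and Spearman."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mobgait import StatsConfig
from mobgait.groupstats import (
    GroupStatsReport,
    adjust_bh,
    choose_test,
    dunn_test,
    eta_squared_anova,
    eta_squared_kruskal,
    omnibus,
    posthoc,
    run_group_analysis,
    spearman_matrix,
    strength_of,
)
from mobgait.synth import sample_cohort_features


def bh_bruteforce(p):
    """Independent step-up implementation of Benjamini-Hochberg."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


class TestChooseTest:
    def test_normal_groups_get_anova(self):
        rng = np.random.default_rng(0)
        groups = {k: rng.normal(0, 1, 50) for k in "abc"}
        assert choose_test(groups) == "anova"

    def test_heavy_tailed_groups_get_kruskal(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            groups = {k: rng.lognormal(0, 1, 50) for k in "abc"}
            hits += choose_test(groups) == "kruskal"
        assert hits >= 27

    def test_unequal_variances_get_kruskal(self):
        rng = np.random.default_rng(1)
        groups = {"a": rng.normal(0, 1, 60), "b": rng.normal(0, 1, 60),
                  "c": rng.normal(0, 6, 60)}
        assert choose_test(groups) == "kruskal"

    def test_tiny_group_skipped(self):
        rng = np.random.default_rng(0)
        groups = {"a": rng.normal(0, 1, 30), "b": rng.normal(0, 1, 30),
                  "c": np.array([1.0, 2.0])}
        assert choose_test(groups) is None


class TestEffectSizes:
    def test_identical_group_means_zero(self):
        g = [np.array([1.0, 2.0, 3.0])] * 3
        assert eta_squared_anova(g) == 0.0

    def test_no_within_variance_one(self):
        g = [np.array([1.0, 1.0]), np.array([2.0, 2.0]), np.array([3.0, 3.0])]
        assert eta_squared_anova(g) == 1.0

    def test_kruskal_analogue_floored(self):
        assert eta_squared_kruskal(0.5, 3, 60) == 0.0
        assert 0 < eta_squared_kruskal(10.0, 3, 60) < 1

    def test_power_against_shifted_mean(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            groups = {"a": rng.normal(0, 1, 40), "b": rng.normal(0, 1, 40),
                      "c": rng.normal(1, 1, 40)}
            res = omnibus("f", groups)
            hits += res.p_value < 0.05
        assert hits >= 95

    def test_constant_feature_degenerate(self):
        groups = {k: np.full(5, 2.0) for k in "abc"}
        res = omnibus("f", groups)
        assert res.degenerate


class TestBenjaminiHochberg:
    def test_hand_example(self):
        assert np.allclose(adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert adjust_bh([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert np.all(adjust_bh([1.0, 1.0, 1.0]) == 1.0)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            p = rng.uniform(0, 1, int(rng.integers(1, 40)))
            assert np.abs(adjust_bh(p) - bh_bruteforce(p)).max() < 1e-12

    def test_adjusted_not_smaller_and_bounded(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 25)
        adj = adjust_bh(p)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])


class TestPosthoc:
    def test_identical_samples_nonsignificant(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, 50)
        groups = {"a": base, "b": base.copy(), "c": base.copy()}
        for p in posthoc(groups, parametric=False).values():
            assert p > 0.05

    def test_shifted_group_pattern(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            groups = {"a": rng.normal(0, 1, 40), "b": rng.normal(0, 1, 40),
                      "c": rng.normal(5, 1, 40)}
            p = posthoc(groups, parametric=True)
            hits += (p[("a", "c")] < 0.05 and p[("b", "c")] < 0.05
                     and p[("a", "b")] > 0.05)
        assert hits >= 36

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(4)
        groups = {"a": rng.normal(0, 1, 30), "b": rng.normal(0.5, 1, 30),
                  "c": rng.normal(1, 1, 30)}
        fwd = posthoc(groups, parametric=False)
        rev = posthoc(dict(reversed(groups.items())), parametric=False)
        for (a, b), p in fwd.items():
            assert rev[(b, a)] == pytest.approx(p, abs=1e-12)

    def test_dunn_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        groups = {k: rng.normal(i, 1, 20 + 5 * i) for i, k in enumerate("abc")}
        result = dunn_test(groups)
        # independent evaluation from first principles
        allv = np.concatenate(list(groups.values()))
        ranks = stats.rankdata(allv)
        n = allv.size
        splits = np.cumsum([len(v) for v in groups.values()])[:-1]
        rank_groups = dict(zip(groups, np.split(ranks, splits)))
        _, counts = np.unique(allv, return_counts=True)
        ties = (counts**3 - counts).sum() / (12 * (n - 1))
        for a, b in itertools.combinations(groups, 2):
            ra, rb = rank_groups[a].mean(), rank_groups[b].mean()
            se = np.sqrt((n * (n + 1) / 12 - ties)
                         * (1 / len(groups[a]) + 1 / len(groups[b])))
            z = (ra - rb) / se
            expected = 2 * stats.norm.sf(abs(z))
            assert result[(a, b)] == pytest.approx(expected, abs=1e-12)


class TestSpearman:
    def _table(self):
        rng = np.random.default_rng(6)
        rows = []
        for g in ("MSA", "PSP", "PD"):
            x = rng.normal(0, 1, 20)
            rows.append(pd.DataFrame({
                "group": g, "x": x, "y": x + rng.normal(0, 0.5, 20),
            }))
        return pd.concat(rows, ignore_index=True)

    def test_monotone_perfect_correlation(self):
        df = pd.DataFrame({"group": "MSA", "x": [1, 2, 3, 4, 5],
                           "y": [2, 4, 9, 16, 100]})
        out = spearman_matrix(df, ["x"], ["y"])
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    @pytest.mark.parametrize("rho,label", [
        (0.1, "weak"), (0.25, "weak"), (0.2501, "moderate"), (0.5, "moderate"),
        (0.6, "strong"), (0.75, "strong"), (0.7501, "very strong"),
        (-0.8, "very strong"), (float("nan"), "undefined"),
    ])
    def test_strength_bins_total_on_magnitude(self, rho, label):
        assert strength_of(rho) == label

    def test_invariance_under_monotone_transform(self):
        df = self._table()
        base = spearman_matrix(df, ["x"], ["y"])
        df2 = df.assign(x=np.exp(df.x), y=df.y**3)
        trans = spearman_matrix(df2, ["x"], ["y"])
        assert np.allclose(base.rho.to_numpy(), trans.rho.to_numpy())

    def test_constant_feature_undefined(self):
        df = pd.DataFrame({"group": "MSA", "x": [1.0] * 8, "y": range(8)})
        out = spearman_matrix(df, ["x"], ["y"])
        assert out.loc[0, "strength"] == "undefined"
        assert np.isnan(out.loc[0, "rho"])

    def test_few_pairs_undefined(self):
        df = pd.DataFrame({"group": "MSA", "x": [1, 2, 3, 4], "y": [1, 2, 3, 5]})
        out = spearman_matrix(df, ["x"], ["y"])
        assert np.isnan(out.loc[0, "rho"])


class TestNullCalibration:
    def test_raw_p_uniform_under_null(self):
        # omnibus raw p-values under three identical Normal groups
        ps = []
        for seed in range(400):
            rng = np.random.default_rng(seed)
            groups = {k: rng.normal(0, 1, 20) for k in "abc"}
            ps.append(omnibus("f", groups).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestRunGroupAnalysis:
    def test_report_roundtrip_and_structure(self):
        table = sample_cohort_features(12, seed=8)
        families = {
            "iga": [c for c in table.columns if c.startswith("iga_")],
            "pam": [c for c in table.columns if c.startswith("pam_")],
        }
        report = run_group_analysis(
            table, families,
            correlation_pairs=(["iga_gait_velocity_mean"], ["pigd", "bbs"]),
        )
        assert set(report.omnibus.family) == {"iga", "pam"}
        assert (report.omnibus.p_adjusted >= report.omnibus.p_value - 1e-15).all()
        again = GroupStatsReport.from_json(report.to_json())
        assert report.omnibus.equals(again.omnibus)
        assert report.correlations.equals(again.correlations)

    def test_small_group_features_skipped(self):
        table = sample_cohort_features(2, seed=0)
        report = run_group_analysis(table, {"iga": ["iga_gait_velocity_mean"]})
        assert len(report.omnibus) == 0

    def test_posthoc_only_for_significant(self):
        table = sample_cohort_features(25, seed=9)
        report = run_group_analysis(table, {"iga": ["iga_gait_velocity_mean",
                                                    "iga_stride_time_mean"]})
        pair_cols = [c for c in report.omnibus.columns if c.startswith("p_MSA")]
        for _, row in report.omnibus.iterrows():
            if not row.p_adjusted < 0.05:
                assert row[pair_cols].isna().all()
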