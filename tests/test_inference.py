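"""Cluster-interpretation statistics: split-plot ANOVA against
brute-force and pingouin oracles, post-hocs, Type-3 two-way ANOVA,
correlations, and attrition comparisons."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import wbtraj as w
from wbtraj.inference import retention_percentage


def long_table(values_by_pid, days=(0, 7, 37, 97), sample="s1", outcome="ls"):
    rows = []
    for pid, vals in values_by_pid.items():
        for d, v in zip(days, vals):
            rows.append({"participant_id": pid, "sample_id": sample, "day": d, outcome: v})
    return pd.DataFrame(rows)


def brute_force_split_plot(values_by_pid, labels):
    """Independent SS oracle: plain-loop split-plot decomposition."""
    pids = sorted(values_by_pid)
    y = np.array([values_by_pid[p] for p in pids], dtype=float)
    groups = [labels[p] for p in pids]
    T = y.shape[1]
    M = y.mean()
    ss_total = ((y - M) ** 2).sum()
    subj = y.mean(axis=1)
    grp_names = sorted(set(groups))
    grp_mean = {g: np.mean([subj[i] for i in range(len(pids)) if groups[i] == g])
                for g in grp_names}
    n_g = {g: sum(1 for gg in groups if gg == g) for g in grp_names}
    ss_cluster = T * sum(n_g[g] * (grp_mean[g] - M) ** 2 for g in grp_names)
    ss_subj = T * sum((subj[i] - grp_mean[groups[i]]) ** 2 for i in range(len(pids)))
    tmean = y.mean(axis=0)
    ss_time = len(pids) * ((tmean - M) ** 2).sum()
    cell = {g: y[[i for i in range(len(pids)) if groups[i] == g]].mean(axis=0)
            for g in grp_names}
    ss_inter = sum(
        n_g[g] * (cell[g][t] - grp_mean[g] - tmean[t] + M) ** 2
        for g in grp_names for t in range(T)
    )
    ss_err = ss_total - ss_cluster - ss_subj - ss_time - ss_inter
    return dict(total=ss_total, cluster=ss_cluster, subj=ss_subj, time=ss_time,
                inter=ss_inter, err=ss_err)


class TestMixedAnova:
    def test_all_identical_values_are_degenerate(self):
        vals = {f"p{i}": (20, 20, 20, 20) for i in range(6)}
        labels = {f"p{i}": "a" if i < 3 else "b" for i in range(6)}
        tab = w.mixed_anova_4x4(long_table(vals), labels, (0, 7, 37, 97))
        for effect in ("cluster", "timepoint", "timepoint:cluster"):
            row = tab.row(effect)
            assert row["ss"] == pytest.approx(0.0, abs=1e-10)
            assert row["F"] == 0.0 and row["p"] == 1.0

    def test_pure_group_offset_loads_only_on_cluster(self):
        vals = {f"a{i}": (20.0, 20, 20, 20) for i in range(3)}
        vals |= {f"b{i}": (25.0, 25, 25, 25) for i in range(3)}
        labels = {p: p[0] for p in vals}
        tab = w.mixed_anova_4x4(long_table(vals), labels, (0, 7, 37, 97))
        assert tab.row("timepoint")["F"] == 0.0
        assert tab.row("cluster")["ss"] > 0

    def test_two_by_two_toy_matches_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        vals = {f"p{i}": tuple(rng.normal(20, 4, 4)) for i in range(4)}
        labels = {"p0": "a", "p1": "a", "p2": "b", "p3": "b"}
        oracle = brute_force_split_plot(vals, labels)
        tab = w.mixed_anova_4x4(long_table(vals), labels, (0, 7, 37, 97))
        assert tab.row("cluster")["ss"] == pytest.approx(oracle["cluster"], abs=1e-8)
        assert tab.row("timepoint")["ss"] == pytest.approx(oracle["time"], abs=1e-8)
        assert tab.row("timepoint:cluster")["ss"] == pytest.approx(oracle["inter"], abs=1e-8)
        assert tab.row("error")["ss"] == pytest.approx(oracle["err"], abs=1e-8)
        f_cluster = (oracle["cluster"] / 1) / (oracle["subj"] / 2)
        assert tab.row("cluster")["F"] == pytest.approx(f_cluster, abs=1e-8)

    def test_decomposition_conserves_total_ss_unbalanced(self):
        rng = np.random.default_rng(13)
        vals = {f"p{i}": tuple(rng.normal(20, 4, 4)) for i in range(11)}
        labels = {f"p{i}": ("a", "b", "c")[i % 3] for i in range(11)}
        tab = w.mixed_anova_4x4(long_table(vals), labels, (0, 7, 37, 97))
        assert tab.table["ss"].sum() == pytest.approx(tab.ss_total, abs=1e-8)
        assert (tab.table["eta_sq"] >= 0).all() and (tab.table["eta_sq"] <= 1).all()

    def test_agrees_with_pingouin_on_balanced_data(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(14)
        vals = {f"p{i}": tuple(rng.normal(20, 4, 4)) for i in range(12)}
        labels = {f"p{i}": ("a", "b", "c")[i % 3] for i in range(12)}
        tab = w.mixed_anova_4x4(long_table(vals), labels, (0, 7, 37, 97))
        df = long_table(vals)
        df["cluster"] = df["participant_id"].map(labels)
        pg = pingouin.mixed_anova(
            data=df, dv="ls", within="day", subject="participant_id", between="cluster"
        ).set_index("Source")
        assert tab.row("cluster")["F"] == pytest.approx(pg.loc["cluster", "F"], rel=1e-6)
        assert tab.row("timepoint")["F"] == pytest.approx(pg.loc["day", "F"], rel=1e-6)
        assert tab.row("timepoint:cluster")["F"] == pytest.approx(
            pg.loc["Interaction", "F"], rel=1e-6
        )

    def test_small_cluster_rejected(self):
        vals = {f"p{i}": (20.0, 21, 22, 23) for i in range(3)}
        labels = {"p0": "a", "p1": "a", "p2": "b"}
        with pytest.raises(w.ConfigError, match="fewer than 2"):
            w.mixed_anova_4x4(long_table(vals), labels, (0, 7, 37, 97))

    def test_incomplete_participants_dropped_pairwise(self):
        vals = {f"p{i}": tuple(np.linspace(18, 24, 4) + i) for i in range(6)}
        df = long_table(vals)
        df.loc[(df.participant_id == "p0") & (df.day == 97), "ls"] = np.nan
        labels = {f"p{i}": "a" if i < 3 else "b" for i in range(6)}
        tab = w.mixed_anova_4x4(df, labels, (0, 7, 37, 97))
        # p0 dropped: 5 participants x 4 timepoints remain
        assert tab.row("cluster")["df"] == 1
        assert tab.row("timepoint")["df_error"] == (5 - 2) * 3


class TestPosthoc:
    def test_identical_groups_give_t_zero_p_one(self):
        vals = {f"a{i}": (20.0,) * 4 for i in range(3)} | {
            f"b{i}": (20.0,) * 4 for i in range(3)
        }
        labels = {p: p[0] for p in vals}
        tab = w.posthoc_pairwise(long_table(vals), labels, timepoint=0)
        assert tab.table.iloc[0]["t"] == 0.0 and tab.table.iloc[0]["p_adj"] == 1.0

    def test_bonferroni_arithmetic_and_cap(self):
        rng = np.random.default_rng(15)
        vals = {f"a{i}": tuple(rng.normal(20, 2, 4)) for i in range(5)} | {
            f"b{i}": tuple(rng.normal(24, 2, 4)) for i in range(5)
        }
        labels = {p: p[0] for p in vals}
        t6 = w.posthoc_pairwise(long_table(vals), labels, timepoint=0, family_size=6)
        t1 = w.posthoc_pairwise(long_table(vals), labels, timepoint=0, family_size=1)
        raw = t1.table.iloc[0]["p_raw"]
        assert t6.table.iloc[0]["p_adj"] == pytest.approx(min(1.0, raw * 6), abs=1e-12)
        huge = w.posthoc_pairwise(long_table(vals), labels, timepoint=0, family_size=10_000)
        assert huge.table.iloc[0]["p_adj"] <= 1.0

    def test_matches_pooled_t_formula(self):
        xa = np.array([18.0, 21.0, 20.0, 23.0])
        xb = np.array([24.0, 27.0, 25.0])
        vals = {f"a{i}": (v,) * 4 for i, v in enumerate(xa)}
        vals |= {f"b{i}": (v,) * 4 for i, v in enumerate(xb)}
        labels = {p: p[0] for p in vals}
        tab = w.posthoc_pairwise(long_table(vals), labels, timepoint=0)
        sp2 = ((len(xa) - 1) * xa.var(ddof=1) + (len(xb) - 1) * xb.var(ddof=1)) / (
            len(xa) + len(xb) - 2
        )
        t_hand = (xa.mean() - xb.mean()) / np.sqrt(sp2 * (1 / len(xa) + 1 / len(xb)))
        assert tab.table.iloc[0]["t"] == pytest.approx(t_hand, abs=1e-10)

    def test_tiny_group_skipped_with_note(self):
        vals = {"a0": (20.0,) * 4, "a1": (21.0,) * 4, "b0": (25.0,) * 4}
        labels = {p: p[0] for p in vals}
        tab = w.posthoc_pairwise(long_table(vals), labels, timepoint=0)
        assert "skipped" in tab.table.iloc[0]["note"]


class TestCrossSampleAnova:
    def _view(self, rng, interaction=0.0, n=12):
        rows = []
        for s_i, sample in enumerate(("s1", "s2")):
            for c_i, cluster in enumerate(("a", "b")):
                for i in range(n):
                    y = 20 + 2 * c_i + 1 * s_i + interaction * c_i * s_i + rng.normal()
                    rows.append({"participant_id": f"{sample}{cluster}{i}",
                                 "sample_id": sample, "day": 0, "ls": y})
        view = pd.DataFrame(rows)
        labels = {r["participant_id"]: r["participant_id"][2] for r in rows}
        return view, labels

    def test_balanced_type3_equals_type1(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(16)
        view, labels = self._view(rng)
        tab = w.cross_sample_anova(view, labels)
        df = view.copy()
        df["cluster"] = df["participant_id"].map(labels)
        df = df.rename(columns={"ls": "y", "sample_id": "sample"})
        t1 = sm.stats.anova_lm(
            smf.ols("y ~ C(cluster) * C(sample)", data=df).fit(), typ=1
        )
        assert tab.row("cluster")["ss"] == pytest.approx(t1.loc["C(cluster)", "sum_sq"], abs=1e-8)
        assert tab.row("cluster:sample")["ss"] == pytest.approx(
            t1.loc["C(cluster):C(sample)", "sum_sq"], abs=1e-8
        )

    def test_zero_ss_effect_reports_zero_eta(self):
        view, labels = self._view(np.random.default_rng(17))
        view["ls"] = 20.0
        tab = w.cross_sample_anova(view, labels)
        assert tab.row("cluster:sample")["eta_sq"] == 0.0
        assert tab.row("cluster:sample")["p"] == 1.0

    def test_empty_cell_rejected_by_name(self):
        view, labels = self._view(np.random.default_rng(18))
        keep = ~((view.sample_id == "s2") & view.participant_id.str.contains("b"))
        with pytest.raises(w.ConfigError, match="cell"):
            w.cross_sample_anova(view[keep], labels)


class TestPearson:
    def test_perfect_positive_and_negative(self):
        assert w.pearson_corr([1, 2, 3], [2, 4, 6]).r == pytest.approx(1.0)
        assert w.pearson_corr([1, 2, 3], [6, 4, 2]).r == pytest.approx(-1.0)

    def test_fisher_ci_contains_r_and_shrinks_with_n(self):
        rng = np.random.default_rng(19)
        x = rng.normal(size=400)
        y = 0.6 * x + rng.normal(size=400) * 0.8
        small = w.pearson_corr(x[:50], y[:50])
        big = w.pearson_corr(x, y)
        for res in (small, big):
            assert res.ci_low < res.r < res.ci_high
        assert (big.ci_high - big.ci_low) < (small.ci_high - small.ci_low)

    def test_pairwise_deletion_inside_corr(self):
        x = [1.0, 2, np.nan, 4, 5]
        y = [2.0, 4, 6, np.nan, 10]
        assert w.pearson_corr(x, y).n == 3

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(w.ConfigError):
            w.pearson_corr([1, 1, 1], [2, 3, 4])
        with pytest.raises(w.ConfigError):
            w.pearson_corr([1, 2], [2, 3])


class TestAttritionCompare:
    def _cohort(self, make_cohort, n_inc=(10, 20), n_exc=(30, 40), flat_excluded=False):
        rows = []
        days = {"s1": (0, 7, 37, 97), "s2": (0, 42, 72, 132)}
        for s_i, sample in enumerate(("s1", "s2")):
            for i in range(n_inc[s_i]):
                for d in days[sample]:
                    rows.append((f"{sample}i{i}", sample, d, 20 + (i % 7), 5 + (i % 5), 10 + (i % 9)))
            for i in range(n_exc[s_i]):
                ls = 18.0 if flat_excluded else 18 + (i % 6)
                rows.append((f"{sample}e{i}", sample, 0, ls, 3 + (i % 4), 14 + (i % 8)))
        return make_cohort(rows)

    def test_chi_square_matches_hand_formula(self, make_cohort):
        cohort = self._cohort(make_cohort)
        included = {p for p in cohort.participants() if "i" in p[2:]}
        excluded = set(cohort.participants()) - included
        report = w.attrition_compare(cohort, included, excluded)
        # Pearson chi2 on {{10,20},{30,40}}: sum (O-E)^2/E = 50/63
        assert report.chi2 == pytest.approx(50 / 63, abs=1e-10)
        assert report.chi2_df == 1

    def test_welch_direction_and_report_shape(self, make_cohort):
        cohort = self._cohort(make_cohort)
        included = {p for p in cohort.participants() if "i" in p[2:]}
        excluded = set(cohort.participants()) - included
        report = w.attrition_compare(cohort, included, excluded)
        ls = report.outcomes.set_index("outcome").loc["ls"]
        assert ls["mean_incl"] > ls["mean_excl"]
        assert min(len(included), len(excluded)) - 1 <= ls["df"] <= len(cohort.participants()) - 2

    def test_zero_variance_group_rejected(self, make_cohort):
        cohort = self._cohort(make_cohort, flat_excluded=True)
        included = {p for p in cohort.participants() if "i" in p[2:]}
        excluded = set(cohort.participants()) - included
        with pytest.raises(w.ConfigError, match="zero-variance"):
            w.attrition_compare(cohort, included, excluded)

    def test_random_splits_rarely_significant(self, small_cohort):
        rng = np.random.default_rng(20)
        pids = np.array(small_cohort.participants())
        ok = 0
        n_splits = 60
        for _ in range(n_splits):
            mask = rng.random(len(pids)) < 0.5
            a, b = set(pids[mask]), set(pids[~mask])
            if not a or not b:
                continue
            report = w.attrition_compare(small_cohort, a, b)
            ok += report.outcomes.set_index("outcome").loc["ls", "p"] > 0.05
        assert ok >= 0.9 * n_splits


class TestRetention:
    def test_printed_sample_counts_reproduce_percentage(self):
        assert round(retention_percentage(276, 912), 1) == 30.3

    def test_invalid_counts_rejected(self):
        with pytest.raises(w.ConfigError):
            retention_percentage(10, 0)
        with pytest.raises(w.ConfigError):
            retention_percentage(-1, 10)
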