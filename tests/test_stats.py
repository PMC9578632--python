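"""Unit tests for the yoked statistical layer."""

import subprocess

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from wormloco import (SimDesign, analyze_experiment, build_yoked_table,
                      cohens_d, cohens_d_from_stats, generate_trial_table,
                      normalize_to_baseline, one_sample_t, paired_t,
                      shapiro_wilk_gate, three_factor_anova, tukey_hsd,
                      yoked_difference)


class TestNormalization:
    def test_no_change_is_one(self):
        assert normalize_to_baseline(0.004, 0.004) == 1.0

    def test_halved_locomotion(self):
        assert normalize_to_baseline(0.002, 0.004) == 0.5

    def test_zero_baseline_error_names_trial(self):
        with pytest.raises(ValueError, match="trial_x"):
            normalize_to_baseline(0.1, 0.0, trial="trial_x")

    def test_yoked_difference(self):
        assert yoked_difference(0.9, 0.9) == 0.0
        assert yoked_difference(0.9, 0.8) == pytest.approx(0.1)


class TestBuildYokedTable:
    @staticmethod
    def records(rows):
        return pd.DataFrame(rows, columns=["pair_id", "plate_id", "generation",
                                           "lineage", "condition", "n_worms",
                                           "area_per_worm"])

    def full_pair(self, pid="p1", gen="F1", scores=(0.02, 0.01, 0.02, 0.012)):
        bc, ec, be, ee = scores
        return [
            (pid, pid, gen, "control", "baseline", 10, bc),
            (pid, pid, gen, "control", "etoh", 10, ec),
            (pid, pid, gen, "etoh", "baseline", 10, be),
            (pid, pid, gen, "etoh", "etoh", 10, ee),
        ]

    def test_normalisation_and_difference(self):
        yoked = build_yoked_table(self.records(self.full_pair()))
        assert yoked.loc[0, "normalized_control"] == 0.5
        assert yoked.loc[0, "normalized_etoh"] == pytest.approx(0.6)
        assert yoked.loc[0, "yoked_difference"] == pytest.approx(0.1)

    def test_missing_pair_member_raises(self):
        rows = self.full_pair()[:-1]
        with pytest.raises(ValueError, match="missing"):
            build_yoked_table(self.records(rows))

    def test_zero_baseline_names_offender(self):
        rows = self.full_pair(scores=(0.02, 0.01, 0.0, 0.012))
        with pytest.raises(ValueError, match="p1/etoh"):
            build_yoked_table(self.records(rows))

    def test_difference_identity_holds_exactly(self):
        table = generate_trial_table(SimDesign(seed=2))
        yoked = build_yoked_table(table)
        assert np.array_equal(
            yoked["yoked_difference"].to_numpy(),
            (yoked["normalized_etoh"] - yoked["normalized_control"]).to_numpy())


class TestTTests:
    def test_symmetric_sample_has_zero_t(self):
        res = one_sample_t([-1.0, 0.0, 1.0])
        assert res.t == 0.0 and res.p == 1.0 and res.df == 2

    def test_hand_computed_example(self):
        res = one_sample_t([1.0, 2.0, 3.0])
        assert res.mean == 2.0 and res.sd == 1.0 and res.n == 3
        assert res.t == pytest.approx(2 * np.sqrt(3), abs=1e-12)
        assert res.df == 2

    def test_errors(self):
        with pytest.raises(ValueError):
            one_sample_t([1.0, 2.0])
        with pytest.raises(ValueError):
            one_sample_t([3.0, 3.0, 3.0])
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_paired_equals_one_sample_identity(self, seed):
        """paired_t(a, b) and one_sample_t(a - b) agree to 1e-12 in t, df
        and p — the same equivalence the yoked analysis relies on, checked
        across independent implementations."""
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 60)
        a = rng.normal(0.8, 0.2, n)
        b = rng.normal(0.75, 0.2, n)
        pt = paired_t(a, b)
        ot = one_sample_t(a - b)
        assert pt.df == ot.df
        assert abs(pt.t - ot.t) <= 1e-12
        assert abs(pt.p - ot.p) <= 1e-12
        assert abs(pt.cohens_d - ot.cohens_d) <= 1e-12


class TestCohensD:
    def test_printed_chronic_effect_size(self):
        assert round(cohens_d_from_stats(0.0698, 0.14750), 3) == 0.473

    def test_printed_intermittent_effect_size(self):
        assert round(abs(cohens_d_from_stats(-0.133, 0.127)), 2) == 1.05

    def test_zero_mean(self):
        assert cohens_d_from_stats(0.0, 0.5) == 0.0
        assert cohens_d([-2.0, 0.0, 2.0]) == 0.0

    @pytest.mark.parametrize("c", [0.1, 2.0, 100.0])
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(7)
        x = rng.normal(0.1, 0.2, 40)
        assert cohens_d(c * x) == pytest.approx(cohens_d(x), rel=1e-12)

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0, 1.0])


def _sum_coded(labels, levels):
    """Sum-to-zero contrast columns for one factor (oracle helper)."""
    cols = []
    for lev in levels[:-1]:
        col = np.where(labels == lev, 1.0, 0.0)
        col = col - np.where(labels == levels[-1], 1.0, 0.0)
        cols.append(col)
    return np.column_stack(cols)


def _anova_oracle(data):
    """From-scratch factorial ANOVA via nested linear-model projections."""
    y = data["area_per_worm"].to_numpy(float)
    factors = {
        "Generation": _sum_coded(data["generation"].to_numpy(),
                                 sorted(data["generation"].unique())),
        "Lineage": _sum_coded(data["lineage"].to_numpy(),
                              sorted(data["lineage"].unique())),
        "Condition": _sum_coded(data["condition"].to_numpy(),
                                sorted(data["condition"].unique())),
    }

    def interact(*mats):
        out = mats[0]
        for m in mats[1:]:
            out = np.concatenate([out[:, i:i + 1] * m
                                  for i in range(out.shape[1])], axis=1)
        return out

    terms = dict(factors)
    terms["Generation:Lineage"] = interact(factors["Generation"], factors["Lineage"])
    terms["Generation:Condition"] = interact(factors["Generation"],
                                             factors["Condition"])
    terms["Lineage:Condition"] = interact(factors["Lineage"], factors["Condition"])
    terms["Generation:Lineage:Condition"] = interact(
        factors["Generation"], factors["Lineage"], factors["Condition"])

    def rss(cols):
        X = np.column_stack([np.ones_like(y)] + cols)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float(resid @ resid)

    full_cols = list(terms.values())
    rss_full = rss(full_cols)
    df_resid = len(y) - 1 - sum(m.shape[1] for m in full_cols)
    out = {}
    for name, mat in terms.items():
        reduced = [m for n, m in terms.items() if n != name]
        ss = rss(reduced) - rss_full
        f = (ss / mat.shape[1]) / (rss_full / df_resid)
        out[name] = (ss, mat.shape[1], f)
    out["Residual"] = (rss_full, df_resid, np.nan)
    return out


def balanced_table(noise_sd=1.0, seed=0, n_per_cell=2, condition_effect=1.0):
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for gen in ("F1", "F2", "F3"):
        for lineage in ("control", "etoh"):
            for _ in range(n_per_cell):
                pid += 1
                for condition in ("baseline", "etoh"):
                    y = 10.0 + (condition_effect if condition == "etoh" else 0.0)
                    y += rng.normal(0, noise_sd)
                    rows.append((f"p{pid}", f"p{pid}", gen, lineage, condition,
                                 10, y))
    return pd.DataFrame(rows, columns=["pair_id", "plate_id", "generation",
                                       "lineage", "condition", "n_worms",
                                       "area_per_worm"])


class TestThreeFactorAnova:
    def test_matches_projection_oracle_on_balanced_design(self):
        data = balanced_table(noise_sd=1.0, seed=5, n_per_cell=3)
        table = three_factor_anova(data)
        oracle = _anova_oracle(data)
        for term, (ss, df, f) in oracle.items():
            assert table.loc[term, "sum_sq"] == pytest.approx(ss, rel=1e-8)
            assert table.loc[term, "df"] == df
            if np.isfinite(f):
                assert table.loc[term, "F"] == pytest.approx(f, rel=1e-8)

    def test_type1_equals_type3_when_balanced(self):
        data = balanced_table(noise_sd=0.7, seed=9)
        t3 = three_factor_anova(data, ss_type=3)
        t1 = three_factor_anova(data, ss_type=1)
        for term in t3.index:
            assert t1.loc[term, "sum_sq"] == pytest.approx(
                t3.loc[term, "sum_sq"], rel=1e-8)

    def test_sums_of_squares_conserve_total(self):
        data = balanced_table(noise_sd=1.3, seed=12)
        table = three_factor_anova(data)
        y = data["area_per_worm"].to_numpy()
        total = ((y - y.mean()) ** 2).sum()
        assert table["sum_sq"].sum() == pytest.approx(total, rel=1e-10)

    def test_zero_noise_pure_effect_flags_zero_residual(self):
        data = balanced_table(noise_sd=0.0, condition_effect=2.0)
        with pytest.raises(ValueError, match="residual"):
            three_factor_anova(data)

    def test_constant_response_rejected(self):
        data = balanced_table(noise_sd=0.0, condition_effect=0.0)
        with pytest.raises(ValueError):
            three_factor_anova(data)

    def test_empty_cell_listed_for_type3(self):
        data = balanced_table(noise_sd=1.0, seed=1)
        data = data[~((data["generation"] == "F3") & (data["lineage"] == "etoh")
                      & (data["condition"] == "etoh"))]
        with pytest.raises(ValueError, match="F3"):
            three_factor_anova(data)

    def test_single_level_factor_rejected(self):
        data = balanced_table()
        with pytest.raises(ValueError, match="lineage"):
            three_factor_anova(data[data["lineage"] == "control"])


class TestTukeyHSD:
    def test_equal_means_all_p_near_one(self):
        rng = np.random.default_rng(3)
        groups = []
        for _ in range(3):
            g = rng.standard_normal(8)
            groups.append(5.0 + g - g.mean())  # every group mean exactly 5
        values = np.concatenate(groups)
        labels = np.repeat(["a", "b", "c"], 8)
        res = tukey_hsd(values, labels)
        assert (res["p_adj"] > 0.99).all()

    def test_matches_studentized_range_oracle(self):
        """Adjusted p-values agree with a direct studentized-range
        computation (numerical integration via scipy's distribution)."""
        rng = np.random.default_rng(8)
        groups = {"g1": rng.normal(0.0, 1.0, 5),
                  "g2": rng.normal(1.0, 1.0, 5),
                  "g3": rng.normal(2.5, 1.0, 5)}
        values = np.concatenate(list(groups.values()))
        labels = np.repeat(list(groups), [len(v) for v in groups.values()])
        res = tukey_hsd(values, labels).set_index(["group1", "group2"])

        k = len(groups)
        df = sum(len(v) - 1 for v in groups.values())
        msw = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / df
        for (a, b) in [("g1", "g2"), ("g1", "g3"), ("g2", "g3")]:
            na, nb = len(groups[a]), len(groups[b])
            se = np.sqrt(msw / 2 * (1 / na + 1 / nb))
            q = abs(groups[b].mean() - groups[a].mean()) / se
            p = scipy.stats.studentized_range.sf(q, k, df)
            assert res.loc[(a, b), "p_adj"] == pytest.approx(p, abs=1e-6)

    def test_unequal_n_handled(self):
        rng = np.random.default_rng(4)
        values = np.concatenate([rng.normal(0, 1, 4), rng.normal(3, 1, 9)])
        labels = np.array(["a"] * 4 + ["b"] * 9)
        res = tukey_hsd(values, labels)
        assert res.loc[0, "p_adj"] < 0.01

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            tukey_hsd([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestShapiroGate:
    def test_gaussian_matches_reference_implementation(self, tmp_path):
        """W and p agree with R's shapiro.test on the same sample."""
        rng = np.random.default_rng(15)
        x = rng.normal(0, 1, 50)
        gate = shapiro_wilk_gate(x, group="F3")
        sample = tmp_path / "x.txt"
        sample.write_text("\n".join(f"{v:.17g}" for v in x))
        script = (f'x <- scan("{sample}", quiet=TRUE); r <- shapiro.test(x); '
                  f'cat(sprintf("%.10f %.10g", r$statistic, r$p.value))')
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True).stdout.split()
        assert gate.W == pytest.approx(float(out[0]), abs=1e-6)
        assert gate.p == pytest.approx(float(out[1]), rel=1e-3)

    def test_uniform_samples_mostly_fail(self):
        fails = 0
        for seed in range(40):
            x = np.random.default_rng(seed).uniform(size=50)
            fails += not shapiro_wilk_gate(x).passed
        assert fails > 20

    def test_gross_outlier_fails(self):
        x = np.concatenate([np.random.default_rng(1).normal(0, 1, 49), [100.0]])
        assert not shapiro_wilk_gate(x).passed

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk_gate([2.0, 2.0, 2.0, 2.0])


class TestAnalyzeExperiment:
    def test_report_structure_on_chronic_table(self, chronic_design):
        table = generate_trial_table(chronic_design)
        report = analyze_experiment(table)
        assert set(report.per_generation) == {"F1", "F2", "F3"}
        for gen, g in report.per_generation.items():
            assert g.paired is not None and g.one_sample is not None
            # paired test on normalised values == one-sample test on D
            assert g.paired.t == pytest.approx(g.one_sample.t, abs=1e-12)
            assert g.paired.p == pytest.approx(g.one_sample.p, abs=1e-12)
            assert g.normality is not None
        assert "Condition" in report.anova.index
        assert report.anova.loc["Condition", "p"] < 0.001
        assert report.n_tests_run >= 13
        payload = report.to_dict()
        assert payload["per_generation"]["F3"]["one_sample_t"]["df"] == 37
        assert "Significant?" in report.format_table()

    def test_missing_lineage_rejected(self, chronic_design):
        table = generate_trial_table(chronic_design)
        with pytest.raises(ValueError, match="etoh"):
            analyze_experiment(table[table["lineage"] == "control"])

    def test_degenerate_generation_flagged_not_dropped(self):
        table = generate_trial_table(SimDesign(seed=1))
        # make F1 yoked differences all identical -> t-test impossible
        f1 = table["generation"] == "F1"
        base = table[f1 & (table["condition"] == "baseline")]
        for _, row in base.iterrows():
            mask = ((table["pair_id"] == row["pair_id"])
                    & (table["lineage"] == row["lineage"])
                    & (table["condition"] == "etoh"))
            table.loc[mask, "area_per_worm"] = 0.5 * row["area_per_worm"]
        report = analyze_experiment(table)
        assert report.per_generation["F1"].one_sample is None
        assert any("F1" in flag for flag in report.flags)
        assert report.per_generation["F3"].one_sample is not None
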