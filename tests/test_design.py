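"""Factorial design structure, RT generator, and behavioral statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trackosc.design import (
    CONDITIONS,
    RTGenParams,
    congruency_label,
    factor_contrast,
    generate_design,
    generate_rts,
    median_rt,
    rm_effect_test,
    stimulus_type_label,
    summarize_behavior,
)


class TestGenerateDesign:
    def test_twelve_distinct_conditions_eight_with_response(self):
        assert len(CONDITIONS) == 12
        assert len(set(CONDITIONS)) == 12
        assert sum(1 for _, _, r in CONDITIONS if r != 0) == 8

    def test_block_structure_and_balance(self):
        d = generate_design(n_subjects=2, n_blocks=8, reps_per_condition=10,
                            seed=0)
        for (_, _), block in d.groupby(["subject", "block"]):
            assert len(block) == 120
            counts = block.groupby(["A", "T", "R"]).size()
            assert len(counts) == 12
            assert (counts == 10).all()

    def test_single_rep_block_has_all_distinct_conditions(self):
        d = generate_design(1, 1, 1, seed=3)
        assert len(d) == 12
        assert d.groupby(["A", "T", "R"]).size().eq(1).all()

    def test_order_differs_across_blocks_and_seeds(self):
        d1 = generate_design(1, 2, 10, seed=0)
        d2 = generate_design(1, 2, 10, seed=1)
        b1 = d1[d1["block"] == 1][["A", "T", "R"]].to_numpy()
        b2 = d1[d1["block"] == 2][["A", "T", "R"]].to_numpy()
        assert not np.array_equal(b1, b2)
        assert not np.array_equal(b1, d2[d2["block"] == 1][["A", "T", "R"]].to_numpy())

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            generate_design(0, 1, 1)
        with pytest.raises(ValueError):
            generate_design(1, 1, 0)

    def test_labels_are_deterministic_functions_of_factors(self):
        d = generate_design(1, 2, 3, seed=9)
        for _, row in d.iterrows():
            assert row["stimulus_type"] == stimulus_type_label(row["A"], row["T"])
            assert row["congruency"] == congruency_label(row["T"], row["R"])

    def test_straight_crossed_mapping(self):
        # straight: hand and target labels differ (LR, RL); crossed: LL, RR
        assert stimulus_type_label(-1, 1) == "straight"
        assert stimulus_type_label(1, -1) == "straight"
        assert stimulus_type_label(-1, -1) == "crossed"
        assert stimulus_type_label(1, 1) == "crossed"


class TestGenerateRTs:
    def test_zero_noise_zero_effects_gives_subject_base(self):
        d = generate_design(2, 1, 2, seed=0)
        p = RTGenParams(congruency_effect=0.0, stimulus_type_effect=0.0,
                        noise_scale=0.0, subject_sd=0.0)
        out = generate_rts(d, p, seed=0)
        resp = out[out["R"] != 0]
        assert np.allclose(resp["rt_ms"], p.grand_mean)
        assert out.loc[out["R"] == 0, "rt_ms"].isna().all()

    def test_congruency_effect_recovered_monte_carlo(self):
        d = generate_design(12, 8, 10, seed=1)
        out = generate_rts(d, RTGenParams(), seed=1)
        resp = out[out["R"] != 0]
        diff = (resp.loc[resp["congruency"] == "congruent", "rt_ms"].mean()
                - resp.loc[resp["congruency"] == "incongruent", "rt_ms"].mean())
        assert diff == pytest.approx(-18.0, abs=1.5)

    def test_coupling_matches_closed_form_correlation(self):
        # r = c*sigma_b / sqrt(c^2 sigma_b^2 + sigma_n^2) for additive noise
        d = generate_design(1, 8, 10, seed=2)
        d = pd.concat([d] * 12, ignore_index=True)
        rng = np.random.default_rng(0)
        sigma_b, c = 2.0, 10.0
        bias = sigma_b * rng.standard_normal(len(d))
        p = RTGenParams(congruency_effect=0.0, stimulus_type_effect=0.0,
                        subject_sd=0.0, coupling=c,
                        support=(-1e9, 1e9))  # no truncation
        out = generate_rts(d, p, bias, seed=3)
        resp = out["R"] != 0
        sigma_n = p.noise_scale * np.sqrt(
            (np.exp(p.noise_sigma**2) - 1) * np.exp(p.noise_sigma**2))
        expected = c * sigma_b / np.hypot(c * sigma_b, sigma_n)
        got = stats.pearsonr(out.loc[resp, "rt_ms"], bias[resp.to_numpy()]).statistic
        assert got == pytest.approx(expected, abs=0.03)

    def test_misaligned_bias_rejected(self):
        d = generate_design(1, 1, 1, seed=0)
        with pytest.raises(ValueError):
            generate_rts(d, beta_bias=np.zeros(5))


class TestMedianRT:
    def test_midpoint_and_single_value_conventions(self):
        rows = []
        for i, rt in enumerate([400.0, 500.0]):
            rows.append((1, 1, i, -1, -1, -1, "crossed", "congruent", rt))
        rows.append((1, 1, 3, -1, -1, 1, "crossed", "incongruent", 400.0))
        d = pd.DataFrame(rows, columns=["subject", "block", "trial", "A", "T",
                                        "R", "stimulus_type", "congruency",
                                        "rt_ms"])
        table = median_rt(d)
        assert table.loc[1, (-1, -1, -1)] == 450.0
        assert table.loc[1, (-1, -1, 1)] == 400.0

    def test_matches_sort_and_pick_oracle(self, rt_design):
        table = median_rt(rt_design)
        resp = rt_design[rt_design["R"] != 0]
        for (s, a, t, r), cell in resp.groupby(["subject", "A", "T", "R"]):
            vals = np.sort(cell["rt_ms"].to_numpy())
            n = len(vals)
            oracle = (vals[n // 2] if n % 2 else
                      0.5 * (vals[n // 2 - 1] + vals[n // 2]))
            assert table.loc[s, (a, t, r)] == pytest.approx(oracle)

    def test_empty_cell_warns_and_is_nan(self):
        d = generate_design(1, 1, 1, seed=0)
        d = generate_rts(d, RTGenParams(), seed=0)
        drop = (d["A"] == 1) & (d["T"] == 1) & (d["R"] == 1)
        d.loc[drop, "rt_ms"] = np.nan
        with pytest.warns(UserWarning, match="empty"):
            table = median_rt(d)
        assert np.isnan(table.loc[1, (1, 1, 1)])


class TestRmEffectTest:
    def test_identical_medians_give_zero_F(self):
        cols = pd.MultiIndex.from_tuples(
            [c for c in CONDITIONS if c[2] != 0])
        table = pd.DataFrame(np.full((5, 8), 450.0), columns=cols)
        eff, f, p = rm_effect_test(table, factor_contrast("congruency"))
        assert f == 0.0 and p == 1.0

    def test_equals_squared_paired_t_oracle(self):
        rng = np.random.default_rng(7)
        cols = pd.MultiIndex.from_tuples([c for c in CONDITIONS if c[2] != 0])
        w = factor_contrast("congruency")
        for _ in range(100):
            n = rng.integers(3, 15)
            table = pd.DataFrame(450 + 30 * rng.standard_normal((n, 8)),
                                 columns=cols)
            scores = table.to_numpy() @ np.array([w[c] for c in cols])
            t_oracle = stats.ttest_1samp(scores, 0.0)
            _, f, p = rm_effect_test(table, w)
            assert f == pytest.approx(t_oracle.statistic**2, rel=1e-10)
            assert p == pytest.approx(t_oracle.pvalue, rel=1e-10)

    def test_nonzero_sum_weights_rejected(self):
        cols = pd.MultiIndex.from_tuples([c for c in CONDITIONS if c[2] != 0])
        table = pd.DataFrame(np.ones((4, 8)), columns=cols)
        bad = {c: 1.0 for c in cols}
        with pytest.raises(ValueError, match="sum to 0"):
            rm_effect_test(table, bad)

    def test_agrees_with_pingouin_rm_anova(self, rt_design):
        pingouin = pytest.importorskip("pingouin")
        table = median_rt(rt_design)
        long = table.stack([0, 1, 2], future_stack=True).rename("rt").reset_index()
        long["congruency"] = np.where(long["T"] == long["R"], "c", "i")
        cell = long.groupby(["subject", "congruency"])["rt"].mean().reset_index()
        aov = pingouin.rm_anova(data=cell, dv="rt", within="congruency",
                                subject="subject", detailed=True)
        _, f, p = rm_effect_test(table, factor_contrast("congruency"))
        assert f == pytest.approx(float(aov["F"].iloc[0]), rel=1e-8)
        assert p == pytest.approx(float(aov["p_unc"].iloc[0]), rel=1e-6)


def test_summarize_behavior_reports_all_contrasts(rt_design):
    out = summarize_behavior(rt_design)
    assert set(out.effects["contrast"]) == {"A", "T", "R", "congruency",
                                            "stimulus_type"}
    assert (out.effects["F"] >= 0).all()
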