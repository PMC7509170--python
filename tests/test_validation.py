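import numpy as np
import pandas as pd
import pytest

from methylquad import validation_stats as vs
from methylquad.synthetic_data import SimulationConfig, simulate_cq, simulate_expression_cq
from oracles import auc_pair_count, fisher_exact_2x2


class TestQpcrFormulas:
    @pytest.mark.parametrize("dcq,expected", [(0.0, 1.0), (1.0, 0.5), (-2.0, 4.0)])
    def test_relative_expression_closed_form(self, dcq, expected):
        assert vs.relative_expression(20.0 + dcq, 20.0) == pytest.approx(expected)

    def test_mdre_closed_forms(self):
        assert vs.mdre_methylation(24.0, 24.0) == 0.0
        assert vs.mdre_methylation(24.0, 25.0) == pytest.approx(0.5)

    def test_mdre_noise_overshoot_clamped(self, caplog):
        # Cq_und - Cq_dig = 0.5 gives 1 - 2^0.5 = -0.414, clamped to 0
        with caplog.at_level("WARNING"):
            m = vs.mdre_methylation(24.5, 24.0)
        assert m == 0.0
        assert "clamp" in caplog.text

    def test_msre_closed_forms(self):
        assert vs.msre_methylation(24.0, 24.0) == 1.0
        assert vs.msre_methylation(24.0, 25.0) == pytest.approx(0.5)

    def test_msre_overshoot_clamped(self):
        assert vs.msre_methylation(25.0, 24.0) == 1.0

    def test_control_qc_thresholds(self):
        assert vs.control_qc(0.95, 0.02)
        assert not vs.control_qc(0.80, 0.02)
        assert not vs.control_qc(0.95, 0.15)

    def test_duplicate_discordance_flagged(self, caplog):
        with caplog.at_level("WARNING"):
            mean = vs.average_duplicates([24.0, 25.5])
        assert mean == pytest.approx(24.75)
        assert "discordance" in caplog.text


class TestCqRoundTrip:
    def test_exact_recovery_at_zero_noise(self):
        config = SimulationConfig(seed=3)
        m_true = np.linspace(0.05, 0.95, 10)
        for assay, fn in (("mdre", vs.mdre_methylation), ("msre", vs.msre_methylation)):
            cq = simulate_cq(m_true, assay, config, noise_sd=0.0)
            means = cq.groupby(["sample_id", "condition"])["cq"].mean().unstack()
            rec = [
                fn(row["undigested"], row["digested"]) for _, row in means.iterrows()
            ]
            assert np.allclose(sorted(rec), sorted(m_true), atol=1e-9)

    def test_saturating_inputs_cap_at_max_cycle(self):
        config = SimulationConfig(seed=3)
        cq = simulate_cq([1.0], "mdre", config, noise_sd=0.0)
        dig = cq[cq["condition"] == "digested"]["cq"]
        assert (dig == config.max_cycle).all()
        cq0 = simulate_cq([0.0], "msre", config, noise_sd=0.0)
        assert (cq0[cq0["condition"] == "digested"]["cq"] == config.max_cycle).all()

    def test_recovery_within_tolerance_at_noise(self):
        # Monte-Carlo round trip: noise sd 0.05 cycles, n = 30, duplicates averaged
        config = SimulationConfig(seed=11)
        rng = np.random.default_rng(101)
        m_true = rng.uniform(0.2, 0.8, 30)
        cq = simulate_cq(m_true, "msre", config, noise_sd=0.05, rng=rng)
        means = cq.groupby(["sample_id", "condition"])["cq"].mean().unstack()
        order = sorted(means.index, key=lambda s: int(s[1:]))
        rec = np.array(
            [vs.msre_methylation(means.loc[s, "undigested"], means.loc[s, "digested"]) for s in order]
        )
        assert np.abs(rec - m_true).mean() < 0.02

    def test_expression_cq_round_trip(self):
        config = SimulationConfig(seed=5)
        ratios = np.array([0.25, 1.0, 4.0])
        cq = simulate_expression_cq(ratios, config, noise_sd=0.0)
        means = cq.groupby(["sample_id", "condition"])["cq"].mean().unstack()
        rec = [
            vs.relative_expression(row["target"], row["reference"])
            for _, row in means.sort_index().iterrows()
        ]
        assert np.allclose(rec, ratios)

    def test_quantify_cq_table(self):
        config = SimulationConfig(seed=6)
        cq = simulate_cq([0.5, 0.7], "msre", config, noise_sd=0.0, gene="X")
        out = vs.quantify_cq_table(cq, {"X": "msre"})
        assert sorted(out["quantity"].round(9)) == [0.5, 0.7]


class TestCompareGroups:
    def test_identical_groups_p_is_one(self):
        res = vs.compare_groups([1.0] * 6, ["a"] * 3 + ["b"] * 3)
        assert res.p_value == 1.0

    def test_chi_square_vs_fisher_enumeration_oracle(self):
        table = [[20, 10], [9, 21]]
        res = vs.compare_categorical(table)
        assert res.test == "chi_square"
        # the asymptotic chi-square p tracks the exact enumeration in magnitude
        exact = fisher_exact_2x2(table)
        assert exact / 3 < res.p_value < exact * 3
        assert res.p_value < 0.05 and exact < 0.05
        small = [[2, 8], [7, 3]]
        res_small = vs.compare_categorical(small)
        assert res_small.test == "fisher_exact"
        assert res_small.p_value == pytest.approx(fisher_exact_2x2(small), rel=1e-9)

    def test_normal_data_routes_to_t(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(0, 1, 25), rng.normal(1, 1, 25)])
        labels = ["a"] * 25 + ["b"] * 25
        assert vs.compare_groups(x, labels).test == "student_t"

    def test_heavy_tailed_data_routes_to_mann_whitney(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.standard_cauchy(25), rng.standard_cauchy(25) + 1])
        labels = ["a"] * 25 + ["b"] * 25
        assert vs.compare_groups(x, labels).test == "mann_whitney_u"


class TestCorrelate:
    def test_exact_linear_relationship(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 40)
        res = vs.correlate(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_monotone_nonlinear_with_outliers_uses_spearman(self):
        x = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 50.0])
        res = vs.correlate(x, x**3)
        assert res.method == "spearman"
        assert res.r == pytest.approx(1.0)


class TestStepwise:
    def test_exact_predictor_standardized_beta_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 2, 50)
        X = pd.DataFrame({"x": x, "noise": rng.normal(0, 1, 50)})
        out = vs.stepwise_regression(x, X)
        assert list(out["variable"]) == ["x"]
        assert out.iloc[0]["beta"] == pytest.approx(1.0)
        assert out.iloc[0]["p_value"] < 1e-20

    def test_planted_predictor_selected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(0, 1, (60, 6)), columns=[f"v{i}" for i in range(6)])
            y = X["v0"] + rng.normal(0, 0.5, 60)
            out = vs.stepwise_regression(y, X)
            if "v0" in list(out["variable"]):
                hits += 1
        assert hits >= 18  # >= 90%

    def test_collinear_candidate_skipped(self, caplog):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 50)
        X = pd.DataFrame({"x": x, "x_copy": x})
        y = x + rng.normal(0, 0.3, 50)
        with caplog.at_level("WARNING"):
            out = vs.stepwise_regression(y, X)
        assert len(out) == 1


class TestRoc:
    def test_perfect_separation(self):
        scores = [1, 2, 3, 10, 11, 12]
        labels = [0, 0, 0, 1, 1, 1]
        res = vs.roc_youden(scores, labels)
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert res.youden == pytest.approx(1.0)

    def test_auc_equals_pair_counting_oracle(self):
        scores = [3.1, 2.2, 5.5, 1.0, 4.4, 2.2, 6.0, 0.5, 3.1, 4.9]
        labels = [1, 0, 1, 0, 1, 1, 1, 0, 0, 0]
        res = vs.roc_youden(scores, labels)
        assert res.auc == pytest.approx(auc_pair_count(scores, labels))

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(0, 1, 40)
        labels = (rng.random(40) < 0.5).astype(int)
        labels[:2] = [0, 1]  # both classes present
        a = vs.roc_youden(scores, labels)
        b = vs.roc_youden(np.exp(scores * 3), labels)
        assert a.auc == pytest.approx(b.auc)

    def test_youden_tie_takes_lowest_cutoff(self):
        # two thresholds reach J = 0.5; the lower one must be reported
        scores = [1, 2, 3, 4]
        labels = [0, 1, 0, 1]
        res = vs.roc_youden(scores, labels)
        ties = []
        pos = np.array([2.0, 4.0])
        neg = np.array([1.0, 3.0])
        for c in sorted(set(scores)):
            j = (pos >= c).mean() + (neg < c).mean() - 1
            ties.append((j, c))
        best_j = max(j for j, _ in ties)
        lowest = min(c for j, c in ties if j == best_j)
        assert res.cutoff == lowest

    def test_delong_ci_contains_auc(self):
        rng = np.random.default_rng(5)
        scores = np.concatenate([rng.normal(1, 1, 30), rng.normal(0, 1, 30)])
        labels = np.array([1] * 30 + [0] * 30)
        res = vs.roc_youden(scores, labels)
        assert res.ci_low <= res.auc <= res.ci_high
        assert 0.0 <= res.ci_low and res.ci_high <= 1.0


class TestCombinedPredictor:
    def test_identical_predictors_equal_single_auc(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(1, 1, 30), rng.normal(0, 1, 30)])
        labels = np.array([1] * 30 + [0] * 30)
        single = vs.roc_youden(x, labels)
        combined = vs.combined_predictor(x, x, labels)
        assert combined.auc == pytest.approx(single.auc, abs=1e-9)

    def test_in_sample_dominance(self):
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            labels = np.array([1] * 30 + [0] * 30)
            expr = labels + rng.normal(0, 1.2, 60)
            meth = labels + rng.normal(0, 1.5, 60)
            best_single = max(
                vs.roc_youden(expr, labels).auc, vs.roc_youden(meth, labels).auc
            )
            combined = vs.combined_predictor(expr, meth, labels)
            assert combined.auc >= best_single - 0.01

    def test_uninformative_methylation_tracks_expression(self):
        rng = np.random.default_rng(7)
        labels = np.array([1] * 30 + [0] * 30)
        expr = labels * 2 + rng.normal(0, 1, 60)
        meth = rng.normal(0, 1, 60)
        combined = vs.combined_predictor(expr, meth, labels)
        single = vs.roc_youden(expr, labels)
        assert abs(combined.auc - single.auc) < 0.02
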