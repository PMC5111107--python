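import numpy as np
import pandas as pd
import pytest

from crcbench.rules import (apply_rule_classifier, calls_to_series,
                            classify_by_cutoff, classify_by_group_means,
                            classify_by_tally, delta_ct_transform,
                            score_linear, score_product_ratio,
                            score_signature_mean)
from crcbench.signatures import RuleSpec, Signature, SignatureGene
from conftest import make_matrix


def _cchs_matrix(values_by_gene, samples=("s1",)):
    genes = ["BCCIP", "BNIP3L", "GADD45B", "INSIG2", "TP53"]
    data = [[values_by_gene.get(g, 0.0)] * len(samples) for g in genes]
    return make_matrix(data, genes=genes, samples=list(samples))


class TestDeltaCt:
    def test_gene_at_housekeeping_mean_maps_to_constant(self):
        # all genes at the same level: log terms cancel, value = -15
        m = make_matrix([[5.0], [5.0], [5.0]], genes=["HK1", "HK2", "GX"])
        out = delta_ct_transform(m, ["HK1", "HK2"])
        assert out.values.loc["GX", "s0"] == pytest.approx(-15.0)

    def test_gene_at_twice_housekeeping_mean(self):
        # log2(2m) - log2(m) = 1 so the value is -15 + 1 = -14
        m = make_matrix([[5.0], [5.0], [6.0]], genes=["HK1", "HK2", "GX"])
        out = delta_ct_transform(m, ["HK1", "HK2"])
        assert out.values.loc["GX", "s0"] == pytest.approx(-14.0)

    def test_arithmetic_mean_on_linear_scale(self):
        # housekeeping 4 and 16 on log2 scale 2 and 4: linear mean 10
        m = make_matrix([[2.0], [4.0], [np.log2(10.0)]],
                        genes=["HK1", "HK2", "GX"])
        out = delta_ct_transform(m, ["HK1", "HK2"], mean_mode="arithmetic")
        assert out.values.loc["GX", "s0"] == pytest.approx(-15.0)

    def test_missing_housekeeping_gene_errors(self, toy_matrix):
        with pytest.raises(KeyError, match="housekeeping"):
            delta_ct_transform(toy_matrix, ["ACTB"])

    def test_v7rhs_housekeeping_defaults(self):
        from crcbench.signatures import builtin_rule_defaults

        hk = builtin_rule_defaults()["V7RHS"]["housekeeping"]
        assert hk == ["ACTB", "HMBS", "RPL13A"]


class TestScoreLinear:
    def test_cchs_intercept_only(self, builtin_sigs):
        scores = score_linear(_cchs_matrix({}), builtin_sigs["CCHS"])
        assert scores["s1"] == pytest.approx(1.301)

    def test_cchs_single_gene_contribution(self, builtin_sigs):
        scores = score_linear(_cchs_matrix({"BCCIP": 10.0}),
                              builtin_sigs["CCHS"])
        assert scores["s1"] == pytest.approx(6.731)

    def test_uniform_weight_mean(self, builtin_sigs):
        m = make_matrix([[2.0], [4.0], [6.0]], genes=["TAZ", "AXL", "CTGF"])
        assert score_signature_mean(m, builtin_sigs["Yuen3"])["s0"] == 4.0

    def test_affine_in_weights(self, builtin_sigs):
        sig = builtin_sigs["CCHS"]
        doubled = Signature(
            "CCHS2x",
            [SignatureGene(g.symbol, g.direction, 2 * g.weight)
             for g in sig.genes],
            RuleSpec("linear_cutoff", dict(sig.rule.params)),
            sig.labels)
        m = _cchs_matrix({"BCCIP": 3.0, "TP53": 1.5})
        base = score_linear(m, sig)["s1"] - 1.301
        twice = score_linear(m, doubled)["s1"] - 1.301
        assert twice == pytest.approx(2 * base)


class TestScoreProductRatio:
    def _matrix(self, bmi1, vegfa, h3f3b, etv6, rps10):
        genes = ["BMI1", "VEGFA", "H3F3B", "ETV6", "RPS10",
                 "B2M", "GUSB", "POLR2L", "PSMB6", "UBC"]
        vals = [[v] for v in (bmi1, vegfa, h3f3b, etv6, rps10, 0, 0, 0, 0, 0)]
        return make_matrix(vals, genes=genes)

    def test_hand_evaluation(self, builtin_sigs):
        # |2*3/1| - |1*1/1| = 5 (housekeeping all zero so adjusted = raw)
        s = score_product_ratio(self._matrix(2, 3, 1, 1, 1),
                                builtin_sigs["Oncodefender"])
        assert s["s0"] == pytest.approx(5.0)

    def test_symmetric_all_ones(self, builtin_sigs):
        s = score_product_ratio(self._matrix(1, 1, 1, 1, 1),
                                builtin_sigs["Oncodefender"])
        assert s["s0"] == pytest.approx(0.0)

    def test_zero_denominator_gives_na(self, builtin_sigs, caplog):
        with caplog.at_level("WARNING"):
            s = score_product_ratio(self._matrix(2, 3, 0, 1, 1),
                                    builtin_sigs["Oncodefender"])
        assert np.isnan(s["s0"])
        assert "zero denominator" in caplog.text


class TestClassifyByCutoff:
    @staticmethod
    def _odx_rule():
        return RuleSpec("linear_cutoff", {
            "cutoff_mode": "fixed", "cutoffs": [30, 40],
            "labels": ["low", "intermediate", "high"]})

    @staticmethod
    def _odx_sig(rule):
        return Signature("ODXcolon", [SignatureGene("g", weight=1.0)], rule,
                         [("low", "good"), ("intermediate", "intermediate"),
                          ("high", "bad")])

    def test_odx_three_bands(self):
        rule = self._odx_rule()
        sig = self._odx_sig(rule)
        scores = pd.Series({"a": 29.9, "b": 35.0, "c": 45.0})
        calls = calls_to_series(classify_by_cutoff(scores, rule, sig))
        assert list(calls[["a", "b", "c"]]) == ["low", "intermediate", "high"]

    def test_odx_boundaries_go_intermediate(self):
        rule = self._odx_rule()
        sig = self._odx_sig(rule)
        scores = pd.Series({"x": 30.0, "y": 40.0, "z": 40.0001})
        calls = calls_to_series(classify_by_cutoff(scores, rule, sig))
        assert list(calls[["x", "y", "z"]]) == ["intermediate",
                                                "intermediate", "high"]

    def test_median_tie_goes_to_lower_group(self):
        rule = RuleSpec("linear_cutoff", {"cutoff_mode": "cohort_median",
                                          "labels": ["low", "high"]})
        sig = Signature("t", [SignatureGene("g", weight=1.0)], rule,
                        [("low", "good"), ("high", "bad")])
        scores = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        calls = calls_to_series(classify_by_cutoff(scores, rule, sig))
        assert calls["b"] == "low"  # exactly at the median

    def test_tertiles_split_nine_distinct_evenly(self):
        # empirical-quantile oracle: scores 1..9 split 3/3/3
        rule = RuleSpec("linear_cutoff", {
            "cutoff_mode": "tertile", "labels": ["low", "mid", "high"]})
        sig = Signature("t", [SignatureGene("g", weight=1.0)], rule,
                        [("low", "good"), ("mid", "intermediate"),
                         ("high", "bad")])
        scores = pd.Series(np.arange(1.0, 10.0),
                           index=[f"s{i}" for i in range(9)])
        calls = calls_to_series(classify_by_cutoff(scores, rule, sig))
        assert calls.value_counts().to_dict() == {"low": 3, "mid": 3,
                                                  "high": 3}

    def test_degenerate_cohort_all_na(self):
        rule = RuleSpec("linear_cutoff", {"cutoff_mode": "cohort_median",
                                          "labels": ["low", "high"]})
        sig = Signature("t", [SignatureGene("g", weight=1.0)], rule,
                        [("low", "good"), ("high", "bad")])
        scores = pd.Series({"a": 1.0, "b": 1.0})
        calls = calls_to_series(classify_by_cutoff(scores, rule, sig))
        assert calls.isna().all()


class TestClassifyByTally:
    def test_yuen3_all_above_median_is_worst(self, builtin_sigs):
        rng = np.random.default_rng(5)
        vals = rng.normal(7, 1, size=(3, 21))
        vals[:, 0] = 20.0  # s0 above every per-gene median
        m = make_matrix(vals, genes=["TAZ", "AXL", "CTGF"])
        calls = calls_to_series(classify_by_tally(m, builtin_sigs["Yuen3"]))
        assert calls["s0"] == "3"

    def test_yuen3_labels_partition_cohort(self, builtin_sigs):
        rng = np.random.default_rng(6)
        m = make_matrix(rng.normal(size=(3, 40)),
                        genes=["TAZ", "AXL", "CTGF"])
        calls = calls_to_series(classify_by_tally(m, builtin_sigs["Yuen3"]))
        assert calls.notna().all()
        assert calls.value_counts().sum() == 40
        assert set(calls.unique()) <= {"0", "1", "2", "3"}

    def test_cologuidepro_two_of_seven_is_good(self, builtin_sigs):
        sig = builtin_sigs["ColoGuidePro"]
        rng = np.random.default_rng(7)
        vals = rng.normal(7, 1, size=(7, 21))
        # sample s0: exactly 2 genes at risk levels (2 < 3 -> good)
        vals[0, 0] = 30.0    # DMBT1 up_is_risk, above median
        vals[1:4, 0] = -30.0  # remaining up genes safely below medians
        vals[4, 0] = -30.0   # CXCL9 down_is_risk, below median
        vals[5:7, 0] = 30.0  # remaining down genes safely above medians
        m = make_matrix(vals, genes=sig.gene_symbols)
        calls = calls_to_series(classify_by_tally(m, sig))
        assert calls["s0"] == "good"

    def test_cologuideex_all_thirteen_is_high(self):
        from crcbench.signatures import signature_from_dict

        sig = signature_from_dict({
            "extends": "ColoGuideEx",
            "genes": [{"symbol": f"g{i}", "direction": "up_is_risk"}
                      for i in range(13)]})
        rng = np.random.default_rng(8)
        vals = rng.normal(7, 1, size=(13, 30))
        vals[:, 0] = 50.0  # beyond the 80th percentile on every gene
        m = make_matrix(vals, genes=sig.gene_symbols)
        calls = calls_to_series(classify_by_tally(m, sig))
        assert calls["s0"] == "high"

    def test_constant_gene_never_scores_positive(self, builtin_sigs, caplog):
        vals = np.array([[7.0] * 10,
                         np.r_[np.full(5, 9.0), np.full(5, 5.0)],
                         np.r_[np.full(5, 9.0), np.full(5, 5.0)]])
        m = make_matrix(vals, genes=["TAZ", "AXL", "CTGF"])
        with caplog.at_level("WARNING"):
            calls = calls_to_series(classify_by_tally(m,
                                                      builtin_sigs["Yuen3"]))
        assert "constant gene TAZ" in caplog.text
        assert set(calls.unique()) <= {"0", "2"}

    def test_shift_invariance_of_cohort_relative_rule(self, builtin_sigs):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=(3, 30))
        m1 = make_matrix(vals, genes=["TAZ", "AXL", "CTGF"])
        shifted = vals.copy()
        shifted[1, :] += 100.0  # constant added to every sample of one gene
        m2 = make_matrix(shifted, genes=["TAZ", "AXL", "CTGF"])
        c1 = calls_to_series(classify_by_tally(m1, builtin_sigs["Yuen3"]))
        c2 = calls_to_series(classify_by_tally(m2, builtin_sigs["Yuen3"]))
        pd.testing.assert_series_equal(c1, c2)


class TestGroupMeans:
    def _sig(self):
        genes = [SignatureGene(g) for g in ("a", "b", "c", "d")]
        rule = RuleSpec("group_mean_compare", {
            "g1": ["a", "b"], "g2": ["c", "d"],
            "label_g1_less": "BRAF-mutant-like",
            "label_otherwise": "wild-type-like"})
        return Signature("Popovici", genes, rule,
                         [("BRAF-mutant-like", "bad"),
                          ("wild-type-like", "good")])

    @pytest.mark.parametrize("g1, g2, expected", [
        (1.0, 2.0, "BRAF-mutant-like"),
        (2.0, 1.0, "wild-type-like"),
        (1.5, 1.5, "wild-type-like"),  # tie goes to wild-type-like
    ])
    def test_rule(self, g1, g2, expected):
        m = make_matrix([[g1], [g1], [g2], [g2]], genes=list("abcd"))
        calls = classify_by_group_means(m, self._sig())
        assert calls[0].label == expected


class TestDispatcherDeterminism:
    def test_same_input_same_calls(self, builtin_sigs):
        rng = np.random.default_rng(10)
        genes = sorted({g for s in builtin_sigs.values()
                        for g in s.gene_symbols + s.housekeeping})
        m = make_matrix(rng.normal(7, 1, size=(len(genes), 25)), genes=genes)
        for sig in builtin_sigs.values():
            a = calls_to_series(apply_rule_classifier(m, sig))
            b = calls_to_series(apply_rule_classifier(m, sig))
            pd.testing.assert_series_equal(a, b)


class TestDualMedian:
    def test_high_only_when_both_submodels_high(self):
        from crcbench.signatures import signature_from_dict

        sig = signature_from_dict({
            "extends": "Schetter",
            "name": "Schetter",
            "genes": [{"symbol": "m1"}, {"symbol": "m2"}],
            "rule": {"kind": "dual_median", "params": {
                "model_a": {"m1": 1.0}, "model_b": {"m2": 1.0},
                "label_both_high": "high", "label_else": "low",
                "labels": ["low", "high"]}},
        })
        vals = np.array([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]])
        m = make_matrix(vals, genes=["m1", "m2"])
        calls = calls_to_series(apply_rule_classifier(m, sig))
        # medians are 2.5 for both; no sample is above both simultaneously
        assert (calls == "low").all()
        vals2 = np.array([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]])
        m2 = make_matrix(vals2, genes=["m1", "m2"])
        calls2 = calls_to_series(apply_rule_classifier(m2, sig))
        assert list(calls2) == ["low", "low", "high", "high"]
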