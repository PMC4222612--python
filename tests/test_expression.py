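import numpy as np
import pandas as pd
import pytest

from rbpscreen import expression, simulate
from rbpscreen.expression import DECall, concordance_classify, sam_one_class, screen_summary
from rbpscreen.registry import FeatureAnnotation


def _table_from_matrix(M):
    tab = pd.DataFrame({"feature_id": [f"g{i:03d}" for i in range(M.shape[0])]})
    for j in range(M.shape[1]):
        tab[f"M{j+1}"] = M[:, j]
    return tab


class TestLoessNormalize:
    def test_sine_dye_bias_removed(self):
        spec = simulate.RegulonSpec("s", frozenset(), n_replicates=3)
        table, _ = simulate.gen_expression(
            spec, n_genes=2000, noise_sd=0.2, dye_bias=lambda A: 0.5 * np.sin(A), seed=5
        )
        # span must be small relative to the bias wavelength (~2pi over an
        # 8-unit A range); the 0.4 default is tuned for smoother real bias
        norm = expression.loess_normalize(table, span=0.2)
        for mc, ac in zip(expression.m_columns(norm), expression.a_columns(norm)):
            deciles = pd.qcut(norm[ac], 10, labels=False)
            assert norm.groupby(deciles)[mc].median().abs().max() < 0.05

    def test_null_data_nearly_unchanged(self, null_expression):
        norm = expression.loess_normalize(null_expression)
        for mc in expression.m_columns(null_expression):
            assert (norm[mc] - null_expression[mc]).abs().max() < 0.05

    def test_constant_intensity_rejected(self, null_expression):
        table = null_expression.copy()
        table["A1"] = 8.0
        with pytest.raises(ValueError, match="constant"):
            expression.loess_normalize(table)

    def test_too_few_features_rejected(self, null_expression):
        with pytest.raises(ValueError, match=">=50"):
            expression.loess_normalize(null_expression.head(10))


class TestMedianCenter:
    def test_shift_is_removed_exactly(self, null_expression):
        shifted = null_expression.copy()
        shifted["M1"] = shifted["M1"] + 3.7
        centred = expression.median_center(shifted)
        base = expression.median_center(null_expression)
        pd.testing.assert_series_equal(centred["M1"], base["M1"])

    def test_output_median_is_zero(self, null_expression):
        centred = expression.median_center(null_expression)
        for mc in expression.m_columns(centred):
            assert centred[mc].median() == pytest.approx(0.0, abs=1e-12)

    def test_idempotent_after_loess(self, null_expression):
        once = expression.median_center(expression.loess_normalize(null_expression))
        twice = expression.median_center(once)
        for mc in expression.m_columns(once):
            assert np.allclose(once[mc], twice[mc], atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            expression.median_center(pd.DataFrame({"feature_id": [], "M1": []}))


class TestSamOneClass:
    def test_all_zero_ratios_give_zero_d_and_no_calls(self):
        tab = _table_from_matrix(np.zeros((100, 3)))
        res = sam_one_class(tab, delta=0.5, seed=0)
        assert (res.d == 0).all()
        assert res.calls == []

    def test_d_statistic_matches_brute_force(self):
        rng = np.random.default_rng(3)
        M = rng.normal(0, 1, (10, 3))
        res = sam_one_class(_table_from_matrix(M), delta=0.1, seed=0)
        # independent re-implementation of d = mean / (se + s0)
        expected = M.mean(axis=1) / (M.std(axis=1, ddof=1) / np.sqrt(3) + res.s0)
        assert np.allclose(res.d.to_numpy(), expected)

    def test_d_antisymmetric_under_global_sign_flip(self):
        rng = np.random.default_rng(4)
        M = rng.normal(0, 1, (200, 3))
        d_pos = sam_one_class(_table_from_matrix(M), delta=0.1, seed=0).d
        d_neg = sam_one_class(_table_from_matrix(-M), delta=0.1, seed=0).d
        assert np.allclose(d_pos.to_numpy(), -d_neg.to_numpy())

    def test_spike_in_recovery(self, spike_in_expression):
        table, truth = spike_in_expression
        res = sam_one_class(table, target_fdr=0.05, seed=101)
        called = res.called_ids()
        true = set(truth.loc[truth["is_target"], "feature_id"])
        assert len(called & true) >= 45
        assert len(called - true) <= 5
        assert all(c.direction == "up" for c in res.calls if c.feature_id in true)

    def test_q_values_lie_in_unit_interval(self, spike_in_expression):
        table, _ = spike_in_expression
        res = sam_one_class(table, target_fdr=0.05, seed=101)
        assert ((res.q_values >= 0) & (res.q_values <= 1)).all()
        assert all(c.q_value <= 0.05 + 1e-9 for c in res.calls)

    def test_two_replicates_enumerate_all_sign_flips(self):
        rng = np.random.default_rng(5)
        M = rng.normal(0, 1, (50, 2))
        res = sam_one_class(_table_from_matrix(M), target_fdr=0.05, seed=0)
        assert res.n_permutations == 3  # 2^2 states minus the identity

    def test_parameter_validation(self):
        tab = _table_from_matrix(np.zeros((10, 3)))
        with pytest.raises(ValueError, match="exactly one"):
            sam_one_class(tab, delta=1.0, target_fdr=0.05)
        with pytest.raises(ValueError, match="exactly one"):
            sam_one_class(tab)
        with pytest.raises(ValueError, match=">=2 replicates"):
            sam_one_class(_table_from_matrix(np.zeros((10, 1))), delta=1.0)


class TestConcordanceClassify:
    features = [
        FeatureAnnotation("gA_ex", "gA", "exon"),
        FeatureAnnotation("gA_in", "gA", "intron"),
        FeatureAnnotation("gB_ex", "gB", "exon"),
        FeatureAnnotation("gB_in", "gB", "intron"),
        FeatureAnnotation("gC_ex", "gC", "exon"),
    ]

    @staticmethod
    def _up(fid):
        return DECall(fid, 5.0, 0.01, "up", 4.0)

    def test_intron_only_up_is_pre_mrna_accumulation(self):
        calls = [self._up("gA_in")]
        assert concordance_classify(calls, self.features)["gA"] == "pre_mrna_accumulation"

    def test_intron_and_exon_up_is_transcript_increase(self):
        calls = [self._up("gA_in"), self._up("gA_ex")]
        assert concordance_classify(calls, self.features)["gA"] == "transcript_increase"

    def test_gene_without_introns_cannot_accumulate_pre_mrna(self):
        calls = [self._up("gC_ex")]
        out = concordance_classify(calls, self.features)
        assert out["gC"] == "exon_only"
        assert out["gB"] == "none"

    def test_down_calls_do_not_trigger_up_rules(self):
        calls = [DECall("gA_in", -5.0, 0.01, "down", 0.25)]
        assert concordance_classify(calls, self.features)["gA"] == "none"


class TestScreenSummary:
    @staticmethod
    def _call(gene, direction):
        return DECall(gene, 5.0 if direction == "up" else -5.0, 0.01, direction, 2.0)

    def test_disjoint_up_sets(self):
        calls = {
            "s1": [self._call(f"g{i}", "up") for i in range(10)],
            "s2": [self._call(f"g{i}", "up") for i in range(10, 20)],
        }
        out = screen_summary(calls, total_coding=100)
        assert out["union_size"] == 20
        assert out["up_only"] == 20
        assert out["both"] == 0
        assert out["pct_of_coding"] == 20.0

    def test_gene_up_in_one_strain_down_in_another_counts_as_both(self):
        calls = {"s1": [self._call("g1", "up")], "s2": [self._call("g1", "down")]}
        out = screen_summary(calls, total_coding=100)
        assert out["both"] == 1
        assert out["union_size"] == 1

    def test_partition_conserved(self):
        rng = np.random.default_rng(8)
        calls = {
            f"s{j}": [
                self._call(f"g{rng.integers(30)}", rng.choice(["up", "down"]))
                for _ in range(10)
            ]
            for j in range(5)
        }
        out = screen_summary(calls, total_coding=100)
        assert out["up_only"] + out["down_only"] + out["both"] == out["union_size"]
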