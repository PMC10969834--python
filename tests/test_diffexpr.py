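"""Differential expression: SVA behavior, t-test equivalence, BH, filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import circlex as cx
from circlex.containers import ConfigError
from tests.conftest import make_expr


def _two_group_design(n):
    g = np.zeros(n)
    g[n // 2 :] = 1
    return np.column_stack([np.ones(n), g]), g


class TestSurrogateVariables:
    def test_pure_noise_mostly_zero_svs(self):
        """Parallel analysis keeps no component on structureless noise."""
        zero = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            Y = rng.normal(size=(800, 16))
            X, _ = _two_group_design(16)
            svs = cx.estimate_surrogate_variables(Y, X, seed=seed + 1000)
            zero += svs.n_sv == 0
        assert zero >= 18  # >= 90% of seeds

    def test_planted_batch_recovered(self):
        """A batch hitting 30% of genes at 1 sd appears as SV1 (|r| >= 0.9)."""
        rng = np.random.default_rng(0)
        n = 20
        batch = np.tile([0.0, 1.0], n // 2)  # orthogonal to the group split
        X, _ = _two_group_design(n)
        Y = rng.normal(size=(2000, n))
        affected = rng.random(2000) < 0.3
        coef = rng.normal(0, 1.0, size=2000) * affected
        Y += coef[:, None] * batch[None, :]
        svs = cx.estimate_surrogate_variables(Y, X, seed=77)
        assert svs.n_sv >= 1
        r = np.corrcoef(svs.sv[:, 0], batch)[0, 1]
        assert abs(r) >= 0.9

    def test_unit_norm_columns(self, nsc, de_result):
        svs, _ = de_result
        if svs.n_sv:
            norms = np.linalg.norm(svs.sv, axis=0)
            assert np.allclose(norms, 1.0)

    def test_preconditions(self):
        Y = np.random.default_rng(1).normal(size=(50, 10))
        X, _ = _two_group_design(10)
        with pytest.raises(ConfigError):
            cx.estimate_surrogate_variables(Y, X, n_permutations=0)
        with pytest.raises(ConfigError):
            cx.estimate_surrogate_variables(Y, np.ones((10, 2)))  # rank deficient
        with pytest.raises(ConfigError):
            cx.estimate_surrogate_variables(Y[:, :3], np.eye(3)[:, :2] @ np.eye(2))


class TestDifferentialExpression:
    def test_constant_gene_flagged_p_one(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(5, 8))
        vals[0] = 3.14
        expr = make_expr(vals)
        de = cx.test_differential_expression(expr, expr.metadata["origin"])
        assert de.iloc[0]["t"] == 0.0 and de.iloc[0]["p_value"] == 1.0
        assert de.iloc[0]["zero_variance"]

    def test_matches_two_sample_t_test_without_svs(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(300, 12))
        expr = make_expr(vals)
        de = cx.test_differential_expression(expr, expr.metadata["origin"])
        t_ref, p_ref = stats.ttest_ind(vals[:, 6:], vals[:, :6], axis=1, equal_var=True)
        assert np.abs(de["p_value"].to_numpy() - p_ref).max() < 1e-10
        assert np.abs(de["t"].to_numpy() - t_ref).max() < 1e-8

    def test_planted_x_genes_recovered(self, de_result, expression):
        _, de = de_result
        _, truth = expression
        sig, _ = cx.filter_significant(de, alpha=0.01)
        sens = np.mean([g in set(sig) for g in truth.affected_genes])
        assert sens >= 0.8

    def test_type_one_error_calibrated(self):
        cfg = cx.SyntheticConfig(
            effect_x_log2=0, batch_sd=0, background_sd=0, lineage_sd=0, seed=21
        )
        ann = cx.generate_annotation(cfg)
        expr, _ = cx.generate_expression(cfg, ann)
        nsc = expr.subset_samples(expr.metadata.index[expr.metadata["lineage"] == "NSC"])
        de = cx.test_differential_expression(nsc, nsc.metadata["origin"])
        rate = (de["p_value"] < 0.05).mean()
        assert 0.04 <= rate <= 0.06


class TestBenjaminiHochberg:
    def test_forced_example(self):
        assert np.allclose(cx.benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert np.allclose(cx.benjamini_hochberg(np.ones(5)), 1.0)

    def test_matches_step_up_oracle(self):
        rng = np.random.default_rng(8)
        p = rng.random(1000)
        adj = cx.benjamini_hochberg(p)
        # independent step-up oracle straight from the definition
        m = len(p)
        order = np.argsort(p)
        expected = np.empty(m)
        for rank_pos, idx in enumerate(order):
            candidates = [p[order[j]] * m / (j + 1) for j in range(rank_pos, m)]
            expected[idx] = min(1.0, min(candidates))
        assert np.abs(adj - expected).max() < 1e-12

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_permutation_invariant_and_bounded(self, p):
        p = np.asarray(p)
        adj = cx.benjamini_hochberg(p)
        assert ((adj >= p - 1e-15) & (adj <= 1.0)).all()
        perm = np.random.default_rng(0).permutation(len(p))
        adj_perm = cx.benjamini_hochberg(p[perm])
        assert np.allclose(adj_perm[np.argsort(perm)], adj)

    def test_rejects_out_of_range(self):
        with pytest.raises(ConfigError):
            cx.benjamini_hochberg([0.5, 1.2])


class TestFilterSignificant:
    @pytest.mark.parametrize(
        "adj_p,lfc,in_sig,in_fold",
        [(0.005, 1.32, True, True), (0.005, 0.5, True, False), (0.02, 3.0, False, False)],
    )
    def test_threshold_application(self, adj_p, lfc, in_sig, in_fold):
        de = pd.DataFrame(
            {"adjusted_p": [adj_p], "log2_fold_change": [lfc]}, index=["g"]
        )
        sig, fold = cx.filter_significant(de, alpha=0.01, fold_change=2.0)
        assert ("g" in sig) == in_sig
        assert ("g" in fold) == in_fold

    def test_fold_set_nested_in_significant(self, de_result):
        _, de = de_result
        sig, fold = cx.filter_significant(de)
        assert set(fold) <= set(sig)


class TestPairwise:
    def test_identical_sides_yield_no_calls(self, annotation):
        rng = np.random.default_rng(4)
        gx = annotation.genes
        vals = rng.normal(size=(len(gx), 4))
        vals = np.hstack([vals, vals])  # replicate the same four samples
        expr = make_expr(vals)
        expr.values.index = gx.index
        pairs = [("self", ["s0", "s1", "s2", "s3"], ["s4", "s5", "s6", "s7"])]
        res = cx.pairwise_compare(expr, pairs, gx)
        assert res[0].counts["n_significant"] == 0
        assert res[0].x_enrichment_p == 1.0

    def test_strong_planted_pair_detects_x_enrichment(self, annotation):
        """A constructed pair with a 3-log2 X shift is X-enriched below 1e-5."""
        rng = np.random.default_rng(11)
        genes = annotation.genes
        vals = rng.normal(7, 0.1, size=(len(genes), 6))
        affected = genes.index.isin(annotation.truth.affected_genes)
        vals[affected, 3:] += 3.0
        expr = make_expr(vals)
        expr.values.index = genes.index
        res = cx.pairwise_compare(expr, [("p", ["s3", "s4", "s5"], ["s0", "s1", "s2"])], genes)
        assert res[0].x_enrichment_p < 1e-5

    def test_single_sample_side_rejected(self, nsc, annotation):
        ids = list(nsc.sample_ids)
        with pytest.raises(ConfigError):
            cx.pairwise_compare(nsc, [("bad", ids[:1], ids[1:3])], annotation.genes)


class TestGroupSimilarity:
    def test_identity_and_shift_invariance(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(50, 6))
        vals[:, 3:] = vals[:, :3] + 2.0  # constant shift
        expr = make_expr(vals)
        same = cx.group_similarity(expr, ["s0", "s1", "s2"], ["s0", "s1", "s2"])
        shifted = cx.group_similarity(expr, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert same == pytest.approx(1.0)
        assert shifted == pytest.approx(1.0)

    def test_x_similarity_below_autosomal(self, nsc, annotation):
        meta = nsc.metadata
        esc = meta.index[meta["origin"] == "ESC-NSC"]
        ipsc = meta.index[meta["origin"] == "iPSC-NSC"]
        r_auto = cx.group_similarity(nsc, esc, ipsc, annotation.genes, "autosomal")
        r_x = cx.group_similarity(nsc, esc, ipsc, annotation.genes, "chrX")
        assert r_x < r_auto
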