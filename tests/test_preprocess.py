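"""Differential expression: quantile normalization, Welch t, BH, filtering."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from cernet import preprocess, simulate
from cernet.preprocess import (ExpressionMatrix, bh_adjust, collapse_duplicates,
                               filter_de, quantile_normalize, welch_t)
from oracles import brute_bh


def em_from(values, groups=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    cols = [f"s{j}" for j in range(n)]
    if groups is None:  # first half case, second half control
        groups = {c: ("case" if j < n // 2 else "control")
                  for j, c in enumerate(cols)}
    else:
        groups = dict(zip(cols, groups))
    df = pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])],
                      columns=cols)
    return ExpressionMatrix(values=df, groups=groups)


class TestQuantileNormalize:
    def test_worked_example_monotone_columns(self):
        em = em_from(np.column_stack([[2, 4, 6], [6, 8, 10]]))
        out = quantile_normalize(em).values.to_numpy()
        np.testing.assert_array_equal(out[:, 0], [4, 6, 8])
        np.testing.assert_array_equal(out[:, 1], [4, 6, 8])

    def test_worked_example_permuted_column(self):
        em = em_from(np.column_stack([[2, 4, 6], [10, 6, 8]]))
        out = quantile_normalize(em).values.to_numpy()
        np.testing.assert_array_equal(out[:, 0], [4, 6, 8])
        np.testing.assert_array_equal(out[:, 1], [8, 4, 6])

    def test_identical_columns_are_a_fixed_point(self):
        col = np.array([1.5, -2.0, 7.0, 3.0])
        em = em_from(np.column_stack([col, col, col]))
        out = quantile_normalize(em).values.to_numpy()
        for j in range(3):
            np.testing.assert_array_equal(out[:, j], col)

    def test_ties_get_mean_of_reference_positions(self):
        # column 2 has a tie spanning reference positions 1 and 2
        em = em_from(np.column_stack([[1.0, 2.0, 3.0], [5.0, 5.0, 9.0]]))
        out = quantile_normalize(em).values.to_numpy()
        ref = np.sort(em.values.to_numpy(), axis=0).mean(axis=1)
        np.testing.assert_array_equal(out[:, 0], ref)
        assert out[0, 1] == out[1, 1] == pytest.approx(ref[:2].mean())
        assert out[2, 1] == ref[2]

    @given(st.integers(2, 30), st.integers(2, 6), st.integers(0, 2**31 - 1))
    def test_columns_share_one_multiset_and_ranks_survive(self, n, p, seed):
        rng = np.random.default_rng(seed)
        # continuous draws: tie-free, so all columns must carry the exact
        # reference multiset
        vals = rng.normal(size=(n, p))
        out = quantile_normalize(em_from(vals)).values.to_numpy()
        sorted_cols = np.sort(out, axis=0)
        for j in range(1, p):
            np.testing.assert_array_equal(sorted_cols[:, j], sorted_cols[:, 0])
        # rounding forces ties: order relations (incl. equality) must survive
        tied = np.round(vals, 1)
        out_t = quantile_normalize(em_from(tied)).values.to_numpy()
        for j in range(p):
            a, b = tied[:, j], out_t[:, j]
            for i in range(n - 1):
                if a[i] < a[i + 1]:
                    assert b[i] <= b[i + 1]
                elif a[i] > a[i + 1]:
                    assert b[i] >= b[i + 1]
                else:
                    assert b[i] == b[i + 1]

    def test_nonfinite_input_identifies_cells(self):
        vals = np.ones((3, 2))
        vals[1, 1] = np.nan
        df = pd.DataFrame(vals, index=list("abc"), columns=["s0", "s1"])
        with pytest.raises(ValueError, match=r"\(b, s1\)"):
            ExpressionMatrix(values=df, groups={"s0": "case", "s1": "control"})


class TestWelchT:
    def test_equal_groups_have_zero_fold_change(self):
        block = np.array([[1.0, 2.0, 3.0], [4.0, 4.5, 5.0]])
        em = em_from(np.hstack([block, block]))
        out = welch_t(em)
        np.testing.assert_array_equal(out["log2fc"].to_numpy(), [0.0, 0.0])

    def test_textbook_example_matches_hand_computation(self):
        em = em_from(np.array([[5.0, 6.0, 7.0, 1.0, 2.0, 3.0]]),
                     groups=["case"] * 3 + ["control"] * 3)
        out = welch_t(em)
        assert out["log2fc"].iloc[0] == pytest.approx(4.0, abs=1e-12)
        # hand computation: t = 4 / sqrt(1/3 + 1/3), Welch-Satterthwaite df = 4
        t_stat = 4.0 / np.sqrt(2.0 / 3.0)
        assert t_stat == pytest.approx(4.89898, abs=1e-5)
        p_expected = 2 * stats.t.sf(t_stat, df=4)
        assert out["p"].iloc[0] == pytest.approx(p_expected, rel=1e-10)

    def test_degenerate_zero_variance_rules(self):
        vals = np.array([
            [1.0, 1.0, 1.0, 1.0],   # both constant, equal means -> p = 1
            [2.0, 2.0, 1.0, 1.0],   # both constant, unequal means -> p = 0
        ])
        out = welch_t(em_from(vals))
        assert out["p"].iloc[0] == 1.0 and out["log2fc"].iloc[0] == 0.0
        assert out["p"].iloc[1] == 0.0 and out["log2fc"].iloc[1] == 1.0

    def test_requires_two_samples_per_group(self):
        with pytest.raises(ValueError, match="2 samples per group"):
            welch_t(em_from(np.ones((2, 3)),
                            groups=["case", "control", "control"]))

    def test_type_one_error_calibrated_under_global_null(self):
        cfg = simulate.SimConfig(n_genes=6000, de_fraction=0.0,
                                 effect_size=0.0, noise_sd=0.7, seed=20)
        em, _ = simulate.generate_expression(cfg)
        p = welch_t(em)["p"].to_numpy()
        rate = (p < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / p.size)
        assert abs(rate - 0.05) <= 2 * se


class TestBHAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_trivial_cases(self):
        assert bh_adjust([0.37]) == pytest.approx([0.37])
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0, 1.0]), [1, 1, 1])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError, match="outside"):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=200))
    def test_matches_literal_stepup_definition(self, pvals):
        np.testing.assert_allclose(bh_adjust(pvals), brute_bh(pvals),
                                   rtol=1e-12, atol=1e-15)

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(size=500)
        np.testing.assert_allclose(bh_adjust(p),
                                   multipletests(p, method="fdr_bh")[1],
                                   rtol=1e-12)


class TestFilterAndPipelineStage:
    def test_empty_table(self):
        de = pd.DataFrame(columns=["log2fc", "p", "fdr"]).astype(float)
        res = filter_de(de, {})
        assert res.dels == () and res.degs == ()

    def test_single_gene_split_by_biotype(self):
        de = pd.DataFrame({"log2fc": [1.5], "p": [0.001], "fdr": [0.04]},
                          index=["gX"])
        dels, degs = filter_de(de, {"gX": "lncRNA"})
        assert dels == ["gX"] and degs == []

    def test_strict_thresholds(self):
        de = pd.DataFrame({"log2fc": [1.0, 1.01], "p": [0.01, 0.01],
                           "fdr": [0.05, 0.049]}, index=["a", "b"])
        res = filter_de(de, {"a": "lncRNA", "b": "protein_coding"})
        assert res.dels == () and res.degs == ("b",)

    def test_missing_biotype_dropped_or_raises(self):
        de = pd.DataFrame({"log2fc": [2.0], "p": [1e-5], "fdr": [1e-4]},
                          index=["orphan"])
        res = filter_de(de, {})
        assert res.dropped_missing == 1 and res.dels == () and res.degs == ()
        with pytest.raises(ValueError, match="orphan"):
            filter_de(de, {}, on_missing="error")

    def test_loosening_thresholds_is_monotone(self, rng):
        de = pd.DataFrame({
            "log2fc": rng.normal(scale=2, size=300),
            "p": rng.uniform(size=300),
        }, index=[f"g{i}" for i in range(300)])
        de["fdr"] = bh_adjust(de["p"].to_numpy())
        biotypes = {g: ("lncRNA" if i % 2 else "protein_coding")
                    for i, g in enumerate(de.index)}
        tight = filter_de(de, biotypes, fdr_max=0.05, lfc_min=1.5)
        loose = filter_de(de, biotypes, fdr_max=0.2, lfc_min=0.5)
        assert set(tight.dels) <= set(loose.dels)
        assert set(tight.degs) <= set(loose.degs)

    def test_duplicate_probe_collapse_keeps_highest_mean(self):
        df = pd.DataFrame([[1.0, 1.0], [5.0, 5.0], [2.0, 2.0]],
                          index=["gA", "gA", "gB"], columns=["s0", "s1"])
        out = collapse_duplicates(df)
        assert list(out.index) == ["gA", "gB"]
        assert out.loc["gA"].tolist() == [5.0, 5.0]

    def test_planted_de_recovery_end_to_end(self):
        cfg = simulate.SimConfig(n_genes=1000, de_fraction=0.1,
                                 effect_size=2.0, noise_sd=0.5,
                                 n_per_group=10, seed=42)
        em, truth = simulate.generate_expression(cfg)
        biotypes = {g: "protein_coding" for g in em.values.index}
        de = preprocess.de_table(em, biotypes=biotypes)
        res = filter_de(de, biotypes, fdr_max=0.05, lfc_min=1.0)
        called = set(res.degs)
        planted = set(truth.de_gene_ids)
        recall = len(called & planted) / len(planted)
        false_frac = len(called - planted) / max(len(called), 1)
        assert recall >= 0.90
        assert false_frac <= 0.10
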