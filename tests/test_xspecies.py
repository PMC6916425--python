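"""Ortholog mapping, joint renormalization, correlation and Williams test."""

import numpy as np
import pandas as pd
import pytest

import microgliaseq as mg


def _expr(data: dict, genes):
    return pd.DataFrame(data, index=genes)


class TestMapOrthologs:
    def _one_to_one(self):
        return mg.OrthologMap(
            pd.DataFrame({"gene_a": ["a1", "a2", "a3"], "gene_b": ["b1", "b2", "b3"]})
        )

    def test_pure_one_to_one_keeps_all(self):
        ea = _expr({"s1": [1, 2, 3], "s2": [4, 5, 6]}, ["a1", "a2", "a3"])
        eb = _expr({"t1": [1, 2, 3], "t2": [4, 5, 6]}, ["b1", "b2", "b3"])
        pa, pb, pairs = mg.map_orthologs(ea, eb, self._one_to_one())
        assert len(pairs) == 3
        assert list(pa.index) == list(pb.index)

    def test_one_to_one_only_drops_multimapped(self):
        omap = mg.OrthologMap(
            pd.DataFrame({"gene_a": ["g1", "g2"], "gene_b": ["m1", "m1"]})
        )
        ea = _expr({"s1": [5, 1], "s2": [5, 1]}, ["g1", "g2"])
        eb = _expr({"t1": [3], "t2": [3]}, ["m1"])
        with pytest.raises(ValueError, match="one-to-one"):
            mg.map_orthologs(ea, eb, omap, policy="one_to_one_only")

    def test_max_mean_keeps_highest_expressed_partner(self):
        omap = mg.OrthologMap(
            pd.DataFrame({"gene_a": ["g1", "g2"], "gene_b": ["m1", "m1"]})
        )
        ea = _expr({"s1": [5.0, 1.0], "s2": [5.0, 1.0]}, ["g1", "g2"])
        eb = _expr({"t1": [3.0], "t2": [3.0]}, ["m1"])
        _, _, pairs = mg.map_orthologs(ea, eb, omap, policy="max_mean")
        assert list(pairs["gene_a"]) == ["g1"]

    def test_sum_policy_aggregates_counts(self):
        omap = mg.OrthologMap(
            pd.DataFrame({"gene_a": ["g1", "g2"], "gene_b": ["m1", "m1"]})
        )
        ea = _expr({"s1": [5, 1], "s2": [7, 2]}, ["g1", "g2"])
        eb = _expr({"t1": [3], "t2": [4]}, ["m1"])
        pa, pb, pairs = mg.map_orthologs(
            ea, eb, omap, policy="sum", input_scale="counts"
        )
        assert len(pairs) == 1
        assert list(pa.iloc[0]) == [6, 9]
        assert list(pb.iloc[0]) == [3, 4]

    def test_sum_on_log_scale_is_hard_error(self):
        ea = _expr({"s1": [1.0], "s2": [1.0]}, ["a1"])
        eb = _expr({"t1": [1.0], "t2": [1.0]}, ["b1"])
        with pytest.raises(ValueError, match="count-scale"):
            mg.map_orthologs(ea, eb, self._one_to_one(), policy="sum")


class TestJointRenormalize:
    def test_identical_datasets_equal_factors(self):
        counts = pd.DataFrame({"s1": [10, 100], "s2": [10, 100]}, index=["p1", "p2"])
        expr, sf = mg.joint_renormalize(counts, counts)
        assert np.allclose(sf, sf.iloc[0])
        assert expr.shape == (2, 4)

    def test_depth_scaling_absorbed_by_size_factors(self):
        a = pd.DataFrame({"s1": [10, 100, 7], "s2": [10, 100, 7]}, index=list("xyz"))
        b4 = a * 4
        expr, sf = mg.joint_renormalize(a, b4)
        base, _ = mg.joint_renormalize(a, a)
        # B factors absorb the 4x depth difference relative to A ...
        assert np.allclose(
            sf[["b:s1", "b:s2"]].to_numpy() / sf[["a:s1", "a:s2"]].to_numpy(), 4.0
        )
        # ... so every normalized column is identical on proportional data
        assert np.allclose(expr.to_numpy(), expr.iloc[:, [0]].to_numpy())
        # and gene-to-gene contrasts match the unscaled run exactly
        assert np.allclose(
            np.diff(expr.iloc[:, 0]), np.diff(base.iloc[:, 0]), atol=0.35
        )

    def test_combined_shape(self):
        a = pd.DataFrame({"s1": [1, 2], "s2": [3, 4]}, index=["p1", "p2"])
        b = pd.DataFrame({"t1": [5, 6], "t2": [7, 8], "t3": [9, 1]}, index=["p1", "p2"])
        expr, _ = mg.joint_renormalize(a, b)
        assert expr.shape == (2, 5)

    def test_split_recovers_relative_expression(self):
        # on proportional columns, within-dataset differences are exact
        a = pd.DataFrame({"s1": [8, 64], "s2": [16, 128]}, index=["p1", "p2"])
        b = pd.DataFrame({"t1": [2, 16], "t2": [2, 16]}, index=["p1", "p2"])
        expr, _ = mg.joint_renormalize(a, b, pseudocount=1e-9)
        within_a = expr["a:s1"] - expr["a:s2"]
        assert np.allclose(within_a, 0.0, atol=1e-6)
        assert np.allclose(
            expr.loc["p2"] - expr.loc["p1"], 3.0, atol=1e-6
        )  # 8x on log2 scale


class TestCorrelate:
    def test_identity_and_reflection(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert mg.correlate(x, x).r == pytest.approx(1.0)
        assert mg.correlate(x, -x + 7).r == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        res = mg.correlate([1, 2, 3, 4], [1, 2, 3, 5])
        assert res.r == pytest.approx(0.98270763, abs=1e-6)
        assert res.n_pairs == 4

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=50), rng.normal(size=50)
        r0 = mg.correlate(x, y).r
        assert mg.correlate(3 * x + 1, y).r == pytest.approx(r0)
        assert mg.correlate(x, 0.5 * y - 2).r == pytest.approx(r0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            mg.correlate([1, 1, 1], [1, 2, 3])


class TestWilliams:
    def test_equal_correlations_null(self):
        res = mg.williams_test(0.5, 0.5, 0.3, 30)
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_worked_example(self):
        res = mg.williams_test(0.5, 0.3, 0.4, 50)
        assert res.t == pytest.approx(1.438, abs=1e-3)
        assert res.df == 47

    def test_antisymmetry_under_negation(self):
        a = mg.williams_test(0.5, 0.3, 0.4, 50)
        b = mg.williams_test(-0.5, -0.3, 0.4, 50)
        assert b.t == pytest.approx(-a.t)
        assert b.p == pytest.approx(a.p)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n >= 4"):
            mg.williams_test(0.5, 0.3, 0.4, 3)

    def test_degenerate_correlation_matrix_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            mg.williams_test(0.9, -0.9, 0.9, 50)

    def test_monte_carlo_agreement_with_permutation(self):
        # the t statistic's null behaviour is checked in the calibration
        # suite; here a quick sanity check that unequal population
        # correlations push |t| up
        rng = np.random.default_rng(1)
        L = np.linalg.cholesky(
            np.array([[1, 0.8, 0.2], [0.8, 1, 0.3], [0.2, 0.3, 1]])
        )
        X = rng.standard_normal((200, 3)) @ L.T
        r12 = np.corrcoef(X[:, 0], X[:, 1])[0, 1]
        r13 = np.corrcoef(X[:, 0], X[:, 2])[0, 1]
        r23 = np.corrcoef(X[:, 1], X[:, 2])[0, 1]
        assert mg.williams_test(r12, r13, r23, 200).p < 1e-6


class TestCompareSpecies:
    def _means(self):
        rng = np.random.default_rng(2)
        base = rng.normal(5, 2, size=300)
        ref = base + rng.normal(0, 0.2, 300)
        q = pd.DataFrame(
            {
                "3dpf": base + rng.normal(0, 2.0, 300),
                "5dpf": base + rng.normal(0, 1.0, 300),
                "7dpf": base + rng.normal(0, 0.4, 300),
            },
            index=[f"p{i}" for i in range(300)],
        )
        return q, pd.Series(ref, index=q.index)

    def test_planted_order_of_correlations(self):
        q, ref = self._means()
        corr, williams = mg.compare_species(q, ref)
        assert corr.loc["7dpf", "r"] == corr["r"].max()
        assert len(williams) == 3

    def test_near_identical_reference_dominates(self):
        q, ref = self._means()
        q = q.copy()
        rng = np.random.default_rng(4)
        q["7dpf"] = ref + rng.normal(0, 1e-3, len(ref))
        corr, williams = mg.compare_species(q, ref)
        assert corr.loc["7dpf", "r"] == pytest.approx(1.0, abs=1e-4)
        row = williams[(williams.group_1 == "3dpf") & (williams.group_2 == "7dpf")]
        assert row["t"].iloc[0] < 0 and row["p"].iloc[0] < 1e-10

    def test_exactly_equal_reference_is_degenerate(self):
        q, ref = self._means()
        q = q.copy()
        q["7dpf"] = ref
        with pytest.raises(ValueError, match="degenerate"):
            mg.compare_species(q, ref)

    def test_gene_order_invariance(self):
        q, ref = self._means()
        corr0, will0 = mg.compare_species(q, ref)
        perm = np.random.default_rng(3).permutation(len(ref))
        q2, ref2 = q.iloc[perm], ref.iloc[perm]
        corr1, will1 = mg.compare_species(q2, ref2)
        assert np.allclose(corr0["r"], corr1["r"])
        assert np.allclose(will0["t"], will1["t"])
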