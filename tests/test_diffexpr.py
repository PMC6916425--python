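"""Dispersion estimation, the NB Wald test, BH and the selection filters."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import microgliaseq as mg
from microgliaseq.diffexpr import ALPHA_MIN, estimate_dispersions


def bh_oracle(p):
    """Literal step-up definition: q_(i) = min_{j>=i} m p_(j) / j."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(rank_pos, m)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


class TestBHAdjust:
    def test_worked_example(self):
        assert np.allclose(mg.bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_equal_p_fixed_point(self):
        p = np.full(5, 0.2)
        assert np.allclose(mg.bh_adjust(p), p)

    @given(
        st.lists(
            st.integers(min_value=0, max_value=100), min_size=1, max_size=6
        )
    )
    def test_matches_bruteforce_oracle_on_grid(self, grid_points):
        p = np.array(grid_points) / 100.0
        assert np.allclose(mg.bh_adjust(p), bh_oracle(p), atol=1e-12)

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=8),
        st.randoms(use_true_random=False),
    )
    def test_permutation_equivariance(self, p, rnd):
        p = np.array(p)
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        q = mg.bh_adjust(p)
        q_perm = mg.bh_adjust(p[perm])
        assert np.allclose(q_perm, q[perm])

    def test_matches_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        ref = statsmodels.multipletests(p, method="fdr_bh")[1]
        assert np.allclose(mg.bh_adjust(p), ref, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mg.bh_adjust([0.5, 1.5])


class TestDispersions:
    def test_poisson_counts_have_near_zero_moments_estimate(self):
        cfg = mg.SimConfig(
            n_genes=2000, groups={"A": 3, "B": 3}, dispersion_a0=0.0,
            dispersion_a1=0.0, de_fraction=0.0, seed=0,
        )
        counts, design, _ = mg.simulate_experiment(cfg)
        disp = estimate_dispersions(counts, design, ("A", "B"))
        assert np.median(disp["alpha_mom"]) <= 0.01

    def test_nb_truth_recovered_at_larger_n(self):
        cfg = mg.SimConfig(
            n_genes=2000, groups={"A": 10, "B": 10}, dispersion_a0=0.5,
            dispersion_a1=0.0, de_fraction=0.0,
            baseline_log_mean=np.log(100), baseline_log_sd=0.0, seed=0,
        )
        counts, design, _ = mg.simulate_experiment(cfg)
        disp = estimate_dispersions(counts, design, ("A", "B"))
        assert 0.4 <= np.median(disp["alpha"]) <= 0.6

    def test_constant_gene_floored(self):
        df = pd.DataFrame(
            {f"s{i}": [7, 100, 3] for i in range(1, 5)},
            index=["flat1", "flat2", "flat3"],
        )
        design = mg.SampleDesign(
            pd.DataFrame(
                {
                    "sample_id": [f"s{i}" for i in range(1, 5)],
                    "group": ["A", "A", "B", "B"],
                    "replicate": [1, 2, 1, 2],
                    "species": ["z"] * 4,
                }
            )
        )
        disp = estimate_dispersions(df, design, ("A", "B"))
        assert np.allclose(disp["alpha"], ALPHA_MIN)

    def test_single_replicate_group_is_hard_error(self, small_counts):
        design = mg.SampleDesign(
            pd.DataFrame(
                {
                    "sample_id": ["s1", "s2", "s3", "s4"],
                    "group": ["A", "A", "A", "B"],
                    "replicate": [1, 2, 3, 1],
                    "species": ["z"] * 4,
                }
            )
        )
        with pytest.raises(ValueError, match="replicate"):
            estimate_dispersions(small_counts, design, ("A", "B"))


class TestDETest:
    def test_contrast_antisymmetry(self, null_experiment):
        counts, design, _ = null_experiment
        ab = mg.de_test(counts, design, ("A", "B"))
        ba = mg.de_test(counts, design, ("B", "A"))
        tested = ab["tested"]
        assert np.allclose(
            ab.loc[tested, "log2fc"], -ba.loc[tested, "log2fc"], atol=1e-6
        )
        assert np.allclose(ab.loc[tested, "p"], ba.loc[tested, "p"], atol=1e-6)

    def test_all_zero_genes_excluded_from_bh_family(self, null_experiment):
        counts, design, _ = null_experiment
        df = counts.df.copy()
        df.loc["dead1"] = 0
        df.loc["dead2"] = 0
        res = mg.de_test(mg.CountMatrix(df), design, ("A", "B"))
        assert not res.loc["dead1", "tested"]
        assert np.isnan(res.loc["dead1", "p"])
        inner = mg.de_test(counts, design, ("A", "B"))
        assert np.allclose(
            res.loc[inner.index, "q"].dropna(), inner["q"].dropna()
        )

    def test_null_pvalues_close_to_uniform(self, null_experiment):
        counts, design, _ = null_experiment
        res = mg.de_test(counts, design, ("A", "B"))
        p = res.loc[res["tested"], "p"].to_numpy()
        frac = np.mean(p < 0.05)
        assert 0.01 <= frac <= 0.12  # single-seed smoke; tight band in acceptance

    def test_strong_planted_effect_detected(self):
        cfg = mg.SimConfig(
            n_genes=400, groups={"A": 3, "B": 3}, dispersion_a0=0.05,
            dispersion_a1=0.0, de_n=20, lfc_value=3.0, min_de_mean=100.0,
            seed=11,
        )
        counts, design, truth = mg.simulate_experiment(cfg)
        res = mg.de_test(counts, design, ("A", "B"))
        sel = mg.filter_de(res)
        planted = set(truth.genes.index[truth.genes.is_de])
        assert len(set(sel.genes) & planted) / len(planted) >= 0.9

    def test_absent_group_is_hard_error(self, null_experiment):
        counts, design, _ = null_experiment
        with pytest.raises(ValueError, match="absent"):
            mg.de_test(counts, design, ("A", "C"))


class TestFilterDE:
    @pytest.mark.parametrize(
        "q,log2fc,kept",
        [
            (0.04, np.log2(2.5), True),
            (0.04, np.log2(1.5), False),
            (0.06, 2.0, False),
            (0.05, 1.0, True),  # boundary: both thresholds inclusive
        ],
    )
    def test_filter_boundaries(self, q, log2fc, kept):
        res = pd.DataFrame(
            {
                "base_mean": [10.0],
                "log2fc": [log2fc],
                "se": [0.1],
                "wald": [log2fc / 0.1],
                "p": [q / 2],
                "q": [q],
                "tested": [True],
            },
            index=["g"],
        )
        sel = mg.filter_de(res)
        assert ("g" in sel.genes) is kept

    def test_monotone_in_thresholds(self, null_experiment):
        counts, design, _ = null_experiment
        res = mg.de_test(counts, design, ("A", "B"))
        tight = set(mg.filter_de(res, fdr_max=0.05, min_fold=2).genes)
        loose_fdr = set(mg.filter_de(res, fdr_max=0.2, min_fold=2).genes)
        loose_fold = set(mg.filter_de(res, fdr_max=0.05, min_fold=1.2).genes)
        assert tight <= loose_fdr
        assert tight <= loose_fold

    def test_min_fold_below_one_rejected(self, null_experiment):
        counts, design, _ = null_experiment
        res = mg.de_test(counts, design, ("A", "B"))
        with pytest.raises(ValueError, match="min_fold"):
            mg.filter_de(res, min_fold=0.5)
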