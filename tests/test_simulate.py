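"""Determinism, truth consistency and moment identities of the generators."""

import numpy as np
import pandas as pd
import pytest

import microgliaseq as mg

from conftest import pattern_signs


class TestSimulateExperiment:
    def test_same_seed_bit_identical(self):
        cfg = mg.SimConfig(n_genes=200, seed=42)
        c1, d1, t1 = mg.simulate_experiment(cfg)
        c2, d2, t2 = mg.simulate_experiment(cfg)
        assert c1 == c2
        pd.testing.assert_frame_equal(t1.genes, t2.genes)
        pd.testing.assert_frame_equal(d1.df, d2.df)

    def test_different_seed_differs(self):
        c1, _, _ = mg.simulate_experiment(mg.SimConfig(n_genes=200, seed=1))
        c2, _, _ = mg.simulate_experiment(mg.SimConfig(n_genes=200, seed=2))
        assert not c1.df.equals(c2.df)

    def test_zero_de_fraction_no_true_effects(self):
        cfg = mg.SimConfig(n_genes=300, de_fraction=0.0, seed=5)
        _, _, truth = mg.simulate_experiment(cfg)
        lfc_cols = [c for c in truth.genes.columns if c.startswith("lfc_")]
        assert (truth.genes[lfc_cols] == 0).all().all()
        assert not truth.genes["is_de"].any()

    def test_truth_counts_match_de_n(self):
        cfg = mg.SimConfig(n_genes=500, de_n=37, seed=6)
        _, _, truth = mg.simulate_experiment(cfg)
        assert truth.genes["is_de"].sum() == 37

    def test_nb_moment_identity(self):
        # var ~ mu + alpha mu^2: regressing the per-gene sample variance on
        # mu + alpha*mu^2 across 50 replicates gives slope ~1
        cfg = mg.SimConfig(
            n_genes=2000, groups={"A": 50}, dispersion_a0=0.2,
            dispersion_a1=0.0, de_fraction=0.0,
            libsize_low=1.0, libsize_high=1.0, seed=0,
        )
        counts, _, truth = mg.simulate_experiment(cfg)
        x = counts.df.to_numpy(dtype=float)
        mu = truth.genes["baseline"].to_numpy()
        predicted = mu + 0.2 * mu**2
        observed = x.var(axis=1, ddof=1)
        slope = np.sum(predicted * observed) / np.sum(predicted**2)
        assert 0.9 <= slope <= 1.1

    def test_library_size_bounds_respected(self):
        cfg = mg.SimConfig(n_genes=50, seed=9, libsize_low=0.5, libsize_high=2.0)
        _, _, truth = mg.simulate_experiment(cfg)
        assert truth.lib_sizes.between(0.5, 2.0).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            mg.SimConfig(groups={"A": 1, "B": 3})
        with pytest.raises(ValueError, match="de_fraction"):
            mg.SimConfig(de_fraction=1.5)


class TestSimulateTemporalPatterns:
    def test_planted_counts_sum(self):
        cfg = mg.SimConfig(n_genes=400, groups={"3dpf": 3, "5dpf": 3, "7dpf": 3}, seed=0)
        _, _, truth = mg.simulate_temporal_patterns(cfg, genes_per_group=20)
        sizes = truth.genes["temporal_group"].value_counts()
        assert all(sizes[g] == 20 for g in pattern_signs())
        assert truth.genes["is_de"].sum() == 120

    def test_g2_pattern_means_ordered(self):
        cfg = mg.SimConfig(n_genes=100, groups={"3dpf": 3, "5dpf": 3, "7dpf": 3}, seed=1)
        _, _, truth = mg.simulate_temporal_patterns(cfg, genes_per_group=5, effect_size=2.0)
        g2 = truth.genes[truth.genes.temporal_group == "G2"]
        assert (g2["lfc_3dpf"] == g2["lfc_5dpf"]).all()
        assert (g2["lfc_3dpf"] > g2["lfc_7dpf"]).all()

    def test_true_sign_triples_match_canonical(self):
        cfg = mg.SimConfig(n_genes=200, groups={"3dpf": 3, "5dpf": 3, "7dpf": 3}, seed=2)
        _, _, truth = mg.simulate_temporal_patterns(cfg, genes_per_group=10)
        canon = pattern_signs()
        for group, expected in canon.items():
            sub = truth.genes[truth.genes.temporal_group == group]
            s35 = np.sign(sub["lfc_3dpf"] - sub["lfc_5dpf"]).astype(int)
            s37 = np.sign(sub["lfc_3dpf"] - sub["lfc_7dpf"]).astype(int)
            s57 = np.sign(sub["lfc_5dpf"] - sub["lfc_7dpf"]).astype(int)
            triples = set(zip(s35, s37, s57))
            assert triples == {expected}


class TestSimulateDualSpecies:
    def _run(self, conservation, seed=0, **kw):
        cfg = mg.SimConfig(n_genes=400, seed=seed)
        return mg.simulate_dual_species(
            cfg, conservation_fraction=conservation, signature_size=40, **kw
        )

    def test_relation_labels_match_multiplicities(self):
        _, _, _, _, omap, _, _ = self._run(1.0)
        df = omap.df
        counts_a = df["gene_a"].value_counts()
        for _, row in df.iterrows():
            if row.relation == "one_to_one":
                assert counts_a[row.gene_a] == 1
            else:
                assert counts_a[row.gene_a] > 1

    def test_full_conservation_signatures_share_orthologs(self):
        _, _, _, _, omap, truth_a, truth_b = self._run(1.0)
        sig_a = set(truth_a.genes.index[truth_a.genes.signature])
        sig_b = set(truth_b.genes.index[truth_b.genes.signature])
        mapped = omap.df[omap.df["gene_a"].isin(sig_a)]
        assert len(sig_a) == len(sig_b) == 40
        assert set(mapped["gene_b"]) & sig_b  # conserved orthologs present
        assert truth_a.genes["conserved"].sum() == 40

    def test_zero_conservation_signatures_disjoint(self):
        _, _, _, _, omap, truth_a, truth_b = self._run(0.0)
        assert truth_a.genes["conserved"].sum() == 0
        sig_a = set(truth_a.genes.index[truth_a.genes.signature])
        sig_b = set(truth_b.genes.index[truth_b.genes.signature])
        first_ortholog = (
            omap.df[omap.df["gene_a"].isin(sig_a)]
            .sort_values(["gene_a", "gene_b"])
            .drop_duplicates("gene_a")
        )
        # only chance-level overlap (expected ~4 of 40 under independence)
        assert len(set(first_ortholog["gene_b"]) & sig_b) <= 15

    def test_signature_elevated_in_all_microglia_groups(self):
        _, _, _, _, _, truth_a, truth_b = self._run(1.0)
        sig = truth_a.genes[truth_a.genes.signature]
        for g in ("3dpf", "5dpf", "7dpf"):
            assert (sig[f"lfc_{g}"] > 0).all()
        assert (sig["lfc_brain"] == 0).all()
        sig_b = truth_b.genes[truth_b.genes.signature]
        assert (sig_b["lfc_microglia"] > 0).all()

    def test_deterministic(self):
        out1 = self._run(0.5, seed=3)
        out2 = self._run(0.5, seed=3)
        assert out1[0] == out2[0]
        assert out1[2] == out2[2]
        pd.testing.assert_frame_equal(out1[4].df, out2[4].df)
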