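"""Normalization, BH, NB exact test and the DEG-allele gate."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import triploid_ase as ta
from triploid_ase.deg_calling import Direction, estimate_dispersions
from triploid_ase.errors import ConfigError, DomainError, NormalizationError


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        c = np.tile([[10], [20], [30]], (1, 4))
        np.testing.assert_allclose(ta.size_factors(c), np.ones(4))

    def test_doubled_column_hand_value(self):
        # column 2 = 2 x column 1 elementwise -> factors (1/sqrt2, sqrt2)
        c = np.array([[10, 20], [5, 10], [40, 80]])
        np.testing.assert_allclose(
            ta.size_factors(c), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )

    def test_genes_with_zero_excluded_from_reference(self):
        base = np.array([[10, 10], [20, 20]])
        with_zero = np.vstack([base, [[0, 1000]]])
        # the zero-containing gene has geometric mean 0 and cannot move the factors
        np.testing.assert_allclose(ta.size_factors(with_zero), [1.0, 1.0])

    def test_no_all_positive_gene_raises(self):
        with pytest.raises(NormalizationError):
            ta.size_factors(np.array([[0, 1], [1, 0]]))

    def test_scaling_one_sample_scales_factor_ratios(self):
        """Scaling sample j's library by c multiplies its size factor
        relative to every other sample by c, and normalized counts change
        only by a constant common to all samples."""
        rng = np.random.default_rng(0)
        c = rng.poisson(50, (200, 4)) + 1
        f0 = ta.size_factors(c)
        scaled = c.astype(float).copy()
        scaled[:, 1] *= 5
        f1 = ta.size_factors(scaled)
        ratio0 = f0[1] / f0
        ratio1 = f1[1] / f1
        np.testing.assert_allclose(ratio1[[0, 2, 3]], 5 * ratio0[[0, 2, 3]], rtol=1e-9)
        norm0 = c / f0
        norm1 = scaled / f1
        np.testing.assert_allclose(norm1 / norm0, (norm1 / norm0)[0, 0], rtol=1e-9)


class TestBHAdjust:
    def test_single_p(self):
        np.testing.assert_allclose(ta.bh_adjust([0.03]), [0.03])

    def test_hand_step_up(self):
        np.testing.assert_allclose(
            ta.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            ta.bh_adjust([0.5, 1.2])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_bounds_and_dominance(self, ps):
        q = ta.bh_adjust(ps)
        assert ((0 <= q) & (q <= 1)).all()
        assert (q >= np.asarray(ps) - 1e-15).all()

    def test_matches_independent_implementation_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 60))
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(ta.bh_adjust(p), expected, atol=1e-12)


class TestNBTest:
    def test_all_zero_gene_p_is_one(self):
        c1 = np.array([[0, 0, 0], [5, 6, 7]])
        c2 = np.array([[0, 0, 0], [5, 7, 6]])
        p = ta.nb_test(c1, c2, np.ones(3), np.ones(3))
        assert p[0] == 1.0

    def test_type_one_error_near_nominal(self, null_nb_pvalues):
        rate = (null_nb_pvalues < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_global_null_bh_discovery_rate_controlled(self, null_nb_pvalues):
        q = ta.bh_adjust(null_nb_pvalues)
        n = null_nb_pvalues.size
        se = np.sqrt(0.05 * 0.95 / n)
        assert (q < 0.05).mean() <= 0.05 + 2 * se

    def test_power_at_tenfold_shift(self):
        rng = np.random.default_rng(21)
        n_genes, disp = 400, 0.05
        size = 1 / disp
        mu1 = np.full(n_genes, 200.0)
        mu2 = 10 * mu1
        c1 = rng.negative_binomial(size, size / (size + mu1[:, None]), (n_genes, 3))
        c2 = rng.negative_binomial(size, size / (size + mu2[:, None]), (n_genes, 3))
        p = ta.nb_test(c1, c2, np.ones(3), np.ones(3), dispersions=np.full(n_genes, disp))
        assert (p < 1e-3).mean() >= 0.95

    def test_dispersion_modes_ordering(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(100, (300, 6))
        factors = np.ones(6)
        groups = np.array([0, 0, 0, 1, 1, 1])
        gene = estimate_dispersions(counts, factors, groups, mode="gene")
        fit = estimate_dispersions(counts, factors, groups, mode="fit")
        mx = estimate_dispersions(counts, factors, groups, mode="max")
        assert (mx >= np.maximum(gene, fit) - 1e-12).all()
        with pytest.raises(ConfigError):
            estimate_dispersions(counts, factors, groups, mode="bogus")


class TestDEGGate:
    def _matrix(self, counts_base, counts_stage):
        """Two-stage design, 3 replicates, with a spike-in gene grid."""
        n = counts_base.shape[0]
        genes = pd.DataFrame(
            {"subgenome": ["A"] * n, "length_bp": [1000] * n},
            index=pd.Index([f"g{i}" for i in range(n)], name="gene_id"),
        )
        design = pd.DataFrame(
            {
                "cultivar": ["FJ"] * 6,
                "stage_dph": [0, 0, 0, 3, 3, 3],
                "replicate": [1, 2, 3, 1, 2, 3],
            },
            index=pd.Index([f"s{i}" for i in range(6)], name="sample_id"),
        )
        counts = pd.DataFrame(
            np.hstack([counts_base, counts_stage]), index=genes.index,
            columns=design.index,
        )
        return ta.ExpressionMatrix(genes, design, counts=counts)

    def test_two_condition_gate(self):
        """A gene at exactly 2-fold with negligible dispersion passes (the
        fold threshold is inclusive); a large-fold gene with huge
        within-group spread fails the significance condition."""
        stable = np.full((50, 3), 500)
        base = np.vstack([[400, 400, 400], [10, 1500, 20], stable])
        test = np.vstack([[800, 800, 800], [4000, 30, 2500], stable])
        m = self._matrix(base, test)
        rec = ta.deg_table(m, ta.PipelineConfig(), dispersion_mode="gene")
        rec = rec.set_index("gene_id")
        assert rec.loc["g0", "log2fc"] == pytest.approx(1.0)
        assert rec.loc["g0", "direction"] == Direction.UP  # exactly 2-fold
        noisy = rec.loc["g1"]
        assert abs(noisy["log2fc"]) > 1  # big fold change...
        assert noisy["direction"] == Direction.NS  # ...but not significant

    def test_missing_baseline_stage_raises(self, sim_small):
        _, matrix, pairs, _ = sim_small
        cfg = ta.PipelineConfig(baseline_stage_dph=99)
        with pytest.raises(ConfigError):
            ta.call_deg_alleles(matrix, pairs, cfg)

    def test_fold_change_only_fallback_without_counts(self, sim_small):
        _, matrix, pairs, _ = sim_small
        rpkm_only = ta.ExpressionMatrix(matrix.genes, matrix.design, rpkm=matrix.rpkm)
        rec = ta.deg_table(rpkm_only, ta.PipelineConfig())
        assert rec["p_value"].isna().all()
        called = rec[rec["direction"] != Direction.NS]
        assert (called["log2fc"].abs() >= 1 - 1e-9).all()

    def test_deg_pairs_subset_of_input(self, sim_bench, deg_bench):
        _, _, pairs, _ = sim_bench
        assert set(deg_bench.pair_ids) <= set(pairs.pairs["pair_id"])
        assert len(deg_bench.records) > 0

    def test_recall_and_fdr_on_injected_degs(self, sim_bench, deg_bench):
        """Genes injected at |log2FC| >= the configured mean are recalled at
        >= 0.9 with empirical FDR <= 0.1."""
        cfg, _, _, truth = sim_bench
        tdeg = truth.deg.set_index("gene_id")
        hits = set(
            deg_bench.records.loc[
                deg_bench.records["direction"] != Direction.NS, "gene_id"
            ]
        )
        strong = tdeg[
            (tdeg["true_deg"] != "NULL")
            & (tdeg["true_log2fc"].abs() >= cfg.deg_log2fc_mean)
        ]
        recall = np.mean([g in hits for g in strong.index])
        null_genes = set(tdeg[tdeg["true_deg"] == "NULL"].index)
        fdr = np.mean([g in null_genes for g in hits])
        assert recall >= 0.9
        assert fdr <= 0.1
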