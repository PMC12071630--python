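"""Dosage-adjusted classifier: examples, invariants and recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import triploid_ase as ta
from triploid_ase.ase_calling import ASEClass, calls_from_counts
from triploid_ase.errors import ConsistencyError, DomainError, PairLookupError

ABB = ta.PloidyModel()  # copies (1, 2), fold factor 2 -> B > 4A / B < A


class TestClassifyPair:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (10, 45, ASEClass.B_DOMINANT),  # 45 > 4*10
            (10, 8, ASEClass.A_DOMINANT),  # 8 < 10
            (10, 20, ASEClass.BALANCED),  # exactly dosage-proportional
            (10, 40, ASEClass.BALANCED),  # boundary: strict inequality
            (10, 10, ASEClass.BALANCED),  # boundary: strict inequality
            (0, 0, ASEClass.NOT_EXPRESSED),
            (0, 5, ASEClass.B_DOMINANT),  # silent A, expressed B
            (5, 0, ASEClass.A_DOMINANT),
        ],
    )
    def test_abb_examples(self, a, b, expected):
        assert ta.classify_pair(a, b, ABB) is expected

    def test_negative_input_rejected(self):
        with pytest.raises(DomainError):
            ta.classify_pair(-1, 5, ABB)
        with pytest.raises(DomainError):
            ta.classify_pair(1, float("nan"), ABB)

    def test_diploid_reduction(self):
        """With copies (1,1) and k=2 the classifier is exactly the standard
        diploid 2-fold rule, checked against a direct implementation on
        1,000 random pairs."""
        diploid = ta.PloidyModel(copies_a=1, copies_b=1, fold_factor=2.0)

        def diploid_rule(a, b):
            if a + b < 1.0:
                return ASEClass.NOT_EXPRESSED
            if b > 2 * a:
                return ASEClass.B_DOMINANT
            if b < a / 2:
                return ASEClass.A_DOMINANT
            return ASEClass.BALANCED

        rng = np.random.default_rng(13)
        a = rng.uniform(0, 50, 1000)
        b = rng.uniform(0, 50, 1000)
        for ai, bi in zip(a, b):
            assert ta.classify_pair(ai, bi, diploid) is diploid_rule(ai, bi)

    @settings(derandomize=True, max_examples=200)
    @given(
        a=st.floats(0, 1e6), b=st.floats(0, 1e6),
        k=st.floats(1.01, 10), k2=st.floats(0.01, 5),
    )
    def test_monotonicity_in_k(self, a, b, k, k2):
        """Raising the fold factor never creates a new ASE call."""
        lo = ta.PloidyModel(fold_factor=k)
        hi = ta.PloidyModel(fold_factor=k + k2)
        ase = {ASEClass.B_DOMINANT, ASEClass.A_DOMINANT}
        if ta.classify_pair(a, b, hi) in ase:
            assert ta.classify_pair(a, b, lo) in ase

    @settings(derandomize=True, max_examples=200)
    @given(a=st.floats(0, 1e6), b=st.floats(0, 1e6))
    def test_subgenome_swap_symmetry(self, a, b):
        """Swapping subgenome labels and inverting the dosage ratio swaps
        B-dominant and A-dominant calls exactly."""
        fwd = ta.classify_pair(a, b, ABB)
        swapped = ta.classify_pair(
            b, a, ta.PloidyModel(copies_a=2, copies_b=1, fold_factor=2.0)
        )
        mirror = {
            ASEClass.B_DOMINANT: ASEClass.A_DOMINANT,
            ASEClass.A_DOMINANT: ASEClass.B_DOMINANT,
            ASEClass.BALANCED: ASEClass.BALANCED,
            ASEClass.NOT_EXPRESSED: ASEClass.NOT_EXPRESSED,
        }
        assert swapped is mirror[fwd]


class TestClassifyAll:
    def test_cardinality(self, sim_small):
        _, matrix, pairs, _ = sim_small
        three = pairs.subset(pairs.pairs["pair_id"][:3])
        calls = ta.classify_all(matrix, three, ABB)
        assert len(calls) == 3 * 2  # 3 pairs x 2 non-baseline stages

    def test_missing_member_raises(self, sim_small):
        _, matrix, pairs, _ = sim_small
        bad = pairs.pairs.head(2).copy()
        bad.loc[bad.index[0], "gene_a"] = "ghost_gene"
        with pytest.raises(PairLookupError, match="ghost_gene"):
            ta.classify_all(matrix, ta.AllelePairSet(bad), ABB)

    def test_every_pair_gets_exactly_one_call_per_stage(self, sim_bench):
        _, matrix, pairs, _ = sim_bench
        calls = ta.classify_all(matrix, pairs, ABB)
        per_stage = calls.groupby("stage_dph")["pair_id"].nunique()
        assert (per_stage == len(pairs)).all()
        assert len(calls) == len(pairs) * 2

    def test_raising_k_shrinks_call_set(self, sim_bench):
        _, matrix, pairs, _ = sim_bench
        ase = {ASEClass.B_DOMINANT, ASEClass.A_DOMINANT}

        def ase_ids(k):
            calls = ta.classify_all(matrix, pairs, ta.PloidyModel(fold_factor=k))
            hit = calls[calls["call"].isin(ase)]
            return set(zip(hit["pair_id"], hit["stage_dph"]))

        assert ase_ids(3.0) <= ase_ids(2.0)

    def test_recovery_of_injected_classes(self, sim_bench):
        """Sensitivity and specificity >= 0.95 for well-expressed pairs at
        effect multiplier 2."""
        cfg, matrix, pairs, truth = sim_bench
        calls = ta.classify_all(matrix, pairs, cfg.ploidy_model())
        stage = max(cfg.stages_dph)
        got = calls[calls["stage_dph"] == stage].set_index("pair_id")["call"]
        want = truth.ase.query("stage_dph == @stage").set_index("pair_id")["true_class"]

        mean_counts = matrix.counts.mean(axis=1)
        p = pairs.pairs.set_index("pair_id")
        ok = (
            (mean_counts.loc[p["gene_a"]].to_numpy() >= 50)
            & (mean_counts.loc[p["gene_b"]].to_numpy() >= 50)
        )
        ids = p.index[ok]
        got, want = got.loc[ids].astype(str), want.loc[ids].astype(str)

        is_ase = want.isin(["B_DOMINANT", "A_DOMINANT"])
        sens = (is_ase & (got == want)).sum() / is_ase.sum()
        spec = (~is_ase & (got == "BALANCED")).sum() / (~is_ase).sum()
        assert sens >= 0.95
        assert spec >= 0.95


class TestGenomeSummary:
    def test_reported_composition_reproduces_percentages(self):
        """Expanding the reported 3-d counts (1,722 B-dominant + 2,469
        A-dominant of 15,415 DEG alleles) gives 27.2% ASE."""
        calls = calls_from_counts(3, 1722, 2469, 15415 - 1722 - 2469)
        summary = ta.genome_wide_summary(calls, n_deg_alleles=15415)
        assert summary.loc[0, "ase_percent"] == 27.2
        assert summary.loc[0, "n_pairs_tested"] == 15415

    def test_zero_and_full_ase(self):
        zero = calls_from_counts(3, 0, 0, 100)
        assert ta.genome_wide_summary(zero, 100).loc[0, "ase_percent"] == 0.0
        full = calls_from_counts(3, 60, 40, 0)
        assert ta.genome_wide_summary(full, 100).loc[0, "ase_percent"] == 100.0

    def test_counts_partition_the_call_list(self, sim_small):
        _, matrix, pairs, _ = sim_small
        calls = ta.classify_all(matrix, pairs, ABB)
        summary = ta.genome_wide_summary(calls, n_deg_alleles=len(pairs))
        for _, row in summary.iterrows():
            stage_calls = calls[calls["stage_dph"] == row["stage_dph"]]
            total = (
                row["n_b_dominant"] + row["n_a_dominant"]
                + row["n_balanced"] + row["n_not_expressed"]
            )
            assert total == len(stage_calls)
            assert row["n_pairs_tested"] + row["n_not_expressed"] == len(stage_calls)

    def test_inconsistent_denominator_raises(self):
        calls = calls_from_counts(3, 10, 10, 80)
        with pytest.raises(ConsistencyError):
            ta.genome_wide_summary(calls, n_deg_alleles=50)
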