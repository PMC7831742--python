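import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cislnc.paired_de import (
    PairedExpressionSet,
    bh_adjust,
    call_deregulated,
    fold_change,
    mann_whitney,
    two_group_test,
    wilcoxon_signed_rank,
)
from oracles import bh_direct, mannwhitney_exact_p, wilcoxon_exact_p

small_ints = st.lists(st.integers(0, 20), min_size=1, max_size=8)


def _cohort(tumor: np.ndarray, normal: np.ndarray, genes=None) -> PairedExpressionSet:
    n = tumor.shape[1]
    genes = genes or [f"g{i}" for i in range(tumor.shape[0])]
    patients = [f"p{i}" for i in range(n)]
    values = pd.DataFrame(
        np.hstack([tumor, normal]),
        index=pd.Index(genes, name="gene_id"),
        columns=[f"{p}T" for p in patients] + [f"{p}N" for p in patients],
    )
    samples = pd.DataFrame(
        {
            "sample_id": list(values.columns),
            "patient_id": patients * 2,
            "condition": ["tumor"] * n + ["normal"] * n,
        }
    )
    return PairedExpressionSet(values=values, samples=samples)


class TestWilcoxonSignedRank:
    def test_three_positive_differences(self):
        w, p = wilcoxon_signed_rank([11, 12, 13], [10, 10, 10])
        assert w == 6.0
        assert p == pytest.approx(0.25)

    def test_all_pairs_equal_gives_p_one(self):
        _, p = wilcoxon_signed_rank([5, 5, 5], [5, 5, 5])
        assert p == 1.0

    def test_two_sided_p_symmetric_under_swap(self):
        x, y = [3.0, 7.0, 1.0, 9.0, 4.0], [2.0, 8.0, 0.5, 3.0, 4.5]
        assert wilcoxon_signed_rank(x, y)[1] == pytest.approx(
            wilcoxon_signed_rank(y, x)[1]
        )

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            wilcoxon_signed_rank([1, 2], [1, 2, 3])

    @given(x=small_ints, y=small_ints)
    @settings(max_examples=200, deadline=None)
    def test_exact_p_matches_enumeration_oracle(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        w, p = wilcoxon_signed_rank(x, y, mode="exact")
        w_ref, p_ref = wilcoxon_exact_p(x, y)
        assert w == pytest.approx(w_ref)
        assert p == pytest.approx(p_ref)

    def test_approx_close_to_exact_at_moderate_n(self):
        rng = np.random.default_rng(7)
        x = rng.normal(1.0, 1.0, 24)
        y = rng.normal(0.0, 1.0, 24)
        _, p_exact = wilcoxon_signed_rank(x, y, mode="exact")
        _, p_approx = wilcoxon_signed_rank(x, y, mode="approx")
        assert p_approx == pytest.approx(p_exact, abs=0.02)


class TestMannWhitney:
    def test_fully_separated_groups(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_groups_p_near_one(self):
        _, p = mann_whitney([1, 2, 3], [3, 1, 2])
        assert p >= 0.99

    def test_scale_invariance(self):
        a, b = [1.0, 5.0, 2.0, 8.0], [3.0, 9.0, 4.0]
        u1, p1 = mann_whitney(a, b)
        u2, p2 = mann_whitney([7 * v for v in a], [7 * v for v in b])
        assert (u1, p1) == (u2, p2)

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney([], [1.0])

    @given(a=st.lists(st.integers(0, 10), min_size=1, max_size=4),
           b=st.lists(st.integers(0, 10), min_size=1, max_size=4))
    @settings(max_examples=200, deadline=None)
    def test_exact_p_matches_enumeration_oracle(self, a, b):
        u, p = mann_whitney(a, b, mode="exact")
        u_ref, p_ref = mannwhitney_exact_p(a, b)
        assert u == pytest.approx(u_ref)
        assert p == pytest.approx(p_ref)

    def test_two_group_test_requires_two_levels(self):
        with pytest.raises(ValueError, match="two levels"):
            two_group_test([1, 2, 3], ["I", "I", "I"])

    def test_two_group_test_matches_mann_whitney(self):
        values = [3.0, 1.0, 4.0, 1.5, 9.0, 2.6]
        labels = ["I", "II", "I", "II", "I", "II"]
        u, p = two_group_test(values, labels)
        u_ref, p_ref = mann_whitney([3.0, 4.0, 9.0], [1.0, 1.5, 2.6])
        assert (u, p) == (u_ref, p_ref)


class TestFoldChange:
    def test_three_fold(self):
        fc, log2fc = fold_change([15.0], [5.0], pseudocount=1e-9)
        assert fc == pytest.approx(3.0)
        assert log2fc == pytest.approx(np.log2(3.0))

    def test_identity_for_equal_inputs(self):
        fc, log2fc = fold_change([2.0, 4.0], [4.0, 2.0], pseudocount=0.37)
        assert fc == 1.0 and log2fc == 0.0

    def test_zero_denominator_stays_finite(self):
        fc, _ = fold_change([1.0], [0.0], pseudocount=0.01)
        assert fc == pytest.approx(101.0)

    def test_nonpositive_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            fold_change([1.0], [1.0], pseudocount=0.0)


class TestBHAdjust:
    def test_worked_example(self):
        q = bh_adjust([0.005, 0.009, 0.05, 0.5])
        assert q == pytest.approx([0.018, 0.018, 0.0666667, 0.5], rel=1e-5)

    def test_single_p_identity(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_constant_vector_unchanged(self):
        assert bh_adjust([0.3] * 7) == pytest.approx([0.3] * 7)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_matches_direct_formula(self, p):
        assert bh_adjust(p) == pytest.approx(bh_direct(p))

    @given(
        p=st.lists(st.floats(0.01, 0.99), min_size=2, max_size=15),
        idx=st.integers(0, 14),
        bump=st.floats(0.001, 0.5),
    )
    @settings(max_examples=150, deadline=None)
    def test_monotone_in_each_raw_p(self, p, idx, bump):
        idx = idx % len(p)
        bumped = p.copy()
        bumped[idx] = min(1.0, bumped[idx] + bump)
        assert np.all(bh_adjust(bumped) >= bh_adjust(p) - 1e-12)


class TestCallDeregulated:
    def test_planted_shift_is_called_up(self):
        rng = np.random.default_rng(11)
        n_pairs, n_genes = 20, 100
        normal = rng.lognormal(3.0, 0.5, (n_genes, n_pairs))
        tumor = normal * rng.lognormal(0.0, 0.2, (n_genes, n_pairs))
        tumor[0] *= 4.0  # planted 4-fold upshift in gene 0
        de = call_deregulated(_cohort(tumor, normal))
        assert bool(de.loc["g0", "deregulated"]) is True
        assert de.loc["g0", "direction"] == "up"
        assert not de.drop("g0")["deregulated"].any()

    def test_condition_relabel_flips_direction_keeps_p(self):
        rng = np.random.default_rng(3)
        tumor = rng.lognormal(3, 0.5, (10, 15)) * 3
        normal = rng.lognormal(3, 0.5, (10, 15))
        de = call_deregulated(_cohort(tumor, normal))
        de_flipped = call_deregulated(_cohort(normal, tumor))
        assert (de["direction"].map({"up": "down", "down": "up", "flat": "flat"})
                == de_flipped["direction"]).all()
        assert de["p"].to_numpy() == pytest.approx(de_flipped["p"].to_numpy())
        assert de["q"].to_numpy() == pytest.approx(de_flipped["q"].to_numpy())

    def test_all_null_cohort_has_no_calls(self):
        rng = np.random.default_rng(5)
        vals = rng.lognormal(3, 0.5, (50, 12))
        de = call_deregulated(_cohort(vals, vals.copy()))
        assert (de["p"] == 1.0).all()
        assert not de["deregulated"].any()

    def test_unpaired_samples_error_names_patient(self):
        tumor = np.ones((2, 3))
        normal = np.ones((2, 3))
        cohort = _cohort(tumor, normal)
        cohort.samples.loc[0, "patient_id"] = "rogue"
        with pytest.raises(ValueError, match="rogue"):
            call_deregulated(cohort)

    def test_invariant_to_gene_and_sample_order(self):
        rng = np.random.default_rng(9)
        tumor = rng.lognormal(3, 0.5, (12, 8)) * rng.choice([1, 3], size=(12, 1))
        normal = rng.lognormal(3, 0.5, (12, 8))
        cohort = _cohort(tumor, normal)
        de = call_deregulated(cohort)
        perm_genes = rng.permutation(cohort.values.index)
        perm_cols = rng.permutation(cohort.values.columns)
        shuffled = PairedExpressionSet(
            values=cohort.values.loc[perm_genes, perm_cols],
            samples=cohort.samples.sample(frac=1, random_state=2),
        )
        de2 = call_deregulated(shuffled)
        pd.testing.assert_frame_equal(de.sort_index(), de2.sort_index())

    def test_ttest_switch(self):
        rng = np.random.default_rng(13)
        tumor = rng.lognormal(3, 0.3, (5, 10)) * 4
        normal = rng.lognormal(3, 0.3, (5, 10))
        de = call_deregulated(_cohort(tumor, normal), test="ttest")
        assert de["deregulated"].all()
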