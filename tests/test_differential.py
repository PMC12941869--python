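import numpy as np
import pandas as pd
import pytest
from scipy import stats

from recurstrat import bh_adjust, call_de, run_contrasts, student_test, welch_test

from .conftest import make_matrix


def bh_oracle(p):
    """Direct min-over-suffix evaluation of the BH step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    suffix_min = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        suffix_min = min(suffix_min, p[idx] * m / (rank + 1))
        q[idx] = suffix_min
    return q


def _two_group_matrix(rng, n_genes, na, nb):
    matrix = make_matrix(rng.normal(5, 1, size=(n_genes, na + nb)))
    samples = matrix.sample_ids
    return matrix, samples[:na], samples[na:]


class TestWelch:
    def test_matches_scipy_reference(self, rng):
        for _ in range(100):
            na, nb = rng.integers(2, 8, size=2)
            matrix, a, b = _two_group_matrix(rng, 5, na, nb)
            ours = welch_test(matrix, a, b)
            ref_t, ref_p = stats.ttest_ind(
                matrix.data[a], matrix.data[b], axis=1, equal_var=False
            )
            np.testing.assert_allclose(ours["t"], ref_t, atol=1e-10)
            np.testing.assert_allclose(ours["p"], ref_p, atol=1e-10)

    def test_identical_constant_groups_give_null_result(self):
        matrix = make_matrix([[2, 4, 6, 2, 4, 6]])
        res = welch_test(matrix, ["S0", "S1", "S2"], ["S3", "S4", "S5"])
        assert res["t"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0

    def test_zero_variance_in_both_groups_flagged(self):
        matrix = make_matrix([[3, 3, 3, 3]])
        res = welch_test(matrix, ["S0", "S1"], ["S2", "S3"])
        assert res["t"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0
        assert bool(res["zero_var"].iloc[0])

    def test_clear_separation_is_significant(self):
        matrix = make_matrix([[10, 12, 14, 1, 2, 3]])
        res = welch_test(matrix, ["S0", "S1", "S2"], ["S3", "S4", "S5"])
        assert res["p"].iloc[0] < 0.05

    def test_swapping_groups_negates_t_preserves_p(self, rng):
        matrix, a, b = _two_group_matrix(rng, 8, 4, 5)
        fwd = welch_test(matrix, a, b)
        rev = welch_test(matrix, b, a)
        np.testing.assert_allclose(fwd["t"], -rev["t"], atol=1e-12)
        np.testing.assert_allclose(fwd["p"], rev["p"], atol=1e-12)

    def test_small_or_overlapping_groups_rejected(self, rng):
        matrix, a, b = _two_group_matrix(rng, 3, 3, 3)
        with pytest.raises(ValueError, match="at least 2"):
            welch_test(matrix, a[:1], b)
        with pytest.raises(ValueError, match="overlap"):
            welch_test(matrix, a, a)


class TestStudent:
    def test_matches_scipy_pooled_reference(self, rng):
        for _ in range(50):
            na, nb = rng.integers(2, 8, size=2)
            matrix, a, b = _two_group_matrix(rng, 5, na, nb)
            ours = student_test(matrix, a, b)
            ref_t, ref_p = stats.ttest_ind(
                matrix.data[a], matrix.data[b], axis=1, equal_var=True
            )
            np.testing.assert_allclose(ours["t"], ref_t, atol=1e-10)
            np.testing.assert_allclose(ours["p"], ref_p, atol=1e-10)


class TestBHAdjust:
    def test_single_p_is_identity(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_hand_worked_example(self):
        # p_(i) * 4 / i = 0.04 for every i
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 7), [0.2] * 7)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(300):
            p = rng.uniform(size=rng.integers(1, 51))
            np.testing.assert_array_equal(bh_adjust(p), bh_oracle(p))

    def test_matches_statsmodels_reference(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 100))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)

    def test_q_at_least_p_and_permutation_invariant(self, rng):
        p = rng.uniform(size=40)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        perm = rng.permutation(40)
        np.testing.assert_allclose(bh_adjust(p[perm]), q[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])


def _annotated_fixture(values):
    """Matrix with 3 primary and 3 normal samples and a matching annotation."""
    matrix = make_matrix(values)
    ann = pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "group": ["primary"] * 3 + ["normal"] * 3,
        }
    )
    return matrix, ann


class TestCallDE:
    def test_twofold_change_passes_up(self, rng):
        # log2 means differ by exactly 1 (linear 2-fold) with tiny noise
        base = rng.normal(0, 0.01, size=(1, 6))
        base[0, :3] += 5.0
        base[0, 3:] += 4.0
        matrix, ann = _annotated_fixture(base)
        res = call_de(matrix, ann, "primary", "normal")
        row = res.table.iloc[0]
        assert row["passes"] and row["direction"] == "up"
        assert row["log2fc"] == pytest.approx(1.0, abs=0.05)

    def test_small_fold_change_fails_despite_significance(self, rng):
        values = rng.normal(0, 0.01, size=(1, 6))
        values[0, :3] += 5.5
        values[0, 3:] += 5.0  # log2fc = 0.5 < log2(1.5)
        matrix, ann = _annotated_fixture(values)
        res = call_de(matrix, ann, "primary", "normal")
        row = res.table.iloc[0]
        assert row["q"] < 0.05
        assert not row["passes"]
        assert row["direction"] == "none"

    def test_fc_bound_is_inclusive(self):
        # exactly representable means 6.0 and 5.0: log2fc is exactly 1.0,
        # which sits exactly on the bound for a 2-fold threshold
        values = np.array([[6.25, 6.0, 5.75, 5.25, 5.0, 4.75]])
        matrix, ann = _annotated_fixture(values)
        res = call_de(matrix, ann, "primary", "normal", fc_threshold=2.0)
        row = res.table.iloc[0]
        assert row["log2fc"] == 1.0
        assert row["q"] < 0.05
        assert row["passes"]  # would fail if the FC bound were strict

    def test_pass_set_shrinks_as_thresholds_tighten(self, rng):
        matrix = make_matrix(rng.normal(5, 1, size=(60, 12)))
        ann = pd.DataFrame(
            {
                "sample_id": matrix.sample_ids,
                "group": ["primary"] * 6 + ["normal"] * 6,
            }
        )
        matrix.data.iloc[:20, :6] += rng.uniform(0.5, 2.5, size=20)[:, None]
        loose = call_de(matrix, ann, "primary", "normal", fc_threshold=1.2, fdr=0.2)
        tight_fc = call_de(matrix, ann, "primary", "normal", fc_threshold=2.0, fdr=0.2)
        tight_fdr = call_de(matrix, ann, "primary", "normal", fc_threshold=1.2, fdr=0.01)
        assert tight_fc.passing() <= loose.passing()
        assert tight_fdr.passing() <= loose.passing()

    def test_invalid_thresholds_rejected(self, rng):
        matrix, ann = _annotated_fixture(rng.normal(5, 1, size=(2, 6)))
        with pytest.raises(ValueError):
            call_de(matrix, ann, "primary", "normal", fc_threshold=0.5)
        with pytest.raises(ValueError):
            call_de(matrix, ann, "primary", "normal", fdr=1.5)
        with pytest.raises(ValueError):
            call_de(matrix, ann, "primary", "normal", statistic="median")


class TestRunContrasts:
    def test_three_contrasts_share_gene_universe(self, small_cohort):
        contrasts = run_contrasts(small_cohort.matrix, small_cohort.annotation)
        assert set(contrasts) == {
            "tumor_vs_normal",
            "recurrent_vs_normal",
            "recurrent_vs_primary",
        }
        genes = small_cohort.matrix.gene_ids
        for res in contrasts.values():
            assert res.genes == genes

    def test_missing_group_aborts(self, small_cohort):
        ann = small_cohort.annotation
        no_normal = ann[ann.group != "normal"]
        with pytest.raises(ValueError, match="normal"):
            run_contrasts(small_cohort.matrix, no_normal)
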