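import logging

import numpy as np
import pandas as pd
import pytest

from recurstrat import (
    CLASS_NAMES,
    StratificationModel,
    assign_classes,
    fit_thresholds,
    kmeans_1d,
    stratification_report,
)


def scores_frame(ts, rs=None, ids=None):
    ts = np.asarray(ts, dtype=float)
    rs = np.zeros_like(ts) if rs is None else np.asarray(rs, dtype=float)
    ids = ids or [f"s{i}" for i in range(len(ts))]
    return pd.DataFrame({"sample_id": ids, "ts": ts, "rs": rs})


class TestKmeans1D:
    def test_two_cluster_centroids_exact(self):
        centroids = kmeans_1d([-1, -1, -1, 1, 1, 1], 2)
        np.testing.assert_allclose(centroids, [-1, 1])

    def test_three_cluster_centroids_exact(self):
        centroids = kmeans_1d([0, 0, 0, 1, 1, 1, 2, 2, 2], 3)
        np.testing.assert_allclose(centroids, [0, 1, 2])

    def test_finds_global_optimum_under_imbalance(self, rng):
        # a dominant cluster plus two small ones: the optimal partition
        # separates the three, regardless of their sizes
        x = np.concatenate(
            [rng.normal(0, 0.05, 100), rng.normal(3, 0.05, 8), rng.normal(6, 0.05, 5)]
        )
        centroids = kmeans_1d(x, 3)
        np.testing.assert_allclose(centroids, [0, 3, 6], atol=0.2)

    def test_permutation_invariant(self, rng):
        x = rng.normal(size=40)
        np.testing.assert_array_equal(kmeans_1d(x, 3), kmeans_1d(rng.permutation(x), 3))

    def test_k_bounds(self):
        with pytest.raises(ValueError):
            kmeans_1d([1.0, 2.0], 3)


class TestFitThresholds:
    def test_symmetric_two_cluster_midpoint(self):
        model = fit_thresholds(scores_frame([-1, -1, -1, 1, 1, 1]))
        assert model.tau_ts == pytest.approx(0.0)

    def test_rs_cut_points_from_three_clusters(self):
        ts = np.concatenate([[-5.0, -5.0, -5.0], np.full(9, 1.0)])
        rs = np.concatenate([[0.0, 0.0, 0.0], [0, 0, 0, 1, 1, 1, 2, 2, 2]])
        model = fit_thresholds(scores_frame(ts, rs))
        assert model.c_low == pytest.approx(0.5)
        assert model.c_high == pytest.approx(1.5)

    def test_refit_is_deterministic(self, rng):
        scores = scores_frame(rng.normal(size=30), rng.normal(size=30))
        a = fit_thresholds(scores)
        b = fit_thresholds(scores)
        assert (a.tau_ts, a.c_low, a.c_high) == (b.tau_ts, b.c_low, b.c_high)

    def test_sample_order_does_not_matter(self, rng):
        scores = scores_frame(rng.normal(size=30), rng.normal(size=30))
        shuffled = scores.sample(frac=1, random_state=0).reset_index(drop=True)
        a = fit_thresholds(scores)
        b = fit_thresholds(shuffled)
        assert (a.tau_ts, a.c_low, a.c_high) == (b.tau_ts, b.c_low, b.c_high)

    def test_few_tumor_samples_fall_back_to_tertiles(self, caplog):
        ts = [-1.0, -1.0, -1.0, 5.0, 5.0]
        rs = [0.0, 0.1, 0.2, 0.5, 0.5]
        with caplog.at_level(logging.WARNING):
            model = fit_thresholds(scores_frame(ts, rs))
        assert model.method == "fixed"
        assert "tertile" in caplog.text

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            fit_thresholds(scores_frame([1.0, 2.0, 3.0]))


class TestAssignClasses:
    @pytest.fixture
    def model(self):
        return StratificationModel(tau_ts=0.0, c_low=1.0, c_high=2.0, method="fixed")

    def test_four_quadrants(self, model):
        scores = scores_frame(
            ts=[-1.0, 1.0, 1.0, 1.0], rs=[5.0, 0.5, 1.5, 2.5]
        )
        out = assign_classes(scores, model)
        assert out["class_id"].tolist() == [1, 2, 3, 4]
        assert out["class_name"].tolist() == [CLASS_NAMES[i] for i in (1, 2, 3, 4)]

    def test_rs_ignored_for_normal_like(self, model):
        out = assign_classes(scores_frame([-0.5], [100.0]), model)
        assert out["class_id"].tolist() == [1]

    def test_boundary_ties_go_to_higher_class(self, model):
        out = assign_classes(
            scores_frame(ts=[0.0, 1.0, 1.0], rs=[0.0, 1.0, 2.0]), model
        )
        # ts exactly at tau -> tumor-like; rs exactly at cut -> higher class
        assert out["class_id"].tolist() == [2, 3, 4]

    def test_monotone_in_rs_and_ts(self, model, rng):
        ts = rng.normal(size=50)
        rs = rng.normal(size=50)
        base = assign_classes(scores_frame(ts, rs), model)["class_id"]
        higher_rs = assign_classes(scores_frame(ts, rs + 0.8), model)["class_id"]
        tumor = ts >= model.tau_ts
        assert (higher_rs[tumor] >= base[tumor]).all()
        higher_ts = assign_classes(scores_frame(ts + 0.8, rs), model)["class_id"]
        assert not ((base > 1) & (higher_ts == 1)).any()

    def test_non_finite_scores_rejected(self, model):
        with pytest.raises(ValueError, match="non-finite"):
            assign_classes(scores_frame([np.nan], [0.0]), model)

    def test_well_separated_scores_recover_latent_classes(self, rng):
        # cluster gaps far exceed within-cluster spread -> exact recovery
        latent = rng.integers(1, 5, size=120)
        ts = np.where(latent == 1, -10.0, 10.0) + rng.normal(0, 0.1, 120)
        rs = np.select(
            [latent == 2, latent == 3, latent == 4], [0.0, 6.0, 12.0], default=0.0
        ) + rng.normal(0, 0.1, 120)
        scores = scores_frame(ts, rs)
        model = fit_thresholds(scores)
        out = assign_classes(scores, model)
        assert (out["class_id"].to_numpy() == latent).all()


class TestModelValidation:
    def test_cut_order_enforced(self):
        with pytest.raises(ValueError, match="c_low"):
            StratificationModel(tau_ts=0.0, c_low=2.0, c_high=1.0)

    def test_finite_thresholds_required(self):
        with pytest.raises(ValueError, match="finite"):
            StratificationModel(tau_ts=np.inf, c_low=0.0, c_high=1.0)


class TestStratificationReport:
    def _assignment(self, class_ids, ids=None):
        ids = ids or [f"s{i}" for i in range(len(class_ids))]
        return pd.DataFrame(
            {
                "sample_id": ids,
                "ts": np.zeros(len(class_ids)),
                "rs": np.zeros(len(class_ids)),
                "class_id": class_ids,
                "class_name": [CLASS_NAMES[c] for c in class_ids],
            }
        )

    def _annotation(self, groups, ids=None):
        ids = ids or [f"s{i}" for i in range(len(groups))]
        return pd.DataFrame({"sample_id": ids, "group": groups})

    def test_cross_tab_rows_sum_to_group_sizes(self):
        assignment = self._assignment([1, 2, 2, 3, 4, 4])
        annotation = self._annotation(
            ["normal", "primary", "primary", "primary", "recurrent", "recurrent"]
        )
        report = stratification_report(assignment, annotation)
        row_sums = report["by_group"].sum(axis=1)
        assert row_sums["normal"] == 1
        assert row_sums["primary"] == 3
        assert row_sums["recurrent"] == 2
        assert report["classes_observed"] == [1, 2, 3, 4]

    def test_single_class_degenerate(self):
        assignment = self._assignment([2, 2, 2])
        annotation = self._annotation(["primary"] * 3)
        report = stratification_report(assignment, annotation)
        assert report["classes_observed"] == [2]
        assert report["class_counts"] == {2: 3}

    def test_id_mismatch_is_error(self):
        assignment = self._assignment([1, 2])
        annotation = self._annotation(["normal"], ids=["other"])
        with pytest.raises(ValueError, match="ids do not match"):
            stratification_report(assignment, annotation)
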