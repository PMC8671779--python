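"""Clustering, stability, discriminant validation, and projection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone
from sklearn.metrics import adjusted_rand_score

from eegbiotype import (
    BiotypeClustering,
    BiotypeDiscriminant,
    clara_consistency,
    fit_discriminant,
    jackknife_accuracy,
    kmeans_best_silhouette,
    match_labels,
    project,
    rerun_excluding,
    select_k,
    simulate_feature_cohort,
    zscore,
)
from eegbiotype.validity import majority_k


@pytest.fixture(scope="module")
def blobs():
    table, labels = simulate_feature_cohort(60, separation=3.0, seed=17)
    return table, labels


class TestZScore:
    def test_columns_standardised(self, blobs):
        z, _ = zscore(blobs[0])
        np.testing.assert_allclose(z.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(ddof=0), 1.0, atol=1e-12)

    def test_constant_column_error_names_column(self, blobs):
        bad = blobs[0].copy()
        bad["cs_prestim"] = 3.0
        with pytest.raises(ValueError, match="cs_prestim"):
            zscore(bad)

    def test_projection_of_training_table_is_idempotent(self, blobs):
        z, params = zscore(blobs[0])
        np.testing.assert_allclose(
            params.transform(blobs[0]), z.to_numpy(), atol=1e-12
        )

    def test_feature_mismatch_lists_missing_columns(self, blobs):
        _, params = zscore(blobs[0])
        with pytest.raises(ValueError, match="sw_modulation"):
            params.transform(blobs[0].drop(columns=["sw_modulation"]))


class TestSelectK:
    def test_majority_vote(self):
        votes = dict(
            [(f"i{n}", 2) for n in range(10)]
            + [(f"j{n}", 3) for n in range(8)]
            + [(f"k{n}", 4) for n in range(8)]
        )
        assert majority_k(votes) == 2

    def test_draw_broken_toward_smallest(self):
        votes = dict(
            [(f"i{n}", 3) for n in range(9)] + [(f"j{n}", 2) for n in range(9)]
        )
        assert majority_k(votes) == 2

    def test_two_blobs_select_two(self, blobs):
        z, _ = zscore(blobs[0])
        k, votes = select_k(z, k_range=(2, 8), seed=0)
        assert k == 2
        assert len(votes) >= 12

    def test_too_few_subjects_rejected(self):
        table, _ = simulate_feature_cohort(3, separation=1.0, seed=0)
        with pytest.raises(ValueError, match="subjects"):
            select_k(table, k_range=(2, 8), seed=0)


class TestKMeansBestSilhouette:
    def test_recovers_separated_blobs(self, blobs):
        table, labels = blobs
        z, _ = zscore(table)
        sol = kmeans_best_silhouette(z, k=2, seed=0)
        assert adjusted_rand_score(labels, sol.labels) >= 0.9
        assert len(sol.restart_seeds) == 50

    def test_winning_centroids_are_a_fixed_point(self, blobs):
        from sklearn.cluster import KMeans

        z, _ = zscore(blobs[0])
        sol = kmeans_best_silhouette(z, k=2, seed=0)
        km = KMeans(
            n_clusters=2, init=sol.cluster_centers_, n_init=1, max_iter=1
        ).fit(z.to_numpy())
        _, agreement = match_labels(sol.labels, km.labels_)
        assert agreement == 1.0

    def test_deterministic_under_seed(self, blobs):
        z, _ = zscore(blobs[0])
        a = kmeans_best_silhouette(z, k=2, seed=5)
        b = kmeans_best_silhouette(z, k=2, seed=5)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.silhouette == b.silhouette


class TestClaraConsistency:
    def test_unambiguous_geometry_gives_full_agreement(self):
        table, labels = simulate_feature_cohort(40, separation=8.0, seed=2)
        z, _ = zscore(table)
        sol = kmeans_best_silhouette(z, k=2, seed=0)
        agreement, _ = clara_consistency(z, 2, sol.labels, seed=0)
        assert agreement == 1.0

    def test_three_sd_blobs_reach_published_agreement(self, blobs):
        table, _ = blobs
        z, _ = zscore(table)
        sol = kmeans_best_silhouette(z, k=2, seed=0)
        agreement, _ = clara_consistency(z, 2, sol.labels, seed=0)
        assert agreement >= 0.96

    def test_degenerate_k_rejected(self, blobs):
        z, _ = zscore(blobs[0])
        with pytest.raises(ValueError, match="k < 2"):
            clara_consistency(z, 1, np.zeros(len(z), dtype=int))

    def test_subset_smaller_than_k_rejected(self, blobs):
        z, _ = zscore(blobs[0])
        with pytest.raises(ValueError, match="subset"):
            clara_consistency(
                z, 3, np.zeros(len(z), dtype=int), subset_size=2
            )


class TestDiscriminant:
    def test_axis_aligned_separation_dominates_coefficients(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((80, 6))
        y = np.repeat([0, 1], 40)
        x[y == 1, 0] += 5.0
        model = fit_discriminant(pd.DataFrame(x, columns=list("abcdef")), y)
        coefs = model.coefficients_.abs()
        assert coefs["a"] > 3 * coefs.drop("a").max()

    def test_class_swap_negates_coefficients(self, blobs):
        table, labels = blobs
        z, _ = zscore(table)
        m1 = fit_discriminant(z, labels)
        m2 = fit_discriminant(z, 1 - labels)
        np.testing.assert_allclose(
            m1.coefficients_.to_numpy(),
            -m2.coefficients_.to_numpy(),
            rtol=1e-6,
        )
        assert jackknife_accuracy(z, labels) == pytest.approx(
            jackknife_accuracy(z, 1 - labels)
        )

    def test_group_with_larger_means_scores_higher(self, blobs):
        table, labels = blobs
        z, _ = zscore(table)
        model = fit_discriminant(z, labels)
        scores = model.scores_
        # group 1 sits at the positive centroid in every feature
        assert scores[labels == 1].mean() > scores[labels == 0].mean()

    def test_scaled_coefficients_anchor_modulation_pl_at_one(self, blobs):
        table, labels = blobs
        model = fit_discriminant(table, labels)
        assert model.coefficients_scaled_["pl_modulation"] == pytest.approx(1.0)

    def test_singular_covariance_suggests_shrinkage(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((30, 3))
        x = np.hstack([x, x[:, :1]])  # duplicated feature
        y = np.repeat([0, 1], 15)
        with pytest.raises(ValueError, match="shrinkage"):
            fit_discriminant(x, y)
        model = BiotypeDiscriminant(shrinkage=0.1).fit(x, y)
        assert len(model.coefficients_) == 4

    def test_class_size_requirements(self):
        x = np.random.default_rng(0).standard_normal((5, 2))
        with pytest.raises(ValueError, match="two classes"):
            fit_discriminant(x, np.zeros(5))
        with pytest.raises(ValueError, match=">= 2 members"):
            fit_discriminant(x, np.array([0, 0, 0, 0, 1]))


class TestJackknife:
    def test_linearly_separable_classes_reach_one(self):
        table, labels = simulate_feature_cohort(30, separation=8.0, seed=3)
        z, _ = zscore(table)
        assert jackknife_accuracy(z, labels) == 1.0

    def test_permuted_labels_fall_to_chance(self, blobs):
        table, _ = blobs
        z, _ = zscore(table)
        rng = np.random.default_rng(8)
        perm = rng.permutation(np.repeat([0, 1], 60))
        acc = jackknife_accuracy(z, perm)
        n = len(perm)
        assert abs(acc - 0.5) <= 3 * np.sqrt(0.25 / n)

    def test_unseparated_groups_fall_to_chance(self):
        table, labels = simulate_feature_cohort(50, separation=0.0, seed=9)
        z, _ = zscore(table)
        acc = jackknife_accuracy(z, labels)
        assert abs(acc - 0.5) <= 3 * np.sqrt(0.25 / len(labels))

    def test_vanishing_class_fold_skipped_with_warning(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((7, 2))
        x[5:, 0] += 8.0
        y = np.array([0, 0, 0, 0, 0, 1, 1])
        with pytest.warns(UserWarning, match="skipped"):
            jackknife_accuracy(x, y)


class TestProjection:
    def test_training_projection_matches_training_classification(self, blobs):
        table, labels = blobs
        z, params = zscore(table)
        model = fit_discriminant(z, labels)
        out = project(model, table, params)
        np.testing.assert_array_equal(out["labels"], model.predict(z))

    def test_replication_cohort_agreement(self):
        main, _ = simulate_feature_cohort(60, separation=3.0, seed=30)
        repl, _ = simulate_feature_cohort(30, separation=3.0, seed=31)
        z, params = zscore(main)
        clus = kmeans_best_silhouette(z, k=2, seed=0)
        model = fit_discriminant(z, clus.labels)
        repl_clus = BiotypeClustering(k=2, random_state=0).fit(repl)
        out = project(model, repl, params,
                      reference_labels=repl_clus.labels_)
        assert out["agreement"] >= 0.8

    def test_control_scores_fall_between_group_means(self):
        main, labels = simulate_feature_cohort(60, separation=3.0, seed=32)
        controls, _ = simulate_feature_cohort(20, separation=0.0, seed=33)
        z, params = zscore(main)
        model = fit_discriminant(z, labels)
        out = project(model, controls, params)
        g0 = model.scores_[labels == 0].mean()
        g1 = model.scores_[labels == 1].mean()
        lo, hi = sorted((g0, g1))
        assert lo < np.mean(out["scores"]) < hi


class TestRerunExcluding:
    def test_excluding_nobody_reproduces_solution(self, blobs):
        table, _ = blobs
        base = BiotypeClustering(k=2, random_state=4).fit(table)
        sol, crosstab = rerun_excluding(
            table,
            np.zeros(len(table), dtype=bool),
            base_labels=base.labels_,
            k=2,
            random_state=4,
        )
        np.testing.assert_array_equal(sol.labels, base.labels_)
        assert crosstab.to_numpy().sum() == len(table)

    def test_excluding_ten_percent_leaves_labels_stable(self, blobs):
        table, _ = blobs
        base = BiotypeClustering(k=2, random_state=4).fit(table)
        rng = np.random.default_rng(0)
        mask = np.zeros(len(table), dtype=bool)
        mask[rng.choice(len(table), 12, replace=False)] = True
        sol, _ = rerun_excluding(
            table, mask, base_labels=base.labels_, k=2, random_state=4
        )
        _, agreement = match_labels(base.labels_[~mask], sol.labels)
        assert agreement == 1.0

    def test_excluding_constructed_outlier_restores_clean_solution(self):
        table, labels = simulate_feature_cohort(30, separation=4.0, seed=40)
        outlier = table.iloc[:1] * 0 + 50.0
        spiked = pd.concat([table, outlier], ignore_index=True)
        mask = np.zeros(len(spiked), dtype=bool)
        mask[-1] = True
        sol, _ = rerun_excluding(spiked, mask, k=2, random_state=1)
        _, agreement = match_labels(labels, sol.labels)
        assert agreement == 1.0

    def test_too_few_retained_rejected(self, blobs):
        table, _ = blobs
        mask = np.ones(len(table), dtype=bool)
        mask[:3] = False
        with pytest.raises(ValueError, match="retained"):
            rerun_excluding(table, mask, k=2, random_state=0)


class TestEstimatorContract:
    def test_fit_attributes_and_determinism(self, blobs):
        table, labels = blobs
        m1 = BiotypeClustering(k_range=(2, 5), random_state=7).fit(table)
        m2 = BiotypeClustering(k_range=(2, 5), random_state=7).fit(table)
        assert m1.k_ == m2.k_ == 2
        np.testing.assert_array_equal(m1.labels_, m2.labels_)
        assert m1.stability_agreement_ == m2.stability_agreement_
        assert m1.silhouette_ == m2.silhouette_
        assert adjusted_rand_score(labels, m1.labels_) >= 0.9

    def test_sklearn_clone_and_params_round_trip(self):
        model = BiotypeClustering(k=2, n_init=10, random_state=3)
        cloned = clone(model)
        assert cloned.get_params() == model.get_params()
        disc = BiotypeDiscriminant(shrinkage=0.2)
        assert clone(disc).get_params() == {"shrinkage": 0.2}

    def test_predict_routes_new_points_to_nearest_centroid(self, blobs):
        table, labels = blobs
        model = BiotypeClustering(k=2, random_state=0).fit(table)
        pred = model.predict(table)
        np.testing.assert_array_equal(pred, model.labels_)


class TestLabelMatching:
    def test_permutation_invariance_of_agreement(self, rng):
        a = rng.integers(0, 2, 50)
        b = 1 - a
        relabelled, agreement = match_labels(a, b)
        assert agreement == 1.0
        np.testing.assert_array_equal(relabelled, a)
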