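"""Metric closed forms and brute-force oracles: FID, Coverage, batch-mixing
scores, cluster impurity, random-forest importances."""

import numpy as np
import pytest

from cellstyle.metrics import (
    FeatureMoments,
    FeatureProbeClassifier,
    batch_mixing_scores,
    cluster_impurity,
    coverage,
    extract_features,
    fid,
    fid_from_features,
    moa_accuracy,
    rf_feature_importance,
)
from cellstyle.synth import BatchEffectSpec, PhenotypeSpec, make_dataset


def eig_fid(m_r, C_r, m_g, C_g):
    """Independent FID evaluation: trace term via the eigenvalues of
    C_r^{1/2} C_g C_r^{1/2} (symmetric route, no scipy sqrtm)."""
    wr, vr = np.linalg.eigh(C_r)
    r_half = vr @ np.diag(np.sqrt(np.clip(wr, 0, None))) @ vr.T
    inner = r_half @ C_g @ r_half
    wi = np.clip(np.linalg.eigvalsh(inner), 0, None)
    diff = np.asarray(m_g) - np.asarray(m_r)
    return float(
        diff @ diff + np.trace(C_g) + np.trace(C_r) - 2 * np.sqrt(wi).sum()
    )


class TestFID:
    def test_identical_moments_give_zero(self):
        rng = np.random.default_rng(0)
        feats = rng.standard_normal((50, 4))
        assert abs(fid_from_features(feats, feats)) < 1e-9

    def test_one_dimensional_closed_form(self):
        a = FeatureMoments(mean=np.array([0.0]), cov=np.array([[1.0]]), n=10)
        b = FeatureMoments(mean=np.array([1.0]), cov=np.array([[1.0]]), n=10)
        assert abs(fid(a, b) - 1.0) < 1e-12

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(1)
        fr = rng.standard_normal((200, 3)) @ rng.standard_normal((3, 3))
        fg = rng.standard_normal((180, 3)) @ rng.standard_normal((3, 3)) + 0.3
        mr, Cr = fr.mean(0), np.cov(fr, rowvar=False)
        mg, Cg = fg.mean(0), np.cov(fg, rowvar=False)
        ours = fid(FeatureMoments(mr, Cr, 200), FeatureMoments(mg, Cg, 180))
        assert abs(ours - eig_fid(mr, Cr, mg, Cg)) < 1e-6

    def test_symmetric(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((60, 4))
        b = rng.standard_normal((60, 4)) * 2.0 + 1.0
        assert abs(fid_from_features(a, b) - fid_from_features(b, a)) < 1e-8

    def test_commuting_covariances_closed_form(self):
        # diagonal covariances commute: trace term = sum (sqrt(a)-sqrt(b))^2
        Ca, Cb = np.diag([1.0, 4.0]), np.diag([9.0, 1.0])
        a = FeatureMoments(np.zeros(2), Ca, 10)
        b = FeatureMoments(np.zeros(2), Cb, 10)
        expected = (1 - 3) ** 2 * 1.0 + (2 - 1) ** 2
        assert abs(fid(a, b) - expected) < 1e-9

    def test_dimension_mismatch_rejected(self):
        a = FeatureMoments(np.zeros(2), np.eye(2), 5)
        b = FeatureMoments(np.zeros(3), np.eye(3), 5)
        with pytest.raises(ValueError, match="dimensionalities"):
            fid(a, b)


def brute_force_coverage(real, gen, k):
    n = len(real)
    hits = 0
    for i in range(n):
        dists = sorted(np.linalg.norm(real - real[i], axis=1))
        radius = dists[k]  # k-th neighbour (index 0 is self)
        if any(np.linalg.norm(gen - real[i], axis=1) <= radius):
            hits += 1
    return hits / n


class TestCoverage:
    def test_generated_equals_real_is_fully_covered(self):
        rng = np.random.default_rng(0)
        real = rng.standard_normal((10, 2))
        assert coverage(real, real.copy(), k=1) == 1.0

    def test_distant_generated_covers_nothing(self):
        rng = np.random.default_rng(1)
        real = rng.standard_normal((12, 2))
        assert coverage(real, real + 1e6, k=2) == 0.0

    def test_matches_brute_force_on_small_sets(self):
        rng = np.random.default_rng(2)
        real = rng.standard_normal((6, 2))
        gen = rng.standard_normal((4, 2))
        assert coverage(real, gen, k=2) == brute_force_coverage(real, gen, 2)

    def test_monotone_in_k(self):
        rng = np.random.default_rng(3)
        real = rng.standard_normal((30, 3))
        gen = rng.standard_normal((25, 3)) + 0.5
        values = [coverage(real, gen, k) for k in (1, 2, 4, 8)]
        assert all(a <= b for a, b in zip(values, values[1:]))

    def test_invalid_k_rejected(self):
        real = np.zeros((5, 2))
        with pytest.raises(ValueError, match="k"):
            coverage(real, real, k=5)


class TestBatchMixing:
    def test_identical_point_clouds_mix_perfectly(self):
        rng = np.random.default_rng(0)
        cloud = rng.standard_normal((40, 3))
        feats = np.vstack([cloud, cloud + 1e-9])
        labels = np.array([0] * 40 + [1] * 40)
        asw, ilisi = batch_mixing_scores(feats, labels, k=10)
        assert ilisi > 0.95
        assert asw > 0.95

    def test_separated_batches_score_zero(self):
        rng = np.random.default_rng(1)
        feats = np.vstack(
            [rng.standard_normal((30, 3)), rng.standard_normal((30, 3)) + 100.0]
        )
        labels = np.array([0] * 30 + [1] * 30)
        _, ilisi = batch_mixing_scores(feats, labels, k=10)
        assert ilisi < 0.05

    def test_ilisi_matches_hand_computed_inverse_simpson(self):
        feats = np.array(
            [[0.0], [0.1], [0.2], [0.3], [10.0], [10.1], [10.2], [10.3]]
        )
        labels = np.array([0, 1, 0, 1, 0, 0, 1, 1])
        k = 3
        simpson = []
        for i in range(8):
            order = np.argsort(np.abs(feats[:, 0] - feats[i, 0]))
            neigh = [j for j in order if j != i][:k]
            p0 = np.mean(labels[neigh] == 0)
            p1 = np.mean(labels[neigh] == 1)
            simpson.append(1.0 / (p0**2 + p1**2))
        expected = (np.mean(simpson) - 1.0) / 1.0
        _, ilisi = batch_mixing_scores(feats, labels, k=k)
        assert abs(ilisi - np.clip(expected, 0, 1)) < 1e-9

    def test_single_batch_rejected(self):
        with pytest.raises(ValueError, match="two batches"):
            batch_mixing_scores(np.zeros((10, 2)), np.zeros(10))


class TestClusterImpurity:
    def test_pure_cluster_scores_zero(self):
        feats = np.zeros((6, 2))
        labels = np.zeros(6, dtype=int)
        clusters = np.zeros(6, dtype=int)
        h, g, _ = cluster_impurity(feats, labels, clustering=clusters)
        assert h == 0.0 and g == 0.0

    def test_uniform_two_batch_cluster_closed_form(self):
        labels = np.array([0, 1, 0, 1])
        clusters = np.zeros(4, dtype=int)
        h, g, _ = cluster_impurity(np.zeros((4, 2)), labels, clustering=clusters)
        assert abs(h - 1.0) < 1e-12
        assert abs(g - 0.5) < 1e-12

    def test_three_to_one_frequencies_match_formulas(self):
        labels = np.array([0, 0, 0, 1])
        clusters = np.zeros(4, dtype=int)
        h, g, _ = cluster_impurity(np.zeros((4, 2)), labels, clustering=clusters)
        expected_h = -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))
        assert abs(h - expected_h) < 1e-12
        assert abs(g - (1 - 0.75**2 - 0.25**2)) < 1e-12

    def test_means_are_unweighted_across_clusters(self):
        labels = np.array([0, 1] + [0] * 10)
        clusters = np.array([0, 0] + [1] * 10)
        h, g, _ = cluster_impurity(np.zeros((12, 1)), labels, clustering=clusters)
        assert abs(h - 0.5) < 1e-12  # (1.0 + 0.0) / 2

    def test_bounds_at_uniform_frequencies(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 3, size=60)
        clusters = rng.integers(0, 4, size=60)
        h, g, df = cluster_impurity(rng.standard_normal((60, 2)), labels,
                                    clustering=clusters)
        assert 0.0 <= h <= np.log2(3) + 1e-12
        assert 0.0 <= g <= 1 - 1 / 3 + 1e-12

    def test_leiden_default_runs_on_small_data(self):
        rng = np.random.default_rng(1)
        feats = np.vstack(
            [rng.standard_normal((20, 2)), rng.standard_normal((20, 2)) + 8.0]
        )
        labels = np.array([0] * 20 + [1] * 20)
        h, g, df = cluster_impurity(feats, labels)
        assert len(df) >= 1
        assert np.isfinite(h) and np.isfinite(g)


class TestRandomForestImportance:
    def test_separating_feature_ranks_first(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 5))
        y = (X[:, 2] > 0).astype(int)
        X[:, 2] += y * 3.0
        ranked, oob = rf_feature_importance(X, y, n_runs=3, n_trees=100)
        assert ranked["feature"].iloc[0] == "f2"
        assert oob > 0.8

    def test_pure_noise_has_no_stable_ranking(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((80, 4))
        y = rng.integers(0, 2, size=80)
        ranked, _ = rf_feature_importance(X, y, n_runs=3, n_trees=100)
        spread = ranked["importance"].max() - ranked["importance"].min()
        assert spread < 0.15
        assert len(ranked) == 4

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            rf_feature_importance(np.zeros((10, 2)), np.zeros(10))


class TestClassificationScores:
    class Oracle:
        def __init__(self, labels, classes=None):
            self._labels = np.asarray(labels)
            self.classes_ = (
                np.asarray(classes) if classes is not None
                else np.unique(self._labels)
            )

        def predict(self, images):
            return self._labels[: len(images)]

    def test_oracle_classifier_scores_one(self):
        imgs = np.zeros((5, 1, 8, 8))
        labels = np.array([0, 1, 0, 1, 0])
        assert moa_accuracy(imgs, labels, self.Oracle(labels)) == 1.0

    def test_fixed_wrong_label_scores_zero(self):
        imgs = np.zeros((4, 1, 8, 8))
        clf = self.Oracle(np.array([1, 1, 1, 1]), classes=[0, 1])
        assert moa_accuracy(imgs, np.zeros(4, dtype=int), clf) == 0.0

    def test_unknown_target_label_rejected(self):
        clf = self.Oracle(np.array([0, 0]))
        with pytest.raises(ValueError, match="absent"):
            moa_accuracy(np.zeros((2, 1, 8, 8)), np.array([0, 5]), clf)

    def test_probe_separates_well_separated_synthetic_conditions(self):
        specs = [
            PhenotypeSpec(condition_id=0, intensity_gain=(1.0, 1.0, 1.0)),
            PhenotypeSpec(condition_id=1, intensity_gain=(1.0, 0.4, 0.4)),
        ]
        ds = make_dataset(specs, [BatchEffectSpec(batch_id=0)], 20, size=32,
                          seed=5)
        train = ds.training_set(split="train")
        test = ds.training_set(split="test")
        probe = FeatureProbeClassifier(seed=0).fit(train.images, train.condition_ids)
        assert probe.score(test.images, test.condition_ids) > 0.95


class TestFeatureExtraction:
    def test_identical_images_identical_rows(self):
        img = np.random.default_rng(0).uniform(-1, 1, size=(1, 3, 16, 16))
        feats = extract_features(np.repeat(img, 3, axis=0))
        assert np.array_equal(feats[0], feats[1]) and np.array_equal(feats[1], feats[2])

    def test_constant_image_has_zero_texture_variance(self):
        feats = extract_features(np.zeros((1, 3, 16, 16)))
        # per-channel std and laplacian variance are zero
        assert feats[0][1] == 0.0 and feats[0][5] == 0.0

    def test_unregistered_extractor_lists_registry(self):
        with pytest.raises(KeyError, match="morphology"):
            extract_features(np.zeros((1, 1, 8, 8)), extractor="nope")
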