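"""Standardization, PCA, K-means, medoid picking and the full selection
pipeline, each checked against exhaustive or closed-form oracles."""

import numpy as np
import pandas as pd
import pytest

from loopshape import (
    InputError,
    ScoreRecord,
    SelectionConfig,
    kmeans_cluster,
    lowest_dope,
    pca_reduce,
    run_selection,
    select_representatives,
    standardize,
    three_regime_ensemble,
)
from loopshape.descriptors import descriptor_matrix


class TestStandardize:
    def test_unit_sample_sd_column(self):
        out = standardize(pd.DataFrame({"x": [9.0, 10.0, 11.0]}))
        assert np.allclose(out["x"], [-1.0, 0.0, 1.0])

    def test_constant_column_zeroed_with_warning(self):
        with pytest.warns(UserWarning, match="zero variance"):
            out = standardize(pd.DataFrame({"x": [5.0, 5.0, 5.0], "y": [1.0, 2.0, 3.0]}))
        assert (out["x"] == 0.0).all()

    def test_idempotent(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        once = standardize(df)
        twice = standardize(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_missing_values_named(self):
        df = pd.DataFrame({"good": [1.0, 2.0], "bad": [1.0, np.nan]})
        with pytest.raises(InputError, match="bad"):
            standardize(df)


class TestPCA:
    def test_exactly_correlated_features_need_one_component(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        df = standardize(pd.DataFrame({"x": x, "y": 2 * x}))
        scores, loadings, explained = pca_reduce(df, 0.95)
        assert scores.shape[1] == 1
        assert explained[0] == pytest.approx(1.0)

    def test_isotropic_gaussian_needs_all_components(self, rng):
        df = standardize(pd.DataFrame(rng.normal(size=(2000, 3)), columns=list("abc")))
        scores, _, explained = pca_reduce(df, 0.95)
        assert scores.shape[1] == 3  # near-equal eigenvalues: no 2 of 3 reach 95%

    def test_full_projection_reconstructs(self, rng):
        df = standardize(pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde")))
        scores, loadings, _ = pca_reduce(df, 1.0)
        reconstructed = scores @ loadings.T
        assert np.allclose(reconstructed, df.to_numpy(), atol=1e-10)

    def test_agrees_with_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(60, 6))
        df = standardize(pd.DataFrame(X, columns=list("abcdef")))
        _, loadings, explained = pca_reduce(df, 1.0)
        cov = np.cov(df.to_numpy(), rowvar=False, ddof=1)
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        assert np.allclose(explained, eigvals[: len(explained)] / eigvals.sum(), atol=1e-9)
        for j in range(loadings.shape[1]):
            v = eigvecs[:, j]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            assert np.allclose(loadings[:, j], v, atol=1e-9)

    def test_largest_loading_positive_sign_convention(self, rng):
        df = standardize(pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd")))
        _, loadings, _ = pca_reduce(df, 1.0)
        for j in range(loadings.shape[1]):
            assert loadings[np.argmax(np.abs(loadings[:, j])), j] > 0


class TestKMeans:
    def test_recovers_well_separated_blobs(self, rng):
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [5.0, 10.0 * np.sqrt(3) / 2 * 2]])
        pts = np.vstack([c + rng.normal(0, 0.1, size=(100, 2)) for c in centers])
        truth = np.repeat([0, 1, 2], 100)
        labels, _ = kmeans_cluster(pts, k=3, seed=0)
        # partition must match exactly, up to label permutation
        for blob in range(3):
            assert len(set(labels[truth == blob])) == 1
        assert len(set(labels)) == 3

    def test_k_one_is_global_mean(self, rng):
        pts = rng.normal(size=(20, 3))
        labels, centroids = kmeans_cluster(pts, k=1, seed=0)
        assert (labels == 0).all()
        assert np.allclose(centroids[0], pts.mean(axis=0))

    def test_k_equals_n_zero_inertia(self, rng):
        pts = rng.uniform(size=(6, 2)) * 100
        labels, centroids = kmeans_cluster(pts, k=6, seed=0)
        assert len(set(labels)) == 6
        inertia = sum(np.sum((pts[i] - centroids[labels[i]]) ** 2) for i in range(6))
        assert inertia == pytest.approx(0.0, abs=1e-9)

    def test_k_above_n_rejected(self, rng):
        with pytest.raises(InputError):
            kmeans_cluster(rng.normal(size=(3, 2)), k=4, seed=0)

    def test_deterministic_for_fixed_seed(self, rng):
        pts = rng.normal(size=(200, 3))
        a, _ = kmeans_cluster(pts, k=4, seed=7)
        b, _ = kmeans_cluster(pts, k=4, seed=7)
        assert (a == b).all()


class TestMedoid:
    def test_singleton_cluster(self):
        reps = select_representatives(np.array([[0.0], [5.0]]), [0, 1], ["a", "b"])
        assert reps == [(0, "a"), (1, "b")]

    def test_collinear_members_exhaustive(self):
        pts = np.array([[0.0], [1.0], [10.0]])
        reps = select_representatives(pts, [0, 0, 0], ["p0", "p1", "p10"])
        # distance sums: 0 -> 11, 1 -> 10, 10 -> 19
        assert reps == [(0, "p1")]

    def test_symmetric_tie_takes_lower_index(self):
        reps = select_representatives(np.array([[-1.0], [1.0]]), [0, 0], ["first", "second"])
        assert reps == [(0, "first")]

    def test_medoid_matches_exhaustive_search(self, rng):
        pts = rng.normal(size=(40, 3))
        labels = rng.integers(0, 3, size=40)
        ids = [f"m{i}" for i in range(40)]
        reps = dict(select_representatives(pts, labels, ids))
        for cluster in range(3):
            idx = np.flatnonzero(labels == cluster)
            sums = [sum(np.linalg.norm(pts[i] - pts[j]) for j in idx) for i in idx]
            assert reps[cluster] == ids[idx[int(np.argmin(sums))]]


class TestLowestDope:
    def test_minimum_and_tie_rules(self):
        records = [ScoreRecord("m1", -100, 0), ScoreRecord("m2", -120, 0), ScoreRecord("m3", -90, 0)]
        assert lowest_dope(records) == "m2"
        assert lowest_dope([ScoreRecord("only", 1.0, 1.0)]) == "only"
        assert lowest_dope([ScoreRecord("m1", -5, 0), ScoreRecord("m2", -5, 0)]) == "m1"
        with pytest.raises(InputError):
            lowest_dope([])


class TestRunSelection:
    @pytest.fixture(scope="class")
    def regimes(self):
        synth, labels = three_regime_ensemble(n_models=300, seed=7)
        matrix = descriptor_matrix(synth.ensemble, synth.loop_spec, scores=synth.scores)
        return synth, labels, matrix

    def test_one_representative_per_generating_regime(self, regimes):
        synth, truth, matrix = regimes
        with pytest.warns(UserWarning):  # fixed anchors: ach_ach_dist is constant
            result = run_selection(matrix, scores=synth.scores, config=SelectionConfig(k=3, seed=1))
        assert len(result.representatives) == 3
        id_to_pos = {m: i for i, m in enumerate(result.model_ids)}
        rep_regimes = {int(truth[id_to_pos[m]]) for _, m in result.representatives}
        assert rep_regimes == {0, 1, 2}
        # clusters reproduce the generating partition exactly
        for regime in range(3):
            assert len(set(result.labels[truth == regime])) == 1

    def test_four_candidates_with_dope_baseline(self, regimes):
        synth, _, matrix = regimes
        with pytest.warns(UserWarning):
            result = run_selection(matrix, scores=synth.scores, config=SelectionConfig(k=3, seed=1))
        candidates = [m for _, m in result.representatives] + [result.lowest_dope_id]
        assert len(candidates) == 4
        assert result.lowest_dope_id == min(synth.scores, key=lambda r: r.dope).model_id

    def test_representative_belongs_to_its_cluster(self, regimes):
        synth, _, matrix = regimes
        with pytest.warns(UserWarning):
            result = run_selection(matrix, scores=synth.scores, config=SelectionConfig(k=3, seed=1))
        id_to_pos = {m: i for i, m in enumerate(result.model_ids)}
        for cluster, model_id in result.representatives:
            assert result.labels[id_to_pos[model_id]] == cluster

    def test_deterministic(self, regimes):
        synth, _, matrix = regimes
        config = SelectionConfig(k=3, seed=42)
        with pytest.warns(UserWarning):
            a = run_selection(matrix, scores=synth.scores, config=config)
        with pytest.warns(UserWarning):
            b = run_selection(matrix, scores=synth.scores, config=config)
        assert a.representatives == b.representatives
        assert (a.labels == b.labels).all()
        assert np.allclose(a.explained_variance, b.explained_variance)

    def test_row_permutation_preserves_cluster_geometry(self, regimes):
        synth, _, matrix = regimes
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(matrix))
        shuffled = matrix.iloc[perm]
        config = SelectionConfig(k=3, seed=1, use_scores=False)
        with pytest.warns(UserWarning):
            a = run_selection(matrix, config=config)
        with pytest.warns(UserWarning):
            b = run_selection(shuffled, config=config)

        def inertia(result):
            total = 0.0
            for c in range(3):
                pts = result.reduced[result.labels == c]
                total += float(np.sum((pts - pts.mean(axis=0)) ** 2))
            return total

        assert inertia(a) == pytest.approx(inertia(b), abs=1e-9)

    def test_n_equals_k_each_model_its_own_cluster(self, regimes):
        synth, _, matrix = regimes
        small = matrix.iloc[:3]
        with pytest.warns(UserWarning):
            result = run_selection(small, config=SelectionConfig(k=3, seed=0, use_scores=False))
        assert sorted(m for _, m in result.representatives) == sorted(small.index)
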