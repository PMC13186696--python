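"""Feature assembly, PCA embedding, loadings and separation scoring."""

import numpy as np
import pandas as pd
import pytest

from glycoatlas.embedding import (
    FeatureMatrix,
    assemble_features,
    loadings_report,
    run_pca,
    separation_score,
)
from glycoatlas.errors import ParameterError, SchemaError
from glycoatlas.glyco import GlycoClassTable
from glycoatlas.nn import NNPeakMatrix


def peak_mat(labels, values):
    return NNPeakMatrix(list(labels), np.asarray(values, dtype=float), {})


def glyco_table(densities: dict):
    rows = [
        {"label": k, "size": 2, "count": 1, "density_per_um2": v} for k, v in densities.items()
    ]
    return GlycoClassTable(
        pd.DataFrame(rows, columns=["label", "size", "count", "density_per_um2"]),
        pd.DataFrame(), 1.0, 0, 0,
    )


def features(values, conditions=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return FeatureMatrix(
        [f"s{i}" for i in range(n)],
        conditions or [""] * n,
        [f"f{j}" for j in range(p)],
        values,
        np.zeros_like(values, dtype=bool),
    )


class TestAssembly:
    def test_nn_peaks_shape(self, rng):
        mats = [peak_mat("ABCDE", rng.uniform(1, 100, (5, 5))) for _ in range(2)]
        fm = assemble_features(mats, "nn_peaks")
        assert fm.values.shape == (2, 25)

    def test_absent_glyco_class_is_zero(self):
        a = glyco_table({"SNA+WGA": 2.0, "AAL+PSA": 1.0})
        b = glyco_table({"AAL+PSA": 3.0})
        fm = assemble_features([a, b], "glyco")
        col = fm.feature_names.index("density:SNA+WGA")
        assert fm.values[1, col] == 0.0

    def test_missing_peaks_imputed_and_masked(self, rng):
        v1, v2 = rng.uniform(1, 100, (2, 2)), rng.uniform(1, 100, (2, 2))
        v1[0, 1] = np.nan
        fm = assemble_features([peak_mat("AB", v1), peak_mat("AB", v2)], "nn_peaks")
        assert fm.missing_mask[0, 1]
        assert fm.values[0, 1] == pytest.approx(v2[0, 1])  # cross-sample mean

    def test_inconsistent_panels_rejected(self, rng):
        a = peak_mat("AB", rng.uniform(1, 10, (2, 2)))
        b = peak_mat("AC", rng.uniform(1, 10, (2, 2)))
        with pytest.raises(SchemaError):
            assemble_features([a, b], "nn_peaks")


class TestPCA:
    def test_collinear_samples_put_all_variance_on_pc1(self):
        t = np.linspace(0, 1, 5)[:, None]
        fm = features(np.hstack([3 * t, -2 * t, 7 * t]))
        emb = run_pca(fm)
        assert emb.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_strongest_separating_feature_has_top_loading(self, rng):
        """Two planted clusters: the feature carrying the cleanest split has
        the largest |loading| on PC1."""
        cluster = np.repeat([0.0, 1.0], 20)[:, None]
        noise = rng.normal(0, 1.0, size=(40, 4))
        X = cluster * np.array([0.5, 0.5, 10.0, 0.5]) + noise * np.array(
            [1.0, 1.0, 0.05, 1.0]
        )
        emb = run_pca(features(X))
        report = loadings_report(emb)
        assert report[report["component"] == 1].iloc[0]["feature"] == "f2"

    def test_sign_convention_deterministic(self, rng):
        fm = features(rng.normal(size=(8, 5)))
        emb = run_pca(fm)
        for c in range(emb.loadings.shape[1]):
            top = np.argmax(np.abs(emb.loadings[:, c]))
            assert emb.loadings[top, c] > 0

    def test_score_variance_matches_explained_ratio(self, rng):
        fm = features(rng.normal(size=(12, 6)))
        emb = run_pca(fm, n_components=3)
        var = emb.scores.var(axis=0, ddof=1)
        assert np.all(np.diff(emb.explained_variance_ratio) <= 1e-12)
        np.testing.assert_allclose(
            var / var.sum(),
            emb.explained_variance_ratio / emb.explained_variance_ratio.sum(),
            atol=1e-9,
        )

    def test_sample_order_invariance(self, rng):
        X = rng.normal(size=(9, 4))
        emb1 = run_pca(features(X))
        perm = rng.permutation(9)
        emb2 = run_pca(features(X[perm]))
        np.testing.assert_allclose(emb2.scores, emb1.scores[perm], atol=1e-8)
        np.testing.assert_allclose(
            emb2.explained_variance_ratio, emb1.explained_variance_ratio, atol=1e-12
        )

    def test_raw_feature_scale_invariance(self, rng):
        """Z-scoring absorbs any per-feature rescaling."""
        X = rng.normal(size=(10, 5))
        Y = X * np.array([1.0, 100.0, 0.01, 7.0, 1e4])
        emb1, emb2 = run_pca(features(X)), run_pca(features(Y))
        np.testing.assert_allclose(emb2.scores, emb1.scores, atol=1e-8)

    def test_single_sample_rejected(self):
        with pytest.raises((ParameterError, SchemaError)):
            run_pca(features(np.ones((1, 3))))


class TestLoadingsReport:
    def test_ties_lexicographic(self):
        emb = run_pca(features(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])))
        rep = loadings_report(emb)
        pc1 = rep[rep["component"] == 1]
        assert list(pc1["feature"]) == ["f0", "f1"]  # equal |loading|, lexicographic

    def test_top_n_larger_than_features(self, rng):
        emb = run_pca(features(rng.normal(size=(6, 3))))
        rep = loadings_report(emb, top_n=99)
        assert len(rep[rep["component"] == 1]) == 3


class TestSeparation:
    def test_two_tight_clusters_score_high(self, rng):
        X = np.vstack([rng.normal(0, 0.05, (5, 3)), rng.normal(5, 0.05, (5, 3))])
        emb = run_pca(features(X, ["A"] * 5 + ["B"] * 5))
        assert separation_score(emb) > 0.9

    def test_permuted_labels_score_near_zero(self, rng):
        X = np.vstack([rng.normal(0, 0.05, (6, 3)), rng.normal(5, 0.05, (6, 3))])
        emb = run_pca(features(X, ["A"] * 6 + ["B"] * 6))
        hits = 0
        for _ in range(100):
            labels = list(rng.permutation(["A"] * 6 + ["B"] * 6))
            if abs(separation_score(emb, labels)) < 0.2:
                hits += 1
        assert hits >= 95

    def test_coincident_conditions_not_separable(self):
        """Condition B duplicates condition A's points exactly: each point's
        nearest neighbours include its own duplicate in the OTHER condition,
        so the silhouette cannot be positive."""
        base = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        X = np.vstack([base, base])
        emb = run_pca(features(X, ["A"] * 3 + ["B"] * 3))
        assert separation_score(emb) <= 0.0

    def test_singleton_condition_excluded(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (3, 2)), rng.normal(5, 0.1, (3, 2)),
                       rng.normal(10, 0.1, (1, 2))])
        emb = run_pca(features(X, ["A"] * 3 + ["B"] * 3 + ["C"]))
        s = separation_score(emb)  # C dropped with warning, A/B remain
        assert s > 0.5
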