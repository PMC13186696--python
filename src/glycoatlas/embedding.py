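"""Per-sample feature assembly, PCA state embedding and separation scoring.

Each imaged cell (sample) is summarized either by its flattened K x K NN peak
matrix, by its GlyCo class densities (union of class labels across samples,
absent class = 0), or by its concatenated full NN distance distributions.
Features are z-scored across samples — they mix units (nm, µm^-2) and the
loadings-as-correlations reading presumes standardized inputs — and embedded
by PCA. Loadings are reported as the correlation between each standardized
feature and each PC score; high absolute loadings identify the glycan
features that drive state separation. A silhouette score on the first two
PCs quantifies how well known condition labels separate in the embedding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .errors import ParameterError, SchemaError
from .glyco import GlycoClassTable
from .nn import NNPeakMatrix, full_distribution_features

logger = logging.getLogger("glycoatlas")

FEATURE_MODES = ("nn_peaks", "glyco", "nn_full")


@dataclass
class FeatureMatrix:
    sample_ids: list[str]
    condition_labels: list[str]
    feature_names: list[str]
    values: np.ndarray  # samples x features, missing entries imputed
    missing_mask: np.ndarray  # True where a value was imputed

    def __post_init__(self):
        n, p = self.values.shape
        if not (len(self.sample_ids) == len(self.condition_labels) == n):
            raise SchemaError("sample ids / condition labels / rows inconsistent")
        if len(self.feature_names) != p:
            raise SchemaError("feature names / columns inconsistent")


@dataclass
class StateEmbedding:
    sample_ids: list[str]
    condition_labels: list[str]
    feature_names: list[str]  # features retained after zero-variance drop
    scores: np.ndarray  # samples x components
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # features x components, correlations in [-1, 1]


def _impute_column_means(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mask = ~np.isfinite(values)
    if mask.any():
        col_means = np.nanmean(np.where(mask, np.nan, values), axis=0)
        col_means = np.nan_to_num(col_means)  # all-missing column -> 0
        values = np.where(mask, col_means[None, :], values)
    return values, mask


def assemble_features(
    samples: list,
    mode: str,
    sample_ids: list[str] | None = None,
    condition_labels: list[str] | None = None,
) -> FeatureMatrix:
    """Build the samples x features matrix for one feature mode.

    ``samples`` holds one object per sample: an :class:`NNPeakMatrix` for
    modes ``nn_peaks`` / ``nn_full``, or a :class:`GlycoClassTable` for mode
    ``glyco``. Missing entries (flagged NN pairs) are imputed by the
    per-feature cross-sample mean and recorded in the missing mask.
    """
    if mode not in FEATURE_MODES:
        raise ParameterError(f"unknown feature mode '{mode}'")
    if len(samples) < 2:
        raise SchemaError("feature assembly needs >= 2 samples")
    n = len(samples)
    sample_ids = sample_ids or [f"sample{i}" for i in range(n)]
    condition_labels = condition_labels or [""] * n

    if mode == "nn_peaks":
        panels = [tuple(s.channel_order) for s in samples]
        if len(set(panels)) != 1:
            raise SchemaError(f"inconsistent channel panels: {sorted(set(panels))}")
        labels = samples[0].channel_order
        names = [f"peak:{a}->{b}" for a in labels for b in labels]
        values = np.vstack([s.peaks.ravel() for s in samples])
    elif mode == "nn_full":
        vectors, names_ref = [], None
        for s in samples:
            vec, names = full_distribution_features(s)
            if names_ref is None:
                names_ref = names
            elif names != names_ref:
                raise SchemaError("inconsistent histogram layout across samples")
            vectors.append(vec)
        names = names_ref
        values = np.vstack(vectors)
    else:  # glyco: union of class labels, absent class = 0 density
        all_labels = sorted(set().union(*[set(s.classes["label"]) for s in samples]))
        names = [f"density:{lab}" for lab in all_labels]
        values = np.array(
            [[s.density_of(lab) for lab in all_labels] for s in samples], dtype=np.float64
        )

    values, mask = _impute_column_means(values)
    return FeatureMatrix(list(sample_ids), list(condition_labels), list(names), values, mask)


def run_pca(features: FeatureMatrix, n_components: int = 2) -> StateEmbedding:
    """Z-score standardization + SVD-based PCA with a deterministic sign.

    Zero-variance columns are dropped before standardization. The sign of
    each component is fixed so that its largest-magnitude loading is
    positive. ``n_components`` is capped at min(samples - 1, features).
    """
    X = features.values
    n = X.shape[0]
    if n < 2:
        raise ParameterError("PCA needs >= 2 samples")
    std = X.std(axis=0, ddof=0)
    keep = std > 0
    if not keep.any():
        raise ParameterError("all features have zero variance across samples")
    if (~keep).any():
        logger.info("dropping %d zero-variance feature(s) before PCA", int((~keep).sum()))
    Xk = X[:, keep]
    names = [f for f, k in zip(features.feature_names, keep) if k]
    Z = (Xk - Xk.mean(axis=0)) / std[keep]

    n_components = min(n_components, n - 1, Z.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Z)

    # loadings = correlation of each standardized feature with each PC score
    loadings = np.zeros((Z.shape[1], n_components))
    score_std = scores.std(axis=0, ddof=0)
    for c in range(n_components):
        if score_std[c] > 0:
            loadings[:, c] = (Z * scores[:, c : c + 1]).mean(axis=0) / score_std[c]
    # deterministic sign: largest-|loading| feature per component is positive
    for c in range(n_components):
        top = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[top, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    return StateEmbedding(
        sample_ids=features.sample_ids,
        condition_labels=features.condition_labels,
        feature_names=names,
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=loadings,
    )


def loadings_report(embedding: StateEmbedding, top_n: int | None = None) -> pd.DataFrame:
    """Ranked feature contributions per component.

    Long-format frame (component, rank, feature, loading), sorted within
    each component by |loading| descending, ties lexicographic by feature.
    """
    rows = []
    for c in range(embedding.loadings.shape[1]):
        df = pd.DataFrame(
            {"feature": embedding.feature_names, "loading": embedding.loadings[:, c]}
        )
        df["abs_loading"] = df["loading"].abs()
        df = df.sort_values(
            ["abs_loading", "feature"], ascending=[False, True], kind="stable"
        ).reset_index(drop=True)
        if top_n is not None:
            df = df.head(top_n)
        for rank, r in df.iterrows():
            rows.append(
                {
                    "component": c + 1,
                    "rank": rank + 1,
                    "feature": r["feature"],
                    "loading": r["loading"],
                }
            )
    return pd.DataFrame(rows)


def separation_score(
    embedding: StateEmbedding, condition_labels: list[str] | None = None
) -> float:
    """Mean silhouette of the condition labels on the first two PC scores.

    Conditions with a single sample are excluded with a warning; at least
    two conditions with >= 2 samples each are required.
    """
    labels = np.array(condition_labels or embedding.condition_labels)
    scores = embedding.scores[:, : min(2, embedding.scores.shape[1])]
    uniq, counts = np.unique(labels, return_counts=True)
    small = uniq[counts < 2]
    if len(small):
        logger.warning("excluding single-sample condition(s): %s", list(small))
        keep = ~np.isin(labels, small)
        labels, scores = labels[keep], scores[keep]
        uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ParameterError("separation score needs >= 2 conditions with >= 2 samples each")
    return float(silhouette_score(scores, labels, metric="euclidean"))
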