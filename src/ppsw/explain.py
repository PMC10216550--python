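"""Interpretability: feature importances, SHAP summaries, bias statistic,
and SHAP-space 2-D embeddings for supervised clustering.

Attributions come from the exact Tree SHAP implementation in
:mod:`ppsw.treeshap` and live in probability space, so local accuracy
(base value + attributions = predicted class probability) is dimensionless
and directly checkable.  "Supervised clustering" embeds per-sample SHAP
vectors instead of raw feature rows: dimensions are weighted by their
relevance to the trained model, which suppresses noise features and
sharpens class structure in the 2-D map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ml import ModelResult, feature_matrix
from .treeshap import expected_value, tree_shap_values

__all__ = [
    "ShapSummary",
    "BiasResult",
    "Embedding2D",
    "impurity_importance",
    "permutation_importance",
    "shap_summarize",
    "shap_bias",
    "embed",
]


@dataclass
class ShapSummary:
    """Per-sample, per-feature, per-class Shapley attributions."""

    values: np.ndarray  # (n_samples, n_features, n_classes)
    base_values: np.ndarray  # (n_classes,)
    feature_names: list[str]
    class_names: list[str]

    @property
    def mean_abs(self) -> np.ndarray:
        """Mean |phi| per feature per class (the bar-plot statistic)."""
        return np.abs(self.values).mean(axis=0)

    def sample_vectors(self, reduction: str = "concat") -> np.ndarray:
        """Per-sample SHAP vectors for embedding.

        ``concat`` flattens feature x class attributions into one row
        (preserves all class-discriminative structure); ``mean`` averages
        attributions over classes.
        """
        if reduction == "concat":
            return self.values.reshape(self.values.shape[0], -1)
        if reduction == "mean":
            return self.values.mean(axis=2)
        raise ValueError(f"unknown reduction {reduction!r}; allowed: concat, mean")

    def to_long_frame(self) -> pd.DataFrame:
        n, f, c = self.values.shape
        idx = pd.MultiIndex.from_product(
            [range(n), self.feature_names, self.class_names],
            names=["sample", "feature", "class"],
        )
        return pd.DataFrame({"value": self.values.ravel()}, index=idx).reset_index()


@dataclass
class BiasResult:
    """Mean paired difference of per-sample average |SHAP|, variant A - B."""

    per_class_bias: dict[str, float]
    variant_a: str
    variant_b: str


@dataclass
class Embedding2D:
    coords: np.ndarray  # (n_samples, 2)
    source: str  # "raw_features" or "shap_values"
    labels: np.ndarray


def _require_tree_model(result: ModelResult):
    model = result.fitted_model
    if not hasattr(model, "feature_importances_") and not hasattr(model, "tree_"):
        raise TypeError(f"{type(model).__name__} is not a tree model")
    return model


def impurity_importance(result: ModelResult) -> pd.Series:
    """Impurity-decrease importances, normalized to sum to 1."""
    model = _require_tree_model(result)
    imp = np.asarray(model.feature_importances_, dtype=np.float64)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return pd.Series(imp, index=result.feature_names, name="impurity_importance")


def permutation_importance(
    result: ModelResult, test: pd.DataFrame, n_repeats: int = 10, seed: int = 0
) -> pd.Series:
    """Mean held-out accuracy drop when each feature column is permuted."""
    if n_repeats < 1:
        raise ValueError(f"n_repeats must be >= 1, got {n_repeats}")
    from sklearn.inspection import permutation_importance as _perm

    x_test, names = feature_matrix(test)
    y_test = test[f"{result.target}_label"].to_numpy()
    model = result.fitted_model
    if result.model_name == "xgboost":
        class_to_int = {c: i for i, c in enumerate(result.classes)}
        y_test = np.array([class_to_int[c] for c in y_test])
    r = _perm(
        model, x_test, y_test, scoring="accuracy",
        n_repeats=n_repeats, random_state=seed, n_jobs=1,
    )
    return pd.Series(r.importances_mean, index=names, name="permutation_importance")


def shap_summarize(result: ModelResult, data: pd.DataFrame) -> ShapSummary:
    """Exact Tree SHAP attributions of ``data`` under the fitted model."""
    model = _require_tree_model(result)
    x, names = feature_matrix(data)
    values = tree_shap_values(model, x)
    base = expected_value(model)
    return ShapSummary(
        values=values,
        base_values=base,
        feature_names=names,
        class_names=[str(c) for c in result.classes],
    )


def shap_bias(summary_a: ShapSummary, summary_b: ShapSummary,
              variant_a: str = "A", variant_b: str = "B") -> BiasResult:
    """Per-class mean over samples of (feature-averaged |phi_a| - |phi_b|).

    The two summaries must cover the same samples and classes; feature sets
    may differ because the comparison averages over features first.
    """
    if summary_a.values.shape[0] != summary_b.values.shape[0]:
        raise ValueError(
            f"sample-count mismatch: {summary_a.values.shape[0]} vs {summary_b.values.shape[0]}"
        )
    if summary_a.class_names != summary_b.class_names:
        raise ValueError("class sets differ between summaries")
    avg_a = np.abs(summary_a.values).mean(axis=1)  # (n_samples, n_classes)
    avg_b = np.abs(summary_b.values).mean(axis=1)
    diff = (avg_a - avg_b).mean(axis=0)
    per_class = {c: float(diff[k]) for k, c in enumerate(summary_a.class_names)}
    return BiasResult(per_class_bias=per_class, variant_a=variant_a, variant_b=variant_b)


def embed(
    source_matrix: np.ndarray,
    labels,
    source_tag: str = "raw_features",
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> Embedding2D:
    """2-D neighborhood-preserving (UMAP) embedding, deterministic per seed."""
    source_matrix = np.asarray(source_matrix, dtype=np.float64)
    if source_matrix.shape[0] < 10:
        raise ValueError(f"need >= 10 samples to embed, got {source_matrix.shape[0]}")
    if source_matrix.shape[0] <= n_neighbors:
        raise ValueError(
            f"n_neighbors={n_neighbors} requires more than that many samples "
            f"(got {source_matrix.shape[0]})"
        )
    import umap

    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist,
        random_state=seed, n_jobs=1,
    )
    coords = reducer.fit_transform(source_matrix)
    return Embedding2D(coords=np.asarray(coords), source=source_tag, labels=np.asarray(labels))


def silhouette(embedding: Embedding2D) -> float:
    """Silhouette score of the 2-D coordinates against the carried labels."""
    from sklearn.metrics import silhouette_score

    return float(silhouette_score(embedding.coords, embedding.labels))


def plot_importance_bar(summary: ShapSummary, path, top: int = 15):
    """Mean-|SHAP| bar chart (summed over classes), saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores = summary.mean_abs.sum(axis=1)
    order = np.argsort(scores)[::-1][:top]
    fig, ax = plt.subplots(figsize=(6, 0.3 * top + 1))
    ax.barh([summary.feature_names[i] for i in order][::-1], scores[order][::-1])
    ax.set_xlabel("mean |SHAP value|")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_embedding(embedding: Embedding2D, path):
    """Scatter of the 2-D embedding colored by label, saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for lab in np.unique(embedding.labels):
        sel = embedding.labels == lab
        ax.scatter(embedding.coords[sel, 0], embedding.coords[sel, 1], s=8, label=str(lab))
    ax.legend(markerscale=2, fontsize=8)
    ax.set_title(embedding.source)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
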