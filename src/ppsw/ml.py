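"""Tree-model zoo: 70:30 split, training, and macro-averaged metrics.

Feature tables are split once into train/test by random sampling (70:30,
stratified by default), models are fitted on the training rows only, and
accuracy plus macro-averaged precision/recall/F1 are reported on the
held-out rows, all as percentages.  No feature standardization and no
cross-validation are applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, precision_recall_fscore_support

__all__ = ["SplitSpec", "ModelResult", "MODEL_NAMES", "split", "train_evaluate", "run_matrix"]

MODEL_NAMES = (
    "decision_tree",
    "random_forest",
    "adaboost",
    "xgboost",
    "gbdt",
    "hist_gbdt",
    "lightgbm",
)

LABEL_COLUMNS = ("density_label", "media_label", "source_variant")


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.7
    seed: int = 0
    stratified: bool = True


@dataclass
class ModelResult:
    model_name: str
    target: str
    accuracy: float
    precision_macro: float
    recall_macro: float
    f1_macro: float
    fitted_model: object
    feature_names: list[str]
    classes: list[str]


def feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols = [c for c in table.columns if c not in LABEL_COLUMNS]
    return table[cols].to_numpy(dtype=np.float64), cols


def split(table: pd.DataFrame, spec: SplitSpec = SplitSpec()) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random 70:30 row partition, stratified on density then media labels."""
    from sklearn.model_selection import train_test_split

    if len(table) == 0:
        raise ValueError("cannot split an empty feature table")
    strat = None
    if spec.stratified:
        strat_cols = [c for c in ("density_label", "media_label") if c in table.columns]
        # prefer the joint key (preserves the factorial balance); back off to
        # coarser keys when a stratum is too small to split
        candidates = ([strat_cols] if len(strat_cols) > 1 else []) + [[c] for c in strat_cols]
        for cols in candidates:
            key = table[cols].astype(str).agg("|".join, axis=1)
            if key.value_counts().min() >= 2:
                strat = key
                break
    # integer size avoids float round-off inflating the test partition
    n_train = int(round(spec.train_fraction * len(table)))
    train, test = train_test_split(
        table,
        train_size=n_train,
        random_state=spec.seed,
        stratify=strat,
        shuffle=True,
    )
    return train.reset_index(drop=True), test.reset_index(drop=True)


def make_model(model_name: str, seed: int = 0, n_estimators: int | None = None):
    """Construct one member of the zoo with the package's reference settings.

    Forests use 500 trees with unlimited depth; boosting learners use 300
    rounds at learning rate 0.1.  ``n_estimators`` overrides the tree /
    round count when a smaller model is wanted.
    """
    from sklearn.ensemble import (
        AdaBoostClassifier,
        GradientBoostingClassifier,
        HistGradientBoostingClassifier,
        RandomForestClassifier,
    )
    from sklearn.tree import DecisionTreeClassifier

    if model_name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if model_name == "random_forest":
        return RandomForestClassifier(n_estimators=n_estimators or 500, random_state=seed, n_jobs=1)
    if model_name == "adaboost":
        return AdaBoostClassifier(n_estimators=n_estimators or 300, learning_rate=0.1, random_state=seed)
    if model_name == "gbdt":
        return GradientBoostingClassifier(n_estimators=n_estimators or 300, learning_rate=0.1, random_state=seed)
    if model_name == "hist_gbdt":
        return HistGradientBoostingClassifier(max_iter=n_estimators or 300, learning_rate=0.1, random_state=seed)
    if model_name == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=n_estimators or 300, learning_rate=0.1, random_state=seed,
            n_jobs=1, verbosity=0,
        )
    if model_name == "lightgbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(
            n_estimators=n_estimators or 300, learning_rate=0.1, random_state=seed,
            n_jobs=1, verbose=-1,
        )
    raise ValueError(f"unknown model_name {model_name!r}; allowed: {MODEL_NAMES}")


def classification_metrics(y_true, y_pred) -> dict[str, float]:
    """Accuracy and unweighted (macro) precision/recall/F1, as percentages."""
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, average="macro", zero_division=0
    )
    return {
        "accuracy": 100.0 * accuracy_score(y_true, y_pred),
        "precision_macro": 100.0 * prec,
        "recall_macro": 100.0 * rec,
        "f1_macro": 100.0 * f1,
    }


def train_evaluate(
    train: pd.DataFrame,
    test: pd.DataFrame,
    model_name: str,
    target: str = "density",
    seed: int = 0,
    n_estimators: int | None = None,
) -> ModelResult:
    """Fit on the training rows only; score on the held-out rows only."""
    label_col = f"{target}_label"
    if label_col not in train.columns:
        raise ValueError(f"target column {label_col!r} missing from the table")
    x_train, feature_names = feature_matrix(train)
    x_test, _ = feature_matrix(test)
    y_train = train[label_col].to_numpy()
    y_test = test[label_col].to_numpy()
    classes = sorted(np.unique(y_train).tolist())
    if len(classes) < 2:
        raise ValueError("training set contains a single class")
    missing = set(np.unique(y_test)) - set(classes)
    if missing:
        raise ValueError(f"test classes {sorted(missing)} absent from the training set")

    model = make_model(model_name, seed=seed, n_estimators=n_estimators)
    class_to_int = {c: i for i, c in enumerate(classes)}
    if model_name == "xgboost":
        model.fit(x_train, np.array([class_to_int[c] for c in y_train]))
        y_pred = np.array(classes, dtype=object)[model.predict(x_test)]
    else:
        model.fit(x_train, y_train)
        y_pred = model.predict(x_test)

    metrics = classification_metrics(y_test, y_pred)
    return ModelResult(
        model_name=model_name,
        target=target,
        fitted_model=model,
        feature_names=feature_names,
        classes=classes,
        **metrics,
    )


def run_matrix(
    tables: dict[str, pd.DataFrame],
    targets=("density", "media"),
    models=MODEL_NAMES,
    seed: int = 0,
    split_spec: SplitSpec | None = None,
    n_estimators: int | None = None,
) -> pd.DataFrame:
    """One metric row per (source variant, target, model), shaped like a
    benchmark table: rows sorted by variant then ascending accuracy."""
    split_spec = split_spec or SplitSpec(seed=seed)
    rows = []
    for variant, table in tables.items():
        train, test = split(table, split_spec)
        for target in targets:
            if f"{target}_label" not in table.columns:
                continue
            for model_name in models:
                res = train_evaluate(train, test, model_name, target, seed, n_estimators)
                rows.append(
                    {
                        "variant": variant,
                        "target": target,
                        "model": model_name,
                        "accuracy": res.accuracy,
                        "precision": res.precision_macro,
                        "recall": res.recall_macro,
                        "f1_score": res.f1_macro,
                    }
                )
    out = pd.DataFrame(rows)
    return out.sort_values(["variant", "target", "accuracy"]).reset_index(drop=True)
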