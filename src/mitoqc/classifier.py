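"""Four-class random-forest mitochondrial morphology classifier.

Objects are classified as *network* (branched), *unbranched* (tubule),
*swollen* (large round) or *punctate* (small round) from their 32 shape
descriptors.  Training mirrors the reference protocol: a stratified 80/20
train/test split, a 25-iteration bootstrap-resampled search over ``mtry``
(the number of candidate predictors per split), and a final forest of
500 trees with mtry = 2.

Labeled tables are plain DataFrames carrying the 32 descriptor columns
plus a ``class`` column.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .morphometry import FEATURE_NAMES

__all__ = [
    "MORPHOLOGY_CLASSES",
    "MorphologyModel",
    "hand_label_schema",
    "split_train_test",
    "train_morphology_model",
    "predict_morphology",
    "evaluate_model",
    "save_morphology_model",
    "load_morphology_model",
]

#: The closed four-class morphology enumeration, in canonical order.
MORPHOLOGY_CLASSES = ("network", "unbranched", "swollen", "punctate")

#: Tuning grid for mtry: the configured minimum, sqrt(d), d/2, d.
MTRY_GRID = (2, 6, 16, 32)


def hand_label_schema() -> dict:
    """Reference schema for hand-labeled input tables: the per-class label
    counts of the curated training corpus this classifier design was built
    around (shipped as package data)."""
    with resources.files("mitoqc.data").joinpath("hand_label_schema.json").open() as fh:
        return json.load(fh)


@dataclass
class MorphologyModel:
    forest: RandomForestClassifier
    classes: tuple
    n_trees: int
    mtry: int
    seed: int
    tuning_history: list
    evaluation: dict = field(default_factory=dict)


def _check_labeled(df: pd.DataFrame) -> None:
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"labeled table lacks descriptor column(s): {missing}")
    if "class" not in df.columns:
        raise ValueError("labeled table lacks a 'class' column")
    if df[list(FEATURE_NAMES)].isna().any().any():
        raise ValueError("labeled table contains missing descriptor values")
    bad = set(df["class"]) - set(MORPHOLOGY_CLASSES)
    if bad:
        raise ValueError(f"unknown morphology class(es): {sorted(bad)}")


def split_train_test(lt: pd.DataFrame, train_fraction: float, seed: int):
    """Stratified split: per class, ceil(fraction * n_c) rows go to the
    training set (deterministic given the seed); train and test partition
    the input."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    _check_labeled(lt)
    rng = np.random.default_rng(int(seed))
    train_idx: list = []
    test_idx: list = []
    for cls in MORPHOLOGY_CLASSES:
        idx = lt.index[lt["class"] == cls].to_numpy()
        if idx.size == 0:
            continue
        if idx.size < 2:
            raise ValueError(
                f"class {cls!r} has only {idx.size} row(s); cannot stratify"
            )
        perm = rng.permutation(idx)
        k = math.ceil(train_fraction * idx.size)
        train_idx.extend(perm[:k])
        test_idx.extend(perm[k:])
    return lt.loc[sorted(train_idx)], lt.loc[sorted(test_idx)]


def train_morphology_model(train: pd.DataFrame, cfg, seed: int) -> MorphologyModel:
    """Tune then fit the morphology forest.

    ``cfg.rf_tune_iters`` bootstrap-resampling iterations score every mtry in
    the grid by out-of-bootstrap accuracy (100-tree forests during the
    search); the final model always honors ``cfg.rf_final_trees`` and
    ``cfg.rf_mtry``.  The tuning history is recorded on the model.
    """
    _check_labeled(train)
    classes = sorted(set(train["class"]))
    if len(classes) < 2:
        raise ValueError(f"training requires >= 2 classes, got {classes}")
    X = train[list(FEATURE_NAMES)].to_numpy(dtype=np.float64)
    y = train["class"].to_numpy()
    rng = np.random.default_rng(int(seed))
    n = len(y)

    history = []
    for it in range(int(cfg.rf_tune_iters)):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        for mtry in MTRY_GRID:
            forest = RandomForestClassifier(
                n_estimators=100,
                max_features=min(mtry, X.shape[1]),
                random_state=int(rng.integers(0, 2**31 - 1)),
                n_jobs=1,
            )
            forest.fit(X[boot], y[boot])
            if oob.size and len(set(y[boot])) >= 2:
                acc = float((forest.predict(X[oob]) == y[oob]).mean())
            else:
                acc = float("nan")
            history.append({"iteration": it, "mtry": mtry, "accuracy": acc})

    final = RandomForestClassifier(
        n_estimators=int(cfg.rf_final_trees),
        max_features=min(int(cfg.rf_mtry), X.shape[1]),
        random_state=int(seed),
        n_jobs=1,
    )
    final.fit(X, y)
    return MorphologyModel(
        forest=final,
        classes=tuple(c for c in MORPHOLOGY_CLASSES if c in classes),
        n_trees=int(cfg.rf_final_trees),
        mtry=int(cfg.rf_mtry),
        seed=int(seed),
        tuning_history=history,
    )


def predict_morphology(model: MorphologyModel, features: pd.DataFrame):
    """Class call and per-class probabilities for each row.

    Returns a DataFrame with a ``class`` column and one ``p_<class>`` column
    per class in canonical enumeration order; the call is the probability
    argmax with ties broken toward the class listed first in the
    enumeration.  An empty input gives an empty output.
    """
    missing = [c for c in FEATURE_NAMES if c not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks descriptor column(s): {missing}")
    cols = [f"p_{c}" for c in model.classes]
    if len(features) == 0:
        return pd.DataFrame(columns=["class", *cols])
    X = features[list(FEATURE_NAMES)].to_numpy(dtype=np.float64)
    proba = model.forest.predict_proba(X)
    order = {c: i for i, c in enumerate(model.forest.classes_)}
    P = np.column_stack([proba[:, order[c]] for c in model.classes])
    calls = [model.classes[i] for i in np.argmax(P, axis=1)]
    out = pd.DataFrame({"class": calls}, index=features.index)
    for j, c in enumerate(model.classes):
        out[f"p_{c}"] = P[:, j]
    return out


def evaluate_model(model: MorphologyModel, test: pd.DataFrame) -> dict:
    """Confusion matrix (rows = true class, columns = predicted) plus
    overall and per-class accuracy on a labeled test table."""
    _check_labeled(test)
    if len(test) == 0:
        raise ValueError("test set is empty")
    pred = predict_morphology(model, test)["class"].to_numpy()
    true = test["class"].to_numpy()
    classes = list(model.classes)
    cm = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(true, pred):
        cm.loc[t, p] += 1
    total = cm.to_numpy().sum()
    accuracy = float(np.trace(cm.to_numpy()) / total)
    per_class = {}
    for c in classes:
        row = cm.loc[c].to_numpy().sum()
        per_class[c] = float(cm.loc[c, c] / row) if row else float("nan")
    report = {
        "confusion_matrix": cm,
        "accuracy": accuracy,
        "per_class_recall": per_class,
        "n_test": int(total),
    }
    model.evaluation = {
        "accuracy": accuracy,
        "per_class_recall": per_class,
        "n_test": int(total),
    }
    return report


def save_morphology_model(model: MorphologyModel, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "classes": list(model.classes),
        "n_trees": model.n_trees,
        "mtry": model.mtry,
        "seed": model.seed,
        "tuning_history": model.tuning_history,
        "evaluation": model.evaluation,
    }
    with open(directory / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    joblib.dump(model.forest, directory / "forest.joblib")


def load_morphology_model(directory) -> MorphologyModel:
    directory = Path(directory)
    with open(directory / "metadata.json") as fh:
        meta = json.load(fh)
    return MorphologyModel(
        forest=joblib.load(directory / "forest.joblib"),
        classes=tuple(meta["classes"]),
        n_trees=meta["n_trees"],
        mtry=meta["mtry"],
        seed=meta["seed"],
        tuning_history=meta["tuning_history"],
        evaluation=meta.get("evaluation", {}),
    )
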