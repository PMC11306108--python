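"""Random-forest discrimination of cells from non-cell structures.

Detected objects are classified into two categories — cells (including cell
conglomerates) and non-cells (vessels, vasculature fragments, artifacts) —
from their gyration-tensor shape descriptors and denoised-intensity
summaries.  Evaluation follows an 80%:20% stratified random split of the
labeled objects, repeated over several seeds, reporting per-split and mean ±
SD accuracies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from clearcount3d.morphology import FEATURE_COLUMNS

__all__ = [
    "ClassifierModel",
    "split_labels",
    "train_classifier",
    "predict",
    "evaluate_repeated",
    "save_model",
    "load_model",
]

LABELS = ("cell", "non-cell")


@dataclass
class ClassifierModel:
    """A fitted forest plus the frozen feature ordering and its split accuracies."""

    forest: RandomForestClassifier
    feature_order: list[str]
    seed: int
    train_accuracy: float
    test_accuracy: float
    n_train: int = 0
    n_test: int = 0
    extra: dict = field(default_factory=dict)


def _check_labeled(df: pd.DataFrame) -> None:
    if "label" not in df.columns:
        raise ValueError("labeled feature set needs a 'label' column")
    bad = set(df["label"].unique()) - set(LABELS)
    if bad:
        raise ValueError(f"labels must be in {LABELS}; got extras {sorted(bad)}")
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature set missing columns: {missing}")
    if df[FEATURE_COLUMNS].isna().any().any():
        raise ValueError("feature set contains missing values")


def split_labels(
    labeled: pd.DataFrame,
    train_fraction: float = 0.8,
    seed: int = 0,
    stratify: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/test partition of a labeled feature set.

    Train size is ``round(train_fraction × N)``; the split is class-stratified
    by default (plain random with ``stratify=False``) and reproducible by seed.
    """
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must be in (0, 1); got {train_fraction}")
    if labeled.empty:
        raise ValueError("cannot split an empty feature set")
    _check_labeled(labeled)
    n_train = int(round(train_fraction * len(labeled)))
    n_train = min(max(n_train, 1), len(labeled) - 1)
    strat = labeled["label"] if stratify else None
    try:
        train, test = train_test_split(
            labeled, train_size=n_train, random_state=seed, stratify=strat, shuffle=True
        )
    except ValueError as exc:
        raise ValueError(f"stratified split failed (a class too small?): {exc}") from exc
    for name, part in (("train", train), ("test", test)):
        present = set(part["label"].unique())
        if len(set(labeled["label"].unique())) == 2 and present != set(LABELS):
            raise ValueError(f"{name} split lost a class; too few labeled objects for this fraction")
    return train.reset_index(drop=True), test.reset_index(drop=True)


def train_classifier(
    train: pd.DataFrame,
    test: pd.DataFrame,
    seed: int = 0,
    n_estimators: int = 100,
    max_depth: int | None = None,
    max_features: str | float = "sqrt",
) -> ClassifierModel:
    """Fit the forest on the training split and record both split accuracies."""
    _check_labeled(train)
    _check_labeled(test)
    if train["label"].nunique() < 2:
        raise ValueError("training split contains a single class")
    forest = RandomForestClassifier(
        n_estimators=n_estimators,
        max_depth=max_depth,
        max_features=max_features,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(train[FEATURE_COLUMNS].to_numpy(), train["label"].to_numpy())
    train_acc = float(forest.score(train[FEATURE_COLUMNS].to_numpy(), train["label"].to_numpy()))
    test_acc = float(forest.score(test[FEATURE_COLUMNS].to_numpy(), test["label"].to_numpy()))
    return ClassifierModel(
        forest=forest,
        feature_order=list(FEATURE_COLUMNS),
        seed=seed,
        train_accuracy=train_acc,
        test_accuracy=test_acc,
        n_train=len(train),
        n_test=len(test),
    )


def predict(model: ClassifierModel, features: pd.DataFrame) -> np.ndarray:
    """Labels for a feature table; columns must cover the model's feature order."""
    missing = [c for c in model.feature_order if c not in features.columns]
    if missing:
        raise ValueError(f"feature table missing model columns: {missing}")
    if features.empty:
        return np.array([], dtype=object)
    return model.forest.predict(features[model.feature_order].to_numpy())


def evaluate_repeated(
    labeled: pd.DataFrame,
    train_fraction: float = 0.8,
    n_repeats: int = 10,
    seed: int = 0,
    **forest_kwargs,
) -> dict:
    """Repeat split → train → score over ``n_repeats`` derived seeds.

    Returns per-split train/test accuracies plus their means and sample SDs —
    the averaged-over-splits protocol behind a "98% train / 90% test" style
    summary.
    """
    rng = np.random.default_rng(seed)
    split_seeds = rng.integers(0, 2**31 - 1, size=n_repeats)
    train_accs, test_accs = [], []
    for s in split_seeds:
        train, test = split_labels(labeled, train_fraction, seed=int(s))
        model = train_classifier(train, test, seed=int(s), **forest_kwargs)
        train_accs.append(model.train_accuracy)
        test_accs.append(model.test_accuracy)
    train_accs = np.array(train_accs)
    test_accs = np.array(test_accs)
    return {
        "train_accuracies": train_accs.tolist(),
        "test_accuracies": test_accs.tolist(),
        "train_mean": float(train_accs.mean()),
        "train_sd": float(train_accs.std(ddof=1)) if n_repeats > 1 else float("nan"),
        "test_mean": float(test_accs.mean()),
        "test_sd": float(test_accs.std(ddof=1)) if n_repeats > 1 else float("nan"),
        "n_repeats": n_repeats,
    }


def save_model(model: ClassifierModel, path: str) -> None:
    """Persist the model as a joblib archive with a JSON metadata sidecar string."""
    meta = {
        "feature_order": model.feature_order,
        "seed": model.seed,
        "train_accuracy": model.train_accuracy,
        "test_accuracy": model.test_accuracy,
        "n_train": model.n_train,
        "n_test": model.n_test,
    }
    joblib.dump({"forest": model.forest, "meta": json.dumps(meta)}, path)


def load_model(path: str) -> ClassifierModel:
    payload = joblib.load(path)
    meta = json.loads(payload["meta"])
    return ClassifierModel(
        forest=payload["forest"],
        feature_order=list(meta["feature_order"]),
        seed=int(meta["seed"]),
        train_accuracy=float(meta["train_accuracy"]),
        test_accuracy=float(meta["test_accuracy"]),
        n_train=int(meta["n_train"]),
        n_test=int(meta["n_test"]),
    )
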