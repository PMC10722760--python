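"""Cascade (deep) forest classifier with out-of-fold probability augmentation.

Each cascade layer holds several forests (by default two random forests and
two completely-random forests, 17 trees each, entropy criterion).  Layer
t >= 2 is trained on the original features concatenated with layer t-1's
class-probability outputs; to keep those outputs honest, the probabilities a
training row receives come from a fold model that never saw that row
(stratified cross-validation inside each layer).  Depth grows until the
internal cross-validated accuracy stops improving, and the best-scoring
depth is retained.  At inference the same augmentation is replayed with the
full-data forests and the final score is the mean of the last layer's
forest probabilities.

Multi-grained scanning is not used: the pair features here are unordered
vectors, so the cascade operates on them directly.

A small registry (``fit_predict_classifier``) lets baseline classifiers be
plugged in behind the same interface without being re-implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

__all__ = ["CascadeConfig", "CascadeModel", "fit_cascade", "predict_proba",
           "register_classifier", "fit_predict_classifier"]


@dataclass(frozen=True)
class CascadeConfig:
    """Cascade layout: forests per layer, trees per forest, growth control."""

    forests_per_layer: int = 4  # 2 random + 2 completely-random
    n_estimators: int = 17
    split_criterion: str = "entropy"
    cv_folds: int = 5
    max_layers: int = 10
    early_stop_patience: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.forests_per_layer < 1 or self.n_estimators < 1:
            raise ValueError("forests_per_layer and n_estimators must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class CascadeModel:
    """Fitted cascade: one list of full-data forests per retained layer."""

    layers: list[list]
    cv_accuracy: list[float]
    n_classes: int
    base_width: int
    config: CascadeConfig

    @property
    def n_layers(self) -> int:
        return len(self.layers)


def _make_forest(k: int, cfg: CascadeConfig, seed: int):
    """Forest k of a layer: first half random forests, second half
    completely-random forests (ExtraTrees with single-feature splits)."""
    if k < cfg.forests_per_layer / 2:
        return RandomForestClassifier(
            n_estimators=cfg.n_estimators,
            criterion=cfg.split_criterion,
            random_state=seed,
            n_jobs=1,
        )
    return ExtraTreesClassifier(
        n_estimators=cfg.n_estimators,
        criterion=cfg.split_criterion,
        max_features=1,
        random_state=seed,
        n_jobs=1,
    )


def _fit_layer(
    X: np.ndarray, y: np.ndarray, cfg: CascadeConfig, layer_idx: int, n_classes: int
) -> tuple[list, np.ndarray]:
    """Fit one layer; returns (full-data forests, out-of-fold probabilities).

    The OOF probability block has one column group per forest; each row's
    entries come exclusively from the fold model that held that row out.
    """
    oof = np.zeros((len(y), cfg.forests_per_layer * n_classes))
    skf = StratifiedKFold(
        n_splits=cfg.cv_folds, shuffle=True, random_state=(cfg.seed + layer_idx) % 2**31
    )
    for k in range(cfg.forests_per_layer):
        seed = (cfg.seed + 1000 * layer_idx + k) % 2**31
        for train_idx, hold_idx in skf.split(X, y):
            fold_model = _make_forest(k, cfg, seed)
            fold_model.fit(X[train_idx], y[train_idx])
            oof[hold_idx, k * n_classes : (k + 1) * n_classes] = fold_model.predict_proba(
                X[hold_idx]
            )
    forests = []
    for k in range(cfg.forests_per_layer):
        seed = (cfg.seed + 1000 * layer_idx + k) % 2**31
        model = _make_forest(k, cfg, seed)
        model.fit(X, y)
        forests.append(model)
    return forests, oof


def _layer_accuracy(oof: np.ndarray, y: np.ndarray, n_classes: int) -> float:
    """Internal CV accuracy of a layer: argmax of the forest-averaged OOF probabilities."""
    mean_proba = oof.reshape(len(y), -1, n_classes).mean(axis=1)
    return float(np.mean(mean_proba.argmax(axis=1) == y))


def fit_cascade(X: np.ndarray, y: np.ndarray, cfg: CascadeConfig | None = None) -> CascadeModel:
    """Grow the cascade layer by layer with early stopping on internal CV accuracy.

    Raises
    ------
    ValueError
        If only one class is present or X and y disagree in length.
    """
    cfg = cfg or CascadeConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one label per row")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to fit the cascade")
    y_idx = np.searchsorted(classes, y)
    n_classes = len(classes)

    layers: list[list] = []
    accs: list[float] = []
    aug = X
    best_acc = -np.inf
    best_depth = 0
    stale = 0
    for t in range(cfg.max_layers):
        forests, oof = _fit_layer(aug, y_idx, cfg, t, n_classes)
        layers.append(forests)
        acc = _layer_accuracy(oof, y_idx, n_classes)
        accs.append(acc)
        if acc > best_acc + 1e-12:
            best_acc = acc
            best_depth = t + 1
            stale = 0
        else:
            stale += 1
            if stale >= cfg.early_stop_patience:
                break
        aug = np.hstack([X, oof])
    return CascadeModel(
        layers=layers[:best_depth],
        cv_accuracy=accs[:best_depth],
        n_classes=n_classes,
        base_width=X.shape[1],
        config=cfg,
    )


def predict_proba(model: CascadeModel, X: np.ndarray) -> np.ndarray:
    """Class probabilities: replay the cascade with full-layer augmentation,
    then average the final layer's forest probabilities (rows sum to 1)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.base_width:
        raise ValueError(
            f"feature width {X.shape[1] if X.ndim == 2 else 'n/a'} != "
            f"training width {model.base_width}"
        )
    aug = X
    for t, forests in enumerate(model.layers):
        probas = [f.predict_proba(aug) for f in forests]
        if t + 1 < model.n_layers:
            aug = np.hstack([X] + probas)
    return np.mean(probas, axis=0)


# --- pluggable-classifier registry (baseline hook) -------------------------

_REGISTRY: dict[str, Callable] = {}


def register_classifier(name: str, fn: Callable) -> None:
    """Register ``fn(X, y, X_test, seed) -> positive-class scores`` under ``name``."""
    _REGISTRY[name] = fn


def fit_predict_classifier(
    name: str, X: np.ndarray, y: np.ndarray, X_test: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Unified train-and-score interface; "cascade" is built in."""
    if name == "cascade":
        model = fit_cascade(X, y, CascadeConfig(seed=seed))
        return predict_proba(model, X_test)[:, 1]
    if name in _REGISTRY:
        return np.asarray(_REGISTRY[name](X, y, X_test, seed))
    known = ["cascade", *sorted(_REGISTRY)]
    raise KeyError(f"unknown classifier {name!r}; registered: {known}")


def save_model(model: CascadeModel, outdir) -> None:
    """Persist a fitted cascade to a directory: one joblib file per forest
    plus a JSON manifest with the layout and configuration."""
    import dataclasses
    import json
    from pathlib import Path

    import joblib

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for t, forests in enumerate(model.layers):
        for k, forest in enumerate(forests):
            joblib.dump(forest, out / f"layer{t}_forest{k}.joblib")
    manifest = {
        "n_layers": model.n_layers,
        "forests_per_layer": [len(f) for f in model.layers],
        "cv_accuracy": model.cv_accuracy,
        "n_classes": model.n_classes,
        "base_width": model.base_width,
        "config": dataclasses.asdict(model.config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_model(outdir) -> CascadeModel:
    """Inverse of :func:`save_model`."""
    import json
    from pathlib import Path

    import joblib

    out = Path(outdir)
    manifest = json.loads((out / "manifest.json").read_text())
    layers = [
        [joblib.load(out / f"layer{t}_forest{k}.joblib") for k in range(n_forests)]
        for t, n_forests in enumerate(manifest["forests_per_layer"])
    ]
    return CascadeModel(
        layers=layers,
        cv_accuracy=manifest["cv_accuracy"],
        n_classes=manifest["n_classes"],
        base_width=manifest["base_width"],
        config=CascadeConfig(**manifest["config"]),
    )
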