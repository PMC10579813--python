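"""Cascade of multi-label forests with measure-aware reuse and layer growth.

Each layer holds two forest groups built from different split criteria:

* ``rfpct`` — trees splitting by multi-label variance reduction over the
  whole label matrix (predictive-clustering criterion), leaves predicting
  the mean label vector;
* ``mlrf`` — trees splitting by per-label-averaged Gini reduction.

Both use bootstrap resampling and sqrt-of-features subsampling per split.
A layer's training-time representation ``H`` (n x 2m, one m-block per
forest group) comes from out-of-fold cross-fitting so no row is scored by a
forest that saw it. Low-confidence rows keep the previous layer's
representation (measure-aware reuse); growth stops once the tracked measure
has not improved for ``patience`` consecutive layers, and prediction uses
the depth where it peaked.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from . import metrics as M

logger = logging.getLogger(__name__)

__all__ = [
    "CascadeConfig",
    "MultiLabelForest",
    "CascadeLayer",
    "CascadeModel",
    "fit_tree",
    "forest_predict",
    "layer_fit",
    "measure_reuse",
    "row_confidence",
    "cascade_fit",
    "cascade_predict",
    "growth_trace",
    "scores_to_labels",
    "save_model",
    "load_model",
]

FOREST_KINDS = ("rfpct", "mlrf")


@dataclass(frozen=True)
class CascadeConfig:
    n_trees: int = 40
    n_folds: int = 5
    max_layers: int = 20
    patience: int = 3
    tracked_measure: str = "average_precision"
    threshold: float = 0.5
    reuse_quantile: float = 0.30
    improvement_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.tracked_measure not in M.MEASURE_DIRECTIONS:
            raise ValueError(
                f"tracked_measure must be one of {sorted(M.MEASURE_DIRECTIONS)}"
            )
        if self.max_layers < 1 or self.patience < 1 or self.n_trees < 1:
            raise ValueError("n_trees, max_layers and patience must be >= 1")


class _MLTree:
    """One multi-label tree fitted on a bootstrap sample."""

    def __init__(self, kind: str, seed: int):
        if kind not in FOREST_KINDS:
            raise ValueError(f"unknown tree kind {kind!r}")
        self.kind = kind
        self.seed = seed
        self._tree = None
        self._classes: list[np.ndarray] | None = None

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "_MLTree":
        rng = np.random.default_rng(self.seed)
        n = X.shape[0]
        boot = rng.integers(0, n, size=n)
        Xb, Yb = X[boot], Y[boot]
        tree_seed = int(rng.integers(0, 2**31 - 1))
        if self.kind == "rfpct":
            self._tree = DecisionTreeRegressor(
                criterion="squared_error", max_features="sqrt", random_state=tree_seed
            )
            self._tree.fit(Xb, Yb.astype(float))
        else:
            self._tree = DecisionTreeClassifier(
                criterion="gini", max_features="sqrt", random_state=tree_seed
            )
            self._tree.fit(Xb, Yb.astype(int))
            classes = self._tree.classes_
            self._classes = list(classes) if isinstance(classes, list) else [classes]
        self._m = Y.shape[1]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._tree is None:
            raise RuntimeError("tree is not fitted")
        if self.kind == "rfpct":
            out = np.asarray(self._tree.predict(X))
            if out.ndim == 1:
                out = out[:, None]
            return np.clip(out, 0.0, 1.0)
        proba = self._tree.predict_proba(X)
        if isinstance(proba, np.ndarray):
            proba = [proba]
        cols = []
        for j in range(self._m):
            pj, classes = np.asarray(proba[j]), self._classes[j]
            if 1 in classes:
                cols.append(pj[:, list(classes).index(1)])
            else:  # label constant 0 in the bootstrap
                cols.append(np.zeros(X.shape[0]))
        return np.column_stack(cols)


def fit_tree(X: np.ndarray, Y: np.ndarray, kind: str, seed: int) -> _MLTree:
    """Fit one multi-label tree (bootstrap + sqrt feature subsampling)."""
    if X.shape[0] < 1:
        raise ValueError("empty training set")
    return _MLTree(kind, seed).fit(np.asarray(X, dtype=float), np.asarray(Y))


@dataclass
class MultiLabelForest:
    kind: str
    n_trees: int
    trees: list[_MLTree] = field(default_factory=list)

    def fit(self, X: np.ndarray, Y: np.ndarray, seed: int) -> "MultiLabelForest":
        ss = np.random.SeedSequence(seed)
        self.trees = [
            fit_tree(X, Y, self.kind, int(s.generate_state(1)[0]))
            for s in ss.spawn(self.n_trees)
        ]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return forest_predict(self, X)


def forest_predict(forest: MultiLabelForest, X: np.ndarray) -> np.ndarray:
    """Mean of the per-tree leaf label vectors; entries stay in [0, 1]."""
    if not forest.trees:
        raise RuntimeError("forest is not fitted")
    X = np.asarray(X, dtype=float)
    acc = forest.trees[0].predict(X).astype(float)
    for t in forest.trees[1:]:
        acc += t.predict(X)
    return acc / len(forest.trees)


@dataclass
class CascadeLayer:
    forests: dict[str, MultiLabelForest]
    H: np.ndarray | None = None  # out-of-fold representation, training only
    G: np.ndarray | None = None  # after measure-aware reuse

    def predict_representation(self, X_aug: np.ndarray) -> np.ndarray:
        return np.hstack([self.forests[k].predict(X_aug) for k in FOREST_KINDS])


def layer_fit(X_aug: np.ndarray, Y: np.ndarray, cfg: CascadeConfig, seed: int) -> CascadeLayer:
    """Fit one layer: cross-fitted H plus full-data forests for test time.

    H's column blocks are ordered (rfpct block, mlrf block).
    """
    X_aug = np.asarray(X_aug, dtype=float)
    Y = np.asarray(Y)
    n, m = Y.shape
    n_folds = cfg.n_folds
    if n < n_folds:
        warnings.warn(f"only {n} rows; reducing cross-fitting folds from {n_folds} to {n}")
        n_folds = max(2, n)
    ss = np.random.SeedSequence(seed)
    fold_seed, *forest_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(2 * n_folds + 3)]

    H = np.zeros((n, 2 * m))
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=fold_seed % (2**31))
    si = 0
    for train_idx, val_idx in kf.split(X_aug):
        for block, kind in enumerate(FOREST_KINDS):
            forest = MultiLabelForest(kind, cfg.n_trees).fit(
                X_aug[train_idx], Y[train_idx], forest_seeds[si]
            )
            si += 1
            H[np.ix_(val_idx, np.arange(block * m, (block + 1) * m))] = forest.predict(
                X_aug[val_idx]
            )
    full = {
        kind: MultiLabelForest(kind, cfg.n_trees).fit(X_aug, Y, forest_seeds[si + b])
        for b, kind in enumerate(FOREST_KINDS)
    }
    return CascadeLayer(forests=full, H=H)


def _block_mean(H: np.ndarray) -> np.ndarray:
    """Average the two m-wide forest blocks into one n x m score matrix."""
    m = H.shape[1] // 2
    return (H[:, :m] + H[:, m:]) / 2.0


def row_confidence(H: np.ndarray, tracked_measure: str = "average_precision") -> np.ndarray:
    """Per-instance confidence: mean over labels of max(score, 1 - score).

    Scores near 0 or 1 are decisive under every supported measure; scores
    near 0.5 are not. The tracked measure keeps the contract explicit even
    though the same proxy serves all six.
    """
    if tracked_measure not in M.MEASURE_DIRECTIONS:
        raise ValueError(f"unknown measure {tracked_measure!r}")
    S = _block_mean(H)
    return np.maximum(S, 1.0 - S).mean(axis=1)


def measure_reuse(
    H_t: np.ndarray,
    G_prev: np.ndarray | None,
    tracked_measure: str,
    conf_threshold: float,
) -> np.ndarray:
    """Row-wise splice: low-confidence rows keep the previous representation."""
    if G_prev is None:
        return H_t.copy()
    if G_prev.shape != H_t.shape:
        raise ValueError("H and G_prev shapes differ")
    conf = row_confidence(H_t, tracked_measure)
    keep_prev = conf < conf_threshold
    G = H_t.copy()
    G[keep_prev] = G_prev[keep_prev]
    return G


def scores_to_labels(scores: np.ndarray, threshold: float) -> np.ndarray:
    """Threshold scores; rows left empty get their top-scoring label promoted."""
    labels = (scores > threshold).astype(np.int8)
    empty = labels.sum(axis=1) == 0
    if empty.any():
        labels[np.flatnonzero(empty), np.argmax(scores[empty], axis=1)] = 1
    return labels


def _evaluate(measure: str, Y: np.ndarray, scores: np.ndarray, threshold: float) -> float:
    H = scores_to_labels(scores, threshold)
    if measure == "hamming_loss":
        return M.hamming_loss(Y, H)
    if measure == "macro_auc":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return M.macro_auc(Y, scores)[0]
    return getattr(M, measure)(Y, scores)


def growth_trace(
    history: list[float], direction: int, patience: int = 3, tol: float = 1e-6
) -> tuple[int, int]:
    """Replay the layer-growth rule on a measure history.

    Returns (best_depth, layers_grown): growth stops after ``patience``
    consecutive layers without strict improvement beyond ``tol``; the best
    layer (first occurrence) is the selected depth.
    """
    best, best_depth, stall = None, 0, 0
    for t, val in enumerate(history, start=1):
        improved = best is None or direction * (val - best) > tol
        if improved:
            best, best_depth, stall = val, t, 0
        else:
            stall += 1
        if stall >= patience:
            return best_depth, t
    return best_depth, len(history)


@dataclass
class CascadeModel:
    config: CascadeConfig
    layers: list[CascadeLayer] = field(default_factory=list)
    history: list[float] = field(default_factory=list)
    best_depth: int = 0
    conf_threshold: float = 0.0
    n_features: int = 0
    n_labels: int = 0
    seed: int = 0

    @property
    def threshold(self) -> float:
        return self.config.threshold


def cascade_fit(X, Y, cfg: CascadeConfig = CascadeConfig(), seed: int = 0) -> CascadeModel:
    """Grow the cascade layer by layer under the measure-aware stopping rule.

    After each layer the tracked measure is evaluated on that layer's
    out-of-fold representation; growth exits once it has not improved for
    ``cfg.patience`` consecutive layers (or at ``cfg.max_layers``), and the
    best layer becomes the model's prediction depth.
    """
    X = X.X if hasattr(X, "X") else np.asarray(X, dtype=float)
    Y = Y.Y if hasattr(Y, "Y") else np.asarray(Y)
    n, m = Y.shape
    direction = M.MEASURE_DIRECTIONS[cfg.tracked_measure]
    model = CascadeModel(
        config=cfg, n_features=X.shape[1], n_labels=m, seed=seed
    )
    ss = np.random.SeedSequence(seed)
    layer_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(cfg.max_layers)]

    G_prev: np.ndarray | None = None
    best: float | None = None
    stall = 0
    for t in range(1, cfg.max_layers + 1):
        X_aug = X if G_prev is None else np.hstack([X, G_prev])
        layer = layer_fit(X_aug, Y, cfg, layer_seeds[t - 1])
        if t == 1:
            model.conf_threshold = float(
                np.quantile(row_confidence(layer.H, cfg.tracked_measure), cfg.reuse_quantile)
            )
        layer.G = measure_reuse(layer.H, G_prev, cfg.tracked_measure, model.conf_threshold)
        val = _evaluate(cfg.tracked_measure, Y, _block_mean(layer.H), cfg.threshold)
        model.layers.append(layer)
        model.history.append(val)
        logger.info("layer %d: %s = %.6f", t, cfg.tracked_measure, val)

        improved = best is None or direction * (val - best) > cfg.improvement_tol
        if improved:
            best, model.best_depth, stall = val, t, 0
        else:
            stall += 1
        if stall >= cfg.patience:
            logger.info("no improvement for %d layers; stopping growth", cfg.patience)
            break
        G_prev = layer.G
    return model


def cascade_predict(model: CascadeModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Scores and thresholded label decisions at the model's selected depth."""
    X = X.X if hasattr(X, "X") else np.asarray(X, dtype=float)
    if model.best_depth < 1:
        raise RuntimeError("model is not fitted")
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {X.shape[1]}"
        )
    G_prev: np.ndarray | None = None
    H: np.ndarray | None = None
    for layer in model.layers[: model.best_depth]:
        X_aug = X if G_prev is None else np.hstack([X, G_prev])
        H = layer.predict_representation(X_aug)
        G_prev = measure_reuse(H, G_prev, model.config.tracked_measure, model.conf_threshold)
    scores = _block_mean(H)
    return scores, scores_to_labels(scores, model.threshold)


def save_model(model: CascadeModel, out_dir: str | Path) -> None:
    """JSON manifest + one joblib blob per layer's forests."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": model.config.__dict__,
        "history": model.history,
        "best_depth": model.best_depth,
        "conf_threshold": model.conf_threshold,
        "n_features": model.n_features,
        "n_labels": model.n_labels,
        "seed": model.seed,
        "n_layers": len(model.layers),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    for t, layer in enumerate(model.layers, start=1):
        joblib.dump(layer.forests, out / f"layer_{t:03d}.joblib")


def load_model(in_dir: str | Path) -> CascadeModel:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    cfg = CascadeConfig(**manifest["config"])
    model = CascadeModel(
        config=cfg,
        history=manifest["history"],
        best_depth=manifest["best_depth"],
        conf_threshold=manifest["conf_threshold"],
        n_features=manifest["n_features"],
        n_labels=manifest["n_labels"],
        seed=manifest["seed"],
    )
    for t in range(1, manifest["n_layers"] + 1):
        model.layers.append(CascadeLayer(forests=joblib.load(src / f"layer_{t:03d}.joblib")))
    return model
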