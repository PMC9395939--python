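"""Baseline/extended classifier training and evaluation under nested CV.

The outer loop (default 10 stratified folds) estimates generalization; the
inner loop (5 stratified folds of the outer-train split) selects
hyperparameters by mean validation binary cross-entropy.  The search is a
seeded random draw from the grid (budget ``n_trials``), or exhaustive when
the grid is small.  The inner-fold winner is retrained on the full
outer-train split; the extended model reuses the trained baseline with
frozen weights and trains only its feature branch at a fixed learning rate.

Metric conventions: macro F1 is the unweighted mean of the per-class F1
scores; "micro" here is the pooled positive-class F1 (precision/recall/F1 of
the positive label over all predictions).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .nn import (BiLSTMClassifier, bce_loss, build_vocab, predict_extended_cached,
                 texts_to_ids, train_extension_cached, train_model)

logger = logging.getLogger(__name__)

EMBED_DIM_GRID = (50, 100, 200, 300)
LSTM_UNITS_GRID = (32, 48, 64, 80, 96)
DENSE_UNITS_GRID = (192, 224, 256, 288, 320)
LEARNING_RATE_GRID = (1e-3, 5e-3, 7e-3, 1e-2)


@dataclass(frozen=True)
class ModelSpec:
    embed_dim: int = 50
    lstm_units: int = 32
    dense_units: int = 192
    learning_rate: float = 1e-3
    trainable_embeddings: bool = True   # fixed
    bidirectional: bool = True          # fixed

    def __post_init__(self) -> None:
        checks = ((self.embed_dim, EMBED_DIM_GRID, "embed_dim"),
                  (self.lstm_units, LSTM_UNITS_GRID, "lstm_units"),
                  (self.dense_units, DENSE_UNITS_GRID, "dense_units"),
                  (self.learning_rate, LEARNING_RATE_GRID, "learning_rate"))
        for value, grid, name in checks:
            if value not in grid:
                raise ValueError(f"{name}={value} not in grid {grid}")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    epochs: int = 1
    extended_lr: float = 1e-2
    max_len: int = 256
    seed: int = 0


def full_grid(embed_dims=EMBED_DIM_GRID, lstm_units=LSTM_UNITS_GRID,
              dense_units=DENSE_UNITS_GRID, learning_rates=LEARNING_RATE_GRID,
              ) -> list[ModelSpec]:
    return [ModelSpec(e, u, d, lr) for e in embed_dims for u in lstm_units
            for d in dense_units for lr in learning_rates]


def build_baseline(spec: ModelSpec, vocab: dict[str, int],
                   word_vectors: dict[str, np.ndarray] | None = None,
                   feature_dim: int = 0, seed: int = 0) -> BiLSTMClassifier:
    """Embedding (pretrained init) -> BiLSTM -> dense ReLU -> dense sigmoid."""
    if word_vectors:
        any_dim = len(next(iter(word_vectors.values())))
        if any_dim != spec.embed_dim:
            raise ValueError(f"word-vector dim {any_dim} != spec.embed_dim {spec.embed_dim}")
    model = BiLSTMClassifier(embed_dim=spec.embed_dim, lstm_units=spec.lstm_units,
                             dense_units=spec.dense_units, vocab=vocab,
                             feature_dim=feature_dim, seed=seed)
    if word_vectors:
        model.load_pretrained(word_vectors)
    return model


def extend_model(model: BiLSTMClassifier, feature_dim: int,
                 seed: int | None = None) -> BiLSTMClassifier:
    """Attach the feature branch to a trained baseline (base stays frozen:
    only the new dense layer is ever trained afterwards)."""
    model.add_extension(feature_dim, seed=seed)
    return model


@dataclass
class FoldResult:
    fold: int
    spec: ModelSpec
    test_idx: np.ndarray
    y_true: np.ndarray
    proba_base: np.ndarray
    proba_ext: np.ndarray
    train_idx: np.ndarray          # every id touched during inner search/training
    inner_val_loss: float
    metrics: dict = field(default_factory=dict)
    model: object | None = None            # kept only when keep_models is set
    vocab: dict[str, int] | None = None


@dataclass
class NCVResult:
    folds: list[FoldResult]
    thresholds: tuple[float, float] = (0.5, 0.7)   # baseline, extended

    def fold_metric(self, which: str, threshold: float, averaging: str = "macro",
                    ) -> np.ndarray:
        out = []
        for f in self.folds:
            probs = f.proba_base if which == "baseline" else f.proba_ext
            out.append(evaluate(probs, f.y_true, threshold, averaging)["f1"])
        return np.asarray(out)

    def summary(self) -> dict:
        t_base, t_ext = self.thresholds
        base = self.fold_metric("baseline", t_base)
        ext = self.fold_metric("extended", t_ext)
        return {"baseline_macro_f1_mean": float(base.mean()),
                "baseline_macro_f1_sd": float(base.std(ddof=1)),
                "extended_macro_f1_mean": float(ext.mean()),
                "extended_macro_f1_sd": float(ext.std(ddof=1)),
                "winning_specs": [vars(f.spec) for f in self.folds]}


def _fit_once(spec: ModelSpec, texts: list[list[str]], y: np.ndarray,
              word_vectors: dict[str, np.ndarray] | None, cfg: TrainConfig,
              seed: int) -> tuple[BiLSTMClassifier, dict[str, int]]:
    vocab = build_vocab(texts)
    x = texts_to_ids(texts, vocab, cfg.max_len)
    model = build_baseline(spec, vocab, word_vectors, seed=seed)
    train_model(model, x, y, lr=spec.learning_rate, epochs=cfg.epochs,
                batch_size=cfg.batch_size, seed=seed)
    return model, vocab


def nested_cv(texts: list[list[str]], labels: np.ndarray, features: np.ndarray,
              word_vectors: dict[str, np.ndarray] | None = None,
              grid: list[ModelSpec] | None = None, k_outer: int = 10, k_inner: int = 5,
              n_trials: int = 10, cfg: TrainConfig | None = None, seed: int = 0,
              thresholds: tuple[float, float] = (0.5, 0.7),
              keep_models: bool = False, tune_thresholds: bool = False) -> NCVResult:
    """Stratified nested cross-validation of baseline and extended models.

    ``thresholds`` are the fixed (baseline, extended) decision thresholds.
    With ``tune_thresholds`` each fold additionally records, in its metrics,
    the threshold from the standard sweep grid that maximizes macro F1 on the
    outer-train predictions (opt-in; the fixed thresholds stay in force for
    the reported fold metrics)."""
    cfg = cfg or TrainConfig(seed=seed)
    labels = np.asarray(labels, dtype=np.float64)
    features = np.asarray(features, dtype=np.float64)
    if len(texts) != len(labels) or len(features) != len(labels):
        raise ValueError("texts, labels and features must be aligned")
    counts = np.bincount(labels.astype(int), minlength=2)
    if counts.min() < k_outer:
        raise ValueError(f"each class needs >= {k_outer} members for stratification, "
                         f"got counts {counts.tolist()}")
    grid = grid or full_grid()
    rng = np.random.default_rng(seed)

    outer = StratifiedKFold(n_splits=k_outer, shuffle=True, random_state=seed)
    folds: list[FoldResult] = []
    for fold_i, (train_idx, test_idx) in enumerate(outer.split(np.zeros(len(labels)), labels)):
        y_train = labels[train_idx]
        train_texts = [texts[i] for i in train_idx]

        if len(grid) <= n_trials:
            trial_specs = list(grid)
        else:
            trial_specs = [grid[i] for i in rng.choice(len(grid), size=n_trials,
                                                       replace=False)]
        inner = StratifiedKFold(n_splits=k_inner, shuffle=True,
                                random_state=seed + 1000 + fold_i)
        best_spec, best_loss = None, np.inf
        for trial_i, spec in enumerate(trial_specs):
            losses = []
            for in_train, in_val in inner.split(np.zeros(len(train_idx)), y_train):
                sub_texts = [train_texts[i] for i in in_train]
                model, vocab = _fit_once(spec, sub_texts, y_train[in_train],
                                         word_vectors, cfg,
                                         seed=seed + 7 * fold_i + trial_i)
                x_val = texts_to_ids([train_texts[i] for i in in_val], vocab, cfg.max_len)
                losses.append(bce_loss(model.predict_proba(x_val), y_train[in_val]))
            mean_loss = float(np.mean(losses))
            logger.info("fold %d trial %d %s: val loss %.4f", fold_i, trial_i, spec, mean_loss)
            if mean_loss < best_loss:
                best_spec, best_loss = spec, mean_loss

        # winner retrained on the full outer-train split
        model, vocab = _fit_once(best_spec, train_texts, y_train, word_vectors, cfg,
                                 seed=seed + 7 * fold_i)
        x_test = texts_to_ids([texts[i] for i in test_idx], vocab, cfg.max_len)
        proba_base = model.predict_proba(x_test)

        extend_model(model, features.shape[1])
        x_train = texts_to_ids(train_texts, vocab, cfg.max_len)
        a1_train = model.text_dense_out(x_train)
        train_extension_cached(model, features[train_idx], a1_train, y_train,
                               lr=cfg.extended_lr, epochs=cfg.epochs,
                               batch_size=cfg.batch_size, seed=seed + 7 * fold_i)
        a1_test = model.text_dense_out(x_test)
        proba_ext = predict_extended_cached(model, features[test_idx], a1_test)

        fold = FoldResult(fold=fold_i, spec=best_spec, test_idx=test_idx,
                          y_true=labels[test_idx], proba_base=proba_base,
                          proba_ext=proba_ext, train_idx=train_idx,
                          inner_val_loss=best_loss,
                          model=model if keep_models else None,
                          vocab=vocab if keep_models else None)
        fold.metrics = {
            "baseline_macro_f1": evaluate(proba_base, fold.y_true, thresholds[0])["f1"],
            "extended_macro_f1": evaluate(proba_ext, fold.y_true, thresholds[1])["f1"],
        }
        if tune_thresholds:
            train_base = model.predict_proba(texts_to_ids(train_texts, vocab, cfg.max_len))
            train_ext = predict_extended_cached(model, features[train_idx], a1_train)
            grid_t = np.round(np.arange(0.5, 0.951, 0.05), 10)
            for name, probs in (("baseline", train_base), ("extended", train_ext)):
                scores = [evaluate(probs, y_train, float(t))["f1"] for t in grid_t]
                fold.metrics[f"tuned_threshold_{name}"] = float(grid_t[int(np.argmax(scores))])
        folds.append(fold)
    return NCVResult(folds=folds, thresholds=thresholds)


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def evaluate(probabilities: np.ndarray, labels: np.ndarray, threshold: float = 0.5,
             averaging: str = "macro") -> dict[str, float]:
    """Precision/recall/F1 at a probability threshold.

    macro: unweighted mean of the two per-class scores; micro: pooled
    positive-class scores.  A single-class label vector triggers a warning and
    scores the absent class as 0.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    labels = np.asarray(labels).astype(int)
    preds = (np.asarray(probabilities) >= threshold).astype(int)
    if len(set(labels.tolist())) < 2:
        warnings.warn("single-class label vector: metrics for the absent class are 0",
                      stacklevel=2)
    tp = int(((preds == 1) & (labels == 1)).sum())
    fp = int(((preds == 1) & (labels == 0)).sum())
    fn = int(((preds == 0) & (labels == 1)).sum())
    tn = int(((preds == 0) & (labels == 0)).sum())
    p1, r1, f1_pos = _prf(tp, fp, fn)
    p0, r0, f1_neg = _prf(tn, fn, fp)
    if averaging == "macro":
        return {"precision": (p1 + p0) / 2, "recall": (r1 + r0) / 2,
                "f1": (f1_pos + f1_neg) / 2}
    if averaging == "micro":
        return {"precision": p1, "recall": r1, "f1": f1_pos}
    raise ValueError(f"averaging must be macro or micro, got {averaging!r}")


def threshold_sweep(fold_probs: list[np.ndarray], fold_labels: list[np.ndarray],
                    lo: float = 0.5, hi: float = 0.95, step: float = 0.05,
                    averaging: str = "macro") -> dict:
    """Per-threshold macro F1 across folds with mean and sd (the curve the
    extended-vs-baseline threshold analysis plots)."""
    thresholds = np.round(np.arange(lo, hi + step / 2, step), 10)
    table = np.zeros((len(fold_probs), len(thresholds)))
    for i, (probs, y) in enumerate(zip(fold_probs, fold_labels)):
        for j, t in enumerate(thresholds):
            table[i, j] = evaluate(probs, y, float(t), averaging)["f1"]
    ddof = 1 if len(fold_probs) > 1 else 0
    return {"thresholds": thresholds, "per_fold_f1": table,
            "mean_f1": table.mean(axis=0), "sd_f1": table.std(axis=0, ddof=ddof)}
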