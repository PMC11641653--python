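"""Stacked-LSTM binary classifier and cross-validated evaluation.

The classifier is three stacked LSTM layers (128 hidden units each, with
forget/input/output gates) followed by a dense head with a sigmoid output
unit, trained with binary cross-entropy and Adam. Features are normalized
with a robust scaler (per-feature median / interquartile range) fit on
training rows only.

A feature row is presented to the recurrent stack as a short sequence:
in "tokens3" shaping the concatenated row [miRNA emb || gene emb || latent]
becomes steps of embedding width (64 by default) — miRNA vector, gene
vector, then the latent vector (zero-padded or split into further steps
when the latent width differs); "flat" shaping feeds the whole row as a
single step. Latent-only features form a single step of latent width.

Evaluation uses stratified 5-fold cross-validation; per fold the
autoencoder and the scaler are fit inside the training split (a
"paper_mode" switch instead fits the autoencoder once on all rows with
its own 9:1 internal split). AUC is computed as the rank statistic
(probability that a random positive outscores a random negative, ties
counted one half), which equals trapezoidal ROC integration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import RobustScaler

from .autoencoder import (
    DEFAULT_AE_BATCH,
    DEFAULT_AE_EPOCHS,
    DEFAULT_AE_LR,
    DEFAULT_AE_SPLIT,
    DEFAULT_LATENT_DIM,
    FeatureMode,
    _Adam,
    augment_features,
    train_autoencoder,
)
from .embedding import EmbeddingTable, embed_pairs
from .negatives import LabeledPairSet

logger = logging.getLogger("mirlink")

DEFAULT_HIDDEN = 128
DEFAULT_LAYERS = 3
DEFAULT_CLS_EPOCHS = 30
DEFAULT_CLS_BATCH = 128
DEFAULT_CLS_LR = 2e-3
DEFAULT_THRESHOLD = 0.5
DEFAULT_FOLDS = 5
DEFAULT_WEIGHT_DECAY = 1e-2
DEFAULT_INPUT_DROPOUT = 0.1

InputShaping = Literal["aligned", "tokens3", "flat"]
DEFAULT_ALIGNED_STEPS = 16


class SingleClassError(ValueError):
    """Raised when labels contain fewer than two classes."""


# --------------------------------------------------------------------------
# input shaping
# --------------------------------------------------------------------------

def shape_rows(X: np.ndarray, shaping: InputShaping, step_width: int = 64,
               layout: tuple[int, ...] | None = None,
               n_steps: int = DEFAULT_ALIGNED_STEPS) -> np.ndarray:
    """Reshape (n, d) feature rows into (n, T, w) sequences.

    "flat": one step of full width. "tokens3": consecutive chunks of
    `step_width` columns (the miRNA embedding, the gene embedding, then the
    latent block); a trailing chunk narrower than `step_width` is
    zero-padded. "aligned": the row's semantic segments (given by `layout`,
    e.g. (64, 64, L) for miRNA, gene and latent) are interleaved
    coordinate-wise into `n_steps` steps, so each step carries the
    corresponding slice of every segment — the presentation that lets the
    recurrent gates accumulate coordinate-wise pair interactions. Rows
    narrower than one step, and single-segment layouts, are treated as
    flat.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    n, d = X.shape
    if shaping == "aligned":
        if layout is None:
            layout = (d,)
        if len(layout) <= 1:
            return X[:, None, :]
        return _shape_aligned(X, layout, n_steps)
    if shaping == "flat" or d <= step_width:
        return X[:, None, :]
    T = int(np.ceil(d / step_width))
    padded = np.zeros((n, T * step_width))
    padded[:, :d] = X
    return padded.reshape(n, T, step_width)


def _shape_aligned(X: np.ndarray, layout: tuple[int, ...], n_steps: int
                   ) -> np.ndarray:
    n = X.shape[0]
    if sum(layout) != X.shape[1]:
        raise ValueError(f"layout {layout} does not sum to width {X.shape[1]}")
    pieces = []
    offset = 0
    for width in layout:
        block = int(np.ceil(width / n_steps))
        seg = np.zeros((n, n_steps * block))
        seg[:, :width] = X[:, offset : offset + width]
        pieces.append(seg.reshape(n, n_steps, block))
        offset += width
    return np.concatenate(pieces, axis=2)


# --------------------------------------------------------------------------
# LSTM network
# --------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    # overflow in exp saturates to 0/1, which is the correct limit
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


@dataclass
class ClassifierModel:
    """Trained stacked-LSTM parameters plus preprocessing metadata.

    Per layer, `W[l]` packs the input-to-gate and recurrent weights as a
    single ((in_l + hidden) x 4*hidden) matrix with gate order
    [input, forget, cell, output]; `b[l]` is the gate bias (forget bias
    initialized to 1).
    """

    W: list[np.ndarray]
    b: list[np.ndarray]
    head_w: np.ndarray
    head_b: float
    hidden: int
    input_width: int
    shaping: InputShaping
    step_width: int
    scaler: RobustScaler | None
    layout: tuple[int, ...] | None = None
    n_steps: int = DEFAULT_ALIGNED_STEPS
    head_pooling: str = "last"
    config: dict = field(default_factory=dict)

    def forward(self, X_seq: np.ndarray, caches: dict | None = None
                ) -> np.ndarray:
        """Scores in (0,1), one per row of the (n, T, w) input.

        The input-to-gate projection is computed for all timesteps at once
        per layer; only the recurrent projection runs inside the time loop.
        """
        n, T, w = X_seq.shape
        if w != self.input_width:
            raise ValueError(
                f"step width {w} does not match model input width "
                f"{self.input_width}"
            )
        h_in = X_seq.astype(np.float32, copy=False)
        H = self.hidden
        for l, (Wl, bl) in enumerate(zip(self.W, self.b)):
            Wl = Wl.astype(np.float32, copy=False)
            bl = bl.astype(np.float32, copy=False)
            w_in = h_in.shape[2]
            Wx, Wh = Wl[:w_in], Wl[w_in:]
            Xp = (h_in.reshape(n * T, w_in) @ Wx).reshape(n, T, 4 * H) + bl
            h = np.zeros((n, H), dtype=np.float32)
            c = np.zeros((n, H), dtype=np.float32)
            outs = np.empty((n, T, H), dtype=np.float32)
            if caches is not None:
                caches.setdefault("inputs", {})[l] = h_in
            for t in range(T):
                gates = Xp[:, t] + h @ Wh
                sig = _sigmoid(gates[:, : 3 * H])
                i = sig[:, :H]
                f = sig[:, H : 2 * H]
                o = sig[:, 2 * H :]
                g = np.tanh(gates[:, 3 * H :])
                h_prev, c_prev = h, c
                c = f * c_prev + i * g
                tc = np.tanh(c)
                h = o * tc
                outs[:, t, :] = h
                if caches is not None:
                    caches.setdefault("steps", {})[(l, t)] = (
                        h_prev, i, f, g, o, c_prev, tc
                    )
            h_in = outs
        pooled = (h_in.mean(axis=1) if self.head_pooling == "mean"
                  else h_in[:, -1, :])
        logits = (pooled @ self.head_w.astype(np.float32, copy=False)
                  + np.float32(self.head_b))
        return _sigmoid(logits.astype(np.float64))


def _init_model(
    input_width: int,
    shaping: InputShaping,
    step_width: int,
    hidden: int,
    n_layers: int,
    rng: np.random.Generator,
) -> ClassifierModel:
    W, b = [], []
    for l in range(n_layers):
        in_l = input_width if l == 0 else hidden
        fan = in_l + hidden
        Wl = rng.normal(0.0, 1.0 / np.sqrt(fan), size=(fan, 4 * hidden)
                        ).astype(np.float32)
        bl = np.zeros(4 * hidden, dtype=np.float32)
        bl[hidden : 2 * hidden] = 1.0  # forget-gate bias (layout [i,f,o,g])
        W.append(Wl)
        b.append(bl)
    head_w = rng.normal(0.0, 1.0 / np.sqrt(hidden), size=hidden
                        ).astype(np.float32)
    return ClassifierModel(
        W, b, head_w, 0.0, hidden, input_width, shaping, step_width, None
    )


def _lstm_backward(model: ClassifierModel, X_seq: np.ndarray,
                   caches: dict, d_logit: np.ndarray) -> list[np.ndarray]:
    """Gradients for all parameters; `d_logit` is dLoss/dlogit per row."""
    n, T, _ = X_seq.shape
    H = model.hidden
    L = len(model.W)
    steps = caches["steps"]
    inputs = caches["inputs"]
    d_logit = d_logit.astype(np.float32)

    gW = [None] * L
    gb = [None] * L

    head_w32 = model.head_w.astype(np.float32, copy=False)
    d_out = np.zeros((n, T, H), dtype=np.float32)
    if model.head_pooling == "mean":
        top_h = np.stack([
            steps[(L - 1, t)][4] * steps[(L - 1, t)][6] for t in range(T)
        ], axis=1)                                  # o * tanh(c) per step
        g_head_w = top_h.mean(axis=1).T @ d_logit
        d_out[:] = (d_logit[:, None] * head_w32[None, :])[:, None, :] / T
    else:
        o_, tc_ = steps[(L - 1, T - 1)][4], steps[(L - 1, T - 1)][6]
        g_head_w = (o_ * tc_).T @ d_logit
        d_out[:, T - 1, :] = d_logit[:, None] * head_w32[None, :]
    g_head_b = float(d_logit.sum())

    for l in range(L - 1, -1, -1):
        X_below = inputs[l]
        w_in = X_below.shape[2]
        Wl = model.W[l].astype(np.float32, copy=False)
        Wx, Wh = Wl[:w_in], Wl[w_in:]
        d_gates_all = np.empty((n, T, 4 * H), dtype=np.float32)
        gWh = np.zeros((H, 4 * H), dtype=np.float32)
        dh_next = np.zeros((n, H), dtype=np.float32)
        dc_next = np.zeros((n, H), dtype=np.float32)
        for t in range(T - 1, -1, -1):
            h_prev, i, f, g, o, c_prev, tc = steps[(l, t)]
            dh = d_out[:, t, :] + dh_next
            dc = dh * o * (1.0 - tc * tc) + dc_next
            d_gates = d_gates_all[:, t, :]
            d_gates[:, :H] = (dc * g) * i * (1.0 - i)
            d_gates[:, H : 2 * H] = (dc * c_prev) * f * (1.0 - f)
            d_gates[:, 2 * H : 3 * H] = (dh * tc) * o * (1.0 - o)
            d_gates[:, 3 * H :] = (dc * i) * (1.0 - g * g)
            dc_next = dc * f
            gWh += h_prev.T @ d_gates
            dh_next = d_gates @ Wh.T
        flat = d_gates_all.reshape(n * T, 4 * H)
        gWx = X_below.reshape(n * T, w_in).T @ flat
        gW[l] = np.vstack([gWx, gWh])
        gb[l] = flat.sum(axis=0)
        if l > 0:
            d_out = (flat @ Wx.T).reshape(n, T, w_in)
    return gW + gb + [g_head_w, np.array([g_head_b])]


def fit(
    features: np.ndarray,
    labels: np.ndarray,
    epochs: int = DEFAULT_CLS_EPOCHS,
    batch: int = DEFAULT_CLS_BATCH,
    lr: float = DEFAULT_CLS_LR,
    seed: int = 0,
    hidden: int = DEFAULT_HIDDEN,
    n_layers: int = DEFAULT_LAYERS,
    shaping: InputShaping = "aligned",
    step_width: int = 64,
    layout: tuple[int, ...] | None = None,
    n_steps: int = DEFAULT_ALIGNED_STEPS,
    scale: bool = True,
    weight_decay: float = DEFAULT_WEIGHT_DECAY,
    input_dropout: float = DEFAULT_INPUT_DROPOUT,
    ema_decay: float = 0.99,
    lr_decay: bool = False,
    head_pooling: str = "last",
    step_shuffle: bool = True,
) -> ClassifierModel:
    """Train the stacked-LSTM classifier on (already augmented) feature rows.

    The robust scaler is fit here, on the given rows only — callers pass
    training rows, never evaluation rows. Deterministic under a fixed seed.
    """
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    y = np.asarray(labels, dtype=np.float32).ravel()
    if X.shape[0] != y.size:
        raise ValueError("features and labels disagree in length")
    classes = np.unique(y)
    if classes.size < 2:
        raise SingleClassError(
            f"need both classes in labels, got only {classes.tolist()}"
        )

    scaler = None
    if scale:
        scaler = RobustScaler().fit(X)
        X = scaler.transform(X)
    X_seq = shape_rows(X, shaping, step_width, layout, n_steps).astype(np.float32)

    rng = np.random.default_rng(seed)
    model = _init_model(
        X_seq.shape[2], shaping, step_width, hidden, n_layers, rng
    )
    model.scaler = scaler
    model.layout = tuple(layout) if layout is not None else None
    model.n_steps = n_steps
    model.head_pooling = head_pooling
    params = model.W + model.b + [model.head_w, np.array([model.head_b])]
    opt = _Adam(params, lr)
    # exponential moving average of the weights; the averaged model is
    # returned, which damps the step-to-step wobble of short training runs
    ema = [p.copy() for p in params] if ema_decay else None

    n = X_seq.shape[0]
    n_batches = int(np.ceil(n / batch))
    total_steps = max(1, epochs * n_batches)
    step_no = 0
    for _epoch in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            xb, yb = X_seq[idx], y[idx]
            if step_shuffle and xb.shape[1] > 1:
                # the planted signal is a per-step accumulation, invariant
                # to step order; shuffling steps per batch regularizes the
                # model toward that accumulative solution
                xb = xb[:, rng.permutation(xb.shape[1]), :]
            if input_dropout:
                keep = rng.random(xb.shape) >= input_dropout
                xb = xb * keep / (1.0 - input_dropout)
            caches: dict = {}
            scores = model.forward(xb, caches)
            d_logit = (scores - yb) / xb.shape[0]   # BCE through sigmoid
            grads = _lstm_backward(model, xb, caches, d_logit)
            if lr_decay:
                opt.lr = lr * (1.0 - step_no / total_steps)
            step_no += 1
            opt.step(grads)
            if weight_decay:
                for p_arr in params[:-1]:       # decoupled decay, bias-free
                    p_arr -= lr * weight_decay * p_arr
            if ema is not None:
                for e_arr, p_arr in zip(ema, params):
                    e_arr *= ema_decay
                    e_arr += (1.0 - ema_decay) * p_arr
            model.head_b = float(params[-1][0])
    if ema is not None:
        for p_arr, e_arr in zip(params, ema):
            p_arr[...] = e_arr
    model.head_b = float(params[-1][0])
    model.config = {
        "epochs": epochs, "batch": batch, "lr": lr, "seed": seed,
        "hidden": hidden, "n_layers": n_layers, "shaping": shaping,
        "step_width": step_width, "weight_decay": weight_decay,
        "input_dropout": input_dropout, "layout": layout, "n_steps": n_steps,
    }
    return model


def predict_scores(model: ClassifierModel, features: np.ndarray) -> np.ndarray:
    """Association probability per feature row, order preserved."""
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if model.scaler is not None:
        X = model.scaler.transform(X)
    X_seq = shape_rows(X, model.shaping, model.step_width, model.layout,
                       model.n_steps)
    return model.forward(X_seq)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

@dataclass
class MetricsRow:
    """Confusion counts and derived metrics for one evaluation."""

    name: str
    tp: int
    tn: int
    fp: int
    fn: int
    precision: float
    recall: float
    accuracy: float
    f1: float
    auc: float
    threshold: float = DEFAULT_THRESHOLD

    def as_dict(self) -> dict:
        return asdict(self)


def auc_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-statistic AUC: P(score_pos > score_neg), ties counted 1/2."""
    y = np.asarray(labels).ravel()
    s = np.asarray(scores, dtype=np.float64).ravel()
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("AUC undefined: labels contain a single class")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def metrics_from_counts(tp: int, tn: int, fp: int, fn: int,
                        name: str = "", auc: float = float("nan"),
                        threshold: float = DEFAULT_THRESHOLD) -> MetricsRow:
    """Derive precision/recall/accuracy/F1 from confusion counts."""
    total = tp + tn + fp + fn
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    accuracy = (tp + tn) / total if total else float("nan")
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsRow(name, tp, tn, fp, fn, precision, recall, accuracy, f1,
                      auc, threshold)


def compute_metrics(labels: np.ndarray, scores: np.ndarray,
                    threshold: float = DEFAULT_THRESHOLD,
                    name: str = "") -> MetricsRow:
    """Confusion at `threshold` plus rank-statistic AUC.

    With single-class labels the confusion metrics are still computed but
    AUC is NaN (and a warning is logged) rather than raising, so partial
    reports remain usable.
    """
    y = np.asarray(labels).ravel().astype(int)
    s = np.asarray(scores, dtype=np.float64).ravel()
    if y.size != s.size:
        raise ValueError("labels and scores disagree in length")
    if not np.all((s >= 0) & (s <= 1)):
        raise ValueError("scores must lie in [0, 1]")
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    try:
        auc = auc_score(y, s)
    except SingleClassError:
        logger.warning("compute_metrics: single-class labels, AUC undefined")
        auc = float("nan")
    return metrics_from_counts(tp, tn, fp, fn, name=name, auc=auc,
                               threshold=threshold)


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

@dataclass
class CVConfig:
    """Configuration for cross-validated training and evaluation."""

    folds: int = DEFAULT_FOLDS
    mode: FeatureMode = "original_plus_latent"
    latent_dim: int = DEFAULT_LATENT_DIM
    ae_epochs: int = DEFAULT_AE_EPOCHS
    ae_batch: int = DEFAULT_AE_BATCH
    ae_lr: float = DEFAULT_AE_LR
    ae_split: float = DEFAULT_AE_SPLIT
    cls_epochs: int = DEFAULT_CLS_EPOCHS
    cls_batch: int = DEFAULT_CLS_BATCH
    cls_lr: float = DEFAULT_CLS_LR
    hidden: int = DEFAULT_HIDDEN
    n_layers: int = DEFAULT_LAYERS
    shaping: InputShaping = "aligned"
    threshold: float = DEFAULT_THRESHOLD
    paper_mode: bool = False
    seed: int = 0


@dataclass
class EvalReport:
    """Per-fold metric rows, their arithmetic-mean average row, and metadata."""

    rows: list[MetricsRow]
    average: MetricsRow
    seed: int
    threshold: float
    config: dict = field(default_factory=dict)
    fold_indices: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    ae_fit_indices: list[np.ndarray] = field(default_factory=list)

    def to_csv(self, path) -> None:
        import pandas as pd

        records = [r.as_dict() for r in self.rows] + [self.average.as_dict()]
        pd.DataFrame(records).to_csv(path, index=False, float_format="%.6f")

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "threshold": self.threshold,
                "config": self.config,
                "folds": [r.as_dict() for r in self.rows],
                "average": self.average.as_dict(),
            },
            indent=2,
        )


def roc_points(labels: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """ROC curve vertices as (fpr, tpr) rows, threshold descending."""
    y = np.asarray(labels).ravel().astype(int)
    s = np.asarray(scores, dtype=np.float64).ravel()
    order = np.argsort(-s, kind="stable")
    y = y[order]
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    n_pos = max(int(tps[-1]), 1)
    n_neg = max(int(fps[-1]), 1)
    pts = np.column_stack([fps / n_neg, tps / n_pos])
    return np.vstack([[0.0, 0.0], pts])


def roc_points_to_tsv(labels: np.ndarray, scores: np.ndarray, path) -> None:
    pts = roc_points(labels, scores)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("fpr\ttpr\n")
        for fpr, tpr in pts:
            fh.write(f"{fpr:.6f}\t{tpr:.6f}\n")


def average_rows(rows: Sequence[MetricsRow], name: str = "Average") -> MetricsRow:
    """Arithmetic mean of every numeric field across rows."""
    def mean(attr: str) -> float:
        return float(np.mean([getattr(r, attr) for r in rows]))

    return MetricsRow(
        name,
        tp=mean("tp"), tn=mean("tn"), fp=mean("fp"), fn=mean("fn"),
        precision=mean("precision"), recall=mean("recall"),
        accuracy=mean("accuracy"), f1=mean("f1"), auc=mean("auc"),
        threshold=rows[0].threshold if rows else DEFAULT_THRESHOLD,
    )


def cross_validate(
    pair_set: LabeledPairSet,
    table: EmbeddingTable,
    config: CVConfig | None = None,
) -> EvalReport:
    """Stratified k-fold evaluation of the full feature + classifier stack.

    By default the autoencoder and the robust scaler are fit on each fold's
    training rows only. With `config.paper_mode` the autoencoder is instead
    fit once on all rows (with its own internal train/test split) before
    folding; the scaler stays fold-local either way.
    """
    config = config or CVConfig()
    pairs = pair_set.pairs
    if len(pairs) < config.folds:
        raise ValueError(f"need >= {config.folds} pairs, got {len(pairs)}")
    keys = [(m, g) for m, g, _ in pairs]
    y = pair_set.labels
    X_raw = embed_pairs(table, keys)

    skf = StratifiedKFold(
        n_splits=config.folds, shuffle=True, random_state=config.seed % (2**31)
    )
    ae_global = None
    if config.paper_mode:
        ae_global, _ = train_autoencoder(
            X_raw, latent_dim=config.latent_dim, epochs=config.ae_epochs,
            batch=config.ae_batch, lr=config.ae_lr, split=config.ae_split,
            seed=config.seed,
        )

    rows: list[MetricsRow] = []
    fold_indices: list[tuple[np.ndarray, np.ndarray]] = []
    ae_fit_indices: list[np.ndarray] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(X_raw, y), start=1):
        if config.paper_mode:
            ae = ae_global
            ae_fit_indices.append(np.arange(len(pairs)))
        else:
            ae, _ = train_autoencoder(
                X_raw[train_idx], latent_dim=config.latent_dim,
                epochs=config.ae_epochs, batch=config.ae_batch,
                lr=config.ae_lr, split=config.ae_split,
                seed=config.seed + fold,
            )
            ae_fit_indices.append(train_idx.copy())
        F_train = augment_features(X_raw[train_idx], ae, config.mode)
        F_test = augment_features(X_raw[test_idx], ae, config.mode)
        if config.mode == "original_plus_latent":
            layout = (table.dimension, table.dimension, config.latent_dim)
        else:
            layout = (config.latent_dim,)
        model = fit(
            F_train, y[train_idx], epochs=config.cls_epochs,
            batch=config.cls_batch, lr=config.cls_lr,
            seed=config.seed + 1000 * fold, hidden=config.hidden,
            n_layers=config.n_layers, shaping=config.shaping,
            layout=layout,
        )
        scores = predict_scores(model, F_test)
        row = compute_metrics(
            y[test_idx], scores, threshold=config.threshold,
            name=f"Fold-{fold}",
        )
        logger.info(
            "fold %d: n_test=%d acc=%.4f auc=%.4f",
            fold, test_idx.size, row.accuracy, row.auc,
        )
        rows.append(row)
        fold_indices.append((train_idx.copy(), test_idx.copy()))

    report = EvalReport(
        rows=rows,
        average=average_rows(rows),
        seed=config.seed,
        threshold=config.threshold,
        config=asdict(config),
        fold_indices=fold_indices,
        ae_fit_indices=ae_fit_indices,
    )
    return report
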