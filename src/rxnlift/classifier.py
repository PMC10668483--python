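"""One-hidden-layer MLP EC classifiers (ECX / ECXY / ECXYZ) on DRFP inputs.

Architecture and training recipe: linear input layer sized to the
fingerprint, a single hidden layer (default 1664 nodes, ReLU), a linear
output layer over the level-truncated EC vocabulary; cross-entropy loss,
Adam at learning rate 0.001, an exponential learning-rate schedule with
gamma 0.9 per epoch, and early stopping that monitors the mean validation
loss of the 5 most recent epochs, halting once the improvement of the
current validation loss over that mean drops below 0.001.

The network is implemented directly on numpy so that the attribution engine
has first-class access to the weights, and so training is deterministic for
a given master seed (which expands into separate fold / init / shuffle
streams).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import f1_score as _sk_f1

from .chem_io import ReactionRecord, make_cv_folds
from .drfp import FingerprintParams, encode_corpus
from .errors import InputError, RxnliftError

__all__ = [
    "TrainConfig",
    "ModelBundle",
    "EvalReport",
    "CVSummary",
    "train_mlp",
    "predict",
    "predict_proba",
    "evaluate",
    "run_cv",
    "label_shuffle_ablation",
    "hierarchy_inconsistency_rate",
]


@dataclass(frozen=True)
class TrainConfig:
    hidden_size: int = 1664
    learning_rate: float = 0.001
    scheduler_gamma: float = 0.9
    early_stop_window: int = 5
    early_stop_min_delta: float = 0.001
    max_epochs: int = 100
    batch_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.hidden_size, self.max_epochs, self.batch_size) < 1:
            raise InputError("hidden_size, max_epochs, batch_size must be positive")
        if self.early_stop_window < 1:
            raise InputError("early_stop_window must be >= 1")
        if self.learning_rate <= 0 or self.scheduler_gamma <= 0:
            raise InputError("learning_rate and scheduler_gamma must be positive")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class ModelBundle:
    """Self-describing trained MLP: weights, vocabulary, provenance."""

    W1: np.ndarray  # (input_dim, hidden)
    b1: np.ndarray
    W2: np.ndarray  # (hidden, n_classes)
    b2: np.ndarray
    hidden_activation: str
    label_vocabulary: list[str]
    fingerprint_params: FingerprintParams
    train_config: Optional[TrainConfig] = None

    @property
    def layer_dims(self) -> tuple[int, int, int]:
        return (self.W1.shape[0], self.W1.shape[1], self.W2.shape[1])

    def logits(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=self.W1.dtype))
        if X.shape[1] != self.W1.shape[0]:
            raise InputError(
                f"input dim {X.shape[1]} != model input dim {self.W1.shape[0]}"
            )
        h = np.maximum(X @ self.W1 + self.b1, 0.0)
        return h @ self.W2 + self.b2

    def save(self, path) -> None:
        meta = {
            "hidden_activation": self.hidden_activation,
            "label_vocabulary": self.label_vocabulary,
            "fingerprint_params": self.fingerprint_params.to_dict(),
            "train_config": self.train_config.to_dict() if self.train_config else None,
        }
        np.savez_compressed(
            path, W1=self.W1, b1=self.b1, W2=self.W2, b2=self.b2, meta=json.dumps(meta)
        )

    @classmethod
    def load(cls, path) -> "ModelBundle":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            return cls(
                W1=data["W1"],
                b1=data["b1"],
                W2=data["W2"],
                b2=data["b2"],
                hidden_activation=meta["hidden_activation"],
                label_vocabulary=list(meta["label_vocabulary"]),
                fingerprint_params=FingerprintParams.from_dict(meta["fingerprint_params"]),
                train_config=TrainConfig(**meta["train_config"]) if meta["train_config"] else None,
            )


@dataclass
class EvalReport:
    accuracy: float
    macro_f1: float
    confusion: np.ndarray
    labels: list[str]
    per_class: list[tuple[str, int, float]]  # (label, support, accuracy)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "labels": self.labels,
            "confusion": self.confusion.tolist(),
            "per_class": [
                {"label": l, "support": s, "accuracy": a} for l, s, a in self.per_class
            ],
        }


@dataclass
class CVSummary:
    fold_reports: list[EvalReport]
    models: list[ModelBundle]
    mean_accuracy: float
    sd_accuracy: float
    mean_macro_f1: float
    sd_macro_f1: float
    loss_histories: list[dict]


# --------------------------------------------------------------------------
# Training
# --------------------------------------------------------------------------

def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _xent(logits: np.ndarray, y_idx: np.ndarray) -> float:
    p = _softmax(logits)
    return float(-np.mean(np.log(np.clip(p[np.arange(len(y_idx)), y_idx], 1e-12, None))))


def expand_seed(master: int, *names: str) -> dict[str, int]:
    """Expand one master seed into named deterministic sub-seeds (< 2^31)."""
    ss = np.random.SeedSequence(master)
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(names, children)
    }


def train_mlp(
    X: np.ndarray,
    y: Sequence[str],
    X_val: np.ndarray,
    y_val: Sequence[str],
    config: Optional[TrainConfig] = None,
    fingerprint_params: Optional[FingerprintParams] = None,
) -> tuple[ModelBundle, dict]:
    """Train the MLP; return the bundle and per-epoch loss history.

    History dict: {"train_loss": [...], "val_loss": [...], "stopped_epoch": e}.
    """
    if config is None:
        config = TrainConfig()
    X = np.asarray(X, dtype=np.float32)
    X_val = np.asarray(X_val, dtype=np.float32)
    if X.shape[0] != len(y):
        raise InputError("X rows must match y length")
    vocab = sorted(set(y) | set(y_val))
    if len(set(y)) < 2:
        raise InputError("training labels must contain >= 2 distinct classes")
    lab_to_idx = {l: i for i, l in enumerate(vocab)}
    y_idx = np.array([lab_to_idx[l] for l in y])
    yv_idx = np.array([lab_to_idx[l] for l in y_val])

    d, h, c = X.shape[1], config.hidden_size, len(vocab)
    seeds = expand_seed(config.seed, "init", "shuffle")
    rng_init = np.random.default_rng(seeds["init"])
    rng_shuf = np.random.default_rng(seeds["shuffle"])

    # He-normal initialisation for ReLU
    W1 = (rng_init.standard_normal((d, h)) * np.sqrt(2.0 / d)).astype(np.float32)
    b1 = np.zeros(h, dtype=np.float32)
    W2 = (rng_init.standard_normal((h, c)) * np.sqrt(2.0 / h)).astype(np.float32)
    b2 = np.zeros(c, dtype=np.float32)

    params = [W1, b1, W2, b2]
    m_state = [np.zeros_like(p) for p in params]
    v_state = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0

    history: dict = {"train_loss": [], "val_loss": [], "stopped_epoch": None}
    n = X.shape[0]
    for epoch in range(config.max_epochs):
        lr = config.learning_rate * config.scheduler_gamma**epoch
        order = rng_shuf.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X[idx], y_idx[idx]
            z1 = xb @ W1 + b1
            a1 = np.maximum(z1, 0.0)
            logits = a1 @ W2 + b2
            p = _softmax(logits)
            loss = -np.mean(np.log(np.clip(p[np.arange(len(yb)), yb], 1e-12, None)))
            if not np.isfinite(loss):
                raise RxnliftError(f"NaN/inf loss at epoch {epoch}; aborting")
            epoch_losses.append(float(loss))
            # backward
            g_logits = p
            g_logits[np.arange(len(yb)), yb] -= 1.0
            g_logits /= len(yb)
            gW2 = a1.T @ g_logits
            gb2 = g_logits.sum(axis=0)
            g_a1 = g_logits @ W2.T
            g_z1 = g_a1 * (z1 > 0)
            gW1 = xb.T @ g_z1
            gb1 = g_z1.sum(axis=0)
            t += 1
            for p_, g_, m_, v_ in zip(params, [gW1, gb1, gW2, gb2], m_state, v_state):
                m_ *= beta1
                m_ += (1 - beta1) * g_
                v_ *= beta2
                v_ += (1 - beta2) * g_ * g_
                mhat = m_ / (1 - beta1**t)
                vhat = v_ / (1 - beta2**t)
                p_ -= lr * mhat / (np.sqrt(vhat) + eps)

        history["train_loss"].append(float(np.mean(epoch_losses)))
        val_loss = _xent(
            np.maximum(X_val @ W1 + b1, 0.0) @ W2 + b2, yv_idx
        ) if len(yv_idx) else history["train_loss"][-1]
        history["val_loss"].append(val_loss)

        w = config.early_stop_window
        if len(history["val_loss"]) > w:
            recent_mean = float(np.mean(history["val_loss"][-w - 1 : -1]))
            if recent_mean - val_loss < config.early_stop_min_delta:
                history["stopped_epoch"] = epoch
                break

    if fingerprint_params is None:
        fingerprint_params = FingerprintParams(dim=d)
    bundle = ModelBundle(
        W1=W1,
        b1=b1,
        W2=W2,
        b2=b2,
        hidden_activation="relu",
        label_vocabulary=vocab,
        fingerprint_params=fingerprint_params,
        train_config=config,
    )
    return bundle, history


# --------------------------------------------------------------------------
# Inference & evaluation
# --------------------------------------------------------------------------

def predict_proba(model: ModelBundle, X: np.ndarray) -> np.ndarray:
    # float64 softmax so the probabilities are normalised to ~1e-16
    return _softmax(model.logits(X).astype(np.float64))


def predict(model: ModelBundle, x: np.ndarray, top_k: int = 3) -> list[tuple[str, float]]:
    """Ranked (label, probability) list for one input vector."""
    p = predict_proba(model, np.atleast_2d(x))[0]
    order = np.argsort(-p, kind="stable")
    return [(model.label_vocabulary[i], float(p[i])) for i in order[:top_k]]


def evaluate(model: ModelBundle, X_test: np.ndarray, y_test: Sequence[str]) -> EvalReport:
    """Accuracy, macro F1 (unweighted per-class mean) and confusion counts."""
    if len(y_test) == 0:
        raise InputError("empty test set")
    p = predict_proba(model, X_test)
    pred_idx = p.argmax(axis=1)
    y_pred = [model.label_vocabulary[i] for i in pred_idx]
    labels = list(model.label_vocabulary)
    labels += sorted(set(y_test) - set(labels))
    cm = _sk_confusion(list(y_test), y_pred, labels=labels)
    acc = float(np.trace(cm) / cm.sum())
    macro = float(_sk_f1(list(y_test), y_pred, labels=labels, average="macro", zero_division=0))
    per_class = []
    for i, lab in enumerate(labels):
        support = int(cm[i].sum())
        if support:
            per_class.append((lab, support, float(cm[i, i] / support)))
    return EvalReport(accuracy=acc, macro_f1=macro, confusion=cm, labels=labels, per_class=per_class)


def _corpus_arrays(records, params):
    index = encode_corpus(records, params, keep_fingerprints=False)
    return index.matrix.astype(np.float32), index


def run_cv(
    records: Sequence[ReactionRecord],
    level: int = 1,
    k: int = 4,
    params: Optional[FingerprintParams] = None,
    config: Optional[TrainConfig] = None,
    X: Optional[np.ndarray] = None,
) -> CVSummary:
    """k-fold cross-validated training at one EC level (default 4-fold)."""
    if params is None:
        params = FingerprintParams()
    if config is None:
        config = TrainConfig()
    if X is None:
        X, _ = _corpus_arrays(records, params)
    y = np.array([r.ec.truncate(level) for r in records])
    seeds = expand_seed(config.seed, "folds", "train")
    folds = make_cv_folds(records, k=k, level=level, seed=seeds["folds"])
    reports, models, histories = [], [], []
    for f, (tr, va, te) in enumerate(folds):
        fold_cfg = TrainConfig(**{**config.to_dict(), "seed": seeds["train"] + f})
        bundle, hist = train_mlp(
            X[tr], y[tr], X[va], y[va], fold_cfg, fingerprint_params=params
        )
        reports.append(evaluate(bundle, X[te], y[te]))
        models.append(bundle)
        histories.append(hist)
    accs = [r.accuracy for r in reports]
    f1s = [r.macro_f1 for r in reports]
    return CVSummary(
        fold_reports=reports,
        models=models,
        mean_accuracy=float(np.mean(accs)),
        sd_accuracy=float(np.std(accs)),
        mean_macro_f1=float(np.mean(f1s)),
        sd_macro_f1=float(np.std(f1s)),
        loss_histories=histories,
    )


def shuffle_labels(y: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Permute ceil(fraction * n) labels uniformly among themselves."""
    if not 0.0 <= fraction <= 1.0:
        raise InputError("shuffle fraction must be in [0, 1]")
    y = np.array(y, copy=True)
    m = int(np.ceil(fraction * len(y)))
    if m < 2:
        return y
    pos = rng.choice(len(y), size=m, replace=False)
    y[pos] = y[pos[rng.permutation(m)]]
    return y


def label_shuffle_ablation(
    records: Sequence[ReactionRecord],
    fractions: Sequence[float],
    level: int = 1,
    params: Optional[FingerprintParams] = None,
    config: Optional[TrainConfig] = None,
    seed: Optional[int] = None,
) -> list[dict]:
    """Robustness-to-label-noise ablation.

    For each fraction p, every training fold has ceil(p*n) of its labels
    permuted (test labels untouched) before training; returns rows of
    {fraction, mean_accuracy, sd_accuracy}.
    """
    if params is None:
        params = FingerprintParams()
    if config is None:
        config = TrainConfig()
    if seed is None:
        seed = config.seed
    X, _ = _corpus_arrays(records, params)
    y = np.array([r.ec.truncate(level) for r in records])
    seeds = expand_seed(config.seed, "folds", "train")
    shuffle_seeds = expand_seed(seed, "shuffle")
    folds = make_cv_folds(records, k=4, level=level, seed=seeds["folds"])
    rows = []
    for p in fractions:
        rng = np.random.default_rng(shuffle_seeds["shuffle"])
        accs = []
        for f, (tr, va, te) in enumerate(folds):
            y_tr = shuffle_labels(y[tr], p, rng)
            fold_cfg = TrainConfig(**{**config.to_dict(), "seed": seeds["train"] + f})
            try:
                bundle, _ = train_mlp(X[tr], y_tr, X[va], y[va], fold_cfg, fingerprint_params=params)
            except InputError:
                continue  # degenerate shuffle collapsed training to one class
            accs.append(evaluate(bundle, X[te], y[te]).accuracy)
        rows.append(
            {
                "fraction": float(p),
                "mean_accuracy": float(np.mean(accs)),
                "sd_accuracy": float(np.std(accs)),
            }
        )
    return rows


def hierarchy_inconsistency_rate(
    models: Sequence[ModelBundle], X: np.ndarray
) -> float:
    """Fraction of inputs whose top-1 predictions across independently
    trained level models disagree on their shared EC prefix.

    The three level models are trained independently, so nothing constrains
    e.g. the ECXYZ top prediction to start with the ECX top prediction; this
    reports how often that happens rather than "fixing" it.
    """
    X = np.atleast_2d(X)
    preds = []
    for m in models:
        p = predict_proba(m, X)
        preds.append([m.label_vocabulary[i] for i in p.argmax(axis=1)])
    bad = 0
    for row in zip(*preds):
        ordered = sorted(row, key=lambda s: s.count("."))
        for shorter, longer in zip(ordered, ordered[1:]):
            if not (longer + ".").startswith(shorter + "."):
                bad += 1
                break
    return bad / X.shape[0]
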