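"""Network assembly, training, metrics and the stratified CV harness.

Architecture: kernel layer (Nystrom projection of every window) -> flatten
-> linear fully-connected layer (``hidden_units`` nodes, no activation)
-> linear output layer (``n_classes`` nodes).  Keeping the head strictly
linear is what makes the positive-weight-path interpretation exact.

Training minimizes elementwise binary cross-entropy-with-logits against
one-hot targets with Adam.  Anchor motifs and positions are trainable;
after every optimizer step the anchor constraints are re-projected and the
Gram inverse square root is recomputed (it is treated as a constant within
a step: stop-gradient).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from cmkn.nystrom_layer import (
    AnchorSet,
    NystromState,
    gram_inverse_sqrt,
    init_anchors,
    project_motif_array,
    project_position_array,
    sample_pairs,
)
from cmkn.pam_kernel import PAMParams, sequence_windows
from cmkn.seq_io import EncodedSequence, circle_positions

logger = logging.getLogger("cmkn")


class MetricUndefinedError(ValueError):
    """A rank metric was requested on a single-class label vector."""


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of a CMKN model.

    ``beta`` may be the string ``"auto"``, meaning ``|x|^2 / 10`` resolved
    from the (fixed) training sequence length at build time.
    """

    k: int = 5
    alpha: float = 1.0
    beta: float | str = "auto"
    sigma: float = 4.0
    n_anchors: int = 50
    hidden_units: int = 200
    n_classes: int = 2
    epochs: int = 50
    learning_rate: float = 1e-3
    anchor_learning_rate: float | None = None  # None: same as learning_rate
    batch_size: int | None = None  # None: full batch if <= 2048 samples, else 128
    seed: int = 0
    optimizer_name: str = "adam"
    weight_decay: float = 0.0
    loss: str = "bce"  # "bce" (elementwise, one-hot targets) or "softmax"
    train_positions: bool = True
    epsilon: float = 1e-6
    m_pairs: int | None = None  # None: max(100 * n_anchors, 3000), capped

    def __post_init__(self) -> None:
        for name in ("k", "n_anchors", "hidden_units", "n_classes", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if isinstance(self.beta, str) and self.beta != "auto":
            raise ValueError("beta must be a positive float or 'auto'")
        if self.optimizer_name not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer_name!r}")
        if self.loss not in ("bce", "softmax"):
            raise ValueError(f"unknown loss {self.loss!r}")

    def pam_params(self, length: int) -> PAMParams:
        beta = length**2 / 10.0 if self.beta == "auto" else float(self.beta)
        return PAMParams(alpha=self.alpha, beta=beta, sigma=self.sigma, k=self.k)


def synthetic_protocol_config(seed: int = 0) -> ModelConfig:
    """Training recipe for the synthetic two-class benchmark.

    Kernel hyperparameters follow the published protocol (k=5, sigma=4,
    alpha=1, beta=1000, 50 anchors, 50 epochs, 200 hidden units).  The
    optimizer settings are unreported in the original work and were tuned
    here: Adam with lr 1e-2 for the head, 0.2 for the anchor motifs,
    weight decay 5e-5, mini-batches of 64, anchor positions frozen after
    k-means init, 20000 sampled init pairs.
    """
    return ModelConfig(
        k=5,
        alpha=1.0,
        beta=1000.0,
        sigma=4.0,
        n_anchors=50,
        hidden_units=200,
        epochs=50,
        learning_rate=1e-2,
        anchor_learning_rate=0.2,
        batch_size=64,
        weight_decay=5e-5,
        train_positions=False,
        m_pairs=20000,
        seed=seed,
    )


@dataclass
class TrainedModel:
    anchors: AnchorSet
    nystrom: NystromState
    W1: np.ndarray  # hidden x (n_windows * n_anchors)
    b1: np.ndarray
    W2: np.ndarray  # n_classes x hidden
    b2: np.ndarray
    config: ModelConfig
    pam: PAMParams
    input_length: int
    training_log: list[float] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return self.input_length - self.pam.k + 1

    @property
    def weight_stack(self) -> list[np.ndarray]:
        """FC weight matrices from the kernel layer towards the output."""
        return [self.W1, self.W2]


def _check_lengths(data: Sequence[EncodedSequence], k: int) -> int:
    lengths = {x.length for x in data}
    if len(lengths) != 1:
        raise ValueError(f"fixed-length model requires equal sequence lengths, got {sorted(lengths)}")
    (length,) = lengths
    if length < k:
        raise ValueError(f"sequence length {length} < motif length {k}")
    return length


def build_model(
    config: ModelConfig,
    train_data: Sequence[EncodedSequence],
    seed: int | None = None,
) -> TrainedModel:
    """Initialize anchors from the training data and FC weights from a
    symmetric uniform scheme (untrained model)."""
    if not train_data:
        raise ValueError("empty training set")
    seed = config.seed if seed is None else seed
    length = _check_lengths(train_data, config.k)
    pam = config.pam_params(length)

    n_windows = length - config.k + 1
    total_windows = n_windows * len(train_data)
    m = config.m_pairs or max(100 * config.n_anchors, 3000)
    m = min(m, total_windows)
    if m < config.n_anchors:
        raise ValueError("not enough windows to initialize the anchors")
    pairs = sample_pairs(list(train_data), m, config.k, seed=seed)
    anchors = init_anchors(pairs, config.n_anchors, seed=seed)
    nystrom = gram_inverse_sqrt(anchors, pam, epsilon=config.epsilon)

    rng = np.random.default_rng(seed)
    fan1 = n_windows * config.n_anchors
    W1 = rng.uniform(-1, 1, size=(config.hidden_units, fan1)) / np.sqrt(fan1)
    b1 = np.zeros(config.hidden_units)
    W2 = rng.uniform(-1, 1, size=(config.n_classes, config.hidden_units)) / np.sqrt(
        config.hidden_units
    )
    b2 = np.zeros(config.n_classes)
    return TrainedModel(
        anchors=anchors,
        nystrom=nystrom,
        W1=W1,
        b1=b1,
        W2=W2,
        b2=b2,
        config=config,
        pam=pam,
        input_length=length,
    )


def _window_tensor(data: Sequence[EncodedSequence], k: int) -> np.ndarray:
    """Stack flattened windows of equal-length sequences: (B, P, |A|k)."""
    return np.stack([sequence_windows(x, k) for x in data])


def _forward(
    win: np.ndarray,
    pos: np.ndarray,
    model: TrainedModel,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Returns (k0, psi_flat, hidden, logits)."""
    p = model.pam
    dots = win @ model.anchors.motifs_flat.T  # B x P x n
    cosines = pos @ model.anchors.positions.T  # P x n
    k0 = np.exp(p.alpha * (dots - p.k) + p.position_scale * (cosines - 1.0)[None])
    psi = k0 @ model.nystrom.K_ZZ_inv_sqrt
    flat = psi.reshape(psi.shape[0], -1)
    hidden = flat @ model.W1.T + model.b1
    logits = hidden @ model.W2.T + model.b2
    return k0, flat, hidden, logits


def _bce_with_logits(z: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean elementwise BCE-with-logits loss and its gradient wrt z."""
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    grad = (1.0 / (1.0 + np.exp(-z)) - t) / z.size
    return float(loss.mean()), grad


def _softmax_ce(z: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    zmax = z.max(axis=1, keepdims=True)
    logsumexp = zmax + np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    loss = float(((logsumexp - z) * t).sum(axis=1).mean())
    grad = (np.exp(z - logsumexp) - t) / z.shape[0]
    return loss, grad


class _Adam:
    def __init__(self, params: list[np.ndarray], lrs: list[float], beta1=0.9, beta2=0.999, eps=1e-8):
        self.lrs, self.b1, self.b2, self.eps = lrs, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lrs[i] * mhat / (np.sqrt(vhat) + self.eps)


class _SGD:
    def __init__(self, params: list[np.ndarray], lrs: list[float]):
        self.lrs = lrs

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        for p, g, lr in zip(params, grads, self.lrs):
            p -= lr * g


def train(
    model: TrainedModel,
    data: Sequence[EncodedSequence],
    labels: Sequence[int] | np.ndarray,
) -> TrainedModel:
    """Train in place (and return) the model on equal-length sequences."""
    cfg = model.config
    labels = np.asarray(labels, dtype=int)
    if labels.ndim == 2:  # one-hot input accepted
        targets = labels.astype(float)
        labels = labels.argmax(axis=1)
    else:
        targets = np.eye(cfg.n_classes)[labels]
    if labels.min() < 0 or labels.max() >= cfg.n_classes:
        raise ValueError("labels out of range for the configured class count")
    length = _check_lengths(data, cfg.k)
    if length != model.input_length:
        raise ValueError(f"model was built for length {model.input_length}, got {length}")

    win = _window_tensor(data, cfg.k)
    pos = circle_positions(length, count=model.n_windows)
    B = win.shape[0]
    batch = cfg.batch_size or (B if B <= 2048 else 128)
    loss_fn = _bce_with_logits if cfg.loss == "bce" else _softmax_ce

    anchor_lr = cfg.anchor_learning_rate if cfg.anchor_learning_rate is not None else cfg.learning_rate
    params = [model.W1, model.b1, model.W2, model.b2, model.anchors.motifs]
    lrs = [cfg.learning_rate] * 4 + [anchor_lr]
    if cfg.train_positions:
        params.append(model.anchors.positions)
        lrs.append(anchor_lr)
    opt_cls = _Adam if cfg.optimizer_name == "adam" else _SGD
    opt = opt_cls(params, lrs)
    rng = np.random.default_rng(cfg.seed)
    p = model.pam

    for epoch in range(cfg.epochs):
        order = rng.permutation(B)
        epoch_losses = []
        for start in range(0, B, batch):
            idx = order[start : start + batch]
            wb, tb = win[idx], targets[idx]

            # K_ZZ^{-1/2} from current anchors; constant within the step
            model.nystrom = gram_inverse_sqrt(model.anchors, p, epsilon=cfg.epsilon)
            k0, flat, hidden, logits = _forward(wb, pos, model)
            loss, dz = loss_fn(logits, tb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch + 1}; "
                    "reduce the learning rate or check the kernel hyperparameters"
                )
            epoch_losses.append(loss)

            dW2 = dz.T @ hidden
            db2 = dz.sum(axis=0)
            dh = dz @ model.W2
            dW1 = dh.T @ flat
            db1 = dh.sum(axis=0)
            dflat = dh @ model.W1
            dpsi = dflat.reshape(k0.shape)
            dk0 = (dpsi @ model.nystrom.K_ZZ_inv_sqrt) * k0  # inv-sqrt symmetric
            n, a, kk = model.anchors.motifs.shape
            dmot_flat = p.alpha * np.einsum("bpi,bpd->id", dk0, wb)
            dmot = dmot_flat.reshape(n, kk, a).transpose(0, 2, 1)
            if cfg.weight_decay:
                dW1 = dW1 + cfg.weight_decay * model.W1
                dW2 = dW2 + cfg.weight_decay * model.W2
            grads = [dW1, db1, dW2, db2, dmot]
            if cfg.train_positions:
                grads.append(p.position_scale * np.einsum("bpi,pc->ic", dk0, pos))
            opt.step(params, grads)

            # re-impose the anchor constraints after the step
            model.anchors.motifs[...] = project_motif_array(model.anchors.motifs)
            model.anchors.positions[...] = project_position_array(model.anchors.positions)

        mean_loss = float(np.mean(epoch_losses))
        model.training_log.append(mean_loss)
        logger.info("epoch %d/%d loss %.6f", epoch + 1, cfg.epochs, mean_loss)

    model.nystrom = gram_inverse_sqrt(model.anchors, p, epsilon=cfg.epsilon)
    return model


def predict(
    model: TrainedModel,
    data: Sequence[EncodedSequence],
) -> tuple[np.ndarray, np.ndarray]:
    """Output logits (B x n_classes) and argmax labels for a batch."""
    length = _check_lengths(data, model.pam.k)
    if length != model.input_length:
        raise ValueError(f"model expects length {model.input_length}, got {length}")
    win = _window_tensor(data, model.pam.k)
    pos = circle_positions(length, count=model.n_windows)
    *_, logits = _forward(win, pos, model)
    return logits, logits.argmax(axis=1)


# -- metrics ----------------------------------------------------------------

@dataclass
class EvalReport:
    accuracy: float
    f1: float
    auroc: float
    auprc: float
    mcc: float
    confusion: np.ndarray
    per_fold: list["EvalReport"] = field(default_factory=list)
    std: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "f1": self.f1,
            "auroc": self.auroc,
            "auprc": self.auprc,
            "mcc": self.mcc,
            "confusion": self.confusion.tolist(),
        }
        if self.per_fold:
            d["per_fold"] = [r.to_dict() for r in self.per_fold]
            d["std"] = self.std
        return d


def _positive_scores(scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 2:
        return scores[:, 1] - scores[:, 0]
    return scores


def _predicted_labels(scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 2:
        return scores.argmax(axis=1)
    return (scores > 0).astype(int)


def confusion_table(pred: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """2x2 table [[TN, FP], [FN, TP]] with class 1 as positive."""
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    tp = int(np.sum((pred == 1) & (labels == 1)))
    return np.array([[tn, fp], [fn, tp]])


def mcc_from_confusion(confusion: np.ndarray) -> float:
    (tn, fp), (fn, tp) = confusion.astype(float)
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        warnings.warn("MCC undefined (zero denominator); reporting 0", RuntimeWarning)
        return 0.0
    return float((tp * tn - fp * fn) / denom)


def _roc_pr_points(score: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, ...]:
    """Cumulative TP/FP counts at every distinct descending threshold."""
    order = np.argsort(-score, kind="mergesort")
    s, y = score[order], labels[order]
    tps = np.cumsum(y == 1).astype(float)
    fps = np.cumsum(y == 0).astype(float)
    distinct = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    return tps[distinct], fps[distinct]


def auroc_score(score: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoidal area under the ROC curve."""
    tps, fps = _roc_pr_points(score, labels)
    tpr = np.r_[0.0, tps / tps[-1]]
    fpr = np.r_[0.0, fps / fps[-1]]
    return float(np.trapezoid(tpr, fpr))


def auprc_score(score: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoidal area under the precision-recall curve (anchored at
    recall 0 with precision 1, matching the usual curve construction)."""
    tps, fps = _roc_pr_points(score, labels)
    recall = np.r_[0.0, tps / tps[-1]]
    precision = np.r_[1.0, tps / (tps + fps)]
    return float(np.trapezoid(precision, recall))


def evaluate(scores: np.ndarray, labels: Sequence[int] | np.ndarray) -> EvalReport:
    """Compute accuracy/F1/MCC at the argmax threshold plus trapezoidal
    auROC and auPRC from continuous scores.

    ``scores`` is either a (B, 2) logit array or a 1-D positive-class
    score vector (argmax threshold then = score > 0).
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty label vector")
    if len(np.unique(labels)) < 2:
        raise MetricUndefinedError(
            "rank metrics (auROC/auPRC) are undefined on a single-class label vector"
        )
    score = _positive_scores(scores)
    pred = _predicted_labels(scores)
    conf = confusion_table(pred, labels)
    (tn, fp), (fn, tp) = conf
    accuracy = (tp + tn) / conf.sum()
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    return EvalReport(
        accuracy=float(accuracy),
        f1=float(f1),
        auroc=auroc_score(score, labels),
        auprc=auprc_score(score, labels),
        mcc=mcc_from_confusion(conf),
        confusion=conf,
    )


def stratified_folds(
    labels: np.ndarray, folds: int, seed: int | None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic stratified partition, reusable across configs."""
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels)
    if np.any(counts[counts > 0] < folds):
        raise ValueError(f"every class needs at least {folds} members for {folds}-fold CV")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(labels.size), labels)]


def cross_validate(
    config: ModelConfig,
    data: Sequence[EncodedSequence],
    labels: Sequence[int] | np.ndarray,
    folds: int = 5,
    seed: int | None = None,
) -> EvalReport:
    """Fivefold (by default) stratified CV; fold splits depend only on
    ``labels``, ``folds`` and ``seed``, so they are fixed across configs."""
    labels = np.asarray(labels, dtype=int)
    seed = config.seed if seed is None else seed
    reports: list[EvalReport] = []
    for fold, (tr, te) in enumerate(stratified_folds(labels, folds, seed)):
        model = build_model(config, [data[i] for i in tr], seed=seed + fold)
        train(model, [data[i] for i in tr], labels[tr])
        scores, _ = predict(model, [data[i] for i in te])
        reports.append(evaluate(scores, labels[te]))
        logger.info("fold %d/%d accuracy %.4f", fold + 1, folds, reports[-1].accuracy)
    metrics = {
        name: np.array([getattr(r, name) for r in reports])
        for name in ("accuracy", "f1", "auroc", "auprc", "mcc")
    }
    agg = EvalReport(
        accuracy=float(metrics["accuracy"].mean()),
        f1=float(metrics["f1"].mean()),
        auroc=float(metrics["auroc"].mean()),
        auprc=float(metrics["auprc"].mean()),
        mcc=float(metrics["mcc"].mean()),
        confusion=np.sum([r.confusion for r in reports], axis=0),
        per_fold=reports,
        std={name: float(v.std(ddof=0)) for name, v in metrics.items()},
    )
    return agg


# -- model archive (JSON text) ----------------------------------------------

def save_model(path: str | Path, model: TrainedModel, alphabet_kind: str) -> None:
    cfg = model.config.__dict__.copy()
    payload = {
        "config": cfg,
        "alphabet": alphabet_kind,
        "input_length": model.input_length,
        "pam": {
            "alpha": model.pam.alpha,
            "beta": model.pam.beta,
            "sigma": model.pam.sigma,
            "k": model.pam.k,
        },
        "anchors": {
            "motifs": model.anchors.motifs.tolist(),
            "positions": model.anchors.positions.tolist(),
        },
        "weights": {
            "W1": model.W1.tolist(),
            "b1": model.b1.tolist(),
            "W2": model.W2.tolist(),
            "b2": model.b2.tolist(),
        },
        "training_log": model.training_log,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> tuple[TrainedModel, str]:
    payload = json.loads(Path(path).read_text())
    config = ModelConfig(**payload["config"])
    pam = PAMParams(**payload["pam"])
    anchors = AnchorSet(
        motifs=np.array(payload["anchors"]["motifs"]),
        positions=np.array(payload["anchors"]["positions"]),
    )
    model = TrainedModel(
        anchors=anchors,
        nystrom=gram_inverse_sqrt(anchors, pam, epsilon=config.epsilon),
        W1=np.array(payload["weights"]["W1"]),
        b1=np.array(payload["weights"]["b1"]),
        W2=np.array(payload["weights"]["W2"]),
        b2=np.array(payload["weights"]["b2"]),
        config=config,
        pam=pam,
        input_length=payload["input_length"],
        training_log=list(payload["training_log"]),
    )
    return model, payload["alphabet"]
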