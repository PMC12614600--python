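"""Frozen-embedding probing: MLP probes and every reported metric.

Embeddings are never updated; a small MLP (capacity capped well below
1.5M parameters) is trained per task with the task-appropriate loss.
Metrics: Spearman rank correlation (average ranks on ties), ROC AUC (the
normalized Mann-Whitney U statistic, ties counting one half), the
protein-centric Fmax with precision/recall averaged over *all* proteins
(0/0 precision defined as 0; the convention that averages only over
proteins with at least one prediction sits behind a flag), and the
step-wise (non-interpolated) per-class AUPR.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .autodiff import Adam, Tensor

TASK_KINDS = ("regression", "binary", "multiclass", "multilabel")


@dataclasses.dataclass
class ProbeTask:
    name: str
    kind: str
    labels: Mapping[str, object]   # id -> scalar / class index / binary vector
    n_classes: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in TASK_KINDS:
            raise ValueError(f"kind must be one of {TASK_KINDS}")


@dataclasses.dataclass
class ProbeConfig:
    hidden: int = 64
    epochs: int = 60
    lr: float = 1e-2
    batch_size: int = 64
    max_parameters: int = 1_500_000


# ---------------------------------------------------------------------------
# The MLP probe
# ---------------------------------------------------------------------------

class MLPProbe:
    """One-hidden-layer MLP head trained on frozen embeddings."""

    def __init__(self, in_dim: int, out_dim: int, kind: str,
                 config: ProbeConfig, seed: int = 0):
        self.kind = kind
        self.config = config
        n_params = in_dim * config.hidden + config.hidden \
            + config.hidden * out_dim + out_dim
        if n_params > config.max_parameters:
            raise ValueError(f"probe capacity {n_params} exceeds cap "
                             f"{config.max_parameters}")
        rng = np.random.default_rng(seed)
        self.W1 = Tensor(rng.normal(scale=1.0 / np.sqrt(in_dim),
                                    size=(in_dim, config.hidden)),
                         requires_grad=True)
        self.b1 = Tensor(np.zeros(config.hidden), requires_grad=True)
        self.W2 = Tensor(rng.normal(scale=1.0 / np.sqrt(config.hidden),
                                    size=(config.hidden, out_dim)),
                         requires_grad=True)
        self.b2 = Tensor(np.zeros(out_dim), requires_grad=True)
        self._shuffle_rng = np.random.default_rng(seed + 1)

    def _forward(self, X: np.ndarray) -> Tensor:
        h = (Tensor(X) @ self.W1 + self.b1).relu()
        return h @ self.W2 + self.b2

    def _loss(self, logits: Tensor, y: np.ndarray) -> Tensor:
        n = logits.shape[0]
        if self.kind == "regression":
            diff = logits.reshape(-1) - Tensor(y)
            return (diff * diff).mean()
        if self.kind == "multiclass":
            shifted = logits - Tensor(logits.data.max(axis=1, keepdims=True))
            lse = shifted.exp().sum(axis=1).log()
            picked = shifted[(np.arange(n), y.astype(int))]
            return (lse - picked).mean()
        # binary / multilabel: per-label logistic loss, stable softplus form
        z = logits if self.kind == "multilabel" else logits.reshape(-1)
        t = Tensor(y.astype(float))
        # log(1 + e^z) - t*z  ==  softplus(z) - t*z
        zmax = Tensor(np.maximum(z.data, 0.0))
        softplus = zmax + ((z - zmax).exp() + (-zmax).exp()).log()
        return (softplus - t * z).mean()

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MLPProbe":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        opt = Adam([self.W1, self.b1, self.W2, self.b2], lr=self.config.lr)
        n = len(X)
        bs = min(self.config.batch_size, n)
        for _ in range(self.config.epochs):
            order = self._shuffle_rng.permutation(n)
            for lo in range(0, n, bs):
                idx = order[lo:lo + bs]
                loss = self._loss(self._forward(X[idx]), y[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Scores: value (regression), probabilities otherwise."""
        logits = self._forward(np.asarray(X, dtype=float)).data
        if self.kind == "regression":
            return logits.reshape(-1)
        if self.kind == "multiclass":
            e = np.exp(logits - logits.max(axis=1, keepdims=True))
            return e / e.sum(axis=1, keepdims=True)
        probs = 1.0 / (1.0 + np.exp(-logits))
        return probs.reshape(-1) if self.kind == "binary" else probs


def fit_probe(embeddings: Mapping[str, np.ndarray], task: ProbeTask,
              config: ProbeConfig | None = None, seed: int = 0,
              ids: Sequence[str] | None = None) -> MLPProbe:
    """Train a probe on the embeddings of ``ids`` (default: all labeled)."""
    config = config or ProbeConfig()
    ids = list(ids) if ids is not None else [i for i in embeddings
                                             if i in task.labels]
    missing = [i for i in ids if i not in task.labels or i not in embeddings]
    if missing:
        raise KeyError(f"ids lacking labels or embeddings: {missing[:5]}")
    X = np.stack([embeddings[i] for i in ids])
    y = np.array([task.labels[i] for i in ids])
    out_dim = {"regression": 1, "binary": 1,
               "multiclass": task.n_classes or int(y.max()) + 1,
               "multilabel": y.shape[1] if y.ndim > 1 else 1}[task.kind]
    probe = MLPProbe(X.shape[1], out_dim, task.kind, config, seed)
    return probe.fit(X, y)


def predict_probe(probe: MLPProbe, embeddings: Mapping[str, np.ndarray],
                  ids: Sequence[str]) -> np.ndarray:
    return probe.predict(np.stack([embeddings[i] for i in ids]))


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation of average ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: rank correlation undefined")
    rx, ry = rankdata(x), rankdata(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def roc_auc(scores_pos: Sequence[float], scores_neg: Sequence[float]) -> float:
    """Normalized Mann-Whitney U statistic; ties count one half."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score groups must be nonempty")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (pos.size * neg.size))


def roc_auc_from_labels(y_true: Sequence[int], scores: Sequence[float]) -> float:
    y = np.asarray(y_true).astype(bool)
    s = np.asarray(scores, dtype=float)
    return roc_auc(s[y], s[~y])


def accuracy(y_true: Sequence[int], y_pred: Sequence[int]) -> float:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return float(np.mean(y_true == y_pred))


def fmax(true_labels: Sequence[Sequence[int]], scores: np.ndarray,
         all_proteins: bool = True) -> tuple[float, float]:
    """Protein-centric maximum F1 over a threshold scan.

    ``true_labels[i]`` is the set/vector of true label indices of protein
    i; ``scores`` is (N, n_labels) in [0, 1]. Labels scoring strictly
    above the threshold are predicted positive. The scan set is every
    distinct score plus {0, 1}. With ``all_proteins`` (the printed
    convention) precision is averaged over all N proteins, counting 0/0
    as 0; otherwise only proteins with >= 1 prediction enter the
    precision average (CAFA convention).

    Returns (Fmax, argmax threshold).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    n, n_labels = scores.shape
    truth = np.zeros((n, n_labels), dtype=bool)
    for i, labels in enumerate(true_labels):
        labels = np.asarray(list(labels), dtype=int) if not isinstance(
            labels, np.ndarray) else np.asarray(labels)
        if labels.ndim and labels.size == n_labels and set(
                np.unique(labels)).issubset({0, 1}):
            truth[i] = labels.astype(bool)
        else:
            truth[i, labels.astype(int)] = True

    thresholds = np.unique(np.concatenate([scores.ravel(), [0.0, 1.0]]))
    best_f1, best_thr = 0.0, 0.0
    for thr in thresholds:
        pred = scores > thr
        tp = (pred & truth).sum(axis=1).astype(float)
        fp = (pred & ~truth).sum(axis=1).astype(float)
        fn = (~pred & truth).sum(axis=1).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
            rec = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        if all_proteins:
            precision = prec.mean()
        else:
            has_pred = (tp + fp) > 0
            precision = prec[has_pred].mean() if has_pred.any() else 0.0
        recall = rec.mean()
        if precision + recall > 0:
            f1 = 2 * precision * recall / (precision + recall)
            if f1 > best_f1:
                best_f1, best_thr = f1, float(thr)
    return float(best_f1), best_thr


def aupr_per_class(y_true: np.ndarray, scores: np.ndarray, cls: int) -> float:
    """Step-wise area under the one-vs-rest precision-recall curve.

    ``y_true`` holds class indices (or a binary matrix); ``scores`` is
    (N, n_classes). AP = sum over descending-score prefixes of
    (recall step) * precision, with tied scores processed together.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if y_true.ndim == 1:
        positives = y_true == cls
    else:
        positives = y_true[:, cls].astype(bool)
    n_pos = int(positives.sum())
    if n_pos == 0:
        raise ValueError(f"class {cls} has no positives")
    s = scores[:, cls]
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    pos_sorted = positives[order].astype(float)

    tp = np.cumsum(pos_sorted)
    fp = np.cumsum(1.0 - pos_sorted)
    # keep only the last index of each tied-score block
    distinct = np.nonzero(np.diff(s_sorted, append=np.nan))[0]
    tp, fp = tp[distinct], fp[distinct]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


# ---------------------------------------------------------------------------
# The downstream suite
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MetricCell:
    model: str
    task: str
    run: int
    metric: str
    value: float


@dataclasses.dataclass
class MetricTable:
    cells: list[MetricCell]

    def values(self, model: str, task: str, metric: str | None = None
               ) -> np.ndarray:
        return np.array([c.value for c in self.cells
                         if c.model == model and c.task == task
                         and (metric is None or c.metric == metric)])

    def aggregate(self) -> list[dict]:
        keys = sorted({(c.model, c.task, c.metric) for c in self.cells})
        rows = []
        for model, task, metric in keys:
            vals = self.values(model, task, metric)
            rows.append({"model": model, "task": task, "metric": metric,
                         "mean": float(vals.mean()),
                         "std": float(vals.std(ddof=1)) if len(vals) > 1
                         else 0.0,
                         "n_runs": len(vals)})
        return rows

    def rows(self) -> list[dict]:
        return [dataclasses.asdict(c) for c in self.cells]


def _score_task(task: ProbeTask, probe: MLPProbe,
                embeddings: Mapping[str, np.ndarray],
                test_ids: Sequence[str]) -> dict[str, float]:
    scores = predict_probe(probe, embeddings, test_ids)
    y = np.array([task.labels[i] for i in test_ids])
    if task.kind == "regression":
        return {"spearman": spearman_rho(scores, y)}
    if task.kind == "binary":
        out = {"accuracy": accuracy(y, (scores > 0.5).astype(int))}
        if 0 < y.sum() < len(y):
            out["auc"] = roc_auc_from_labels(y, scores)
        return out
    if task.kind == "multiclass":
        return {"accuracy": accuracy(y, scores.argmax(axis=1))}
    value, _ = fmax(list(y), scores)
    return {"fmax": value}


def run_downstream_suite(embeddings_per_model: Mapping[str, Mapping[str, np.ndarray]],
                         tasks: Sequence[ProbeTask],
                         train_ids: Sequence[str], test_ids: Sequence[str],
                         n_runs: int = 6, base_seed: int = 0,
                         config: ProbeConfig | None = None) -> MetricTable:
    """Per (model, task, run) metric cells from freshly trained probes."""
    config = config or ProbeConfig()
    cells: list[MetricCell] = []
    for model_name, embeddings in embeddings_per_model.items():
        for task in tasks:
            for run in range(n_runs):
                probe = fit_probe(embeddings, task, config,
                                  seed=base_seed + run, ids=train_ids)
                for metric, value in _score_task(task, probe, embeddings,
                                                 test_ids).items():
                    cells.append(MetricCell(model=model_name, task=task.name,
                                            run=run, metric=metric,
                                            value=value))
    return MetricTable(cells)
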