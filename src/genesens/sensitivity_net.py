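"""Input-gradient sensitivity ranking from a small expression classifier.

A fully connected m-h-2 network (sigmoid hidden layer, softmax output, h = 3
by default) is trained by per-sample stochastic gradient descent on
cross-entropy to map a patient's z-scored gene-expression vector to the
probability of the case class.  The sensitivity of gene i is the average over
patients of |d p_case / d x_i|, the absolute input gradient of the predicted
case probability; genes are ranked by this average and the top fraction
(default 20%) forms the sensitive set.

All gradients are analytic (chain rule through sigmoid and softmax); the test
suite cross-checks them against central finite differences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .expr_io import GROUP_CASE, GROUP_CONTROL, ExpressionMatrix, Phenotype

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization settings for the m-h-2 classifier."""

    epochs: int = 100
    learning_rate: float = 1e-4
    train_fraction: float = 0.8
    cv_folds: int = 10
    seed: int = 0
    hidden_units: int = 3
    batch_mode: str = "per-sample"  # or "full-batch"

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.batch_mode not in ("per-sample", "full-batch"):
            raise ValueError(f"unknown batch_mode {self.batch_mode!r}")


@dataclass
class TrainedModel:
    """Weights of the m-h-2 network; class_order fixes the output columns."""

    w_hidden: np.ndarray  # m x h
    b_hidden: np.ndarray  # h
    w_out: np.ndarray  # h x 2
    b_out: np.ndarray  # 2
    gene_ids: list[str]
    class_order: tuple[str, str] = (GROUP_CONTROL, GROUP_CASE)

    def __post_init__(self) -> None:
        for name in ("w_hidden", "b_hidden", "w_out", "b_out"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")
        m, h = self.w_hidden.shape
        if self.b_hidden.shape != (h,) or self.w_out.shape != (h, 2) or self.b_out.shape != (2,):
            raise ValueError("inconsistent weight shapes")
        if len(self.gene_ids) != m:
            raise ValueError("gene_ids length does not match input width")

    @property
    def m(self) -> int:
        return self.w_hidden.shape[0]


@dataclass
class SensitivityResult:
    """Gradient matrix, per-gene averages, descending ranking and top set.

    ``derivative_matrix`` and ``mean_abs_derivative`` follow ``gene_ids``
    (the matrix's original gene order); ``ranking`` is the same ids in
    descending mean-absolute-gradient order.
    """

    gene_ids: list[str]
    derivative_matrix: np.ndarray  # m x n, d_ij = dp_case/dx_ij
    mean_abs_derivative: np.ndarray  # length m
    ranking: list[str]
    top_set: set[str]
    fraction: float


def _softmax2(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def forward(model: TrainedModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hidden activations and class probabilities for samples in rows of x."""
    a = _sigmoid(x @ model.w_hidden + model.b_hidden)
    p = _softmax2(a @ model.w_out + model.b_out)
    return a, p


def predict_probability(model: TrainedModel, sample: np.ndarray) -> tuple[float, float]:
    """(p_control, p_case) for one length-m expression vector."""
    sample = np.asarray(sample, dtype=float)
    if sample.shape != (model.m,):
        raise ValueError(f"sample length {sample.shape} does not match m={model.m}")
    if not np.all(np.isfinite(sample)):
        raise ValueError("non-finite sample values")
    _, p = forward(model, sample[None, :])
    return float(p[0, 0]), float(p[0, 1])


def input_gradient(model: TrainedModel, sample: np.ndarray) -> np.ndarray:
    """Analytic gradient of p_case with respect to each input gene.

    With a = sigmoid(W_h^T x + b_h) and p = softmax(W_o^T a + b_o), the
    two-class softmax gives dp_case/da_k = p_case p_control (w_k,case -
    w_k,control), and the sigmoid contributes a_k (1 - a_k) W_h[i, k].
    """
    sample = np.asarray(sample, dtype=float)
    if sample.shape != (model.m,):
        raise ValueError(f"sample length {sample.shape} does not match m={model.m}")
    if not np.all(np.isfinite(sample)):
        raise ValueError("non-finite sample values")
    a, p = forward(model, sample[None, :])
    a, p = a[0], p[0]
    dcase = p[1] * p[0] * (model.w_out[:, 1] - model.w_out[:, 0])
    return model.w_hidden @ (a * (1.0 - a) * dcase)


def gradient_matrix(model: TrainedModel, x: np.ndarray) -> np.ndarray:
    """m x n matrix of dp_case/dx_ij for samples in the columns of x."""
    a, p = forward(model, x.T)  # n x h, n x 2
    dcase = (p[:, 1] * p[:, 0])[:, None] * (model.w_out[:, 1] - model.w_out[:, 0])
    return model.w_hidden @ (a * (1.0 - a) * dcase).T


def _labels(ph: Phenotype) -> np.ndarray:
    return np.asarray([g == GROUP_CASE for g in ph.group], dtype=int)


def _init_model(m: int, h: int, gene_ids: list[str], rng: np.random.Generator) -> TrainedModel:
    return TrainedModel(
        w_hidden=rng.uniform(-0.05, 0.05, size=(m, h)),
        b_hidden=rng.uniform(-0.05, 0.05, size=h),
        w_out=rng.uniform(-0.05, 0.05, size=(h, 2)),
        b_out=rng.uniform(-0.05, 0.05, size=2),
        gene_ids=gene_ids,
    )


def _fit(
    x: np.ndarray,
    y: np.ndarray,
    gene_ids: list[str],
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> TrainedModel:
    """SGD on cross-entropy; x has samples in rows."""
    model = _init_model(x.shape[1], cfg.hidden_units, gene_ids, rng)
    wh, bh, wo, bo = model.w_hidden, model.b_hidden, model.w_out, model.b_out
    lr = cfg.learning_rate
    onehot = np.eye(2)[y]
    for epoch in range(cfg.epochs):
        if cfg.batch_mode == "full-batch":
            a = _sigmoid(x @ wh + bh)
            p = _softmax2(a @ wo + bo)
            dz_out = (p - onehot) / len(y)
            da = dz_out @ wo.T
            dz_h = da * a * (1.0 - a)
            wo -= lr * a.T @ dz_out
            bo -= lr * dz_out.sum(axis=0)
            wh -= lr * x.T @ dz_h
            bh -= lr * dz_h.sum(axis=0)
            loss = -np.mean(np.log(np.clip(p[np.arange(len(y)), y], 1e-300, None)))
        else:
            loss = 0.0
            for j in rng.permutation(len(y)):
                xj = x[j]
                a = _sigmoid(xj @ wh + bh)
                p = _softmax2(a @ wo + bo)
                loss -= math.log(max(p[y[j]], 1e-300))
                dz_out = p - onehot[j]
                da = wo @ dz_out
                dz_h = da * a * (1.0 - a)
                wo -= lr * np.outer(a, dz_out)
                bo -= lr * dz_out
                wh -= lr * np.outer(xj, dz_h)
                bh -= lr * dz_h
            loss /= len(y)
        if not math.isfinite(loss):
            raise FloatingPointError(f"non-finite training loss at epoch {epoch + 1}")
    return TrainedModel(wh, bh, wo, bo, gene_ids)


def _stratified_split(
    y: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_idx: list[int] = []
    test_idx: list[int] = []
    for label in (0, 1):
        members = np.flatnonzero(y == label)
        members = rng.permutation(members)
        k = int(round(train_fraction * len(members)))
        k = min(max(k, 1), len(members) - 1) if len(members) > 1 else len(members)
        train_idx.extend(members[:k])
        test_idx.extend(members[k:])
    return np.sort(np.asarray(train_idx)), np.sort(np.asarray(test_idx))


def train_model(em: ExpressionMatrix, ph: Phenotype, cfg: TrainConfig) -> TrainedModel:
    """Train the classifier on a seeded stratified train split.

    The holdout fraction is kept for an accuracy report only; the returned
    model is the one trained on the training split.
    """
    if not em.normalized:
        raise ValueError("expression matrix must be normalized before training")
    if em.sample_ids != ph.sample_ids:
        raise ValueError("expression matrix and phenotype are not aligned")
    y = _labels(ph)
    if len(np.unique(y)) < 2:
        raise ValueError("both diagnostic groups must be present")
    rng = np.random.default_rng(cfg.seed)
    x = em.values.T  # samples in rows
    train_idx, test_idx = _stratified_split(y, cfg.train_fraction, rng)
    model = _fit(x[train_idx], y[train_idx], list(em.gene_ids), cfg, rng)
    _, p_train = forward(model, x[train_idx])
    train_acc = float(np.mean(p_train.argmax(axis=1) == y[train_idx]))
    if len(test_idx):
        _, p_test = forward(model, x[test_idx])
        test_acc = float(np.mean(p_test.argmax(axis=1) == y[test_idx]))
    else:
        test_acc = float("nan")
    logger.info(
        "trained m-%d-2 model on %d samples: train acc %.3f, holdout acc %.3f",
        cfg.hidden_units, len(train_idx), train_acc, test_acc,
    )
    return model


def holdout_accuracy(em: ExpressionMatrix, ph: Phenotype, cfg: TrainConfig) -> float:
    """Accuracy of a freshly trained model on its held-out split."""
    if not em.normalized:
        raise ValueError("expression matrix must be normalized before training")
    y = _labels(ph)
    if len(np.unique(y)) < 2:
        raise ValueError("both diagnostic groups must be present")
    rng = np.random.default_rng(cfg.seed)
    x = em.values.T
    train_idx, test_idx = _stratified_split(y, cfg.train_fraction, rng)
    model = _fit(x[train_idx], y[train_idx], list(em.gene_ids), cfg, rng)
    _, p_test = forward(model, x[test_idx])
    return float(np.mean(p_test.argmax(axis=1) == y[test_idx]))


def rank_descending(gene_ids: list[str], scores: np.ndarray) -> list[str]:
    """Gene ids sorted by descending score, ties broken lexicographically."""
    order = sorted(range(len(gene_ids)), key=lambda i: (-scores[i], gene_ids[i]))
    return [gene_ids[i] for i in order]


def top_fraction(ranking: list[str], fraction: float) -> set[str]:
    return set(ranking[: int(math.floor(fraction * len(ranking)))])


def sensitivity_scores(
    model: TrainedModel, em: ExpressionMatrix, fraction: float = 0.2
) -> SensitivityResult:
    """Average absolute case-probability gradients per gene, ranked descending."""
    if list(model.gene_ids) != list(em.gene_ids):
        raise ValueError("model and matrix gene orderings differ")
    d = gradient_matrix(model, em.values)
    mean_abs = np.abs(d).mean(axis=1)
    ranking = rank_descending(list(em.gene_ids), mean_abs)
    return SensitivityResult(
        list(em.gene_ids), d, mean_abs, ranking, top_fraction(ranking, fraction), fraction
    )


def crossvalidate(em: ExpressionMatrix, ph: Phenotype, cfg: TrainConfig) -> dict:
    """Seeded k-fold cross-validated accuracy of the classifier.

    Folds are stratified by group; when cv_folds equals the sample count a
    plain leave-one-out split is used instead (a stratified split is
    impossible there).
    """
    if not em.normalized:
        raise ValueError("expression matrix must be normalized")
    y = _labels(ph)
    n = len(y)
    if cfg.cv_folds > n:
        raise ValueError("more folds than samples")
    counts = np.bincount(y, minlength=2)
    if cfg.cv_folds == n:
        folds = [np.asarray([j]) for j in range(n)]
    elif cfg.cv_folds > counts.min():
        raise ValueError("folds exceed the size of the smaller class")
    else:
        rng_folds = np.random.default_rng(cfg.seed)
        folds = [[] for _ in range(cfg.cv_folds)]
        for label in (0, 1):
            members = rng_folds.permutation(np.flatnonzero(y == label))
            for k, j in enumerate(members):
                folds[k % cfg.cv_folds].append(j)
        folds = [np.sort(np.asarray(f)) for f in folds]
    x = em.values.T
    accuracies: list[float] = []
    for k, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        rng = np.random.default_rng(cfg.seed + 1000 + k)
        model = _fit(x[train_idx], y[train_idx], list(em.gene_ids), cfg, rng)
        _, p = forward(model, x[test_idx])
        accuracies.append(float(np.mean(p.argmax(axis=1) == y[test_idx])))
    result = {"fold_accuracy": accuracies, "mean_accuracy": float(np.mean(accuracies))}
    logger.info("%d-fold CV mean accuracy %.3f", len(folds), result["mean_accuracy"])
    return result


def write_sensitivity_tsv(result: SensitivityResult, path) -> None:
    means = dict(zip(result.gene_ids, result.mean_abs_derivative))
    with open(path, "w") as fh:
        fh.write("gene_id\tmean_abs_derivative\trank\n")
        for rank, g in enumerate(result.ranking, start=1):
            fh.write(f"{g}\t{means[g]:.10g}\t{rank}\n")


def serialize_model(model: TrainedModel) -> dict:
    return {
        "w_hidden": model.w_hidden.tolist(),
        "b_hidden": model.b_hidden.tolist(),
        "w_out": model.w_out.tolist(),
        "b_out": model.b_out.tolist(),
        "gene_ids": list(model.gene_ids),
        "class_order": list(model.class_order),
    }


def deserialize_model(payload: dict) -> TrainedModel:
    return TrainedModel(
        np.asarray(payload["w_hidden"], dtype=float),
        np.asarray(payload["b_hidden"], dtype=float),
        np.asarray(payload["w_out"], dtype=float),
        np.asarray(payload["b_out"], dtype=float),
        list(payload["gene_ids"]),
        tuple(payload["class_order"]),
    )
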