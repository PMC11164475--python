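"""Follow-up statistics on candidate genes.

Differential expression (Welch t-test per gene), cosine-similarity
correlation matrices within each diagnostic group with their case-minus-
control difference, univariate regressions of clinical scores (MMSE, tangle
counts) on single-gene expression, and a support-vector-machine biomarker
panel with a stratified 80/20 split and ten-fold cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .expr_io import GROUP_CASE, GROUP_CONTROL, ExpressionMatrix, Phenotype

logger = logging.getLogger(__name__)


@dataclass
class DERow:
    gene_id: str
    mean_control: float
    mean_case: float
    t_statistic: float
    p_value: float


@dataclass
class CorrelationMatrices:
    genes: list[str]
    control_matrix: np.ndarray
    case_matrix: np.ndarray
    difference_matrix: np.ndarray
    orientation: str = "case-minus-control"


@dataclass
class RegressionFit:
    gene_id: str
    indicator: str  # "MMSE" or "NFT"
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int


@dataclass
class SvmReport:
    panel: list[str]
    train_fraction: float
    seed: int
    kernel: str
    test_accuracy: float
    cv_accuracies: list[float]
    decision_thresholds: dict[str, float] | None = None


def differential_expression(
    em: ExpressionMatrix, ph: Phenotype, genes: list[str] | None = None
) -> list[DERow]:
    """Welch two-sided t-test of case vs control per gene, in input order."""
    if em.sample_ids != ph.sample_ids:
        raise ValueError("matrix and phenotype are not aligned")
    control = ph.group_mask(GROUP_CONTROL)
    case = ph.group_mask(GROUP_CASE)
    if control.sum() < 2 or case.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    genes = list(genes) if genes is not None else list(em.gene_ids)
    sub = em.subset_genes(genes)
    rows: list[DERow] = []
    for i, gene in enumerate(genes):
        xc = sub.values[i, control]
        xa = sub.values[i, case]
        if np.var(xc) == 0 and np.var(xa) == 0 and xc.mean() == xa.mean():
            t, p = 0.0, 1.0  # identical constant groups: no evidence of a shift
        else:
            t, p = stats.ttest_ind(xa, xc, equal_var=False)
        rows.append(DERow(gene, float(xc.mean()), float(xa.mean()), float(t), float(p)))
    return rows


def _cosine_matrix(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1)
    zero = norms == 0
    if zero.any():
        logger.warning("%d zero-vector genes: cosine similarities set to 0", int(zero.sum()))
    safe = np.where(zero, 1.0, norms)
    unit = x / safe[:, None]
    sim = unit @ unit.T
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    np.clip(sim, -1.0, 1.0, out=sim)
    return sim


def correlation_analysis(
    em: ExpressionMatrix,
    ph: Phenotype,
    genes: list[str],
    orientation: str = "case-minus-control",
) -> CorrelationMatrices:
    """Cosine similarity between gene vectors within each group.

    The difference matrix is case minus control by default, so positive
    entries mean the pairwise expression trend strengthened in cases.
    """
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    if orientation not in ("case-minus-control", "control-minus-case"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sub = em.subset_genes(genes)
    control = ph.group_mask(GROUP_CONTROL)
    case = ph.group_mask(GROUP_CASE)
    if not control.any() or not case.any():
        raise ValueError("each group must be nonempty")
    ctrl_m = _cosine_matrix(sub.values[:, control])
    case_m = _cosine_matrix(sub.values[:, case])
    diff = case_m - ctrl_m if orientation == "case-minus-control" else ctrl_m - case_m
    return CorrelationMatrices(list(genes), ctrl_m, case_m, diff, orientation)


def regress_clinical(
    em: ExpressionMatrix, ph: Phenotype, gene: str, indicator: str
) -> RegressionFit:
    """OLS of a clinical indicator on one gene's expression."""
    indicator = indicator.upper()
    if indicator == "MMSE":
        y = ph.mmse
    elif indicator == "NFT":
        y = ph.nft
    else:
        raise ValueError(f"unknown indicator {indicator!r}")
    if y is None:
        raise ValueError(f"{indicator} not present in phenotype")
    x = em.subset_genes([gene]).values[0]
    mask = np.isfinite(y) & np.isfinite(x)
    if mask.sum() < 3:
        raise ValueError(f"{indicator} present for fewer than 3 samples")
    x, y = x[mask], y[mask]
    if np.ptp(x) == 0:
        raise ValueError(f"constant expression for {gene}: slope undefined")
    fit = stats.linregress(x, y)
    return RegressionFit(
        gene, indicator, float(fit.slope), float(fit.intercept),
        float(fit.rvalue), float(fit.pvalue), int(mask.sum()),
    )


def svm_biomarker(
    em: ExpressionMatrix,
    ph: Phenotype,
    panel: list[str],
    train_fraction: float = 0.8,
    seed: int = 0,
    kernel: str = "linear",
    cv_folds: int = 10,
) -> SvmReport:
    """SVM diagnosis from a gene panel on a seeded stratified 80/20 split.

    Features are standardized inside the training split (pipeline), test
    accuracy comes from the held-out 20%, and ten-fold cross-validated
    accuracies are reported alongside.  For 2-gene panels, per-gene
    decision thresholds (boundary crossing with the other gene at its mean)
    are exported for threshold-style plots.
    """
    if em.sample_ids != ph.sample_ids:
        raise ValueError("matrix and phenotype are not aligned")
    sub = em.subset_genes(panel)
    x = sub.values.T
    y = np.asarray([g == GROUP_CASE for g in ph.group], dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    x_train, x_test, y_train, y_test = train_test_split(
        x, y, train_size=train_fraction, random_state=seed, stratify=y
    )
    if len(np.unique(y_train)) < 2 or len(np.unique(y_test)) < 2:
        raise ValueError("degenerate split: a class is missing from a split")
    clf = make_pipeline(StandardScaler(), SVC(kernel=kernel, random_state=seed))
    clf.fit(x_train, y_train)
    test_accuracy = float(clf.score(x_test, y_test))
    folds = min(cv_folds, int(np.bincount(y).min()))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    cv_accuracies = [
        float(a)
        for a in cross_val_score(
            make_pipeline(StandardScaler(), SVC(kernel=kernel, random_state=seed)),
            x, y, cv=cv,
        )
    ]
    thresholds = None
    if len(panel) == 2 and kernel == "linear":
        scaler: StandardScaler = clf.named_steps["standardscaler"]
        svc: SVC = clf.named_steps["svc"]
        w = svc.coef_[0] / scaler.scale_
        b = float(svc.intercept_[0] - np.dot(svc.coef_[0], scaler.mean_ / scaler.scale_))
        means = x_train.mean(axis=0)
        thresholds = {}
        for i, gene in enumerate(panel):
            if w[i] != 0:
                other = 1 - i
                thresholds[gene] = float(-(b + w[other] * means[other]) / w[i])
    logger.info(
        "SVM panel %s: test accuracy %.3f, %d-fold CV mean %.3f",
        panel, test_accuracy, folds, float(np.mean(cv_accuracies)),
    )
    return SvmReport(
        list(panel), train_fraction, seed, kernel, test_accuracy, cv_accuracies, thresholds
    )


# ---------------------------------------------------------------------------
# table exports


def de_frame(rows: list[DERow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


def correlation_frames(cm: CorrelationMatrices) -> dict[str, pd.DataFrame]:
    return {
        "control": pd.DataFrame(cm.control_matrix, index=cm.genes, columns=cm.genes),
        "case": pd.DataFrame(cm.case_matrix, index=cm.genes, columns=cm.genes),
        "difference": pd.DataFrame(cm.difference_matrix, index=cm.genes, columns=cm.genes),
    }
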