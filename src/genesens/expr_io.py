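"""Reading, collapsing, normalizing and organizing expression data.

The pipeline consumes microarray-style expression tables (probes x samples,
tab separated, first column the probe identifier) together with an optional
probe-to-gene annotation and a phenotype table.  Multiple probes mapping to
one gene are collapsed by averaging, then each sample's gene vector is
z-score normalized so that every column of the genes x samples matrix has
mean 0 and (sample) standard deviation 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNMAPPED = None  # sentinel gene symbol for probes without an annotation

GROUP_CONTROL = "control"
GROUP_CASE = "case"


@dataclass
class TableDialect:
    """How to interpret an expression table.

    sep: column separator.
    na_action: "error" rejects non-numeric cells with coordinates;
        "drop" removes any probe row containing a non-numeric cell.
    """

    sep: str = "\t"
    na_action: str = "error"


@dataclass
class ProbeMatrix:
    """Probes x samples matrix before collapsing to genes.

    ``gene_symbols`` maps each probe id to exactly one gene symbol, or to
    ``None`` for unmapped probes (dropped at collapse time).
    """

    probe_ids: list[str]
    gene_symbols: dict[str, str | None]
    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("duplicated probe ids")
        missing = [p for p in self.probe_ids if p not in self.gene_symbols]
        if missing:
            raise ValueError(f"probes without a gene-symbol entry: {missing[:5]}")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix; ``values[i, j]`` = expression of gene i in sample j."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match gene/sample ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids not unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids not unique")

    @property
    def m(self) -> int:
        return len(self.gene_ids)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def sample_vector(self, j: int) -> np.ndarray:
        """The j-th patient's length-m expression column."""
        return self.values[:, j]

    def gene_vector(self, i: int) -> np.ndarray:
        """The i-th gene's length-n expression row."""
        return self.values[i, :]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(
            list(gene_ids), list(self.sample_ids), self.values[rows, :], self.normalized
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class Phenotype:
    """Per-sample diagnosis labels and optional clinical covariates."""

    sample_ids: list[str]
    group: list[str]
    mmse: np.ndarray | None = None  # 0-30 cognitive score
    nft: np.ndarray | None = None  # tangle count, >= 0
    stage: list[str] | None = None

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if len(self.group) != n:
            raise ValueError("group length does not match sample ids")
        bad = sorted(set(self.group) - {GROUP_CONTROL, GROUP_CASE})
        if bad:
            raise ValueError(f"unknown group labels: {bad}")
        for name in ("mmse", "nft"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (n,):
                    raise ValueError(f"{name} length does not match sample ids")
                setattr(self, name, v)
        if self.mmse is not None:
            finite = self.mmse[np.isfinite(self.mmse)]
            if finite.size and (finite.min() < 0 or finite.max() > 30):
                raise ValueError("mmse values outside [0, 30]")
        if self.nft is not None:
            finite = self.nft[np.isfinite(self.nft)]
            if finite.size and finite.min() < 0:
                raise ValueError("negative nft values")
        if self.stage is not None and len(self.stage) != n:
            raise ValueError("stage length does not match sample ids")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def group_mask(self, label: str) -> np.ndarray:
        return np.asarray([g == label for g in self.group], dtype=bool)

    def subset(self, indices: Sequence[int]) -> "Phenotype":
        idx = list(indices)
        return Phenotype(
            [self.sample_ids[i] for i in idx],
            [self.group[i] for i in idx],
            None if self.mmse is None else self.mmse[idx],
            None if self.nft is None else self.nft[idx],
            None if self.stage is None else [self.stage[i] for i in idx],
        )


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_table(
    path: str | Path,
    annotation: str | Path | Mapping[str, str | None] | None = None,
    dialect: TableDialect | None = None,
) -> ProbeMatrix:
    """Read a probes x samples expression table into a :class:`ProbeMatrix`.

    The first column holds probe ids, the header row holds sample ids.
    ``annotation`` maps probe -> gene symbol (two-column TSV path or mapping);
    without one, every probe is taken to be its own gene symbol.
    """
    dialect = dialect or TableDialect()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        columns = header.split(dialect.sep)
        if len(columns) < 2:
            raise ValueError(f"{path}: header has fewer than two columns")
        sample_ids = columns[1:]
        probe_ids: list[str] = []
        rows: list[list[float]] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split(dialect.sep)
            if len(cells) != len(columns):
                raise ValueError(
                    f"{path}: row {lineno} has {len(cells)} fields, expected {len(columns)}"
                )
            probe = cells[0]
            if probe in seen:
                raise ValueError(f"{path}: duplicated probe id {probe!r} at row {lineno}")
            parsed: list[float] = []
            drop = False
            for col, cell in enumerate(cells[1:], start=2):
                try:
                    parsed.append(float(cell))
                except ValueError:
                    if dialect.na_action == "drop":
                        drop = True
                        break
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} at row {lineno}, column {col}"
                    ) from None
            if drop:
                logger.warning("dropping probe %s: non-numeric cell at row %d", probe, lineno)
                continue
            seen.add(probe)
            probe_ids.append(probe)
            rows.append(parsed)
    if not probe_ids:
        raise ValueError(f"{path}: no probe rows parsed")
    mapping = _load_annotation(annotation, probe_ids)
    return ProbeMatrix(probe_ids, mapping, np.asarray(rows, dtype=float), sample_ids)


def _load_annotation(
    annotation: str | Path | Mapping[str, str | None] | None, probe_ids: Sequence[str]
) -> dict[str, str | None]:
    if annotation is None:
        return {p: p for p in probe_ids}
    if isinstance(annotation, (str, Path)):
        table = pd.read_csv(annotation, sep="\t", header=None, dtype=str, keep_default_na=False)
        if table.shape[1] < 2:
            raise ValueError(f"annotation {annotation} needs two columns")
        loaded = dict(zip(table.iloc[:, 0], table.iloc[:, 1]))
    else:
        loaded = dict(annotation)
    mapping: dict[str, str | None] = {}
    for p in probe_ids:
        symbol = loaded.get(p, UNMAPPED)
        mapping[p] = symbol if symbol not in (UNMAPPED, "", "NA") else UNMAPPED
    return mapping


def read_phenotype(path: str | Path) -> Phenotype:
    """Read a phenotype CSV with columns sample_id, group[, mmse, nft, stage]."""
    table = pd.read_csv(path, dtype={"sample_id": str, "group": str})
    for required in ("sample_id", "group"):
        if required not in table.columns:
            raise ValueError(f"{path}: missing column {required!r}")
    return Phenotype(
        table["sample_id"].tolist(),
        table["group"].tolist(),
        table["mmse"].to_numpy(float) if "mmse" in table.columns else None,
        table["nft"].to_numpy(float) if "nft" in table.columns else None,
        table["stage"].tolist() if "stage" in table.columns else None,
    )


def write_expression_tsv(em: ExpressionMatrix, path: str | Path) -> None:
    em.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def write_phenotype_csv(ph: Phenotype, path: str | Path) -> None:
    data: dict[str, object] = {"sample_id": ph.sample_ids, "group": ph.group}
    if ph.mmse is not None:
        data["mmse"] = ph.mmse
    if ph.nft is not None:
        data["nft"] = ph.nft
    if ph.stage is not None:
        data["stage"] = ph.stage
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# transforms


def collapse_probes(pm: ProbeMatrix) -> ExpressionMatrix:
    """Average the probe rows of each gene into a single gene row.

    Unmapped probes are dropped.  Output genes are ordered lexicographically
    so downstream rank tie-breaking is reproducible.  The result is not yet
    normalized.
    """
    by_gene: dict[str, list[int]] = {}
    for i, probe in enumerate(pm.probe_ids):
        symbol = pm.gene_symbols[probe]
        if symbol is UNMAPPED:
            continue
        by_gene.setdefault(symbol, []).append(i)
    if not by_gene:
        raise ValueError("no probe maps to a gene symbol")
    gene_ids = sorted(by_gene)
    values = np.empty((len(gene_ids), len(pm.sample_ids)), dtype=float)
    for row, gene in enumerate(gene_ids):
        values[row] = pm.values[by_gene[gene], :].mean(axis=0)
    return ExpressionMatrix(gene_ids, list(pm.sample_ids), values, normalized=False)


def zscore_per_sample(em: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each sample column across genes (sample sd, divisor n-1).

    Zero-variance columns become all zeros.  A single-gene matrix is rejected:
    a per-sample z-score over one gene is identically zero and carries no
    ranking information.
    """
    if em.normalized:
        raise ValueError("matrix already normalized")
    if em.m < 2:
        raise ValueError("z-score per sample needs at least 2 genes")
    means = em.values.mean(axis=0, keepdims=True)
    sds = em.values.std(axis=0, ddof=1, keepdims=True)
    centered = em.values - means
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sds > 0, centered / sds, 0.0)
    return ExpressionMatrix(list(em.gene_ids), list(em.sample_ids), z, normalized=True)


def align_phenotype(em: ExpressionMatrix, ph: Phenotype) -> tuple[ExpressionMatrix, Phenotype]:
    """Restrict and reorder matrix and phenotype to their common samples.

    The matrix's sample order (filtered to the intersection) defines the
    shared ordering.
    """
    common = set(em.sample_ids) & set(ph.sample_ids)
    if not common:
        raise ValueError("expression matrix and phenotype share no samples")
    em_keep = [j for j, s in enumerate(em.sample_ids) if s in common]
    order = [em.sample_ids[j] for j in em_keep]
    ph_index = {s: i for i, s in enumerate(ph.sample_ids)}
    ph_out = ph.subset([ph_index[s] for s in order])
    em_out = ExpressionMatrix(
        list(em.gene_ids), order, em.values[:, em_keep], em.normalized
    )
    n_control = sum(g == GROUP_CONTROL for g in ph_out.group)
    n_case = sum(g == GROUP_CASE for g in ph_out.group)
    logger.info("aligned %d samples (%d control, %d case)", len(order), n_control, n_case)
    return em_out, ph_out
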