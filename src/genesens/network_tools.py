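"""Network topology and gene-set statistics.

Betweenness centrality g(v) = sum over node pairs {s, t} (s != v != t) of
sigma_st(v) / sigma_st, where sigma_st counts unweighted shortest s-t paths
and sigma_st(v) those passing through v.  Pairs are unordered and unreachable
pairs contribute nothing, so disconnected graphs are handled per component.

Over-representation analysis is database-free: gene-set collections are
supplied as GMT files and tested against a user-defined universe with a
one-sided hypergeometric tail, Benjamini-Hochberg adjusted across sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class GeneNetwork:
    """Undirected gene graph with optional per-node centrality scores."""

    nodes: list[str]
    edges: set[tuple[str, str]]
    centrality: dict[str, float] | None = None

    def __post_init__(self) -> None:
        known = set(self.nodes)
        normalized: set[tuple[str, str]] = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on node {a!r}")
            if a not in known or b not in known:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown node")
            normalized.add((a, b) if a <= b else (b, a))
        self.edges = normalized

    @classmethod
    def from_edges(
        cls, nodes: Iterable[str], edges: Iterable[tuple[str, str]]
    ) -> "GeneNetwork":
        return cls(list(nodes), set(edges))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


def read_edge_list(
    path: str | Path, score_threshold: float | None = None
) -> GeneNetwork:
    """Read a two- or three-column TSV edge list (node, node[, score]).

    Edges are undirected and deduplicated; self-loop rows are dropped with a
    warning; with ``score_threshold`` only rows whose third column is >= the
    threshold are kept.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) < 2:
                raise ValueError(f"{path}: line {lineno} has fewer than two columns")
            a, b = cells[0], cells[1]
            if a == b:
                logger.warning("%s: line %d is a self-loop on %r, dropped", path, lineno, a)
                continue
            if score_threshold is not None:
                if len(cells) < 3:
                    raise ValueError(f"{path}: line {lineno} lacks a score column")
                try:
                    score = float(cells[2])
                except ValueError:
                    raise ValueError(
                        f"{path}: line {lineno} has non-numeric score {cells[2]!r}"
                    ) from None
                if score < score_threshold:
                    continue
            nodes.update((a, b))
            edges.add((a, b) if a <= b else (b, a))
    return GeneNetwork(sorted(nodes), edges)


def betweenness_centrality(g: GeneNetwork) -> dict[str, float]:
    """Unnormalized betweenness over unordered node pairs for every node.

    Isolated nodes and nodes in separate components score from their own
    component only; an empty graph yields an empty result.
    """
    if g.n_nodes == 0:
        return {}
    scores = nx.betweenness_centrality(g.to_networkx(), normalized=False)
    return {node: float(scores[node]) for node in g.nodes}


def write_centrality_tsv(centrality: Mapping[str, float], path: str | Path) -> None:
    ranked = sorted(centrality.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(path, "w") as fh:
        fh.write("gene_id\tbetweenness\n")
        for node, score in ranked:
            fh.write(f"{node}\t{score:.10g}\n")


# ---------------------------------------------------------------------------
# over-representation analysis


@dataclass
class EnrichmentRow:
    set_name: str
    set_size: int
    overlap: int
    universe_size: int
    query_size: int
    p_value: float
    adjusted_p: float = field(default=float("nan"))


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    collections: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) < 3:
                raise ValueError(f"{path}: line {lineno} has no member genes")
            collections[cells[0]] = set(cells[2:])
    return collections


def hypergeometric_ora(
    query: set[str],
    collections: Mapping[str, set[str]] | str | Path,
    universe: set[str],
) -> list[EnrichmentRow]:
    """One-sided hypergeometric over-representation test per gene set.

    For each set the tail probability P(X >= overlap) is computed with the
    set first intersected with the universe; zero overlap gives p = 1.
    Benjamini-Hochberg adjustment is applied across all tested sets and rows
    are returned sorted by raw p-value.
    """
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    if isinstance(collections, (str, Path)):
        collections = read_gmt(collections)
    rows: list[EnrichmentRow] = []
    big_n, n_query = len(universe), len(query)
    for name in sorted(collections):
        members = collections[name] & universe
        overlap = len(members & query)
        # P(X >= overlap) for X ~ Hypergeom(N, K, n); sf(k-1) is the upper tail
        p = float(stats.hypergeom.sf(overlap - 1, big_n, len(members), n_query))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        rows.append(EnrichmentRow(name, len(members), overlap, big_n, n_query, p))
    if rows:
        adjusted = stats.false_discovery_control([r.p_value for r in rows], method="bh")
        for row, adj in zip(rows, adjusted):
            row.adjusted_p = float(min(adj, 1.0))
    rows.sort(key=lambda r: (r.p_value, r.set_name))
    return rows


def write_enrichment_tsv(rows: Sequence[EnrichmentRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "set_name\tset_size\toverlap\tuniverse_size\tquery_size\tp_value\tadjusted_p\n"
        )
        for r in rows:
            fh.write(
                f"{r.set_name}\t{r.set_size}\t{r.overlap}\t{r.universe_size}\t"
                f"{r.query_size}\t{r.p_value:.6g}\t{r.adjusted_p:.6g}\n"
            )
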