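"""Synthetic expression cohorts with planted signal.

Emulates the statistical structure of a two-group microarray cohort of a few
hundred brain samples: thousands of genes, a small informative subset whose
mean shifts with diagnosis, correlated gene blocks sharing a latent factor,
several probes per gene, and clinical scores (MMSE, tangle counts) linearly
coupled to the informative genes.  Every downstream stage of the pipeline can
therefore be tested for recovery of known, planted structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expr_io import GROUP_CASE, GROUP_CONTROL, Phenotype, ProbeMatrix
from .network_tools import GeneNetwork


@dataclass
class ClinicalCoupling:
    """Linear coupling of clinical scores to the informative-gene mean.

    MMSE_j = 30 + mmse_slope * mean_informative_j + noise, clipped to [0, 30].
    NFT_j  = max(0, nft_slope * mean_informative_j + noise).
    """

    mmse_slope: float = -1.5
    nft_slope: float = 2.0
    noise_sd: float = 1.0


@dataclass
class SimulationParams:
    """Cohort layout and signal strengths.

    Defaults emulate a 363-sample two-group cohort (187 control / 176 case)
    with a small informative panel shifted by one within-group SD in cases.
    """

    n_control: int = 187
    n_case: int = 176
    m_genes: int = 2000
    informative_genes: list[int] = field(default_factory=lambda: list(range(10)))
    effect_size: float = 1.0  # mean shift in within-group SD units
    informative_signs: list[int] | None = None  # +1/-1 per informative gene
    block_spec: list[tuple[list[int], float]] = field(default_factory=list)
    probes_per_gene: int = 1
    probe_noise_sd: float = 0.0
    clinical_coupling: ClinicalCoupling = field(default_factory=ClinicalCoupling)
    seed: int = 0

    def validate(self) -> None:
        if self.n_control + self.n_case < 4:
            raise ValueError("need at least 4 samples in total")
        if self.n_control < 0 or self.n_case < 0:
            raise ValueError("negative group size")
        if self.m_genes < 1:
            raise ValueError("m_genes must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.probes_per_gene < 1:
            raise ValueError("probes_per_gene must be >= 1")
        if self.probe_noise_sd < 0:
            raise ValueError("probe_noise_sd must be >= 0")
        for idx in self.informative_genes:
            if not 0 <= idx < self.m_genes:
                raise ValueError(f"informative gene index {idx} outside [0, {self.m_genes})")
        if self.informative_signs is not None:
            if len(self.informative_signs) != len(self.informative_genes):
                raise ValueError("informative_signs length mismatch")
            if any(s not in (-1, 1) for s in self.informative_signs):
                raise ValueError("informative_signs must be +1 or -1")
        seen: set[int] = set()
        for genes, rho in self.block_spec:
            if not 0 <= rho < 1:
                raise ValueError(f"block correlation {rho} outside [0, 1)")
            for idx in genes:
                if not 0 <= idx < self.m_genes:
                    raise ValueError(f"block gene index {idx} outside range")
                if idx in seen:
                    raise ValueError(f"gene index {idx} appears in two blocks")
                seen.add(idx)


def gene_label(i: int, m: int) -> str:
    width = max(4, len(str(m - 1)))
    return f"G{i:0{width}d}"


def simulate_cohort(p: SimulationParams) -> tuple[ProbeMatrix, Phenotype]:
    """Draw one cohort: a probe-level matrix plus phenotype table.

    Background genes are standard normal per sample.  Genes in a block share a
    Gaussian latent factor: value = sqrt(rho) * factor + sqrt(1 - rho) * noise,
    giving pairwise correlation rho within the block.  Informative genes gain
    +/- effect_size in case samples.  Each gene is emitted as
    ``probes_per_gene`` probe rows with independent Gaussian measurement noise.
    """
    p.validate()
    rng = np.random.default_rng(p.seed)
    n = p.n_control + p.n_case
    m = p.m_genes

    latent = rng.standard_normal((m, n))
    for genes, rho in p.block_spec:
        factor = rng.standard_normal(n)
        noise = rng.standard_normal((len(genes), n))
        latent[genes, :] = np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * noise

    group = [GROUP_CONTROL] * p.n_control + [GROUP_CASE] * p.n_case
    case_mask = np.asarray([g == GROUP_CASE for g in group])
    signs = p.informative_signs or [1] * len(p.informative_genes)
    for idx, sign in zip(p.informative_genes, signs):
        latent[idx, case_mask] += sign * p.effect_size

    sample_ids = [f"S{j:04d}" for j in range(n)]
    gene_ids = [gene_label(i, m) for i in range(m)]

    if p.informative_genes:
        informative_mean = latent[p.informative_genes, :].mean(axis=0)
    else:
        informative_mean = np.zeros(n)
    cc = p.clinical_coupling
    mmse = 30.0 + cc.mmse_slope * informative_mean + cc.noise_sd * rng.standard_normal(n)
    mmse = np.clip(mmse, 0.0, 30.0)
    nft = cc.nft_slope * informative_mean + cc.noise_sd * rng.standard_normal(n)
    nft = np.maximum(nft, 0.0)

    k = p.probes_per_gene
    probe_values = np.repeat(latent, k, axis=0)
    if p.probe_noise_sd > 0:
        probe_values = probe_values + p.probe_noise_sd * rng.standard_normal(probe_values.shape)
    probe_ids = [f"{g}_p{r + 1}" for g in gene_ids for r in range(k)]
    symbols = {f"{g}_p{r + 1}": g for g in gene_ids for r in range(k)}

    pm = ProbeMatrix(probe_ids, symbols, probe_values, sample_ids)
    ph = Phenotype(sample_ids, group, mmse=mmse, nft=nft)
    return pm, ph


def simulate_graph(
    n_nodes: int,
    topology: str = "path",
    p: float | None = None,
    edges: list[tuple[str, str]] | None = None,
    seed: int | None = None,
) -> GeneNetwork:
    """Small deterministic or seeded graph fixtures for centrality tests.

    ``topology`` is one of ``path``, ``star``, ``erdos_renyi`` (needs ``p``),
    or ``edge-list`` (needs ``edges``).  Path and star nodes are labelled
    v0..v{n-1}; the star's center is v0.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    nodes = [f"v{i}" for i in range(n_nodes)]
    if topology == "path":
        edge_set = {(nodes[i], nodes[i + 1]) for i in range(n_nodes - 1)}
    elif topology == "star":
        edge_set = {(nodes[0], nodes[i]) for i in range(1, n_nodes)}
    elif topology == "erdos_renyi":
        if p is None or not 0 <= p <= 1:
            raise ValueError("erdos_renyi needs edge probability p in [0, 1]")
        rng = np.random.default_rng(seed)
        edge_set = set()
        for i in range(n_nodes):
            for j in range(i + 1, n_nodes):
                if rng.random() < p:
                    edge_set.add((nodes[i], nodes[j]))
    elif topology == "edge-list":
        if edges is None:
            raise ValueError("edge-list topology needs explicit edges")
        names = sorted({v for e in edges for v in e})
        return GeneNetwork.from_edges(names, edges)
    else:
        raise ValueError(f"unknown topology {topology!r}")
    return GeneNetwork.from_edges(nodes, sorted(edge_set))
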