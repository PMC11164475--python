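"""Shapley-value gene attribution and the retraining contrast.

Each gene is a player; the value of a coalition S at patient j is the
trained classifier's case probability evaluated on a vector whose
coordinates in S come from the patient and whose remaining coordinates come
from a baseline (all zeros by default — the per-sample mean after z-scoring).
The Shapley value phi_ij is gene i's average marginal contribution over
coalition orderings, computed by exact enumeration for small gene panels and
by antithetic permutation sampling otherwise.  Ranking genes by the average
of |phi_ij| over patients yields the network-contribution ranking, and its
top fraction intersected with the gradient-sensitivity top set gives the
final candidate set.

The retraining contrast is also provided: for a small gene network, train a
model with and without one gene and compare per-patient case probabilities
(delta = p_full - p_reduced), the direct "remove the gene and retrain"
notion of contribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .expr_io import ExpressionMatrix, Phenotype
from .sensitivity_net import (
    TrainConfig,
    TrainedModel,
    _sigmoid,
    _softmax2,
    forward,
    rank_descending,
    top_fraction,
    train_model,
)

logger = logging.getLogger(__name__)

EXACT_LIMIT = 20  # 2^m coalition enumerations beyond this are refused
AUTO_EXACT_LIMIT = 12  # exact mode auto-selected up to here


@dataclass
class ShapleyResult:
    """Per-gene/sample attributions, averages, ranking and top set."""

    gene_ids: list[str]
    phi_matrix: np.ndarray  # m x n
    mean_phi: np.ndarray  # length m, mean over samples of |phi|
    ranking: list[str]
    top_set: set[str]
    fraction: float
    method: str  # "exact" or "permutation-sampling"
    n_permutations: int
    seed: int
    baseline: np.ndarray


@dataclass
class DeltaResult:
    """Retraining contrast for one gene within a small network."""

    gene_id: str
    delta_values: np.ndarray  # per-sample p_case(full) - p_case(reduced)
    mean_delta: float  # mean of |delta|
    full_model_ref: TrainedModel
    reduced_model_ref: TrainedModel


def _case_prob_from_hidden_preact(
    z: np.ndarray, w_out: np.ndarray, b_out: np.ndarray
) -> np.ndarray:
    a = _sigmoid(z)
    return _softmax2(a @ w_out + b_out)[..., 1]


def _phi_from_subset_values(v: np.ndarray, m: int) -> np.ndarray:
    """Shapley values from the value of every coalition (bitmask-indexed)."""
    bits = ((np.arange(1 << m)[:, None] >> np.arange(m)) & 1).astype(bool)
    pop = bits.sum(axis=1)
    fact = [math.factorial(k) for k in range(m + 1)]
    weights = np.asarray(
        [fact[s] * fact[m - 1 - s] / fact[m] for s in range(m)], dtype=float
    )
    phi = np.empty(m)
    idx = np.arange(1 << m)
    for i in range(m):
        without = idx[~bits[:, i]]
        phi[i] = float(
            np.sum(weights[pop[without]] * (v[without + (1 << i)] - v[without]))
        )
    return phi


def exact_shapley_from_value(value_fn, m: int) -> np.ndarray:
    """Exact Shapley values of an arbitrary coalition value function.

    ``value_fn`` receives a frozenset of player indices; all 2^m coalitions
    are evaluated, so m must stay small (<= 20).
    """
    if m > EXACT_LIMIT:
        raise ValueError(f"exact enumeration infeasible for m={m} (> {EXACT_LIMIT})")
    v = np.asarray(
        [
            value_fn(frozenset(i for i in range(m) if idx >> i & 1))
            for idx in range(1 << m)
        ],
        dtype=float,
    )
    return _phi_from_subset_values(v, m)


def _exact_phi(model: TrainedModel, sample: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Exact Shapley values by enumerating all 2^m coalitions."""
    m = model.m
    contrib = (sample - baseline)[:, None] * model.w_hidden  # m x h
    z_empty = baseline @ model.w_hidden + model.b_hidden
    n_sub = 1 << m
    bits = ((np.arange(n_sub)[:, None] >> np.arange(m)) & 1).astype(bool)
    z = np.broadcast_to(z_empty, (n_sub, z_empty.size)).copy()
    for i in range(m):
        z[bits[:, i]] += contrib[i]
    v = _case_prob_from_hidden_preact(z, model.w_out, model.b_out)
    return _phi_from_subset_values(v, m)


def _sampled_phi_batch(
    model: TrainedModel,
    x: np.ndarray,
    baseline: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Permutation-sampled phi for all samples (columns of x) at once.

    Permutations are drawn in antithetic pairs (a permutation and its
    reverse), which cancels first-order ordering noise.  For each
    permutation the coalition is grown one gene at a time; the hidden
    pre-activation is accumulated by cumulative sums so one permutation
    costs one vectorized forward pass over all samples and prefixes.
    """
    m, n = x.shape
    diff = x - baseline[:, None]
    z_empty = baseline @ model.w_hidden + model.b_hidden
    v_empty = float(_case_prob_from_hidden_preact(z_empty[None, :], model.w_out, model.b_out)[0])
    phi = np.zeros((m, n))

    def accumulate(order: np.ndarray) -> None:
        # n x m x h cumulative hidden pre-activation along the permutation
        c = diff[order].T[:, :, None] * model.w_hidden[order][None, :, :]
        z = z_empty + np.cumsum(c, axis=1)
        v = _case_prob_from_hidden_preact(z, model.w_out, model.b_out)  # n x m
        prev = np.concatenate([np.full((n, 1), v_empty), v[:, :-1]], axis=1)
        phi[order] += (v - prev).T

    n_pairs, odd = divmod(n_permutations, 2)
    for _ in range(n_pairs):
        order = rng.permutation(m)
        accumulate(order)
        accumulate(order[::-1])
    if odd:
        accumulate(rng.permutation(m))
    return phi / n_permutations


def shapley_attribution(
    model: TrainedModel,
    sample: np.ndarray,
    baseline: np.ndarray,
    method: str = "auto",
    n_permutations: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Length-m Shapley attribution of p_case for one sample.

    ``method``: "exact" (all coalitions, m <= 20), "sampling", or "auto"
    (exact up to m = 12, sampling beyond).
    """
    sample = np.asarray(sample, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if sample.shape != (model.m,) or baseline.shape != (model.m,):
        raise ValueError("sample/baseline length does not match model input width")
    if not (np.all(np.isfinite(sample)) and np.all(np.isfinite(baseline))):
        raise ValueError("non-finite sample or baseline")
    if method == "auto":
        method = "exact" if model.m <= AUTO_EXACT_LIMIT else "sampling"
    if method == "exact":
        if model.m > EXACT_LIMIT:
            raise ValueError(
                f"exact enumeration infeasible for m={model.m} (> {EXACT_LIMIT}); "
                "use method='sampling'"
            )
        return _exact_phi(model, sample, baseline)
    if method == "sampling":
        rng = np.random.default_rng(seed)
        return _sampled_phi_batch(model, sample[:, None], baseline, n_permutations, rng)[:, 0]
    raise ValueError(f"unknown method {method!r}")


def resolve_baseline(em: ExpressionMatrix, baseline_rule: str | np.ndarray) -> np.ndarray:
    if isinstance(baseline_rule, str):
        if baseline_rule == "zeros":
            return np.zeros(em.m)
        if baseline_rule == "gene_means":
            return em.values.mean(axis=1)
        raise ValueError(f"unknown baseline rule {baseline_rule!r}")
    baseline = np.asarray(baseline_rule, dtype=float)
    if baseline.shape != (em.m,):
        raise ValueError("baseline length does not match gene count")
    return baseline


def average_shapley(
    model: TrainedModel,
    em: ExpressionMatrix,
    baseline_rule: str | np.ndarray = "zeros",
    fraction: float = 0.2,
    method: str = "auto",
    n_permutations: int = 200,
    seed: int = 0,
    absolute: bool = True,
) -> ShapleyResult:
    """Shapley attributions for every gene and sample, ranked by mean |phi|.

    ``absolute=False`` averages signed phi instead (class-symmetric effects
    then cancel; kept as an option).
    """
    if list(model.gene_ids) != list(em.gene_ids):
        raise ValueError("model and matrix gene orderings differ")
    if not em.normalized:
        raise ValueError("expression matrix must be normalized")
    baseline = resolve_baseline(em, baseline_rule)
    if method == "auto":
        method = "exact" if em.m <= AUTO_EXACT_LIMIT else "sampling"
    if method == "exact":
        if em.m > EXACT_LIMIT:
            raise ValueError(f"exact enumeration infeasible for m={em.m}")
        phi = np.column_stack(
            [_exact_phi(model, em.values[:, j], baseline) for j in range(em.n)]
        )
        method_name = "exact"
    elif method == "sampling":
        rng = np.random.default_rng(seed)
        phi = _sampled_phi_batch(model, em.values, baseline, n_permutations, rng)
        method_name = "permutation-sampling"
    else:
        raise ValueError(f"unknown method {method!r}")
    mean_phi = np.abs(phi).mean(axis=1) if absolute else phi.mean(axis=1)
    ranking = rank_descending(list(em.gene_ids), mean_phi)
    return ShapleyResult(
        list(em.gene_ids),
        phi,
        mean_phi,
        ranking,
        top_fraction(ranking, fraction),
        fraction,
        method_name,
        n_permutations if method_name == "permutation-sampling" else 0,
        seed,
        baseline,
    )


def network_delta(
    em: ExpressionMatrix,
    ph: Phenotype,
    cfg: TrainConfig,
    network_genes: set[str],
    removed_gene: str,
) -> DeltaResult:
    """Retrain-without-the-gene contrast for one gene in a small network.

    A full model f1 is trained on the network's genes and a reduced model f2
    on the network minus ``removed_gene`` under the identical seed/epoch
    protocol, so the per-sample difference of case probabilities reflects
    feature removal rather than training noise.
    """
    if removed_gene not in network_genes:
        raise ValueError(f"{removed_gene!r} is not in the network")
    if len(network_genes) < 2:
        raise ValueError("network needs at least 2 genes")
    try:
        em_full = em.subset_genes(sorted(network_genes))
        em_reduced = em.subset_genes(sorted(network_genes - {removed_gene}))
    except KeyError as exc:
        raise ValueError(f"network gene absent from matrix: {exc}") from exc
    f1 = train_model(em_full, ph, cfg)
    f2 = train_model(em_reduced, ph, cfg)
    _, p1 = forward(f1, em_full.values.T)
    _, p2 = forward(f2, em_reduced.values.T)
    delta = p1[:, 1] - p2[:, 1]
    return DeltaResult(removed_gene, delta, float(np.abs(delta).mean()), f1, f2)


def intersect_sets(a: set[str], b: set[str]) -> list[str]:
    """Exact set intersection, returned sorted lexicographically."""
    return sorted(set(a) & set(b))


def write_shapley_tsv(result: ShapleyResult, path) -> None:
    means = dict(zip(result.gene_ids, result.mean_phi))
    with open(path, "w") as fh:
        fh.write("gene_id\tmean_abs_shapley\trank\n")
        for rank, g in enumerate(result.ranking, start=1):
            fh.write(f"{g}\t{means[g]:.10g}\t{rank}\n")
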