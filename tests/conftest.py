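"""Shared fixtures: planted cohorts, small panels, random models."""

from __future__ import annotations

import numpy as np
import pytest

from genesens import (
    ExpressionMatrix,
    Phenotype,
    SimulationParams,
    TrainConfig,
    align_phenotype,
    collapse_probes,
    simulate_cohort,
    train_model,
    zscore_per_sample,
)
from genesens.expr_io import GROUP_CASE, GROUP_CONTROL
from genesens.sensitivity_net import TrainedModel

# The paper-style defaults (lr 1e-4) barely move the weights on desk-scale
# cohorts; experiments use a learning rate suited to these problem sizes.
EXPERIMENT_LR = 0.1


def experiment_config(seed: int = 0, **overrides) -> TrainConfig:
    kwargs = dict(learning_rate=EXPERIMENT_LR, seed=seed)
    kwargs.update(overrides)
    return TrainConfig(**kwargs)


def separable_panel(
    seed: int = 0, n: int = 200, effect: float = 3.0, m: int = 2
) -> tuple[ExpressionMatrix, Phenotype]:
    """Two-group panel with every gene shifted by ``effect`` in cases.

    Built directly as a normalized matrix, the way a small network panel is
    sliced out of a full z-scored cohort.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((m, n))
    x[:, n // 2:] += effect
    ids = [f"s{j:03d}" for j in range(n)]
    em = ExpressionMatrix([f"g{i}" for i in range(m)], ids, x, normalized=True)
    ph = Phenotype(ids, [GROUP_CONTROL] * (n // 2) + [GROUP_CASE] * (n - n // 2))
    return em, ph


def permuted_labels(ph: Phenotype, seed: int = 0) -> Phenotype:
    rng = np.random.default_rng(seed)
    order = rng.permutation(ph.n)
    return Phenotype(list(ph.sample_ids), [ph.group[j] for j in order])


def random_model(rng: np.random.Generator, m: int = 10, h: int = 3, scale: float = 1.0) -> TrainedModel:
    return TrainedModel(
        rng.normal(0, scale, (m, h)),
        rng.normal(0, scale, h),
        rng.normal(0, scale, (h, 2)),
        rng.normal(0, scale, 2),
        [f"g{i}" for i in range(m)],
    )


PLANTED_SEED = 0
PLANTED_GENES = [f"G{i:04d}" for i in range(10)]


@pytest.fixture(scope="session")
def planted_cohort() -> tuple[ExpressionMatrix, Phenotype]:
    """The m=500, n=400 cohort with 10 informative genes at effect 2."""
    params = SimulationParams(
        n_control=200,
        n_case=200,
        m_genes=500,
        informative_genes=list(range(10)),
        effect_size=2.0,
        seed=PLANTED_SEED,
    )
    pm, ph = simulate_cohort(params)
    em = zscore_per_sample(collapse_probes(pm))
    return align_phenotype(em, ph)


@pytest.fixture(scope="session")
def planted_model(planted_cohort):
    em, ph = planted_cohort
    return train_model(em, ph, experiment_config(seed=PLANTED_SEED))
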