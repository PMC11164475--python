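"""Shapley axioms, closed forms, sampling behaviour, retraining contrast."""

import itertools

import numpy as np
import pytest
from scipy.stats import spearmanr

from genesens import (
    ExpressionMatrix,
    average_shapley,
    intersect_sets,
    network_delta,
    sensitivity_scores,
    shapley_attribution,
)
from genesens.sensitivity_net import TrainedModel, predict_probability
from conftest import experiment_config, random_model, separable_panel


def oracle_shapley(value_fn, m):
    """Shapley values straight from the permutation definition (oracle)."""
    phi = np.zeros(m)
    perms = list(itertools.permutations(range(m)))
    for perm in perms:
        coalition = set()
        prev = value_fn(coalition)
        for i in perm:
            coalition = coalition | {i}
            cur = value_fn(coalition)
            phi[i] += cur - prev
            prev = cur
    return phi / len(perms)


def model_value_fn(model, sample, baseline):
    def v(coalition):
        x = baseline.copy()
        for i in coalition:
            x[i] = sample[i]
        return predict_probability(model, x)[1]

    return v


class TestExactShapley:
    def test_matches_permutation_definition_oracle(self):
        rng = np.random.default_rng(41)
        for _ in range(5):
            model = random_model(rng, m=5)
            sample = rng.standard_normal(5)
            baseline = rng.standard_normal(5)
            expected = oracle_shapley(model_value_fn(model, sample, baseline), 5)
            got = shapley_attribution(model, sample, baseline, method="exact")
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_efficiency_axiom(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            m = int(rng.integers(2, 13))
            model = random_model(rng, m=m)
            sample = rng.standard_normal(m)
            baseline = rng.standard_normal(m)
            phi = shapley_attribution(model, sample, baseline, method="exact")
            v_full = predict_probability(model, sample)[1]
            v_empty = predict_probability(model, baseline)[1]
            assert phi.sum() == pytest.approx(v_full - v_empty, abs=1e-9)

    def test_null_player_axiom(self):
        rng = np.random.default_rng(43)
        model = random_model(rng, m=8)
        model.w_hidden[5, :] = 0.0  # disconnected gene
        phi = shapley_attribution(model, rng.standard_normal(8), np.zeros(8), method="exact")
        assert phi[5] == 0.0

    def test_symmetry_axiom(self):
        rng = np.random.default_rng(44)
        model = random_model(rng, m=6)
        model.w_hidden[2, :] = model.w_hidden[4, :]  # identical players
        sample = rng.standard_normal(6)
        sample[4] = sample[2]
        baseline = np.zeros(6)
        phi = shapley_attribution(model, sample, baseline, method="exact")
        assert phi[2] == pytest.approx(phi[4], abs=1e-9)

    def test_additive_value_function_closed_form(self):
        # one pass-through hidden unit in its linear regime makes the game
        # nearly additive; the exact check uses a directly additive game
        rng = np.random.default_rng(45)
        w = rng.standard_normal(7)
        x = rng.standard_normal(7)
        baseline = rng.standard_normal(7)

        def v(coalition):
            return sum(w[i] * x[i] for i in coalition) + sum(
                w[i] * baseline[i] for i in range(7) if i not in coalition
            )

        phi = oracle_shapley(v, 7)
        np.testing.assert_allclose(phi, w * (x - baseline), atol=1e-9)

    def test_exact_refused_beyond_limit(self):
        rng = np.random.default_rng(46)
        model = random_model(rng, m=21)
        with pytest.raises(ValueError, match="sampling"):
            shapley_attribution(model, np.zeros(21), np.zeros(21), method="exact")


class TestSampledShapley:
    def test_sampling_preserves_efficiency(self):
        # each sampled permutation telescopes, so efficiency holds exactly
        rng = np.random.default_rng(51)
        model = random_model(rng, m=15)
        sample = rng.standard_normal(15)
        baseline = np.zeros(15)
        phi = shapley_attribution(model, sample, baseline, method="sampling",
                                  n_permutations=50, seed=4)
        v_full = predict_probability(model, sample)[1]
        v_empty = predict_probability(model, baseline)[1]
        assert phi.sum() == pytest.approx(v_full - v_empty, abs=1e-9)

    def test_unbiased_against_exact(self):
        rng = np.random.default_rng(52)
        model = random_model(rng, m=10)
        sample = rng.standard_normal(10)
        baseline = np.zeros(10)
        exact = shapley_attribution(model, sample, baseline, method="exact")
        draws = np.array([
            shapley_attribution(model, sample, baseline, method="sampling",
                                n_permutations=200, seed=s)
            for s in range(50)
        ])
        se = draws.std(axis=0, ddof=1) / np.sqrt(50)
        z = np.abs(draws.mean(axis=0) - exact) / np.maximum(se, 1e-12)
        assert z.max() < 3.0

    def test_doubling_permutations_shrinks_se(self):
        rng = np.random.default_rng(53)
        model = random_model(rng, m=12)
        sample = rng.standard_normal(12)
        baseline = np.zeros(12)
        sd = {}
        for n_perm, base in ((100, 0), (200, 500)):
            draws = np.array([
                shapley_attribution(model, sample, baseline, method="sampling",
                                    n_permutations=n_perm, seed=base + s)
                for s in range(40)
            ])
            sd[n_perm] = draws.std(axis=0, ddof=1)
        ratio = np.median(sd[100] / np.maximum(sd[200], 1e-15))
        assert np.sqrt(2) * 0.7 <= ratio <= np.sqrt(2) * 1.3


class TestAverageShapley:
    def test_null_cohort_no_dominant_gene(self):
        rng = np.random.default_rng(54)
        n, m = 300, 10
        x = rng.standard_normal((m, n))
        ids = [f"s{j}" for j in range(n)]
        em = ExpressionMatrix([f"g{i}" for i in range(m)], ids, x, normalized=True)
        from genesens import Phenotype, train_model

        ph = Phenotype(ids, ["control"] * (n // 2) + ["case"] * (n // 2))
        model = train_model(em, ph, experiment_config(seed=54))
        res = average_shapley(model, em, method="exact")
        assert res.mean_phi.max() <= 3 * np.median(res.mean_phi)

    def test_planted_panel_recovered(self):
        # 50-gene panel, 5 informative: all 5 in the top 10 of the ranking
        rng = np.random.default_rng(55)
        n, m = 300, 50
        x = rng.standard_normal((m, n))
        x[:5, n // 2:] += 2.0
        ids = [f"s{j}" for j in range(n)]
        em = ExpressionMatrix([f"g{i:02d}" for i in range(m)], ids, x, normalized=True)
        from genesens import Phenotype, train_model

        ph = Phenotype(ids, ["control"] * (n // 2) + ["case"] * (n // 2))
        model = train_model(em, ph, experiment_config(seed=55))
        res = average_shapley(model, em, method="sampling", n_permutations=200, seed=55)
        planted = {f"g{i:02d}" for i in range(5)}
        assert planted <= set(res.ranking[:10])
        assert res.method == "permutation-sampling"
        assert len(res.top_set) == 10

    def test_rank_correlation_with_sensitivity(self, planted_model, planted_cohort):
        em, _ = planted_cohort
        sens = sensitivity_scores(planted_model, em)
        shap = average_shapley(planted_model, em, method="sampling",
                               n_permutations=100, seed=3)
        pos = {g: i for i, g in enumerate(sens.ranking)}
        rho = spearmanr(
            [pos[g] for g in em.gene_ids],
            [{g: i for i, g in enumerate(shap.ranking)}[g] for g in em.gene_ids],
        ).statistic
        assert rho > 0.3


@pytest.fixture(scope="module")
def panel():
    rng = np.random.default_rng(60)
    n = 300
    x = rng.standard_normal((6, n))
    x[0, n // 2:] += 3.0  # g0 informative, g5 pure noise
    ids = [f"s{j}" for j in range(n)]
    from genesens import Phenotype

    em = ExpressionMatrix([f"g{i}" for i in range(6)], ids, x, normalized=True)
    ph = Phenotype(ids, ["control"] * (n // 2) + ["case"] * (n // 2))
    return em, ph


class TestNetworkDelta:
    def test_noise_gene_small_delta(self, panel):
        em, ph = panel
        res = network_delta(em, ph, experiment_config(seed=60), set(em.gene_ids), "g5")
        assert res.mean_delta < 0.05

    def test_informative_gene_dominates_noise_gene(self, panel):
        em, ph = panel
        cfg = experiment_config(seed=60)
        noise = network_delta(em, ph, cfg, set(em.gene_ids), "g5")
        info = network_delta(em, ph, cfg, set(em.gene_ids), "g0")
        assert info.mean_delta >= 3 * noise.mean_delta

    def test_redundant_twin_gene_small_delta(self, panel):
        _, ph = panel
        rng = np.random.default_rng(61)
        n = ph.n
        x = rng.standard_normal((2, n))
        x[0, n // 2:] += 3.0
        x[1] = x[0]
        em = ExpressionMatrix(["h0", "h1"], list(ph.sample_ids), x, normalized=True)
        res = network_delta(em, ph, experiment_config(seed=61), {"h0", "h1"}, "h0")
        assert res.mean_delta < 0.05

    def test_removed_gene_must_be_in_network(self, panel):
        em, ph = panel
        with pytest.raises(ValueError):
            network_delta(em, ph, experiment_config(), {"g0", "g1"}, "g5")

    def test_absent_gene_rejected(self, panel):
        em, ph = panel
        with pytest.raises(ValueError):
            network_delta(em, ph, experiment_config(), {"g0", "nope"}, "nope")


class TestIntersect:
    def test_basic_and_disjoint(self):
        assert intersect_sets({"a", "b", "c"}, {"b", "c", "d"}) == ["b", "c"]
        assert intersect_sets({"a"}, {"b"}) == []
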