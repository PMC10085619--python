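import numpy as np
import pytest

from revscreen import (
    SignatureConfig,
    SimulationConfig,
    ValidationError,
    compute_fc,
    extract_signature,
    ora,
    simulate_agent_library,
    simulate_correlated_fc,
    simulate_expression,
    simulate_gene_sets,
    spearman_reversal,
    truth_profile,
    validate_reversal,
)


def small_config(**overrides) -> SimulationConfig:
    defaults = dict(
        n_genes=400, n_case=5, n_control=5, n_agents=12,
        n_reversers=3, n_mimickers=3, seed=1,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestSimulateExpression:
    def test_same_seed_reproduces_matrix_exactly(self):
        m1, t1 = simulate_expression(small_config())
        m2, t2 = simulate_expression(small_config())
        np.testing.assert_array_equal(m1.values.to_numpy(), m2.values.to_numpy())
        assert t1.equals(t2)

    def test_different_seeds_differ(self):
        m1, _ = simulate_expression(small_config(seed=1))
        m2, _ = simulate_expression(small_config(seed=2))
        assert not np.array_equal(m1.values.to_numpy(), m2.values.to_numpy())

    def test_null_simulation_has_no_signal(self):
        config = small_config(de_fraction=0.0, noise_sd=0.05)
        matrix, truth = simulate_expression(config)
        assert (truth["log2fc"] == 0).all()
        profile = compute_fc(matrix)
        fcs = np.array(list(profile.entries.values()))
        assert np.abs(np.log2(fcs)).max() < 0.5  # within noise of FC = 1

    def test_planted_fraction_and_dimensions(self):
        config = small_config(de_fraction=0.25)
        matrix, truth = simulate_expression(config)
        assert truth["is_de"].sum() == 100
        assert matrix.values.shape == (400, 10)
        assert len(matrix.group_samples("case")) == 5

    def test_signature_recovers_planted_genes(self):
        config = SimulationConfig(
            n_genes=5000, de_fraction=0.1, de_log2fc_mean=1.5,
            n_case=10, n_control=10, seed=11,
        )
        matrix, truth = simulate_expression(config)
        sig = extract_signature(compute_fc(matrix), SignatureConfig(1.50, 0.67))
        planted = set(truth.index[truth["is_de"]])
        recall = len(sig.genes & planted) / len(planted)
        assert recall >= 0.8


class TestSimulateAgentLibrary:
    def test_labels_and_counts(self):
        config = small_config()
        _, truth = simulate_expression(config)
        library, labels = simulate_agent_library(truth, config)
        assert len(library) == 12
        counts = {k: sum(v == k for v in labels.values()) for k in
                  ("reverser", "mimicker", "null")}
        assert counts == {"reverser": 3, "mimicker": 3, "null": 6}

    def test_noiseless_full_strength_reverser_is_exact_reciprocal(self):
        config = small_config(reversal_strength=1.0, agent_noise_sd=0.0)
        _, truth = simulate_expression(config)
        library, _ = simulate_agent_library(truth, config)
        disease = truth_profile(truth)
        reverser = library["reverser_001"]
        recip = disease.reciprocal()
        for g in disease.genes:
            assert reverser[g] == pytest.approx(recip[g], rel=1e-9)
        assert spearman_reversal(disease, reverser).rho == pytest.approx(-1.0)

    def test_null_agents_permute_disease_magnitudes(self):
        config = small_config(agent_noise_sd=0.0)
        _, truth = simulate_expression(config)
        library, labels = simulate_agent_library(truth, config)
        null_id = next(a for a, l in labels.items() if l == "null")
        null_mags = sorted(
            round(abs(np.log2(v)), 9) for v in library[null_id].entries.values()
        )
        disease_mags = sorted(round(abs(v), 9) for v in truth["log2fc"])
        assert null_mags == disease_mags

    def test_same_seed_reproduces_library(self):
        config = small_config()
        _, truth = simulate_expression(config)
        lib1, _ = simulate_agent_library(truth, config)
        lib2, _ = simulate_agent_library(truth, config)
        for (id1, p1), (id2, p2) in zip(lib1, lib2):
            assert id1 == id2 and p1.entries == p2.entries

    def test_agent_counts_validated(self):
        with pytest.raises(ValidationError, match="exceeds"):
            small_config(n_agents=4, n_reversers=3, n_mimickers=3)


class TestSimulateGeneSets:
    def test_deterministic_given_seed(self):
        uni = [f"G{i}" for i in range(100)]
        c1 = simulate_gene_sets(5, (5, 15), uni, seed=3)
        c2 = simulate_gene_sets(5, (5, 15), uni, seed=3)
        assert c1.sets == c2.sets

    def test_set_size_exceeding_universe_rejected(self):
        with pytest.raises(ValidationError, match="exceeds"):
            simulate_gene_sets(2, (5, 50), [f"G{i}" for i in range(10)], seed=0)

    def test_enriched_set_ranks_first_in_most_replicates(self):
        rng = np.random.default_rng(17)
        uni = [f"G{i:04d}" for i in range(2000)]
        wins = 0
        n_reps = 100
        for rep in range(n_reps):
            degs = set(rng.choice(uni, 150, replace=False))
            collection = simulate_gene_sets(
                10, (40, 80), uni, enriched_in=degs,
                oversample_rate=5.0, seed=1000 + rep,
            )
            results = ora(degs, collection)
            wins += results[0].set_name == "enriched_set"
        assert wins / n_reps >= 0.95


class TestSimulateCorrelatedFc:
    def test_planted_spearman_recovered(self):
        rng = np.random.default_rng(0)
        from revscreen import FoldChangeProfile

        disease = FoldChangeProfile(
            "disease",
            {f"G{i:05d}": float(v) for i, v in
             enumerate(2.0 ** rng.normal(0, 1, 10000))},
        )
        treatment = simulate_correlated_fc(disease, -0.2, seed=7)
        res = validate_reversal(treatment, disease)
        assert res.rho == pytest.approx(-0.2, abs=0.05)
        assert res.label == "reversal"

    def test_deterministic_given_seed(self, disease_profile):
        a = simulate_correlated_fc(disease_profile, 0.5, seed=4)
        b = simulate_correlated_fc(disease_profile, 0.5, seed=4)
        assert a.entries == b.entries

    def test_extreme_target_rejected(self, disease_profile):
        with pytest.raises(ValidationError):
            simulate_correlated_fc(disease_profile, 1.0, seed=0)


def test_seed_is_mandatory():
    with pytest.raises(ValidationError, match="seed"):
        SimulationConfig()
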