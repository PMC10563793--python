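"""Synthetic study generator: planted structure, determinism, calibration."""

import numpy as np
import pandas as pd
import pytest

from duplicability import classify, features, simulate
from duplicability.simulate import FeatureSpec, SimulationConfig, SizingError


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_chromosomes": -1},
            {"dataset_noise": 1.5},
            {"age_confound_strength": 2.0},
            {"node_age_table": {"Vertebrata": -5.0}},
            {"n_singletons": -2},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_unknown_distribution_family_rejected(self):
        with pytest.raises(ValueError, match="cauchy"):
            SimulationConfig(feature_specs={"x": FeatureSpec(distribution="cauchy")})

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=5, n_ohnolog_families=4, dataset_noise=0.2)
        path = tmp_path / "config.yaml"
        cfg.to_yaml(path)
        back = SimulationConfig.from_yaml(path)
        assert back.seed == 5 and back.dataset_noise == 0.2
        assert back.feature_specs.keys() == cfg.feature_specs.keys()


class TestGenomeLayout:
    def test_determinism_identical_outputs(self):
        cfg = SimulationConfig(seed=11)
        a = simulate.simulate_study(cfg)
        b = simulate.simulate_study(SimulationConfig(seed=11))
        for key in ("genes", "pairs", "segments", "features", "expression"):
            pd.testing.assert_frame_equal(a[key], b[key])
        assert a["ohnolog_sets"] == b["ohnolog_sets"]
        assert (a["truth"].true_class == b["truth"].true_class).all()

    def test_different_seeds_differ(self):
        a = simulate.simulate_genome(SimulationConfig(seed=1))[0]
        b = simulate.simulate_genome(SimulationConfig(seed=2))[0]
        assert not a.equals(b)

    def test_no_ohnolog_families_means_no_called_blocks(self):
        cfg = SimulationConfig(seed=3, n_ohnolog_families=0)
        genes, pairs, segments, truth = simulate.simulate_genome(cfg)
        assert truth.wgd_pairs == []
        assert classify.call_ohnolog_pairs(pairs, genes) == set()

    def test_fewer_than_three_families_is_a_sizing_error(self):
        with pytest.raises(SizingError, match="three linking pairs"):
            simulate.simulate_genome(SimulationConfig(n_ohnolog_families=2))

    def test_oversized_layout_is_a_sizing_error(self):
        cfg = SimulationConfig(
            n_chromosomes=2, genes_per_chromosome=10, n_ohnolog_families=30
        )
        with pytest.raises(SizingError):
            simulate.simulate_genome(cfg)

    def test_explicit_singleton_count_must_match_layout(self):
        cfg = SimulationConfig(seed=1, n_singletons=1)
        with pytest.raises(SizingError, match="n_singletons"):
            simulate.simulate_genome(cfg)

    def test_planted_structure_obeys_classification_rules(self):
        cfg = SimulationConfig(seed=4)
        genes, pairs, segments, truth = simulate.simulate_genome(cfg)
        # ohnolog pairs recoverable from synteny exactly
        assert classify.call_ohnolog_pairs(pairs, genes) == set(truth.wgd_pairs)
        # retro pairs satisfy the intron screen
        retro = truth.true_pairs[truth.true_pairs["kind"] == "RETRO"]
        for a, b in zip(retro["gene_a"], retro["gene_b"]):
            assert classify.detect_retroduplication((a, b), genes, pairs)
        # SSD nodes strictly inside the vertebrate lineage
        ssd = truth.true_pairs[truth.true_pairs["kind"] == "SSD"]
        root = cfg.node_age_table["Vertebrata"]
        assert all(cfg.node_age_table[n] < root for n in ssd["duplication_node"])
        # singletons appear in no vertebrate-node pair
        singles = set(truth.true_class[truth.true_class == "SINGLETON"].index)
        vert = truth.true_pairs[truth.true_pairs["kind"] != "PRE_VERTEBRATE"]
        assert singles.isdisjoint(set(vert["gene_a"]) | set(vert["gene_b"]))
        # each gene in at most one segment, members contiguous
        assert segments["gene_id"].is_unique

    def test_gene_order_indices_unique_per_chromosome(self):
        genes = simulate.simulate_genome(SimulationConfig(seed=5))[0]
        assert not genes.duplicated(["chromosome", "order_index"]).any()


class TestOhnologReplicates:
    def test_zero_noise_gives_identical_true_sets(self):
        cfg = SimulationConfig(seed=6, dataset_noise=0.0)
        genes, pairs, _, truth = simulate.simulate_genome(cfg)
        reps = simulate.simulate_ohnolog_replicates(pairs, truth, cfg)
        assert all(r == set(truth.wgd_pairs) for r in reps)

    def test_full_noise_with_empty_pools_gives_empty_sets(self):
        cfg = SimulationConfig(
            seed=7, n_ohnolog_families=0, n_ssd_families=0, n_retro_pairs=0,
            n_prevertebrate_pairs=0, dataset_noise=1.0,
        )
        genes, pairs, _, truth = simulate.simulate_genome(cfg)
        reps = simulate.simulate_ohnolog_replicates(pairs, truth, cfg)
        assert all(r == set() for r in reps)

    def test_dropout_rate_matches_binomial_expectation(self):
        cfg = SimulationConfig(
            seed=8, n_chromosomes=10, genes_per_chromosome=100,
            n_ohnolog_families=100, n_ssd_families=0, n_retro_pairs=0,
            n_prevertebrate_pairs=0, dataset_noise=0.1, include_cds=False,
        )
        genes, pairs, _, truth = simulate.simulate_genome(cfg)
        reps = simulate.simulate_ohnolog_replicates(pairs, truth, cfg)
        true_set = set(truth.wgd_pairs)
        for r in reps:
            kept = len(r & true_set)
            # Binomial(100, 0.9): 4 sd tolerance around 90
            assert 78 <= kept <= 100


class TestFeatureTable:
    def test_class_means_match_configured_locations(self):
        specs = {
            "up": FeatureSpec("normal", {"WGD": 2.0, "SSD": -1.0}, 1.0),
            "flat": FeatureSpec("normal", {}, 2.0),
        }
        cfg = SimulationConfig(
            seed=9, n_chromosomes=12, genes_per_chromosome=150,
            n_ohnolog_families=150, n_ssd_families=150, n_retro_pairs=0,
            n_prevertebrate_pairs=0, feature_specs=specs, include_cds=False,
        )
        genes, pairs, _, truth = simulate.simulate_genome(cfg)
        feats, _ = simulate.simulate_feature_table(truth, cfg)
        for cls, loc in [("WGD", 2.0), ("SSD", -1.0)]:
            vals = feats.loc[truth.true_class == cls, "up"]
            se = vals.std() / np.sqrt(len(vals))
            assert abs(vals.mean() - loc) < 3.5 * se + 1e-9
        flat = feats["flat"]
        assert abs(flat.mean()) < 3.5 * flat.std() / np.sqrt(len(flat))

    def test_zero_confound_leaves_features_age_free(self):
        specs = {f"f{i}": FeatureSpec("normal", {}, 1.0) for i in range(5)}
        cfg = SimulationConfig(
            seed=10, n_chromosomes=12, genes_per_chromosome=250,
            n_ohnolog_families=250, n_ssd_families=250, n_retro_pairs=0,
            n_prevertebrate_pairs=0, feature_specs=specs,
            age_confound_strength=0.0, include_cds=False,
        )
        genes, pairs, _, truth = simulate.simulate_genome(cfg)
        feats, _ = simulate.simulate_feature_table(truth, cfg)
        ages = features.assign_duplicate_age(pairs, genes)
        has_age = ages.notna()
        assert has_age.sum() >= 1000
        for col in feats.columns:
            r = np.corrcoef(feats.loc[has_age, col], ages[has_age])[0, 1]
            assert abs(r) < 0.1

    def test_confounded_feature_correlates_with_age_at_strength(self):
        specs = {"proxy": FeatureSpec("normal", {}, 1.0, age_confounded=True)}
        cfg = SimulationConfig(
            seed=11, n_chromosomes=12, genes_per_chromosome=250,
            n_ohnolog_families=250, n_ssd_families=250, n_retro_pairs=0,
            n_prevertebrate_pairs=0, feature_specs=specs,
            age_confound_strength=0.8, include_cds=False,
        )
        genes, pairs, _, truth = simulate.simulate_genome(cfg)
        feats, _ = simulate.simulate_feature_table(truth, cfg)
        ages = features.assign_duplicate_age(pairs, genes)
        has_age = ages.notna()
        r = np.corrcoef(feats.loc[has_age, "proxy"], ages[has_age])[0, 1]
        assert r == pytest.approx(0.8, abs=0.06)

    def test_shared_latent_produces_correlated_features(self):
        specs = {
            "a": FeatureSpec("normal", {}, 1.0, latent="L", loading=0.9),
            "b": FeatureSpec("normal", {}, 1.0, latent="L", loading=0.9),
            "c": FeatureSpec("normal", {}, 1.0),
        }
        cfg = SimulationConfig(
            seed=12, n_chromosomes=6, genes_per_chromosome=80,
            feature_specs=specs, include_cds=False,
        )
        genes, pairs, _, truth = simulate.simulate_genome(cfg)
        feats, _ = simulate.simulate_feature_table(truth, cfg)
        assert np.corrcoef(feats["a"], feats["b"])[0, 1] == pytest.approx(0.81, abs=0.08)
        assert abs(np.corrcoef(feats["a"], feats["c"])[0, 1]) < 0.15

    def test_expression_matrix_reflects_planted_breadth(self, small_study):
        truth = small_study["truth"]
        expr = small_study["expression"]
        tau = features.tissue_specificity(expr)
        assert (expr.to_numpy() >= 0).all()
        assert tau[truth.true_class == "SSD"].median() > tau[truth.true_class == "WGD"].median()
        mx = expr.max(axis=1)
        assert mx[truth.true_class == "WGD"].median() > mx[truth.true_class == "SSD"].median()
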