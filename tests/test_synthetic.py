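"""Planted-structure audits of the synthetic study generator."""

import networkx as nx
import numpy as np
import pytest

from modcross import synthetic as syn
from modcross.degs import DISEASE, NORMAL, UP
from modcross.synthetic import (
    PlantedCrosstalkSpec,
    PlantedModuleSpec,
    PlantedPivotSpec,
    SyntheticConfig,
)


def small_config(**kwargs) -> SyntheticConfig:
    defaults = dict(
        rng_seed=5,
        n_genes=200,
        background_attachment=2,
        planted_modules=[
            PlantedModuleSpec(6, 1.0, "inflammation"),
            PlantedModuleSpec(8, 0.9, "cancer"),
        ],
        n_datasets_per_context=2,
        samples_per_group=5,
        background_deg_fraction=0.0,
        n_regulators=4,
    )
    defaults.update(kwargs)
    return SyntheticConfig(**defaults)


class TestInteractome:
    def test_density_one_forces_clique(self):
        net, truth = syn.generate_interactome(small_config())
        members = truth.module_members[0]
        sub = net.subgraph(members)
        assert sub.number_of_edges() == 15  # C(6,2)

    def test_planted_density_is_lower_bound_and_connected(self):
        net, truth = syn.generate_interactome(small_config())
        members = truth.module_members[1]
        sub = net.subgraph(members)
        n = len(members)
        assert nx.is_connected(sub)
        assert sub.number_of_edges() >= np.ceil(0.9 * n * (n - 1) / 2)

    def test_same_seed_identical_edges(self):
        cfg = small_config()
        net1, _ = syn.generate_interactome(cfg)
        net2, _ = syn.generate_interactome(cfg)
        assert set(map(frozenset, net1.edges)) == set(map(frozenset, net2.edges))

    def test_different_seed_differs(self):
        net1, _ = syn.generate_interactome(small_config(rng_seed=1))
        net2, _ = syn.generate_interactome(small_config(rng_seed=2))
        assert set(map(frozenset, net1.edges)) != set(map(frozenset, net2.edges))

    def test_planted_crosstalk_exact_count_by_enumeration(self):
        cfg = small_config(
            planted_crosstalk=[PlantedCrosstalkSpec(0, 1, 12)],
        )
        net, truth = syn.generate_interactome(cfg)
        a, b = truth.module_members[0], truth.module_members[1]
        assert not (a & b)
        crossing = [
            e for e in net.edges
            if (e[0] in a and e[1] in b) or (e[1] in a and e[0] in b)
        ]
        assert len(crossing) == 12

    def test_simple_graph_all_scores_one(self):
        net, _ = syn.generate_interactome(small_config())
        assert nx.number_of_selfloops(net) == 0
        assert all(d["score"] == 1.0 for _, _, d in net.edges(data=True))

    def test_degree_distribution_right_skewed(self, default_study):
        _, net, _ = default_study
        degrees = np.array([d for _, d in net.degree])
        assert degrees.max() > 3 * np.median(degrees)

    def test_every_planted_gene_in_graph(self, default_study):
        _, net, truth = default_study
        assert set(truth.module_memberships) <= set(net.nodes)

    def test_infeasible_module_size_errors(self):
        with pytest.raises(ValueError, match="size"):
            small_config(
                planted_modules=[PlantedModuleSpec(1, 1.0, "cancer")]
            ).validate()

    def test_module_sizes_exceeding_universe_error(self):
        with pytest.raises(ValueError, match="exceed"):
            small_config(
                n_genes=10,
                planted_modules=[PlantedModuleSpec(8, 0.5, "cancer")] * 2,
            ).validate()


class TestExpression:
    def test_planted_shift_recovered_within_sampling_error(self):
        cfg = small_config(samples_per_group=10, deg_effect_size=5.0, noise_sd=1.0)
        _, truth = syn.generate_interactome(cfg)
        datasets = syn.generate_expression(cfg, truth)
        ds = datasets[0]
        dz, nz = ds.group_mask(DISEASE), ds.group_mask(NORMAL)
        diffs = []
        for gene, direction in truth.true_deg_sets["inflammation"].items():
            i = ds.genes.index(gene)
            diff = ds.values[i, dz].mean() - ds.values[i, nz].mean()
            diffs.append(diff if direction == UP else -diff)
        assert abs(np.mean(diffs) - 5.0) < 0.5

    def test_direction_consistent_across_datasets(self):
        cfg = small_config()
        _, truth = syn.generate_interactome(cfg)
        datasets = [d for d in syn.generate_expression(cfg, truth)
                    if d.dataset_id.startswith("cancer")]
        assert len(datasets) == 2
        for gene, direction in truth.true_deg_sets["cancer"].items():
            for ds in datasets:
                i = ds.genes.index(gene)
                diff = (ds.values[i, ds.group_mask(DISEASE)].mean()
                        - ds.values[i, ds.group_mask(NORMAL)].mean())
                assert (diff > 0) == (direction == UP)

    def test_null_generator_has_no_systematic_shift(self):
        cfg = small_config(deg_effect_size=0.0)
        _, truth = syn.generate_interactome(cfg)
        ds = syn.generate_expression(cfg, truth)[0]
        dz, nz = ds.group_mask(DISEASE), ds.group_mask(NORMAL)
        diffs = ds.values[:, dz].mean(axis=1) - ds.values[:, nz].mean(axis=1)
        assert abs(diffs.mean()) < 0.1

    def test_too_few_samples_error(self):
        cfg = small_config(samples_per_group=1)
        _, truth = syn.generate_interactome(small_config())
        with pytest.raises(ValueError, match="samples_per_group"):
            syn.generate_expression(cfg, truth)

    def test_determinism(self):
        cfg = small_config()
        _, truth = syn.generate_interactome(cfg)
        a = syn.generate_expression(cfg, truth)[0]
        b = syn.generate_expression(cfg, truth)[0]
        np.testing.assert_array_equal(a.values, b.values)


class TestRegulators:
    def test_planted_pivot_targets_both_modules(self):
        cfg = small_config(
            planted_pivots=[PlantedPivotSpec("TF_P", 0, 1, 4)],
        )
        _, truth = syn.generate_interactome(cfg)
        rmap = syn.generate_regulator_map(cfg, truth)
        targets = rmap.targets("TF_P")
        assert len(targets & truth.module_members[0]) >= 4
        assert len(targets & truth.module_members[1]) >= 4

    def test_decoy_overlap_matches_hypergeometric_expectation(self):
        cfg = small_config(n_genes=1000, n_regulators=200, targets_per_decoy=10,
                           planted_modules=[PlantedModuleSpec(10, 0.9, "cancer")])
        _, truth = syn.generate_interactome(cfg)
        rmap = syn.generate_regulator_map(cfg, truth)
        module = truth.module_members[0]
        overlaps = [len(rmap.targets(r) & module) for r in rmap.entries]
        # expectation n*K/N = 10*10/1000 = 0.1 per decoy
        assert abs(np.mean(overlaps) - 0.1) < 0.08

    def test_no_pivots_means_only_decoys(self):
        cfg = small_config(planted_pivots=[], n_regulators=6)
        _, truth = syn.generate_interactome(cfg)
        rmap = syn.generate_regulator_map(cfg, truth)
        assert len(rmap) == 6
        assert all("DECOY" in r for r in rmap.entries)

    def test_oversized_pivot_request_errors(self):
        with pytest.raises(ValueError, match="targets_per_module"):
            small_config(
                planted_pivots=[PlantedPivotSpec("TF_P", 0, 1, 7)],
            ).validate()
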