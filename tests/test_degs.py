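"""Unit tests for the SAM-style statistic, permutation calling, integration."""

import numpy as np
import pytest

from modcross import (
    ExpressionDataset,
    call_degs,
    integrate_degs,
    sam_statistic,
    set_overlap,
)
from modcross.degs import (
    DEGRecord,
    DOWN,
    UP,
    pooled_standard_errors,
    read_expression,
    write_expression,
)


def make_dataset(values, n_disease, dataset_id="ds"):
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    samples = [f"s{i}" for i in range(n)]
    return ExpressionDataset(
        dataset_id=dataset_id,
        genes=[f"g{i}" for i in range(values.shape[0])],
        samples=samples,
        values=values,
        group_labels={s: ("disease" if i < n_disease else "normal")
                      for i, s in enumerate(samples)},
    )


class TestSamStatistic:
    def test_hand_computed_pooled_se_example(self, two_group_dataset):
        # groups (4,5,6) vs (1,2,3): s = sqrt((1/3+1/3)*(2+2)/4) ~ 0.8165
        se = pooled_standard_errors(two_group_dataset)
        assert se[0] == pytest.approx(np.sqrt(2 / 3), rel=1e-12)
        d = sam_statistic(two_group_dataset, s0=0.0)
        assert d["g1"] == pytest.approx(3.0 / np.sqrt(2 / 3), rel=1e-12)
        assert d["g1"] == pytest.approx(3.674, abs=5e-4)

    def test_identical_group_means_give_zero(self, two_group_dataset):
        assert sam_statistic(two_group_dataset, s0=0.0)["g2"] == 0.0

    def test_sign_positive_iff_disease_higher(self):
        ds = make_dataset([[1.0, 2.0, 5.0, 6.0]], n_disease=2)
        assert sam_statistic(ds, s0=0.5)["g0"] < 0

    def test_increasing_s0_shrinks_magnitude(self, two_group_dataset):
        d1 = abs(sam_statistic(two_group_dataset, s0=0.1)["g1"])
        d2 = abs(sam_statistic(two_group_dataset, s0=0.2)["g1"])
        assert d2 < d1

    def test_zero_variance_with_zero_s0_raises(self):
        ds = make_dataset([[1.0, 1.0, 2.0, 2.0]], n_disease=2)
        with pytest.raises(ZeroDivisionError):
            sam_statistic(ds, s0=0.0)

    def test_zero_variance_flagged_infinite_when_configured(self):
        ds = make_dataset([[1.0, 1.0, 2.0, 2.0]], n_disease=2)
        d = sam_statistic(ds, s0=0.0, on_zero_variance="inf")
        assert np.isneginf(d["g0"])

    def test_within_group_relabeling_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(20, 10))
        ds = make_dataset(x, n_disease=5)
        shuffled = x[:, [2, 0, 1, 4, 3, 7, 9, 5, 6, 8]]  # permute inside groups
        ds2 = make_dataset(shuffled, n_disease=5)
        np.testing.assert_allclose(
            sam_statistic(ds, s0=0.1).to_numpy(),
            sam_statistic(ds2, s0=0.1).to_numpy(),
        )


class TestCallDegs:
    def test_null_dataset_calls_almost_nothing(self):
        rng = np.random.default_rng(42)
        ds = make_dataset(rng.normal(size=(500, 20)), n_disease=10)
        records = call_degs(ds, fdr_target=0.01, n_permutations=100, rng_seed=1)
        assert len(records) <= 0.02 * 500

    def test_planted_effects_recovered_with_directions(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(300, 20))
        x[:20, :10] += 5.0   # up
        x[20:40, :10] -= 5.0  # down
        ds = make_dataset(x, n_disease=10)
        records = call_degs(ds, fdr_target=0.01, n_permutations=100, rng_seed=2)
        by_gene = {r.gene: r for r in records}
        hits_up = [f"g{i}" for i in range(20) if f"g{i}" in by_gene]
        hits_down = [f"g{i}" for i in range(20, 40) if f"g{i}" in by_gene]
        assert len(hits_up) + len(hits_down) >= 36
        assert all(by_gene[g].direction == UP for g in hits_up)
        assert all(by_gene[g].direction == DOWN for g in hits_down)
        assert all(r.q_value <= 0.01 for r in records)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(100, 12))
        x[:5, :6] += 4
        ds = make_dataset(x, n_disease=6)
        r1 = call_degs(ds, rng_seed=9)
        r2 = call_degs(ds, rng_seed=9)
        assert r1 == r2


class TestIntegration:
    def rec(self, gene, direction):
        return DEGRecord(gene=gene, d_stat=1.0 if direction == UP else -1.0,
                         direction=direction, q_value=0.005)

    def test_two_dataset_consistent_gene_kept(self):
        out = integrate_degs([
            ("A", [self.rec("g1", UP)]),
            ("B", [self.rec("g1", UP)]),
        ])
        assert out.members == {"g1": UP}
        assert out.support["g1"] == ["A", "B"]

    def test_direction_conflict_excluded(self):
        out = integrate_degs([
            ("A", [self.rec("g1", UP)]),
            ("B", [self.rec("g1", DOWN)]),
        ])
        assert "g1" not in out.members

    def test_single_dataset_gene_excluded(self):
        out = integrate_degs([
            ("A", [self.rec("g1", UP)]),
            ("B", []),
        ])
        assert len(out) == 0

    def test_duplicate_dataset_id_errors(self):
        with pytest.raises(ValueError, match="duplicate"):
            integrate_degs([("A", []), ("A", [])])

    def test_single_comparison_mode_for_direct_disease_contrast(self):
        # inflammation-vs-cancer run with one dataset pair available
        out = integrate_degs([("A", [self.rec("g1", UP)])],
                             context="inflammation-vs-cancer", min_datasets=1)
        assert out.members == {"g1": UP}


class TestSetOverlap:
    def make_set(self, genes, context="inflammation"):
        from modcross.degs import IntegratedDEGSet
        return IntegratedDEGSet(
            context=context,
            members={g: UP for g in genes},
            support={g: ["A", "B"] for g in genes},
        )

    def test_partition_of_union(self):
        a = self.make_set({"g1", "g2", "g3"})
        b = self.make_set({"g2", "g3", "g4"}, context="cancer")
        shared, a_only, b_only = set_overlap(a, b)
        assert shared == {"g2", "g3"}
        assert a_only == {"g1"}
        assert b_only == {"g4"}
        assert len(shared) + len(a_only) == len(a.genes())

    def test_identical_and_disjoint(self):
        a = self.make_set({"g1", "g2"})
        assert set_overlap(a, a)[0] == {"g1", "g2"}
        b = self.make_set({"g9"})
        shared, a_only, b_only = set_overlap(a, b)
        assert shared == set() and a_only == {"g1", "g2"} and b_only == {"g9"}


def test_expression_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(1)
    ds = make_dataset(rng.normal(size=(10, 8)).round(4), n_disease=4, dataset_id="rt")
    write_expression(ds, tmp_path / "m.tsv", tmp_path / "l.tsv")
    back = read_expression(tmp_path / "m.tsv", tmp_path / "l.tsv", dataset_id="rt")
    assert back.genes == ds.genes and back.samples == ds.samples
    assert back.group_labels == ds.group_labels
    np.testing.assert_allclose(back.values, ds.values, atol=1e-9)
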