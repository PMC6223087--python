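"""Correlation-distance gene clustering and cluster-subset selection."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from deblend.clustering import cluster_genes, select_cluster_subsets
from deblend.datatypes import ExpressionMatrix, ValidationError


def three_group_matrix(seed=0, per_group=50, p=12):
    """Genes proportional to one of 3 orthogonal patterns (plus tiny jitter)."""
    rng = np.random.default_rng(seed)
    patterns = np.zeros((3, p))
    patterns[0, :4] = 10.0
    patterns[1, 4:8] = 10.0
    patterns[2, 8:] = 10.0
    patterns += 1.0
    rows, labels = [], []
    for g in range(3):
        for _ in range(per_group):
            rows.append(patterns[g] * rng.uniform(0.5, 2.0)
                        + rng.normal(0, 0.01, size=p) ** 2)
            labels.append(g)
    values = np.abs(np.vstack(rows))
    genes = [f"g{i}" for i in range(len(rows))]
    samples = [f"s{j}" for j in range(p)]
    return ExpressionMatrix(values, genes, samples), np.array(labels)


@pytest.mark.parametrize("method", ["kmeans", "kmedoids"])
def test_recovers_planted_groups(method):
    expr, truth = three_group_matrix()
    result = cluster_genes(expr, 3, method=method, replicates=20, seed=1)
    found = np.array([result.assignment[g] for g in expr.gene_ids])
    assert adjusted_rand_score(truth, found) == 1.0


def test_k_below_two_rejected():
    expr, _ = three_group_matrix()
    with pytest.raises(ValidationError):
        cluster_genes(expr, 1)


def test_same_seed_same_result():
    expr, _ = three_group_matrix()
    a = cluster_genes(expr, 3, replicates=5, seed=7)
    b = cluster_genes(expr, 3, replicates=5, seed=7)
    assert a.assignment == b.assignment
    np.testing.assert_array_equal(a.exemplars, b.exemplars)


def test_scale_invariance_of_correlation_distance():
    expr, _ = three_group_matrix()
    scaled = ExpressionMatrix(
        np.vstack([expr.values[0] * 37.0, expr.values[1:]]),
        expr.gene_ids, expr.sample_ids)
    a = cluster_genes(expr, 3, replicates=5, seed=3)
    b = cluster_genes(scaled, 3, replicates=5, seed=3)
    assert a.assignment == b.assignment


def test_objective_beats_every_single_restart():
    expr, _ = three_group_matrix(seed=5)
    multi = cluster_genes(expr, 3, replicates=10, seed=11)
    singles = []
    for s in range(8):
        try:
            singles.append(cluster_genes(expr, 3, replicates=1, seed=s).objective)
        except ValidationError:
            pass  # a collapsed restart is excluded, not compared
    assert singles and multi.objective <= min(singles) + 1e-9


def test_kmeans_exemplar_is_linear_mean_profile():
    expr, _ = three_group_matrix()
    result = cluster_genes(expr, 3, replicates=5, seed=1)
    for t in range(1, 4):
        members = result.members(t)
        idx = [expr.gene_ids.index(g) for g in members]
        np.testing.assert_allclose(result.exemplars[t - 1],
                                   expr.values[idx].mean(axis=0), atol=1e-10)


def test_log_space_exemplars_still_linear():
    expr, _ = three_group_matrix()
    result = cluster_genes(expr, 3, space="log", replicates=5, seed=1)
    assert result.space == "log"
    # exemplar magnitudes match the linear data, not log2 values
    assert result.exemplars.max() > np.log2(expr.values.max() + 1)


def test_zero_variance_gene_is_an_error():
    values = np.vstack([np.ones(6), np.arange(6.0) + 1])
    expr = ExpressionMatrix(values, ["flat", "ok"], [f"s{j}" for j in range(6)])
    with pytest.raises(ValidationError, match="CV"):
        cluster_genes(expr, 2, replicates=2, seed=0)


class TestClusterSubsets:
    def test_fraction_100_returns_full_clusters(self):
        expr, _ = three_group_matrix()
        result = cluster_genes(expr, 3, replicates=5, seed=1)
        subsets = select_cluster_subsets(expr, result, 100)
        assert sorted(subsets.all_genes()) == sorted(expr.gene_ids)

    def test_takes_closest_half_by_distance(self):
        # 4 genes at controlled correlation distances from the exemplar
        p = 8
        base = np.linspace(1, 8, p)
        rng = np.random.default_rng(0)
        rows = [base + rng.normal(0, s, size=p) for s in (0.01, 0.3, 0.8, 2.0)]
        far = [10.0 - base + rng.normal(0, 0.01, size=p) for _ in range(2)]
        values = np.abs(np.vstack(rows + far)) + 0.1
        expr = ExpressionMatrix(values, [f"g{i}" for i in range(6)],
                                [f"s{j}" for j in range(p)])
        result = cluster_genes(expr, 2, replicates=10, seed=2)
        subsets = select_cluster_subsets(expr, result, 50)
        cluster_of_g0 = result.assignment["g0"]
        chosen = subsets.sets[f"cluster_{cluster_of_g0}"]
        assert len(chosen) == 2 and "g0" in chosen

    def test_ceiling_rule_keeps_at_least_one(self):
        expr, _ = three_group_matrix()
        result = cluster_genes(expr, 3, replicates=5, seed=1)
        subsets = select_cluster_subsets(expr, result, 1)
        assert all(len(v) == 1 for v in subsets.sets.values())

    def test_fraction_out_of_range_rejected(self):
        expr, _ = three_group_matrix()
        result = cluster_genes(expr, 3, replicates=2, seed=1)
        with pytest.raises(ValidationError):
            select_cluster_subsets(expr, result, 0)
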