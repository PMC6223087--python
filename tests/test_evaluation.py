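"""Component matching and proportion-accuracy metrics."""

from itertools import permutations

import numpy as np
import pytest

from deblend.clustering import cluster_genes
from deblend.datatypes import ProportionMatrix, SignatureMatrix, ValidationError
from deblend.evaluation import (
    assign_clusters_by_reference,
    evaluate_proportions,
    match_components,
)
from deblend.synthetic import generate_mixture, MixtureSpec


def prop(values):
    values = np.asarray(values, dtype=float)
    return ProportionMatrix(values, [f"t{i}" for i in range(values.shape[0])],
                            [f"s{j}" for j in range(values.shape[1])])


class TestMatchComponents:
    def test_swapped_rows_recovered(self):
        rng = np.random.default_rng(0)
        A = rng.dirichlet(np.ones(3), size=6).T
        ref, est = prop(A), prop(A[[2, 0, 1]])
        perm = match_components(est, ref)
        np.testing.assert_allclose(est.values[list(perm)], ref.values)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            E = rng.dirichlet(np.ones(4), size=5).T
            R = rng.dirichlet(np.ones(4), size=5).T
            perm = match_components(prop(E), prop(R))
            best = max(permutations(range(4)),
                       key=lambda p: np.corrcoef(E[list(p)].ravel(), R.ravel())[0, 1])
            got = np.corrcoef(E[list(perm)].ravel(), R.ravel())[0, 1]
            want = np.corrcoef(E[list(best)].ravel(), R.ravel())[0, 1]
            assert got == pytest.approx(want, abs=1e-12)

    def test_hungarian_agrees_for_well_separated_rows(self):
        rng = np.random.default_rng(2)
        A = rng.dirichlet(np.ones(5), size=12).T
        est = A[[3, 1, 4, 0, 2]]
        perm_ex = match_components(est, A, exhaustive=True)
        perm_hu = match_components(est, A, exhaustive=False)
        assert perm_ex == perm_hu


class TestEvaluateProportions:
    def test_identity_is_perfect(self):
        rng = np.random.default_rng(3)
        A = prop(rng.dirichlet(np.ones(3), size=5).T)
        rep = evaluate_proportions(A, A)
        assert rep.pearson_overall == pytest.approx(1.0)
        assert rep.rmse_full == 0.0 and rep.mrmse == 0.0

    def test_hand_computed_example(self):
        ref = prop([[0.6, 0.3], [0.4, 0.7]])
        est = prop([[0.5, 0.4], [0.5, 0.6]])
        rep = evaluate_proportions(est, ref)
        assert rep.rmse_full == pytest.approx(0.1, abs=1e-12)
        assert rep.mrmse == pytest.approx(0.1, abs=1e-12)
        # cov 0.04, variances 0.10 and 0.02: r = 0.04 / sqrt(0.002)
        assert rep.pearson_overall == pytest.approx(0.894427191, abs=1e-9)

    def test_single_row_collapses_to_full_rmse(self):
        ref = np.array([[0.2, 0.5, 0.9]])
        est = np.array([[0.3, 0.4, 0.7]])
        rep = evaluate_proportions(est, ref)
        assert rep.rmse_per_type[0] == rep.rmse_full == rep.mrmse

    def test_rmse_symmetric_in_arguments(self):
        rng = np.random.default_rng(4)
        A = prop(rng.dirichlet(np.ones(3), size=6).T)
        B = prop(rng.dirichlet(np.ones(3), size=6).T)
        r1 = evaluate_proportions(A, B)
        r2 = evaluate_proportions(B, A)
        assert r1.rmse_full == r2.rmse_full and r1.mrmse == r2.mrmse
        assert r1.pearson_overall == pytest.approx(r2.pearson_overall)

    def test_matching_never_lowers_correlation(self):
        rng = np.random.default_rng(5)
        E = prop(rng.dirichlet(np.ones(4), size=7).T)
        R = prop(rng.dirichlet(np.ones(4), size=7).T)
        matched = evaluate_proportions(E, R, permute=True)
        unmatched = evaluate_proportions(E, R, permute=False)
        assert matched.pearson_overall >= unmatched.pearson_overall - 1e-12

    def test_mrmse_is_mean_of_per_type(self):
        rng = np.random.default_rng(6)
        E = prop(rng.dirichlet(np.ones(3), size=8).T)
        R = prop(rng.dirichlet(np.ones(3), size=8).T)
        rep = evaluate_proportions(E, R)
        assert rep.mrmse == pytest.approx(np.mean(rep.rmse_per_type), abs=1e-12)

    def test_constant_matrix_correlation_undefined(self):
        flat = prop(np.full((2, 3), 0.5))
        with pytest.raises(ValidationError, match="zero variance"):
            evaluate_proportions(flat, flat)


class TestClusterIdentityAssignment:
    def test_majority_peak_assignment(self):
        bundle = generate_mixture(MixtureSpec(n_genes=300, k=3, p=10,
                                              markers_per_type=20,
                                              noise_sd=0.0, seed=11))
        clusters = cluster_genes(bundle.X, 3, replicates=10, seed=11)
        mapping = assign_clusters_by_reference(clusters, bundle.S_true)
        # each marker block peaks in its own type; clusters must follow it
        for t, (label, genes) in enumerate(bundle.markers.sets.items()):
            cluster_ids = {clusters.assignment[g] for g in genes}
            assert len(cluster_ids) == 1
            assert mapping[cluster_ids.pop()] == t

    def test_tie_prefers_lower_type_index(self):
        S = SignatureMatrix(np.array([[5.0, 1.0], [1.0, 5.0]]),
                            ["g1", "g2"], ["A", "B"], lb=0.0, ub=10.0)
        from deblend.clustering import ClusterResult
        clusters = ClusterResult(assignment={"g1": 1, "g2": 1},
                                 exemplars=np.ones((2, 2)),
                                 sample_ids=["s1", "s2"], method="kmeans",
                                 exemplar_kind="mean_profile", space="linear",
                                 seed=0, objective=0.0,
                                 space_centroids=np.ones((2, 2)))
        mapping = assign_clusters_by_reference(clusters, S)
        assert mapping[1] == 0
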