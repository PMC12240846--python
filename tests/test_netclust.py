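import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from hsqtl import netclust
from hsqtl.netclust import (SimilarityNetwork, allele_by_cluster_test,
                            build_similarity_network, cluster_contrasts,
                            fit_sbm, label_clusters, standardize_within_group)
from hsqtl.simdata import simulate_clustered_cohort
from conftest import planted_partition_graph


class TestStandardize:
    def test_single_cell_plain_zscores(self):
        table = pd.DataFrame({"id": list("abcd"), "sex": ["F"] * 4,
                              "site": ["site1"] * 4, "y": [1.0, 2, 3, 4]})
        z = standardize_within_group(table, ["y"])
        np.testing.assert_allclose(z["y"], (table["y"] - 2.5) / np.std([1, 2, 3, 4]))

    def test_cell_means_removed(self):
        table = pd.DataFrame({
            "id": [f"i{k}" for k in range(40)],
            "sex": ["F"] * 20 + ["M"] * 20,
            "site": ["site1"] * 40,
            "y": np.r_[np.random.default_rng(0).normal(0, 1, 20),
                       np.random.default_rng(1).normal(100, 1, 20)],
        })
        z = standardize_within_group(table, ["y"])
        assert abs(z["y"][:20].mean()) < 1e-10 and abs(z["y"][20:].mean()) < 1e-10

    def test_affine_invariance_per_cell(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame({"id": [f"i{k}" for k in range(60)],
                              "sex": np.where(np.arange(60) % 2 == 0, "F", "M"),
                              "site": "site1", "y": rng.standard_normal(60)})
        warped = table.copy()
        warped.loc[warped["sex"] == "F", "y"] = 3 * warped.loc[warped["sex"] == "F", "y"] + 7
        np.testing.assert_allclose(standardize_within_group(table, ["y"]),
                                   standardize_within_group(warped, ["y"]),
                                   atol=1e-10)

    def test_zero_variance_cell_becomes_zeros(self):
        table = pd.DataFrame({"id": list("abc"), "sex": ["F"] * 3,
                              "site": ["site1"] * 3, "y": [5.0, 5.0, 5.0]})
        z = standardize_within_group(table, ["y"])
        np.testing.assert_array_equal(z["y"], 0.0)


class TestNetwork:
    def test_identical_individuals_form_clique(self):
        Z = pd.DataFrame(np.tile([1.0, -1.0, 0.5, 2.0], (3, 1)))
        Z += 1e-9 * np.random.default_rng(0).standard_normal(Z.shape)
        net = build_similarity_network(Z, ids=list("abc"), edge_quantile=0.5)
        assert net.n_edges == 3

    def test_edge_density_matches_quantile(self):
        rng = np.random.default_rng(1)
        Z = pd.DataFrame(rng.standard_normal((100, 12)))
        net = build_similarity_network(Z, edge_quantile=0.8)
        total_pairs = 100 * 99 // 2
        assert net.n_edges == pytest.approx(0.2 * total_pairs, abs=2)

    def test_planted_groups_denser_within(self):
        table, labels = simulate_clustered_cohort(50, separation=3.0, seed=4)
        traits = [c for c in table.columns if c not in ("id", "site", "sex")]
        Z = standardize_within_group(table, traits)
        net = build_similarity_network(Z, ids=list(table["id"]))
        A = net.adjacency
        same = labels[:, None] == labels[None, :]
        np.fill_diagonal(same, False)
        within = A[same].mean()
        between = A[~same & ~np.eye(len(labels), dtype=bool)].mean()
        assert within > 2 * between

    def test_adjacency_invariants(self):
        rng = np.random.default_rng(5)
        Z = pd.DataFrame(rng.standard_normal((30, 8)))
        net = build_similarity_network(Z)
        np.testing.assert_array_equal(net.adjacency, net.adjacency.T)
        assert np.diag(net.adjacency).sum() == 0


class TestSbm:
    def test_three_cliques_exact_recovery(self):
        z = np.repeat([0, 1, 2], 20)
        A = (z[:, None] == z[None, :]).astype(np.int8)
        np.fill_diagonal(A, 0)
        net = SimilarityNetwork(ids=[str(i) for i in range(60)], adjacency=A)
        fit = fit_sbm(net, K=3, n_sweeps=80, burn_in=30, seed=0)
        assert adjusted_rand_score(z, fit.assignments) == 1.0

    def test_erdos_renyi_has_no_structure(self):
        rng = np.random.default_rng(6)
        n = 120
        A = np.zeros((n, n), dtype=np.int8)
        iu = np.triu_indices(n, 1)
        A[iu] = rng.random(iu[0].size) < 0.15
        A = A + A.T
        net = SimilarityNetwork(ids=[str(i) for i in range(n)], adjacency=A)
        fit = fit_sbm(net, K=3, n_sweeps=80, burn_in=30, seed=1)
        planted = np.repeat([0, 1, 2], n // 3)
        assert abs(adjusted_rand_score(planted, fit.assignments)) < 0.05

    def test_log_posterior_finite_every_sweep(self):
        z, A = planted_partition_graph(90, 3, 0.4, 0.05, seed=2)
        net = SimilarityNetwork(ids=[str(i) for i in range(90)], adjacency=A)
        fit = fit_sbm(net, K=3, n_sweeps=60, burn_in=20, seed=3)
        assert np.isfinite(fit.log_posterior_trace).all()

    def test_empty_graph_and_excess_blocks_rejected(self):
        net = SimilarityNetwork(ids=list("abcd"), adjacency=np.zeros((4, 4), dtype=np.int8))
        with pytest.raises(ValueError):
            fit_sbm(net, K=3)
        z, A = planted_partition_graph(6, 2, 0.9, 0.1, seed=4)
        net2 = SimilarityNetwork(ids=[str(i) for i in range(6)], adjacency=A)
        with pytest.raises(ValueError):
            fit_sbm(net2, K=10)


def labeled_fixture(seed=0):
    table, labels = simulate_clustered_cohort(60, separation=3.0, seed=seed)
    traits = [c for c in table.columns if c not in ("id", "site", "sex")]
    Z = standardize_within_group(table, traits)
    net = build_similarity_network(Z, ids=list(table["id"]))
    fit = fit_sbm(net, K=3, n_sweeps=150, burn_in=50, seed=seed)
    return table, labels, traits, fit


class TestLabeling:
    def test_planted_severity_gradient_matches_labels(self):
        table, labels, traits, fit = labeled_fixture()
        fit = label_clusters(fit, table, traits)
        got = np.array([fit.labels[int(b)] for b in fit.assignments])
        assert np.mean((got == "vulnerable") == (labels == 2)) > 0.9
        assert np.mean((got == "resilient") == (labels == 0)) > 0.9

    def test_internal_block_ids_do_not_matter(self):
        table, _, traits, fit = labeled_fixture(seed=1)
        fit = label_clusters(fit, table, traits)
        ref = np.array([fit.labels[int(b)] for b in fit.assignments])
        permuted = netclust.BlockModelFit(
            ids=fit.ids, K=3, assignments=(2 - fit.assignments),
            edge_prob=fit.edge_prob, posterior_confidence=fit.posterior_confidence,
            log_posterior_trace=fit.log_posterior_trace, seed=fit.seed)
        permuted = label_clusters(permuted, table, traits)
        got = np.array([permuted.labels[int(b)] for b in permuted.assignments])
        np.testing.assert_array_equal(ref, got)

    def test_constant_severity_traits_take_tie_path(self):
        table, _, traits, fit = labeled_fixture(seed=2)
        table = table.copy()
        table["flat"] = 1.0
        fit = label_clusters(fit, table, ["flat"])
        assert any("tie" in w for w in fit.label_warnings)

    def test_contrasts_partition_cohort(self):
        table, _, traits, fit = labeled_fixture(seed=3)
        fit = label_clusters(fit, table, traits)
        contrasts = cluster_contrasts(fit)
        total = sum(c.to_numpy() for c in contrasts.values())
        np.testing.assert_array_equal(total, 1)
        n_vuln = int(contrasts["vulnerable_vs_rest"].sum())
        assert (np.array([fit.labels[int(b)] for b in fit.assignments])
                == "vulnerable").sum() == n_vuln


class TestAlleleByCluster:
    def test_hand_computed_two_by_two(self):
        # [[30,10],[10,30]]: chi2 = n (ad-bc)^2 / (r1 r2 c1 c2) = 20
        g = np.array([0.0] * 40 + [1.0] * 40)
        c = np.array([1] * 30 + [0] * 10 + [1] * 10 + [0] * 30)
        chi2, df, p, table = allele_by_cluster_test(g, c)
        assert chi2 == pytest.approx(20.0)
        assert df == 1

    def test_independence_gives_zero(self):
        g = np.array([0.0, 0, 1, 1] * 20)
        c = np.array([0, 1, 0, 1] * 20)
        chi2, df, p, _ = allele_by_cluster_test(g, c)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_symmetric_under_row_column_swap(self):
        rng = np.random.default_rng(7)
        g = rng.integers(0, 3, 200).astype(float)
        c = rng.integers(0, 2, 200)
        chi2_a, *_ = allele_by_cluster_test(g, c)
        chi2_b, *_ = allele_by_cluster_test(2 - g, 1 - c)
        assert chi2_a == pytest.approx(chi2_b)

    def test_full_genotype_grouping_uses_two_df(self):
        rng = np.random.default_rng(8)
        g = rng.integers(0, 3, 300).astype(float)
        c = rng.integers(0, 2, 300)
        _, df, _, table = allele_by_cluster_test(g, c, grouping="genotype")
        assert df == 2 and table.shape == (3, 2)

    def test_missing_entries_dropped(self):
        g = np.array([0.0, 1, np.nan, 2, 0, 1, 2, 0])
        c = np.array([0, 1, 0, 1, 0, 1, np.nan, 1.0])
        _, _, _, table = allele_by_cluster_test(g, c)
        assert table.to_numpy().sum() == 6
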