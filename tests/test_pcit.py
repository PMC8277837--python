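import numpy as np
import pandas as pd
import pytest

from asmnet import pcit, preprocess
from asmnet.containers import ConfigurationError
from asmnet.simdata import SimConfig, simulate_counts

from conftest import make_expression, pcit_brute_force


class TestCorrelationMatrix:
    def test_duplicated_gene_has_unit_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=5)
        case = np.vstack([x, x, rng.normal(size=5)])
        expr = make_expression(case, rng.normal(size=(3, 5)))
        r, _ = pcit.correlation_matrix(expr, "case")
        assert r.iloc[0, 1] == pytest.approx(1.0)

    def test_exact_anticorrelation(self):
        expr = make_expression(np.array([[1, 2, 3], [3, 2, 1]]), np.ones((2, 3)))
        r, _ = pcit.correlation_matrix(expr, "case")
        assert r.iloc[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        expr = make_expression(np.array([[1, 2, 3, 4], [1, 2, 4, 3]]), np.ones((2, 4)))
        r, _ = pcit.correlation_matrix(expr, "case")
        assert r.iloc[0, 1] == pytest.approx(0.8)

    def test_zero_variance_gene_flagged(self):
        expr = make_expression(np.array([[1.0, 1.0, 1.0], [1, 2, 3]]), np.ones((2, 3)))
        r, valid = pcit.correlation_matrix(expr, "case")
        assert not valid[0] and valid[1]
        assert r.iloc[0, 1] == 0.0

    def test_too_few_samples(self):
        expr = make_expression(np.ones((3, 2)), np.ones((3, 4)))
        with pytest.raises(ConfigurationError):
            pcit.correlation_matrix(expr, "case")


class TestPcitEdges:
    def test_trio_partial_correlation_value(self):
        # r_xy=0.9, r_xz=0.9, r_yz=0.81 -> r_xy.z = (0.9-0.729)/sqrt(0.19*0.3439)
        r_xy, r_xz, r_yz = 0.9, 0.9, 0.81
        expected = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        assert expected == pytest.approx(0.669, abs=1e-3)

    def test_diagonal_only_matrix_matches_oracle(self):
        R = np.eye(5)
        np.testing.assert_array_equal(pcit.pcit_significance(R), pcit_brute_force(R))

    @pytest.mark.parametrize("seed", range(10))
    def test_vectorized_equals_brute_force(self, seed):
        """Central oracle: the vectorized path reproduces the naive O(n^3)
        trio scan pair-for-pair on correlation matrices of simulated data."""
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((30, 12))
        # add some correlated structure so elimination actually fires
        X[:10] += rng.standard_normal((1, 12))
        R = np.corrcoef(X)
        np.testing.assert_array_equal(pcit.pcit_significance(R), pcit_brute_force(R))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((15, 10))
        R = np.corrcoef(X)
        keep = pcit.pcit_significance(R)
        perm = rng.permutation(15)
        keep_perm = pcit.pcit_significance(R[np.ix_(perm, perm)])
        np.testing.assert_array_equal(keep[np.ix_(perm, perm)], keep_perm)

    def test_small_matrix_rejected(self):
        with pytest.raises(ConfigurationError):
            pcit.pcit_significance(np.eye(2))


class TestBuildNetwork:
    def _corr(self, r12):
        genes = ["a", "b", "c"]
        R = np.eye(3)
        R[0, 1] = R[1, 0] = r12
        return pd.DataFrame(R, index=genes, columns=genes)

    def test_strong_anchored_edge_retained(self):
        mask = np.ones((3, 3), bool)
        edges = pcit.build_network(self._corr(0.99), mask, ["a"], n_samples=5)
        assert len(edges) == 1
        assert edges.loc[0, "p"] == pytest.approx(0.0013, abs=3e-4)

    def test_below_rmin_dropped(self):
        edges = pcit.build_network(self._corr(0.8), np.ones((3, 3), bool), ["a"], n_samples=5)
        assert len(edges) == 0

    def test_non_anchor_pair_dropped(self):
        edges = pcit.build_network(self._corr(0.99), np.ones((3, 3), bool), ["c"], n_samples=5)
        assert len(edges) == 0

    def test_retention_monotone_in_rmin(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 6))
        X[:10] += 3 * rng.standard_normal((1, 6))
        genes = [f"g{i}" for i in range(20)]
        R = pd.DataFrame(np.corrcoef(X), index=genes, columns=genes)
        mask = pcit.pcit_significance(R.to_numpy())
        sizes = [len(pcit.build_network(R, mask, genes, 6, r_min=r)) for r in (0.5, 0.7, 0.9, 0.99)]
        assert sizes == sorted(sizes, reverse=True)

    def test_bad_rmin_rejected(self):
        with pytest.raises(ConfigurationError):
            pcit.build_network(self._corr(0.9), np.ones((3, 3), bool), ["a"], 5, r_min=1.5)

    def test_planted_modules_recovered_with_few_cross_edges(self):
        cfg = SimConfig(
            n_genes=120, n_tfs=4, n_modules=4, module_size=15, rho_within=0.98,
            rewired_fraction=0.0, de_fraction=0.0, n_per_group=20, nb_dispersion=0.05, seed=7,
        )
        cm, truth = simulate_counts(cfg)
        expr = preprocess.normalize(preprocess.filter_low_expression(cm))
        corr, valid = pcit.correlation_matrix(expr, "control")
        mask = pcit.pcit_significance(corr.to_numpy(), valid)
        edges = pcit.build_network(corr, mask, list(expr.values.index), 20)
        module_of = {g: truth.module_map.get(g) for g in expr.values.index}
        cross = sum(
            1 for a, b in zip(edges["gene_a"], edges["gene_b"])
            if module_of[a] != module_of[b] or module_of[a] is None
        )
        assert len(edges) > 0
        assert cross / max(len(edges), 1) < 0.01
        # surviving strong within-module pairs pass the full filter chain
        for _, row in edges.iterrows():
            assert abs(row["r"]) >= 0.95 and row["p"] < 0.05


class TestHubs:
    def test_equal_degrees_yield_no_hubs(self):
        edges = pd.DataFrame({"gene_a": ["a", "b", "c"], "gene_b": ["b", "c", "a"]})  # triangle
        report = pcit.hub_genes(edges)
        assert not report["is_hub"].any()

    def test_single_outlier_cannot_exceed_mean_plus_2sd_at_n5(self):
        # degrees [1,1,1,1,10]: mean 2.8, sample SD ~4.02, threshold ~10.85
        degrees = np.array([1, 1, 1, 1, 10])
        thresh = degrees.mean() + 2 * degrees.std(ddof=1)
        assert thresh == pytest.approx(10.85, abs=0.01)
        assert not (degrees > thresh).any()
        degrees = np.array([1, 1, 1, 1, 20])
        thresh = degrees.mean() + 2 * degrees.std(ddof=1)
        assert thresh == pytest.approx(21.79, abs=0.01)
        assert not (degrees > thresh).any()

    def test_star_center_is_unique_hub(self):
        edges = pd.DataFrame({"gene_a": ["hub"] * 50, "gene_b": [f"leaf{i}" for i in range(50)]})
        report = pcit.hub_genes(edges)
        assert list(report.index[report["is_hub"]]) == ["hub"]

    def test_empty_network_rejected(self):
        with pytest.raises(ConfigurationError):
            pcit.hub_genes(pd.DataFrame({"gene_a": [], "gene_b": []}))


class TestScaleFree:
    def test_exact_power_law_fits_perfectly(self):
        ks = 2.0 ** np.arange(10)
        counts = (2.0**18 / ks**2).astype(int)
        degrees = np.repeat(ks, counts)
        assert pcit.scale_free_r2(degrees) == pytest.approx(1.0, abs=1e-9)

    def test_erdos_renyi_fits_poorly(self):
        import networkx as nx

        g = nx.gnp_random_graph(500, 0.05, seed=4)
        degrees = np.array([d for _, d in g.degree()])
        assert pcit.scale_free_r2(degrees) < 0.9

    def test_degenerate_input_returns_nan(self):
        assert np.isnan(pcit.scale_free_r2(np.array([3, 3, 3, 3])))
        assert np.isnan(pcit.scale_free_r2(np.array([])))
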