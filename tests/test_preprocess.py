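import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from asmnet import preprocess
from asmnet.containers import ConfigurationError, CountMatrix
from asmnet.simdata import SimConfig, simulate_counts

from conftest import make_expression


def _cm(columns: dict, conditions: list[str]) -> CountMatrix:
    counts = pd.DataFrame(columns)
    counts.index = [f"g{i}" for i in range(len(counts))]
    samples = pd.DataFrame({"condition": conditions}, index=pd.Index(counts.columns, name="sample_id"))
    return CountMatrix(counts=counts, samples=samples)


class TestCpm:
    def test_single_column_ratios(self):
        cm = _cm({"s1": [1, 0, 3], "s2": [1, 1, 2]}, ["case", "control"])
        c = preprocess.cpm(cm)
        assert list(c["s1"]) == [250000, 0, 750000]

    def test_uniform_counts(self):
        cm = _cm({"s1": [7] * 10, "s2": [3] * 10}, ["case", "control"])
        assert (preprocess.cpm(cm) == 100000).all().all()

    def test_hand_computed_two_columns(self):
        cm = _cm({"s1": [5, 0, 5], "s2": [10, 0, 10]}, ["case", "control"])
        expected = np.array([[500000, 500000], [0, 0], [500000, 500000]], float)
        np.testing.assert_allclose(preprocess.cpm(cm).to_numpy(), expected)

    def test_columns_sum_to_one_million(self, toy_counts):
        np.testing.assert_allclose(preprocess.cpm(toy_counts).sum(axis=0), 1e6)

    def test_zero_library_names_sample(self):
        cm = _cm({"s1": [1, 2], "bad": [0, 0]}, ["case", "control"])
        with pytest.raises(ConfigurationError, match="bad"):
            preprocess.cpm(cm)


class TestFilter:
    def test_all_zero_gene_removed(self, toy_counts):
        kept = preprocess.filter_low_expression(toy_counts)
        assert "g1" not in kept.counts.index  # the all-zero gene

    def test_boundary_gene_kept_at_half_the_samples(self):
        # gene 0 has CPM >= 0.5 in exactly 2 of 4 samples
        cm = _cm(
            {"s1": [1, 10**6 - 1], "s2": [1, 10**6 - 1], "s3": [0, 10**6], "s4": [0, 10**6]},
            ["control", "control", "case", "case"],
        )
        c = preprocess.cpm(cm)
        assert (c.loc["g0"] >= 0.5).sum() == 2
        kept = preprocess.filter_low_expression(cm, 0.5, 0.5)
        assert "g0" in kept.counts.index
        # strict boundary flips the call: CPM == 1.0 > 0.5 still true, so craft exact 0.5
        cm2 = _cm({"s1": [1, 2 * 10**6 - 1], "s2": [1, 2 * 10**6 - 1], "s3": [0, 1], "s4": [0, 1]},
                  ["control", "control", "case", "case"])
        assert preprocess.cpm(cm2).loc["g0", "s1"] == 0.5
        assert "g0" in preprocess.filter_low_expression(cm2).counts.index
        assert "g0" not in preprocess.filter_low_expression(cm2, strict_boundary=True).counts.index

    def test_kept_set_matches_brute_force_rule(self, toy_counts):
        c = preprocess.cpm(toy_counts)
        expected = [g for g in c.index if (c.loc[g] >= 0.5).sum() >= 0.5 * c.shape[1]]
        kept = preprocess.filter_low_expression(toy_counts)
        assert list(kept.counts.index) == expected

    def test_filter_is_idempotent(self, toy_counts):
        once = preprocess.filter_low_expression(toy_counts)
        twice = preprocess.filter_low_expression(once)
        pd.testing.assert_frame_equal(once.counts, twice.counts)


class TestNormalize:
    def test_zero_count_gives_log2_prior(self):
        cm = _cm({"s1": [0, 10], "s2": [5, 5]}, ["case", "control"])
        expr = preprocess.normalize(cm)
        assert expr.values.loc["g0", "s1"] == pytest.approx(np.log2(0.5))

    def test_scale_invariance_of_doubling(self, toy_counts):
        doubled = CountMatrix(counts=toy_counts.counts * 2, samples=toy_counts.samples)
        pd.testing.assert_frame_equal(
            preprocess.normalize(toy_counts).values, preprocess.normalize(doubled).values
        )

    def test_toy_column_values(self):
        cm = _cm({"s1": [99, 1], "s2": [1, 1]}, ["case", "control"])
        expr = preprocess.normalize(cm)
        assert expr.values.loc["g0", "s1"] == pytest.approx(np.log2(990000.5))
        assert expr.values.loc["g1", "s1"] == pytest.approx(np.log2(10000.5))


class TestBenjaminiHochberg:
    def test_hand_stepup(self):
        np.testing.assert_allclose(preprocess.benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(preprocess.benjamini_hochberg([0.3]), [0.3])

    def test_all_ones_clip(self):
        np.testing.assert_allclose(preprocess.benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_nan_rejected(self):
        with pytest.raises(ConfigurationError):
            preprocess.benjamini_hochberg([0.1, np.nan])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=30), st.randoms())
    def test_permutation_invariance(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        adj = preprocess.benjamini_hochberg(pvals)
        adj_perm = preprocess.benjamini_hochberg([pvals[i] for i in perm])
        np.testing.assert_allclose([adj[i] for i in perm], adj_perm)

    def test_padj_dominates_pvalue(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        assert (preprocess.benjamini_hochberg(p) >= p - 1e-12).all()


class TestDifferentialExpression:
    def test_no_signal_gene_gets_p_one(self):
        vals = np.array([[1.0, 1.0, 1.0, 1.0, 1.0, 1.0]])
        expr = make_expression(vals[:, :3], vals[:, 3:])
        de = preprocess.differential_expression(expr, use_covariates=False)
        assert de["log2FC"].iloc[0] == pytest.approx(0.0)
        assert de["pvalue"].iloc[0] == 1.0

    def test_planted_de_recovered(self):
        cfg = SimConfig(
            n_genes=400, n_modules=0, n_per_group=20, de_fraction=0.05, lfc_magnitude=3.0, seed=21
        )
        cm, truth = simulate_counts(cfg)
        expr = preprocess.normalize(preprocess.filter_low_expression(cm))
        de = preprocess.differential_expression(expr)
        called = set(preprocess.deg_ids(de, 0.1))
        planted = set(truth.de_genes) & set(de.index)
        assert len(planted & called) / len(planted) >= 0.9
        # and the calls carry the planted signs
        for g in planted & called:
            assert np.sign(de.loc[g, "log2FC"]) == truth.de_genes[g]

    def test_status_consistent_with_padj_and_sign(self):
        cfg = SimConfig(n_genes=200, n_modules=0, n_per_group=10, de_fraction=0.2, seed=4)
        cm, _ = simulate_counts(cfg)
        de = preprocess.differential_expression(preprocess.normalize(cm), alpha_de=0.1)
        up = (de["padj"] <= 0.1) & (de["log2FC"] > 0)
        down = (de["padj"] <= 0.1) & (de["log2FC"] < 0)
        assert (de.loc[up, "status"] == "up").all()
        assert (de.loc[down, "status"] == "down").all()
        assert (de.loc[~(up | down), "status"] == "ns").all()

    def test_collinear_covariate_reported(self):
        rng = np.random.default_rng(0)
        expr = make_expression(rng.normal(size=(5, 4)), rng.normal(size=(5, 4)))
        expr.samples["age"] = 40.0  # constant after centering -> collinear with intercept
        with pytest.raises(ConfigurationError, match="age"):
            preprocess.differential_expression(expr, use_covariates=True)

    def test_null_call_rate_controlled(self):
        fracs = []
        for seed in range(5):
            cfg = SimConfig(n_genes=500, n_modules=0, n_per_group=10, de_fraction=0.0, seed=seed)
            cm, _ = simulate_counts(cfg)
            de = preprocess.differential_expression(preprocess.normalize(cm), use_covariates=False)
            fracs.append((de["padj"] <= 0.1).mean())
        assert np.mean(fracs) <= 0.1
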