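import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import jensenshannon
from scipy.stats import spearmanr

from capnorm.core import ParameterError, ValidationError, log_transform
from capnorm.diagnostics import (anova_batch_count, ari_separation,
                                 canonical_correlations, gene_batch_spearman,
                                 jensen_shannon_distance, pc_covariate_r2,
                                 radar_baseline, ruvg_baseline,
                                 vector_correlation)
from capnorm.evaluation import expression_pcs
from capnorm.normalization import Procedure, apply_procedure

from .conftest import make_toy_dataset


class TestPcCovariateR2:
    def test_covariate_equal_to_pc1_sign(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 10))
        X[:, 5:] += 8.0  # dominant direction
        labels = ["lo"] * 5 + ["hi"] * 5
        tab = pc_covariate_r2(pd.DataFrame(X), labels, k_max=3)
        assert tab["r2"].iloc[0] > 0.99

    def test_permutation_null_mean(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 13))
        r2s = []
        for _ in range(100):
            labels = rng.permutation(["a"] * 7 + ["b"] * 6)
            r2s.append(pc_covariate_r2(X, labels, k_max=1)["r2"].iloc[0])
        assert np.mean(r2s) == pytest.approx(1 / 12, abs=0.03)

    def test_matches_explicit_least_squares(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 6))
        labels = ["a", "a", "b", "b", "c", "c"]
        tab = pc_covariate_r2(X, labels, k_max=2)
        pcs = expression_pcs(X, 2)
        ind = np.column_stack([(np.array(labels) == l).astype(float)
                               for l in ("a", "b")])
        for k in (1, 2):
            Xd = np.column_stack([np.ones(6), pcs[:, :k]])
            sst = sse = 0.0
            for col in ind.T:
                coef, *_ = np.linalg.lstsq(Xd, col, rcond=None)
                sse += ((col - Xd @ coef) ** 2).sum()
                sst += ((col - col.mean()) ** 2).sum()
            assert tab["r2"].iloc[k - 1] == pytest.approx(1 - sse / sst,
                                                          abs=1e-10)

    def test_non_decreasing_in_k(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 9))
        labels = ["a", "b", "c"] * 3
        r2 = pc_covariate_r2(X, labels, k_max=6)["r2"]
        assert (np.diff(r2) >= -1e-12).all()

    def test_constant_covariate_rejected(self):
        with pytest.raises(ParameterError):
            pc_covariate_r2(np.random.default_rng(0).normal(size=(20, 5)),
                            ["a"] * 5, k_max=2)


class TestAnova:
    def test_saturated_batch_effect(self):
        rng = np.random.default_rng(4)
        batch = np.array(["b1"] * 4 + ["b2"] * 4)
        X = rng.normal(size=(100, 8))
        X[:, batch == "b2"] += 10.0
        assert anova_batch_count(X, batch) == 100

    def test_constant_gene_excluded(self):
        batch = np.array(["b1"] * 3 + ["b2"] * 3)
        X = np.vstack([np.ones(6), np.random.default_rng(5).normal(size=(4, 6))])
        count = anova_batch_count(X, batch)
        assert 0 <= count <= 4

    def test_degenerate_batches_rejected(self):
        with pytest.raises(ParameterError):
            anova_batch_count(np.zeros((5, 3)), np.array(["a", "a", "b"]))


class TestSpearman:
    def test_monotone_gene(self):
        # gene values share the batch's tie pattern: perfect rank agreement
        X = np.repeat([1.0, 2.0, 3.0], 2)[None, :]
        out = gene_batch_spearman(X, [1, 1, 2, 2, 3, 3])
        assert out["rho"].iloc[0] == pytest.approx(1.0)

    def test_constant_gene_flagged_zero(self):
        out = gene_batch_spearman(np.ones((1, 6)), [1, 1, 2, 2, 3, 3])
        assert out["rho"].iloc[0] == 0.0
        assert bool(out["constant"].iloc[0])

    def test_matches_scipy(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 6))
        batch = [1, 1, 2, 2, 3, 3]
        out = gene_batch_spearman(X, batch)
        for i in range(10):
            assert out["rho"].iloc[i] == pytest.approx(
                spearmanr(X[i], batch).statistic, abs=1e-12)


class TestVectorCorrelation:
    def test_covariate_equal_to_pc_gives_one(self):
        rng = np.random.default_rng(7)
        pcs = rng.normal(size=(12, 3))
        assert vector_correlation(pcs, pcs[:, :1]) == pytest.approx(1.0)

    def test_orthogonal_covariate_gives_zero(self):
        pcs = np.array([[1.0], [-1.0], [1.0], [-1.0]])
        cov = np.array([[1.0], [1.0], [-1.0], [-1.0]])
        assert vector_correlation(pcs, cov) == pytest.approx(0.0, abs=1e-12)

    def test_matches_explicit_eigen_computation(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 2))
        Y = rng.normal(size=(10, 2))
        Xc = X - X.mean(0)
        Yc = Y - Y.mean(0)
        # canonical correlations via the eigenvalues of
        # Sxx^-1 Sxy Syy^-1 Syx
        Sxx, Syy = Xc.T @ Xc, Yc.T @ Yc
        Sxy = Xc.T @ Yc
        M = np.linalg.solve(Sxx, Sxy) @ np.linalg.solve(Syy, Sxy.T)
        rho2 = np.sort(np.linalg.eigvals(M).real)[::-1]
        expected = 1 - np.prod(1 - np.clip(rho2, 0, 1))
        assert vector_correlation(X, Y) == pytest.approx(expected, abs=1e-10)

    def test_rank_zero_rejected(self):
        with pytest.raises(ParameterError):
            vector_correlation(np.ones((5, 1)), np.random.default_rng(0).normal(size=(5, 1)))


class TestAri:
    def test_perfect_separation(self):
        rng = np.random.default_rng(9)
        vals = pd.DataFrame(rng.normal(size=(80, 8)))
        vals.iloc[:, 4:] += 15.0
        labels = np.array(["input"] * 4 + ["enrichment"] * 4)
        assert ari_separation(vals, labels) == pytest.approx(1.0)

    def test_permuted_labels_mean_near_zero(self):
        rng = np.random.default_rng(10)
        vals = pd.DataFrame(rng.normal(size=(80, 12)))
        aris = []
        for _ in range(100):
            labels = rng.permutation(["input"] * 6 + ["enrichment"] * 6)
            aris.append(ari_separation(vals, labels))
        assert abs(np.mean(aris)) < 0.1

    def test_matches_contingency_formula(self):
        from scipy.special import comb
        rng = np.random.default_rng(11)
        vals = pd.DataFrame(rng.normal(size=(40, 8)))
        labels = np.array(["input", "enrichment"] * 4)
        from capnorm.evaluation import pam_cluster
        clusters = pam_cluster(expression_pcs(vals, 3), 2)
        # brute-force ARI from the contingency table
        cats = pd.crosstab(labels, clusters).to_numpy()
        n = cats.sum()
        sum_comb = comb(cats, 2).sum()
        a = comb(cats.sum(axis=1), 2).sum()
        b = comb(cats.sum(axis=0), 2).sum()
        expected_idx = a * b / comb(n, 2)
        max_idx = (a + b) / 2
        ari = (sum_comb - expected_idx) / (max_idx - expected_idx)
        assert ari_separation(vals, labels) == pytest.approx(ari, abs=1e-10)


class TestJsd:
    def test_identical_profiles_zero(self):
        P = np.tile([0.2, 0.3, 0.5], (3, 1))
        np.testing.assert_allclose(jensen_shannon_distance(P), 0.0, atol=1e-12)

    def test_hand_computed_value(self):
        # centroid of {(1,0), (0,0.5,...)}: P=(1,0), Q=(0.5,0.5)
        P = np.array([[1.0, 0.0], [0.5, 0.5]])
        pc = P.mean(axis=0)

        def H(q):
            q = q[q > 0]
            return -(q * np.log2(q)).sum()

        jsd_p = H((pc + P[0]) / 2) - (H(pc) + H(P[0])) / 2
        d = jensen_shannon_distance(P)
        assert d[0] == pytest.approx(np.sqrt(jsd_p), abs=1e-10)
        # direct divergence of the disjoint-ish pair via scipy cross-check
        np.testing.assert_allclose(
            d, [jensenshannon(row, pc, base=2) for row in P], atol=1e-10)

    def test_known_pair_value(self):
        # JSD((1,0),(0.5,0.5)) = 0.311278..., distance 0.557923...
        assert jensenshannon([1.0, 0.0], [0.5, 0.5], base=2) == pytest.approx(
            0.55792, abs=1e-5)
        P = np.array([[1.0, 0.0], [0.0, 1.0]])
        # disjoint supports: distance of each sample to the uniform centroid
        d = jensen_shannon_distance(P)
        assert np.allclose(d, d[::-1])  # symmetric configuration
        assert (d <= 1.0 + 1e-12).all() and (d >= 0).all()

    def test_maximal_divergence_disjoint(self):
        assert jensenshannon([1, 0], [0, 1], base=2) == pytest.approx(1.0)

    def test_zero_profile_rejected(self):
        with pytest.raises(ValidationError):
            jensen_shannon_distance(np.array([[0.0, 0.0], [1.0, 1.0]]))

    def test_modification_profiles_nonnegative(self, sim_default,
                                               gene_sets_default):
        from capnorm.diagnostics import modification_profiles
        from capnorm.enrichment import modification_levels
        from capnorm.normalization import Procedure, apply_procedure
        ds, _ = sim_default
        nm = apply_procedure(ds, Procedure("TC", "RUVse", 2),
                             gene_sets_default)
        mod = modification_levels(nm, ds.samples)
        prof = modification_profiles(mod)
        assert prof.shape == (mod.shape[1], mod.shape[0])
        assert (prof.to_numpy() >= 0).all()
        d = jensen_shannon_distance(prof)
        assert ((0 <= d) & (d <= 1)).all()


class TestBaselines:
    def test_radar_constant_fold_gives_equal_factors(self):
        rng = np.random.default_rng(12)
        base = rng.poisson(100, size=(100, 2)) + 1
        counts = np.column_stack([base[:, 0], base[:, 0],
                                  base[:, 1], base[:, 1]])
        ds = make_toy_dataset(counts[:, [0, 1, 2, 3]])
        out = radar_baseline(ds)
        ff = out.provenance["enrichment_fold_factors"]
        vals = np.array(list(ff.values()))
        # enrichment equals input in each pair: all fold factors equal 1
        np.testing.assert_allclose(vals, 1.0, rtol=1e-9)

    def test_radar_recovers_planted_threefold(self):
        rng = np.random.default_rng(13)
        inp = rng.poisson(200, size=100) + 1
        en = np.round(inp * 3.0).astype(int)
        counts = np.column_stack([inp, en, inp, en])
        ds = make_toy_dataset(counts)
        out = radar_baseline(ds, top_fraction=0.1)
        ff = list(out.provenance["enrichment_fold_factors"].values())
        assert np.mean(ff) == pytest.approx(3.0, rel=0.05)

    def test_radar_unpaired_rejected(self):
        ds = make_toy_dataset(np.ones((5, 4), dtype=int) * 10)
        broken_samples = ds.samples.copy()
        import capnorm.diagnostics as diag
        ds2 = ds.subset_samples(list(ds.samples.index))
        ds2.samples = broken_samples
        ds2.samples.loc[ds2.samples.index[1], "assay"] = "input"
        with pytest.raises(Exception):
            diag.radar_baseline(ds2)

    def test_ruvg_baseline_compositional_identity(self, sim_default,
                                                  gene_sets_default):
        ds, _ = sim_default
        a = ruvg_baseline(ds, gene_sets_default, k=4)
        b = apply_procedure(ds, Procedure("none", "RUVg", 4),
                            gene_sets_default)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_ruvg_k0_identity(self, sim_default, gene_sets_default):
        ds, _ = sim_default
        out = ruvg_baseline(ds, gene_sets_default, k=0)
        pd.testing.assert_frame_equal(out.values, log_transform(ds.counts))
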