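"""Genetic PCA, chance baselines and PC-GWAS synthesis."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from genomicpca.errors import InputError
from genomicpca.ldsc import GeneticCorrMatrix
from genomicpca.pca import (NetworkDefinition, eigen_pca, genomic_pca,
                            parallel_analysis, random_grouping_null,
                            read_networks, synthesize_pc_sumstats)

from conftest import build_table


def _gcm(r, labels=None, se=None, cti=None):
    k = r.shape[0]
    labels = labels or [f"t{i+1}" for i in range(k)]
    return GeneticCorrMatrix(
        labels=labels, r_g=r,
        se=np.zeros((k, k)) if se is None else se,
        cti=np.eye(k) if cti is None else cti,
        min_eigen_raw=float(np.linalg.eigvalsh(r).min()))


class TestEigenPca:
    def test_two_by_two_closed_form(self):
        m = _gcm(np.array([[1.0, 0.5], [0.5, 1.0]]))
        res = genomic_pca(m)
        np.testing.assert_allclose(res.eigenvalues, [1.5, 0.5], atol=1e-12)
        assert res.r2[0] == pytest.approx(0.75)
        np.testing.assert_allclose(res.pc1_loadings(),
                                   np.sqrt(0.75), atol=1e-12)

    def test_identity_matrix_uniform_r2(self):
        res = genomic_pca(_gcm(np.eye(4)))
        np.testing.assert_allclose(res.r2, 0.25, atol=1e-12)
        np.testing.assert_allclose(res.eigenvalues, 1.0, atol=1e-12)

    def test_matches_dense_eigensolver_oracle(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((5, 9))
        corr = np.corrcoef(a)
        res = genomic_pca(_gcm(corr))
        # invariants: eigenvalue sum = p, per-trait loading norms = 1
        assert res.eigenvalues.sum() == pytest.approx(5.0, abs=1e-8)
        np.testing.assert_allclose((res.loadings ** 2).sum(axis=1), 1.0,
                                   atol=1e-8)
        # oracle comparison up to sign
        vals, vecs = np.linalg.eigh(corr)
        for c in range(5):
            lam = vals[::-1][c]
            v = vecs[:, ::-1][:, c] * np.sqrt(lam)
            got = res.loadings[:, c]
            assert (np.allclose(got, v, atol=1e-8)
                    or np.allclose(got, -v, atol=1e-8))
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert np.all(res.loadings.mean(axis=0) >= -1e-12)

    def test_subset_restriction_and_errors(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = 0.5
        m = _gcm(r, labels=["a", "b", "c"])
        res = genomic_pca(m, NetworkDefinition("net", ["a", "b"]))
        assert res.labels == ["a", "b"]
        assert res.r2[0] == pytest.approx(0.75)
        with pytest.raises(InputError):
            genomic_pca(m, NetworkDefinition("bad", ["a", "zzz"]))

    def test_non_psd_unsmoothed_input_rejected(self):
        r = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, -0.9], [0.9, -0.9, 1.0]])
        with pytest.raises(InputError, match="nearest_pd"):
            genomic_pca(_gcm(r))

    def test_trait_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal((6, 12))
        corr = np.corrcoef(a)
        labels = [f"t{i}" for i in range(6)]
        perm = [3, 0, 5, 1, 4, 2]
        res = eigen_pca(corr, labels)
        resp = eigen_pca(corr[np.ix_(perm, perm)], [labels[i] for i in perm])
        np.testing.assert_allclose(resp.eigenvalues, res.eigenvalues,
                                   atol=1e-10)
        np.testing.assert_allclose(resp.loadings, res.loadings[perm],
                                   atol=1e-10)


class TestParallelAnalysis:
    def test_zero_se_degenerate_null(self):
        r = np.array([[1.0, 0.6], [0.6, 1.0]])
        res = parallel_analysis(_gcm(r), n_draws=100, seed=1)
        np.testing.assert_allclose(res.null_p95, 1.0)
        assert res.n_retained == 1  # lambda1 = 1.6 > 1

    def test_dominant_factor_retained_against_noisy_null(self):
        p = 10
        r = np.full((p, p), 1 / 3)
        np.fill_diagonal(r, 1.0)  # lambda1 = 4
        se = np.full((p, p), 0.1)
        np.fill_diagonal(se, 0.0)
        res = parallel_analysis(_gcm(r, se=se), n_draws=500, seed=7)
        assert res.n_retained >= 1
        assert res.observed_eigenvalues[0] == pytest.approx(4.0)
        assert res.null_p95[0] < 2.0  # null concentrates near 1 + O(se*sqrt(p))

    def test_retention_monotone_in_quantile(self):
        p = 6
        rng = np.random.default_rng(2)
        a = rng.standard_normal((p, 10))
        r = np.corrcoef(a)
        se = np.full((p, p), 0.05)
        np.fill_diagonal(se, 0.0)
        m = _gcm(r, se=se)
        hi = parallel_analysis(m, n_draws=300, quantile=1.0, seed=3)
        lo = parallel_analysis(m, n_draws=300, quantile=0.95, seed=3)
        assert hi.n_retained <= lo.n_retained

    def test_deterministic_given_seed(self):
        p = 5
        se = np.full((p, p), 0.1)
        np.fill_diagonal(se, 0.0)
        m = _gcm(np.eye(p), se=se)
        a = parallel_analysis(m, n_draws=150, seed=9)
        b = parallel_analysis(m, n_draws=150, seed=9)
        np.testing.assert_array_equal(a.null_p95, b.null_p95)


class TestRandomGrouping:
    def test_full_group_gives_p_one(self):
        rng = np.random.default_rng(4)
        r = np.corrcoef(rng.standard_normal((5, 9)))
        m = _gcm(r)
        res = random_grouping_null(m, group_size=5, n_draws=100,
                                   observed=NetworkDefinition("all", m.labels),
                                   seed=0)
        assert res.p_emp == pytest.approx(1.0)

    def test_identity_matrix_null_is_exactly_half(self):
        m = _gcm(np.eye(6))
        res = random_grouping_null(m, group_size=2, n_draws=100,
                                   observed=NetworkDefinition("n", m.labels[:2]),
                                   seed=0)
        np.testing.assert_allclose(res.null_r2, 0.5)

    def test_planted_block_attains_small_p(self):
        # one tight 4-trait block inside 8 traits; only the true block
        # reaches PC1 r2 = (1 + 3*0.9)/4 = 0.925
        r = np.eye(8)
        r[np.ix_(range(4), range(4))] = 0.9
        np.fill_diagonal(r, 1.0)
        m = _gcm(r)
        obs = NetworkDefinition("block", m.labels[:4])
        res = random_grouping_null(m, group_size=4, n_draws=200, observed=obs,
                                   seed=1)
        assert res.observed_r2 == pytest.approx(0.925)
        assert res.p_emp <= 0.01


class TestSynthesis:
    def test_single_trait_identity(self):
        t = build_table(trait="a", snps=["rs1", "rs2"], a1=["A", "C"],
                        a2=["G", "T"], eaf=[0.3, 0.4], z=[1.5, -0.7],
                        n=[5_000, 6_000])
        pc = synthesize_pc_sumstats([t], [1.0], np.ones((1, 1)))
        np.testing.assert_allclose(pc.df["z_pc"], t.df["z"], atol=1e-12)
        np.testing.assert_allclose(pc.df["n_eff"], t.df["n"], atol=1e-9)

    def test_two_trait_closed_forms(self):
        t1 = build_table(trait="a", snps=["rs1"], a1=["A"], a2=["G"],
                         eaf=[0.3], z=[2.0], n=[10_000])
        t2 = build_table(trait="b", snps=["rs1"], a1=["A"], a2=["G"],
                         eaf=[0.3], z=[1.0], n=[10_000])
        pc = synthesize_pc_sumstats([t1, t2], [1.0, 1.0], np.eye(2))
        assert pc.df.loc[0, "z_pc"] == pytest.approx(3 / np.sqrt(2))

        cti = np.array([[1.0, 0.5], [0.5, 1.0]])
        pc2 = synthesize_pc_sumstats([t1, t2], [0.8, 0.6], cti)
        assert pc2.denom == pytest.approx(np.sqrt(1.48))
        assert pc2.df.loc[0, "z_pc"] == pytest.approx(2.2 / np.sqrt(1.48),
                                                      abs=1e-4)
        assert pc2.df.loc[0, "n_eff"] == pytest.approx(1.4 ** 2 * 10_000
                                                       / 1.48, rel=1e-6)

    def test_beta_se_consistent_with_z(self):
        t1 = build_table(trait="a", snps=["rs1", "rs2"], a1=["A", "C"],
                         a2=["G", "T"], eaf=[0.3, 0.25], z=[2.0, 0.0],
                         n=[10_000, 10_000])
        pc = synthesize_pc_sumstats([t1], [1.0], np.ones((1, 1)))
        df = pc.df
        np.testing.assert_allclose(df["beta"] / df["se"], df["z_pc"],
                                   atol=1e-10)
        assert df.loc[1, "beta"] == 0.0
        assert df.loc[1, "se"] > 0

    @given(st.floats(min_value=0.1, max_value=50.0))
    def test_z_invariant_to_positive_loading_rescale(self, c):
        t1 = build_table(trait="a", snps=["rs1"], a1=["A"], a2=["G"],
                         eaf=[0.3], z=[2.0], n=[10_000])
        t2 = build_table(trait="b", snps=["rs1"], a1=["A"], a2=["G"],
                         eaf=[0.3], z=[1.0], n=[10_000])
        cti = np.array([[1.0, 0.3], [0.3, 1.0]])
        base = synthesize_pc_sumstats([t1, t2], [0.8, 0.6], cti)
        scaled = synthesize_pc_sumstats([t1, t2], [0.8 * c, 0.6 * c], cti)
        np.testing.assert_allclose(scaled.df["z_pc"], base.df["z_pc"],
                                   rtol=1e-10)

    def test_inconsistent_cti_rejected(self):
        t1 = build_table(trait="a", snps=["rs1"], a1=["A"], a2=["G"],
                         eaf=[0.3], z=[2.0], n=[10_000])
        t2 = build_table(trait="b", snps=["rs1"], a1=["A"], a2=["G"],
                         eaf=[0.3], z=[1.0], n=[10_000])
        cti = np.array([[1.0, -1.5], [-1.5, 1.0]])
        with pytest.raises(InputError, match="CTI"):
            synthesize_pc_sumstats([t1, t2], [1.0, 1.0], cti)

    def test_mismatched_variant_frames_rejected(self):
        t1 = build_table(trait="a", snps=["rs1"], a1=["A"], a2=["G"],
                         eaf=[0.3], z=[2.0], n=[10_000])
        t2 = build_table(trait="b", snps=["rs9"], a1=["A"], a2=["G"],
                         eaf=[0.3], z=[1.0], n=[10_000])
        with pytest.raises(InputError, match="frame"):
            synthesize_pc_sumstats([t1, t2], [1.0, 1.0], np.eye(2))


def test_read_networks_yaml(tmp_path):
    p = tmp_path / "nets.yaml"
    p.write_text("central_executive: [t1, t2, t3]\nsalience: [t2, t4]\n")
    nets = read_networks(p)
    assert [n.name for n in nets] == ["central_executive", "salience"]
    assert nets[0].members == ["t1", "t2", "t3"]
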