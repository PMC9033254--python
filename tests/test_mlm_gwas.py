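"""Mixed-model scan machinery: QC, pruning, kinship, REML, GLS tests,
effective marker number, QQ inflation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from alkagerm import mlm_gwas as mg
from alkagerm.io_formats import MISSING


def ols_pvalues(y, X, G):
    """Independent ordinary-least-squares oracle (normal equations + t-test)."""
    out = []
    for g in G:
        Z = np.column_stack([X, g])
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ beta
        df = len(y) - Z.shape[1]
        s2 = resid @ resid / df
        cov = s2 * np.linalg.inv(Z.T @ Z)
        t = beta[-1] / np.sqrt(cov[-1, -1])
        out.append(2 * stats.t.sf(abs(t), df))
    return np.array(out)


class TestFilterVariants:
    def test_boundaries_are_strict(self, variant_table_factory):
        # SNP0: missing 2/10 = 0.20 -> removed (strict <)
        # SNP1: MAF exactly 0.05 -> removed (strict >)
        # SNP2: clean -> kept
        d = np.zeros((3, 10), dtype=np.int8)
        d[0, :2] = MISSING
        d[0, 2:6] = 2
        d[1, 0] = 1  # freq 1/20 = 0.05
        d[2, :5] = 2
        vt = variant_table_factory(d)
        kept, st = mg.filter_variants(vt)
        assert kept.n_snps == 1
        assert kept.snps["snp_id"].tolist() == [vt.snps["snp_id"][2]]
        assert st.n_failed_missing == 1 and st.n_failed_maf == 1

    def test_hand_counted_panel(self, variant_table_factory):
        rng = np.random.default_rng(0)
        d = rng.choice([0, 2], size=(6, 20)).astype(np.int8)
        d[0, :5] = MISSING            # 25% missing -> fails
        d[1] = 0; d[1, 0] = 2         # MAF 0.025 -> fails
        d[2] = 2                      # monomorphic -> fails MAF
        vt = variant_table_factory(d)
        kept, st = mg.filter_variants(vt)
        assert st.n_kept == 3 and st.n_input == 6


class TestLdPrune:
    def test_duplicate_column_keeps_exactly_one(self, variant_table_factory):
        rng = np.random.default_rng(1)
        base = rng.choice([0, 2], size=30).astype(np.int8)
        vt = variant_table_factory(np.vstack([base, base]))
        kept = mg.ld_prune(vt)
        assert len(kept) == 1

    def test_independent_snps_all_kept(self, variant_table_factory):
        rng = np.random.default_rng(2)
        d = rng.choice([0, 2], size=(10, 500)).astype(np.int8)
        vt = variant_table_factory(d)
        assert len(mg.ld_prune(vt)) == 10

    def test_no_retained_pair_exceeds_r2_threshold(self, variant_table_factory):
        """Brute-force exhaustive pairwise check over the pruned window."""
        rng = np.random.default_rng(3)
        base = rng.choice([0, 2], size=200).astype(np.int8)
        rows = [base]
        for flips in (2, 5, 30, 80):  # decreasing LD with the base SNP
            row = base.copy()
            idx = rng.choice(200, flips, replace=False)
            row[idx] = 2 - row[idx]
            rows.append(row)
        vt = variant_table_factory(np.vstack(rows))
        kept = set(mg.ld_prune(vt, r2_max=0.1))
        kept_idx = [i for i, s in enumerate(vt.snps["snp_id"]) if s in kept]
        assert kept_idx
        for a in kept_idx:
            for b in kept_idx:
                if a < b:
                    r = np.corrcoef(vt.dosages[a], vt.dosages[b])[0, 1]
                    assert r * r <= 0.1 + 1e-12


class TestKinship:
    def test_extremes(self, variant_table_factory):
        d = np.array([[0, 0, 2], [2, 2, 0], [0, 0, 2]], dtype=np.int8)
        K = mg.ibs_kinship(variant_table_factory(d))
        assert K[0, 1] == pytest.approx(1.0)   # identical accessions
        assert K[0, 2] == pytest.approx(0.0)   # opposite homozygotes
        assert np.allclose(np.diag(K), 1.0)

    def test_hand_arithmetic(self, variant_table_factory):
        # pairs (0,2),(2,2),(0,0): scores 0, 1, 1 -> 2/3
        d = np.array([[0, 2], [2, 2], [0, 0]], dtype=np.int8)
        K = mg.ibs_kinship(variant_table_factory(d))
        assert K[0, 1] == pytest.approx(2 / 3)

    def test_symmetry_and_range(self, small_dataset):
        vt = small_dataset.variants.take_snps(np.arange(800))
        K = mg.ibs_kinship(vt)
        assert np.allclose(K, K.T)
        assert K.min() >= 0.0 and K.max() <= 1.0 + 1e-12


class TestPcaCovariates:
    def test_pc1_separates_subpopulations(self, small_dataset):
        vt = small_dataset.variants.take_snps(np.arange(1500))
        K = mg.ibs_kinship(vt)
        pcs = mg.pca_covariates(K, 3)
        labels = (small_dataset.metadata["subpopulation"] == "Xian").to_numpy(float)
        r = np.corrcoef(pcs[:, 0], labels)[0, 1]
        assert abs(r) > 0.9

    def test_deterministic_signs(self, small_dataset):
        vt = small_dataset.variants.take_snps(np.arange(500))
        K = mg.ibs_kinship(vt)
        p1, p2 = mg.pca_covariates(K), mg.pca_covariates(K)
        assert np.array_equal(p1, p2)
        assert all(p1[np.argmax(np.abs(p1[:, j])), j] > 0 for j in range(3))


def simulate_mixed_trait(K, h2, rng):
    """y with genetic covariance h2*K + (1-h2)*I (Cholesky construction)."""
    n = K.shape[0]
    jitter = 1e-8 * np.eye(n)
    L = np.linalg.cholesky(h2 * K + (1 - h2) * np.eye(n) + jitter)
    return L @ rng.normal(size=n)


@pytest.fixture(scope="module")
def block_kinship(variant_table_factory):
    rng = np.random.default_rng(7)
    d = rng.choice([0, 2], size=(400, 200), p=[0.5, 0.5]).astype(np.int8)
    # add relatedness: 20 families of 10 sharing most genotypes
    for f in range(20):
        proto = d[:, 10 * f]
        for c in range(10 * f + 1, 10 * f + 10):
            keep = rng.random(400) < 0.8
            d[keep, c] = proto[keep]
    return mg.ibs_kinship(variant_table_factory(d))


class TestRemlFit:
    def test_h2_recovery(self, block_kinship):
        rng = np.random.default_rng(21)
        X = np.ones((200, 1))
        ests = []
        for _ in range(20):
            y = simulate_mixed_trait(block_kinship, 0.5, rng)
            ests.append(mg.reml_fit(y, X, block_kinship).h2)
        assert 0.35 <= float(np.mean(ests)) <= 0.65

    def test_pure_noise_gives_low_h2(self, block_kinship):
        rng = np.random.default_rng(22)
        X = np.ones((200, 1))
        ests = [
            mg.reml_fit(rng.normal(size=200), X, block_kinship).h2
            for _ in range(10)
        ]
        assert float(np.mean(ests)) <= 0.15

    def test_optimum_dominates_grid(self, block_kinship):
        rng = np.random.default_rng(23)
        y = simulate_mixed_trait(block_kinship, 0.4, rng)
        X = np.ones((200, 1))
        vc = mg.reml_fit(y, X, block_kinship)
        # recompute the profiled restricted likelihood on the grid
        from alkagerm.mlm_gwas import _restricted_loglik

        n, q = 200, 1
        Q, _ = np.linalg.qr(X)
        S = np.eye(n) - Q @ Q.T
        M = S @ block_kinship @ S
        vals, vecs = np.linalg.eigh(M)
        order = np.argsort(vals)[::-1][: n - q]
        lam = np.clip(vals[order], 0, None)
        eta2 = (vecs[:, order].T @ y) ** 2
        for p in np.linspace(-10, 10, 121):
            assert vc.reml_loglik >= _restricted_loglik(p, lam, eta2) - 1e-9


class TestAssociationScan:
    def test_identity_kinship_equals_ols(self, variant_table_factory):
        rng = np.random.default_rng(31)
        n, m = 120, 300
        d = rng.choice([0, 2], size=(m, n), p=[0.6, 0.4]).astype(np.int8)
        vt = variant_table_factory(d)
        y = rng.normal(size=n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        K = np.eye(n)
        vc = mg.reml_fit(y, X, K)
        res = mg.association_scan(vt, y, X, K, vc)
        expected = ols_pvalues(y, X, d.astype(float))
        assert np.allclose(res["p"].to_numpy(), expected, atol=1e-8)

    def test_invariant_to_ordering_and_shift(self, variant_table_factory):
        rng = np.random.default_rng(32)
        n, m = 80, 60
        d = rng.choice([0, 2], size=(m, n)).astype(np.int8)
        vt = variant_table_factory(d)
        K = mg.ibs_kinship(vt)
        y = rng.normal(size=n)
        X = np.ones((n, 1))
        vc = mg.reml_fit(y, X, K)
        base = mg.association_scan(vt, y, X, K, vc)
        shifted = mg.association_scan(vt, y + 17.0, X, K, vc)
        assert np.allclose(base["p"], shifted["p"], atol=1e-10)

        perm = rng.permutation(n)
        vt_p = vt.take_samples([vt.samples[i] for i in perm])
        res_p = mg.association_scan(vt_p, y[perm], X[perm], K[np.ix_(perm, perm)], vc)
        assert np.allclose(base["p"], res_p["p"], atol=1e-8)

    def test_large_delta_converges_to_ols(self, variant_table_factory):
        rng = np.random.default_rng(33)
        n, m = 100, 50
        d = rng.choice([0, 2], size=(m, n)).astype(np.int8)
        vt = variant_table_factory(d)
        K = mg.ibs_kinship(vt)
        y = rng.normal(size=n)
        X = np.ones((n, 1))
        vc = mg.VarianceComponents(1.0, 1e8, 1e8, 1e-8, 0.0)
        res = mg.association_scan(vt, y, X, K, vc)
        expected = ols_pvalues(y, X, d.astype(float))
        assert np.allclose(res["p"], expected, atol=1e-5)

    def test_monomorphic_snps_skipped(self, variant_table_factory):
        d = np.array([[0, 0, 0, 0], [0, 2, 0, 2]], dtype=np.int8)
        vt = variant_table_factory(d)
        y = np.array([0.1, 0.2, -0.1, 0.3])
        X = np.ones((4, 1))
        vc = mg.VarianceComponents(0.5, 0.5, 1.0, 0.5, 0.0)
        res = mg.association_scan(vt, y, X, np.eye(4), vc)
        assert len(res) == 1


class TestEffectiveMarkers:
    def test_independent_snps_nearly_all_count(self, variant_table_factory):
        rng = np.random.default_rng(41)
        m = 400
        d = rng.choice([0, 2], size=(m, 500)).astype(np.int8)
        vt = variant_table_factory(d)
        n_eff = mg.effective_marker_number(vt)
        assert n_eff >= 0.9 * m
        assert n_eff <= m

    def test_duplicated_snps_halve_the_count(self, variant_table_factory):
        rng = np.random.default_rng(42)
        base = rng.choice([0, 2], size=(100, 400)).astype(np.int8)
        dup = np.repeat(base, 2, axis=0)  # every SNP duplicated, adjacent
        vt = variant_table_factory(dup)
        n_eff = mg.effective_marker_number(vt)
        assert abs(n_eff - 100) <= 10  # ~M/2 within window-edge effects

    def test_threshold_arithmetic(self):
        assert mg.significance_threshold(500_000) == pytest.approx(2.0e-6)
        assert mg.significance_threshold(1) == 1.0
        # the printed whole-panel threshold corresponds to N ~ 465,116
        assert mg.significance_threshold(465_116) == pytest.approx(2.15e-6, rel=1e-3)


class TestQQLambda:
    def test_uniform_pvalues_lambda_near_one(self):
        rng = np.random.default_rng(51)
        p = rng.uniform(size=10_000)
        lam, table = mg.qq_lambda(p)
        assert 0.9 <= lam <= 1.1
        assert len(table) == 10_000

    def test_halving_p_increases_lambda(self):
        rng = np.random.default_rng(52)
        p = rng.uniform(size=5_000)
        lam1, _ = mg.qq_lambda(p)
        lam2, _ = mg.qq_lambda(p / 2)
        assert lam2 > lam1
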