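"""PCA-outlier and latent-factor ridge scans, scree rule, imputation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adaptscape.genotypes import GenotypeMatrix
from adaptscape.scans import (choose_k_scree, lfmm_impute, lfmm_ridge_scan,
                              ogk_location_scatter, pca_outlier_scan,
                              storey_qvalues)


class TestChooseKScree:
    def test_single_dominant_component(self):
        ev = [10.0, 1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.45, 0.4, 0.35]
        assert choose_k_scree(ev) == 1

    def test_two_dominant_components(self):
        ev = [10.0, 9.0, 1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.45, 0.4]
        assert choose_k_scree(ev) == 2

    def test_flat_spectrum_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="flat"):
            assert choose_k_scree([2.0] * 10) == 1

    def test_increasing_spectrum_rejected(self):
        with pytest.raises(ValueError):
            choose_k_scree([1.0, 2.0, 3.0])


def test_storey_qvalues_properties():
    rng = np.random.default_rng(0)
    p = rng.uniform(size=500)
    q = storey_qvalues(p)
    assert ((q >= 0) & (q <= 1)).all()
    # q preserves the p-value ordering
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


def _geno(counts, pops=None):
    counts = np.asarray(counts, dtype=np.int16)
    n, m = counts.shape
    samples = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "population": pops if pops is not None else ["A"] * n,
        "lon": 0.0, "lat": 0.0})
    loci = pd.DataFrame({"locus_id": [f"L{j}" for j in range(m)],
                         "fragment_id": [f"f{j}" for j in range(m)],
                         "reproducibility": 1.0})
    return GenotypeMatrix(counts=counts, samples=samples, loci=loci)


class TestPcaOutlierScan:
    def test_duplicated_locus_gets_identical_statistics(self, sim_species):
        g = sim_species["genotypes"].subset_loci(np.arange(100))
        src_id = g.loci["locus_id"].iloc[5]
        counts = np.column_stack([g.counts, g.counts[:, 5]])
        loci = pd.concat([g.loci, pd.DataFrame({
            "locus_id": ["dup"], "fragment_id": ["fdup"],
            "reproducibility": [1.0]})], ignore_index=True)
        g2 = GenotypeMatrix(counts=counts.astype(np.int16),
                            samples=g.samples, loci=loci)
        res = pca_outlier_scan(g2, K=2, seed=0)
        t = res.table.set_index("locus_id")
        for col in ("statistic", "p", "q"):
            assert t.loc["dup", col] == pytest.approx(t.loc[src_id, col],
                                                      rel=0, abs=1e-12)

    def test_mahalanobis_matches_explicit_inverse(self, sim_species):
        """D^2 agrees with a brute-force explicit-inverse computation."""
        g = sim_species["genotypes"].subset_loci(np.arange(60))
        res = pca_outlier_scan(g, K=2, seed=0, inflation=1.0)
        z = res.params["zscores"].T
        loc, scatter = res.params["location"], res.params["scatter"]
        inv = np.linalg.inv(scatter)
        d2_brute = np.array([(zi - loc) @ inv @ (zi - loc) for zi in z])
        t = res.table.dropna(subset=["statistic"])
        np.testing.assert_allclose(t["statistic"].to_numpy(), d2_brute,
                                   atol=1e-8)
        # with inflation forced to 1, p is the plain upper chi-square tail
        np.testing.assert_allclose(t["p"], stats.chi2.sf(d2_brute, 2),
                                   atol=1e-12)

    def test_fixed_difference_locus_attains_max_d2(self):
        # two diverged populations (Balding-Nichols background) plus one locus
        # fixed for alternate alleles: that locus shows the most extreme
        # structure association
        rng = np.random.default_rng(3)
        n, L, F = 40, 80, 0.2
        p_anc = rng.uniform(0.2, 0.8, size=L)
        fa = rng.beta(p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F)
        fb = rng.beta(p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F)
        counts = np.vstack([rng.binomial(2, fa, size=(n // 2, L)),
                            rng.binomial(2, fb, size=(n // 2, L))])
        pops = ["A"] * (n // 2) + ["B"] * (n // 2)
        counts[:n // 2, 0] = 0
        counts[n // 2:, 0] = 2
        g = _geno(counts, pops)
        res = pca_outlier_scan(g, K=1, seed=0)
        t = res.table.dropna(subset=["statistic"])
        assert t["statistic"].idxmax() == 0

    def test_k_too_large_rejected(self, toy_genotypes):
        with pytest.raises(ValueError):
            pca_outlier_scan(toy_genotypes, K=5, seed=0)

    def test_locus_order_equivariance(self, sim_species):
        g = sim_species["genotypes"].subset_loci(np.arange(120))
        perm = np.random.default_rng(0).permutation(120)
        res1 = pca_outlier_scan(g, K=2, seed=0)
        res2 = pca_outlier_scan(g.subset_loci(perm), K=2, seed=0)
        t1 = res1.table.set_index("locus_id")["statistic"]
        t2 = res2.table.set_index("locus_id")["statistic"]
        np.testing.assert_allclose(t1.sort_index(), t2.sort_index(), atol=1e-9)


def test_ogk_recovers_simple_covariance():
    rng = np.random.default_rng(4)
    cov = np.array([[2.0, 0.8], [0.8, 1.0]])
    X = rng.multivariate_normal([1.0, -2.0], cov, size=4000)
    loc, scat = ogk_location_scatter(X)
    np.testing.assert_allclose(loc, [1.0, -2.0], atol=0.1)
    np.testing.assert_allclose(scat, cov, atol=0.25)


class TestLfmmImpute:
    def test_no_missing_is_identity(self, toy_genotypes):
        out = lfmm_impute(toy_genotypes, K=1, seed=0)
        np.testing.assert_array_equal(out, toy_genotypes.counts)

    def test_rank_one_matrix_reconstructed(self):
        rng = np.random.default_rng(5)
        u = rng.integers(0, 3, size=60)   # exact rank-1 integer matrix
        v = rng.integers(0, 2, size=40)
        full = np.outer(u, v).astype(float)
        counts = full.astype(np.int16)
        holes = rng.random(counts.shape) < 0.1
        masked = counts.copy()
        masked[holes] = -1
        g = _geno(masked)
        out = lfmm_impute(g, K=1, seed=0)
        rmse = np.sqrt(np.mean((out[holes] - full[holes]) ** 2))
        assert rmse < 0.1

    def test_deterministic(self, sim_species):
        g = sim_species["genotypes"]
        a = lfmm_impute(g, K=2, seed=0)
        b = lfmm_impute(g, K=2, seed=0)
        np.testing.assert_array_equal(a, b)

    def test_fully_missing_locus_rejected(self, toy_genotypes):
        counts = toy_genotypes.counts.copy()
        counts[:, 1] = -1
        g = GenotypeMatrix(counts=counts, samples=toy_genotypes.samples,
                           loci=toy_genotypes.loci)
        with pytest.raises(ValueError, match="entirely missing"):
            lfmm_impute(g, K=1, seed=0)


class TestLfmmRidgeScan:
    def _env(self, n, seed=0, d=2):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.standard_normal((n, d)),
                            columns=[f"e{j}" for j in range(d)])

    def test_k0_matches_closed_form_ols(self):
        rng = np.random.default_rng(6)
        n, L = 80, 30
        Y = rng.binomial(2, 0.4, size=(n, L)).astype(float)
        env = self._env(n, seed=1, d=1)
        res = lfmm_ridge_scan(Y, env, K=0)
        z = res.per_variable["e0"]["z"].to_numpy()
        x = (env["e0"] - env["e0"].mean()) / env["e0"].std(ddof=1)
        X = np.column_stack([np.ones(n), x])
        t_closed = np.empty(L)
        for j in range(L):
            beta, res_ss = np.linalg.lstsq(X, Y[:, j] - Y[:, j].mean(),
                                           rcond=None)[:2]
            sigma2 = res_ss[0] / (n - 2)
            se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
            t_closed[j] = beta[1] / se
        np.testing.assert_allclose(z, t_closed, atol=1e-8)

    def test_duplicated_environment_variable(self, sim_species):
        g = sim_species["genotypes"]
        imputed = lfmm_impute(g, K=2, seed=0)
        env = sim_species["climate"].values.loc[
            sim_species["samples"]["sample_id"], ["temp_seasonality"]].copy()
        env["copy"] = env["temp_seasonality"]
        res = lfmm_ridge_scan(imputed, env, K=2)
        np.testing.assert_allclose(res.per_variable["temp_seasonality"]["z"],
                                   res.per_variable["copy"]["z"], atol=1e-9)

    def test_constant_environment_rejected(self):
        Y = np.random.default_rng(0).binomial(2, 0.5, (20, 5)).astype(float)
        env = pd.DataFrame({"c": np.ones(20)})
        with pytest.raises(ValueError, match="constant"):
            lfmm_ridge_scan(Y, env, K=0)

    def test_planted_cline_detected_at_host_scale_differentiation(self,
                                                                  landscape):
        """A beta=3 logistic cline at F=0.05 reaches q<0.05 in >=4/5 seeds."""
        from adaptscape.climate import extract_at_points
        from adaptscape.simulate import (SimConfig, sample_sites,
                                         simulate_genotypes)
        hits = 0
        for seed in range(5):
            samples = sample_sites(landscape, 10, (15, 15), seed=seed)
            table = extract_at_points(landscape, samples)
            cfg = SimConfig(n_pops=10, n_ind_per_pop=(15, 15), n_neutral=400,
                            n_adaptive=1, driver_map={0: "annual_precip"},
                            effect_beta=3.0, fst_target=0.05, region_frac=0.25,
                            region_axis="ew", missing_rate=0.0, seed=seed)
            g, truth = simulate_genotypes(samples, table.values, cfg)
            env = table.values.loc[samples["sample_id"]]
            res = lfmm_ridge_scan(g.counts.astype(float), env, K=2)
            res.table["locus_id"] = list(g.loci["locus_id"])
            t = res.table.set_index("locus_id")
            if bool(t.loc[truth.adaptive_ids[0], "significant"]):
                hits += 1
        assert hits >= 4
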