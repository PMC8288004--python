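"""Selection scans: PCA-outlier population-differentiation test and
latent-factor ridge environment association.

Both scans calibrate their test statistics with a genomic inflation factor
lambda = median(statistic) / median(chi^2_df), then convert to upper-tail
chi-square p-values.  Multiple testing is controlled with Storey q-values for
the PCA-outlier scan and per-variable Benjamini-Hochberg for the environment
association scan; loci with q < 0.05 (by default) are flagged significant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["ScanResult", "choose_k_scree", "pca_outlier_scan", "lfmm_impute",
           "lfmm_ridge_scan", "storey_qvalues", "ogk_location_scatter"]


@dataclass
class ScanResult:
    """Per-locus statistics of one genome-scan method.

    ``table`` columns: locus_id, statistic, p, q, db, significant.  Per-variable
    detail of environment-association methods lives in ``per_variable``.
    """

    method: str
    table: pd.DataFrame = field(repr=False)
    params: dict = field(default_factory=dict)
    per_variable: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def significant_ids(self) -> set[str]:
        t = self.table
        return set(t.loc[t["significant"].fillna(False).astype(bool), "locus_id"])

    @property
    def locus_ids(self) -> list[str]:
        return list(self.table["locus_id"])

    def to_csv(self, path) -> None:
        t = self.table.copy()
        t.insert(1, "method", self.method)
        t.to_csv(path, index=False)


# ----------------------------------------------------------------- multiple testing
def storey_qvalues(p: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with a single-lambda pi0 estimate."""
    p = np.asarray(p, dtype=float)
    m = p.size
    pi0 = min(1.0, float((p > lam).mean()) / (1.0 - lam)) if m else 1.0
    pi0 = max(pi0, 1.0 / m) if m else 1.0
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        prev = min(prev, pi0 * p[i] * m / (rank + 1))
        q[i] = prev
    return q


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    return stats.false_discovery_control(np.asarray(p, dtype=float), method="bh")


# ------------------------------------------------------------------- scree rule
def choose_k_scree(eigenvalues, k_max: int = 10) -> int:
    """Scree-elbow choice of the number of components (Cattell-style).

    K is the largest index such that the drop (lambda_K - lambda_{K+1})
    exceeds 5% of the total fall (lambda_1 - lambda_{k_max}); minimum 1.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size < 2:
        raise ValueError("need at least 2 eigenvalues")
    if np.any(np.diff(ev) > 1e-12) or np.any(ev <= 0):
        raise ValueError("eigenvalues must be positive and nonincreasing")
    k_max = min(k_max, ev.size)
    denom = ev[0] - ev[k_max - 1]
    if denom <= 0:
        warnings.warn("flat eigenvalue spectrum; K set to 1")
        return 1
    best = 1
    for k in range(1, k_max):
        if (ev[k - 1] - ev[k]) / denom > 0.05:
            best = k
    return best


# ------------------------------------------------------------------ robust scatter
def _mad_scale(x: np.ndarray, axis=0) -> np.ndarray:
    med = np.median(x, axis=axis, keepdims=True)
    return 1.4826 * np.median(np.abs(x - med), axis=axis)


def ogk_location_scatter(X: np.ndarray):
    """Orthogonalized Gnanadesikan-Kettenring robust location/scatter.

    Median/MAD based and fully deterministic: pairwise robust correlations
    from MADs of sums and differences, one orthogonalization step, robust
    rescaling in the eigenbasis.  Rows are observations.
    """
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    s = _mad_scale(X)
    s = np.where(s > 0, s, X.std(axis=0, ddof=1))
    s = np.where(s > 0, s, 1.0)
    Z = X / s
    R = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            sp = _mad_scale(Z[:, i] + Z[:, j])
            sm = _mad_scale(Z[:, i] - Z[:, j])
            denom = sp**2 + sm**2
            r = (sp**2 - sm**2) / denom if denom > 0 else 0.0
            R[i, j] = R[j, i] = np.clip(r, -0.999, 0.999)
    evals, E = np.linalg.eigh(R)
    V = Z @ E
    d = _mad_scale(V)
    d = np.where(d > 0, d, V.std(axis=0, ddof=1))
    d = np.where(d > 0, d, 1e-12)
    m = np.median(V, axis=0)
    cov = (s[:, None] * E) @ np.diag(d**2) @ (E.T * s[None, :])
    loc = s * (E @ m)
    return loc, cov


# --------------------------------------------------------------- PCA outlier scan
def _scaled_genotypes(g: GenotypeMatrix, min_maf: float = 0.05):
    """Mean-impute, MAF-filter, centre and binomial-scale the genotype matrix.

    Returns (scaled matrix n x L_kept, kept locus indices).
    """
    counts = g.counts.astype(float)
    counts[g.counts == MISSING] = np.nan
    col_mean = np.nanmean(counts, axis=0)
    inds = np.where(np.isnan(counts))
    counts[inds] = np.take(col_mean, inds[1])
    p_hat = col_mean / 2.0
    maf = np.minimum(p_hat, 1 - p_hat)
    var = counts.var(axis=0)
    keep = (maf >= min_maf) & (var > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("PCA scan: excluded %d loci (MAF < %.2f or zero variance)",
                    n_dropped, min_maf)
    kept = np.flatnonzero(keep)
    ph = p_hat[kept]
    scaled = (counts[:, kept] - 2 * ph) / np.sqrt(2 * ph * (1 - ph))
    return scaled, kept


def pca_scree_eigenvalues(g: GenotypeMatrix, k_max: int = 10) -> np.ndarray:
    """Leading covariance eigenvalues of the scaled genotype matrix."""
    scaled, _ = _scaled_genotypes(g)
    sv = np.linalg.svd(scaled, compute_uv=False)
    ev = sv**2 / (scaled.shape[0] - 1)
    return ev[:k_max]


def pca_outlier_scan(g: GenotypeMatrix, K: int, fdr: float = 0.05,
                     seed: int = 0, min_maf: float = 0.05,
                     inflation: float | None = None) -> ScanResult:
    """PCA-outlier population-differentiation scan.

    Genotypes are centred and scaled by the binomial SD sqrt(2p(1-p)); the
    per-locus vector of regression slopes on the top-K unit-variance principal
    component scores is summarized with a robust Mahalanobis distance D^2,
    rescaled by the genomic inflation factor, and referred to chi^2_K.
    Significance: Storey q < ``fdr``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K >= min(g.n_samples, g.n_loci):
        raise ValueError(f"K={K} too large for {g.n_samples} x {g.n_loci} matrix")
    scaled, kept = _scaled_genotypes(g, min_maf=min_maf)
    n = scaled.shape[0]
    U, S, _ = np.linalg.svd(scaled, full_matrices=False)
    scores = U[:, :K] * np.sqrt(n)  # unit-variance PC scores
    z = (scores.T @ scaled) / n  # regression slopes (orthogonal design)
    loc, scatter = ogk_location_scatter(z.T)
    dz = z.T - loc
    d2 = np.einsum("ij,ij->i", dz, linalg.solve(scatter, dz.T, assume_a="pos").T)
    lam = (float(np.median(d2)) / stats.chi2.median(K)) if inflation is None \
        else float(inflation)
    p = stats.chi2.sf(d2 / lam, df=K)
    q = storey_qvalues(p)
    table = pd.DataFrame({
        "locus_id": g.loci["locus_id"],
        "statistic": np.nan, "p": np.nan, "q": np.nan, "db": np.nan,
        "significant": False,
    })
    table.loc[kept, "statistic"] = d2
    table.loc[kept, "p"] = p
    table.loc[kept, "q"] = q
    table.loc[kept, "significant"] = q < fdr
    params = {"K": K, "lambda": lam, "fdr": fdr, "seed": seed,
              "n_excluded": g.n_loci - len(kept),
              "location": loc, "scatter": scatter, "zscores": z}
    return ScanResult(method="pca_outlier", table=table, params=params)


# -------------------------------------------------------------------- LFMM ridge
def lfmm_impute(g: GenotypeMatrix, K: int, seed: int = 0, tol: float = 1e-4,
                max_iter: int = 50) -> np.ndarray:
    """Impute missing genotypes by iterative rank-K SVD reconstruction.

    Initialize missing cells with locus means, then alternate a truncated SVD
    of the completed matrix with refilling the missing cells from the rank-K
    reconstruction until the largest change is below ``tol``.  The result is
    clamped into [0, 2] (continuous dosages).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    counts = g.counts.astype(float)
    miss = g.counts == MISSING
    if miss.all(axis=0).any():
        raise ValueError("locus entirely missing; cannot impute")
    if not miss.any():
        return counts
    counts[miss] = np.nan
    col_mean = np.nanmean(counts, axis=0)
    filled = np.where(miss, col_mean[None, :], counts)
    for _ in range(max_iter):
        U, S, Vt = np.linalg.svd(filled, full_matrices=False)
        recon = (U[:, :K] * S[:K]) @ Vt[:K]
        delta = np.max(np.abs(recon[miss] - filled[miss]))
        filled[miss] = recon[miss]
        if delta < tol:
            break
    return np.clip(filled, 0.0, 2.0)


_CHI2_1_MEDIAN = stats.chi2.median(1)  # 0.45494


def lfmm_ridge_scan(genotypes, env: pd.DataFrame, K: int, fdr: float = 0.05,
                    ridge_rel: float = 1e-4) -> ScanResult:
    """Latent-factor ridge environment-association scan.

    The analysis is run once per climatic variable: the K latent factors are
    the leading left singular vectors of the genotype matrix after a ridge
    projection removing that variable's signal, each locus is regressed by
    OLS on [variable, factors], and the z-scores are recalibrated with a
    genomic inflation factor before Benjamini-Hochberg adjustment.  A locus
    is significant when any variable reaches q < ``fdr``.  ``K=0``
    degenerates to simple per-locus regression.

    ``genotypes`` may be a GenotypeMatrix (must be complete) or a complete
    numeric matrix from :func:`lfmm_impute`.
    """
    if isinstance(genotypes, GenotypeMatrix):
        if (genotypes.counts == MISSING).any():
            raise ValueError("genotype matrix has missing data; impute first")
        Y = genotypes.counts.astype(float)
        locus_ids = list(genotypes.loci["locus_id"])
    else:
        Y = np.asarray(genotypes, dtype=float)
        locus_ids = [f"locus{j}" for j in range(Y.shape[1])]
    n, L = Y.shape
    if K >= n:
        raise ValueError("K must be smaller than the number of individuals")
    env = env.copy()
    sd = env.std(axis=0, ddof=1)
    if (sd == 0).any():
        const = list(sd.index[sd == 0])
        raise ValueError(f"constant environmental variable(s): {const}")
    Xall = ((env - env.mean(axis=0)) / sd).to_numpy()
    Yc = Y - Y.mean(axis=0)

    per_variable = {}
    sig_any = np.zeros(L, dtype=bool)
    min_q = np.full(L, np.inf)
    lambdas = {}
    zmax2 = np.zeros(L)
    for v, name in enumerate(env.columns):
        x = Xall[:, v:v + 1]
        if K > 0:
            delta = ridge_rel * float((x**2).sum())
            H = x @ np.linalg.solve(x.T @ x + delta, x.T)
            Ures, _, _ = np.linalg.svd(Yc - H @ Yc, full_matrices=False)
            design = np.column_stack([np.ones(n), x, Ures[:, :K]])
        else:
            design = np.column_stack([np.ones(n), x])
        dof = n - np.linalg.matrix_rank(design)
        G = np.linalg.pinv(design.T @ design)
        B = G @ design.T @ Yc
        resid = Yc - design @ B
        sigma2 = (resid**2).sum(axis=0) / dof
        se = np.sqrt(G[1, 1] * sigma2)
        z = B[1] / np.maximum(se, 1e-300)
        z2 = z ** 2
        lam = max(float(np.median(z2)) / _CHI2_1_MEDIAN, 1e-12)
        p = stats.chi2.sf(z2 / lam, df=1)
        qv = bh_qvalues(p)
        per_variable[name] = pd.DataFrame({
            "locus_id": locus_ids, "z": z, "p": p, "q": qv,
            "significant": qv < fdr,
        })
        lambdas[name] = lam
        sig_any |= qv < fdr
        min_q = np.minimum(min_q, qv)
        zmax2 = np.maximum(zmax2, z2)
    stat = zmax2
    table = pd.DataFrame({
        "locus_id": locus_ids, "statistic": stat, "p": np.nan, "q": min_q,
        "db": np.nan, "significant": sig_any,
    })
    params = {"K": K, "lambda": lambdas, "fdr": fdr, "ridge_rel": ridge_rel}
    return ScanResult(method="lfmm_ridge", table=table, params=params,
                      per_variable=per_variable)
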