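"""Mixed-linear-model association scan for inbred diversity panels.

The model is y = X b + u + e with a random polygenic term u ~ N(0, sg2 K)
whose covariance is the identity-by-state kinship matrix K, and residual
e ~ N(0, se2 I).  Variance components are estimated once per trait on the
null model by spectral REML (eigendecompose K, profile the restricted
log-likelihood over the variance ratio delta = se2/sg2), then held fixed for
every SNP test — the population-parameters-previously-determined
approximation used by EMMAX-class tools.  Each SNP is tested by generalized
least squares in the eigenbasis of K with a Wald t-test.

Supporting steps: variant QC filtering (missingness / MAF), window-based LD
pruning for the kinship SNP subset, kinship principal components as
structure covariates, a simpleM-style effective number of independent
markers, and the 1/N suggestive Bonferroni threshold built from it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_formats import MISSING, VariantTable

logger = logging.getLogger(__name__)

CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))  # 0.4549...


# ---------------------------------------------------------------------------
# variant QC + LD pruning
# ---------------------------------------------------------------------------

@dataclass
class FilterStats:
    n_input: int
    n_kept: int
    n_failed_missing: int
    n_failed_maf: int


def filter_variants(
    variants: VariantTable,
    max_missing: float = 0.20,
    min_maf: float = 0.05,
) -> tuple[VariantTable, FilterStats]:
    """Keep SNPs with missing fraction < ``max_missing`` and MAF > ``min_maf``
    (both strict, matching the usual PLINK-style QC inequalities)."""
    miss = variants.missing_fraction()
    maf = variants.maf()
    ok_miss = miss < max_missing
    ok_maf = maf > min_maf
    keep = ok_miss & ok_maf
    st = FilterStats(
        n_input=variants.n_snps,
        n_kept=int(keep.sum()),
        n_failed_missing=int((~ok_miss).sum()),
        n_failed_maf=int((ok_miss & ~ok_maf).sum()),
    )
    if st.n_kept == 0:
        logger.warning("filter_variants: no SNPs survived QC")
    return variants.take_snps(keep), st


def _imputed_standardized(dosages: np.ndarray) -> np.ndarray:
    """Missing -> per-SNP mean; then center (rows = SNPs)."""
    d = dosages.astype(float)
    d[dosages == MISSING] = np.nan
    mean = np.nanmean(d, axis=1, keepdims=True)
    d = np.where(np.isnan(d), mean, d)
    return d - mean


def ld_prune(
    variants: VariantTable,
    window: int = 50,
    step: int = 10,
    r2_max: float = 0.1,
) -> list[str]:
    """Greedy windowed LD pruning (indep-pairwise style); returns kept SNP ids.

    Within each window of ``window`` SNPs (advanced by ``step``), for every
    pair with r^2 > ``r2_max`` one member is removed: the one with higher
    missingness, ties broken toward the later position.
    """
    removed = np.zeros(variants.n_snps, dtype=bool)
    miss = variants.missing_fraction()
    chroms = variants.snps["chrom"].to_numpy()
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        for w0 in range(0, len(idx), step):
            win = idx[w0 : w0 + window]
            live = win[~removed[win]]
            if len(live) < 2:
                continue
            d = _imputed_standardized(variants.dosages[live])
            sd = d.std(axis=1)
            sd[sd == 0] = np.nan
            r = (d @ d.T) / len(variants.samples) / np.outer(sd, sd)
            r2 = r ** 2
            for a in range(len(live)):
                if removed[live[a]]:
                    continue
                for b in range(a + 1, len(live)):
                    if removed[live[a]]:
                        break
                    if removed[live[b]] or not r2[a, b] > r2_max:
                        continue
                    ia, ib = live[a], live[b]
                    if miss[ia] > miss[ib]:
                        removed[ia] = True
                    elif miss[ib] > miss[ia]:
                        removed[ib] = True
                    else:
                        removed[max(ia, ib)] = True  # later position
            if w0 + window >= len(idx):
                break
    return variants.snps.loc[~removed, "snp_id"].tolist()


# ---------------------------------------------------------------------------
# kinship + structure covariates
# ---------------------------------------------------------------------------

def ibs_kinship(variants: VariantTable) -> np.ndarray:
    """Identity-by-state kinship: mean over shared non-missing SNPs of
    1 - |d_i - d_j| / 2, computed pairwise-complete."""
    if variants.n_samples < 2:
        raise ValueError("kinship needs at least 2 accessions")
    d = variants.dosages
    p0 = (d == 0).astype(np.float64).T
    p1 = (d == 1).astype(np.float64).T
    p2 = (d == 2).astype(np.float64).T
    obs = p0 + p1 + p2
    shared = obs @ obs.T
    if (shared == 0).any():
        raise ValueError("some accession pair shares zero genotyped SNPs")
    eq = p0 @ p0.T + p1 @ p1.T + p2 @ p2.T
    opposite = p0 @ p2.T + p2 @ p0.T
    # score: 1 for equal, 0.5 for one-step difference, 0 for opposite
    score = 0.5 * shared + 0.5 * eq - 0.5 * opposite
    return score / shared


def pca_covariates(kinship: np.ndarray, n_pc: int = 3) -> np.ndarray:
    """Top eigenvectors of the double-centered kinship, deterministic signs.

    Each returned column has its largest-magnitude entry positive.
    """
    n = kinship.shape[0]
    if n_pc >= n:
        raise ValueError("n_pc must be smaller than the number of accessions")
    h = np.eye(n) - np.full((n, n), 1.0 / n)
    b = h @ kinship @ h
    vals, vecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(vals)[::-1][:n_pc]
    pcs = vecs[:, order]
    for j in range(pcs.shape[1]):
        k = np.argmax(np.abs(pcs[:, j]))
        if pcs[k, j] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs


# ---------------------------------------------------------------------------
# spectral REML
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """REML variance components of the null mixed model."""

    sigma_g2: float
    sigma_e2: float
    delta: float  # sigma_e2 / sigma_g2
    h2: float     # sigma_g2 / (sigma_g2 + sigma_e2)
    reml_loglik: float
    at_boundary: bool = False


def _restricted_loglik(log_delta: float, lam: np.ndarray, eta2: np.ndarray) -> float:
    delta = np.exp(log_delta)
    nq = len(lam)
    denom = lam + delta
    s = float((eta2 / denom).sum())
    return 0.5 * (
        nq * (np.log(nq / (2 * np.pi)) - 1.0 - np.log(s)) - np.log(denom).sum()
    )


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    grid: tuple[float, float, int] = (-10.0, 10.0, 121),
) -> VarianceComponents:
    """Estimate (sg2, se2) by restricted maximum likelihood.

    Profiles the restricted log-likelihood of the null model over log(delta)
    on a grid, then refines with bounded scalar optimization around the best
    grid point.  Uses the eigendecomposition of the covariate-projected
    kinship, so each likelihood evaluation is O(n).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(y)
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kinship matrix must be symmetric")
    q = np.linalg.matrix_rank(X)
    if n <= q + 1:
        raise ValueError("too few observations for REML")

    # project out X, eigendecompose S K S on its (n-q)-dim range
    Q, _ = np.linalg.qr(X)
    S = np.eye(n) - Q @ Q.T
    M = S @ ((K + K.T) / 2) @ S
    vals, vecs = np.linalg.eigh((M + M.T) / 2)
    order = np.argsort(vals)[::-1][: n - q]
    lam = np.clip(vals[order], 0.0, None)
    eta = vecs[:, order].T @ y
    eta2 = eta ** 2

    lo, hi, npts = grid
    pts = np.linspace(lo, hi, npts)
    lls = np.array([_restricted_loglik(p, lam, eta2) for p in pts])
    best = int(np.argmax(lls))
    at_boundary = best in (0, npts - 1)
    if at_boundary:
        logger.warning("reml_fit: optimum at grid boundary (log delta = %g)", pts[best])
    a = pts[max(best - 1, 0)]
    b = pts[min(best + 1, npts - 1)]
    res = optimize.minimize_scalar(
        lambda p: -_restricted_loglik(p, lam, eta2),
        bounds=(a, b), method="bounded",
    )
    log_delta = float(res.x)
    if -res.fun < lls[best]:  # keep the grid point if refinement lost ground
        log_delta = float(pts[best])
    delta = float(np.exp(log_delta))
    sigma_g2 = float((eta2 / (lam + delta)).sum() / (n - q))
    sigma_e2 = delta * sigma_g2
    return VarianceComponents(
        sigma_g2=sigma_g2, sigma_e2=sigma_e2, delta=delta,
        h2=1.0 / (1.0 + delta),
        reml_loglik=_restricted_loglik(log_delta, lam, eta2),
        at_boundary=at_boundary,
    )


# ---------------------------------------------------------------------------
# association scan
# ---------------------------------------------------------------------------

def association_scan(
    variants: VariantTable,
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    vc: VarianceComponents,
) -> pd.DataFrame:
    """Per-SNP GLS Wald tests with variance components held fixed.

    Rotates y, the covariates and each (mean-imputed) SNP dosage into the
    eigenbasis of K, weights by 1/(lambda_i + delta) and fits weighted least
    squares per SNP; covariates are partialled out once.  Monomorphic SNPs
    are skipped (logged).  Returns a DataFrame with columns snp_id, chrom,
    pos, beta, se, p, maf, n.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(y)
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("association_scan requires complete-case y and X")
    vals, U = np.linalg.eigh((K + K.T) / 2)
    lam = np.clip(vals, 0.0, None)
    w = 1.0 / np.sqrt(lam + vc.delta)

    ys = (U.T @ y) * w
    Xs = (U.T @ X) * w[:, None]
    Qx, Rx = np.linalg.qr(Xs)
    rank_x = int((np.abs(np.diag(Rx)) > 1e-10).sum())
    ry = ys - Qx @ (Qx.T @ ys)
    df = n - rank_x - 1
    if df <= 0:
        raise ValueError("no residual degrees of freedom")

    d = variants.dosages.astype(float)
    obsmask = variants.dosages != MISSING
    d[~obsmask] = np.nan
    mean = np.nanmean(d, axis=1)
    poly = np.nanstd(d, axis=1) > 0
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("association_scan: skipped %d monomorphic SNP(s)", n_mono)
    G = np.where(np.isnan(d), mean[:, None], d)[poly]

    Gs = (G @ U) * w[None, :]          # (m, n) rotated + whitened
    RG = Gs - (Gs @ Qx) @ Qx.T         # covariates partialled out
    gg = (RG ** 2).sum(axis=1)
    gy = RG @ ry
    beta = gy / gg
    rss = float(ry @ ry) - beta * gy
    sigma2 = np.clip(rss, 0.0, None) / df
    se = np.sqrt(sigma2 / gg)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    snps = variants.snps.loc[poly]
    freq = mean[poly] / 2.0
    return pd.DataFrame(
        {
            "snp_id": snps["snp_id"].to_numpy(),
            "chrom": snps["chrom"].to_numpy(),
            "pos": snps["pos0"].to_numpy() + 1,
            "beta": beta,
            "se": se,
            "p": p,
            "maf": np.minimum(freq, 1.0 - freq),
            "n": obsmask[poly].sum(axis=1),
        }
    )


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def effective_marker_number(
    variants: VariantTable,
    window: int = 200,
    var_fraction: float = 0.995,
) -> int:
    """simpleM-style effective number of independent markers.

    Per chromosome, in non-overlapping windows of ``window`` SNPs, count the
    smallest number of top eigenvalues of the SNP correlation matrix whose
    sum reaches ``var_fraction`` of the trace; return the genome-wide sum.
    """
    total = 0
    chroms = variants.snps["chrom"].to_numpy()
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        for w0 in range(0, len(idx), window):
            win = idx[w0 : w0 + window]
            d = _imputed_standardized(variants.dosages[win])
            sd = d.std(axis=1)
            keep = sd > 0
            d = d[keep] / sd[keep][:, None]
            m = len(d)
            if m == 0:
                continue
            if m == 1:
                total += 1
                continue
            corr = (d @ d.T) / d.shape[1]
            vals = np.sort(np.linalg.eigvalsh(corr))[::-1]
            vals = np.clip(vals, 0.0, None)
            csum = np.cumsum(vals)
            total += int(np.searchsorted(csum, var_fraction * csum[-1]) + 1)
    return total


def significance_threshold(n_effective: int) -> float:
    """Suggestive Bonferroni-style threshold 1/N over effective markers."""
    if n_effective < 1:
        raise ValueError("effective marker number must be >= 1")
    return 1.0 / n_effective


def qq_lambda(p_values: np.ndarray) -> tuple[float, pd.DataFrame]:
    """Genomic-control inflation factor and a QQ table.

    lambda_GC = median(chi2_1 quantile of p) / 0.4549; the table holds the
    sorted expected and observed -log10 p for plotting.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if len(p) < 100:
        raise ValueError("need at least 100 p-values")
    chi2 = stats.chi2.isf(p, 1)
    lam = float(np.median(chi2) / CHI2_MEDIAN_1DF)
    obs = np.sort(p)
    exp = (np.arange(1, len(p) + 1) - 0.5) / len(p)
    table = pd.DataFrame(
        {"expected_mlogp": -np.log10(exp), "observed_mlogp": -np.log10(obs)}
    )
    return lam, table
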