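"""Mixed-linear-model association on the SNP matrix.

Kinship is VanRaden's genomic relationship matrix K = ZZ' / (2 * sum
p_k (1 - p_k)) from centred 0/2-coded genotypes.  The association model is
y = PC beta + snp + u + e with u ~ N(0, K sigma_g^2); variance components are
estimated once on the null model by REML (eigendecomposition, EMMA-style)
and per-SNP Wald tests reuse them (EMMAX approximation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .codes import A, B, HET


# ---------------------------------------------------------------------------
# genotype dosage matrix

def dosage_matrix(calls: np.ndarray) -> np.ndarray:
    """0/1/2 B-allele dosages from call codes (A -> 0, HET -> 1, B -> 2,
    anything else -> NaN)."""
    out = np.full(calls.shape, np.nan)
    out[calls == A] = 0.0
    out[calls == HET] = 1.0
    out[calls == B] = 2.0
    return out


def _impute_and_freq(M: np.ndarray):
    """Mean-impute missing dosages per SNP; return (imputed matrix, allele
    frequency p per SNP)."""
    M = M.copy()
    col_mean = np.nanmean(M, axis=0)
    nan_mask = np.isnan(M)
    M[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    return M, col_mean / 2.0


@dataclass
class KinshipMatrix:
    values: np.ndarray
    method: str = "vanraden"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("kinship must be square")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("kinship must be symmetric")
        self.values = (v + v.T) / 2.0

    def bend(self, eps: float = 1e-6) -> "KinshipMatrix":
        """Force positive semi-definiteness by flooring eigenvalues."""
        w, U = np.linalg.eigh(self.values)
        w = np.maximum(w, eps)
        return KinshipMatrix(U @ np.diag(w) @ U.T, self.method + "+bent")


def vanraden_kinship(dosages: np.ndarray) -> KinshipMatrix:
    """K = ZZ' / (2 sum p_k (1 - p_k)) with Z the per-SNP centred dosage
    matrix.  Missing dosages are mean-imputed; monomorphic SNPs are excluded
    (error if none remain)."""
    M, p = _impute_and_freq(np.asarray(dosages, dtype=float))
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNPs monomorphic; kinship undefined")
    M, p = M[:, poly], p[poly]
    Z = M - 2.0 * p
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    return KinshipMatrix(Z @ Z.T / denom)


def pca_covariates(dosages: np.ndarray, n_pcs: int) -> np.ndarray:
    """Leading principal components of the centred (imputed) dosage matrix."""
    if n_pcs == 0:
        return np.empty((dosages.shape[0], 0))
    M, p = _impute_and_freq(np.asarray(dosages, dtype=float))
    Z = M - M.mean(axis=0)
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    return U[:, :n_pcs] * s[:n_pcs]


# ---------------------------------------------------------------------------
# REML (EMMA eigendecomposition)

@dataclass
class NullModelFit:
    sigma_g2: float
    sigma_e2: float
    log_reml: float
    heritability: float


def reml_null(y: np.ndarray, K: KinshipMatrix, covariates: np.ndarray | None = None,
              bounds: tuple = (-10.0, 10.0)) -> NullModelFit:
    """REML variance components of y = X beta + u + e, u ~ N(0, K sg2).

    Profiles the restricted likelihood over delta = se2/sg2 on the spectrum
    of the projected kinship (EMMA).  Raises on non-convergence or a
    degenerate spectrum.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = np.ones((n, 1)) if covariates is None or covariates.size == 0 \
        else np.column_stack([np.ones(n), covariates])
    p = X.shape[1]
    # project out fixed effects, eigendecompose the projected kinship
    Q, _ = np.linalg.qr(X)
    P = np.eye(n) - Q @ Q.T
    w, U = np.linalg.eigh(P @ K.values @ P)
    order = np.argsort(w)[::-1]
    xi, Ur = w[order[: n - p]], U[:, order[: n - p]]
    if np.any(xi < -1e-6):
        raise ValueError("projected kinship has negative eigenvalues; bend K first")
    xi = np.maximum(xi, 0.0)
    eta2 = (Ur.T @ y) ** 2

    def neg_restricted_ll(log_delta):
        d = np.exp(log_delta)
        denom = xi + d
        s = np.sum(eta2 / denom)
        return 0.5 * ((n - p) * np.log(s) + np.sum(np.log(denom)))

    res = optimize.minimize_scalar(neg_restricted_ll, bounds=bounds, method="bounded",
                                   options={"xatol": 1e-8})
    if not res.success:
        raise RuntimeError(f"REML did not converge: {res.message}")
    delta = float(np.exp(res.x))
    sg2 = float(np.sum(eta2 / (xi + delta)) / (n - p))
    se2 = delta * sg2
    h2 = sg2 / (sg2 + se2)
    return NullModelFit(sg2, se2, -float(res.fun), h2)


# ---------------------------------------------------------------------------
# association scan

@dataclass
class GWASResult:
    table: pd.DataFrame           # chrom, pos, maf, effect, se, p_value
    threshold: float
    null_fit: NullModelFit

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["p_value"] <= self.threshold]


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def mlm_scan(dosages: np.ndarray, y: np.ndarray, K: KinshipMatrix,
             n_pcs: int = 0, chroms: np.ndarray | None = None,
             pos: np.ndarray | None = None, maf_min: float = 0.0,
             alpha: float = 0.05) -> GWASResult:
    """EMMAX association scan.

    The null model is fitted once by REML; per-SNP effects and Wald p-values
    are computed by GLS with V = sg2 K + se2 I held fixed.  SNPs below
    ``maf_min`` (computed from imputed dosages) are excluded before testing,
    and the Bonferroni threshold uses the number of SNPs actually tested.
    """
    y = np.asarray(y, dtype=float)
    if np.all(np.isnan(y)):
        raise ValueError("phenotype entirely missing")
    M, p_freq = _impute_and_freq(np.asarray(dosages, dtype=float))
    maf = np.minimum(p_freq, 1.0 - p_freq)
    test = maf >= maf_min if maf_min > 0 else maf > 0
    C = pca_covariates(dosages, n_pcs)
    fit = reml_null(y, K, C if n_pcs else None)

    w, U = np.linalg.eigh(K.values)
    w = np.maximum(w, 0.0)
    scale = 1.0 / np.sqrt(fit.sigma_g2 * w + fit.sigma_e2)
    T = (U * scale) @ U.T                   # V^{-1/2}
    yt = T @ y
    n = len(y)
    Xf = np.column_stack([np.ones(n), C]) if n_pcs else np.ones((n, 1))
    Xft = T @ Xf
    Q, _ = np.linalg.qr(Xft)
    yt_r = yt - Q @ (Q.T @ yt)
    Mt = T @ M[:, test]
    Mt_r = Mt - Q @ (Q.T @ Mt)

    sxx = np.sum(Mt_r ** 2, axis=0)
    sxy = Mt_r.T @ yt_r
    ok = sxx > 1e-12
    beta = np.where(ok, sxy / np.where(ok, sxx, 1.0), 0.0)
    df = n - Xf.shape[1] - 1
    rss = np.maximum(np.sum(yt_r ** 2) - beta * sxy, 1e-300)
    se = np.sqrt(rss / df / np.where(ok, sxx, 1.0))
    tstat = np.where(ok, beta / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    n_tests = int(test.sum())
    idx = np.flatnonzero(test)
    tbl = pd.DataFrame({
        "snp": idx,
        "chrom": chroms[idx] if chroms is not None else idx,
        "pos": pos[idx] if pos is not None else idx,
        "maf": maf[idx],
        "effect": beta, "se": se, "p_value": pvals,
    })
    return GWASResult(tbl, bonferroni_threshold(alpha, n_tests), fit)


def genomic_inflation(p_values: np.ndarray) -> float:
    """lambda_GC: median association chi-square over its null median."""
    chi2 = stats.chi2.isf(np.asarray(p_values, dtype=float), df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))
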