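"""Genotype PCA and per-SNP covariate-adjusted association.

The split-sample design runs the conditioning trait's GWAS on half 1 and
each metabolic trait's GWAS on half 2, so the two sets of summary
statistics share no samples.  Quantitative traits use OLS (closed-form via
covariate residualization, which is algebraically identical to the full
joint fit); the binary diabetes status uses Newton–Raphson maximum
likelihood logistic regression with Wald tests.

Covariate conventions: the age-at-menarche GWAS adjusts for age at
enrollment, BMI and the principal components; the metabolic-trait GWASs
adjust for education level (ordinal-coded), BMI and the principal
components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .synthdata import MISSING, GenotypeMatrix

P_FLOOR = np.finfo(float).tiny  # p-values are floored here, never 0

DEFAULT_COVARIATES: Dict[str, Tuple[str, ...]] = {
    "aam": ("age", "bmi"),
    "t2dm": ("education", "bmi"),
    "bfp": ("education", "bmi"),
    "fbg": ("education", "bmi"),
    "hba1c": ("education", "bmi"),
}

LOGISTIC_TRAITS = ("t2dm",)


@dataclass
class PCResult:
    """Top-k principal components of the standardized dosage matrix."""

    scores: np.ndarray              # (n_samples, k)
    explained_variance_ratio: np.ndarray  # (k,)


@dataclass
class AssocResult:
    """Single-SNP association fit; ``status`` is "ok", "constant" or
    "separation" (the latter two leave beta/se/p as NaN)."""

    beta: float
    se: float
    p: float
    n: int
    status: str = "ok"


def _impute_standardize(d: np.ndarray) -> np.ndarray:
    x = d.astype(float)
    x[d == MISSING] = np.nan
    mu = np.nanmean(x, axis=0)
    x = np.where(np.isnan(x), mu, x)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    keep = sd > 0
    x = x - mu
    x[:, keep] /= sd[keep]
    x[:, ~keep] = 0.0
    return x


def genotype_pca(G: GenotypeMatrix, k: int = 10,
                 snp_step: int = 1) -> PCResult:
    """PCA of the column-standardized dosage matrix.

    Missing dosages are mean-imputed before the decomposition.  The result
    is deterministic: each component's sign is fixed so its
    largest-magnitude SNP loading is positive.  ``snp_step`` thins the SNP
    panel (every ``snp_step``-th SNP) — customary for ancestry PCs, where
    a subset of markers suffices.
    """
    if k < 1 or k > min(G.n_samples, G.n_snps):
        raise ValueError(f"k={k} must be in [1, min(n, m)]")
    x = _impute_standardize(G.dosages[:, ::snp_step])
    n, m = x.shape
    if k > min(n, m):
        raise ValueError(f"k={k} exceeds thinned panel rank bound")
    total_var = float((x ** 2).sum())
    if n <= m:
        gram = x @ x.T
        vals, vecs = np.linalg.eigh(gram)
        order = np.argsort(vals)[::-1][:k]
        svals = np.sqrt(np.maximum(vals[order], 0.0))
        u = vecs[:, order]
        scores = u * svals
        with np.errstate(invalid="ignore", divide="ignore"):
            loadings = (x.T @ u) / np.where(svals > 0, svals, 1.0)
    else:
        u, svals, vt = np.linalg.svd(x, full_matrices=False)
        u, svals, vt = u[:, :k], svals[:k], vt[:k]
        scores = u * svals
        loadings = vt.T
    for j in range(k):
        lead = np.argmax(np.abs(loadings[:, j]))
        if loadings[lead, j] < 0:
            scores[:, j] = -scores[:, j]
            loadings[:, j] = -loadings[:, j]
    evr = (svals ** 2) / total_var if total_var > 0 else np.zeros(k)
    return PCResult(scores=scores, explained_variance_ratio=evr)


def _design(covars: Optional[np.ndarray], n: int) -> np.ndarray:
    if covars is None or covars.size == 0:
        return np.ones((n, 1))
    c = np.asarray(covars, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    return np.column_stack([np.ones(n), c])


def assoc_linear(y: np.ndarray, g: np.ndarray,
                 covars: Optional[np.ndarray] = None) -> AssocResult:
    """OLS slope of y on one dosage vector with covariates + intercept.

    Two-sided t-test on the slope.  A dosage constant after complete-case
    filtering is flagged non-estimable rather than raising.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    n = len(y)
    if len(g) != n:
        raise ValueError("y and g length mismatch")
    X = np.column_stack([_design(covars, n), g])
    if np.ptp(g) == 0:
        return AssocResult(np.nan, np.nan, np.nan, n, "constant")
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = n - X.shape[1]
    if df <= 0:
        return AssocResult(np.nan, np.nan, np.nan, n, "constant")
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(max(sigma2 * xtx_inv[-1, -1], 0.0)))
    beta = float(coef[-1])
    if se == 0:
        p = P_FLOOR if beta != 0 else 1.0
    else:
        p = max(2.0 * stats.t.sf(abs(beta) / se, df), P_FLOOR)
    return AssocResult(beta, se, float(p), n, "ok")


def assoc_logistic(y: np.ndarray, g: np.ndarray,
                   covars: Optional[np.ndarray] = None,
                   max_iter: int = 50, tol: float = 1e-8,
                   start: Optional[np.ndarray] = None) -> AssocResult:
    """Maximum-likelihood logistic slope with a Wald two-sided p-value.

    Newton–Raphson, converged when the relative log-likelihood change
    drops below ``tol`` (max ``max_iter`` iterations).  Perfect or
    quasi-perfect separation is flagged explicitly instead of returning a
    diverged estimate.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    n = len(y)
    if len(g) != n:
        raise ValueError("y and g length mismatch")
    classes = np.unique(y)
    if not np.isin(classes, [0.0, 1.0]).all() or len(classes) < 2:
        raise ValueError("y must contain both classes coded 0/1")
    if np.ptp(g) == 0:
        return AssocResult(np.nan, np.nan, np.nan, n, "constant")
    X = np.column_stack([_design(covars, n), g])
    p_cols = X.shape[1]
    beta = np.zeros(p_cols) if start is None else start.copy()
    ll_prev = -np.inf
    cov = None
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        w = mu * (1.0 - mu)
        H = (X * w[:, None]).T @ X
        H[np.diag_indices_from(H)] += 1e-10  # guard near-singular Hessian
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return AssocResult(np.nan, np.nan, np.nan, n, "separation")
        beta = beta + step
        if np.isfinite(ll) and abs(ll - ll_prev) <= tol * (abs(ll) + 1e-12):
            ll_prev = ll
            break
        ll_prev = ll
    eta = np.clip(X @ beta, -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    # separation: fitted probabilities pinned at 0/1, diverging slope
    if np.abs(beta[-1]) > 25 or w.max() < 1e-10:
        return AssocResult(np.nan, np.nan, np.nan, n, "separation")
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return AssocResult(np.nan, np.nan, np.nan, n, "separation")
    se = float(np.sqrt(max(cov[-1, -1], 0.0)))
    b = float(beta[-1])
    if se == 0 or not np.isfinite(se):
        return AssocResult(np.nan, np.nan, np.nan, n, "separation")
    z = b / se
    p = max(2.0 * stats.norm.sf(abs(z)), P_FLOOR)
    return AssocResult(b, se, float(p), n, "ok")


def _gwas_linear_vectorized(y: np.ndarray, gmat: np.ndarray,
                            covars: np.ndarray) -> Tuple[np.ndarray, ...]:
    """All-SNP OLS via Frisch–Waugh: residualize y and every dosage column
    on the covariate design, then slope = <e_g, e_y> / <e_g, e_g> with a
    t-test on n - n_covariates - 2 degrees of freedom."""
    n = len(y)
    X = _design(covars, n)
    q, _ = np.linalg.qr(X)
    ey = y - q @ (q.T @ y)
    eg = gmat - q @ (q.T @ gmat)
    gg = (eg ** 2).sum(axis=0)
    estimable = gg > 1e-12
    beta = np.full(gmat.shape[1], np.nan)
    se = np.full(gmat.shape[1], np.nan)
    p = np.full(gmat.shape[1], np.nan)
    df = n - X.shape[1] - 1
    gy = eg.T @ ey
    yy = float(ey @ ey)
    with np.errstate(invalid="ignore", divide="ignore"):
        b = gy / gg
        rss = yy - b * gy
        sigma2 = np.maximum(rss, 0.0) / df
        s = np.sqrt(sigma2 / gg)
        t = np.where(s > 0, b / s, np.inf * np.sign(b))
    pv = 2.0 * stats.t.sf(np.abs(t), df)
    beta[estimable] = b[estimable]
    se[estimable] = s[estimable]
    p[estimable] = np.maximum(pv[estimable], P_FLOOR)
    return beta, se, p, estimable


def run_gwas(G: GenotypeMatrix, phenos: pd.DataFrame, trait: str,
             covariates: Optional[Sequence[str]] = None,
             pcs: Optional[PCResult] = None,
             half: int = 0) -> pd.DataFrame:
    """Per-SNP GWAS of one trait with covariate and PC adjustment.

    Linear regression for quantitative traits, logistic for ``t2dm``.
    Complete-case over the trait and covariates; missing dosages are
    mean-imputed (sample size n is therefore constant per run).  The
    effect allele is the minor allele in the analyzed sample; columns
    where it is the stored other allele are flipped before testing so
    betas are comparable across halves.

    Returns a summary-statistics frame with columns
    chrom, id, pos, a1, a2, maf, beta, se, p, n, trait, half, status.
    """
    if trait not in phenos.columns:
        raise ValueError(f"unknown trait {trait!r}")
    if list(phenos.index) != list(G.sample_ids):
        raise ValueError("phenotype table index does not match genotype "
                         "sample_ids")
    cov_names = list(covariates) if covariates is not None else \
        list(DEFAULT_COVARIATES.get(trait, ()))
    for c in cov_names:
        if c not in phenos.columns:
            raise ValueError(f"covariate {c!r} absent from phenotype table")

    complete = phenos[[trait] + cov_names].notna().all(axis=1).to_numpy()
    y = phenos.loc[complete, trait].to_numpy(dtype=float)
    covar_mat = phenos.loc[complete, cov_names].to_numpy(dtype=float) \
        if cov_names else np.empty((int(complete.sum()), 0))
    if pcs is not None:
        covar_mat = np.column_stack([covar_mat, pcs.scores[complete]])
    d = G.dosages[complete].astype(float)
    d[G.dosages[complete] == MISSING] = np.nan
    mu = np.nanmean(d, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    d = np.where(np.isnan(d), mu, d)
    n = d.shape[0]

    freq = d.mean(axis=0) / 2.0
    flip = freq > 0.5
    d[:, flip] = 2.0 - d[:, flip]
    maf = np.minimum(freq, 1.0 - freq)
    a1 = np.where(flip, G.snp_meta["a2"], G.snp_meta["a1"])
    a2 = np.where(flip, G.snp_meta["a1"], G.snp_meta["a2"])

    m = G.n_snps
    status = np.full(m, "ok", dtype=object)
    if trait in LOGISTIC_TRAITS:
        beta = np.full(m, np.nan)
        se = np.full(m, np.nan)
        p = np.full(m, np.nan)
        for j in range(m):
            res = assoc_logistic(y, d[:, j], covar_mat)
            beta[j], se[j], p[j] = res.beta, res.se, res.p
            status[j] = res.status
    else:
        beta, se, p, estimable = _gwas_linear_vectorized(y, d, covar_mat)
        status[~estimable] = "constant"

    return pd.DataFrame(
        {"chrom": G.snp_meta["chrom"].to_numpy(), "id":
         G.snp_meta["id"].to_numpy(), "pos": G.snp_meta["pos"].to_numpy(),
         "a1": a1, "a2": a2, "maf": maf, "beta": beta, "se": se, "p": p,
         "n": n, "trait": trait, "half": half, "status": status})


def genomic_inflation(p: np.ndarray) -> float:
    """Genomic inflation factor: median observed 1-df chi-square statistic
    over its null median (0.4549)."""
    p = np.asarray(p, dtype=float)
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))
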