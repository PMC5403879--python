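"""Per-SNP association tests for a quantitative trait.

``linear_gwas`` fits, for every SNP, ordinary least squares of the
phenotype on intercept + dosage + covariates (typically MDS components)
and reports the 1-df chi-square statistic (beta/se)^2.  P-values use the
chi-square rather than the t reference: the genomic inflation factor is
defined on the chi-square scale, and at the sample sizes considered here
the difference is negligible.

``mlm_loco_gwas`` is the mixed-model alternative: for each chromosome a
single variance-component fit (restricted maximum likelihood under
y = Xb + u + e with cov(u) proportional to the leave-one-chromosome-out
GRM), then generalized least squares per SNP with the fitted covariance —
the EMMAX-style single-fit approximation rather than exact per-SNP REML.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .ancestry import Grm, MdsComponents
from .simulate import MISSING, GenotypeDataset

_P_FLOOR = 5e-324  # smallest positive subnormal; keeps p in (0, 1]


def design_matrix(covariates, n: int) -> np.ndarray:
    """Build the n x (1+c) design [intercept | covariates] and validate it.

    Accepts None, an ndarray/DataFrame of covariate columns, or
    :class:`~stratsim.ancestry.MdsComponents`.  Constant non-intercept
    columns and rank deficiency raise.
    """
    if covariates is None:
        return np.ones((n, 1))
    if isinstance(covariates, MdsComponents):
        c = covariates.scores
    elif isinstance(covariates, pd.DataFrame):
        c = covariates.to_numpy(dtype=np.float64)
    else:
        c = np.asarray(covariates, dtype=np.float64)
    if c.ndim == 1:
        c = c[:, None]
    if c.shape[0] != n:
        raise ValueError(f"covariates have {c.shape[0]} rows, expected {n}")
    if not np.all(np.isfinite(c)):
        raise ValueError("covariates must be finite")
    if c.shape[1] and np.any(c.std(axis=0) == 0):
        raise ValueError("constant covariate column (the intercept is added automatically)")
    x = np.column_stack([np.ones(n), c])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("covariate matrix is rank deficient after adding the intercept")
    return x


def _fwl_stats(g_resid: np.ndarray, gg: np.ndarray, y_resid: np.ndarray,
               df: int) -> tuple[np.ndarray, ...]:
    """OLS slope/se/chi2 for many SNPs from covariate-residualized data.

    By Frisch-Waugh-Lovell the slope of y on [X, g] equals the simple
    regression of X-residualized y on X-residualized g.
    """
    yy = float(y_resid @ y_resid)
    gy = g_resid.T @ y_resid
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = gy / gg
        rss = np.maximum(yy - beta * gy, 0.0)
        sigma2 = rss / df
        se = np.sqrt(sigma2 / gg)
        stat = np.where(se > 0, (beta / se) ** 2, np.inf)
    return beta, se, stat


def linear_gwas(dataset: GenotypeDataset, phenotype: np.ndarray,
                covariates=None) -> pd.DataFrame:
    """Covariate-adjusted per-SNP linear association scan.

    Missing dosages drop that individual for that SNP (per-SNP case
    deletion).  SNPs collinear with the covariates (or monomorphic within
    the analyzed individuals) are flagged undefined: NaN estimates, and
    the count is recorded in ``result.attrs['n_undefined']``.

    Returns a DataFrame with columns SNP, CHR, POS, BETA, SE, STAT, P, N.
    """
    y = np.asarray(phenotype, dtype=np.float64)
    n, m = dataset.genotypes.shape
    if y.shape != (n,):
        raise ValueError(f"phenotype must have length {n}")
    x = design_matrix(covariates, n)
    q_cols = x.shape[1]
    df = n - q_cols - 1
    if df <= 0:
        raise ValueError("not enough residual degrees of freedom")

    q, _ = np.linalg.qr(x)
    y_resid = y - q @ (q.T @ y)

    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    stat = np.full(m, np.nan)
    nobs = np.full(m, n, dtype=np.int64)

    miss_any = (dataset.genotypes == MISSING).any(axis=0)
    complete = ~miss_any
    # tolerance below which the residualized dosage is collinear with X
    gg_tol = 1e-10 * n

    if complete.any():
        g = dataset.genotypes[:, complete].astype(np.float64)
        g_resid = g - q @ (q.T @ g)
        gg = np.einsum("ij,ij->j", g_resid, g_resid)
        ok = gg > gg_tol
        b, s, t = _fwl_stats(g_resid[:, ok], gg[ok], y_resid, df)
        idx = np.where(complete)[0]
        beta[idx[ok]], se[idx[ok]], stat[idx[ok]] = b, s, t

    for j in np.where(miss_any)[0]:
        keep = dataset.genotypes[:, j] != MISSING
        nj = int(keep.sum())
        nobs[j] = nj
        dfj = nj - q_cols - 1
        if dfj <= 0:
            continue
        xj = x[keep]
        if np.linalg.matrix_rank(xj) < q_cols:
            continue
        qj, _ = np.linalg.qr(xj)
        yj = y[keep]
        yjr = yj - qj @ (qj.T @ yj)
        gj = dataset.genotypes[keep, j].astype(np.float64)
        gjr = gj - qj @ (qj.T @ gj)
        ggj = float(gjr @ gjr)
        if ggj <= 1e-10 * nj:
            continue
        b, s, t = _fwl_stats(gjr[:, None], np.array([ggj]), yjr, dfj)
        beta[j], se[j], stat[j] = b[0], s[0], t[0]

    with np.errstate(invalid="ignore"):
        pval = stats.chi2.sf(stat, df=1)
    pval = np.where(np.isfinite(stat), np.maximum(pval, _P_FLOOR), np.nan)

    out = pd.DataFrame({
        "SNP": dataset.snp_meta["snp_id"].to_numpy(),
        "CHR": dataset.snp_meta["chrom"].to_numpy(),
        "POS": dataset.snp_meta["pos_bp"].to_numpy(),
        "BETA": beta,
        "SE": se,
        "STAT": stat,
        "P": pval,
        "N": nobs,
    })
    out.attrs["n_undefined"] = int(np.isnan(beta).sum())
    return out


# ---------------------------------------------------------------------------
# mixed model (EMMAX-style single variance-component fit per chromosome)


def _reml_neg2ll(log_delta: float, lam: np.ndarray, uty: np.ndarray,
                 utx: np.ndarray) -> float:
    """-2 x restricted log-likelihood profiled over sigma_g^2.

    delta = sigma_e^2 / sigma_g^2; lam are GRM eigenvalues; uty/utx the
    rotated phenotype and fixed-effect design.
    """
    delta = np.exp(log_delta)
    w = 1.0 / (lam + delta)
    xtwx = (utx * w[:, None]).T @ utx
    xtwy = (utx * w[:, None]).T @ uty
    try:
        chol = np.linalg.cholesky(xtwx)
    except np.linalg.LinAlgError:
        return np.inf
    beta = np.linalg.solve(xtwx, xtwy)
    r = uty - utx @ beta
    nq = lam.size - utx.shape[1]
    rwr = float(r @ (w * r))
    if rwr <= 0:
        return np.inf
    logdet_xtwx = 2.0 * float(np.sum(np.log(np.diag(chol))))
    return (nq * np.log(rwr / nq) + float(np.sum(np.log(lam + delta)))
            + logdet_xtwx + nq)


def _fit_reml(lam: np.ndarray, uty: np.ndarray, utx: np.ndarray,
              tol: float = 1e-8) -> tuple[float, float, float]:
    """Scalar REML on the log variance ratio; returns (delta, s2g, s2e).

    Bounded searches restarted from three fixed initial brackets for
    robustness at small n.
    """
    best = (np.inf, 0.0)
    for lo, hi in ((-12.0, 0.0), (-4.0, 4.0), (0.0, 12.0)):
        res = minimize_scalar(_reml_neg2ll, bounds=(lo, hi), args=(lam, uty, utx),
                              method="bounded", options={"xatol": tol})
        if res.fun < best[0]:
            best = (float(res.fun), float(res.x))
    if not np.isfinite(best[0]):
        raise RuntimeError("REML failed to converge")
    delta = float(np.exp(best[1]))
    w = 1.0 / (lam + delta)
    xtwx = (utx * w[:, None]).T @ utx
    beta = np.linalg.solve(xtwx, (utx * w[:, None]).T @ uty)
    r = uty - utx @ beta
    nq = lam.size - utx.shape[1]
    s2g = float(r @ (w * r)) / nq
    return delta, s2g, delta * s2g


def mlm_loco_gwas(dataset: GenotypeDataset, phenotype: np.ndarray,
                  covariates, loco: dict) -> pd.DataFrame:
    """Mixed-model LOCO association scan.

    ``loco`` maps chromosome -> :class:`Grm` built from all other
    chromosomes.  Variance components are fitted once per chromosome; each
    SNP on that chromosome is then tested by GLS under the fitted
    covariance.  Missing dosages are mean-imputed so that the single
    per-chromosome covariance fit applies to all its SNPs.

    The result table matches :func:`linear_gwas`; fitted variance
    components per chromosome are stored in ``attrs['variance_components']``
    and chromosomes whose REML fit failed in ``attrs['failed_chromosomes']``.
    """
    y = np.asarray(phenotype, dtype=np.float64)
    n, m = dataset.genotypes.shape
    x = design_matrix(covariates, n)
    q_cols = x.shape[1]
    chrom_col = dataset.snp_meta["chrom"].to_numpy()
    chroms = np.unique(chrom_col)
    missing_loco = [int(c) for c in chroms if int(c) not in loco]
    if missing_loco:
        raise ValueError(f"no LOCO GRM supplied for chromosomes {missing_loco}")

    g_all = dataset.dosages(impute_mean=True)

    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    stat = np.full(m, np.nan)
    vc: dict[int, tuple[float, float]] = {}
    failed: list[int] = []

    for c in chroms:
        c = int(c)
        grm: Grm = loco[c]
        lam, u = np.linalg.eigh(grm.values)
        lam = np.maximum(lam, 0.0)
        uty = u.T @ y
        utx = u.T @ x
        try:
            delta, s2g, s2e = _fit_reml(lam, uty, utx)
        except (RuntimeError, np.linalg.LinAlgError):
            failed.append(c)
            continue
        vc[c] = (s2g, s2e)
        sw = 1.0 / np.sqrt(lam + delta)
        ys = sw * uty
        xs = utx * sw[:, None]
        qmat, _ = np.linalg.qr(xs)
        ys_r = ys - qmat @ (qmat.T @ ys)
        idx = np.where(chrom_col == c)[0]
        gs = (u.T @ g_all[:, idx]) * sw[:, None]
        gs_r = gs - qmat @ (qmat.T @ gs)
        gg = np.einsum("ij,ij->j", gs_r, gs_r)
        df = n - q_cols - 1
        ok = gg > 1e-10 * n
        b, s, t = _fwl_stats(gs_r[:, ok], gg[ok], ys_r, df)
        beta[idx[ok]], se[idx[ok]], stat[idx[ok]] = b, s, t

    with np.errstate(invalid="ignore"):
        pval = stats.chi2.sf(stat, df=1)
    pval = np.where(np.isfinite(stat), np.maximum(pval, _P_FLOOR), np.nan)

    out = pd.DataFrame({
        "SNP": dataset.snp_meta["snp_id"].to_numpy(),
        "CHR": chrom_col,
        "POS": dataset.snp_meta["pos_bp"].to_numpy(),
        "BETA": beta,
        "SE": se,
        "STAT": stat,
        "P": pval,
        "N": np.full(m, n, dtype=np.int64),
    })
    out.attrs["variance_components"] = vc
    out.attrs["failed_chromosomes"] = failed
    out.attrs["n_undefined"] = int(np.isnan(beta).sum())
    return out
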