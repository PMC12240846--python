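"""Phenotype preparation for a two-site cohort, plus trait summaries.

The two testing sites of an HS behavioral study differ in location and scale,
so traits are prepared per site before merging: covariates (including sex)
that explain more than 2% of the within-site trait variance are regressed
out, the residuals are rank inverse-normal transformed within site (which
equalizes the per-site variances and so weighs the sites equally), the sites
are pooled, and the pooled vector is inverse-normal transformed once more so
the final phenotype is marginally Gaussian — which is also what justifies a
single permutation significance threshold across traits downstream.

Also provides Spearman/Bonferroni trait correlation matrices and a
PCA-with-varimax summary (components retained at eigenvalue >= 1, loadings
displayed at |loading| >= 0.3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "PreparedPhenotype",
    "CorrelationMatrix",
    "PcaResult",
    "quantile_normalize",
    "covariate_variance_explained",
    "prepare_trait",
    "correlation_matrix",
    "pca_varimax",
    "varimax",
]


@dataclass
class PreparedPhenotype:
    """A GWAS-ready trait vector with preparation provenance."""

    trait: str
    values: pd.Series  # indexed by individual id; NaN where missing
    provenance: dict = field(default_factory=dict)


@dataclass
class CorrelationMatrix:
    rho: pd.DataFrame
    p: pd.DataFrame
    p_adjusted: pd.DataFrame
    n: pd.DataFrame
    n_pairs_tested: int


@dataclass
class PcaResult:
    eigenvalues: np.ndarray  # retained components only
    loadings: pd.DataFrame  # trait x component, varimax-rotated
    loading_mask: pd.DataFrame  # |loading| >= threshold
    threshold: float


def quantile_normalize(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform (Blom offset by default).

    Non-missing value with average rank r among n non-missing entries maps to
    Phi^{-1}((r - 3/8) / (n + 1/4)); ties share their average rank; missing
    entries are preserved.  With all values identical, everything maps to 0.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    ok = ~np.isnan(x)
    n = int(ok.sum())
    if n < 2:
        if n == 1:
            out[ok] = 0.0
        return out
    ranks = stats.rankdata(x[ok], method="average")
    out[ok] = stats.norm.ppf((ranks - offset) / (n + 1 - 2 * offset))
    return out


def covariate_variance_explained(trait, covariate) -> float:
    """Fraction of trait variance explained by one covariate (R^2).

    Numeric covariates use the squared Pearson correlation; categorical ones
    are one-hot encoded and R^2 comes from the multi-column least-squares fit.
    A constant covariate explains nothing (R^2 = 0).
    """
    y = pd.Series(trait).reset_index(drop=True)
    c = pd.Series(covariate).reset_index(drop=True)
    ok = y.notna() & c.notna()
    if int(ok.sum()) < 3:
        raise ValueError("need at least 3 paired non-missing observations")
    y = y[ok].to_numpy(dtype=float)
    c = c[ok]
    if c.nunique() < 2:
        return 0.0
    if pd.api.types.is_numeric_dtype(c):
        X = c.to_numpy(dtype=float)[:, None]
    else:
        X = pd.get_dummies(c, drop_first=True).to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        return 0.0
    return float(max(0.0, 1.0 - float(np.sum(resid ** 2)) / tss))


def _regress_out(y: np.ndarray, table: pd.DataFrame, covs: list[str]) -> np.ndarray:
    """Residuals of y on the selected covariates (complete cases only)."""
    if not covs:
        return y - np.nanmean(y)
    cols = [np.ones(len(y))]
    for c in covs:
        s = table[c]
        if pd.api.types.is_numeric_dtype(s):
            cols.append(s.to_numpy(dtype=float))
        else:
            cols.append(pd.get_dummies(s, drop_first=True).to_numpy(dtype=float))
    X = np.column_stack(cols)
    out = np.full(y.shape, np.nan)
    ok = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
    beta, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
    out[ok] = y[ok] - X[ok] @ beta
    return out


def prepare_trait(table: pd.DataFrame, trait: str,
                  candidate_covariates: list[str] | None = None,
                  r2_threshold: float = 0.02,
                  min_per_site: int = 10) -> PreparedPhenotype:
    """Two-site preparation: screen covariates, residualize and INT per site,
    pool, and INT once more.

    Covariate screening is marginal: within each site, each candidate is kept
    when its univariate R^2 on the raw trait exceeds ``r2_threshold``; the
    selected covariates are then regressed out jointly.  Missing trait values
    stay missing; a site with no usable values contributes nothing and is
    flagged in the provenance record.
    """
    if trait not in table.columns:
        raise KeyError(f"trait {trait!r} not in table")
    candidate_covariates = candidate_covariates or []
    y_all = np.full(len(table), np.nan)
    prov: dict = {"trait": trait, "per_site": {}}
    for site, idx in table.groupby("site", sort=True).groups.items():
        sub = table.loc[idx]
        y = sub[trait].to_numpy(dtype=float)
        n_ok = int(np.sum(~np.isnan(y)))
        if n_ok == 0:
            prov["per_site"][str(site)] = {"n": 0, "covariates": [], "skipped": True}
            continue
        if n_ok < min_per_site:
            raise ValueError(
                f"site {site!r} has only {n_ok} non-missing values for {trait!r} "
                f"(need >= {min_per_site})"
            )
        selected = []
        for cov in candidate_covariates:
            try:
                r2 = covariate_variance_explained(y, sub[cov])
            except ValueError:
                continue
            if r2 > r2_threshold:
                selected.append(cov)
        resid = _regress_out(y, sub, selected)
        y_all[table.index.get_indexer(idx)] = quantile_normalize(resid)
        prov["per_site"][str(site)] = {"n": n_ok, "covariates": selected}
    pooled = quantile_normalize(y_all)
    return PreparedPhenotype(
        trait=trait,
        values=pd.Series(pooled, index=table["id"].to_numpy(), name=trait),
        provenance=prov,
    )


def correlation_matrix(prepared: dict[str, pd.Series] | pd.DataFrame) -> CorrelationMatrix:
    """Pairwise-complete Spearman correlations with Bonferroni adjustment.

    The adjustment multiplies each raw two-sided p by the number of distinct
    trait pairs tested (capped at 1).  Pairs with fewer than 3 complete cases
    get NaN rho and p.
    """
    df = pd.DataFrame(prepared)
    traits = list(df.columns)
    if len(traits) < 2:
        raise ValueError("need at least 2 traits")
    k = len(traits)
    rho = np.eye(k)
    p = np.zeros((k, k))
    nmat = np.zeros((k, k), dtype=int)
    np.fill_diagonal(nmat, df.notna().sum().to_numpy())
    m = k * (k - 1) // 2
    for i in range(k):
        for j in range(i + 1, k):
            ok = df.iloc[:, i].notna() & df.iloc[:, j].notna()
            nmat[i, j] = nmat[j, i] = int(ok.sum())
            if ok.sum() < 3:
                rho[i, j] = rho[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            r, pv = stats.spearmanr(df.iloc[:, i][ok], df.iloc[:, j][ok])
            rho[i, j] = rho[j, i] = r
            p[i, j] = p[j, i] = pv
    padj = np.minimum(1.0, p * m)
    np.fill_diagonal(padj, 0.0)
    wrap = lambda a: pd.DataFrame(a, index=traits, columns=traits)
    return CorrelationMatrix(rho=wrap(rho), p=wrap(p), p_adjusted=wrap(padj),
                             n=wrap(nmat), n_pairs_tested=m)


def varimax(loadings: np.ndarray, max_iter: int = 100, tol: float = 1e-10,
            kaiser_normalize: bool = True) -> np.ndarray:
    """Varimax rotation by pairwise Jacobi planar rotations (Kaiser).

    The planar-rotation form solves each 2-factor subproblem exactly, so it
    does not stall on the balanced saddle points where gradient-style
    implementations can sit (e.g. two equally strong factors).  Rows are
    Kaiser-normalized to unit communality during rotation by default, the
    convention of the classic SPSS varimax.
    """
    L = np.array(loadings, dtype=float)
    p, k = L.shape
    if k < 2:
        return L
    comm = np.sqrt(np.sum(L ** 2, axis=1))
    if kaiser_normalize:
        safe = np.where(comm > 0, comm, 1.0)
        L = L / safe[:, None]
    for _ in range(max_iter):
        total_rotation = 0.0
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = L[:, i], L[:, j]
                u = x ** 2 - y ** 2
                v = 2.0 * x * y
                A, B = u.sum(), v.sum()
                C = float(u @ u - v @ v)
                D = float(2.0 * (u @ v))
                num = D - 2.0 * A * B / p
                den = C - (A ** 2 - B ** 2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-12:
                    continue
                c, s = np.cos(phi), np.sin(phi)
                L[:, i], L[:, j] = c * x + s * y, -s * x + c * y
                total_rotation += abs(phi)
        if total_rotation < tol:
            break
    if kaiser_normalize:
        L = L * np.where(comm > 0, comm, 1.0)[:, None]
    return L


def pca_varimax(prepared: dict[str, pd.Series] | pd.DataFrame,
                loading_threshold: float = 0.3) -> PcaResult:
    """PCA on the trait correlation matrix with Kaiser retention and varimax.

    Components with eigenvalue >= 1 are retained, their loadings (eigenvector
    times sqrt(eigenvalue)) are varimax-rotated, and the display mask marks
    |loading| >= ``loading_threshold``.  Complete cases only.
    """
    df = pd.DataFrame(prepared).dropna()
    traits = list(df.columns)
    if len(df) <= len(traits):
        raise ValueError("need more complete cases than traits")
    C = np.corrcoef(df.to_numpy(dtype=float), rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(C)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    keep = eigvals >= 1.0
    if not keep.any():
        log.warning("pca_varimax: no component reaches eigenvalue 1")
        empty = pd.DataFrame(index=traits)
        return PcaResult(eigenvalues=np.array([]), loadings=empty,
                         loading_mask=empty.astype(bool), threshold=loading_threshold)
    ev = eigvals[keep]
    L = eigvecs[:, keep] * np.sqrt(ev)[None, :]
    Lrot = varimax(L)
    # orient each component so its largest-magnitude loading is positive
    for j in range(Lrot.shape[1]):
        if Lrot[np.argmax(np.abs(Lrot[:, j])), j] < 0:
            Lrot[:, j] = -Lrot[:, j]
    cols = [f"PC{i + 1}" for i in range(Lrot.shape[1])]
    loadings = pd.DataFrame(Lrot, index=traits, columns=cols)
    return PcaResult(eigenvalues=ev, loadings=loadings,
                     loading_mask=loadings.abs() >= loading_threshold,
                     threshold=loading_threshold)
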