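"""Genetic relatedness matrices and REML estimation of SNP heritability.

The GRM follows the GCTA convention: per-SNP standardized genotypes,
A_jk = (1/m) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),
with missing dosages mean-imputed per SNP and monomorphic SNPs skipped.
Leave-one-chromosome-out (LOCO) GRMs exclude the tested chromosome so the
polygenic random effect cannot absorb the tested SNP (proximal
contamination); the SNP-count-weighted average of the LOCO GRMs is exactly
the full GRM.

Heritability is estimated with single-component GREML: y = Xb + g + e,
g ~ (0, sigma_g^2 A), e ~ (0, sigma_e^2 I).  The solver works in the
eigenbasis of A (one O(n^3) decomposition, then O(n) per iteration) and runs
Average-Information updates guarded by EM fallback steps, with variance
components clamped at zero.  The null hypothesis h^2 = 0 is tested with the
boundary likelihood-ratio test (0.5 chi2_0 + 0.5 chi2_1 mixture).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genoqc import GenotypeMatrix, chrom_sort_key

log = logging.getLogger(__name__)

__all__ = [
    "Grm",
    "VarCompFit",
    "compute_grm",
    "compute_loco_grms",
    "fit_greml",
    "write_grm",
    "read_grm",
]


@dataclass
class Grm:
    """A symmetric relatedness matrix with provenance."""

    ids: list[str]
    values: np.ndarray  # n x n
    n_snps: int
    excluded_chrom: str | None = None
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition (eigenvalues, eigenvectors)."""
        if self._eig is None:
            D, U = np.linalg.eigh(self.values)
            self._eig = (np.maximum(D, 0.0), U)
        return self._eig


@dataclass
class VarCompFit:
    sigma2_g: float
    sigma2_e: float
    h2: float
    se_h2: float
    log_likelihood: float
    null_log_likelihood: float
    lrt: float
    lrt_p: float
    converged: bool
    n_iter: int
    final_gradient_norm: float
    n: int
    warnings: list[str] = field(default_factory=list)


def compute_grm(G: GenotypeMatrix, exclude_chrom: str | None = None) -> Grm:
    """GCTA-style GRM over the included SNPs (optionally excluding one chromosome)."""
    chroms = G.snps["chrom"].astype(str).to_numpy()
    include = np.ones(G.n_snps, dtype=bool)
    if exclude_chrom is not None:
        include &= chroms != str(exclude_chrom)
    if not include.any():
        raise ValueError("all SNPs excluded from the GRM")
    X = G.imputed_dosages()[:, include]
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic SNPs available for the GRM")
    X = X[:, poly]
    p = p[poly]
    Z = (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    m = Z.shape[1]
    A = (Z @ Z.T) / m
    return Grm(ids=list(G.ids), values=A, n_snps=m,
               excluded_chrom=None if exclude_chrom is None else str(exclude_chrom))


def compute_loco_grms(G: GenotypeMatrix) -> dict[str, Grm]:
    """One GRM per chromosome, each excluding that chromosome's SNPs."""
    chroms = G.chroms
    if len(chroms) < 2:
        raise ValueError(
            "LOCO GRMs need >= 2 chromosomes; use the full GRM (compute_grm) instead"
        )
    return {c: compute_grm(G, exclude_chrom=c) for c in chroms}


def write_grm(grm: Grm, prefix, binary: bool = False) -> None:
    """Write a GRM as TSV (id pairs, lower triangle) or the GCTA binary dialect."""
    prefix = str(prefix)
    n = len(grm.ids)
    if binary:
        tri = grm.values[np.tril_indices(n)]
        tri.astype(np.float32).tofile(prefix + ".grm.bin")
        np.full(tri.shape, grm.n_snps, dtype=np.float32).tofile(prefix + ".grm.N.bin")
        with open(prefix + ".grm.id", "w") as fh:
            for iid in grm.ids:
                fh.write(f"{iid}\t{iid}\n")
    else:
        with open(prefix + ".grm.tsv", "w") as fh:
            fh.write("id1\tid2\tvalue\n")
            for j in range(n):
                for k in range(j + 1):
                    fh.write(f"{grm.ids[j]}\t{grm.ids[k]}\t{grm.values[j, k]:.10g}\n")


def read_grm(prefix, binary: bool = False, n_snps: int = 0) -> Grm:
    prefix = str(prefix)
    if binary:
        ids = [l.split()[1] for l in open(prefix + ".grm.id")]
        n = len(ids)
        tri = np.fromfile(prefix + ".grm.bin", dtype=np.float32).astype(float)
        A = np.zeros((n, n))
        A[np.tril_indices(n)] = tri
        A = A + np.tril(A, -1).T
        nsnp = int(np.fromfile(prefix + ".grm.N.bin", dtype=np.float32)[0])
        return Grm(ids=ids, values=A, n_snps=nsnp)
    df = pd.read_csv(prefix + ".grm.tsv", sep="\t")
    ids = list(dict.fromkeys(df["id1"]))
    index = {iid: i for i, iid in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    for r in df.itertuples(index=False):
        j, k = index[r.id1], index[r.id2]
        A[j, k] = A[k, j] = r.value
    return Grm(ids=ids, values=A, n_snps=n_snps)


# ---------------------------------------------------------------------------
# AI-REML in the eigenbasis of the GRM
# ---------------------------------------------------------------------------

def _reml_pieces(theta, D, ys, Xs):
    """Restricted log-likelihood and its derivative ingredients.

    Works in the eigenbasis of A, where V = sigma_g^2 diag(D) + sigma_e^2 I
    is diagonal.  Returns (loglik, grad, AI, Py) for theta = (sg2, se2).
    """
    sg2, se2 = theta
    w = sg2 * D + se2
    if np.any(w <= 0):
        return -np.inf, None, None, None
    wi = 1.0 / w
    XtWX = Xs.T @ (Xs * wi[:, None])
    try:
        XtWX_chol = np.linalg.cholesky(XtWX)
    except np.linalg.LinAlgError:
        return -np.inf, None, None, None
    logdet_XtWX = 2.0 * float(np.sum(np.log(np.diag(XtWX_chol))))

    def P(v):
        wv = wi * v
        rhs = Xs.T @ wv
        sol = np.linalg.solve(XtWX, rhs)
        return wv - wi * (Xs @ sol)

    Py = P(ys)
    yPy = float(ys @ Py)
    ll = -0.5 * (float(np.sum(np.log(w))) + logdet_XtWX + yPy)

    # traces: tr(P M) for M = diag(D) and M = I
    B = np.linalg.solve(XtWX, Xs.T * wi[None, :])  # k x n
    # tr(P diag(d)) = sum(d * wi) - sum over diag of (Xs B)^T scaled
    xb_diag = np.einsum("ij,ji->i", Xs, B)  # diag of Xs (XtWX)^-1 Xs' W^-1
    trPD = float(np.sum(D * wi)) - float(np.sum(D * wi * xb_diag))
    trPI = float(np.sum(wi)) - float(np.sum(wi * xb_diag))

    PDPy = P(D * Py)
    PPy = P(Py)
    grad = np.array([
        -0.5 * (trPD - float(Py @ (D * Py))),
        -0.5 * (trPI - float(Py @ Py)),
    ])
    AI = 0.5 * np.array([
        [float((D * Py) @ PDPy), float((D * Py) @ PPy)],
        [float((D * Py) @ PPy), float(Py @ PPy)],
    ])
    return ll, grad, AI, Py


def fit_greml(y, grm: Grm, covariates: np.ndarray | None = None,
              max_iter: int = 100, tol: float = 1e-6,
              fixed: tuple[float, float] | None = None) -> VarCompFit:
    """Single-component GREML fit of y on the GRM.

    Parameters
    ----------
    y : array-like or :class:`~hsqtl.phenoprep.PreparedPhenotype`-style Series
        Phenotype aligned with ``grm.ids``; NaN entries (and their GRM rows)
        are dropped.
    covariates : optional fixed-effect design (without intercept); default is
        intercept only.
    fixed : optionally pin (sigma_g^2, sigma_e^2) and skip estimation.
    """
    yv = np.asarray(getattr(y, "values", y), dtype=float).ravel()
    if yv.shape[0] != len(grm.ids):
        raise ValueError("phenotype length does not match GRM")
    X = np.ones((yv.shape[0], 1))
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([X, C])
    ok = ~np.isnan(yv) & ~np.isnan(X).any(axis=1)
    yv, X = yv[ok], X[ok]
    n, k = X.shape
    if n <= k + 2:
        raise ValueError("too few complete cases for GREML")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("singular covariate design")

    warnings: list[str] = []
    if ok.all():
        D, U = grm.eig()
    else:
        A = grm.values[np.ix_(ok, ok)]
        D, U = np.linalg.eigh(A)
        D = np.maximum(D, 0.0)
    if float(np.std(D)) < 1e-8:
        warnings.append("GRM is (numerically) proportional to identity; "
                        "sigma_g^2 and sigma_e^2 are not separately identifiable")
    ys = U.T @ yv
    Xs = U.T @ X

    vary = float(np.var(yv, ddof=1))
    # null model: sg2 = 0, se2 = REML residual variance of y ~ X
    beta0, *_ = np.linalg.lstsq(X, yv, rcond=None)
    rss = float(np.sum((yv - X @ beta0) ** 2))
    se2_null = rss / (n - k)
    ll_null, *_ = _reml_pieces((0.0, se2_null), D, ys, Xs)

    if fixed is not None:
        theta = np.array(fixed, dtype=float)
        ll, grad, AI, _ = _reml_pieces(theta, D, ys, Xs)
        grad_norm, it, converged = 0.0, 0, True
    else:
        theta = np.array([vary / 2.0, vary / 2.0])
        floor = vary * 1e-8
        ll, grad, AI, _ = _reml_pieces(theta, D, ys, Xs)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            if it == 1:
                # one EM-flavored step first for stability
                step = (theta ** 2) * grad * (2.0 / n)
            else:
                try:
                    step = np.linalg.solve(AI, grad)
                except np.linalg.LinAlgError:
                    step = (theta ** 2) * grad * (2.0 / n)
            new_theta = np.maximum(theta + step, 0.0)
            new_theta = np.where(new_theta == 0.0, floor, new_theta)
            new_ll, new_grad, new_AI, _ = _reml_pieces(new_theta, D, ys, Xs)
            halves = 0
            while new_ll < ll - 1e-10 and halves < 30:
                step = step / 2.0
                new_theta = np.maximum(theta + step, 0.0)
                new_theta = np.where(new_theta == 0.0, floor, new_theta)
                new_ll, new_grad, new_AI, _ = _reml_pieces(new_theta, D, ys, Xs)
                halves += 1
            if not np.isfinite(new_ll):
                warnings.append("REML likelihood became non-finite; stopped early")
                break
            delta = new_ll - ll
            theta, ll, grad, AI = new_theta, new_ll, new_grad, new_AI
            if abs(delta) < tol:
                converged = True
                break
        if not converged:
            warnings.append(f"REML did not converge in {max_iter} iterations")
        grad_norm = float(np.linalg.norm(grad))

    sg2, se2 = float(theta[0]), float(theta[1])
    # treat a floor-level component as an exact zero boundary estimate
    if sg2 <= vary * 1e-6:
        sg2 = 0.0
    tot = sg2 + se2
    h2 = sg2 / tot if tot > 0 else 0.0

    # delta-method SE from the inverse AI matrix
    se_h2 = float("nan")
    if AI is not None:
        try:
            cov = np.linalg.inv(AI)
            grad_h = np.array([se2, -sg2]) / tot ** 2
            v = float(grad_h @ cov @ grad_h)
            se_h2 = float(np.sqrt(v)) if v >= 0 else float("nan")
        except np.linalg.LinAlgError:
            pass

    lrt = max(0.0, 2.0 * (ll - ll_null))
    lrt_p = 1.0 if lrt <= 1e-12 else 0.5 * float(stats.chi2.sf(lrt, df=1))
    return VarCompFit(
        sigma2_g=sg2, sigma2_e=se2, h2=h2, se_h2=se_h2,
        log_likelihood=float(ll), null_log_likelihood=float(ll_null),
        lrt=lrt, lrt_p=lrt_p, converged=bool(converged), n_iter=it,
        final_gradient_norm=float(grad_norm) if fixed is None else 0.0,
        n=n, warnings=warnings,
    )
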