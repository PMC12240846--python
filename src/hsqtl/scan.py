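"""LOCO mixed-model association and the QTL-calling machinery.

Association follows the GCTA-MLMA convention: for the SNPs of chromosome c,
variance components are estimated once by REML under the leave-one-
chromosome-out GRM for c and then held fixed; each SNP's additive effect is
tested by generalized least squares under V = sigma_g^2 A_loco(c) +
sigma_e^2 I with a two-sided Wald test.  Everything is computed in the
eigenbasis of each LOCO GRM, and a reusable workspace caches the
eigendecompositions and rotated genotype blocks so that permutation
thresholds and repeated null scans cost only a per-phenotype rotation.

QTL calling implements the study's rules: a genome-wide threshold taken as
the empirical (1 - alpha) quantile of permuted genome-wide maxima; a peak is
reported only with at least one supporting SNP within 0.5 Mb and within
2 -log10(p) units (inclusive); independent signals on a chromosome are found
by conditioning on the peak dosage and re-scanning that chromosome until
nothing passes; interval boundaries are the outermost SNPs with r^2 >= 0.6
to the peak within a 10 Mb search window; expression/coding annotations are
matched within a 3 Mb colocation window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genoqc import GenotypeMatrix, chrom_sort_key
from .varcomp import Grm, fit_greml, _reml_pieces

log = logging.getLogger(__name__)

__all__ = [
    "ScanResult",
    "SignificanceThreshold",
    "Qtl",
    "LocoWorkspace",
    "assoc_scan",
    "permutation_threshold",
    "ld_r2",
    "call_qtls",
    "iterative_conditional_mapping",
    "qtl_interval",
    "colocate",
    "phewas_lookup",
]

_LOG10 = np.log(10.0)


@dataclass
class ScanResult:
    """Per-SNP association records for one trait (sorted by chrom, pos)."""

    trait: str
    records: pd.DataFrame  # chrom, pos, id, beta, se, neglog10_p
    conditioning_snps: list[str] = field(default_factory=list)
    threshold: float | None = None

    def max_record(self):
        r = self.records.dropna(subset=["neglog10_p"])
        if r.empty:
            return None
        return r.loc[r["neglog10_p"].idxmax()]


@dataclass
class SignificanceThreshold:
    alpha: float
    n_permutations: int
    value: float  # on the -log10 p scale
    maxima: np.ndarray | None = None


@dataclass
class Qtl:
    trait: str
    chrom: str
    peak_snp: str
    peak_pos: int
    peak_neglog10_p: float
    support_count: int
    interval_start_bp: int
    interval_end_bp: int
    conditioning_round: int


class LocoWorkspace:
    """Cached per-chromosome eigendecompositions and rotated genotypes.

    Building the workspace costs one eigendecomposition and one dense
    rotation per chromosome; afterwards each scan of a new phenotype on the
    same genotypes only needs O(n^2) per chromosome.
    """

    def __init__(self, G: GenotypeMatrix, loco_grms: dict[str, Grm]):
        self.G = G
        self.X = G.imputed_dosages()
        self.chroms = [c for c in G.chroms if c in loco_grms]
        if not self.chroms:
            raise ValueError("no chromosome shared between genotypes and LOCO GRMs")
        self.cols: dict[str, np.ndarray] = {}
        self.U: dict[str, np.ndarray] = {}
        self.D: dict[str, np.ndarray] = {}
        self.G_rot: dict[str, np.ndarray] = {}
        chrom_arr = G.snps["chrom"].astype(str).to_numpy()
        for c in self.chroms:
            cols = np.flatnonzero(chrom_arr == c)
            D, U = loco_grms[c].eig()
            self.cols[c] = cols
            self.U[c] = U
            self.D[c] = D
            self.G_rot[c] = U.T @ self.X[:, cols]


def _neglog10_from_z(z: np.ndarray) -> np.ndarray:
    """-log10 of the two-sided normal p, safe for huge |z|."""
    logp = np.log(2.0) + stats.norm.logsf(np.abs(z))
    return -logp / _LOG10


def _scan_chrom(ws: LocoWorkspace, c: str, y: np.ndarray, X: np.ndarray,
                variance_components: tuple[float, float] | None):
    """Test every SNP of chromosome c.  Returns (beta, se, neglog10_p)."""
    U, D = ws.U[c], ws.D[c]
    ys = U.T @ y
    Xs = U.T @ X
    if variance_components is None:
        grm = Grm(ids=list(ws.G.ids), values=np.empty((0, 0)), n_snps=0)
        grm._eig = (D, U)
        fit = fit_greml(y, grm, covariates=X[:, 1:] if X.shape[1] > 1 else None)
        sg2, se2 = fit.sigma2_g, fit.sigma2_e
    else:
        sg2, se2 = variance_components
    w = sg2 * D + se2
    if np.any(w <= 0):
        raise ValueError("non-positive phenotypic variance on chromosome " + c)
    sw = 1.0 / np.sqrt(w)
    yt = ys * sw
    Xt = Xs * sw[:, None]
    Q, _ = np.linalg.qr(Xt)
    ry = yt - Q @ (Q.T @ yt)
    Gt = ws.G_rot[c] * sw[:, None]
    RG = Gt - Q @ (Q.T @ Gt)
    xx = np.einsum("ij,ij->j", RG, RG)
    xy = RG.T @ ry
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = xy / xx
        se = 1.0 / np.sqrt(xx)
        z = xy / np.sqrt(xx)
    bad = xx <= 1e-10  # monomorphic or collinear with the covariates
    beta[bad] = np.nan
    se[bad] = np.nan
    neglog = np.full(z.shape, np.nan)
    good = ~bad
    neglog[good] = _neglog10_from_z(z[good])
    return beta, se, neglog


def _build_design(ws: LocoWorkspace, covariates, conditioning_snps) -> np.ndarray:
    n = ws.G.n_individuals
    cols = [np.ones(n)]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        cols.append(C)
    for sid in conditioning_snps:
        cols.append(ws.X[:, ws.G.snp_index(sid)])
    return np.column_stack(cols)


def _align_y(y, G: GenotypeMatrix) -> np.ndarray:
    if hasattr(y, "values") and hasattr(y, "trait"):  # PreparedPhenotype
        return y.values.reindex(G.ids).to_numpy(dtype=float)
    if isinstance(y, pd.Series):
        return y.reindex(G.ids).to_numpy(dtype=float) if not y.index.equals(
            pd.RangeIndex(len(y))) else y.to_numpy(dtype=float)
    return np.asarray(y, dtype=float).ravel()


def assoc_scan(y, G: GenotypeMatrix, loco_grms: dict[str, Grm],
               covariates=None, conditioning_snps: list[str] = (),
               variance_components: tuple[float, float] | None = None,
               chroms: list[str] | None = None,
               workspace: LocoWorkspace | None = None,
               trait: str = "trait") -> ScanResult:
    """LOCO mixed-model single-SNP association scan.

    Missing phenotypes restrict the analysis to complete cases (which
    bypasses any supplied workspace).  ``conditioning_snps`` enter the fixed
    design as dosage covariates; a SNP collinear with them is marked
    untestable (NaN).  ``variance_components`` pins (sigma_g^2, sigma_e^2),
    e.g. ``(0, s2)`` reduces the scan to ordinary least squares.
    """
    yv = _align_y(y, G)
    ok = ~np.isnan(yv)
    if not ok.all():
        keep = np.flatnonzero(ok)
        Gs = GenotypeMatrix(ids=[G.ids[i] for i in keep], snps=G.snps.copy(),
                            dosages=G.dosages[keep])
        sub_grms = {
            c: Grm(ids=Gs.ids, values=g.values[np.ix_(keep, keep)],
                   n_snps=g.n_snps, excluded_chrom=g.excluded_chrom)
            for c, g in loco_grms.items()
        }
        cov = None
        if covariates is not None:
            C = np.asarray(covariates, dtype=float)
            cov = C[keep] if C.ndim > 1 else C[keep]
        return assoc_scan(yv[keep], Gs, sub_grms, covariates=cov,
                          conditioning_snps=conditioning_snps,
                          variance_components=variance_components,
                          chroms=chroms, trait=trait)
    if workspace is None:
        workspace = LocoWorkspace(G, loco_grms)
    X = _build_design(workspace, covariates, conditioning_snps)
    scan_chroms = workspace.chroms if chroms is None else [
        c for c in workspace.chroms if c in set(map(str, chroms))]
    m = G.n_snps
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    neglog = np.full(m, np.nan)
    for c in scan_chroms:
        b, s, nl = _scan_chrom(workspace, c, yv, X, variance_components)
        cols = workspace.cols[c]
        beta[cols], se[cols], neglog[cols] = b, s, nl
    records = pd.DataFrame({
        "chrom": G.snps["chrom"].astype(str),
        "pos": G.snps["pos"].astype(int),
        "id": G.snps["id"],
        "beta": beta, "se": se, "neglog10_p": neglog,
    })
    if chroms is not None:
        keep_c = records["chrom"].isin(set(map(str, chroms)))
        records = records.loc[keep_c].reset_index(drop=True)
    return ScanResult(trait=trait, records=records,
                      conditioning_snps=list(conditioning_snps))


def permutation_threshold(y, G: GenotypeMatrix, loco_grms: dict[str, Grm],
                          n_perm: int, alpha: float = 0.05, seed: int = 0,
                          covariates=None,
                          workspace: LocoWorkspace | None = None
                          ) -> SignificanceThreshold:
    """Permutation-derived family-wise significance threshold.

    The phenotype is shuffled across individuals (which breaks genotype-
    phenotype and relatedness-phenotype links alike), the full LOCO scan is
    re-run, and the genome-wide maximum -log10 p is recorded; the threshold
    is the empirical (1 - alpha) quantile of the maxima (linear
    interpolation, numpy default).
    """
    if n_perm < 20:
        raise ValueError("need at least 20 permutations")
    if n_perm < int(np.ceil(1.0 / alpha)):
        log.warning(
            "permutation_threshold: %d permutations cannot resolve alpha=%g; "
            "achievable alpha is about %g", n_perm, alpha, 1.0 / n_perm)
    yv = _align_y(y, G)
    ok = ~np.isnan(yv)
    yv = np.where(ok, yv, np.nan)
    if workspace is None:
        workspace = LocoWorkspace(G, loco_grms)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(len(yv))
        res = assoc_scan(yv[perm], G, loco_grms, covariates=covariates,
                         workspace=workspace if ok.all() else None)
        rec = res.records["neglog10_p"].to_numpy()
        maxima[b] = np.nanmax(rec)
    value = float(np.quantile(maxima, 1.0 - alpha))
    return SignificanceThreshold(alpha=alpha, n_permutations=n_perm,
                                 value=value, maxima=maxima)


def ld_r2(G: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete cases."""
    a = G.dosages[:, G.snp_index(snp_a)]
    b = G.dosages[:, G.snp_index(snp_b)]
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 3:
        return float("nan")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def call_qtls(scan: ScanResult, threshold: float | SignificanceThreshold,
              support_window: int = 500_000,
              support_delta: float = 2.0) -> list[dict]:
    """Candidate QTL peaks under the support-SNP rule (one per chromosome).

    Among SNPs with -log10 p above the threshold, the most significant SNP on
    each chromosome is a candidate peak; it is reported only when at least
    one *other* SNP lies within ``support_window`` bp (inclusive) and has a
    -log10 p no more than ``support_delta`` units below the peak (inclusive).
    Peak ties break toward the lower position, then the lexicographic id.
    """
    thr = threshold.value if isinstance(threshold, SignificanceThreshold) else float(threshold)
    rec = scan.records.dropna(subset=["neglog10_p"])
    peaks = []
    for chrom, sub in rec.groupby("chrom", sort=False):
        sig = sub[sub["neglog10_p"] > thr]
        if sig.empty:
            continue
        sig = sig.sort_values(["neglog10_p", "pos", "id"],
                              ascending=[False, True, True], kind="stable")
        peak = sig.iloc[0]
        near = sub[(sub["id"] != peak["id"])
                   & ((sub["pos"] - peak["pos"]).abs() <= support_window)]
        support = near[near["neglog10_p"] >= peak["neglog10_p"] - support_delta]
        if len(support) >= 1:
            peaks.append({
                "chrom": str(chrom), "id": str(peak["id"]),
                "pos": int(peak["pos"]),
                "neglog10_p": float(peak["neglog10_p"]),
                "support_count": int(len(support)),
            })
    peaks.sort(key=lambda p: (chrom_sort_key(p["chrom"]), p["pos"]))
    return peaks


def qtl_interval(G: GenotypeMatrix, peak_snp: str, r2_min: float = 0.6,
                 search_window: int = 10_000_000) -> tuple[int, int]:
    """LD-defined QTL boundaries: outermost SNPs with r^2 >= r2_min to the peak.

    Contiguity is not required — an isolated distal SNP in strong LD extends
    the interval — but the search is bounded to +-``search_window`` bp.  The
    peak itself always qualifies (r^2 = 1 with itself), so the interval always
    contains it; with no qualifying neighbor the interval has width zero.
    """
    j = G.snp_index(peak_snp)
    chrom = str(G.snps["chrom"].iloc[j])
    peak_pos = int(G.snps["pos"].iloc[j])
    chrom_arr = G.snps["chrom"].astype(str).to_numpy()
    pos_arr = G.snps["pos"].to_numpy()
    cand = np.flatnonzero((chrom_arr == chrom)
                          & (np.abs(pos_arr - peak_pos) <= search_window))
    start = end = peak_pos
    for k in cand:
        if k == j:
            continue
        r2 = ld_r2(G, peak_snp, str(G.snps["id"].iloc[k]))
        if np.isnan(r2) or r2 < r2_min:
            continue
        p = int(pos_arr[k])
        start, end = min(start, p), max(end, p)
    return start, end


def iterative_conditional_mapping(y, G: GenotypeMatrix,
                                  loco_grms: dict[str, Grm],
                                  scan: ScanResult,
                                  threshold: float | SignificanceThreshold,
                                  covariates=None,
                                  support_window: int = 500_000,
                                  support_delta: float = 2.0,
                                  r2_min: float = 0.6,
                                  search_window: int = 10_000_000,
                                  max_rounds: int = 10,
                                  workspace: LocoWorkspace | None = None
                                  ) -> list[Qtl]:
    """Resolve independent QTLs per chromosome by iterative conditioning.

    Round 0 peaks come from the supplied scan.  Each accepted peak's dosage
    becomes a fixed covariate and the chromosome is re-scanned; the loop
    stops when no SNP passes the threshold plus support rule.  More than
    ``max_rounds`` rounds on one chromosome aborts with a diagnostic
    (collinearity suspected).
    """
    thr = threshold.value if isinstance(threshold, SignificanceThreshold) else float(threshold)
    qtls: list[Qtl] = []
    round0 = call_qtls(scan, thr, support_window, support_delta)
    for peak in round0:
        chrom = peak["chrom"]
        conditioning: list[str] = list(scan.conditioning_snps)
        current = peak
        rnd = 0
        while current is not None:
            s, e = qtl_interval(G, current["id"], r2_min, search_window)
            qtls.append(Qtl(
                trait=scan.trait, chrom=chrom, peak_snp=current["id"],
                peak_pos=current["pos"],
                peak_neglog10_p=current["neglog10_p"],
                support_count=current["support_count"],
                interval_start_bp=s, interval_end_bp=e,
                conditioning_round=rnd,
            ))
            conditioning.append(current["id"])
            rnd += 1
            if rnd > max_rounds:
                raise RuntimeError(
                    f"more than {max_rounds} conditioning rounds on chromosome "
                    f"{chrom}; suspect collinearity among conditioned SNPs")
            re_scan = assoc_scan(y, G, loco_grms, covariates=covariates,
                                 conditioning_snps=conditioning,
                                 chroms=[chrom], workspace=workspace,
                                 trait=scan.trait)
            nxt = call_qtls(re_scan, thr, support_window, support_delta)
            current = nxt[0] if nxt else None
    qtls.sort(key=lambda q: (chrom_sort_key(q.chrom), q.conditioning_round, q.peak_pos))
    return qtls


def colocate(qtl: Qtl, annotation: pd.DataFrame, G: GenotypeMatrix,
             window: int = 3_000_000, strong_r2: float = 0.6) -> pd.DataFrame:
    """Match expression/splicing/coding annotations near a QTL peak.

    ``annotation`` needs columns snp_id, chrom, pos, gene, tissue, modality
    (eQTL / sQTL / coding).  Every annotation SNP within +-``window`` bp of
    the peak is reported with its r^2 to the peak (NaN when the annotation
    SNP is absent from the genotypes) and a strong-LD flag at r^2 >= 0.6.
    """
    required = {"snp_id", "chrom", "pos", "gene", "tissue", "modality"}
    missing = required - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation table lacks columns: {sorted(missing)}")
    near = annotation[
        (annotation["chrom"].astype(str) == str(qtl.chrom))
        & ((annotation["pos"] - qtl.peak_pos).abs() <= window)
    ].copy()
    r2s, strong = [], []
    known = set(G.snps["id"])
    for r in near.itertuples(index=False):
        r2 = ld_r2(G, qtl.peak_snp, str(r.snp_id)) if r.snp_id in known else float("nan")
        r2s.append(r2)
        strong.append(bool(r2 >= strong_r2) if not np.isnan(r2) else False)
    near["distance_bp"] = (near["pos"] - qtl.peak_pos).abs().astype(int)
    near["r2"] = r2s
    near["strong_ld"] = strong
    return near.sort_values(["modality", "distance_bp"]).reset_index(drop=True)


def phewas_lookup(peak_snp: str, other_scans: list[ScanResult]) -> pd.DataFrame:
    """Cross-trait association extract at one SNP, sorted by -log10 p.

    Scans where the SNP was not tested contribute a row with NaN statistics
    rather than raising.
    """
    rows = []
    for s in other_scans:
        hit = s.records[s.records["id"] == peak_snp]
        if hit.empty:
            rows.append({"trait": s.trait, "neglog10_p": np.nan, "beta": np.nan})
        else:
            h = hit.iloc[0]
            rows.append({"trait": s.trait,
                         "neglog10_p": float(h["neglog10_p"]),
                         "beta": float(h["beta"])})
    out = pd.DataFrame(rows)
    return out.sort_values("neglog10_p", ascending=False,
                           na_position="last").reset_index(drop=True)
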