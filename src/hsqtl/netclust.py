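"""Network-based clustering of animals into addiction-severity phenotypes.

Behavioral traits are standardized within sex-by-site cells, pairwise animal
similarity is the Pearson correlation between standardized trait vectors, an
unweighted similarity network keeps the top quantile of pairs as edges, and a
Bayesian stochastic block model with conjugate Beta/Dirichlet priors is fit
by Gibbs sampling.  The three blocks are labeled vulnerable / intermediate /
resilient by a composite heroin-taking/seeking severity score, and one-vs-
rest 0/1 contrasts are derived for use as GWAS phenotypes.  An allele-by-
cluster chi-square (major homozygote vs minor-allele carrier) quantifies how
cluster composition differs between peak-SNP variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment

log = logging.getLogger(__name__)

__all__ = [
    "SimilarityNetwork",
    "BlockModelFit",
    "standardize_within_group",
    "build_similarity_network",
    "fit_sbm",
    "label_clusters",
    "cluster_contrasts",
    "allele_by_cluster_test",
]

SEVERITY_ORDER = ["resilient", "intermediate", "vulnerable"]


@dataclass
class SimilarityNetwork:
    ids: list[str]
    adjacency: np.ndarray  # binary, symmetric, zero diagonal
    construction: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)


@dataclass
class BlockModelFit:
    ids: list[str]
    K: int
    assignments: np.ndarray  # block index per individual, 0..K-1
    edge_prob: np.ndarray  # K x K posterior-mean edge probabilities
    posterior_confidence: np.ndarray  # per-node fraction of sweeps at the mode
    log_posterior_trace: np.ndarray
    seed: int
    labels: dict[int, str] | None = None  # block -> severity label
    label_warnings: list[str] = field(default_factory=list)

    def label_of(self, i: int) -> str:
        if self.labels is None:
            raise ValueError("fit is not labeled yet; run label_clusters")
        return self.labels[int(self.assignments[i])]


def standardize_within_group(table: pd.DataFrame, traits: list[str],
                             by: list[str] = ("sex", "site")) -> pd.DataFrame:
    """Z-score each trait within each grouping cell (default sex x site).

    Missing values are excluded from the moments and propagated; a
    zero-variance cell-trait standardizes to all zeros with a warning.
    Returns a DataFrame of standardized traits indexed like ``table``.
    """
    by = list(by)
    out = pd.DataFrame(index=table.index, columns=traits, dtype=float)
    for cell, idx in table.groupby(by, sort=True, dropna=False).groups.items():
        sub = table.loc[idx, traits]
        if len(idx) < 2:
            raise ValueError(f"cell {cell} has fewer than 2 individuals")
        mu = sub.mean()
        sd = sub.std(ddof=0)
        zero = sd == 0
        if zero.any():
            log.warning("standardize_within_group: zero variance for %s in cell %s",
                        list(sd.index[zero]), cell)
        sd = sd.mask(zero, 1.0)
        z = (sub - mu) / sd
        z.loc[:, zero[zero].index] = z.loc[:, zero[zero].index].where(
            sub[zero[zero].index].isna(), 0.0)
        out.loc[idx] = z
    return out


def build_similarity_network(standardized: pd.DataFrame, ids: list[str] | None = None,
                             edge_quantile: float = 0.8) -> SimilarityNetwork:
    """Threshold the animal-animal correlation matrix into a binary network.

    Similarity between two animals is the Pearson correlation of their
    standardized trait vectors over shared non-missing traits; an edge is
    present when the similarity is at or above the ``edge_quantile`` quantile
    of all pairwise similarities.  Animals with fewer than 2 usable traits
    become isolated nodes (flagged in the construction record).
    """
    Z = standardized.to_numpy(dtype=float)
    n = Z.shape[0]
    if n < 3:
        raise ValueError("need at least 3 individuals")
    if ids is None:
        ids = [str(i) for i in standardized.index]
    sim = np.full((n, n), np.nan)
    isolated = []
    mask = ~np.isnan(Z)
    if mask.all():
        Zc = Z - Z.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(Zc, axis=1)
        bad = norms == 0
        norms[bad] = 1.0
        sim = (Zc / norms[:, None]) @ (Zc / norms[:, None]).T
        sim[bad, :] = np.nan
        sim[:, bad] = np.nan
        isolated = [ids[i] for i in np.flatnonzero(bad)]
    else:
        for i in range(n):
            if mask[i].sum() < 2:
                isolated.append(ids[i])
                continue
            for j in range(i + 1, n):
                shared = mask[i] & mask[j]
                if shared.sum() < 2:
                    continue
                a, b = Z[i, shared], Z[j, shared]
                if a.std() == 0 or b.std() == 0:
                    continue
                sim[i, j] = sim[j, i] = np.corrcoef(a, b)[0, 1]
    iu = np.triu_indices(n, k=1)
    vals = sim[iu]
    finite = vals[~np.isnan(vals)]
    if finite.size == 0:
        raise ValueError("no defined pairwise similarity")
    thr = float(np.quantile(finite, edge_quantile))
    adj = np.zeros((n, n), dtype=np.int8)
    with np.errstate(invalid="ignore"):
        hit = sim >= thr
    hit &= ~np.isnan(sim)
    adj[hit] = 1
    np.fill_diagonal(adj, 0)
    adj = np.maximum(adj, adj.T)
    if isolated:
        log.warning("build_similarity_network: %d isolated node(s)", len(isolated))
    return SimilarityNetwork(
        ids=list(ids), adjacency=adj,
        construction={"similarity": "pearson", "edge_rule": "quantile",
                      "edge_quantile": edge_quantile, "threshold": thr,
                      "isolated": isolated},
    )


def _spectral_init(adj: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """K-means on the leading eigenvectors of the adjacency matrix."""
    from sklearn.cluster import KMeans

    vals, vecs = np.linalg.eigh(adj.astype(float))
    lead = vecs[:, np.argsort(np.abs(vals))[::-1][:K]]
    km = KMeans(n_clusters=K, n_init=5, random_state=int(rng.integers(2**31)))
    return km.fit_predict(lead)


def _align_labels(z: np.ndarray, ref: np.ndarray, K: int) -> np.ndarray:
    """Permute block ids of z to maximize overlap with the reference."""
    overlap = np.zeros((K, K))
    for a in range(K):
        for b in range(K):
            overlap[a, b] = np.sum((z == a) & (ref == b))
    rows, cols = linear_sum_assignment(-overlap)
    remap = {int(a): int(b) for a, b in zip(rows, cols)}
    return np.array([remap[int(v)] for v in z])


def fit_sbm(network: SimilarityNetwork, K: int = 3, n_sweeps: int = 300,
            burn_in: int = 100, seed: int = 0) -> BlockModelFit:
    """Gibbs sampling for a binary stochastic block model.

    Priors: Dirichlet(1) on block proportions, Beta(1, 1) on each block-pair
    edge probability.  Each sweep samples the edge-probability matrix and the
    mixing proportions from their conjugate conditionals, then resamples
    every node's block sequentially.  Assignments are initialized from
    spectral clustering; post-burn-in samples are label-aligned to the first
    retained sweep and the point estimate is the per-node posterior mode.
    """
    adj = network.adjacency
    n = network.n
    if K > n:
        raise ValueError("more blocks than nodes")
    if network.n_edges == 0:
        raise ValueError("empty graph")
    if burn_in >= n_sweeps:
        raise ValueError("burn_in must be smaller than n_sweeps")
    rng = np.random.default_rng(seed)
    z = _spectral_init(adj, K, rng)
    A = adj.astype(np.float64)
    samples = []
    log_post = np.empty(n_sweeps)
    theta_sum = np.zeros((K, K))
    ref = None
    for sweep in range(n_sweeps):
        Zoh = np.zeros((n, K))
        Zoh[np.arange(n), z] = 1.0
        sizes = Zoh.sum(axis=0)
        edges_between = Zoh.T @ A @ Zoh  # counts edge endpoints; diagonal doubled
        pairs = np.outer(sizes, sizes) - np.diag(sizes)
        np.fill_diagonal(edges_between, np.diag(edges_between) / 2.0)
        pairs = pairs.astype(float)
        pairs[np.diag_indices(K)] /= 2.0
        # conjugate draws
        theta = rng.beta(1.0 + edges_between, 1.0 + np.maximum(pairs - edges_between, 0.0))
        theta = (theta + theta.T) / 2.0
        pi = rng.dirichlet(1.0 + sizes)
        logt = np.log(np.clip(theta, 1e-12, 1 - 1e-12))
        log1mt = np.log(np.clip(1.0 - theta, 1e-12, 1 - 1e-12))
        # sequential node updates with incremental neighbor counts
        M = A @ Zoh  # n x K: edges from node i into each block
        counts = sizes.copy()
        for i in rng.permutation(n):
            zi = z[i]
            counts[zi] -= 1.0
            Mi = M[i]  # neighbors of i per block (excludes i: no self-edges)
            others = counts.copy()
            ll = (np.log(pi)
                  + Mi @ logt.T
                  + (others - Mi) @ log1mt.T)
            ll -= ll.max()
            prob = np.exp(ll)
            new = int(rng.choice(K, p=prob / prob.sum()))
            if new != zi:
                ai = A[:, i]
                M[:, zi] -= ai
                M[:, new] += ai
                z[i] = new
            counts[z[i]] += 1.0
        # log posterior (up to a constant) for diagnostics
        Zoh = np.zeros((n, K))
        Zoh[np.arange(n), z] = 1.0
        sizes = Zoh.sum(axis=0)
        eb = Zoh.T @ A @ Zoh
        np.fill_diagonal(eb, np.diag(eb) / 2.0)
        pr = np.outer(sizes, sizes) - np.diag(sizes)
        pr = pr.astype(float)
        pr[np.diag_indices(K)] /= 2.0
        iu = np.triu_indices(K)
        log_post[sweep] = float(
            np.sum(eb[iu] * logt[iu] + (pr[iu] - eb[iu]) * log1mt[iu])
            + np.sum(sizes * np.log(pi))
        )
        if sweep >= burn_in:
            if ref is None:
                ref = z.copy()
                aligned = z.copy()
            else:
                aligned = _align_labels(z, ref, K)
            samples.append(aligned.copy())
            theta_sum += theta
    S = np.array(samples)  # n_kept x n
    mode = np.empty(n, dtype=int)
    conf = np.empty(n)
    for i in range(n):
        counts_i = np.bincount(S[:, i], minlength=K)
        mode[i] = int(np.argmax(counts_i))
        conf[i] = counts_i[mode[i]] / S.shape[0]
    return BlockModelFit(
        ids=list(network.ids), K=K, assignments=mode,
        edge_prob=theta_sum / len(samples), posterior_confidence=conf,
        log_posterior_trace=log_post, seed=seed,
    )


def label_clusters(fit: BlockModelFit, table: pd.DataFrame,
                   severity_traits: list[str]) -> BlockModelFit:
    """Rank the K=3 blocks by composite severity and attach phenotype labels.

    The composite score is the mean of cohort-wide z-scores of the severity
    traits; the block with the highest mean score is vulnerable, the lowest
    resilient, the middle intermediate.  Exact ties break by block size
    (larger first) with a warning.
    """
    if fit.K != 3:
        raise ValueError("severity labeling expects exactly 3 blocks")
    sub = table.set_index("id").loc[fit.ids, severity_traits]
    sd = sub.std(ddof=0).mask(lambda s: s == 0, 1.0)
    z = (sub - sub.mean()) / sd
    composite = z.mean(axis=1).to_numpy()
    means, sizes = [], []
    for k in range(3):
        in_k = fit.assignments == k
        means.append(float(np.nanmean(composite[in_k])) if in_k.any() else -np.inf)
        sizes.append(int(in_k.sum()))
    warnings = list(fit.label_warnings)
    if len(set(np.round(means, 12))) < 3:
        warnings.append("tied composite severity means; tie broken by block size")
        log.warning("label_clusters: tied severity means, breaking ties by block size")
    order = sorted(range(3), key=lambda k: (means[k], sizes[k]))
    labels = {order[i]: SEVERITY_ORDER[i] for i in range(3)}
    fit.labels = labels
    fit.label_warnings = warnings
    return fit


def cluster_contrasts(fit: BlockModelFit) -> dict[str, pd.Series]:
    """One-vs-rest 0/1 phenotype vectors for the three labeled clusters."""
    if fit.labels is None:
        raise ValueError("fit must be labeled first (label_clusters)")
    out: dict[str, pd.Series] = {}
    node_labels = np.array([fit.labels[int(b)] for b in fit.assignments])
    for lab in SEVERITY_ORDER:
        vec = (node_labels == lab).astype(int)
        if vec.sum() == 0:
            log.warning("cluster_contrasts: cluster %r is empty", lab)
        out[f"{lab}_vs_rest"] = pd.Series(vec, index=fit.ids,
                                          name=f"{lab}_vs_rest")
    return out


def allele_by_cluster_test(peak_genotypes, contrast,
                           grouping: str = "carrier"):
    """Chi-square test of cluster composition against peak-SNP variant group.

    Genotypes are grouped as major-allele homozygotes vs minor-allele
    carriers (``grouping='carrier'``, 2x2 table, df = 1) or as the full
    three-genotype table (``grouping='genotype'``, df = 2).  The statistic is
    the plain Pearson chi-square without continuity correction.  Individuals
    with missing genotype or contrast are dropped.  Returns
    (chi2, df, p, contingency table); an expected cell below 1 attaches a
    warning to the log.
    """
    g = np.asarray(pd.Series(peak_genotypes), dtype=float)
    c = np.asarray(pd.Series(contrast), dtype=float)
    ok = ~np.isnan(g) & ~np.isnan(c)
    g, c = g[ok], c[ok]
    alt_freq = g.mean() / 2.0
    minor_is_alt = alt_freq <= 0.5
    if grouping == "carrier":
        carrier = (g > 0) if minor_is_alt else (g < 2)
        group = np.where(carrier, "carrier", "major_hom")
    elif grouping == "genotype":
        group = g.astype(int).astype(str)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    table = pd.crosstab(pd.Series(group, name="variant"),
                        pd.Series(c.astype(int), name="cluster"))
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least 2 genotype groups and 2 cluster levels")
    chi2, p, df, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    if (expected < 1).any():
        log.warning("allele_by_cluster_test: expected cell count below 1")
    return float(chi2), int(df), float(p), table
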