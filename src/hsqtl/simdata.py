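"""Synthetic heterogeneous-stock-like cohorts with known ground truth.

Heterogeneous stock (HS) rats descend from eight inbred founder strains, so
each genome is a fine-grained mosaic of founder haplotypes.  The generator
emulates that structure at desk scale:

* founder haplotypes — one binary allele per founder per SNP, with per-SNP
  allele frequencies drawn from a configurable distribution and spatial
  correlation along the chromosome (an AR(1) latent Gaussian per founder)
  so that nearby SNPs carry correlated founder patterns and the cohort shows
  realistic linkage disequilibrium;
* mosaic genomes — two haplotypes per individual, each switching founder at
  Poisson breakpoints (constant rate per Mb, no interference), representing
  the recombination accumulated over many HS generations;
* phenotypes — additive planted QTLs (default variance share 3%, the effect
  size the study design was powered for), a polygenic background built from
  all non-causal SNPs, additive site and sex effects with a site variance
  scale, and Gaussian noise;
* behavioral-battery extras — the progressive-ratio response ladder and a
  three-group clustered cohort (vulnerable / intermediate / resilient) for
  the network-clustering stage.

All outputs are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genoqc import GenotypeMatrix

__all__ = [
    "SimConfig",
    "PlantedQtl",
    "FounderHaplotypes",
    "simulate_founders",
    "simulate_mosaic_genotypes",
    "simulate_phenotypes",
    "simulate_cohort",
    "progressive_ratio_schedule",
    "simulate_clustered_cohort",
    "DEFAULT_TRAITS",
]

#: Behavioral battery emulated by default: elevated plus maze / open field /
#: tail flick at two time points, plus heroin taking and seeking measures.
DEFAULT_TRAITS = [
    "epm_open_time_t1", "epm_open_time_t2",
    "oft_center_time_t1", "oft_center_time_t2",
    "tf_latency_t1", "tf_latency_t2",
    "consumption", "escalation", "break_point",
    "extinction_burst", "extinction_total",
    "prime_reinstatement", "cue_reinstatement",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class PlantedQtl:
    """An additive causal variant with a target trait-variance share."""

    chrom: str
    pos: int
    variance_fraction: float
    trait: str | None = None  # None -> first trait in the config

    def validate(self, chrom_lengths: dict[str, int]) -> None:
        if self.chrom not in chrom_lengths:
            raise ConfigurationError(f"QTL chromosome {self.chrom!r} not simulated")
        if not 1 <= self.pos <= chrom_lengths[self.chrom]:
            raise ConfigurationError(
                f"QTL position {self.pos} outside chromosome {self.chrom}"
            )
        if not 0.0 < self.variance_fraction < 1.0:
            raise ConfigurationError("QTL variance fraction must be in (0, 1)")


@dataclass
class SimConfig:
    """Parameters of a synthetic HS-like cohort.

    ``recomb_rate`` is the expected number of founder switch points per Mb on
    a sampled haplotype; it represents accumulated recombination in the
    colony, not a single meiosis, so values well above the ~0.6 cM/Mb rat map
    are appropriate (default 0.5/Mb gives ~2 Mb mosaic blocks).
    ``founder_ld_scale_bp`` controls how quickly founder allele patterns
    decorrelate along the chromosome.
    """

    seed: int
    n_individuals: int = 850
    n_founders: int = 8
    chrom_lengths: list[tuple[str, int]] = field(
        default_factory=lambda: [(str(c + 1), 50_000_000) for c in range(10)]
    )
    snp_density: float = 20.0  # SNPs per Mb
    recomb_rate: float = 0.5  # founder switch points per Mb per haplotype
    founder_maf_dist: tuple = ("uniform", 0.1, 0.5)
    founder_ld_scale_bp: float = 1_000_000.0
    qtl_specs: list[PlantedQtl] = field(default_factory=list)
    h2_poly: float = 0.2
    site_effect: tuple[float, float] = (0.3, 1.2)  # additive shift, SD scale for site2
    sex_effect: float = 0.2  # additive shift for males
    traits: list[str] = field(default_factory=lambda: list(DEFAULT_TRAITS))

    def validate(self) -> None:
        if self.n_founders < 2:
            raise ConfigurationError("need at least 2 founders")
        if self.n_individuals < 1:
            raise ConfigurationError("need at least 1 individual")
        if not self.chrom_lengths or any(l <= 0 for _, l in self.chrom_lengths):
            raise ConfigurationError("chromosome lengths must be positive")
        if self.recomb_rate < 0 or self.snp_density <= 0:
            raise ConfigurationError("rates must be non-negative, density positive")
        if not 0.0 <= self.h2_poly < 1.0:
            raise ConfigurationError("h2_poly must be in [0, 1)")
        lengths = dict(self.chrom_lengths)
        per_trait: dict[str, float] = {}
        for q in self.qtl_specs:
            q.validate(lengths)
            t = q.trait or self.traits[0]
            per_trait[t] = per_trait.get(t, 0.0) + q.variance_fraction
        for t, v in per_trait.items():
            if self.h2_poly + v >= 1.0:
                raise ConfigurationError(
                    f"h2_poly + QTL variance for trait {t!r} is {self.h2_poly + v:.3f} >= 1"
                )


@dataclass
class FounderHaplotypes:
    """Binary founder allele matrix (n_founders x n_snps) plus SNP metadata."""

    alleles: np.ndarray
    snps: pd.DataFrame  # chrom, pos, id, ref, alt

    @property
    def n_founders(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]


def _draw_freqs(rng: np.random.Generator, dist: tuple, size: int) -> np.ndarray:
    kind = dist[0]
    if kind == "uniform":
        return rng.uniform(dist[1], dist[2], size)
    if kind == "point":
        return np.full(size, float(dist[1]))
    if kind == "beta":
        return rng.beta(dist[1], dist[2], size)
    raise ConfigurationError(f"unknown founder_maf_dist {dist!r}")


def simulate_founders(config: SimConfig) -> FounderHaplotypes:
    """Draw founder haplotypes with spatially correlated allele patterns.

    Per chromosome each founder carries a latent AR(1) Gaussian process over
    SNP positions (correlation exp(-d / founder_ld_scale_bp) at distance d);
    the allele at SNP i is 1 when the latent uniform falls below the SNP's
    pool frequency, so the marginal frequency follows ``founder_maf_dist``
    while nearby SNPs share founder patterns.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    all_alleles, rows = [], []
    for chrom, length in config.chrom_lengths:
        n_snps = max(2, int(round(config.snp_density * length / 1e6)))
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=n_snps, replace=False))
        freqs = _draw_freqs(rng, config.founder_maf_dist, n_snps)
        # AR(1) latent per founder along the chromosome
        rho = np.exp(-np.diff(pos) / config.founder_ld_scale_bp)
        z = np.empty((config.n_founders, n_snps))
        z[:, 0] = rng.standard_normal(config.n_founders)
        innov = rng.standard_normal((config.n_founders, n_snps - 1))
        for i in range(1, n_snps):
            z[:, i] = rho[i - 1] * z[:, i - 1] + math.sqrt(1 - rho[i - 1] ** 2) * innov[:, i - 1]
        from scipy.stats import norm

        alleles = (norm.cdf(z) < freqs[None, :]).astype(np.int8)
        all_alleles.append(alleles)
        for p in pos:
            rows.append({"chrom": str(chrom), "pos": int(p),
                         "id": f"chr{chrom}:{int(p)}", "ref": "A", "alt": "C"})
    snps = pd.DataFrame(rows)
    return FounderHaplotypes(alleles=np.concatenate(all_alleles, axis=1), snps=snps)


def simulate_mosaic_genotypes(founders: FounderHaplotypes,
                              config: SimConfig) -> GenotypeMatrix:
    """Compose diploid mosaic genomes from the founder haplotypes.

    Each haplotype switches to a uniformly chosen founder at breakpoints drawn
    from a Poisson process at ``recomb_rate`` per Mb (uniform genetic map, no
    interference).  Dosage = sum of the two haplotype alleles; no missingness.
    """
    config.validate()
    if founders.n_snps == 0:
        raise ConfigurationError("empty founder haplotypes")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.n_individuals
    chrom_arr = founders.snps["chrom"].to_numpy()
    pos_arr = founders.snps["pos"].to_numpy()
    dosages = np.zeros((n, founders.n_snps), dtype=np.float64)
    for chrom, length in config.chrom_lengths:
        snp_idx = np.flatnonzero(chrom_arr == str(chrom))
        if snp_idx.size == 0:
            continue
        cpos = pos_arr[snp_idx]
        mean_breaks = config.recomb_rate * length / 1e6
        for hap in range(2):
            for ind in range(n):
                n_breaks = rng.poisson(mean_breaks) if mean_breaks > 0 else 0
                if n_breaks:
                    breaks = np.sort(rng.uniform(1, length, n_breaks))
                    seg = np.searchsorted(breaks, cpos, side="right")
                else:
                    seg = np.zeros(cpos.size, dtype=np.intp)
                founders_per_seg = rng.integers(0, config.n_founders, n_breaks + 1)
                origin = founders_per_seg[seg]
                dosages[ind, snp_idx] += founders.alleles[origin, snp_idx]
    ids = [f"rat{i:05d}" for i in range(n)]
    return GenotypeMatrix(ids=ids, snps=founders.snps.copy(), dosages=dosages)


def _standardize_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column z-scores; zero-variance columns become all-zero (mask returned)."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    ok = sd > 0
    Z = np.zeros_like(X, dtype=np.float64)
    Z[:, ok] = (X[:, ok] - mu[ok]) / sd[ok]
    return Z, ok


def simulate_phenotypes(G: GenotypeMatrix, config: SimConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[pd.DataFrame, dict]:
    """Simulate the behavioral battery on top of a genotype matrix.

    Each trait y = site + sex + sum_k beta_k x_k + u + e, with standardized
    causal dosages x_k scaled so each planted QTL contributes its configured
    variance fraction, a polygenic term u built from all non-causal SNPs
    scaled to ``h2_poly``, and independent Gaussian noise filling the rest.
    Site 2 additionally applies the configured additive shift and SD scale,
    emulating the between-site variance difference of a two-site design.

    Returns the cohort table (id, site, sex, traits) and a ground-truth dict
    recording realized causal SNPs, effect sizes and variance fractions.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = G.n_individuals
    pos = G.snps["pos"].to_numpy()
    chrom = G.snps["chrom"].to_numpy()

    # site / sex assignment: balanced, deterministic given rng
    site = np.where(rng.random(n) < 0.5, "site1", "site2")
    sex = np.where(rng.random(n) < 0.5, "F", "M")

    # snap each planted QTL to the nearest simulated SNP
    truth_qtls = []
    causal_idx_per_trait: dict[str, list[tuple[int, float]]] = {}
    dosage_sd = G.dosages.std(axis=0)
    for q in config.qtl_specs:
        on_chrom = np.flatnonzero((chrom == str(q.chrom)) & (dosage_sd > 0))
        if on_chrom.size == 0:
            raise ConfigurationError(
                f"no polymorphic SNP on chromosome {q.chrom} to host the QTL")
        j = on_chrom[np.argmin(np.abs(pos[on_chrom] - q.pos))]
        trait = q.trait or config.traits[0]
        causal_idx_per_trait.setdefault(trait, []).append((int(j), q.variance_fraction))
    all_causal = sorted({j for lst in causal_idx_per_trait.values() for j, _ in lst})

    X = G.imputed_dosages()
    Z, poly_ok = _standardize_columns(X)
    poly_cols = np.array([j for j in range(G.n_snps)
                          if poly_ok[j] and j not in set(all_causal)])

    table = pd.DataFrame({"id": G.ids, "site": site, "sex": sex})
    shift, scale = config.site_effect
    is_site2 = site == "site2"
    is_male = sex == "M"

    for trait in config.traits:
        causal = causal_idx_per_trait.get(trait, [])
        g_qtl = np.zeros(n)
        for j, vfrac in causal:
            sd = X[:, j].std()
            if sd == 0:
                raise ConfigurationError(f"planted QTL SNP {G.snps['id'][j]} is monomorphic")
            beta = math.sqrt(vfrac)
            g_qtl += beta * (X[:, j] - X[:, j].mean()) / sd
            truth_qtls.append({
                "trait": trait, "chrom": str(chrom[j]), "pos": int(pos[j]),
                "snp_id": str(G.snps["id"][j]), "beta": beta,
                "variance_fraction": vfrac,
            })
        if config.h2_poly > 0 and poly_cols.size > 0:
            w = rng.standard_normal(poly_cols.size) * math.sqrt(
                config.h2_poly / poly_cols.size)
            u = Z[:, poly_cols] @ w
        else:
            u = np.zeros(n)
        v_e = 1.0 - config.h2_poly - sum(v for _, v in causal)
        e = rng.standard_normal(n) * math.sqrt(v_e)
        y = g_qtl + u + e
        y = np.where(is_site2, shift + scale * y, y)
        y = y + np.where(is_male, config.sex_effect, 0.0)
        table[trait] = y

    truth = {
        "qtls": truth_qtls,
        "h2_poly": config.h2_poly,
        "site_effect": list(config.site_effect),
        "sex_effect": config.sex_effect,
    }
    return table, truth


def simulate_cohort(config: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame, dict]:
    """Founders -> mosaic genotypes -> phenotypes in one call."""
    founders = simulate_founders(config)
    G = simulate_mosaic_genotypes(founders, config)
    table, truth = simulate_phenotypes(G, config)
    return G, table, truth


def progressive_ratio_schedule(n_max: int) -> list[int]:
    """Response requirements of the exponential progressive-ratio schedule.

    Requirement n is round(5 * exp(0.2 * n) - 5), floored at 1 press, for
    n = 1..n_max; the resulting ladder 1, 2, 4, 6, 9, 12, 15, 20, 25, ... is
    the canonical exponential PR ladder used in self-administration studies.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    out = []
    for n in range(1, n_max + 1):
        req = max(1, round(5.0 * math.exp(0.2 * n) - 5.0))
        out.append(int(req))
    return out


def simulate_clustered_cohort(n_per_cluster: int, trait_spec: list[str] | None = None,
                              separation: float = 3.0, seed: int = 0
                              ) -> tuple[pd.DataFrame, np.ndarray]:
    """Three-group cohort emulating vulnerable / intermediate / resilient rats.

    Group k (k = 0 resilient, 1 intermediate, 2 vulnerable) gets a
    group-specific behavioral *profile* plus a uniform severity shift, both
    scaled by ``separation`` (in standard-deviation units), with unit Gaussian
    noise.  The profile elevates group k on its own third of the trait list,
    which is what a correlation-based animal-animal similarity can see (a
    uniform shift on all traits is removed by the per-animal centering inside
    a Pearson correlation); the uniform ``0.5 * separation * k`` shift orders
    the groups on the composite severity score used for labeling.  Sites and
    sexes are assigned round-robin so group structure is orthogonal to the
    standardization cells.

    Returns the cohort table and the ground-truth integer labels (0/1/2).
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    if trait_spec is None:
        # mirrors the size of the heroin-taking/seeking battery; pairwise
        # animal correlations over too few traits are too noisy to cluster
        trait_spec = ["consumption", "escalation", "break_point",
                      "extinction_burst", "extinction_total",
                      "prime_reinstatement", "cue_reinstatement",
                      "training_infusions", "active_presses",
                      "inactive_presses", "seeking_index", "refrain_index"]
    rng = np.random.default_rng(seed)
    n = 3 * n_per_cluster
    labels = np.repeat([0, 1, 2], n_per_cluster)
    table = pd.DataFrame({
        "id": [f"rat{i:05d}" for i in range(n)],
        "site": np.where(np.arange(n) % 2 == 0, "site1", "site2"),
        "sex": np.where(np.arange(n) % 4 < 2, "F", "M"),
    })
    d = len(trait_spec)
    group_of_trait = np.minimum(np.arange(d) * 3 // max(d, 1), 2)
    for t_idx, t in enumerate(trait_spec):
        profile = separation * (labels == group_of_trait[t_idx]).astype(float)
        severity = 0.5 * separation * labels
        table[t] = profile + severity + rng.standard_normal(n)
    perm = rng.permutation(n)
    return table.iloc[perm].reset_index(drop=True), labels[perm]
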