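"""Genotype containers, PLINK/VCF IO, per-SNP quality statistics and filtering.

Dosages are stored as the count of the alternate allele (0/1/2) in a dense
float matrix with NaN marking missing calls.  SNPs are kept sorted by
(chromosome, position); chromosome labels sort numerically when they parse as
integers and lexicographically otherwise.

The three SNP filters follow the conventional GBS pipeline for heterogeneous
stock rats: per-SNP missingness at most 10%, minor allele frequency at least
0.5%, and a Hardy-Weinberg equilibrium deviation p-value of at least 1e-10.
All three thresholds are inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

SNP_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]
STAT_COLUMNS = ["call_rate", "maf", "hwe_p"]

__all__ = [
    "GenotypeMatrix",
    "read_genotypes",
    "write_genotypes",
    "snp_stats",
    "hwe_test",
    "filter_snps",
]


def chrom_sort_key(label: str):
    """Numeric-first ordering for chromosome labels ('2' < '10' < 'X')."""
    s = str(label)
    try:
        return (0, int(s), "")
    except ValueError:
        return (1, 0, s)


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic SNPs dosage matrix with per-SNP metadata.

    Attributes
    ----------
    ids : list of str
        Ordered individual identifiers.
    snps : pandas.DataFrame
        One row per SNP with columns chrom, pos, id, ref, alt and, after
        :func:`snp_stats`, call_rate, maf and hwe_p.  Sorted by (chrom, pos).
    dosages : numpy.ndarray
        Shape ``(n_individuals, n_snps)``, entries in {0, 1, 2} or NaN.
    """

    ids: list[str]
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.shape != (len(self.ids), len(self.snps)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.snps)} SNPs"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("individual ids are not unique")
        self._sort_snps()

    def _sort_snps(self):
        key = [
            (chrom_sort_key(c), int(p))
            for c, p in zip(self.snps["chrom"], self.snps["pos"])
        ]
        order = np.asarray(sorted(range(len(key)), key=key.__getitem__))
        if not np.array_equal(order, np.arange(len(order))):
            self.snps = self.snps.iloc[order].reset_index(drop=True)
            self.dosages = self.dosages[:, order]
        else:
            self.snps = self.snps.reset_index(drop=True)

    # -- basic introspection -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def chroms(self) -> list[str]:
        return sorted(set(self.snps["chrom"].astype(str)), key=chrom_sort_key)

    def snp_index(self, snp_id: str) -> int:
        idx = np.flatnonzero(self.snps["id"].to_numpy() == snp_id)
        if idx.size == 0:
            raise KeyError(f"SNP {snp_id!r} not found")
        return int(idx[0])

    def subset_snps(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            ids=list(self.ids),
            snps=self.snps.loc[mask].reset_index(drop=True),
            dosages=self.dosages[:, mask],
        )

    def imputed_dosages(self) -> np.ndarray:
        """Dosages with missing entries replaced by the per-SNP mean."""
        X = self.dosages.copy()
        if np.isnan(X).any():
            means = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
            means = np.where(np.isnan(means), 0.0, means)
            nan_r, nan_c = np.nonzero(np.isnan(X))
            X[nan_r, nan_c] = means[nan_c]
        return X


# ---------------------------------------------------------------------------
# IO: PLINK bed/bim/fam (variant-major v1.00) and VCF 4.2
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit codes in variant-major bed: 00 hom A1, 01 missing, 10 het, 11 hom A2.
# bim allele 1 is the alt allele here, so dosage(alt): 00->2, 10->1, 11->0.
_BED_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_DOSAGE_TO_BED_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


def write_genotypes(G: GenotypeMatrix, prefix_or_path, fmt: str = "plink",
                    sex: dict[str, str] | None = None) -> None:
    """Write genotypes as PLINK bed/bim/fam (``fmt='plink'``) or VCF 4.2."""
    if fmt == "plink":
        _write_plink(G, Path(str(prefix_or_path)), sex or {})
    elif fmt == "vcf":
        _write_vcf(G, Path(str(prefix_or_path)))
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")


def _ext(prefix: Path, ext: str) -> Path:
    return Path(str(prefix) + ext)


def _write_plink(G: GenotypeMatrix, prefix: Path, sex: dict[str, str]) -> None:
    sexcode = {"M": "1", "F": "2"}
    with open(_ext(prefix, ".fam"), "w") as fh:
        for iid in G.ids:
            fh.write(f"{iid} {iid} 0 0 {sexcode.get(sex.get(iid, ''), '0')} -9\n")
    with open(_ext(prefix, ".bim"), "w") as fh:
        for row in G.snps.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.id}\t0\t{int(row.pos)}\t{row.alt}\t{row.ref}\n")
    n = G.n_individuals
    with open(_ext(prefix, ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        for j in range(G.n_snps):
            col = G.dosages[:, j]
            codes = np.empty(n, dtype=np.uint8)
            for k in range(n):
                d = col[k]
                codes[k] = 0b01 if np.isnan(d) else _DOSAGE_TO_BED_CODE[float(d)]
            padded = np.zeros(-(-n // 4) * 4, dtype=np.uint8)
            padded[:n] = codes
            packed = (
                padded[0::4] | (padded[1::4] << 2) | (padded[2::4] << 4) | (padded[3::4] << 6)
            )
            fh.write(packed.astype(np.uint8).tobytes())


def _read_plink(prefix: Path) -> GenotypeMatrix:
    fam = pd.read_csv(_ext(prefix, ".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype=str)
    bim = pd.read_csv(_ext(prefix, ".bim"), sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "id": str, "a1": str, "a2": str})
    ids = list(fam["iid"])
    n, m = len(ids), len(bim)
    raw = np.fromfile(_ext(prefix, ".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError(f"{_ext(prefix, '.bed')}: not a variant-major PLINK 1 bed file")
    body = raw[3:]
    bytes_per_snp = -(-n // 4)
    if body.size != bytes_per_snp * m:
        raise ValueError(
            f"{_ext(prefix, '.bed')}: size inconsistent with fam/bim "
            f"({body.size} bytes for {n} individuals x {m} SNPs)"
        )
    blocks = body.reshape(m, bytes_per_snp)
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for shift, k in ((0, 0), (2, 1), (4, 2), (6, 3)):
        codes[:, k::4] = (blocks >> shift) & 0b11
    dosages = _BED_CODE_TO_DOSAGE[codes[:, :n]].T
    snps = pd.DataFrame({
        "chrom": bim["chrom"].astype(str), "pos": bim["pos"].astype(int),
        "id": bim["id"], "ref": bim["a2"], "alt": bim["a1"],
    })
    return GenotypeMatrix(ids=ids, snps=snps, dosages=dosages)


def _write_vcf(G: GenotypeMatrix, path: Path) -> None:
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in G.chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.ids) + "\n")
        for j, row in enumerate(G.snps.itertuples(index=False)):
            gts = "\t".join(
                "./." if np.isnan(d) else gt_map[float(d)] for d in G.dosages[:, j]
            )
            fh.write(f"{row.chrom}\t{int(row.pos)}\t{row.id}\t{row.ref}\t{row.alt}"
                     f"\t.\t.\t.\tGT\t{gts}\n")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    rows, cols = [], []
    for i, var in enumerate(vcf):
        alts = var.ALT
        if len(alts) != 1:
            raise ValueError(f"{path}: record {var.CHROM}:{var.POS} is not biallelic")
        rows.append({
            "chrom": str(var.CHROM), "pos": int(var.POS),
            "id": var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}",
            "ref": var.REF, "alt": alts[0],
        })
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = var.gt_types.astype(float)
        col = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        cols.append(col)
    if not rows:
        raise ValueError(f"{path}: no variant records")
    return GenotypeMatrix(
        ids=ids, snps=pd.DataFrame(rows), dosages=np.column_stack(cols)
    )


def read_genotypes(path, fmt: str = "plink") -> GenotypeMatrix:
    """Read genotypes from a PLINK prefix (``fmt='plink'``) or a VCF file.

    Dosages are oriented as the count of the alternate allele; missing calls
    are preserved as NaN; SNPs are sorted by (chrom, pos) on load.
    """
    path = Path(str(path))
    if fmt == "plink":
        return _read_plink(path)
    if fmt == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


# ---------------------------------------------------------------------------
# Per-SNP statistics and filters
# ---------------------------------------------------------------------------

def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Hardy-Weinberg goodness-of-fit p-value (1-df chi-square).

    Expected genotype counts come from the sample allele frequency; the test
    is the plain Pearson chi-square with 1 degree of freedom (genotype classes
    minus alleles estimated).  Monomorphic input returns p = 1 by convention.
    """
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("HWE test needs at least one genotype")
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1.0 - p
    if p <= 0.0 or q <= 0.0:
        return 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def snp_stats(G: GenotypeMatrix) -> GenotypeMatrix:
    """Annotate ``G.snps`` with call_rate, maf and hwe_p (in place; returns G).

    Missing dosages are excluded from allele-frequency and HWE computation.
    An all-missing SNP gets call_rate 0 and NaN maf/hwe_p.
    """
    if G.n_snps == 0:
        raise ValueError("empty genotype matrix")
    X = G.dosages
    n = G.n_individuals
    miss = np.isnan(X)
    n_called = n - miss.sum(axis=0)
    call_rate = n_called / n
    with np.errstate(invalid="ignore"):
        alt_freq = np.nansum(X, axis=0) / (2 * n_called)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    n_hom_ref = np.sum(X == 0.0, axis=0)
    n_het = np.sum(X == 1.0, axis=0)
    n_hom_alt = np.sum(X == 2.0, axis=0)
    hwe_p = np.full(G.n_snps, np.nan)
    for j in range(G.n_snps):
        if n_called[j] > 0:
            hwe_p[j] = hwe_test(int(n_hom_alt[j]), int(n_het[j]), int(n_hom_ref[j]))
    maf = np.where(n_called > 0, maf, np.nan)
    G.snps = G.snps.assign(call_rate=call_rate, maf=maf, hwe_p=hwe_p)
    return G


def filter_snps(G: GenotypeMatrix, max_missing: float = 0.10,
                min_maf: float = 0.005, min_hwe_p: float = 1e-10) -> GenotypeMatrix:
    """Apply the three conjunctive SNP filters (all thresholds inclusive).

    Retains SNPs with missingness <= ``max_missing``, minor allele frequency
    >= ``min_maf`` and HWE deviation p >= ``min_hwe_p``.  Per-filter removal
    counts are logged; an empty result is a warning, not an error.
    """
    if not set(STAT_COLUMNS) <= set(G.snps.columns):
        G = snp_stats(G)
    s = G.snps
    miss_ok = (1.0 - s["call_rate"].to_numpy()) <= max_missing
    maf_ok = s["maf"].to_numpy() >= min_maf
    hwe_ok = s["hwe_p"].to_numpy() >= min_hwe_p
    # all-missing SNPs (NaN maf/hwe) fail on missingness alone
    maf_ok = np.where(np.isnan(s["maf"].to_numpy()), False, maf_ok)
    hwe_ok = np.where(np.isnan(s["hwe_p"].to_numpy()), False, hwe_ok)
    keep = miss_ok & maf_ok & hwe_ok
    log.info(
        "filter_snps: %d/%d retained (removed: missingness %d, MAF %d, HWE %d)",
        int(keep.sum()), len(keep),
        int((~miss_ok).sum()), int((~maf_ok).sum()), int((~hwe_ok).sum()),
    )
    if keep.sum() == 0:
        log.warning("filter_snps: no SNPs pass the filters")
    return G.subset_snps(keep)
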