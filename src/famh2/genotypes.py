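"""Genotype matrices in the PLINK text (PED/MAP) dialect and genotype QC.

Dosages count copies of the A1 (by convention minor) allele, stored as a
float matrix with NaN for missing calls.  QC applies the conventional
filter cascade: individual missingness, SNP missingness, minor-allele
frequency, founders-only Hardy-Weinberg exact test, and heterozygosity
(inbreeding-coefficient) outliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = [
    "GenotypeMatrix",
    "QcThresholds",
    "QcReport",
    "read_ped_map",
    "write_ped_map",
    "qc_genotypes",
    "hwe_exact_pvalue",
]


@dataclass
class GenotypeMatrix:
    ids: list[tuple[str, str]]          # (FID, IID)
    snps: pd.DataFrame                  # columns: snp, chrom, pos, a1, a2
    dosage: np.ndarray                  # n_individuals x n_snps, NaN = missing

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        valid = np.isin(self.dosage[~np.isnan(self.dosage)], [0.0, 1.0, 2.0])
        if not valid.all():
            raise ValueError("dosages must be 0/1/2 or missing")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Sample frequency of the counted (A1) allele per SNP."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosage, axis=0) / 2.0

    def subset(self, *, individuals: Sequence[int] | None = None,
               snps: Sequence[int] | None = None) -> "GenotypeMatrix":
        ii = (np.arange(self.n_individuals) if individuals is None
              else np.asarray(individuals, dtype=int))
        jj = (np.arange(self.n_snps) if snps is None
              else np.asarray(snps, dtype=int))
        return GenotypeMatrix(
            [self.ids[i] for i in ii],
            self.snps.iloc[jj].reset_index(drop=True),
            self.dosage[np.ix_(ii, jj)],
        )


def write_ped_map(g: GenotypeMatrix, ped: Pedigree | None,
                  prefix: str | Path) -> None:
    """Write PLINK text PED/MAP.  Allele pairs: dosage 2 -> a1 a1, 1 -> a1 a2,
    0 -> a2 a2, missing -> 0 0.  Pedigree columns come from ``ped`` when given."""
    prefix = Path(prefix)
    snps = g.snps
    with open(prefix.with_suffix(".map"), "w") as fh:
        for r in snps.itertuples():
            fh.write(f"{r.chrom}\t{r.snp}\t0\t{r.pos}\n")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, (fid, iid) in enumerate(g.ids):
            if ped is not None and (fid, iid) in ped:
                ind = ped[(fid, iid)]
                lead = [fid, iid, ind.father, ind.mother, str(ind.sex),
                        "1" if ind.phenotyped else "-9"]
            else:
                lead = [fid, iid, "0", "0", "0", "-9"]
            alleles: list[str] = []
            for j in range(g.n_snps):
                d = g.dosage[i, j]
                a1, a2 = snps.a1.iloc[j], snps.a2.iloc[j]
                if np.isnan(d):
                    alleles += ["0", "0"]
                elif d == 2:
                    alleles += [a1, a1]
                elif d == 1:
                    alleles += [a1, a2]
                else:
                    alleles += [a2, a2]
            fh.write("\t".join(lead + alleles) + "\n")


def read_ped_map(prefix: str | Path) -> GenotypeMatrix:
    """Read PLINK text PED/MAP written by :func:`write_ped_map`.

    In this package's own dialect the counted (A1) allele is always
    written as "A", so files round-trip losslessly; for externally
    produced files with other allele labels the minor allele is counted
    (PLINK convention), which can flip the dosage direction -- analyses
    built on the GRM or kinship are invariant to such flips.
    """
    prefix = Path(prefix)
    mp = pd.read_csv(prefix.with_suffix(".map"), sep=r"\s+", header=None,
                     names=["chrom", "snp", "cm", "pos"], dtype={"snp": str})
    rows = []
    ids = []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            ids.append((parts[0], parts[1]))
            rows.append(parts[6:])
    raw = np.array(rows, dtype=object)
    n, m = len(ids), len(mp)
    if raw.shape[1] != 2 * m:
        raise ValueError("PED allele count does not match MAP SNP count")
    a_first = raw[:, 0::2]
    a_second = raw[:, 1::2]
    dosage = np.full((n, m), np.nan)
    a1_list, a2_list = [], []
    for j in range(m):
        col = np.concatenate([a_first[:, j], a_second[:, j]])
        obs = [a for a in pd.unique(col) if a != "0"]
        if not obs:
            a1_list.append("A"); a2_list.append("B")
            continue
        if set(obs) <= {"A", "B"}:
            # package dialect: "A" is the counted allele by construction
            a1, a2 = "A", "B"
        else:
            # counted allele = least frequent (ties: lexicographic)
            counts = {a: int((col == a).sum()) for a in obs}
            order = sorted(obs, key=lambda a: (counts[a], a))
            a1 = order[0]
            a2 = order[-1] if len(order) > 1 else ("B" if a1 != "B" else "A")
        a1_list.append(a1); a2_list.append(a2)
        miss = (a_first[:, j] == "0") | (a_second[:, j] == "0")
        d = (a_first[:, j] == a1).astype(float) + (a_second[:, j] == a1)
        d[miss] = np.nan
        dosage[:, j] = d
    snps = pd.DataFrame({"snp": mp.snp, "chrom": mp.chrom, "pos": mp.pos,
                         "a1": a1_list, "a2": a2_list})
    return GenotypeMatrix(ids, snps, dosage)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_pvalue(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test P-value (sum of probabilities <= observed).

    Conditions on the observed allele counts and sums the probability of
    all heterozygote counts no more likely than the observed one, using the
    standard stable recurrence over heterozygote numbers.
    """
    n_hom_min, n_hom_maj = sorted((n_hom1, n_hom2))
    n = n_het + n_hom_min + n_hom_maj
    if n == 0:
        return 1.0
    rare = 2 * n_hom_min + n_het          # rare-allele count
    # heterozygote counts share the parity of the rare allele count
    het_max = min(rare, 2 * n - rare)
    probs = np.zeros(het_max + 1)
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    probs[mid] = 1.0
    # downward recurrence: P(h-2)/P(h) = h(h-1) / (4 * hom_r(h) + ... )
    h = mid
    while h >= 2:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[h - 2] = probs[h] * h * (h - 1.0) / (4.0 * (hom_r + 1.0) * (hom_c + 1.0))
        h -= 2
    h = mid
    while h + 2 <= het_max:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
        h += 2
    total = probs.sum()
    p_obs = probs[n_het] / total
    return float(min(1.0, probs[probs / total <= p_obs * (1 + 1e-12)].sum() / total))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass
class QcThresholds:
    mind: float = 0.05       # max individual missingness
    geno: float = 0.05       # max SNP missingness
    maf: float = 0.01        # min minor-allele frequency
    hwe: float = 1e-8        # min founders-only HWE exact P
    het_sd: float = 3.0      # inbreeding-F outlier cutoff in SDs


@dataclass
class QcReport:
    steps: list[tuple[str, int]] = field(default_factory=list)  # (filter, n removed)
    n_individuals_in: int = 0
    n_snps_in: int = 0
    n_individuals_out: int = 0
    n_snps_out: int = 0

    def removed(self, step: str) -> int:
        return dict(self.steps).get(step, 0)


def _qc_pass(g: GenotypeMatrix, ped: Pedigree, th: QcThresholds
             ) -> tuple[GenotypeMatrix, dict[str, int]]:
    removed: dict[str, int] = {}

    miss_ind = np.isnan(g.dosage).mean(axis=1)
    keep_i = np.where(miss_ind <= th.mind)[0]
    removed["mind"] = g.n_individuals - len(keep_i)
    g = g.subset(individuals=keep_i)

    miss_snp = np.isnan(g.dosage).mean(axis=0)
    keep_j = np.where(miss_snp <= th.geno)[0]
    removed["geno"] = g.n_snps - len(keep_j)
    g = g.subset(snps=keep_j)
    if g.n_snps == 0:
        raise ValueError("all SNPs removed by QC (call-rate filter)")

    freq = g.allele_frequencies()
    maf = np.minimum(freq, 1.0 - freq)
    keep_j = np.where(maf >= th.maf)[0]
    removed["maf"] = g.n_snps - len(keep_j)
    g = g.subset(snps=keep_j)
    if g.n_snps == 0:
        raise ValueError("all SNPs removed by QC (MAF filter)")

    founder_keys = {f.key for f in ped.founders()}
    fidx = [i for i, k in enumerate(g.ids) if k in founder_keys]
    keep_j = []
    for j in range(g.n_snps):
        col = g.dosage[fidx, j] if fidx else g.dosage[:, j]
        col = col[~np.isnan(col)]
        n_het = int((col == 1).sum())
        n_hom1 = int((col == 2).sum())
        n_hom2 = int((col == 0).sum())
        if hwe_exact_pvalue(n_het, n_hom1, n_hom2) >= th.hwe:
            keep_j.append(j)
    removed["hwe"] = g.n_snps - len(keep_j)
    g = g.subset(snps=keep_j)
    if g.n_snps == 0:
        raise ValueError("all SNPs removed by QC (HWE filter)")

    # method-of-moments inbreeding coefficient per individual
    freq = g.allele_frequencies()
    exp_het = 2.0 * freq * (1.0 - freq)
    mask = ~np.isnan(g.dosage)
    obs_het = np.where(mask, g.dosage == 1, 0.0).sum(axis=1)
    exp_sum = (mask * exp_het[None, :]).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_hat = 1.0 - obs_het / exp_sum
    mu, sd = f_hat.mean(), f_hat.std()
    if sd > 0:
        keep_i = np.where(np.abs(f_hat - mu) <= th.het_sd * sd)[0]
    else:
        keep_i = np.arange(g.n_individuals)
    removed["het"] = g.n_individuals - len(keep_i)
    g = g.subset(individuals=keep_i)
    return g, removed


def qc_genotypes(g: GenotypeMatrix, ped: Pedigree,
                 thresholds: QcThresholds | None = None
                 ) -> tuple[GenotypeMatrix, QcReport]:
    """Filter cascade mind -> geno -> maf -> hwe -> het-outliers.

    The cascade is iterated to a fixed point (removing individuals can
    shift allele frequencies and vice versa), so applying QC to its own
    output removes nothing further.
    """
    th = thresholds or QcThresholds()
    rep = QcReport(n_individuals_in=g.n_individuals, n_snps_in=g.n_snps)
    totals = {"mind": 0, "geno": 0, "maf": 0, "hwe": 0, "het": 0}
    for _ in range(25):
        g, removed = _qc_pass(g, ped, th)
        for k, v in removed.items():
            totals[k] += v
        if sum(removed.values()) == 0:
            break
    rep.steps = list(totals.items())
    rep.n_individuals_out = g.n_individuals
    rep.n_snps_out = g.n_snps
    return g, rep
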