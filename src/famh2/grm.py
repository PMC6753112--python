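"""Genetic relationship matrix (GRM) construction and IBS thresholding.

The GRM is the realized genome-wide relationship estimated from SNP
dosages.  Off-diagonal entries average the product of standardized
dosages; the diagonal uses the variance-corrected single-individual form,
so that under Hardy-Weinberg sampling the mean diagonal is 1.  Zeroing
off-diagonal entries below a cutoff (default 0.05) restricts the
heritability signal to close relatives, approximating identity-by-descent
sharing in family data.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genotypes import GenotypeMatrix

__all__ = ["Grm", "compute_grm", "threshold_grm", "write_grm", "read_grm"]


@dataclass
class Grm:
    ids: list[tuple[str, str]]
    values: np.ndarray          # n x n symmetric
    n_snps: int                 # SNPs used (max per-entry count)
    counts: np.ndarray | None = None   # per-entry SNP counts
    cutoff: float | None = None        # IBS threshold applied, if any


def compute_grm(g: GenotypeMatrix) -> Grm:
    """GRM from dosages with sample allele frequencies.

    A_jk = mean_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)) for j != k;
    A_jj = 1 + mean_i (x_ij^2 - (1 + 2 p_i) x_ij + 2 p_i^2) / (2 p_i (1 - p_i)).
    Missing dosages are skipped pairwise with a per-entry SNP count.
    Monomorphic SNPs are excluded with a warning.
    """
    p = g.allele_frequencies()
    poly = (p > 0) & (p < 1)
    if not poly.all():
        warnings.warn(f"excluding {int((~poly).sum())} monomorphic SNPs from GRM")
    x = g.dosage[:, poly]
    p = p[poly]
    m = x.shape[1]
    if m == 0:
        raise ValueError("no polymorphic SNPs for GRM")
    denom = 2.0 * p * (1.0 - p)
    mask = ~np.isnan(x)
    z = np.where(mask, (x - 2.0 * p) / np.sqrt(denom), 0.0)
    counts = mask.astype(float) @ mask.T.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (z @ z.T) / counts
    # diagonal: 1 + mean of (x^2 - (1+2p)x + 2p^2) / (2p(1-p))
    diag_terms = np.where(
        mask, (x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p) / denom, 0.0)
    n_per_ind = mask.sum(axis=1)
    np.fill_diagonal(a, 1.0 + diag_terms.sum(axis=1) / n_per_ind)
    return Grm(list(g.ids), a, n_snps=m, counts=counts)


def threshold_grm(a: Grm, cutoff: float = 0.05) -> Grm:
    """Zero off-diagonal entries below ``cutoff``; diagonal untouched."""
    v = a.values.copy()
    off = ~np.eye(len(v), dtype=bool)
    v[off & (v < cutoff)] = 0.0
    return Grm(list(a.ids), v, a.n_snps, counts=a.counts, cutoff=cutoff)


def write_grm(a: Grm, prefix: str | Path) -> None:
    """GCTA text dialect: gzipped lower-triangle triples plus an ID file."""
    prefix = Path(prefix)
    n = len(a.ids)
    with gzip.open(str(prefix) + ".grm.gz", "wt") as fh:
        for j in range(n):
            for k in range(j + 1):
                cnt = a.counts[j, k] if a.counts is not None else a.n_snps
                fh.write(f"{j + 1}\t{k + 1}\t{int(cnt)}\t{a.values[j, k]:.10g}\n")
    with open(str(prefix) + ".grm.id", "w") as fh:
        for fid, iid in a.ids:
            fh.write(f"{fid}\t{iid}\n")


def read_grm(prefix: str | Path) -> Grm:
    prefix = Path(prefix)
    ids = []
    with open(str(prefix) + ".grm.id") as fh:
        for line in fh:
            fid, iid = line.split()
            ids.append((fid, iid))
    n = len(ids)
    values = np.zeros((n, n))
    counts = np.zeros((n, n))
    with gzip.open(str(prefix) + ".grm.gz", "rt") as fh:
        for line in fh:
            j, k, cnt, v = line.split()
            j, k = int(j) - 1, int(k) - 1
            values[j, k] = values[k, j] = float(v)
            counts[j, k] = counts[k, j] = float(cnt)
    return Grm(ids, values, n_snps=int(counts.max()), counts=counts)
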