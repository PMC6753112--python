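"""Cross-modality comparison statistics.

Relative-pair correlations (double-entry for symmetric pair classes),
Fisher-z comparison of two correlations, a normal heterogeneity test
between two heritability estimates, the Spearman confounding check, and
the design power simulation that predicts the sampling SE of the
variance-components heritability estimate on a family panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._streams import stream
from .heritability import KernelEigen, fit_vc_ml
from .pedigree import Pedigree, RelativePairSet, kinship_matrix
from .simulate import PedigreeSpec, simulate_pedigrees, simulate_polygenic

__all__ = [
    "CorrelationResult",
    "PowerResult",
    "relative_pair_correlation",
    "fisher_z_compare",
    "heterogeneity_test",
    "spearman_confounding",
    "power_simulation",
]


@dataclass
class CorrelationResult:
    r: float
    n_pairs: int
    label: str
    p_value: float | None = None
    available: bool = True


@dataclass
class PowerResult:
    true_h2: float
    n_replicates: int
    mean_h2: float
    empirical_se: float      # SD of the replicate estimates
    mean_wald_se: float
    n_families: int
    n_individuals: int
    n_dropped: int = 0


def relative_pair_correlation(residuals: pd.Series | dict,
                              pairs: RelativePairSet,
                              pair_class: str) -> CorrelationResult:
    """Pearson correlation across relative pairs of one class.

    Symmetric classes (sibling, avuncular) are double-entered -- each pair
    contributes in both orders -- so the coefficient is invariant to
    within-pair ordering; parent-child pairs use parent as x.  The
    reported count is of distinct pairs, not the doubled entries.
    """
    res = dict(residuals) if not isinstance(residuals, dict) else residuals
    xs, ys = [], []
    n_pairs = 0
    for a, b in pairs[pair_class]:
        if a in res and b in res and not (
                math.isnan(res[a]) or math.isnan(res[b])):
            n_pairs += 1
            xs.append(res[a]); ys.append(res[b])
            if pair_class != "parent-child":
                xs.append(res[b]); ys.append(res[a])
    if n_pairs < 3:
        return CorrelationResult(float("nan"), n_pairs, pair_class,
                                 available=False)
    r = float(np.corrcoef(xs, ys)[0, 1])
    return CorrelationResult(r, n_pairs, pair_class)


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int
                     ) -> tuple[float, float]:
    """Fisher z-test of two independent correlations.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); two-sided
    normal P.
    """
    if not (abs(r1) < 1 and abs(r2) < 1):
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("group sizes must exceed 3")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return z, float(2.0 * stats.norm.sf(abs(z)))


def heterogeneity_test(h2_a: float, se_a: float, h2_b: float, se_b: float
                       ) -> tuple[float, float]:
    """Normal z-test of two heritability estimates.

    Treats the estimates as independent (their covariance on overlapping
    individuals is ignored -- an approximation stated in output metadata
    by callers).
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    z = (h2_a - h2_b) / math.sqrt(se_a ** 2 + se_b ** 2)
    return z, float(2.0 * stats.norm.sf(abs(z)))


def spearman_confounding(x, y, label: str = "spearman") -> CorrelationResult:
    """Spearman rank correlation with average-rank ties; P from the
    t-approximation.  Pairs with a missing member are dropped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 5:
        raise ValueError("need at least 5 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), len(x), label, available=False)
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(float(rho), len(x), label, p_value=float(p))


def power_simulation(spec: PedigreeSpec, true_h2: float,
                     n_replicates: int = 200, seed: int = 0,
                     pedigree: Pedigree | None = None) -> PowerResult:
    """Predicted sampling SE of the heritability estimate by simulation.

    Simulates a polygenic trait at ``true_h2`` on the family panel,
    refits the pedigree ML variance-components model per replicate, and
    reports the mean and empirical SD of the estimates.  The kernel
    eigendecomposition is computed once and shared across replicates.
    """
    if n_replicates < 100:
        raise ValueError("need at least 100 replicates")
    ped = pedigree if pedigree is not None else simulate_pedigrees(spec)
    ids = ped.phenotyped_ids()
    kin = kinship_matrix(ped, ids)
    eig = KernelEigen.from_matrix(kin.relationship(), ids)
    id_pos = {k: i for i, k in enumerate(ped.ids)}
    sel = np.array([id_pos[k] for k in ids])
    rng = stream(seed, "power-noise")
    h2_hat, wald = [], []
    dropped = 0
    for rep in range(n_replicates):
        g = simulate_polygenic(ped, true_h2, "pedigree-mvn",
                               seed=seed * 100003 + rep)
        y = g[sel] + rng.normal(0.0, math.sqrt(1.0 - true_h2), len(sel))
        try:
            fit = fit_vc_ml(y, eig)
        except (RuntimeError, ValueError):
            dropped += 1
            continue
        h2_hat.append(fit.h2)
        if fit.se_h2 is not None:
            wald.append(fit.se_h2)
    if dropped > 0.05 * n_replicates:
        raise RuntimeError(f"{dropped}/{n_replicates} replicates failed to fit")
    h2_hat = np.array(h2_hat)
    return PowerResult(
        true_h2=true_h2, n_replicates=len(h2_hat),
        mean_h2=float(h2_hat.mean()),
        empirical_se=float(h2_hat.std(ddof=1)),
        mean_wald_se=float(np.mean(wald)) if wald else float("nan"),
        n_families=len(ped.family_ids), n_individuals=len(ids),
        n_dropped=dropped,
    )
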