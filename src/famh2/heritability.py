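"""Variance-components heritability estimation.

Two fitters share one covariance model V = sigma_g^2 K + sigma_e^2 I,
where K is either the expected additive relationship 2*Phi from the
pedigree or a (thresholded) SNP-derived GRM:

* :func:`fit_vc_ml` -- maximum likelihood with the grand mean as the only
  fixed effect, matching family variance-components tools.  The full
  (polygenic + individual-specific) model is compared to the
  individual-specific-only null by a likelihood-ratio test; the SE of h2
  comes from approximating the LRT as a Wald test, SE = h2 / sqrt(LRT).

* :func:`fit_greml` -- REML via average-information updates with EM
  fallback steps, matching GREML.  Constrained fits clamp components at
  zero; unconstrained fits allow negative components.  SE of h2 by the
  delta method from the inverse average-information matrix.

Both work in the eigenbasis of K, computed once per kernel (O(n^3)) and
reused, after which every likelihood evaluation is O(n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .grm import Grm
from .pedigree import KinshipMatrix

__all__ = [
    "KernelEigen",
    "VcFit",
    "GremlFit",
    "fit_vc_ml",
    "fit_greml",
    "wald_se_from_lrt",
    "lrt_pvalue",
    "vc_loglik",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class KernelEigen:
    """Eigendecomposition of a covariance kernel K = Q diag(lam) Q'."""

    ids: list
    lam: np.ndarray
    q: np.ndarray

    @classmethod
    def from_matrix(cls, k: np.ndarray, ids: Sequence | None = None,
                    psd_tol: float = 1e-6) -> "KernelEigen":
        k = np.asarray(k, dtype=float)
        lam, q = np.linalg.eigh((k + k.T) / 2.0)
        scale = max(1.0, float(lam.max(initial=1.0)))
        if lam.min() < -psd_tol * scale and lam.min() < -psd_tol:
            raise ValueError(
                f"kernel is not positive semidefinite (min eigenvalue {lam.min():.3g})")
        return cls(list(ids) if ids is not None else list(range(len(lam))), lam, q)

    @classmethod
    def from_kernel(cls, kernel, require_psd: bool = True) -> "KernelEigen":
        """Accept a KinshipMatrix (uses 2*Phi), a Grm, or a raw array."""
        if isinstance(kernel, KernelEigen):
            return kernel
        if isinstance(kernel, KinshipMatrix):
            return cls.from_matrix(kernel.relationship(), kernel.ids)
        if isinstance(kernel, Grm):
            return cls.from_matrix(kernel.values, kernel.ids,
                                   psd_tol=np.inf if not require_psd else 1.0)
        return cls.from_matrix(np.asarray(kernel))

    def rotate(self, v: np.ndarray) -> np.ndarray:
        return self.q.T @ v


@dataclass
class VcFit:
    sigma_g2: float
    sigma_e2: float
    h2: float
    loglik_full: float
    loglik_null: float
    lrt: float
    p_value: float
    se_h2: float | None
    mu: float
    n: int
    method: str = "ML"


@dataclass
class GremlFit(VcFit):
    constrained: bool = True
    cutoff: float | None = None
    converged: bool = True
    n_iter: int = 0


def wald_se_from_lrt(h2: float, lrt: float) -> float | None:
    """SE of h2 from the Wald approximation of the LRT: h2 / sqrt(LRT).

    Returns None (missing) when the LRT is zero.
    """
    if lrt < 0:
        raise ValueError("LRT statistic cannot be negative")
    if lrt == 0:
        return None
    return h2 / math.sqrt(lrt)


def lrt_pvalue(lrt: float, boundary_mixture: bool = True) -> float:
    """P-value of the variance-component LRT.

    With ``boundary_mixture`` (default) uses the 50:50 chi2_0 / chi2_1
    mixture appropriate for a variance tested at its boundary; otherwise
    the plain chi2_1 tail.
    """
    if lrt < 0:
        raise ValueError("LRT statistic cannot be negative")
    tail = float(stats.chi2.sf(lrt, 1))
    if not boundary_mixture:
        return tail
    return 1.0 if lrt == 0 else 0.5 * tail


# ---------------------------------------------------------------------------
# ML fit (pedigree-style variance components)
# ---------------------------------------------------------------------------

def _profile_ml(yt: np.ndarray, ot: np.ndarray, lam: np.ndarray, h2: float):
    """Profile out mu and total variance at heritability ratio ``h2``.

    Returns (-2 loglik contributions aside) the profiled (mu, sigma_p2,
    loglik) for V = sigma_p2 * (h2 * K + (1 - h2) * I) in the eigenbasis.
    """
    n = len(yt)
    w = h2 * lam + (1.0 - h2)
    if w.min() <= 0:
        return np.nan, np.nan, -np.inf
    sw = float(np.sum(ot * ot / w))
    mu = float(np.sum(ot * yt / w)) / sw
    r = yt - mu * ot
    sp2 = float(np.sum(r * r / w)) / n
    if sp2 <= 0:
        return mu, sp2, -np.inf
    ll = -0.5 * (n * _LOG2PI + float(np.log(w).sum()) + n * math.log(sp2) + n)
    return mu, sp2, ll


def vc_loglik(y: np.ndarray, eig: KernelEigen, mu: float,
              sigma_g2: float, sigma_e2: float) -> float:
    """Multivariate-normal log-likelihood of y under V = sg2 K + se2 I,
    evaluated through the kernel eigendecomposition (O(n))."""
    yt = eig.rotate(np.asarray(y, dtype=float) - mu)
    d = sigma_g2 * eig.lam + sigma_e2
    if d.min() <= 0:
        return -np.inf
    return float(-0.5 * (len(yt) * _LOG2PI + np.log(d).sum() + np.sum(yt * yt / d)))


def fit_vc_ml(y, kernel, boundary_mixture: bool = True,
              grid_points: int = 101) -> VcFit:
    """Maximum-likelihood variance-components fit with kernel K.

    Profiles the likelihood over h2 in [0, 1] (grid + bounded refinement),
    with the mean and total variance concentrated out analytically.  The
    null model (sigma_g2 = 0) is nested; LRT, boundary-aware P-value and
    the Wald-approximation SE are returned.
    """
    eig = KernelEigen.from_kernel(kernel)
    y = np.asarray(y, dtype=float)
    if y.shape[0] != len(eig.lam):
        raise ValueError("phenotype length does not match kernel dimension")
    if np.isnan(y).any():
        raise ValueError("phenotype must be casewise-complete")
    n = len(y)
    yt = eig.rotate(y)
    ot = eig.rotate(np.ones(n))

    grid = np.linspace(0.0, 1.0 - 1e-9, grid_points)
    lls = np.array([_profile_ml(yt, ot, eig.lam, h)[2] for h in grid])
    i = int(np.argmax(lls))
    lo, hi = grid[max(0, i - 1)], grid[min(len(grid) - 1, i + 1)]
    res = optimize.minimize_scalar(
        lambda h: -_profile_ml(yt, ot, eig.lam, h)[2],
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-8})
    h2 = float(res.x)
    mu, sp2, ll_full = _profile_ml(yt, ot, eig.lam, h2)
    mu0, se20, ll_null = _profile_ml(yt, ot, eig.lam, 0.0)
    if ll_full < ll_null:      # boundary optimum
        h2, mu, sp2, ll_full = 0.0, mu0, se20, ll_null
    lrt = max(0.0, 2.0 * (ll_full - ll_null))
    return VcFit(
        sigma_g2=h2 * sp2, sigma_e2=(1.0 - h2) * sp2, h2=h2,
        loglik_full=ll_full, loglik_null=ll_null, lrt=lrt,
        p_value=lrt_pvalue(lrt, boundary_mixture),
        se_h2=wald_se_from_lrt(h2, lrt), mu=mu, n=n, method="ML",
    )


# ---------------------------------------------------------------------------
# REML fit (GREML-style)
# ---------------------------------------------------------------------------

def _reml_pieces(yt, ot, lam, sg2, se2):
    """Restricted-likelihood ingredients in the eigenbasis (all O(n)).

    Returns loglik, scores (dL/dsg2, dL/dse2), AI matrix and Py.
    """
    d = sg2 * lam + se2
    if d.min() <= 0:
        return None
    s = float(np.sum(ot * ot / d))
    a = float(np.sum(ot * yt / d))
    py = yt / d - (a / s) * (ot / d)
    ypy = float(np.sum(yt * py))
    n = len(yt)
    ll = -0.5 * ((n - 1) * _LOG2PI + float(np.log(d).sum()) + math.log(s) + ypy)

    def p_apply(v):
        return v / d - (float(np.sum(ot * v / d)) / s) * (ot / d)

    tr_pk = float(np.sum(lam / d)) - float(np.sum(lam * ot * ot / d / d)) / s
    tr_p = float(np.sum(1.0 / d)) - float(np.sum(ot * ot / d / d)) / s
    kpy = lam * py
    pkpy = p_apply(kpy)
    ppy = p_apply(py)
    score_g = -0.5 * (tr_pk - float(np.sum(py * kpy)))
    score_e = -0.5 * (tr_p - float(np.sum(py * py)))
    ai_gg = 0.5 * float(np.sum(kpy * pkpy))
    ai_ge = 0.5 * float(np.sum(kpy * ppy))
    ai_ee = 0.5 * float(np.sum(py * ppy))
    ai = np.array([[ai_gg, ai_ge], [ai_ge, ai_ee]])
    return ll, np.array([score_g, score_e]), ai, py


def _reml_null_loglik(yt, ot, lam):
    n = len(yt)
    mu = float(np.sum(ot * yt)) / float(np.sum(ot * ot))
    rss = float(np.sum((yt - mu * ot) ** 2))
    se2 = rss / (n - 1)
    return -0.5 * ((n - 1) * _LOG2PI + n * math.log(se2)
                   + math.log(float(np.sum(ot * ot)) / se2) + (n - 1))


def fit_greml(y, grm, constrained: bool = True,
              boundary_mixture: bool = True, max_iter: int = 200,
              tol: float = 1e-8) -> GremlFit:
    """REML variance-components fit against a (thresholded) GRM.

    Average-information updates with EM fallback whenever an AI step
    leaves the feasible region or decreases the restricted likelihood.
    Constrained fits clamp components at ~0; unconstrained fits allow
    negative components provided V stays positive definite.
    """
    eig = KernelEigen.from_kernel(grm, require_psd=False)
    y = np.asarray(y, dtype=float)
    if y.shape[0] != len(eig.lam):
        raise ValueError("phenotype length does not match kernel dimension")
    if np.isnan(y).any():
        raise ValueError("phenotype must be casewise-complete")
    n = len(y)
    yt = eig.rotate(y)
    ot = eig.rotate(np.ones(n))
    lam = eig.lam
    vp = float(np.var(y, ddof=1))
    floor = 1e-8 * vp
    sg2, se2 = 0.5 * vp, 0.5 * vp

    pieces = _reml_pieces(yt, ot, lam, sg2, se2)
    if pieces is None:
        raise RuntimeError("initial variance components give a singular V")
    ll, score, ai, py = pieces
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # average-information proposal
        step = None
        try:
            step = np.linalg.solve(ai, score)
        except np.linalg.LinAlgError:
            pass
        accepted = False
        if step is not None:
            cand = np.array([sg2, se2]) + step
            if constrained:
                cand = np.maximum(cand, floor)
            new = _reml_pieces(yt, ot, lam, cand[0], cand[1])
            if new is not None and new[0] >= ll - 1e-10:
                sg2, se2 = float(cand[0]), float(cand[1])
                ll_new, score, ai, py = new
                accepted = True
        if not accepted:
            # EM fallback: sigma_i^2 <- sigma_i^2 + sigma_i^4 (y'PKiPy - tr(PKi)) / n
            d = sg2 * lam + se2
            tr_pk = float(np.sum(lam / d)) \
                - float(np.sum(lam * ot * ot / d / d)) / float(np.sum(ot * ot / d))
            tr_p = float(np.sum(1.0 / d)) \
                - float(np.sum(ot * ot / d / d)) / float(np.sum(ot * ot / d))
            em_g = sg2 + (sg2 ** 2) * (float(np.sum(py * (lam * py))) - tr_pk) / n
            em_e = se2 + (se2 ** 2) * (float(np.sum(py * py)) - tr_p) / n
            cand = np.array([em_g, em_e])
            if constrained:
                cand = np.maximum(cand, floor)
            new = _reml_pieces(yt, ot, lam, cand[0], cand[1])
            if new is None:
                raise RuntimeError(
                    f"REML non-convergence at iteration {it}: singular V after EM step "
                    f"(sg2={sg2:.4g}, se2={se2:.4g}, loglik={ll:.6g})")
            sg2, se2 = float(cand[0]), float(cand[1])
            ll_new, score, ai, py = new
        if abs(ll_new - ll) < tol * max(1.0, abs(ll)):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    if not converged:
        raise RuntimeError(
            f"REML failed to converge in {max_iter} iterations "
            f"(last loglik {ll:.6g}, sg2={sg2:.4g}, se2={se2:.4g})")

    total = sg2 + se2
    if total <= 0:
        raise RuntimeError("REML converged to non-positive total variance")
    h2 = sg2 / total
    ll_null = _reml_null_loglik(yt, ot, lam)
    lrt = max(0.0, 2.0 * (ll - ll_null))
    # delta-method SE of h2 from the inverse AI matrix
    se_h2 = None
    try:
        cov = np.linalg.inv(ai)
        grad = np.array([se2, -sg2]) / total ** 2
        var_h2 = float(grad @ cov @ grad)
        if var_h2 > 0:
            se_h2 = math.sqrt(var_h2)
    except np.linalg.LinAlgError:
        pass
    return GremlFit(
        sigma_g2=sg2, sigma_e2=se2, h2=h2,
        loglik_full=ll, loglik_null=ll_null, lrt=lrt,
        p_value=lrt_pvalue(lrt, boundary_mixture), se_h2=se_h2,
        mu=float("nan"), n=n, method="REML",
        constrained=constrained,
        cutoff=getattr(grm, "cutoff", None),
        converged=converged, n_iter=it,
    )
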