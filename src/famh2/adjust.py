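"""Pre-heritability phenotype adjustment.

Pipeline order: treatment adjustment of blood pressure (+15 mmHg SBP,
+10 mmHg DBP in treated individuals), Box-Cox normalization by profile
maximum likelihood, forward-backward stepwise covariate selection at
P < 0.01 by ordinary least squares, residual extraction.  Residuals (not
mixed-model-adjusted values) feed the heritability fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

__all__ = [
    "BoxCoxFit",
    "AdjustmentModel",
    "treatment_adjust_bp",
    "boxcox_loglik",
    "boxcox_mle",
    "stepwise_select",
    "residualize",
    "adjust_trait",
]

SBP_TREATMENT_OFFSET = 15.0
DBP_TREATMENT_OFFSET = 10.0


def treatment_adjust_bp(sbp, dbp, treated):
    """Add +15/+10 mmHg to SBP/DBP of treated individuals (apply once)."""
    treated = np.asarray(treated, dtype=bool)
    sbp = np.asarray(sbp, dtype=float) + SBP_TREATMENT_OFFSET * treated
    dbp = np.asarray(dbp, dtype=float) + DBP_TREATMENT_OFFSET * treated
    if sbp.ndim == 0:
        return float(sbp), float(dbp)
    return sbp, dbp


# ---------------------------------------------------------------------------
# Box-Cox
# ---------------------------------------------------------------------------

@dataclass
class BoxCoxFit:
    lmbda: float
    loglik: float
    transformed: np.ndarray


def _boxcox_transform(y: np.ndarray, lmbda: float) -> np.ndarray:
    if abs(lmbda) < 1e-12:
        return np.log(y)
    return (np.power(y, lmbda) - 1.0) / lmbda


def boxcox_loglik(y: np.ndarray, lmbda: float) -> float:
    """Profile log-likelihood of the Box-Cox transform at ``lmbda``:
    normal likelihood of the transformed data plus the Jacobian term."""
    n = len(y)
    z = _boxcox_transform(y, lmbda)
    var = z.var()
    return float(-0.5 * n * np.log(var) + (lmbda - 1.0) * np.log(y).sum())


def boxcox_mle(y, interval: tuple[float, float] = (-3.0, 3.0),
               grid_points: int = 601) -> BoxCoxFit:
    """Maximum-likelihood Box-Cox transform over ``interval``.

    Coarse grid search followed by bounded scalar refinement to ~1e-5.
    Requires strictly positive, non-constant input; no automatic shifting.
    """
    y = np.asarray(y, dtype=float)
    y = y[~np.isnan(y)]
    if len(y) < 10:
        raise ValueError("Box-Cox needs at least 10 observations")
    if (y <= 0).any():
        raise ValueError("Box-Cox requires strictly positive values")
    if np.ptp(y) == 0:
        raise ValueError("Box-Cox undefined for constant input")
    grid = np.linspace(interval[0], interval[1], grid_points)
    lls = np.array([boxcox_loglik(y, lm) for lm in grid])
    i = int(np.argmax(lls))
    lo = grid[max(0, i - 1)]
    hi = grid[min(len(grid) - 1, i + 1)]
    res = optimize.minimize_scalar(lambda lm: -boxcox_loglik(y, lm),
                                   bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-5})
    lmbda = float(res.x)
    return BoxCoxFit(lmbda, boxcox_loglik(y, lmbda), _boxcox_transform(y, lmbda))


# ---------------------------------------------------------------------------
# Stepwise covariate selection
# ---------------------------------------------------------------------------

@dataclass
class AdjustmentModel:
    selected: list[str]
    params: pd.Series          # intercept + coefficients on selected covariates
    threshold: float
    pvalues: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


def _fit_ols(y: np.ndarray, X: pd.DataFrame):
    design = sm.add_constant(X, has_constant="add")
    return sm.OLS(y, design).fit()


def stepwise_select(y, candidates: pd.DataFrame,
                    threshold: float = 0.01) -> AdjustmentModel:
    """Classic forward-backward stepwise OLS selection.

    Each step enters the candidate with the smallest partial-test P-value
    if below ``threshold`` (partial t-test, equivalent to a 1-df partial
    F), then removes any entered covariate whose P-value is at or above
    the threshold; iterates to a fixed point.  Deterministic: ties break
    by column order.  Perfectly collinear candidates are skipped with a
    warning.
    """
    y = np.asarray(y, dtype=float)
    cols = list(candidates.columns)
    selected: list[str] = []
    while True:
        changed = False
        # forward step
        best_p, best_c = None, None
        for c in cols:
            if c in selected:
                continue
            X = candidates[selected + [c]]
            if np.linalg.matrix_rank(sm.add_constant(X, has_constant="add")) \
                    < len(selected) + 2:
                warnings.warn(f"candidate {c!r} collinear with entered set; skipped")
                continue
            p = float(_fit_ols(y, X).pvalues[c])
            if best_p is None or p < best_p:
                best_p, best_c = p, c
        if best_c is not None and best_p < threshold:
            selected.append(best_c)
            changed = True
        # backward step(s)
        while selected:
            fit = _fit_ols(y, candidates[selected])
            pv = fit.pvalues.drop("const")
            worst = pv.idxmax()
            if pv[worst] >= threshold:
                selected.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break
    fit = _fit_ols(y, candidates[selected] if selected else
                   pd.DataFrame(index=candidates.index))
    return AdjustmentModel(selected, fit.params, threshold,
                           fit.pvalues.drop("const", errors="ignore"))


def residualize(y, model: AdjustmentModel,
                candidates: pd.DataFrame) -> np.ndarray:
    """Residuals of y against the selected covariates (mean-centred)."""
    y = np.asarray(y, dtype=float)
    if not model.selected:
        return y - y.mean()
    X = sm.add_constant(candidates[model.selected], has_constant="add")
    fitted = np.asarray(X @ model.params)
    return y - fitted


def adjust_trait(df: pd.DataFrame, trait: str, candidates: list[str],
                 threshold: float = 0.01, use_boxcox: bool = True
                 ) -> tuple[pd.Series, dict]:
    """Full adjustment of one trait: Box-Cox, stepwise selection, residuals.

    SBP/DBP candidates are assumed already treatment-adjusted.  Casewise
    deletion over trait + candidates; returns residuals indexed like the
    input rows retained, plus a report dictionary.
    """
    cols = [trait] + candidates
    sub = df[cols].dropna()
    y = sub[trait].to_numpy(dtype=float)
    report: dict = {"trait": trait, "n": len(sub), "boxcox": use_boxcox}
    if use_boxcox:
        if (y <= 0).any():
            raise ValueError(f"trait {trait!r} has non-positive values; "
                             "disable Box-Cox or shift upstream")
        fit = boxcox_mle(y)
        y = fit.transformed
        report["lambda"] = fit.lmbda
    model = stepwise_select(y, sub[candidates], threshold)
    report["selected"] = model.selected
    report["coefficients"] = model.params.to_dict()
    resid = residualize(y, model, sub[candidates])
    return pd.Series(resid, index=sub.index, name=trait), report
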