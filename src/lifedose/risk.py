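"""Logistic risk regression on imputed datasets with Rubin's-rules pooling.

The risk model is ``ln p/(1-p) = A + beta * (Z_calc + Z_imp)`` with the
covariate contributions folded into A.  Each of the M imputed datasets is
fit by maximum likelihood; estimates are then combined with Rubin's rules:
pooled point estimate q_bar = mean(q_m), within-imputation variance
W = mean(u_m), between-imputation variance B = var(q_m), total variance
T = W + (1 + 1/M) B, with t-based confidence limits on
df = (M-1) (1 + W / ((1+1/M) B))^2.

Analyses can be repeated under caps on the PDI incompleteness index: the
cap-0 analysis is complete-case, cap-100 uses the full population, and
consistency of the estimates across caps is the recall-bias check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass(frozen=True)
class RiskModelSpec:
    """Design of the logistic fit.

    ``dose_col`` names the effective-dose column entering as Z (None for
    an intercept/covariate-only model); the threshold indicator (optional,
    for the B3 threshold model) adds a ``Z_peak > theta`` dummy.  Age is a
    covariate by default because group-level surrogates are strongly
    age-correlated.
    """

    dose_col: str | None = "z_total"
    covariates: tuple[str, ...] = ("age",)
    threshold: float | None = None
    threshold_col: str = "z_peak"


@dataclass(frozen=True)
class PooledEstimate:
    name: str
    estimate: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    ci_low: float
    ci_high: float
    m: int

    def __post_init__(self) -> None:
        if self.total_var < self.within_var - 1e-12:
            raise ValueError("total variance below within-imputation variance")
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("CI must contain the point estimate")

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))


class SeparationError(RuntimeError):
    """Complete separation or rank deficiency in a logistic fit."""


def fit_logistic(data: pd.DataFrame, spec: RiskModelSpec,
                 outcome_col: str = "case") -> pd.DataFrame:
    """ML logistic fit; returns a frame of (term, estimate, variance).

    Raises :class:`SeparationError` on complete separation or a rank-
    deficient design.  Convergence is Newton-Raphson with tolerance 1e-8.
    """
    y = data[outcome_col].to_numpy(dtype=float)
    if y.min() == y.max():
        raise SeparationError("only one outcome class present")
    cols = ([spec.dose_col] if spec.dose_col is not None else []) \
        + [c for c in spec.covariates if c in data.columns]
    X = data[cols].to_numpy(dtype=float)
    names = ["intercept"] + cols
    if spec.threshold is not None:
        X = np.column_stack(
            [X, (data[spec.threshold_col] > spec.threshold).astype(float)])
        names.append("above_threshold")
    X = np.column_stack([np.ones(len(X)), X])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SeparationError("rank-deficient design matrix")
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(method="newton", tol=1e-8, disp=False,
                                     maxiter=100)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise SeparationError(str(exc)) from exc
    params = np.asarray(fit.params, dtype=float)
    var = np.diag(np.asarray(fit.cov_params(), dtype=float))
    if not np.all(np.isfinite(params)) or not np.all(np.isfinite(var)):
        raise SeparationError("non-finite estimates (likely separation)")
    return pd.DataFrame({"term": names, "estimate": params, "variance": var})


def rubin_pool(estimates, variances, name: str = "beta",
               small_sample: bool = False,
               complete_df: float | None = None) -> PooledEstimate:
    """Combine per-imputation (q_m, u_m) pairs with Rubin's rules.

    The default uses the classical degrees of freedom
    ``(M-1)(1 + W/((1+1/M)B))^2``.  With ``small_sample=True`` and a
    complete-data df, the Barnard-Rubin adjustment caps the df at the
    observed-data value, which matters for small cohorts.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = q.size
    if m < 2:
        raise ValueError("Rubin pooling needs M >= 2 imputations")
    if np.any(u <= 0):
        raise ValueError("within-imputation variances must be positive")
    q_bar = float(q.mean())
    w = float(u.mean())
    b = float(q.var(ddof=1))
    t = w + (1.0 + 1.0 / m) * b
    if b == 0.0:
        df = np.inf
        half = stats.norm.ppf(0.975) * np.sqrt(t)
    else:
        df = (m - 1) * (1.0 + w / ((1.0 + 1.0 / m) * b)) ** 2
        if small_sample:
            if complete_df is None:
                raise ValueError("small_sample df needs complete_df")
            gamma = (1.0 + 1.0 / m) * b / t
            df_obs = ((complete_df + 1.0) / (complete_df + 3.0)
                      * complete_df * (1.0 - gamma))
            df = 1.0 / (1.0 / df + 1.0 / df_obs)
        half = stats.t.ppf(0.975, df) * np.sqrt(t)
    return PooledEstimate(name=name, estimate=q_bar, within_var=w,
                          between_var=b, total_var=t, df=float(df),
                          ci_low=q_bar - half, ci_high=q_bar + half, m=m)


def pool_fits(fits: list[pd.DataFrame]) -> dict[str, PooledEstimate]:
    """Rubin-pool every coefficient across a list of fit frames."""
    terms = fits[0]["term"].tolist()
    out = {}
    for term in terms:
        q = [float(f.loc[f["term"] == term, "estimate"].iloc[0])
             for f in fits]
        u = [float(f.loc[f["term"] == term, "variance"].iloc[0])
             for f in fits]
        out[term] = rubin_pool(q, u, name=term)
    return out


def pdi_limited_analysis(datasets: list[pd.DataFrame], spec: RiskModelSpec,
                         pdi_caps=(0.0, 20.0, 40.0, 60.0, 80.0, 100.0),
                         outcome_col: str = "case") -> pd.DataFrame:
    """Rubin-pooled fits restricted to subjects with PDI <= cap.

    Each element of ``datasets`` is one imputed dataset's analysis frame
    (one row per subject, with outcome, dose, covariates and a ``pdi``
    column).  Subsets are formed per imputation, since a subject's PDI can
    vary with the imputed values.  Caps whose subset loses an outcome
    class are reported absent.
    """
    rows = []
    for cap in pdi_caps:
        fits = []
        ns = []
        try:
            for d in datasets:
                sub = d[d["pdi"] <= cap]
                ns.append(len(sub))
                fits.append(fit_logistic(sub, spec, outcome_col))
        except (SeparationError, KeyError):
            continue
        pooled = pool_fits(fits)
        for term, est in pooled.items():
            rows.append({
                "pdi_cap": cap, "term": term, "n_mean": float(np.mean(ns)),
                "estimate": est.estimate, "se_total": est.se,
                "df": est.df, "ci_low": est.ci_low, "ci_high": est.ci_high,
                "m": est.m, "between_var": est.between_var,
                "within_var": est.within_var,
            })
    return pd.DataFrame(rows)
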