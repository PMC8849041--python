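"""Risk-difference estimators for two-arm trials with nonadherence.

All point estimators model the binary outcome with a Gaussian-family
linear model (identity link) so that the coefficient of interest is the
risk difference directly, with heteroskedasticity-robust sandwich
standard errors compensating for the misspecified error distribution.
The catalogue:

* ``ITT`` / ``NAIVE_PP`` / ``NAIVE_AT`` — regress Y on Z (all subjects),
  Y on Z among adherent subjects (Z == A), and Y on A (all subjects).
* ``B_ITT`` / ``B_PP`` — the same with measured confounders L1, L2 as
  additional regressors.
* ``IPW_PP`` — marginal structural model: Y on Z among adherent
  subjects, weighted by stabilized inverse-probability-of-adherence
  weights from a logistic model of A on L1, L2.
* ``TSLS_*`` — two-stage least squares with a logistic first stage of A
  on Z (optionally plus L); the second stage regresses Y on the fitted
  adherence probability.
* ``TSRI_*`` — two-stage residual inclusion: the second stage regresses
  Y on A plus the first-stage residual A - Ahat.

``npcb_bounds`` computes the nonparametric causal (instrumental-variable
partial identification) bounds on the risk difference from the joint
distribution of (Y, A) within each arm; the closed-form eight-term
expressions equal the linear program over the sixteen principal-stratum
response types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .simulate import TrialData

__all__ = [
    "Method", "EstimateResult", "RegressionFit", "AdherenceWeights",
    "ObservedProbabilities", "BoundResult", "fit_linear_rd",
    "estimate_naive", "estimate_baseline_adjusted",
    "compute_stabilized_weights", "estimate_ipw_pp", "estimate_two_stage",
    "estimate", "estimate_pyaz", "npcb_bounds",
]

Z_975 = 1.959963984540054  # 97.5% normal quantile for Wald 95% intervals


class Method(str, Enum):
    ITT = "ITT"
    B_ITT = "B_ITT"
    NAIVE_PP = "NAIVE_PP"
    B_PP = "B_PP"
    IPW_PP = "IPW_PP"
    NAIVE_AT = "NAIVE_AT"
    TSLS_NAIVE = "TSLS_NAIVE"
    TSLS_FIRST = "TSLS_FIRST"
    TSLS_BOTH = "TSLS_BOTH"
    TSRI_NAIVE = "TSRI_NAIVE"
    TSRI_FIRST = "TSRI_FIRST"
    TSRI_BOTH = "TSRI_BOTH"


#: methods whose model includes the measured confounders L1, L2
COVARIATE_METHODS = frozenset({
    Method.B_ITT, Method.B_PP, Method.IPW_PP,
    Method.TSLS_FIRST, Method.TSLS_BOTH,
    Method.TSRI_FIRST, Method.TSRI_BOTH,
})


@dataclass
class EstimateResult:
    method: Method
    rd: float
    se: float
    ci_lower: float
    ci_upper: float
    converged: bool
    n_used: int
    message: str = ""

    @classmethod
    def failed(cls, method: Method, n_used: int, message: str) -> "EstimateResult":
        return cls(method=method, rd=np.nan, se=np.nan, ci_lower=np.nan,
                   ci_upper=np.nan, converged=False, n_used=n_used,
                   message=message)


@dataclass
class RegressionFit:
    coefficients: np.ndarray
    fitted_values: np.ndarray
    residuals: np.ndarray
    robust_cov: np.ndarray
    ok: bool
    message: str = ""


@dataclass
class AdherenceWeights:
    """Stabilized IP-of-adherence weights on the Z == A subset."""
    weights: np.ndarray
    p_adherence: np.ndarray     # fitted P_A per subject of the subset
    marginal_p: float           # sample Pr(A=1) on the subset
    ok: bool
    message: str = ""


@dataclass
class ObservedProbabilities:
    """Empirical p[y, a, z] = Pr(Y=y, A=a | Z=z), an array of shape (2,2,2)."""
    p: np.ndarray

    def validate(self, tol: float = 1e-12) -> None:
        if self.p.shape != (2, 2, 2):
            raise ValueError("probability array must have shape (2, 2, 2)")
        if (self.p < -tol).any() or (self.p > 1 + tol).any():
            raise ValueError("probabilities must lie in [0, 1]")
        sums = self.p.sum(axis=(0, 1))
        if not np.allclose(sums, 1.0, atol=tol):
            raise ValueError(f"per-arm probabilities must sum to 1, got {sums}")


@dataclass
class BoundResult:
    lower: float
    upper: float


def fit_linear_rd(outcome: np.ndarray, regressors: np.ndarray,
                  weights: Optional[np.ndarray] = None,
                  cov_type: str = "HC0") -> RegressionFit:
    """Gaussian-family identity-link fit with a robust sandwich covariance.

    ``regressors`` must include the intercept column.  ``cov_type`` is
    any heteroskedasticity-consistent variant statsmodels supports
    (HC0 plain sandwich by default; HC1/HC3 selectable).  A
    rank-deficient design is flagged (``ok=False``) rather than raised.
    """
    X = np.asarray(regressors, float)
    y = np.asarray(outcome, float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("regressor matrix rows must match outcome length")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        k = X.shape[1]
        return RegressionFit(np.full(k, np.nan), np.full(len(y), np.nan),
                             np.full(len(y), np.nan), np.full((k, k), np.nan),
                             ok=False, message="rank-deficient design")
    if weights is None:
        res = sm.OLS(y, X).fit(cov_type=cov_type)
    else:
        w = np.asarray(weights, float)
        if (w <= 0).any() or not np.isfinite(w).all():
            raise ValueError("weights must be positive and finite")
        res = sm.WLS(y, X, weights=w).fit(cov_type=cov_type)
    return RegressionFit(coefficients=res.params, fitted_values=res.fittedvalues,
                         residuals=y - res.fittedvalues,
                         robust_cov=np.asarray(res.cov_params()), ok=True)


def _wald(method: Method, fit: RegressionFit, coef_index: int,
          n_used: int) -> EstimateResult:
    if not fit.ok:
        return EstimateResult.failed(method, n_used, fit.message)
    rd = float(fit.coefficients[coef_index])
    se = float(np.sqrt(fit.robust_cov[coef_index, coef_index]))
    return EstimateResult(method=method, rd=rd, se=se,
                          ci_lower=rd - Z_975 * se, ci_upper=rd + Z_975 * se,
                          converged=True, n_used=n_used)


def _design(*cols: np.ndarray) -> np.ndarray:
    n = len(cols[0])
    return np.column_stack([np.ones(n), *cols])


def _require_covariates(data: TrialData, method: Method) -> None:
    if not data.has_covariates:
        raise ValueError(
            f"method {method.value} adjusts for measured confounders but the "
            "trial has no l1/l2 columns")


def estimate_naive(data: TrialData, method: Method,
                   cov_type: str = "HC0") -> EstimateResult:
    """ITT (Y on Z), naive PP (Y on Z where Z == A) or naive AT (Y on A)."""
    method = Method(method)
    if method is Method.ITT:
        y, x, n_used = data.Y, data.Z, data.n
    elif method is Method.NAIVE_AT:
        y, x, n_used = data.Y, data.A, data.n
    elif method is Method.NAIVE_PP:
        keep = data.Z == data.A
        y, x, n_used = data.Y[keep], data.Z[keep], int(keep.sum())
    else:
        raise ValueError(f"{method} is not a naive method")
    if n_used == 0 or len(np.unique(x)) < 2:
        return EstimateResult.failed(method, n_used,
                                     "empty analysis subset or constant regressor")
    return _wald(method, fit_linear_rd(y, _design(x), cov_type=cov_type), 1, n_used)


def estimate_baseline_adjusted(data: TrialData, method: Method,
                               cov_type: str = "HC0") -> EstimateResult:
    """Baseline-adjusted ITT or PP: Y on Z plus L1, L2."""
    method = Method(method)
    if method not in (Method.B_ITT, Method.B_PP):
        raise ValueError(f"{method} is not a baseline-adjusted method")
    _require_covariates(data, method)
    if method is Method.B_PP:
        keep = data.Z == data.A
    else:
        keep = np.ones(data.n, bool)
    y = data.Y[keep]
    z, l1, l2 = data.Z[keep], data.L1[keep], data.L2[keep]
    n_used = int(keep.sum())
    if n_used == 0 or len(np.unique(z)) < 2:
        return EstimateResult.failed(method, n_used,
                                     "empty analysis subset or constant regressor")
    return _wald(method, fit_linear_rd(y, _design(z, l1, l2), cov_type=cov_type),
                 1, n_used)


def _fit_logistic(y: np.ndarray, X: np.ndarray):
    """Logistic fit returning (fitted_probs, ok, message).

    One-sided nonadherence puts a structural zero in one arm, driving an
    intercept to -inf; Newton stalls there, so BFGS is used as a
    fallback, whose fitted probabilities converge to the cell
    proportions.  Complete separation (the model reproduces y exactly)
    is reported as non-convergence.
    """
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with np.errstate(all="ignore"):
            for method, maxiter in (("newton", 50), ("bfgs", 500)):
                try:
                    cand = sm.Logit(y, X).fit(disp=0, method=method,
                                              maxiter=maxiter)
                except (PerfectSeparationError, np.linalg.LinAlgError):
                    continue
                if (cand.mle_retvals.get("converged", True)
                        and np.isfinite(cand.params).all()):
                    res = cand
                    break
    if res is None:
        return None, False, "logistic model did not converge"
    p = np.asarray(res.predict(X))
    if np.max(np.abs(y - p)) < 1e-3:
        return None, False, "first-stage perfect separation: fitted model reproduces the response"
    return p, True, ""


def compute_stabilized_weights(data: TrialData) -> AdherenceWeights:
    """Stabilized inverse-probability-of-adherence weights.

    Restricted to the adherent subset (Z == A): fit a logistic model of
    A on L1, L2, take the fitted probability ``P_A`` and the subset
    sample proportion ``Pr(A=1)``, and form
    ``W = Pr(A=1) * A / P_A + Pr(A=0) * (1 - A) / (1 - P_A)``.
    """
    _require_covariates(data, Method.IPW_PP)
    keep = data.Z == data.A
    a = data.A[keep].astype(float)
    if keep.sum() == 0 or len(np.unique(a)) < 2:
        return AdherenceWeights(np.array([]), np.array([]), np.nan, ok=False,
                                message="adherent subset lacks both treatment levels")
    X = _design(data.L1[keep], data.L2[keep])
    p_a, ok, msg = _fit_logistic(a, X)
    if not ok:
        return AdherenceWeights(np.array([]), np.array([]), np.nan, ok=False,
                                message=msg)
    eps = np.finfo(float).eps
    if (p_a <= eps).any() or (p_a >= 1 - eps).any():
        return AdherenceWeights(np.array([]), p_a, np.nan, ok=False,
                                message="fitted adherence probability of 0 or 1")
    marg = float(a.mean())
    w = marg * a / p_a + (1 - marg) * (1 - a) / (1 - p_a)
    if not np.isfinite(w).all() or (w <= 0).any():
        return AdherenceWeights(w, p_a, marg, ok=False,
                                message="non-finite stabilized weight")
    return AdherenceWeights(weights=w, p_adherence=p_a, marginal_p=marg, ok=True)


def estimate_ipw_pp(data: TrialData, cov_type: str = "HC0") -> EstimateResult:
    """IP-weighted PP: weighted fit of Y on Z over the adherent subset."""
    keep = data.Z == data.A
    n_used = int(keep.sum())
    try:
        aw = compute_stabilized_weights(data)
    except ValueError:
        raise
    if not aw.ok:
        return EstimateResult.failed(Method.IPW_PP, n_used, aw.message)
    y, z = data.Y[keep], data.Z[keep]
    fit = fit_linear_rd(y, _design(z), weights=aw.weights, cov_type=cov_type)
    return _wald(Method.IPW_PP, fit, 1, n_used)


def estimate_two_stage(data: TrialData, flavor: str, adjustment: str = "none",
                       cov_type: str = "HC0") -> EstimateResult:
    """2SLS or 2SRI with a logistic first stage of A on Z (+ L).

    ``flavor`` is ``"TSLS"`` or ``"TSRI"``; ``adjustment`` is ``"none"``,
    ``"first"`` (L in the first stage only) or ``"both"`` (L in both
    stages).  For 2SLS the risk difference is the coefficient on the
    first-stage fitted probability; for 2SRI it is the coefficient on A
    with the first-stage residual included as a regressor.
    """
    flavor = flavor.upper()
    if flavor not in ("TSLS", "TSRI"):
        raise ValueError("flavor must be 'TSLS' or 'TSRI'")
    if adjustment not in ("none", "first", "both"):
        raise ValueError("adjustment must be 'none', 'first' or 'both'")
    method = Method[f"{flavor}_{ {'none': 'NAIVE', 'first': 'FIRST', 'both': 'BOTH'}[adjustment] }"]
    if adjustment != "none":
        _require_covariates(data, method)
    if len(np.unique(data.Z)) < 2:
        return EstimateResult.failed(method, data.n, "randomization does not vary")

    if adjustment == "none":
        X1 = _design(data.Z)
    else:
        X1 = _design(data.Z, data.L1, data.L2)
    a_hat, ok, msg = _fit_logistic(data.A.astype(float), X1)
    if not ok:
        return EstimateResult.failed(method, data.n, msg)
    if np.ptp(a_hat) < 1e-12:
        return EstimateResult.failed(method, data.n,
                                     "constant first-stage fitted probability")

    extra = (data.L1, data.L2) if adjustment == "both" else ()
    if flavor == "TSLS":
        X2 = _design(a_hat, *extra)
    else:
        resid = data.A - a_hat
        X2 = _design(data.A, resid, *extra)
    fit = fit_linear_rd(data.Y, X2, cov_type=cov_type)
    return _wald(method, fit, 1, data.n)


_TWO_STAGE = {
    Method.TSLS_NAIVE: ("TSLS", "none"), Method.TSLS_FIRST: ("TSLS", "first"),
    Method.TSLS_BOTH: ("TSLS", "both"), Method.TSRI_NAIVE: ("TSRI", "none"),
    Method.TSRI_FIRST: ("TSRI", "first"), Method.TSRI_BOTH: ("TSRI", "both"),
}


def estimate(data: TrialData, method: Method, cov_type: str = "HC0") -> EstimateResult:
    """Dispatch a single method on one trial."""
    method = Method(method)
    if method in (Method.ITT, Method.NAIVE_PP, Method.NAIVE_AT):
        return estimate_naive(data, method, cov_type)
    if method in (Method.B_ITT, Method.B_PP):
        return estimate_baseline_adjusted(data, method, cov_type)
    if method is Method.IPW_PP:
        return estimate_ipw_pp(data, cov_type)
    flavor, adjustment = _TWO_STAGE[method]
    return estimate_two_stage(data, flavor, adjustment, cov_type)


def estimate_pyaz(data: TrialData) -> ObservedProbabilities:
    """Empirical joint proportions p[y, a, z] = Pr(Y=y, A=a | Z=z)."""
    p = np.zeros((2, 2, 2))
    for z in (0, 1):
        arm = data.Z == z
        n_arm = int(arm.sum())
        if n_arm == 0:
            raise ValueError(f"arm Z={z} is empty")
        for y in (0, 1):
            for a in (0, 1):
                p[y, a, z] = np.count_nonzero(arm & (data.A == a) & (data.Y == y)) / n_arm
    return ObservedProbabilities(p=p)


def npcb_bounds(probs: ObservedProbabilities) -> BoundResult:
    """Nonparametric causal bounds on the risk difference.

    The eight lower- and eight upper-bound expressions are the facets of
    the principal-stratum linear program: minimize/maximize
    E[Y(1)] - E[Y(0)] over the sixteen response-type frequencies that
    reproduce the observed p[y, a | z].
    """
    probs.validate()
    p = probs.p

    def q(y, a, z):
        return p[y, a, z]

    lower = max(
        q(1, 1, 1) + q(0, 0, 1) - 1,
        q(1, 1, 0) + q(0, 0, 1) - 1,
        q(0, 0, 0) + q(1, 1, 1) - 1,
        q(0, 0, 0) + q(1, 1, 0) - 1,
        q(1, 0, 0) + q(1, 1, 0) + 2 * q(0, 0, 1) + q(1, 1, 1) - 2,
        q(0, 0, 0) + 2 * q(1, 1, 0) + q(0, 0, 1) + q(0, 1, 1) - 2,
        q(0, 0, 0) + q(0, 1, 0) + q(0, 0, 1) + 2 * q(1, 1, 1) - 2,
        2 * q(0, 0, 0) + q(1, 1, 0) + q(1, 0, 1) + q(1, 1, 1) - 2,
    )
    upper = min(
        q(0, 0, 1) + q(1, 1, 1),
        q(0, 0, 0) + q(1, 1, 0),
        q(0, 0, 0) + q(0, 1, 0) + q(1, 1, 0) + q(0, 0, 1) + q(1, 0, 1) + q(1, 1, 1) - 1,
        q(0, 0, 0) + q(1, 0, 0) + q(1, 1, 0) + q(0, 0, 1) + q(0, 1, 1) + q(1, 1, 1) - 1,
        q(1, 0, 0) + q(1, 1, 0) + 2 * q(0, 0, 1) + q(0, 1, 1) + 2 * q(1, 1, 1) - 1,
        q(0, 0, 0) + q(0, 1, 0) + 2 * q(0, 0, 1) + q(1, 0, 1) + 2 * q(1, 1, 1) - 1,
        2 * q(0, 0, 0) + q(0, 1, 0) + 2 * q(1, 1, 0) + q(1, 0, 1) + q(1, 1, 1) - 1,
        2 * q(0, 0, 0) + q(1, 0, 0) + 2 * q(1, 1, 0) + q(0, 0, 1) + q(0, 1, 1) - 1,
    )
    return BoundResult(lower=float(lower), upper=float(upper))
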