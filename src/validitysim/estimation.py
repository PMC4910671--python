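"""Maximum-likelihood fitting of a ModelSpec to a sample matrix.

The discrepancy is the normal-theory ML fit function

    F_ML(S, Sigma) = ln|Sigma| + tr(S Sigma^{-1}) - ln|S| - p,

nonnegative and zero iff S = Sigma.  The sample Pearson correlation matrix
is treated as a covariance matrix with the classic (n - 1) multiplier:
chi2 = (n - 1) * F_hat, referred to chi-square with degrees of freedom
equal to the number of distinct moments minus the number of *identified*
parameters (the rank of the implied-covariance Jacobian; see
``sem_models.effective_df``), and

    RMSEA = sqrt(max(0, (chi2 - df) / (df * (n - 1)))).

Minimization is quasi-Newton (L-BFGS-B) with the analytic gradient

    dF/dtheta_k = tr[(Sigma^{-1} - Sigma^{-1} S Sigma^{-1}) dSigma/dtheta_k],

run on log-transformed variance parameters so admissibility (positive
variances) holds by construction.  A single jittered restart is attempted
when the first pass fails to converge; a fit that still fails is returned
with ``converged=False`` rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize, stats

from .sem_models import (
    ModelSpec,
    ParameterVector,
    VARIANCE_ROLES,
    effective_df,
    implied_sigma_and_grad,
    start_values,
)

_LOG_CLIP = 30.0  # bounds for log-variances during optimization


def fml(S: np.ndarray, Sigma: np.ndarray) -> float:
    """ML discrepancy between a sample matrix S and an implied matrix Sigma.

    Both must be positive-definite and of the same order p.  Zero iff
    S == Sigma.
    """
    S = np.asarray(S, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    p = S.shape[0]
    if S.shape != Sigma.shape or S.shape != (p, p):
        raise ValueError("S and Sigma must be square matrices of equal order")
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(Sigma)
    if sign_s <= 0:
        raise ValueError("S is not positive-definite")
    if sign_m <= 0:
        raise ValueError("Sigma is not positive-definite (inadmissible theta)")
    trace = np.trace(linalg.solve(Sigma, S, assume_a="pos"))
    return float(logdet_m + trace - logdet_s - p)


def rmsea(chi2: float, df: int, n: int) -> float:
    """Root mean square error of approximation, clamped at zero when the
    model chi-square falls below its degrees of freedom."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if n < 2:
        raise ValueError("n must be >= 2")
    return float(np.sqrt(max(0.0, (chi2 - df) / (df * (n - 1)))))


@dataclass(frozen=True)
class FitResult:
    """A converged (or flagged) ML solution with its fit statistics."""

    theta_hat: ParameterVector
    f_min: float
    chi2: float
    df: int
    p_value: float
    rmsea: float
    converged: bool
    n: int
    n_fev: int = 0
    model: str = ""

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "theta_hat": np.asarray(self.theta_hat).tolist(),
            "f_min": self.f_min,
            "chi2": self.chi2,
            "df": self.df,
            "p_value": self.p_value,
            "rmsea": self.rmsea,
            "converged": self.converged,
            "n": self.n,
        }


@dataclass(frozen=True)
class DeltaTest:
    """Chi-square difference test between a restrictive and a flexible model
    fitted to the same sample matrix."""

    delta_chi2: float
    delta_df: int
    p_value: float
    significant: bool
    alpha: float = 0.05
    valid: bool = True


@dataclass(frozen=True)
class DecisionFlags:
    """Table-style accept/reject flags for one fit."""

    accept_h0: bool
    rmsea_ok: bool


def _transforms(spec: ModelSpec):
    """Indices of free variance parameters (log-transformed internally)."""
    is_var = np.array(
        [e.role in VARIANCE_ROLES for e in spec.free_entries], dtype=bool
    )
    return is_var


def _to_internal(theta: np.ndarray, is_var: np.ndarray) -> np.ndarray:
    x = np.array(theta, dtype=float)
    x[is_var] = np.log(np.maximum(x[is_var], 1e-10))
    return x


def _to_natural(x: np.ndarray, is_var: np.ndarray) -> np.ndarray:
    theta = np.array(x, dtype=float)
    theta[is_var] = np.exp(theta[is_var])
    return theta


def _objective(x, spec, S, is_var):
    theta = _to_natural(x, is_var)
    sigma, grads = implied_sigma_and_grad(spec, theta)
    sign, logdet_m = np.linalg.slogdet(sigma)
    if sign <= 0 or not np.isfinite(logdet_m):
        return 1e10, np.zeros_like(x)
    sigma_inv = np.linalg.inv(sigma)
    _, logdet_s = np.linalg.slogdet(S)
    p = S.shape[0]
    f = logdet_m + np.trace(sigma_inv @ S) - logdet_s - p
    # dF/dtheta = tr[(Sigma^-1 - Sigma^-1 S Sigma^-1) dSigma]
    w = sigma_inv - sigma_inv @ S @ sigma_inv
    g = np.array([np.sum(w * d) for d in grads])
    # chain rule for log-variances
    g[is_var] *= theta[is_var]
    if not np.isfinite(f):
        return 1e10, np.zeros_like(x)
    return f, g


def fit(
    spec: ModelSpec,
    S: np.ndarray,
    n: int,
    gtol: float = 1e-8,
    max_iter: int = 1000,
) -> FitResult:
    """Fit ``spec`` to the sample matrix ``S`` by maximum likelihood.

    Returns a :class:`FitResult`; non-convergence (after one jittered
    restart) is reported through ``converged=False``, never an exception.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if n < p + 1:
        raise ValueError(f"sample size {n} too small for {p} variables")
    is_var = _transforms(spec)
    x0 = _to_internal(np.asarray(start_values(spec, S)), is_var)
    bounds = [
        (-_LOG_CLIP, _LOG_CLIP) if v else (None, None) for v in is_var
    ]

    best = None
    n_fev = 0
    rng = np.random.default_rng(0)
    for attempt in range(2):
        xa = x0 if attempt == 0 else x0 + rng.normal(0.0, 0.1, size=x0.size)
        res = optimize.minimize(
            _objective,
            xa,
            args=(spec, S, is_var),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-14, "gtol": gtol},
        )
        n_fev += res.nfev
        grad_norm = np.max(np.abs(res.jac))
        if grad_norm > 1e-6 and np.isfinite(res.fun) and res.fun < 1e9:
            # L-BFGS-B line searches stall on this badly scaled surface;
            # a full-memory BFGS polish from its solution finishes the job
            polish = optimize.minimize(
                _objective,
                res.x,
                args=(spec, S, is_var),
                jac=True,
                method="BFGS",
                options={"maxiter": 300, "gtol": gtol},
            )
            n_fev += polish.nfev
            if polish.fun <= res.fun:
                res = polish
                grad_norm = np.max(np.abs(res.jac))
        converged = bool(np.isfinite(res.fun)) and res.fun < 1e9 and (
            res.success or grad_norm < 1e-5
        )
        if best is None or res.fun < best[0].fun:
            best = (res, converged)
        if converged:
            best = (res, True)
            break

    res, converged = best
    theta_hat = _to_natural(res.x, is_var)
    f_min = float(max(res.fun, 0.0))
    # rank-based df: the threat model carries one parameter redundancy that
    # the naive count misses, and the chi-square reference must reflect it
    df = effective_df(spec, theta_hat)
    chi2 = (n - 1) * f_min
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return FitResult(
        theta_hat=ParameterVector(theta_hat),
        f_min=f_min,
        chi2=chi2,
        df=df,
        p_value=p_value,
        rmsea=rmsea(chi2, df, n) if df > 0 else 0.0,
        converged=converged,
        n=n,
        n_fev=n_fev,
        model=spec.name,
    )


def delta_chi2_test(
    fit_restrictive: FitResult,
    fit_flexible: FitResult,
    alpha: float = 0.05,
) -> DeltaTest:
    """Chi-square difference test (restrictive minus flexible model).

    Both fits must come from the same sample matrix.  A pair containing a
    non-converged fit yields an invalid test (``valid=False``), which the
    Monte Carlo harness excludes from its percentage denominators.
    """
    if fit_restrictive.df == fit_flexible.df:
        raise ValueError("models have equal df; difference test undefined")
    valid = fit_restrictive.converged and fit_flexible.converged
    delta_df = abs(fit_restrictive.df - fit_flexible.df)
    delta = max(0.0, fit_restrictive.chi2 - fit_flexible.chi2)
    p_value = float(stats.chi2.sf(delta, delta_df))
    return DeltaTest(
        delta_chi2=delta,
        delta_df=delta_df,
        p_value=p_value,
        significant=bool(valid and p_value < alpha),
        alpha=alpha,
        valid=valid,
    )


def decide(
    fit_result: FitResult, alpha: float = 0.05, rmsea_cut: float = 0.08
) -> DecisionFlags:
    """Exact-fit and approximate-fit decisions for one converged fit.

    ``accept_h0`` holds when the chi-square p-value is at least ``alpha``;
    ``rmsea_ok`` requires RMSEA strictly below the cutoff.
    """
    return DecisionFlags(
        accept_h0=bool(fit_result.p_value >= alpha),
        rmsea_ok=bool(fit_result.rmsea < rmsea_cut),
    )
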