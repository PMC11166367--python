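"""Left-censored (tobit) regression by maximum likelihood.

A fatigability score is bounded below at 0 and right-skewed with a
point mass at the bound, so a linear model for the *latent* score
y* = x'beta + eps, eps ~ N(0, sigma^2), observed as y = max(0, y*), is
fitted by maximizing

    l(beta, sigma) = sum_{y=0} log Phi((0 - x'beta)/sigma)
                   + sum_{y>0} [log phi((y - x'beta)/sigma) - log sigma]

The model is parameterized in log(sigma) for unconstrained quasi-Newton
optimization with the analytic gradient; the coefficient covariance is
the inverse observed information at the optimum, and 95% CIs are
normal-based.  With no censored rows the likelihood reduces to the
Gaussian linear model, so the MLE coincides with OLS.

Variance explained is summarized on the latent scale with the
McKelvey-Zavoina R^2, var(x'beta) / (var(x'beta) + sigma^2), the
standard choice for censored/limited outcomes; the partial R^2 of an
exposure compares full and exposure-free fits on the same rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess

_GTOL = 1e-6
_MAX_RESTARTS = 5


class TobitConvergenceError(RuntimeError):
    """Raised when the optimizer fails to drive the gradient below
    tolerance after jittered restarts."""


@dataclass
class DesignMatrix:
    """Outcome and named predictors for one censored regression.

    The outcome is censored from below at ``censor_limit`` (0 for a
    percent-scale fatigability score).  Rows must be complete;
    missing-exposure handling is the caller's job.  By convention the
    exposure column is standardized and sign-flipped upstream so its
    coefficient reads "per 1 SD lower".
    """

    y: np.ndarray
    X: np.ndarray
    names: list[str]
    censor_limit: float = 0.0

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.y):
            raise ValueError("X must be 2-D with one row per outcome")
        if self.X.shape[1] != len(self.names):
            raise ValueError("one name per column required")
        if np.isnan(self.y).any() or np.isnan(self.X).any():
            raise ValueError("design contains missing cells; complete cases only")
        if np.any(self.y < self.censor_limit):
            raise ValueError("outcome below the censoring limit")

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        outcome: str,
        predictors: list[str],
        censor_limit: float = 0.0,
        add_intercept: bool = True,
    ) -> "DesignMatrix":
        cols = [outcome] + predictors
        sub = df[cols].dropna()
        X = sub[predictors].to_numpy(dtype=float)
        names = list(predictors)
        if add_intercept:
            X = np.column_stack([np.ones(len(sub)), X])
            names = ["intercept"] + names
        return cls(sub[outcome].to_numpy(dtype=float), X, names, censor_limit)

    @property
    def censored(self) -> np.ndarray:
        return self.y <= self.censor_limit


@dataclass
class TobitFit:
    beta: pd.Series
    sigma: float
    se: pd.Series
    ci95: pd.DataFrame  # columns lo, hi
    cov: np.ndarray  # covariance of (beta, log sigma)
    loglik: float
    n: int
    n_censored: int
    design: DesignMatrix = field(repr=False)
    partial_r2_exposure: float | None = None

    def mz_r2(self) -> float:
        """McKelvey-Zavoina latent-scale R^2."""
        xb = self.design.X @ self.beta.to_numpy()
        v = float(np.var(xb))
        return v / (v + self.sigma**2)


def tobit_loglik(beta: np.ndarray, log_sigma: float, design: DesignMatrix) -> float:
    """Log-likelihood of a left-censored Gaussian linear model,
    parameterized in log(sigma); computed in log space so deep-tail
    censored terms stay finite."""
    beta = np.asarray(beta, dtype=float)
    sigma = np.exp(log_sigma)
    xb = design.X @ beta
    cens = design.censored
    ll = 0.0
    if cens.any():
        a = (design.censor_limit - xb[cens]) / sigma
        ll += float(np.sum(stats.norm.logcdf(a)))
    if (~cens).any():
        r = (design.y[~cens] - xb[~cens]) / sigma
        ll += float(np.sum(stats.norm.logpdf(r) - log_sigma))
    return ll


def _negloglik_grad(theta: np.ndarray, design: DesignMatrix) -> tuple[float, np.ndarray]:
    beta, log_sigma = theta[:-1], theta[-1]
    sigma = np.exp(log_sigma)
    xb = design.X @ beta
    cens = design.censored
    grad = np.zeros_like(theta)
    ll = 0.0
    if (~cens).any():
        r = (design.y[~cens] - xb[~cens]) / sigma
        ll += float(np.sum(stats.norm.logpdf(r) - log_sigma))
        grad[:-1] += design.X[~cens].T @ (r / sigma)
        grad[-1] += float(np.sum(r**2 - 1.0))
    if cens.any():
        a = (design.censor_limit - xb[cens]) / sigma
        logmills = stats.norm.logpdf(a) - stats.norm.logcdf(a)
        lam = np.exp(logmills)  # inverse Mills ratio phi/Phi
        ll += float(np.sum(stats.norm.logcdf(a)))
        grad[:-1] += design.X[cens].T @ (-lam / sigma)
        grad[-1] += float(np.sum(-lam * a))
    return -ll, -grad


def _newton_polish(
    theta: np.ndarray, design: DesignMatrix, max_iter: int = 20
) -> tuple[np.ndarray, float]:
    """Newton steps with step-halving from a near-optimal point; sharpens
    the BFGS solution so the gradient meets tolerance even when predictor
    columns are on very different scales."""
    nll, grad = _negloglik_grad(theta, design)
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < 0.1 * _GTOL:
            break
        hess = approx_hess(theta, lambda th: _negloglik_grad(th, design)[0])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(30):
            cand = theta - scale * step
            cand_nll, cand_grad = _negloglik_grad(cand, design)
            if np.isfinite(cand_nll) and cand_nll <= nll + 1e-12:
                theta, nll, grad = cand, cand_nll, cand_grad
                break
            scale *= 0.5
        else:
            break
    return theta, nll


def tobit_fit(
    design: DesignMatrix,
    exposure: str | None = None,
    _compute_partial: bool = True,
) -> TobitFit:
    """Maximum-likelihood tobit fit.

    Starts from OLS (with the OLS residual SD), runs BFGS with the
    analytic gradient, and verifies the gradient infinity-norm at the
    solution; up to five jittered restarts on failure.  When
    ``exposure`` names a predictor, the exposure-free model is refit on
    the same rows and the McKelvey-Zavoina partial R^2 is attached.
    """
    n, p = design.X.shape
    if n <= p + 2:
        raise ValueError(f"need n > p + 2 (n={n}, p={p})")
    if design.censored.all():
        raise ValueError("all outcomes censored; model unidentified")

    beta0, *_ = np.linalg.lstsq(design.X, design.y, rcond=None)
    resid = design.y - design.X @ beta0
    sigma0 = max(float(np.std(resid)), 1e-3)
    theta0 = np.append(beta0, np.log(sigma0))

    rng = np.random.default_rng(0)
    theta_best, best_nll, gnorm_best = None, np.inf, np.inf
    for attempt in range(_MAX_RESTARTS + 1):
        start = theta0 if attempt == 0 else theta0 + rng.normal(0.0, 0.1, len(theta0))
        res = optimize.minimize(
            _negloglik_grad,
            start,
            args=(design,),
            jac=True,
            method="BFGS",
            options={"gtol": 1e-9, "maxiter": 500},
        )
        theta, nll = _newton_polish(res.x, design)
        gnorm = float(np.max(np.abs(_negloglik_grad(theta, design)[1])))
        if nll < best_nll:
            theta_best, best_nll, gnorm_best = theta, nll, gnorm
        if gnorm < _GTOL:
            theta_best, best_nll, gnorm_best = theta, nll, gnorm
            break
    if gnorm_best >= _GTOL:
        raise TobitConvergenceError(
            f"gradient inf-norm {gnorm_best:.2e} after {_MAX_RESTARTS} restarts"
        )

    beta = theta_best[:-1]
    sigma = float(np.exp(theta_best[-1]))
    hess = approx_hess(theta_best, lambda th: _negloglik_grad(th, design)[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cov = np.linalg.inv(hess)
    se = np.sqrt(np.clip(np.diag(cov)[:-1], 0.0, None))
    z = stats.norm.ppf(0.975)
    ci = pd.DataFrame(
        {"lo": beta - z * se, "hi": beta + z * se}, index=design.names
    )
    fit = TobitFit(
        beta=pd.Series(beta, index=design.names),
        sigma=sigma,
        se=pd.Series(se, index=design.names),
        ci95=ci,
        cov=cov,
        loglik=-best_nll,
        n=n,
        n_censored=int(design.censored.sum()),
        design=design,
    )
    if exposure is not None and _compute_partial:
        if exposure not in design.names:
            raise ValueError(f"exposure {exposure!r} not in design")
        keep = [i for i, nm in enumerate(design.names) if nm != exposure]
        reduced_design = DesignMatrix(
            design.y,
            design.X[:, keep],
            [design.names[i] for i in keep],
            design.censor_limit,
        )
        reduced = tobit_fit(reduced_design, _compute_partial=False)
        fit.partial_r2_exposure = partial_r2(fit, reduced)
    return fit


def partial_r2(full: TobitFit, reduced: TobitFit) -> float:
    """McKelvey-Zavoina partial R^2 of the predictors present in the
    full model but not the reduced one, on identical rows."""
    if full.n != reduced.n or not np.array_equal(full.design.y, reduced.design.y):
        raise ValueError("full and reduced fits must use the same rows")
    r2_full = full.mz_r2()
    r2_red = reduced.mz_r2()
    return max(0.0, (r2_full - r2_red) / (1.0 - r2_red))


def tidy(fit: TobitFit) -> pd.DataFrame:
    """One row per coefficient: term, beta, se, ci_lo, ci_hi, plus the
    fit-level log-likelihood and exposure partial R^2."""
    out = pd.DataFrame(
        {
            "term": fit.beta.index,
            "beta": fit.beta.to_numpy(),
            "se": fit.se.to_numpy(),
            "ci_lo": fit.ci95["lo"].to_numpy(),
            "ci_hi": fit.ci95["hi"].to_numpy(),
        }
    )
    out["loglik"] = fit.loglik
    out["partial_r2"] = fit.partial_r2_exposure
    return out
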