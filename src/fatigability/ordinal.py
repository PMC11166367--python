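"""Proportional-odds ordinal regression for fatigability severity.

Severity strata (none < mild < moderate-to-severe) are modelled with a
cumulative-logit proportional-odds model: one common slope vector
across the J-1 cut-points, so exp(beta) is the odds ratio of being in
a *higher* (worse) stratum per unit predictor.  With the exposure
standardized and sign-flipped upstream, OR > 1 reads "per 1 SD lower
energetics, greater odds of worse fatigability".

The likelihood is maximized through statsmodels' ``OrderedModel``;
the proportional-odds assumption is checked with the Brant-Wald test,
which fits the J-1 separate binary cumulative logits and tests
equality of each predictor's coefficient across them with a chi-square
statistic on (J-2)*p degrees of freedom (Brant's formula for the joint
covariance of the binary estimates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel

MIN_PER_LEVEL_FOR_BRANT = 10


class SeparationError(RuntimeError):
    """Raised when (quasi-)complete separation prevents a finite fit."""


@dataclass
class OrdinalFit:
    thresholds: np.ndarray  # J-1 ordered cut-points on the logit scale
    beta: pd.Series  # common log-odds per unit predictor
    se: pd.Series
    or_per_sd: float | None  # odds ratio for the exposure
    or_ci95: tuple[float, float] | None
    loglik: float
    n: int
    exposure: str | None = None
    brant_stat: float | None = None
    brant_df: int | None = None
    brant_p: float | None = None

    def odds_ratios(self) -> pd.DataFrame:
        z = stats.norm.ppf(0.975)
        return pd.DataFrame(
            {
                "or": np.exp(self.beta),
                "ci_lo": np.exp(self.beta - z * self.se),
                "ci_hi": np.exp(self.beta + z * self.se),
            }
        )


def _codes(y: pd.Series | np.ndarray, order: list | None) -> np.ndarray:
    if order is not None:
        cat = pd.Categorical(y, categories=order, ordered=True)
    elif isinstance(y, pd.Series) and isinstance(y.dtype, pd.CategoricalDtype):
        cat = pd.Categorical(y, categories=y.cat.categories, ordered=True)
    else:
        cat = pd.Categorical(y, ordered=True)
    codes = np.asarray(cat.codes)
    if (codes < 0).any():
        raise ValueError("outcome contains values outside the stated order")
    return codes


def ordinal_fit(
    y,
    X: pd.DataFrame,
    order: list | None = None,
    exposure: str | None = None,
    run_brant: bool = True,
) -> OrdinalFit:
    """Fit the proportional-odds model; optionally attach Brant-Wald.

    ``order`` gives the outcome levels from least to most severe; each
    must be observed at least once.  ``exposure`` selects the predictor
    whose odds ratio (with normal-based 95% CI) is reported.
    """
    codes = _codes(y, order)
    levels, counts = np.unique(codes, return_counts=True)
    j = len(levels)
    if j < 2:
        raise ValueError("outcome must have at least 2 observed levels")
    if order is not None and j < len(order):
        raise ValueError("every outcome level must be observed at least once")
    X = X.astype(float)
    if exposure is not None and exposure not in X.columns:
        raise ValueError(f"exposure {exposure!r} not among predictors")

    model = OrderedModel(codes, X, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="bfgs", maxiter=500, disp=False, gtol=1e-7)
        if not res.mle_retvals.get("converged", True):
            res = model.fit(method="newton", maxiter=200, disp=False)
    if not res.mle_retvals.get("converged", True) or not np.all(
        np.isfinite(res.params)
    ):
        raise SeparationError("ordinal likelihood did not converge (separation?)")
    p = X.shape[1]
    beta = pd.Series(res.params[:p].to_numpy(), index=X.columns)
    se = pd.Series(res.bse[:p].to_numpy(), index=X.columns)
    if np.max(np.abs(beta)) > 30:
        raise SeparationError("diverging coefficients indicate separation")
    # statsmodels stores the first threshold then log-increments
    raw = res.params[p:].to_numpy()
    thresholds = np.concatenate([[raw[0]], raw[0] + np.cumsum(np.exp(raw[1:]))])

    or_val = or_ci = None
    if exposure is not None:
        z = stats.norm.ppf(0.975)
        b, s = beta[exposure], se[exposure]
        or_val = float(np.exp(b))
        or_ci = (float(np.exp(b - z * s)), float(np.exp(b + z * s)))

    fit = OrdinalFit(
        thresholds=thresholds,
        beta=beta,
        se=se,
        or_per_sd=or_val,
        or_ci95=or_ci,
        loglik=float(res.llf),
        n=len(codes),
        exposure=exposure,
    )
    if run_brant and j >= 3:
        if counts.min() < MIN_PER_LEVEL_FOR_BRANT:
            warnings.warn(
                "fewer than 10 observations in an outcome level; "
                "Brant-Wald test may be unstable",
                stacklevel=2,
            )
        fit.brant_stat, fit.brant_df, fit.brant_p = brant_wald(codes, X)
    return fit


def brant_wald(y_codes: np.ndarray, X: pd.DataFrame) -> tuple[float, int, float]:
    """Brant-Wald chi-square test of the proportional-odds assumption.

    Fits the J-1 binary logits of I(y > j), stacks their slope
    estimates, builds the joint covariance from Brant's moment formula,
    and tests pairwise equality of each predictor's slopes across the
    logits; df = (J-2) * p.
    """
    y_codes = np.asarray(y_codes)
    levels = np.unique(y_codes)
    j = len(levels)
    if j < 3:
        raise ValueError("Brant-Wald requires at least 3 outcome levels")
    Xc = sm.add_constant(np.asarray(X, dtype=float), prepend=True)
    n, p1 = Xc.shape
    p = p1 - 1
    m = j - 1

    betas, pis = [], []
    for cut in levels[:-1]:
        z = (y_codes > cut).astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(z, Xc).fit(disp=False, maxiter=200)
            except Exception as exc:  # perfect separation raises inside
                raise SeparationError(f"binary logit at cut {cut} failed: {exc}")
        if not res.mle_retvals.get("converged", True) or np.max(np.abs(res.params)) > 30:
            raise SeparationError(f"binary logit at cut {cut} separated")
        betas.append(res.params)
        pis.append(res.predict(Xc))

    # joint covariance of the stacked slope vectors (Brant 1990)
    V = np.zeros((m * p, m * p))
    inv_info = []
    for a in range(m):
        w = pis[a] * (1.0 - pis[a])
        inv_info.append(np.linalg.inv(Xc.T @ (Xc * w[:, None])))
    for a in range(m):
        for b in range(a, m):
            if a == b:
                block = inv_info[a]
            else:
                w_ab = pis[b] - pis[a] * pis[b]  # pi_b(1 - pi_a), b > a
                block = inv_info[a] @ (Xc.T @ (Xc * w_ab[:, None])) @ inv_info[b]
            V[a * p : (a + 1) * p, b * p : (b + 1) * p] = block[1:, 1:]
            if b != a:
                V[b * p : (b + 1) * p, a * p : (a + 1) * p] = block[1:, 1:].T
    beta_stack = np.concatenate([b[1:] for b in betas])

    # contrasts: slopes of logit 1 minus each later logit, per predictor
    D = np.zeros(((m - 1) * p, m * p))
    for a in range(m - 1):
        D[a * p : (a + 1) * p, 0:p] = np.eye(p)
        D[a * p : (a + 1) * p, (a + 1) * p : (a + 2) * p] = -np.eye(p)
    diff = D @ beta_stack
    stat = float(diff @ np.linalg.solve(D @ V @ D.T, diff))
    df = (j - 2) * p
    return stat, df, float(stats.chi2.sf(stat, df))


def tidy(fit: OrdinalFit) -> pd.DataFrame:
    """Tidy odds-ratio table with the Brant-Wald diagnostic attached."""
    out = fit.odds_ratios().reset_index(names="term")
    out["brant_stat"] = fit.brant_stat
    out["brant_p"] = fit.brant_p
    return out
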