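"""Left-censored maximum likelihood: likelihood terms, fitting,
equivariance, and an independent cross-check against R's survreg."""

import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import fatigability as fg
from fatigability.tobit import DesignMatrix, partial_r2, tobit_fit, tobit_loglik


def simulate_tobit(n, beta, sigma, seed=0, intercept=0.0):
    rng = np.random.default_rng(seed)
    p = len(beta)
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
    lat = X @ np.r_[intercept, beta] + rng.normal(0, sigma, n)
    y = np.maximum(0.0, lat)
    names = ["intercept"] + [f"x{i}" for i in range(p)]
    return DesignMatrix(y, X, names)


class TestLoglik:
    def test_equals_gaussian_when_uncensored(self, rng):
        n = 50
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = 5.0 + X[:, 1] + rng.normal(0, 1.0, n)
        y = y - y.min() + 1.0  # strictly positive: no censoring
        d = DesignMatrix(y, X, ["intercept", "x"])
        beta = np.array([5.0, 1.0])
        sigma = 1.3
        expected = float(np.sum(stats.norm.logpdf(y, X @ beta, sigma)))
        assert tobit_loglik(beta, np.log(sigma), d) == pytest.approx(expected)

    def test_censored_at_linear_predictor_gives_log_half(self):
        d = DesignMatrix(np.array([0.0]), np.array([[1.0]]), ["intercept"])
        assert tobit_loglik(np.array([0.0]), 0.0, d) == pytest.approx(np.log(0.5))

    def test_five_row_hand_oracle(self):
        # term-by-term brute force with explicit cdf/pdf calls
        y = np.array([0.0, 0.0, 1.2, 3.4, 0.7])
        x = np.array([-1.0, 0.5, 0.2, 1.5, -0.3])
        X = np.column_stack([np.ones(5), x])
        beta = np.array([0.4, 0.9])
        sigma = 1.1
        expected = 0.0
        for yi, xi in zip(y, X):
            mu = xi @ beta
            if yi == 0.0:
                expected += np.log(stats.norm.cdf((0.0 - mu) / sigma))
            else:
                expected += np.log(stats.norm.pdf((yi - mu) / sigma) / sigma)
        d = DesignMatrix(y, X, ["intercept", "x"])
        assert tobit_loglik(beta, np.log(sigma), d) == pytest.approx(expected, abs=1e-10)


class TestFit:
    def test_reduces_to_ols_without_censoring(self, rng):
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = 20.0 + X[:, 1] - 0.5 * X[:, 2] + rng.normal(0, 1.0, n)
        d = DesignMatrix(y, X, ["intercept", "x1", "x2"])
        fit = tobit_fit(d)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.max(np.abs(fit.beta.to_numpy() - ols)) < 1e-4
        assert fit.n_censored == 0

    def test_consistency_at_large_n(self):
        # beta=(1,2), sigma=3 with ~40% censoring
        d = simulate_tobit(10000, [1.0, 2.0], 3.0, seed=4, intercept=0.8)
        assert 0.3 < d.censored.mean() < 0.5
        fit = tobit_fit(d)
        for name, truth in [("intercept", 0.8), ("x0", 1.0), ("x1", 2.0)]:
            assert abs(fit.beta[name] - truth) < 3.0 * fit.se[name]
        assert fit.sigma == pytest.approx(3.0, rel=0.05)

    def test_outcome_rescaling_equivariance(self):
        d = simulate_tobit(400, [1.0], 2.0, seed=5, intercept=1.0)
        c = 7.0
        d_scaled = DesignMatrix(c * d.y, d.X, d.names)
        f1 = tobit_fit(d)
        f2 = tobit_fit(d_scaled)
        assert np.allclose(f2.beta.to_numpy(), c * f1.beta.to_numpy(), rtol=1e-5)
        assert f2.sigma == pytest.approx(c * f1.sigma, rel=1e-5)

    def test_optimum_dominates_random_perturbations(self, rng):
        d = simulate_tobit(300, [0.7, -0.4], 1.5, seed=6, intercept=0.5)
        fit = tobit_fit(d)
        theta_hat = np.append(fit.beta.to_numpy(), np.log(fit.sigma))
        ll_hat = fit.loglik
        for _ in range(100):
            pert = theta_hat + rng.normal(0, 0.05, len(theta_hat))
            assert tobit_loglik(pert[:-1], pert[-1], d) <= ll_hat + 1e-9

    def test_ci_is_beta_plus_minus_1_96_se(self):
        d = simulate_tobit(300, [0.7], 1.5, seed=8)
        fit = tobit_fit(d)
        z = stats.norm.ppf(0.975)
        assert np.allclose(
            fit.ci95["hi"] - fit.beta, z * fit.se, rtol=1e-10
        )

    def test_all_censored_rejected(self):
        d = DesignMatrix(np.zeros(30), np.ones((30, 1)), ["intercept"])
        with pytest.raises(ValueError, match="censored"):
            tobit_fit(d)

    def test_missing_cells_rejected(self):
        X = np.ones((30, 1))
        y = np.ones(30)
        y[3] = np.nan
        with pytest.raises(ValueError, match="missing"):
            DesignMatrix(y, X, ["intercept"])

    def test_matches_r_survreg(self):
        """Independent oracle: survival::survreg left-censored gaussian."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; cross-check cannot run")
        d = simulate_tobit(300, [0.8, -0.5], 1.5, seed=11, intercept=1.0)
        fit = tobit_fit(d)
        with tempfile.TemporaryDirectory() as td:
            csv = Path(td) / "d.csv"
            pd.DataFrame({"y": d.y, "x1": d.X[:, 1], "x2": d.X[:, 2]}).to_csv(
                csv, index=False
            )
            rcode = (
                "suppressMessages(library(survival));"
                f"d <- read.csv('{csv}');"
                "f <- survreg(Surv(y, y>0, type='left') ~ x1 + x2,"
                "             data=d, dist='gaussian');"
                "cat(coef(f), f$scale, f$loglik[2], sep='\\n')"
            )
            out = subprocess.run(
                ["Rscript", "-e", rcode], capture_output=True, text=True, check=True
            )
        vals = [float(v) for v in out.stdout.split()]
        assert np.allclose(fit.beta.to_numpy(), vals[:3], atol=2e-4)
        assert fit.sigma == pytest.approx(vals[3], abs=2e-4)
        assert fit.loglik == pytest.approx(vals[4], abs=1e-3)


class TestPartialR2:
    def test_zero_when_exposure_has_no_effect(self):
        rng = np.random.default_rng(3)
        n = 2000
        x_cov = rng.normal(size=n)
        x_expo = rng.normal(size=n)  # independent of the outcome
        y = np.maximum(0.0, 1.0 + 0.8 * x_cov + rng.normal(0, 2.0, n))
        full = tobit_fit(
            DesignMatrix(
                y,
                np.column_stack([np.ones(n), x_expo, x_cov]),
                ["intercept", "expo", "cov"],
            ),
            exposure="expo",
        )
        assert 0.0 <= full.partial_r2_exposure < 0.01

    def test_matches_ols_r2_single_predictor_uncensored(self):
        rng = np.random.default_rng(9)
        n = 3000
        x = rng.normal(size=n)
        y = 30.0 + 2.0 * x + rng.normal(0, 3.0, n)  # far from 0: uncensored
        X = np.column_stack([np.ones(n), x])
        fit = tobit_fit(DesignMatrix(y, X, ["intercept", "x"]), exposure="x")
        ss_res = np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2_ols = 1.0 - ss_res / ss_tot
        assert fit.partial_r2_exposure == pytest.approx(r2_ols, abs=0.01)

    def test_monotone_in_generating_effect(self):
        means = []
        for effect in (0.55, 2.0):
            vals = []
            for seed in range(5):
                df = fg.simulate_cohort(
                    fg.default_params(n=795, effect_per_sd=effect, seed=seed)
                )
                seq = fg.run_model_sequence(
                    df, "max_oxphos", tiers=(3,), fit_ordinal=False
                )
                vals.append(seq.tobit_fits[3].partial_r2_exposure)
            means.append(np.mean(vals))
        assert means[1] > means[0]

    def test_row_mismatch_rejected(self):
        d1 = simulate_tobit(100, [1.0], 2.0, seed=1)
        d2 = simulate_tobit(120, [1.0], 2.0, seed=2)
        with pytest.raises(ValueError, match="same rows"):
            partial_r2(tobit_fit(d1), tobit_fit(d2))
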