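"""Simulation studies validating the pipeline end to end.

These drivers run the package against its own synthetic generators at
study scale: parameter recovery for the censored-regression effect,
calibration of the generator's censored outcome, spectral cadence
accuracy against ground truth, score-bound sweeps, and type-I-error
calibration of the Brant-Wald and interaction Wald tests under their
respective nulls.  Every study takes a single integer seed and derives
independent per-replicate streams from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import synthetic
from .analysis import interaction_and_strata, run_model_sequence
from .cadence import extract
from .ordinal import brant_wald
from .ppfi import compute_ppfi, smooth_trajectory, SmoothedTrajectory
from .synthetic import WalkProfile, default_params, linear_decline, simulate_cohort

_SEED_MAX = 2**31 - 1


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, _SEED_MAX, size=n)


@dataclass
class RecoveryStudy:
    betas: np.ndarray
    covered: np.ndarray
    true_effect: float

    @property
    def mean_beta(self) -> float:
        return float(self.betas.mean())

    @property
    def mc_se(self) -> float:
        return float(self.betas.std(ddof=1) / np.sqrt(len(self.betas)))

    @property
    def coverage(self) -> float:
        return float(self.covered.mean())


def tobit_recovery_study(
    n_cohorts: int = 500, n: int = 795, seed: int = 0
) -> RecoveryStudy:
    """Repeatedly simulate default cohorts and refit the fully adjusted
    tobit; returns the exposure-estimate distribution and the 95% CI
    coverage of the generating per-1-SD effect."""
    seeds = _child_seeds(seed, n_cohorts)
    truth = default_params().effect_per_sd
    term = f"{default_params().primary_exposure}_neg_z"
    betas = np.empty(n_cohorts)
    covered = np.empty(n_cohorts, dtype=bool)
    for i, s in enumerate(seeds):
        df = simulate_cohort(default_params(n=n, seed=int(s)))
        seq = run_model_sequence(
            df,
            default_params().primary_exposure,
            tiers=(3,),
            fit_ordinal=False,
            compute_partial=False,
        )
        fit = seq.tobit_fits[3]
        betas[i] = fit.beta[term]
        covered[i] = fit.ci95.loc[term, "lo"] <= truth <= fit.ci95.loc[term, "hi"]
    return RecoveryStudy(betas, covered, truth)


def calibration_study(n: int = 50000, seed: int = 7) -> dict:
    """Zero fraction and median of the simulated score at large n,
    against the calibration targets baked into the defaults."""
    df = simulate_cohort(default_params(n=n, seed=seed))
    return {
        "zero_fraction": float((df["ppfi"] == 0).mean()),
        "median": float(df["ppfi"].median()),
        "n": n,
    }


def cadence_accuracy_study(n_profiles: int = 100, seed: int = 0) -> dict:
    """Pooled RMSE and bias of extracted versus true cadence over random
    declining-walk profiles."""
    seeds = _child_seeds(seed, n_profiles)
    errs = []
    for s in seeds:
        rng = np.random.default_rng(int(s))
        c0 = rng.uniform(95.0, 120.0)
        c1 = c0 - rng.uniform(0.0, 25.0)
        profile = WalkProfile(
            cadence_fn=linear_decline(c0, c1, rng.uniform(250.0, 420.0)),
            seed=int(s),
        )
        rec, truth = synthetic.simulate_walk(profile)
        series = extract(rec)
        m = min(len(series.cadence_spm), len(truth.cadence_spm))
        sl = slice(5, m - 5)
        errs.append(series.cadence_spm[sl] - truth.cadence_spm[sl])
    errs = np.concatenate(errs)
    return {
        "rmse": float(np.sqrt(np.mean(errs**2))),
        "bias": float(np.mean(errs)),
        "n_profiles": n_profiles,
    }


def score_bound_study(n_trajectories: int = 1000, seed: int = 0) -> dict:
    """Smooth and score random non-negative trajectories; returns the
    extreme scores observed (all must lie in [0, 100])."""
    seeds = _child_seeds(seed, n_trajectories)
    scores = np.empty(n_trajectories)
    for i, s in enumerate(seeds):
        rng = np.random.default_rng(int(s))
        m = rng.integers(60, 400)
        t = np.arange(m, dtype=float)
        base = rng.uniform(60.0, 130.0)
        drift = rng.uniform(-0.15, 0.05) * t
        wander = np.cumsum(rng.normal(0.0, rng.uniform(0.0, 1.0), m))
        vals = np.clip(base + drift + wander + rng.normal(0, 2.0, m), 0.0, 300.0)
        from .cadence import CadenceSeries

        smoothed = smooth_trajectory(CadenceSeries(t, vals))
        if smoothed.fitted_spm.max() <= 0:
            scores[i] = 0.0
            continue
        scores[i] = compute_ppfi(smoothed, completion_time_s=400.0).score
    return {
        "min": float(scores.min()),
        "max": float(scores.max()),
        "n": n_trajectories,
    }


def _simulate_proportional_odds(
    n: int, beta: float, thresholds: tuple[float, ...], rng: np.random.Generator
) -> tuple[np.ndarray, pd.DataFrame]:
    x = rng.normal(size=n)
    latent = beta * x + rng.logistic(size=n)
    return np.digitize(latent, thresholds), pd.DataFrame({"x": x})


def brant_type1_study(
    n_sims: int = 500, n: int = 795, beta: float = 0.5, seed: int = 0
) -> dict:
    """Rejection rate of the Brant-Wald test at alpha = 0.05 on data
    generated from a proportional-odds model (its null)."""
    seeds = _child_seeds(seed, n_sims)
    rejections = 0
    for s in seeds:
        rng = np.random.default_rng(int(s))
        y, X = _simulate_proportional_odds(n, beta, (-1.0, 1.0), rng)
        if len(np.unique(y)) < 3:
            y[:3] = [0, 1, 2]  # vanishing chance at this n
        _, _, p = brant_wald(y, X)
        rejections += p < 0.05
    return {"rejection_rate": rejections / n_sims, "n_sims": n_sims}


def interaction_type1_study(
    n_sims: int = 500, n: int = 795, seed: int = 0, modifier: str = "sppb_binary"
) -> dict:
    """Rejection rate of the exposure-by-modifier Wald test on default
    cohorts, which contain no interaction (its null)."""
    seeds = _child_seeds(seed, n_sims)
    rejections = 0
    for s in seeds:
        df = simulate_cohort(default_params(n=n, seed=int(s)))
        res = interaction_and_strata(df, default_params().primary_exposure, modifier)
        rejections += res.interaction_p < 0.05
    return {"rejection_rate": rejections / n_sims, "n_sims": n_sims}
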