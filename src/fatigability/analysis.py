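"""Cohort-level analysis: descriptives, correlations, tiered models.

Reproduces the structure of a muscle-energetics / fatigability study:
per-stratum descriptive table with trend tests, Spearman correlations
between each exposure and the fatigability score, tobit and
proportional-odds models with progressive covariate adjustment, and
interaction / physical-function-stratified analyses.

Model tiers accumulate covariates:

* Model 1 — technician/site, age, sex, race
* Model 2 — Model 1 + height, weight
* Model 3 — Model 2 + total activity count

Exposures are standardized to z-scores on their complete cases and
sign-flipped before modelling, so every reported coefficient or odds
ratio is "per 1 SD lower" exposure.  Analyses are complete-case per
exposure: subjects missing an exposure are excluded only from that
exposure's models.  Alpha is 0.05 two-sided throughout, with no
multiplicity adjustment.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import ordinal as ordinal_mod
from . import tobit as tobit_mod
from .ppfi import STRATA

EXPOSURES = ["max_oxphos", "max_ets", "atp_max"]

MODEL_TIERS = {
    1: ["age", "female", "white"],  # plus site/technician dummies
    2: ["age", "female", "white", "height_cm", "weight_kg"],
    3: ["age", "female", "white", "height_cm", "weight_kg", "total_activity_count"],
}

# pre-declared test families (a config choice, not a runtime normality test)
SKEWED_VARS = ["ppfi", "max_oxphos", "max_ets", "atp_max"]
NORMAL_VARS = ["age", "height_cm", "weight_kg", "sppb", "total_activity_count"]
CATEGORICAL_VARS = {"sex": "female", "race": "white"}

SPPB_CUT = 10  # better function: SPPB >= 10


def standardize_exposures(
    table: pd.DataFrame, exposures: list[str] | None = None
) -> tuple[pd.DataFrame, dict]:
    """Add z-score and negated-z columns per exposure.

    Means/SDs come from each exposure's complete cases.  The negated
    copy ``<name>_neg_z`` is what the models use, so coefficients read
    "per 1 SD lower".  Returns the augmented table and a registry
    {exposure: {"mean": m, "sd": s, "n": n}} for reporting effects on
    the raw scale.
    """
    exposures = exposures or [e for e in EXPOSURES if e in table.columns]
    out = table.copy()
    registry: dict[str, dict] = {}
    for name in exposures:
        vals = out[name].dropna()
        sd = float(vals.std(ddof=1))
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"exposure {name!r} has zero variance")
        mean = float(vals.mean())
        out[f"{name}_z"] = (out[name] - mean) / sd
        out[f"{name}_neg_z"] = -out[f"{name}_z"]
        registry[name] = {"mean": mean, "sd": sd, "n": int(vals.size)}
    return out, registry


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p (t approximation);
    mid-ranks for ties.  Requires >= 4 complete pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 4:
        raise ValueError("need at least 4 complete pairs")
    r, p = stats.spearmanr(x[ok], y[ok])
    return float(r), float(p)


def _prep_model_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Analytic codings: indicator covariates and site/technician
    dummies (reference level dropped)."""
    df = table.copy()
    df["female"] = (df["sex"] == "female").astype(float)
    df["white"] = (df["race"] == "white").astype(float)
    dummies = pd.get_dummies(df["site_tech"], prefix="st", drop_first=True)
    for c in dummies.columns:
        df[c] = dummies[c].astype(float)
    df.attrs["site_tech_dummies"] = list(dummies.columns)
    return df


def _tier_predictors(df: pd.DataFrame, tier: int) -> list[str]:
    return df.attrs["site_tech_dummies"] + MODEL_TIERS[tier]


def describe_by_strata(table: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum descriptive table with trend tests.

    Pre-declared skewed variables get median [IQR] and Kruskal-Wallis;
    approximately normal ones get mean±sd and one-way ANOVA;
    categoricals get n (%) and a chi-square test.  An empty stratum
    yields n = 0 summaries and a skipped test with a warning.
    """
    groups = {s: table[table["stratum"] == s] for s in STRATA}
    empty = [s for s, g in groups.items() if len(g) == 0]
    if empty:
        warnings.warn(f"empty strata {empty}; trend tests skipped", stacklevel=2)

    rows = []

    def _cell_cont(g, var, skewed):
        v = g[var].dropna()
        if len(v) == 0:
            return "n=0"
        if skewed:
            return f"{v.median():.2f} [{v.quantile(0.25):.2f}, {v.quantile(0.75):.2f}]"
        return f"{v.mean():.1f} ± {v.std(ddof=1):.1f}"

    for var in SKEWED_VARS + NORMAL_VARS:
        if var not in table.columns:
            continue
        skewed = var in SKEWED_VARS
        samples = [g[var].dropna().to_numpy() for g in groups.values() if len(g)]
        p = np.nan
        if not empty and all(len(s) > 1 for s in samples):
            if skewed:
                p = stats.kruskal(*samples).pvalue
            else:
                p = stats.f_oneway(*samples).pvalue
        rows.append(
            {
                "variable": var,
                "summary": "median [IQR]" if skewed else "mean ± sd",
                **{s: _cell_cont(g, var, skewed) for s, g in groups.items()},
                "p_trend": p,
            }
        )

    for var, level in CATEGORICAL_VARS.items():
        if var not in table.columns:
            continue
        counts = [(g[var] == level).sum() for g in groups.values()]
        ns = [len(g) for g in groups.values()]
        p = np.nan
        if not empty:
            contingency = np.array([counts, [n - c for n, c in zip(ns, counts)]])
            p = stats.chi2_contingency(contingency, correction=False).pvalue
        rows.append(
            {
                "variable": f"{var}={level}",
                "summary": "n (%)",
                **{
                    s: f"{c} ({100 * c / n:.1f}%)" if n else "n=0"
                    for s, c, n in zip(groups, counts, ns)
                },
                "p_trend": p,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ModelSequenceResult:
    exposure: str
    sd_registry: dict
    tobit_fits: dict[int, tobit_mod.TobitFit] = field(default_factory=dict)
    ordinal_fits: dict[int, ordinal_mod.OrdinalFit] = field(default_factory=dict)
    n_used: dict[int, int] = field(default_factory=dict)

    def tidy(self) -> pd.DataFrame:
        rows = []
        for tier in sorted(self.tobit_fits):
            tf = self.tobit_fits[tier]
            of = self.ordinal_fits.get(tier)
            term = f"{self.exposure}_neg_z"
            rows.append(
                {
                    "exposure": self.exposure,
                    "model": tier,
                    "n": tf.n,
                    "beta": tf.beta[term],
                    "se": tf.se[term],
                    "ci_lo": tf.ci95.loc[term, "lo"],
                    "ci_hi": tf.ci95.loc[term, "hi"],
                    "partial_r2": tf.partial_r2_exposure,
                    "or": of.or_per_sd if of else np.nan,
                    "or_ci_lo": of.or_ci95[0] if of else np.nan,
                    "or_ci_hi": of.or_ci95[1] if of else np.nan,
                    "brant_p": of.brant_p if of else np.nan,
                }
            )
        return pd.DataFrame(rows)


def run_model_sequence(
    table: pd.DataFrame,
    exposure: str,
    tiers: tuple[int, ...] = (1, 2, 3),
    fit_ordinal: bool = True,
    compute_partial: bool = True,
) -> ModelSequenceResult:
    """Tobit (continuous score) and proportional-odds (severity) fits
    for one exposure across the covariate tiers, complete-case on that
    exposure.  ``compute_partial=False`` skips the exposure-free refit
    (useful in simulation loops that only need the coefficient)."""
    df = _prep_model_frame(table)
    df, registry = standardize_exposures(df, [exposure])
    result = ModelSequenceResult(exposure=exposure, sd_registry=registry)
    term = f"{exposure}_neg_z"
    for tier in tiers:
        predictors = [term] + _tier_predictors(df, tier)
        sub = df.dropna(subset=[term] + predictors + ["ppfi"])
        design = tobit_mod.DesignMatrix.from_frame(sub, "ppfi", predictors)
        result.tobit_fits[tier] = tobit_mod.tobit_fit(
            design, exposure=term if compute_partial else None
        )
        result.n_used[tier] = design.X.shape[0]
        if fit_ordinal:
            result.ordinal_fits[tier] = ordinal_mod.ordinal_fit(
                sub["stratum"],
                sub[predictors],
                order=list(STRATA),
                exposure=term,
            )
    return result


@dataclass
class InteractionResult:
    exposure: str
    modifier: str
    interaction_beta: float
    interaction_se: float
    interaction_p: float
    stratified: dict[str, tobit_mod.TobitFit | None]


def interaction_and_strata(
    table: pd.DataFrame, exposure: str, modifier: str, stratified: bool = True
) -> InteractionResult:
    """Exposure-by-modifier interaction on the Model-3 tobit, plus
    physical-function-stratified fits.

    ``modifier`` is ``"sex"`` (female indicator) or ``"sppb_binary"``
    (SPPB >= 10).  The Wald p-value of the product term tests effect
    modification; stratified Model-3 fits are run within SPPB >= 10
    and SPPB < 10 regardless of modifier (a stratum with fewer than
    p + 5 rows is skipped with a warning).
    """
    df = _prep_model_frame(table)
    df, _ = standardize_exposures(df, [exposure])
    term = f"{exposure}_neg_z"

    if modifier == "sex":
        df["modifier"] = df["female"]
    elif modifier == "sppb_binary":
        df["modifier"] = (df["sppb"] >= SPPB_CUT).astype(float)
    else:
        raise ValueError("modifier must be 'sex' or 'sppb_binary'")
    if df["modifier"].nunique() < 2:
        raise ValueError(f"modifier {modifier!r} is constant in this cohort")
    df["interaction"] = df[term] * df["modifier"]

    base = _tier_predictors(df, 3)
    predictors = [term] + base + (["modifier"] if modifier == "sppb_binary" else [])
    predictors = predictors + ["interaction"]
    sub = df.dropna(subset=[term, "ppfi"])
    design = tobit_mod.DesignMatrix.from_frame(sub, "ppfi", predictors)
    fit = tobit_mod.tobit_fit(design)
    b = fit.beta["interaction"]
    s = fit.se["interaction"]
    p = float(2.0 * stats.norm.sf(abs(b / s)))

    strat_fits: dict[str, tobit_mod.TobitFit | None] = {}
    high = (df["sppb"] >= SPPB_CUT).to_numpy()
    labelled = (("sppb_ge_10", high), ("sppb_lt_10", ~high)) if stratified else ()
    for label, mask in labelled:
        strat = df[mask].dropna(subset=[term, "ppfi"])
        strat_pred = [term] + base
        if len(strat) < len(strat_pred) + 6:
            warnings.warn(f"stratum {label} too small; fit skipped", stacklevel=2)
            strat_fits[label] = None
            continue
        d = tobit_mod.DesignMatrix.from_frame(strat, "ppfi", strat_pred)
        strat_fits[label] = tobit_mod.tobit_fit(d)
    return InteractionResult(exposure, modifier, float(b), float(s), p, strat_fits)


def analyze(
    table: pd.DataFrame,
    out_dir: str | Path,
    exposures: list[str] | None = None,
    seed: int | None = None,
    config: dict | None = None,
) -> dict:
    """Full pipeline over all exposures; writes table1.csv,
    correlations.csv, models.csv, interactions.csv and a run manifest.
    Returns the in-memory report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    exposures = exposures or [e for e in EXPOSURES if e in table.columns]

    table1 = describe_by_strata(table)
    table1.to_csv(out_dir / "table1.csv", index=False)

    corr_rows = []
    for e in exposures:
        r, p = spearman(table[e], table["ppfi"])
        corr_rows.append({"exposure": e, "r_s": r, "p": p, "n": table[e].notna().sum()})
    correlations = pd.DataFrame(corr_rows)
    correlations.to_csv(out_dir / "correlations.csv", index=False)

    model_frames = []
    for e in exposures:
        model_frames.append(run_model_sequence(table, e).tidy())
    models = pd.concat(model_frames, ignore_index=True)
    models.to_csv(out_dir / "models.csv", index=False)

    inter_rows = []
    for e in exposures:
        for modifier in ("sex", "sppb_binary"):
            res = interaction_and_strata(table, e, modifier)
            row = {
                "exposure": e,
                "modifier": modifier,
                "interaction_beta": res.interaction_beta,
                "interaction_p": res.interaction_p,
            }
            for label, f in res.stratified.items():
                term = f"{e}_neg_z"
                row[f"beta_{label}"] = f.beta[term] if f is not None else np.nan
            inter_rows.append(row)
    interactions = pd.DataFrame(inter_rows)
    interactions.to_csv(out_dir / "interactions.csv", index=False)

    cfg_repr = json.dumps(config or {}, sort_keys=True, default=str)
    manifest = {
        "n": int(len(table)),
        "exposures": exposures,
        "seed": seed,
        "config_hash": hashlib.sha256(cfg_repr.encode()).hexdigest()[:16],
        "strata_counts": table["stratum"].value_counts().to_dict(),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "table1": table1,
        "correlations": correlations,
        "models": models,
        "interactions": interactions,
        "manifest": manifest,
    }
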