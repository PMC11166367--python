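"""Cohort analysis: standardization, correlations, descriptive table,
tiered models, interactions, and pipeline determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import fatigability as fg
from fatigability.analysis import (
    analyze,
    describe_by_strata,
    interaction_and_strata,
    run_model_sequence,
    spearman,
    standardize_exposures,
)


class TestStandardize:
    def test_z_columns_have_zero_mean_unit_sd(self, default_cohort):
        out, registry = standardize_exposures(default_cohort)
        for e in ("max_oxphos", "max_ets", "atp_max"):
            z = out[f"{e}_z"].dropna()
            assert z.mean() == pytest.approx(0.0, abs=1e-10)
            assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-10)
            assert np.allclose(out[f"{e}_neg_z"], -out[f"{e}_z"], equal_nan=True)

    def test_registry_matches_generating_sds(self, default_cohort):
        _, registry = standardize_exposures(default_cohort)
        # generating SDs 18.4 / 22.1 / 0.15; sample SD error ~ sd/sqrt(2n)
        assert registry["max_oxphos"]["sd"] == pytest.approx(18.4, rel=0.08)
        assert registry["max_ets"]["sd"] == pytest.approx(22.1, rel=0.08)
        assert registry["atp_max"]["sd"] == pytest.approx(0.15, rel=0.08)

    def test_constant_column_rejected(self, default_cohort):
        df = default_cohort.copy()
        df["max_oxphos"] = 50.0
        with pytest.raises(ValueError, match="variance"):
            standardize_exposures(df, ["max_oxphos"])


class TestSpearman:
    def test_strictly_monotone_gives_one(self):
        x = np.arange(10.0)
        r, _ = spearman(x, np.exp(x))
        assert r == pytest.approx(1.0)

    def test_hand_ranked_example(self):
        # sum d^2 = 4 -> 1 - 6*4/(5*24) = 0.8
        r, p = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert r == pytest.approx(0.8, abs=1e-12)
        assert 0.0 < p < 1.0

    def test_equals_pearson_on_ranks(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50) + 0.5 * x
        r, _ = spearman(x, y)
        oracle = stats.pearsonr(stats.rankdata(x), stats.rankdata(y))[0]
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2, 3])

    def test_exposure_score_correlation_is_negative(self):
        # the default effect makes lower energetics go with higher PPFI
        negative = 0
        n_seeds = 50
        for seed in range(n_seeds):
            df = fg.simulate_cohort(fg.default_params(n=795, seed=seed))
            r, _ = spearman(df["max_oxphos"], df["ppfi"])
            negative += r < 0
        assert negative >= 0.95 * n_seeds


class TestDescribeByStrata:
    def test_null_kruskal_wallis_p_is_uniform(self):
        # identical distributions across strata: p ~ U(0,1)
        pvals = []
        for seed in range(300):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(
                {
                    "stratum": np.repeat(
                        ["none", "mild", "moderate_to_severe"], 60
                    ),
                    "ppfi": rng.exponential(2.0, 180),
                }
            )
            block = describe_by_strata(df)
            pvals.append(block.loc[block.variable == "ppfi", "p_trend"].iloc[0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_homogeneous_categorical_gives_p_one(self):
        df = pd.DataFrame(
            {
                "stratum": np.repeat(["none", "mild", "moderate_to_severe"], 40),
                "sex": ["female", "male"] * 60,
            }
        )
        block = describe_by_strata(df)
        p = block.loc[block.variable == "sex=female", "p_trend"].iloc[0]
        assert p == pytest.approx(1.0)

    def test_separated_means_detected(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "stratum": np.repeat(["none", "mild", "moderate_to_severe"], 200),
                "age": np.concatenate(
                    [rng.normal(m, 1.0, 200) for m in (0.0, 1.0, 2.0)]
                ),
            }
        )
        block = describe_by_strata(df)
        assert block.loc[block.variable == "age", "p_trend"].iloc[0] < 0.001

    def test_empty_stratum_warns_and_skips_tests(self, default_cohort):
        df = default_cohort[default_cohort["stratum"] != "moderate_to_severe"]
        with pytest.warns(UserWarning, match="empty"):
            block = describe_by_strata(df)
        assert block["p_trend"].isna().all()


class TestModelSequence:
    def test_complete_case_bookkeeping(self, default_cohort):
        n_missing = default_cohort["max_ets"].isna().sum()
        seq = run_model_sequence(
            default_cohort, "max_ets", tiers=(3,), fit_ordinal=False
        )
        assert seq.n_used[3] == len(default_cohort) - n_missing

    def test_null_covariates_leave_exposure_stable_across_tiers(self):
        # covariate effects are zero in the generator, so adjustment
        # should not move the exposure estimate beyond Monte-Carlo noise
        diffs, ses = [], []
        for seed in range(20):
            df = fg.simulate_cohort(fg.default_params(n=795, seed=100 + seed))
            seq = run_model_sequence(df, "max_oxphos", tiers=(1, 3), fit_ordinal=False)
            term = "max_oxphos_neg_z"
            diffs.append(seq.tobit_fits[1].beta[term] - seq.tobit_fits[3].beta[term])
            ses.append(seq.tobit_fits[3].se[term])
        mc_se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 2.0 * max(mc_se, 1e-6)

    def test_tidy_layout(self, default_cohort):
        seq = run_model_sequence(default_cohort, "max_oxphos", tiers=(3,))
        tidy = seq.tidy()
        assert set(tidy.columns) >= {"beta", "ci_lo", "ci_hi", "or", "partial_r2"}
        row = tidy.iloc[0]
        assert row.ci_lo < row.beta < row.ci_hi
        assert 0.0 <= row.partial_r2 < 1.0


class TestInteractions:
    def test_constant_modifier_rejected(self, default_cohort):
        df = default_cohort.copy()
        df["sppb"] = 12
        with pytest.raises(ValueError, match="constant"):
            interaction_and_strata(df, "max_oxphos", "sppb_binary")

    def test_stratified_effect_pattern(self):
        # effect present only in the better-function stratum shows up there
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            df = fg.simulate_cohort(
                fg.default_params(n=795, effect_per_sd=0.0, seed=300 + seed)
            )
            high = df["sppb"] >= 10
            z = -(df["max_oxphos"] - df["max_oxphos"].mean()) / df["max_oxphos"].std()
            df.loc[high, "ppfi"] = np.maximum(
                0.0, df.loc[high, "ppfi"] + 1.5 * z[high]
            )
            res = interaction_and_strata(df, "max_oxphos", "sppb_binary")
            term = "max_oxphos_neg_z"
            b_hi = res.stratified["sppb_ge_10"].beta[term]
            b_lo = res.stratified["sppb_lt_10"].beta[term]
            hits += b_hi > b_lo
        assert hits >= 9

    def test_interaction_p_in_unit_interval(self, default_cohort):
        res = interaction_and_strata(default_cohort, "max_oxphos", "sex")
        assert 0.0 <= res.interaction_p <= 1.0


class TestAnalyzePipeline:
    def test_outputs_and_determinism(self, tmp_path, default_cohort):
        out1 = tmp_path / "r1"
        out2 = tmp_path / "r2"
        analyze(default_cohort, out1, exposures=["max_oxphos"], seed=1)
        analyze(default_cohort, out2, exposures=["max_oxphos"], seed=1)
        for name in ("table1.csv", "correlations.csv", "models.csv", "interactions.csv"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()

    def test_strata_counts_sum_to_n(self, tmp_path, default_cohort):
        report = analyze(
            default_cohort, tmp_path / "r", exposures=["max_oxphos"], seed=1
        )
        counts = report["manifest"]["strata_counts"]
        assert sum(counts.values()) == len(default_cohort)
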