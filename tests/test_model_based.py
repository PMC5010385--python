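"""Exponential fits, residual structure, and the mixed-ANOVA engine."""

import itertools

import numpy as np
import pandas as pd
import pytest

from memtag.model_based import (
    MixedAnova,
    fit_exponential,
    mixed_anova,
    residual_anova,
    residual_block_means,
    residual_block_table,
    training_anova,
    velocity_anova,
)
from memtag.synthcohort import CohortConfig, GenerativeParams, simulate_cohort
from memtag.preprocess import subtract_baseline
from oracles import bruteforce_anova_2x2x2

N = np.arange(1, 89.0)


# ----------------------------------------------------------------- fitting


class TestExponentialFit:
    def test_noiseless_double_recovery(self):
        y = -1.5 * np.exp(-0.15 * N) - 0.5 * np.exp(-0.01 * N) + 0.2
        fit = fit_exponential(y, model="double")
        assert fit.sse < 1e-10
        assert fit.params["A1"] == pytest.approx(-1.5, abs=1e-6)
        assert fit.params["B1"] == pytest.approx(-0.15, abs=1e-6)
        assert fit.params["A2"] == pytest.approx(-0.5, abs=1e-6)
        assert fit.params["B2"] == pytest.approx(-0.01, abs=1e-6)
        assert fit.params["C"] == pytest.approx(0.2, abs=1e-6)
        assert abs(fit.params["B1"]) >= abs(fit.params["B2"])  # canonical order

    def test_constant_series(self):
        fit = fit_exponential(np.full(88, 0.7))
        assert fit.params["C"] == 0.7
        np.testing.assert_allclose(fit.residuals, 0.0)
        assert fit.sse == 0.0

    def test_single_model_and_nesting(self):
        y = -1.2 * np.exp(-0.05 * N) + 0.3
        single = fit_exponential(y, model="single")
        double = fit_exponential(y, model="double")
        assert single.sse < 1e-10
        assert double.sse <= single.sse * (1 + 1e-9) + 1e-12

    def test_nesting_on_noisy_series(self, rng):
        for _ in range(10):
            y = -1.5 * np.exp(-0.15 * N) - 0.5 * np.exp(-0.01 * N) \
                + rng.normal(0, 0.3, 88)
            d = fit_exponential(y, model="double").sse
            s = fit_exponential(y, model="single").sse
            assert d <= s * (1 + 1e-9) + 1e-12

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential(np.ones(5))

    def test_summary_mentions_model(self):
        fit = fit_exponential(np.full(88, 1.0))
        assert "double-exponential" in fit.summary()


class TestResidualBlocks:
    def test_zero_residuals(self):
        np.testing.assert_allclose(residual_block_means(np.zeros(88)), 0.0)

    def test_square_wave_blocks(self):
        r = np.tile(np.repeat([0.5, -0.5], 22), 2)
        np.testing.assert_allclose(
            residual_block_means(r), [0.5, -0.5, 0.5, -0.5]
        )

    def test_modulated_cohort_residuals_alternate(self, small_tt_records):
        """With m > 0, residual block means alternate with polarity for most
        participants (the decay fit absorbs part of the modulation)."""
        tab = residual_block_table(small_tt_records)
        good = 0
        for pid, g in tab.groupby("participant_id"):
            bm = g.sort_values("block")["residual"].to_numpy()
            s = np.sign(bm)
            if (s[0] == s[2]) and (s[1] == s[3]) and (s[0] == -s[1]):
                good += 1
        assert good > tab["participant_id"].nunique() / 2


# ------------------------------------------------------------- mixed ANOVA


def _toy_mixed_dataset(rng, n_per_group=4, effects=None):
    """Balanced 2 (between) × 2 × 2 (within) long-format dataset."""
    effects = effects or {}
    rows = []
    pid = 0
    for g in ("g1", "g2"):
        for _ in range(n_per_group):
            pid += 1
            subj_off = rng.normal(0, 1)
            for p in ("p1", "p2"):
                for q in ("q1", "q2"):
                    y = rng.normal(0, 1) + subj_off
                    y += effects.get((g, p, q), 0.0)
                    rows.append(
                        {"participant_id": f"S{pid}", "between": g,
                         "P": p, "Q": q, "y": y}
                    )
    return pd.DataFrame(rows)


class TestMixedAnovaOracle:
    def test_matches_bruteforce_on_random_balanced_designs(self, rng):
        """F and dfs agree with an independent general-linear-model
        decomposition on 20 random balanced 2×2×2 datasets to 1e-8."""
        for _ in range(20):
            df = _toy_mixed_dataset(rng)
            res = mixed_anova(df, "y", within=("P", "Q"), between=("between",))
            ss, ss_subj, err = bruteforce_anova_2x2x2(df)
            n_subj = 8
            df_subj = n_subj - 2
            for _, row in res.table.iterrows():
                name = row["effect"]
                parts = name.split(":")
                wpart = ":".join(p for p in parts if p in ("P", "Q"))
                ss_err = err[wpart] if wpart else ss_subj
                df_err = df_subj  # all within factors are 2-level here
                f_oracle = (ss[name] / row["df_num"]) / (ss_err / df_err)
                assert row["SS"] == pytest.approx(ss[name], rel=1e-8, abs=1e-10)
                assert row["F"] == pytest.approx(f_oracle, rel=1e-8, abs=1e-10)
                assert row["df_den"] == df_err

    def test_cross_check_against_pingouin(self, rng):
        """1-between × 1-within sub-design agrees with pingouin."""
        pingouin = pytest.importorskip("pingouin")
        df = _toy_mixed_dataset(rng, effects={("g1", "p1", "q1"): 1.0})
        agg = df.groupby(["participant_id", "between", "P"], as_index=False)["y"].mean()
        ours = mixed_anova(agg, "y", within=("P",), between=("between",))
        theirs = pingouin.mixed_anova(
            data=agg, dv="y", within="P", between="between",
            subject="participant_id",
        )
        for src, effect in (("between", "between"), ("P", "P"),
                            ("Interaction", "between:P")):
            want = float(theirs.loc[theirs["Source"] == src, "F"].iloc[0])
            assert ours.effect(effect)["F"] == pytest.approx(want, rel=1e-6)


class TestMixedAnovaProperties:
    def test_no_within_variation_zero_f(self, rng):
        df = _toy_mixed_dataset(rng)
        # make the within cells identical per subject
        df["y"] = df.groupby("participant_id")["y"].transform("mean")
        res = mixed_anova(df, "y", within=("P", "Q"), between=("between",))
        for effect in ("P", "Q", "P:Q"):
            assert res.effect(effect)["F"] == 0.0

    def test_location_invariance(self, rng):
        df = _toy_mixed_dataset(rng, effects={("g1", "p1", "q1"): 0.8})
        res1 = mixed_anova(df, "y", within=("P", "Q"), between=("between",))
        df2 = df.assign(y=df["y"] + 10.0)
        res2 = mixed_anova(df2, "y", within=("P", "Q"), between=("between",))
        np.testing.assert_allclose(res1.table["F"], res2.table["F"], atol=1e-9)

    def test_eta_p_sq_bounds_and_zero_iff_zero_ss(self, rng):
        df = _toy_mixed_dataset(rng)
        res = mixed_anova(df, "y", within=("P", "Q"), between=("between",))
        assert ((res.table["eta_p_sq"] >= 0) & (res.table["eta_p_sq"] <= 1)).all()
        zero = res.table["SS"] == 0
        np.testing.assert_array_equal(zero, res.table["eta_p_sq"] == 0)

    def test_unbalanced_rejected(self, rng):
        df = _toy_mixed_dataset(rng)
        df = df[~((df["participant_id"] == "S1") & (df["P"] == "p1"))]
        with pytest.raises(ValueError, match="unbalanced"):
            mixed_anova(df, "y", within=("P", "Q"), between=("between",))
        df2 = _toy_mixed_dataset(rng)
        df2 = df2[df2["participant_id"] != "S1"]  # unequal group sizes
        with pytest.raises(ValueError, match="unbalanced"):
            mixed_anova(df2, "y", within=("P", "Q"), between=("between",))

    def test_within_only_design_supported(self, rng):
        """Simple main effects within one subgroup: no between factor."""
        df = _toy_mixed_dataset(rng)
        one = df[df["between"] == "g1"]
        res = mixed_anova(one, "y", within=("P",))
        assert res.effect("P")["df_den"] == 3  # (n_subj - 1) * (levels - 1)


# --------------------------------------------------------- canned analyses


class TestCannedAnovas:
    def test_residual_anova_detects_polarity_effect(self, small_tt_records):
        res = residual_anova(small_tt_records)
        key = res.effect("subgroup:block_order")
        assert key["df_num"] == 1 and key["df_den"] == 6
        assert key["p"] < 0.05  # m=0.7 with low noise: strong interaction
        assert 0 <= key["eta_p_sq"] <= 1

    def test_velocity_anova_constant_velocity_zero_ss(self, small_tt_cohort):
        rec = small_tt_cohort.copy()
        rec["peak_vel_mps"] = 0.4
        res = velocity_anova(rec)
        assert (res.table["SS"] < 1e-20).all()

    def test_training_anova_block_df(self, small_tt_records):
        res = training_anova(small_tt_records)
        assert res.effect("block_rep")["df_num"] == 5
        assert res.effect("polarity:block_rep")["df_num"] == 5

    def test_training_anova_all_equal_zero_f(self, small_tt_cohort):
        rec = small_tt_cohort.copy()
        rec.loc[rec["trial_type"] == "field", "lateral_dev_m"] = rec.loc[
            rec["trial_type"] == "field", "field_direction"
        ].map({"rightward": 0.01, "leftward": -0.01})
        res = training_anova(rec)
        for _, row in res.table.iterrows():
            assert row["F"] == pytest.approx(0.0, abs=1e-12)

    def test_training_gating_contrast_detected(self):
        """Separate-memory cohorts vs shared-memory cohorts differ in
        first-trial interference (between-cohort effect)."""
        recs = []
        for gamma, group in ((1.0, "T-T"), (0.0, "S-T")):
            p = GenerativeParams(gamma=gamma, sigma_dev=0.001,
                                 baseline_offset_sd=0.0)
            cfg = CohortConfig(groups=(group,), n_per_subgroup=4,
                               params=p, seed=31)
            coh = simulate_cohort(cfg)
            coh["participant_id"] = group + "-" + coh["participant_id"]
            recs.append(coh)
        rec = pd.concat(recs, ignore_index=True)
        res = training_anova(rec, measure="first_trial")
        assert res.effect("stim_type")["p"] < 0.01
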