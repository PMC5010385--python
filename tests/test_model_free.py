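"""ΔForce arithmetic, bootstrap, and permutation inference."""

import itertools

import numpy as np
import pandas as pd
import pytest

from memtag.model_free import (
    DeltaForceSeries,
    ModelFreeAnalysis,
    between_group_permutation,
    block_order_contrast,
    bootstrap_delta_force,
    consecutive_block_change,
    delta_force,
    moving_average,
    period_blockorder_interaction,
    permutation_test,
)
from memtag.schedule import generate_schedule
from memtag.synthcohort import (
    CohortConfig,
    GenerativeParams,
    simulate_cohort,
)


def _records_from_matrix(forces: np.ndarray, subgroups: list[str]) -> pd.DataFrame:
    """Tidy test-phase records from a (participants × 88) force matrix."""
    rows = []
    for i, (row, sub) in enumerate(zip(forces, subgroups)):
        for j, f in enumerate(row):
            rows.append(
                {"participant_id": f"P{i:02d}", "group": "T-T",
                 "subgroup": sub, "phase": "test", "trial_global": 286 + j,
                 "trial_type": "clamp", "force_N": f}
            )
    return pd.DataFrame(rows)


class TestDeltaForce:
    def test_identical_subgroups_zero(self):
        m = np.tile(np.linspace(0, 1, 88), (4, 1))
        rec = _records_from_matrix(m, ["CACA", "CACA", "ACAC", "ACAC"])
        s = delta_force(rec[rec.subgroup == "CACA"], rec[rec.subgroup == "ACAC"])
        np.testing.assert_allclose(s.values, 0.0)

    def test_constant_offset(self):
        m = np.vstack([np.ones((2, 88)), -np.ones((2, 88))])
        rec = _records_from_matrix(m, ["CACA", "CACA", "ACAC", "ACAC"])
        s = delta_force(rec[rec.subgroup == "CACA"], rec[rec.subgroup == "ACAC"])
        np.testing.assert_allclose(s.values, 2.0)
        np.testing.assert_allclose(s.block_means, 2.0)

    def test_matches_hand_computed_means(self, rng):
        m = rng.normal(size=(6, 88))
        subs = ["CACA"] * 3 + ["ACAC"] * 3
        rec = _records_from_matrix(m, subs)
        s = delta_force(rec[rec.subgroup == "CACA"], rec[rec.subgroup == "ACAC"])
        np.testing.assert_allclose(s.values, m[:3].mean(0) - m[3:].mean(0))

    def test_orientation_flip_negates(self, rng):
        m = rng.normal(size=(4, 88))
        rec = _records_from_matrix(m, ["CACA", "CACA", "ACAC", "ACAC"])
        a = delta_force(rec[rec.subgroup == "CACA"], rec[rec.subgroup == "ACAC"])
        b = delta_force(rec[rec.subgroup == "CACA"], rec[rec.subgroup == "ACAC"],
                        orientation="acac_minus_caca")
        np.testing.assert_allclose(b.values, -a.values)


class TestContrasts:
    @pytest.mark.parametrize(
        "blocks,expected",
        [((0, 1, 0, 1), 2.0), ((3, 3, 3, 3), 0.0), ((-1, 1, -1, 1), 4.0)],
    )
    def test_block_order_contrast(self, blocks, expected):
        assert block_order_contrast(np.array(blocks)) == expected

    @pytest.mark.parametrize(
        "blocks,expected",
        [((0, 1, 0, 1), 0.0), ((0, 2, 0, 1), 1.0), ((0, 1, 1, 1), 1.0)],
    )
    def test_period_blockorder_interaction(self, blocks, expected):
        assert period_blockorder_interaction(np.array(blocks)) == expected

    def test_consecutive_changes_and_identity(self, rng):
        b = rng.normal(size=4)
        assert consecutive_block_change(b, 1) == pytest.approx(b[1] - b[0])
        with pytest.raises(ValueError):
            consecutive_block_change(b, 4)
        # BO = (b2-b1) + (b4-b3), numerically
        assert block_order_contrast(b) == pytest.approx(
            consecutive_block_change(b, 1)
            + (b[3] - b[2])
        )


class TestBootstrap:
    def test_zero_variance_zero_sd(self):
        m = np.vstack([np.ones((3, 88)), np.zeros((3, 88))])
        rec = _records_from_matrix(m, ["CACA"] * 3 + ["ACAC"] * 3)
        s = bootstrap_delta_force(rec, n_boot=50, seed=0)
        np.testing.assert_allclose(s.boot_sd, 0.0)
        np.testing.assert_allclose(s.boot_mean, 1.0)

    def test_boot_mean_consistent_with_point_estimate(self, small_tt_records):
        s = bootstrap_delta_force(small_tt_records, n_boot=4000, seed=1)
        # MC error of the bootstrap mean per trial
        mc_se = s.boot_sd / np.sqrt(s.n_boot)
        assert np.all(np.abs(s.boot_mean - s.values) < 4 * mc_se + 1e-12)

    def test_invalid_n_boot(self, small_tt_records):
        with pytest.raises(ValueError):
            bootstrap_delta_force(small_tt_records, n_boot=0)


class TestPermutation:
    def test_identical_participants_degenerate(self):
        m = np.ones((4, 88))
        rec = _records_from_matrix(m, ["CACA", "CACA", "ACAC", "ACAC"])
        res = permutation_test(rec)
        assert res.observed == 0.0
        assert res.p_value == 1.0

    def test_exact_enumeration_matches_independent_oracle(self, rng):
        """p from the implementation equals brute-force enumeration of all
        subgroup assignments computed directly from block means."""
        for n_per in (2, 3):
            m = rng.normal(size=(2 * n_per, 88))
            subs = ["CACA"] * n_per + ["ACAC"] * n_per
            rec = _records_from_matrix(m, subs)
            res = permutation_test(rec)
            assert res.exact

            # oracle: independent recomputation from scratch
            bm = m.reshape(2 * n_per, 4, 22).mean(axis=2)
            contrast = bm[:, 1] + bm[:, 3] - bm[:, 0] - bm[:, 2]
            obs = contrast[:n_per].mean() - contrast[n_per:].mean()
            null = [
                contrast[list(c)].mean()
                - contrast[[i for i in range(2 * n_per) if i not in c]].mean()
                for c in itertools.combinations(range(2 * n_per), n_per)
            ]
            p_oracle = np.mean(np.abs(null) >= abs(obs) - 1e-12)
            assert res.observed == pytest.approx(obs)
            assert res.p_value == pytest.approx(p_oracle)

    def test_sampled_agrees_with_exact_within_mc_error(self, rng):
        m = rng.normal(size=(8, 88))
        rec = _records_from_matrix(m, ["CACA"] * 4 + ["ACAC"] * 4)
        exact = permutation_test(rec)
        sampled = permutation_test(rec, exact_threshold=0, n_resamples=4000, seed=9)
        mc_se = np.sqrt(exact.p_value * (1 - exact.p_value) / 4000)
        assert abs(sampled.p_value - exact.p_value) < 3 * mc_se + 2 / 4000

    def test_p_invariant_to_shift_and_positive_scaling(self, rng):
        m = rng.normal(size=(6, 88))
        rec = _records_from_matrix(m, ["CACA"] * 3 + ["ACAC"] * 3)
        p0 = permutation_test(rec).p_value
        rec2 = rec.copy()
        rec2["force_N"] = rec2["force_N"] * 3.7 + 11.0
        assert permutation_test(rec2).p_value == pytest.approx(p0)

    def test_antisymmetry_under_subgroup_swap(self, rng):
        m = rng.normal(size=(6, 88))
        rec = _records_from_matrix(m, ["CACA"] * 3 + ["ACAC"] * 3)
        swapped = rec.copy()
        swapped["subgroup"] = swapped["subgroup"].map(
            {"CACA": "ACAC", "ACAC": "CACA"}
        )
        a = permutation_test(rec)
        b = permutation_test(swapped)
        assert b.observed == pytest.approx(-a.observed)
        assert b.p_value == pytest.approx(a.p_value)


class TestBetweenGroup:
    def _two_group_records(self, rng, m2_shift=0.0):
        recs = []
        for g, shift in (("T-T", 0.0), ("S-T", m2_shift)):
            m = rng.normal(size=(8, 88)) + shift
            rec = _records_from_matrix(m, ["CACA"] * 4 + ["ACAC"] * 4)
            rec["group"] = g
            rec["participant_id"] = g + rec["participant_id"]
            recs.append(rec)
        return recs

    def test_same_data_observed_zero_p_one(self, rng):
        rec, _ = self._two_group_records(rng)
        res = between_group_permutation(rec, rec, n_resamples=200, seed=0)
        assert res.observed == 0.0
        assert res.p_value == 1.0

    def test_label_swap_antisymmetry(self, rng):
        g1, g2 = self._two_group_records(rng)
        a = between_group_permutation(g1, g2, n_resamples=300, seed=4)
        b = between_group_permutation(g2, g1, n_resamples=300, seed=4)
        assert b.observed == pytest.approx(-a.observed)

    def test_detects_modulation_difference(self):
        """T-T cohort with modulation vs sham-like cohort without: the
        between-group BO difference approaches BO of the modulated group."""
        p = GenerativeParams(sigma_trial=0.05, sigma_subject=0.0,
                             baseline_offset_sd=0.0)
        tt = simulate_cohort(CohortConfig(groups=("T-T",), n_per_subgroup=8,
                                          params=p, seed=21))
        st = simulate_cohort(CohortConfig(groups=("S-T",), n_per_subgroup=8,
                                          params=p.replace(m=0.0), seed=22))
        res = between_group_permutation(tt, st, n_resamples=500, seed=5)
        from memtag.synthcohort import expected_block_order_contrast

        assert res.observed == pytest.approx(
            expected_block_order_contrast(p), abs=0.15
        )
        assert res.p_value < 0.05


class TestMovingAverage:
    def test_constant_unchanged(self):
        np.testing.assert_allclose(moving_average(np.full(20, 3.3)), 3.3)

    def test_impulse_spreads(self):
        x = np.zeros(11)
        x[5] = 5.0
        out = moving_average(x, window=5)
        np.testing.assert_allclose(out[3:8], 1.0)
        np.testing.assert_allclose(out[:2], 0.0)

    def test_linear_unchanged(self):
        x = np.arange(30, dtype=float)
        np.testing.assert_allclose(moving_average(x), x)

    def test_bad_window(self):
        with pytest.raises(ValueError):
            moving_average(np.zeros(10), window=4)


class TestModelFreeAnalysis:
    def test_fit_returns_all_statistics(self, small_tt_records):
        res = ModelFreeAnalysis(small_tt_records, group="T-T").fit(
            n_boot=100, n_resamples=100, seed=0
        )
        assert set(res.tests) == {
            "block_order", "period_block_order",
            "change_1_2", "change_2_3", "change_3_4",
        }
        assert "ΔForce" in res.summary()
        assert len(res.to_frame()) == 5
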