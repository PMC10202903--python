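"""Variability measures, dependent-correlation tests, and the aligned rank
transform ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ellipsekin.core import ValidationError
from ellipsekin.stats import (
    STAT_PARAMETERS,
    align_rank_transform,
    art_anova,
    coefficient_of_variation,
    correlation_accuracy,
    correlation_precision,
    steiger_test,
    summarize_condition,
    tukey_hsd,
)


def _balanced_obs(n_sub, fill, rng=None):
    rows = []
    for i in range(n_sub):
        for h in ("D", "ND"):
            for s in ("S", "N", "F"):
                rows.append({"subject_id": f"S{i}", "hand": h, "speed": s,
                             "value": fill(i, h, s, rng)})
    return pd.DataFrame(rows)


class TestCoefficientOfVariation:
    def test_constant_values(self):
        assert coefficient_of_variation([5, 5, 5]) == 0.0

    def test_two_point_value(self):
        # sd = sqrt(2), mean = 3
        assert coefficient_of_variation([2, 4]) == pytest.approx(0.4714, abs=1e-4)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValidationError, match="mean"):
            coefficient_of_variation([-1, 1])

    @settings(derandomize=True, max_examples=50)
    @given(values=st.lists(st.floats(0.1, 1e3), min_size=2, max_size=20),
           scale=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, values, scale):
        arr = np.asarray(values)
        base = coefficient_of_variation(arr)
        scaled = coefficient_of_variation(arr * scale)
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-12)


class TestSummarize:
    def test_identical_cycles_have_zero_spread(self):
        row = {"subject_id": "S1", "hand": "D", "speed": "N"}
        row.update({p: 1.5 for p in STAT_PARAMETERS})
        row["rotation_angle"] = 45.0
        feats = pd.DataFrame([{**row, "cycle_index": i} for i in range(7)])
        summary = summarize_condition(feats)
        assert summary.n_cycles == 7
        assert (summary.table["sd"] == 0).all()
        assert (summary.table["cv"].dropna() == 0).all()

    def test_single_cycle_rejected(self):
        row = {"subject_id": "S1", "hand": "D", "speed": "N", "cycle_index": 0}
        row.update({p: 1.0 for p in STAT_PARAMETERS})
        row["rotation_angle"] = 0.0
        with pytest.raises(ValidationError, match=">= 2"):
            summarize_condition(pd.DataFrame([row]))

    def test_recovers_injected_duration_jitter(self):
        """Generator -> analysis round trip: a 5% duration jitter shows up
        as a duration CV near 0.05."""
        from ellipsekin import RecordingSpec, analyze_recording, generate_recording

        cvs = []
        for seed in range(6):
            spec = RecordingSpec(n_cycles=10, jitter_cv=0.05, noise_sd=0.0)
            traj = generate_recording(spec, seed=seed)
            _, summary = analyze_recording(traj)
            cvs.append(summary.table.set_index("parameter").loc["duration", "cv"])
        # CV of 7 draws at 0.05 is itself noisy; the mean over runs is not
        assert np.mean(cvs) == pytest.approx(0.05, abs=0.02)


def _summaries_from_vectors(param, d_vals, nd_vals, speed="N", col="mean"):
    rows = []
    for i, (d, nd) in enumerate(zip(d_vals, nd_vals)):
        for hand, val in (("D", d), ("ND", nd)):
            rows.append({"subject_id": f"S{i}", "hand": hand, "speed": speed,
                         "parameter": param, "mean": np.nan, "cv": np.nan,
                         col: val})
    return pd.DataFrame(rows)


class TestCorrelations:
    def test_identical_vectors_give_r_one(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        s = _summaries_from_vectors("duration", vals, vals)
        assert correlation_accuracy(s, "duration", "N").r == pytest.approx(1.0)

    def test_identical_cv_vectors_give_r_one(self):
        vals = [0.03, 0.05, 0.08, 0.02]
        s = _summaries_from_vectors("duration", vals, vals, col="cv")
        assert correlation_precision(s, "duration", "N").r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        s = _summaries_from_vectors("duration", [1, 1, 1, 1], [1, 2, 3, 4])
        with pytest.raises(ValidationError, match="zero variance"):
            correlation_accuracy(s, "duration", "N")

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        d = rng.normal(size=20)
        nd = d + rng.normal(scale=0.5, size=20)
        r1 = correlation_accuracy(
            _summaries_from_vectors("beta", d, nd), "beta", "N").r
        r2 = correlation_accuracy(
            _summaries_from_vectors("beta", 3 * d + 1, -2 * nd + 5), "beta", "N").r
        assert abs(r2) == pytest.approx(abs(r1), abs=1e-12)

    def test_null_cohort_correlation_near_zero(self):
        """Independent hands across many draws: mean r within the null CI."""
        rng = np.random.default_rng(1)
        rs = []
        for _ in range(100):
            d = rng.normal(size=40)
            nd = rng.normal(size=40)
            rs.append(correlation_accuracy(
                _summaries_from_vectors("K", d, nd), "K", "N").r)
        # null SE of mean r over 100 draws of n=40 is about 0.016
        assert abs(np.mean(rs)) < 0.05


class TestSteiger:
    def test_zero_cross_correlation_oracle(self):
        res = steiger_test(0.8, 0.3, (0, 0, 0, 0), n=40)
        expected = (np.arctanh(0.8) - np.arctanh(0.3)) / np.sqrt(2 / 37)
        assert res.Z == pytest.approx(expected, abs=1e-9)
        assert res.Z == pytest.approx(3.394, abs=1e-3)

    def test_equal_correlations_give_zero(self):
        res = steiger_test(0.5, 0.5, (0.2, 0.1, 0.1, 0.2), n=40)
        assert res.Z == 0.0
        assert res.p == pytest.approx(1.0)

    def test_antisymmetry(self):
        cross = (0.3, 0.2, 0.25, 0.1)
        a = steiger_test(0.7, 0.2, cross, n=30)
        # swapping the two correlations permutes the quadruple (j,k) <-> (h,m)
        b = steiger_test(0.2, 0.7, (0.25, 0.1, 0.3, 0.2), n=30)
        assert b.Z == pytest.approx(-a.Z, abs=1e-12)

    def test_non_psd_matrix_rejected(self):
        with pytest.raises(ValidationError, match="positive semi-definite"):
            steiger_test(0.9, -0.9, (0.9, 0.9, 0.9, 0.9), n=40)

    def test_overlapping_variant_runs(self):
        res = steiger_test(0.6, 0.4, 0.3, n=50, overlapping=True)
        assert np.isfinite(res.Z) and 0 <= res.p <= 1

    def test_null_calibration(self):
        """Equal population correlations: rejection rate near alpha."""
        rng = np.random.default_rng(7)
        rho = 0.5
        cov = np.eye(4)
        cov[0, 1] = cov[1, 0] = rho
        cov[2, 3] = cov[3, 2] = rho
        n, reps, alpha = 40, 1000, 0.05
        chol = np.linalg.cholesky(cov)
        rejections = 0
        for _ in range(reps):
            data = rng.normal(size=(n, 4)) @ chol.T
            c = np.corrcoef(data, rowvar=False)
            res = steiger_test(c[0, 1], c[2, 3],
                               (c[0, 2], c[0, 3], c[1, 2], c[1, 3]), n)
            rejections += res.p < alpha
        rate = rejections / reps
        assert 0.03 <= rate <= 0.07  # binomial 99% CI around 0.05 at 1000 reps


class TestHolm:
    def test_step_down_values(self):
        from ellipsekin.stats import holm_adjust

        adj = holm_adjust([0.01, 0.04, 0.03])
        np.testing.assert_allclose(adj, [0.03, 0.06, 0.06])

    def test_monotone_and_bounded(self):
        from ellipsekin.stats import holm_adjust

        rng = np.random.default_rng(9)
        p = rng.uniform(size=12)
        adj = holm_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()


class TestAlignRankTransform:
    def test_constant_response_all_zero_midranks(self):
        obs = _balanced_obs(4, lambda i, h, s, r: 1.0)
        art = align_rank_transform(obs)
        assert (art["aligned_hand"] == 0).all()
        assert art["rank_hand"].nunique() == 1  # all tied at midrank

    def test_aligned_columns_sum_to_zero(self):
        rng = np.random.default_rng(2)
        obs = _balanced_obs(6, lambda i, h, s, r: r.normal(), rng)
        art = align_rank_transform(obs)
        for col in ("aligned_hand", "aligned_speed", "aligned_hand_speed"):
            assert abs(art[col].sum()) < 1e-9

    def test_pure_speed_effect_leaves_other_alignments_zero(self):
        shift = {"S": 1.0, "N": 2.0, "F": 3.0}
        obs = _balanced_obs(5, lambda i, h, s, r: shift[s])
        art = align_rank_transform(obs)
        assert np.allclose(art["aligned_hand"], 0.0)
        assert np.allclose(art["aligned_hand_speed"], 0.0)
        assert not np.allclose(art["aligned_speed"], 0.0)

    def test_single_level_factor_rejected(self):
        obs = _balanced_obs(4, lambda i, h, s, r: 1.0)
        with pytest.raises(ValidationError, match="hand"):
            align_rank_transform(obs[obs.hand == "D"])


class TestArtAnova:
    def test_error_df_matches_blocking_decomposition(self):
        """40 subjects x 2 x 3 with one value per cell: error df must be
        240 - 1 - 1 - 2 - 2 - 39 = 195."""
        rng = np.random.default_rng(3)
        obs = _balanced_obs(40, lambda i, h, s, r: r.normal(), rng)
        for res in art_anova(obs):
            assert res.df_den == 195
        dfs = {r.effect: r.df_num for r in art_anova(obs)}
        assert dfs == {"hand": 1, "speed": 2, "hand:speed": 2}

    def test_strong_speed_effect_detected_without_hand_effect(self):
        rng = np.random.default_rng(4)
        shift = {"S": 2.0, "N": 0.0, "F": -2.0}
        obs = _balanced_obs(20, lambda i, h, s, r: shift[s] + r.normal(0, 0.5),
                            rng)
        res = {r.effect: r for r in art_anova(obs)}
        assert res["speed"].p < 0.001
        assert res["hand"].p > 0.05
        assert res["speed"].partial_eta_sq > 0.5

    def test_degenerate_constant_response_flagged(self):
        obs = _balanced_obs(5, lambda i, h, s, r: 2.0)
        for res in art_anova(obs):
            assert res.degenerate and np.isnan(res.F)

    def test_matches_statsmodels_rank_anova(self):
        """Cross-check: the balanced decomposition on one effect's ranks
        agrees with an OLS factorial ANOVA with subject blocking."""
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(5)
        obs = _balanced_obs(10, lambda i, h, s, r: r.normal(), rng)
        art = align_rank_transform(obs)
        ours = {r.effect: r for r in art_anova(obs)}
        for effect, col, key in (("hand", "hand", "C(hand)"),
                                 ("speed", "speed", "C(speed)"),
                                 ("hand:speed", "hand_speed", "C(hand):C(speed)")):
            model = ols(f"rank_{col} ~ C(hand) * C(speed) + C(subject_id)",
                        data=art).fit()
            table = sm.stats.anova_lm(model, typ=2)
            assert ours[effect].F == pytest.approx(table.loc[key, "F"], rel=1e-6)
            assert ours[effect].p == pytest.approx(table.loc[key, "PR(>F)"],
                                                   abs=1e-9)

    def test_unbalanced_layout_rejected(self):
        obs = _balanced_obs(4, lambda i, h, s, r: 1.0)
        with pytest.raises(ValidationError, match="unbalanced|incomplete"):
            art_anova(obs.iloc[:-1])


class TestTukey:
    def test_identical_groups_not_significant(self):
        obs = pd.DataFrame({"speed": ["S"] * 10 + ["N"] * 10,
                            "rank": list(range(10)) * 2})
        res = tukey_hsd(obs, "speed", "rank")
        assert res["p_adj"].iloc[0] > 0.95

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(6)
        obs = pd.DataFrame({
            "speed": ["S"] * 20 + ["N"] * 20 + ["F"] * 20,
            "rank": np.concatenate([rng.normal(0, 1, 20), rng.normal(0, 1, 20),
                                    rng.normal(6, 1, 20)]),
        })
        res = tukey_hsd(obs, "speed", "rank").set_index(["level_a", "level_b"])
        assert res.loc[("F", "N"), "p_adj"] < 0.001
        assert res.loc[("F", "S"), "p_adj"] < 0.001
        assert res.loc[("N", "S"), "p_adj"] > 0.05

    def test_adjusted_p_at_least_pairwise_t(self):
        from scipy import stats as sps

        rng = np.random.default_rng(8)
        groups = {lv: rng.normal(0, 1, 15) for lv in ("S", "N", "F")}
        obs = pd.DataFrame({
            "speed": sum(([lv] * 15 for lv in groups), []),
            "rank": np.concatenate(list(groups.values())),
        })
        res = tukey_hsd(obs, "speed", "rank")
        for row in res.itertuples():
            t_p = sps.ttest_ind(groups[row.level_a], groups[row.level_b]).pvalue
            assert row.p_adj >= t_p - 1e-9
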