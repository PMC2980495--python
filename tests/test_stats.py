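"""Screen statistics: Z'-factor, z-scores, median polish, B-scores, ranks,
hit calling, dose-response, agreement regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormhcs import (ControlStats, PlateData, ScreenSimConfig,
                     agreement_regression, bscore, call_hits, dose_response,
                     make_dose_series, median_polish, plate_zscores,
                     rank_scores, simulate_measured_plate, simulate_screen,
                     zprime)
from wormhcs.errors import (DataError, DegeneratePlateError,
                            UndefinedStatisticError)

from oracles import median_polish_reference


def _plate(values, roles=None):
    values = np.asarray(values, dtype=float)
    if roles is None:
        roles = np.full(values.shape, "sample", dtype=object)
    compounds = np.empty(values.shape, dtype=object)
    compounds[:] = ""
    k = 0
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            if roles[i, j] == "sample":
                compounds[i, j] = f"C{k:03d}"
                k += 1
    return PlateData(plate_id="t", values=values, roles=roles,
                     compound_ids=compounds)


class TestZPrime:
    def test_published_control_statistics_give_excellent_assay(self):
        z = zprime(ControlStats(mu_p=98.1, sigma_p=9.0, mu_n=1.3, sigma_n=1.5))
        assert z == pytest.approx(0.6745867768595042)
        assert round(z, 1) == 0.7

    def test_zero_variance_controls_give_one(self):
        assert zprime(ControlStats(1.0, 0.0, 0.0, 0.0)) == 1.0

    def test_closed_form_example(self):
        assert zprime(ControlStats(1.0, 0.1, 0.0, 0.1)) == pytest.approx(0.4)

    def test_equal_means_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            zprime(ControlStats(5.0, 1.0, 5.0, 1.0))

    @given(st.floats(0.1, 100), st.floats(-50, 50))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_scale_and_translation_invariance(self, c, shift):
        base = ControlStats(98.1, 9.0, 1.3, 1.5)
        scaled = ControlStats(98.1 * c, 9.0 * c, 1.3 * c, 1.5 * c)
        shifted = ControlStats(98.1 + shift, 9.0, 1.3 + shift, 1.5)
        assert zprime(scaled) == pytest.approx(zprime(base), rel=1e-9)
        assert zprime(shifted) == pytest.approx(zprime(base), rel=1e-9)


class TestZScores:
    def test_three_samples_standardize_with_sample_sd(self):
        z = plate_zscores(_plate([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(z[0], [-1.0, 0.0, 1.0])

    def test_constant_plate_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            plate_zscores(_plate([[2.0, 2.0, 2.0]]))

    def test_mean_zero_sd_one_per_plate(self):
        rng = np.random.default_rng(1)
        plate = _plate(rng.normal(100, 10, (16, 24)))
        z = plate_zscores(plate)
        vals = z[np.isfinite(z)]
        assert vals.mean() == pytest.approx(0.0, abs=1e-12)
        assert vals.std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_controls_do_not_enter_sample_statistics(self):
        roles = np.full((2, 4), "sample", dtype=object)
        roles[:, 0] = "negative_control"
        plate = _plate([[1000.0, 1.0, 2.0, 3.0], [1000.0, 4.0, 5.0, 6.0]], roles)
        z = plate_zscores(plate)
        assert np.isnan(z[0, 0])
        vals = z[np.isfinite(z)]
        assert vals.mean() == pytest.approx(0.0, abs=1e-12)

    def test_null_screen_tail_mass_matches_normal(self):
        """~10^4 null sample wells produce z-scores with ~0.27% beyond |z|>3."""
        cfg = ScreenSimConfig(n_plates=32, hit_fraction_down=0, hit_fraction_up=0,
                              rng_seed=6)
        rng = np.random.default_rng(6)
        zs = []
        for p in range(cfg.n_plates):
            plate, _ = simulate_measured_plate(cfg, p, rng=rng)
            z = plate_zscores(plate)
            zs.append(z[np.isfinite(z)])
        zs = np.concatenate(zs)
        assert zs.size >= 10_000
        frac = np.mean(np.abs(zs) > 3)
        se = np.sqrt(0.0027 * (1 - 0.0027) / zs.size)
        assert abs(frac - 0.0027) < 4 * se


class TestMedianPolish:
    def test_additive_two_by_two_decomposes_exactly(self):
        res = median_polish(_plate([[1.0, 2.0], [3.0, 4.0]]))
        assert res.mu_hat == pytest.approx(2.5)
        np.testing.assert_allclose(res.row_effects, [-1.0, 1.0])
        np.testing.assert_allclose(res.col_effects, [-0.5, 0.5])
        np.testing.assert_allclose(res.residuals, 0.0, atol=1e-12)

    def test_zero_matrix_gives_zero_components(self):
        res = median_polish(_plate(np.zeros((3, 3))))
        assert res.mu_hat == 0.0
        assert np.all(res.row_effects == 0) and np.all(res.col_effects == 0)

    def test_reconstruction_is_exact(self):
        rng = np.random.default_rng(2)
        plate = _plate(rng.normal(50, 5, (8, 12)))
        res = median_polish(plate)
        fitted = (res.mu_hat + res.row_effects[:, None] + res.col_effects[None, :]
                  + res.residuals)
        np.testing.assert_allclose(fitted[res.sample_mask],
                                   plate.values[res.sample_mask], atol=1e-9)

    @pytest.mark.parametrize("shape", [(3, 3), (4, 6), (8, 8)])
    def test_matches_exhaustive_sweep_oracle(self, shape):
        rng = np.random.default_rng(sum(shape))
        values = rng.normal(0, 1, shape)
        res = median_polish(_plate(values))
        mu, row_eff, col_eff, resid = median_polish_reference(values.tolist())
        assert res.mu_hat == pytest.approx(mu, abs=1e-6)
        np.testing.assert_allclose(res.row_effects, row_eff, atol=1e-6)
        np.testing.assert_allclose(res.col_effects, col_eff, atol=1e-6)
        np.testing.assert_allclose(res.residuals, resid, atol=1e-6)

    def test_median_of_effects_near_zero_at_convergence(self):
        rng = np.random.default_rng(3)
        res = median_polish(_plate(rng.normal(0, 1, (16, 24))))
        assert abs(np.median(res.row_effects)) < 1e-6
        assert abs(np.median(res.col_effects)) < 1e-6

    def test_planted_row_gradient_recovered(self):
        """Row effects recover a planted gradient of >= 3 sigma span."""
        cfg = ScreenSimConfig(n_plates=1, row_gradient=27.0, hit_fraction_down=0,
                              hit_fraction_up=0, rng_seed=7)
        plate, _ = simulate_measured_plate(cfg)
        res = median_polish(plate)
        planted = cfg.row_gradient * np.arange(16) / 15.0
        r = np.corrcoef(res.row_effects, planted)[0, 1]
        assert r > 0.95

    def test_single_row_plate_rejected(self):
        with pytest.raises(DataError):
            median_polish(_plate([[1.0, 2.0, 3.0]]))


class TestBScore:
    def test_symmetric_residuals_give_unit_mad(self):
        values = np.fromfunction(lambda i, j: ((i + j) % 2) * 2.0 - 1.0, (4, 4))
        res = median_polish(_plate(values))
        assert res.mad == pytest.approx(1.0)
        np.testing.assert_allclose(bscore(res), res.residuals, atol=1e-9)

    def test_degenerate_plate_flagged(self):
        res = median_polish(_plate([[1.0, 2.0], [3.0, 4.0]]))
        with pytest.raises(DegeneratePlateError):
            bscore(res)

    def test_row_and_column_offsets_absorbed(self):
        """Adding a constant to an entire row or column of sample wells leaves
        every B-score unchanged to 1e-9."""
        rng = np.random.default_rng(4)
        values = rng.normal(100, 10, (16, 24))
        base = bscore(median_polish(_plate(values)))
        shifted = values.copy()
        shifted[5, :] += 37.0
        shifted[:, 11] -= 12.0
        after = bscore(median_polish(_plate(shifted)))
        np.testing.assert_allclose(after, base, atol=1e-9)

    def test_null_bscore_tails_match_independent_oracle(self):
        """Null-plate B-score tail mass agrees with the same statistic
        computed by the pure-Python sweep oracle on Normal noise.

        The naive expectation — Normal 3-sigma mass beyond |B| > 3/0.6745 —
        does not hold: zeroing every row and column median concentrates
        residuals near 0, so the MAD understates the residual SD (ratio
        ~0.59, not 0.6745) and the B tail is genuinely heavier.  The oracle
        gives the correct reference distribution of the statistic.
        """
        from statistics import median

        cut = 3.0 / 0.6745
        rng = np.random.default_rng(8)

        oracle_tail = []
        for _ in range(30):
            noise = rng.normal(0.0, 1.0, (16, 20))
            _, _, _, resid = median_polish_reference(noise.tolist())
            flat = [v for row in resid for v in row]
            m = median(flat)
            mad = median(abs(v - m) for v in flat)
            oracle_tail += [abs(v / mad) > cut for v in flat]
        oracle_frac = np.mean(oracle_tail)

        cfg = ScreenSimConfig(n_plates=32, hit_fraction_down=0, hit_fraction_up=0,
                              rng_seed=8)
        bs = []
        for p in range(cfg.n_plates):
            plate, _ = simulate_measured_plate(cfg, p, rng=rng)
            b = bscore(median_polish(plate))
            bs.append(b[np.isfinite(b)])
        bs = np.concatenate(bs)
        assert bs.size >= 10_000
        frac = np.mean(np.abs(bs) > cut)
        se = np.sqrt(oracle_frac * (1 - oracle_frac) * (1 / bs.size + 1 / len(oracle_tail)))
        assert abs(frac - oracle_frac) < 4 * se


class TestRankScores:
    def test_concordant_screens_give_integer_ranks(self):
        df = pd.DataFrame({"s1": [-5.0, 0.0, 3.0], "s2": [-4.0, 1.0, 2.0]},
                          index=["A", "B", "C"])
        out = rank_scores(df)
        np.testing.assert_allclose(out["rank_score"], [1.0, 2.0, 3.0])

    def test_ties_averaged_within_screen(self):
        df = pd.DataFrame({"s1": [0.0, 0.0], "s2": [1.0, 2.0]}, index=["A", "B"])
        out = rank_scores(df)
        np.testing.assert_allclose(out["rank_score"], [1.25, 1.75])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(0, 1, (20, 2)), columns=["s1", "s2"],
                          index=[f"C{i}" for i in range(20)])
        base = rank_scores(df)["rank_score"]
        perm = rng.permutation(20)
        shuffled = rank_scores(df.iloc[perm])["rank_score"]
        pd.testing.assert_series_equal(shuffled.sort_index(), base.sort_index())

    def test_invariant_under_monotone_transform_of_one_screen(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(0, 1, (30, 2)), columns=["s1", "s2"],
                          index=[f"C{i}" for i in range(30)])
        base = rank_scores(df)["rank_score"]
        df2 = df.copy()
        df2["s1"] = np.exp(df2["s1"]) * 10 + 3  # strictly increasing
        np.testing.assert_allclose(rank_scores(df2)["rank_score"], base)

    def test_missing_compound_excluded_with_reason(self):
        df = pd.DataFrame({"s1": [1.0, 2.0, np.nan], "s2": [1.0, 2.0, 3.0]},
                          index=["A", "B", "C"])
        out = rank_scores(df)
        assert np.isnan(out.loc["C", "rank_score"])
        assert out.loc["C", "excluded_reason"] != ""


class TestHitCalling:
    def test_boundary_rank_score_is_not_a_hit(self):
        rs = pd.Series([110.0, 109.9, 1225.0, 1225.1], index=list("ABCD"))
        out = call_hits(rs, low_cut=110, high_cut=1225)
        assert out.tolist() == ["none", "decreaser_candidate", "none",
                                "increaser_candidate"]

    def test_cuts_scale_with_compound_count(self):
        rs = pd.Series(np.arange(1.0, 641.0))  # 640 compounds
        out = call_hits(rs)
        # scaled low cut = 110 * 640/1280 = 55 (strict)
        assert (out == "decreaser_candidate").sum() == 54

    def test_planted_strong_decreasers_rank_in_bottom_band(self):
        """10 planted decreasers at ~5 plate-SD effect among 1280 compounds
        all land within the bottom 110 rank-scores."""
        cfg = ScreenSimConfig(n_plates=4, hit_fraction_down=10 / 1280,
                              hit_fraction_up=0.0, effect_size_down=0.54,
                              rng_seed=9)
        screens, truth, _ = simulate_screen(cfg, n_screens=2)
        scores = {}
        for s, plates in enumerate(screens):
            col = {}
            for plate in plates:
                b = bscore(median_polish(plate))
                for (i, j) in zip(*np.nonzero(plate.sample_mask)):
                    col[plate.compound_ids[i, j]] = b[i, j]
            scores[f"s{s + 1}"] = pd.Series(col)
        ranks = rank_scores(pd.DataFrame(scores))
        planted = truth.loc[truth.hit_class == "down", "compound_id"]
        assert (ranks.loc[planted, "rank_score"] < 110).all()

    def test_hit_recall_monotone_in_effect_size(self):
        """Recall of planted decreasers does not fall as the effect grows."""
        recalls = []
        for effect in (0.85, 0.6, 0.3):
            cfg = ScreenSimConfig(n_plates=2, hit_fraction_down=0.02,
                                  hit_fraction_up=0.0, effect_size_down=effect,
                                  rng_seed=10)
            screens, truth, _ = simulate_screen(cfg, n_screens=2)
            scores = {}
            for s, plates in enumerate(screens):
                col = {}
                for plate in plates:
                    b = bscore(median_polish(plate))
                    for (i, j) in zip(*np.nonzero(plate.sample_mask)):
                        col[plate.compound_ids[i, j]] = b[i, j]
                scores[f"s{s + 1}"] = pd.Series(col)
            ranks = rank_scores(pd.DataFrame(scores))
            hits = call_hits(ranks["rank_score"])
            planted = set(truth.loc[truth.hit_class == "down", "compound_id"])
            called = set(hits.index[hits == "decreaser_candidate"])
            recalls.append(len(planted & called) / len(planted))
        assert recalls[0] <= recalls[1] <= recalls[2]
        assert recalls[-1] == 1.0


class TestDoseResponse:
    def test_flat_series_fails(self):
        rng = np.random.default_rng(11)
        series = make_dose_series(lambda c: 98.1, [12.5, 25, 50, 100],
                                  replicates=140, rng=rng)
        dmso = rng.normal(98.1, 9.0, 520)
        assert dose_response(series, dmso, "decrease").verdict == "failed"

    def test_strong_decreasing_series_confirmed(self):
        """A 5-sigma drop at the top dose with the screen's group sizes
        (140 animals/concentration, 520 DMSO) confirms dose dependence."""
        rng = np.random.default_rng(12)
        series = make_dose_series(lambda c: 98.1 - 45.0 * c / 100.0,
                                  [12.5, 25, 50, 100], replicates=140, rng=rng)
        dmso = rng.normal(98.1, 9.0, 520)
        res = dose_response(series, dmso, "decrease")
        assert res.verdict == "confirmed"
        assert res.spearman_rho < 0

    def test_single_significant_nonmonotone_fails(self):
        rng = np.random.default_rng(13)
        rows = []
        for c, mean in [(12.5, 98.1), (25, 40.0), (50, 98.1), (100, 98.1)]:
            rows.append(pd.DataFrame({"concentration": c,
                                      "readout": rng.normal(mean, 9.0, 140)}))
        series = pd.concat(rows, ignore_index=True)
        dmso = rng.normal(98.1, 9.0, 520)
        assert dose_response(series, dmso, "decrease").verdict == "failed"

    def test_too_few_concentrations_rejected(self):
        rng = np.random.default_rng(14)
        series = make_dose_series(lambda c: 98.1, [50, 100], replicates=10, rng=rng)
        with pytest.raises(DataError):
            dose_response(series, rng.normal(98.1, 9.0, 50), "decrease")

    def test_sparse_concentration_dropped_with_warning(self):
        rng = np.random.default_rng(15)
        series = make_dose_series(lambda c: 98.1 - 0.4 * c, [12.5, 25, 50, 100],
                                  replicates=140, rng=rng)
        series = series.drop(series[series.concentration == 12.5].index[1:])
        with pytest.warns(UserWarning):
            res = dose_response(series, rng.normal(98.1, 9.0, 520), "decrease")
        assert 12.5 not in res.pvalues["concentration"].tolist()


class TestAgreementRegression:
    def test_identity_fit_reported_nonsignificant(self):
        truth = np.array([0.0, 25.0, 50.0, 75.0, 100.0])
        res = agreement_regression(truth, truth)
        assert res.slope == 1.0 and res.r_squared == 1.0
        assert res.p_slope_vs_1 == 1.0

    def test_half_scale_detected(self):
        truth = np.array([0.0, 10.0, 20.0, 40.0])
        res = agreement_regression(0.5 * truth, truth)
        assert res.slope == pytest.approx(0.5)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_truth_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            agreement_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
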