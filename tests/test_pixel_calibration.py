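import numpy as np
import pytest

from echofish.pixel_calibration import (
    CorrectionModel,
    MatchedSchoolPair,
    PixelMapping,
    apply_correction,
    bin_sv,
    depth_dependence,
    fit_correction,
    grid_search_mapping,
    paired_rank_test,
    pixel_skewness,
    school_mean_sv,
    select_scenarios,
    sv_db_to_linear,
    sv_linear_to_db,
)
from echofish.synthetic_echogram import generate_matched_pairs

from oracles import exact_signed_rank_p


def pair_from_counts(counts, ses_sv_db=-45.0, time="08:00:00", match_id="m0"):
    return MatchedSchoolPair(
        match_id=match_id, time=time, ses_sv_db=ses_sv_db,
        rff_counts=np.asarray(counts, dtype=int),
    )


class TestSvDuality:
    def test_roundtrip_identity(self):
        vals = np.linspace(-70, -30, 41)
        assert np.allclose(sv_linear_to_db(sv_db_to_linear(vals)), vals, atol=1e-9)


class TestSchoolMeanSv:
    def test_degenerate_single_colour(self):
        mapping = PixelMapping(-50.0, 1.0)  # colour 1 -> -50 dB
        counts = np.array([0, 12])
        _, sv_db = school_mean_sv(counts, mapping)
        assert sv_db == pytest.approx(-50.0, abs=1e-12)

    def test_two_pixel_hand_calculation(self):
        mapping = PixelMapping(-50.0, 10.0)  # colours 1, 2 -> -50, -40 dB
        counts = np.array([0, 1, 1])
        _, sv_db = school_mean_sv(counts, mapping)
        want = 10 * np.log10((1e-5 + 1e-4) / 2)
        assert sv_db == pytest.approx(want, abs=1e-12)
        assert sv_db == pytest.approx(-42.6, abs=0.1)

    def test_count_scaling_invariance(self):
        mapping = PixelMapping(-65.0, 1.3)
        counts = np.array([0, 3, 5, 2, 9])
        _, a = school_mean_sv(counts, mapping)
        _, b = school_mean_sv(counts * 2, mapping)
        assert a == pytest.approx(b, abs=1e-12)

    def test_background_colour_excluded(self):
        mapping = PixelMapping(-50.0, 1.0)
        _, with_bg = school_mean_sv(np.array([100, 5]), mapping)
        _, without = school_mean_sv(np.array([0, 5]), mapping)
        assert with_bg == pytest.approx(without)

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            school_mean_sv(np.array([7, 0, 0]), PixelMapping(-65, 1.0))


class TestPixelSkewness:
    def test_symmetric_zero(self):
        assert pixel_skewness(np.array([0, 2, 5, 2])) == pytest.approx(0.0, abs=1e-12)

    def test_mirror_negates(self):
        counts = np.array([0, 9, 4, 2, 1])
        assert pixel_skewness(counts) == pytest.approx(
            -pixel_skewness(counts[::-1]), abs=1e-12
        )

    def test_matches_expanded_sample_skewness(self):
        from scipy import stats

        counts = np.array([0, 3, 7, 2, 1, 5])
        data = np.repeat(np.arange(6), counts)
        assert pixel_skewness(counts) == pytest.approx(stats.skew(data), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pixel_skewness(np.array([0, 5]))


class TestSelectScenarios:
    def mk(self, g1_targets):
        # craft counts with controlled skewness sign/magnitude
        pairs = []
        for i, g in enumerate(g1_targets):
            if g < -0.1:
                counts = np.array([0, 1, 1, 2, 4, 9])
            elif g > 0.1:
                counts = np.array([0, 9, 4, 2, 1, 1]) * max(int(g * 3), 1)
            else:
                counts = np.array([0, 1, 4, 6, 4, 1])
            pairs.append(pair_from_counts(counts, time=f"08:{i:02d}:00", match_id=f"m{i}"))
        return pairs

    def test_orders_min_zero_max(self):
        pairs = self.mk([-0.4, -0.001, 3.5, 1.0])
        lo, zero, hi = select_scenarios(pairs)
        g1 = [pixel_skewness(p.rff_counts) for p in pairs]
        assert g1[lo] == min(g1)
        assert abs(g1[zero]) == min(abs(g) for g in g1)
        assert g1[hi] == max(g1)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            select_scenarios(self.mk([-0.4, 3.5]))

    def test_tie_break_by_time(self):
        counts = np.array([0, 9, 4, 2, 1, 1])
        pairs = [
            pair_from_counts(counts, time="09:00:00", match_id="late"),
            pair_from_counts(counts, time="08:00:00", match_id="early"),
            pair_from_counts(np.array([0, 1, 4, 6, 4, 1]), time="08:30:00", match_id="z"),
        ]
        with pytest.raises(ValueError, match="distinct"):
            # min and max skewness coincide on the tied pair -> not distinct
            select_scenarios(pairs)


class TestGridSearch:
    def test_round_trip_recovers_truth(self):
        truth = PixelMapping(-65.0, 1.3)
        n_col = 12
        counts = np.zeros(n_col, dtype=int)
        counts[1:8] = [3, 9, 14, 11, 6, 2, 1]
        sv_lin, sv_db = school_mean_sv(counts, truth)
        pair = pair_from_counts(counts, ses_sv_db=sv_db)
        surface, step = grid_search_mapping(pair)
        assert step == pytest.approx(1.3)
        at_truth = surface[
            np.isclose(surface.start_db, -65.0) & np.isclose(surface.step_db, 1.3)
        ]
        assert abs(float(at_truth.dsv_db.iloc[0])) < 1e-9

    def test_start_shift_moves_sv_one_to_one(self):
        counts = np.zeros(10, dtype=int)
        counts[1:5] = [4, 6, 3, 1]
        pair = pair_from_counts(counts)
        surface, _ = grid_search_mapping(pair)
        fixed_step = surface[np.isclose(surface.step_db, 0.7)].sort_values("start_db")
        dsv = fixed_step.dsv_db.to_numpy()
        starts = fixed_step.start_db.to_numpy()
        assert np.allclose(np.diff(dsv), -np.diff(starts), atol=1e-9)


class TestCorrection:
    def test_exact_fit_recovery(self):
        rng = np.random.default_rng(2)
        mapping = PixelMapping(-65.0, 1.3)
        beta0, beta1 = -5.5, 4.0e4
        pairs = []
        for i in range(10):
            counts = np.zeros(10, dtype=int)
            counts[1 + i % 5] = 10 + i
            counts[2 + i % 5] = 5
            sv_lin, _ = school_mean_sv(counts, mapping)
            p = pair_from_counts(counts, match_id=f"m{i}")
            p.ses_sv_db = float(10 * (beta0 + beta1 * sv_lin))  # Sv = 10*log10(sv)
            pairs.append(p)
        model = fit_correction(pairs, mapping)
        assert model.beta0 == pytest.approx(beta0, abs=1e-9)
        assert model.beta1 == pytest.approx(beta1, rel=1e-9)
        assert model.r2 == pytest.approx(1.0, abs=1e-12)

    def test_permutation_invariance(self):
        pairs = generate_matched_pairs(seed=5, n_pairs=12)
        mapping = PixelMapping(-65.0, 1.3)
        a = fit_correction(pairs, mapping)
        b = fit_correction(pairs[::-1], mapping)
        assert a.beta0 == pytest.approx(b.beta0, abs=1e-12)
        assert a.beta1 == pytest.approx(b.beta1, rel=1e-12)

    def test_apply_constant_model(self):
        model = CorrectionModel(beta0=np.log10(3e-5), beta1=0.0, r2=1.0)
        sv, sv_db = apply_correction(model, np.array([1e-6, 1e-4]))
        assert np.allclose(sv, 3e-5)

    def test_monotone_when_slope_positive(self):
        model = CorrectionModel(beta0=-5.0, beta1=2e4, r2=0.9)
        _, sv_db = apply_correction(model, np.array([1e-6, 2e-6, 1e-5]))
        assert np.all(np.diff(sv_db) > 0)


class TestBinSv:
    def test_edge_rule(self):
        counts, edges = bin_sv([-65.0])
        assert edges[0] == pytest.approx(-68.0)
        assert counts[0] == 1

    def test_shift_by_width_shifts_histogram(self):
        vals = np.array([-66.0, -63.2, -58.9, -55.0])
        c1, e1 = bin_sv(vals)
        c2, e2 = bin_sv(vals + 4.0)
        assert np.array_equal(c1, c2)
        assert np.allclose(e2, e1 + 4.0)


class TestPairedRankTest:
    def test_identical_pairs(self):
        x = np.arange(10.0)
        with pytest.warns(UserWarning):
            _, p = paired_rank_test(x, x)
        assert p == 1.0

    def test_exact_small_n_matches_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(6, 11))
            x = rng.normal(0, 1, n)
            d = rng.normal(0.3, 1, n)
            d = np.where(d == 0, 0.1, d)
            y = x - d
            _, p = paired_rank_test(x, y)
            assert p == pytest.approx(exact_signed_rank_p(x - y), abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_rank_test([1.0, 2.0], [1.0])


class TestDepthDependence:
    def test_exact_exponential_decay(self):
        depth = np.linspace(5, 50, 20)
        sv = 10 ** (-4.0 - 0.02 * depth)
        slope, intercept, r2 = depth_dependence(sv, depth)
        assert slope == pytest.approx(-0.02, abs=1e-12)
        assert intercept == pytest.approx(-4.0, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_null_case_flat(self):
        rng = np.random.default_rng(6)
        depth = np.linspace(5, 50, 60)
        sv = 10 ** (-4.5 + rng.normal(0, 0.05, 60))
        slope, _, r2 = depth_dependence(sv, depth)
        assert r2 < 0.1
        # |slope| within 2 SE of zero
        resid_sd = np.std(np.log10(sv))
        se = resid_sd / (np.std(depth) * np.sqrt(60))
        assert abs(slope) < 2 * se
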