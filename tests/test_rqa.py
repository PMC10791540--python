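import numpy as np
import pytest
from _oracles import run_histograms_oracle

from ctrecur import (BinaryRP, FRPMatrix, InputError, LineHistograms, ToySeries,
                     binarize, diag_measures, embed, f_rr, fcm_partition, frp,
                     frqa_measures, gen_toy_series, line_histograms, vert_measures)


def brp(B, **kwargs):
    return BinaryRP(np.asarray(B), threshold=kwargs.pop("threshold", 0.5), **kwargs)


class TestBinarize:
    def test_idempotent_on_binary_input(self, rng):
        B0 = rng.integers(0, 2, (20, 20)).astype(float)
        out = binarize(B0, method="otsu")
        np.testing.assert_array_equal(out.B, B0.astype(bool))

    def test_bimodal_separation(self, rng):
        R = np.where(rng.random((30, 30)) < 0.4, 0.1, 0.9)
        out = binarize(R, method="otsu")
        np.testing.assert_array_equal(out.B, R == 0.9)
        assert 0.1 < out.threshold <= 0.9

    def test_constant_matrix_fallback(self, caplog):
        out = binarize(np.full((10, 10), 0.7), method="otsu")
        assert out.threshold == 0.5
        assert out.B.all()

    def test_constant_below_fallback_threshold(self):
        out = binarize(np.full((10, 10), 0.3), method="otsu")
        assert not out.B.any()

    def test_fixed_threshold(self):
        R = np.array([[1.0, 0.6], [0.6, 1.0]])
        out = binarize(R, method="fixed", threshold=0.6)
        assert out.B.all()  # >= is inclusive
        out = binarize(R, method="fixed", threshold=0.61)
        np.testing.assert_array_equal(out.B, np.eye(2, dtype=bool))

    def test_unknown_method(self):
        with pytest.raises(InputError):
            binarize(np.eye(3), method="kmeans")


class TestLineHistograms:
    def test_all_zeros_empty(self):
        hist = line_histograms(brp(np.zeros((8, 8))))
        assert hist.diagonal.sum() == 0 and hist.vertical.sum() == 0

    def test_all_ones_L10_loi_excluded(self):
        hist = line_histograms(brp(np.ones((10, 10))), exclude_loi=True)
        # off-diagonals come in mirrored pairs: two runs of each length 1..9
        np.testing.assert_array_equal(hist.diagonal, [2] * 9)
        expected_vert = np.zeros(10, dtype=int)
        expected_vert[9] = 10
        np.testing.assert_array_equal(hist.vertical, expected_vert)

    def test_all_ones_L10_loi_included(self):
        hist = line_histograms(brp(np.ones((10, 10))), exclude_loi=False)
        expected = np.zeros(10, dtype=int)
        expected[:9] = 2
        expected[9] = 1  # the main diagonal itself
        np.testing.assert_array_equal(hist.diagonal, expected)

    def test_single_off_diagonal_run(self):
        B = np.zeros((12, 12))
        for i in range(7):
            B[i, i + 3] = 1
        hist = line_histograms(brp(B))
        assert hist.diagonal[6] == 1
        assert hist.diagonal.sum() == 1
        assert hist.vertical[0] == 7  # seven isolated column cells

    def test_run_split_by_zero(self):
        B = np.zeros((9, 9))
        col = np.array([1, 1, 0, 1, 1, 1, 0, 0, 1], dtype=float)
        B[:, 4] = col
        hist = line_histograms(brp(B))
        assert hist.vertical[0] == 1 and hist.vertical[1] == 1 and hist.vertical[2] == 1

    @pytest.mark.parametrize("exclude_loi", [True, False])
    def test_oracle_equivalence_random(self, rng, exclude_loi):
        for _ in range(15):
            L = int(rng.integers(2, 61))
            B = rng.random((L, L)) < rng.uniform(0.2, 0.8)
            got = line_histograms(brp(B), exclude_loi=exclude_loi)
            exp_d, exp_v = run_histograms_oracle(B, exclude_loi)
            np.testing.assert_array_equal(got.diagonal, exp_d)
            np.testing.assert_array_equal(got.vertical, exp_v)


class TestFRR:
    def test_all_ones(self):
        assert f_rr(np.ones((5, 5)), omega=0.5) == 1.0

    def test_all_below_omega(self):
        assert f_rr(np.full((5, 5), 0.3), omega=0.5) == 0.0

    def test_retained_cells_keep_grade(self):
        assert f_rr(np.full((5, 5), 0.6), omega=0.5) == pytest.approx(0.6)

    def test_omega_boundary_inclusive(self):
        assert f_rr(np.full((4, 4), 0.5), omega=0.5) == pytest.approx(0.5)

    def test_invalid_omega(self):
        with pytest.raises(InputError):
            f_rr(np.ones((3, 3)), omega=1.5)


def hist_from_counts(diag=None, vert=None, n_d=10, k=10):
    d = np.zeros(n_d, dtype=int)
    v = np.zeros(k, dtype=int)
    for length, count in (diag or {}).items():
        d[length - 1] = count
    for length, count in (vert or {}).items():
        v[length - 1] = count
    return LineHistograms(diagonal=d, vertical=v)


class TestDiagMeasures:
    def test_single_run_length7(self):
        hist = hist_from_counts(diag={7: 1})
        fDET, fDIV, fENT = diag_measures(hist, lmin_d=5)
        assert fDET == 1.0
        assert fDIV == pytest.approx(1 / 7)
        assert fENT == 0.0

    def test_all_runs_too_short(self):
        hist = hist_from_counts(diag={2: 4, 3: 1})
        fDET, fDIV, fENT = diag_measures(hist, lmin_d=5)
        assert fDET == 0.0
        assert fDIV == pytest.approx(1 / 3)
        assert fENT == 0.0

    def test_all_ones_L10_divergence(self):
        B = brp(np.ones((10, 10)))
        hist = line_histograms(B)
        _, fDIV, _ = diag_measures(hist, lmin_d=5)
        assert fDIV == pytest.approx(1 / 9)

    def test_no_runs_fdiv_missing(self):
        fDET, fDIV, fENT = diag_measures(hist_from_counts(), lmin_d=5)
        assert fDET == 0.0 and fENT == 0.0
        assert np.isnan(fDIV)

    def test_entropy_two_equal_classes_is_one_bit(self):
        hist = hist_from_counts(diag={5: 3, 7: 3})
        _, _, fENT = diag_measures(hist, lmin_d=5)
        assert fENT == pytest.approx(1.0)

    def test_entropy_tail_mode_uses_global_p(self):
        hist = hist_from_counts(diag={2: 2, 6: 2})  # p(6) = 0.5 globally
        _, _, restricted = diag_measures(hist, lmin_d=5, entropy_mode="restricted")
        _, _, tail = diag_measures(hist, lmin_d=5, entropy_mode="tail")
        assert restricted == pytest.approx(0.0)
        assert tail == pytest.approx(0.5)  # -0.5 * log2(0.5)

    def test_fdet_monotone_in_lmin(self, rng):
        counts = {int(l): int(c) for l, c in
                  zip(rng.integers(1, 11, 6), rng.integers(1, 5, 6))}
        hist = hist_from_counts(diag=counts)
        vals = [diag_measures(hist, lmin_d=l)[0] for l in range(1, 11)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


class TestVertMeasures:
    def test_single_run_length6(self):
        fLAM, fTT = vert_measures(hist_from_counts(vert={6: 1}), lmin_v=5)
        assert fLAM == 1.0 and fTT == 6.0

    def test_isolated_points_only(self):
        fLAM, fTT = vert_measures(hist_from_counts(vert={1: 12}), lmin_v=5)
        assert fLAM == 0.0 and fTT == 0.0

    def test_all_ones_10x10(self):
        hist = line_histograms(brp(np.ones((10, 10))))
        fLAM, fTT = vert_measures(hist, lmin_v=5)
        assert fLAM == 1.0 and fTT == 10.0

    def test_mixture(self):
        # runs: 3 of length 2 (mass 6), 2 of length 6 (mass 12)
        fLAM, fTT = vert_measures(hist_from_counts(vert={2: 3, 6: 2}), lmin_v=5)
        assert fLAM == pytest.approx(12 / 18)
        assert fTT == pytest.approx(6.0)

    def test_flam_monotone_in_lmin(self, rng):
        counts = {int(l): int(c) for l, c in
                  zip(rng.integers(1, 11, 6), rng.integers(1, 5, 6))}
        hist = hist_from_counts(vert=counts)
        vals = [vert_measures(hist, lmin_v=l)[0] for l in range(1, 11)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


class TestFrqaMeasures:
    def test_ranges(self, rng):
        x = rng.normal(size=100)
        R = frp(fcm_partition(embed(x, 3, 1), c=10, seed=0))
        q = frqa_measures(R)
        for v in (q.fRR, q.fDET, q.fLAM, q.fDIV):
            assert 0.0 <= v <= 1.0
        assert q.fENT >= 0.0
        assert q.fTT == 0.0 or q.fTT >= q.lmin_v

    def test_trapping_time_floor_when_laminar(self, rng):
        for seed in range(5):
            x = gen_toy_series(ToySeries(kind="sine", length=100,
                                         params={"period": 10, "noise_sd": 0.05},
                                         seed=seed))
            q = frqa_measures(frp(fcm_partition(embed(x, 3, 1), c=10, seed=seed)))
            if q.fLAM > 0:
                assert q.fTT >= q.lmin_v

    def test_periodic_beats_noise_on_determinism(self):
        sine_det, noise_det = [], []
        for seed in range(10):
            sine = gen_toy_series(ToySeries(kind="sine", length=100,
                                            params={"period": 10, "noise_sd": 0.05},
                                            seed=seed))
            noise = gen_toy_series(ToySeries(kind="white_noise", length=100,
                                             seed=seed + 100))
            for x, acc in ((sine, sine_det), (noise, noise_det)):
                q = frqa_measures(frp(fcm_partition(embed(x, 3, 1), c=10, seed=seed)))
                acc.append(q.fDET)
        assert np.mean(sine_det) > np.mean(noise_det)
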