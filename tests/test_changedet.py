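"""Registration, differential images, opening and area accounting."""
import numpy as np
import pytest
from scipy import ndimage

from dugongtrails.changedet import (RegistrationConfig, build_differential,
                                    extract_new_trails, mask_area,
                                    match_block_offset, ncc_score,
                                    opening_filter, two_stage_register)
from dugongtrails.evalmetrics import BufferSpec, buffered_recall
from dugongtrails.mosaic import BlockGrid
from dugongtrails.synthgen import DayPairSpec, SceneConfig, make_day_pair


def _pair(seed, size=320, offset=(0, 0), n_new=0, n_trails=4):
    scene = SceneConfig(image_size_px=(size, size), resolution_cm_per_px=1.8,
                        n_trails=n_trails, seed=seed)
    return make_day_pair(DayPairSpec(scene, offset, n_new))


class TestNcc:
    def test_identical_blocks_score_one(self):
        a = np.random.default_rng(0).random((16, 16))
        assert ncc_score(a, a) == pytest.approx(1.0)

    def test_binary_complement_scores_minus_one(self):
        a = np.random.default_rng(1).random((16, 16)) < 0.4
        assert ncc_score(a.astype(float), (~a).astype(float)) == pytest.approx(-1.0)

    def test_constant_block_is_no_signal(self):
        assert np.isnan(ncc_score(np.ones((8, 8)), np.zeros((8, 8))))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ncc_score(np.ones((4, 4)), np.ones((5, 4)))


class TestMatchBlockOffset:
    def test_recovers_known_shift(self):
        rng = np.random.default_rng(2)
        prev = rng.random((64, 64)).astype(np.float32)
        cur = np.zeros_like(prev)
        cur[5:, :61] = prev[:-5, 3:]   # current = prev shifted by (5, -3)
        res = match_block_offset(prev, cur, 10)
        assert (res.dy, res.dx) == (5, -3)
        assert not res.at_window_edge

    def test_identical_blocks_give_zero_shift(self):
        a = np.random.default_rng(3).random((48, 48)).astype(np.float32)
        res = match_block_offset(a, a, 8)
        assert (res.dy, res.dx) == (0, 0)
        assert res.score == pytest.approx(1.0, abs=1e-5)

    def test_out_of_window_shift_is_flagged_at_edge(self):
        # smooth field whose correlation surface decays away from the true
        # shift, so the in-window argmax sits on the window boundary
        rng = np.random.default_rng(4)
        big = ndimage.gaussian_filter(rng.standard_normal((120, 120)), 6)
        prev = big[35:85, 35:85].astype(np.float32)
        cur = big[16:66, 35:85].astype(np.float32)   # true dy = 19 > window 12
        res = match_block_offset(prev, cur, 12)
        assert abs(res.dy) <= 12 and abs(res.dx) <= 12
        assert res.at_window_edge

    def test_constant_template_is_no_signal(self):
        res = match_block_offset(np.random.default_rng(5).random((32, 32)),
                                 np.ones((32, 32), dtype=np.float32), 4)
        assert res.no_signal and (res.dy, res.dx) == (0, 0)


class TestTwoStageRegister:
    CFG = RegistrationConfig(coarse_block_px=320, fine_block_px=64)

    def test_capacity_matches_stated_maximum(self):
        cfg = RegistrationConfig()
        assert round(cfg.max_correctable_offset_m(0.47), 1) == 3.0

    @pytest.mark.parametrize("offset", [(12, -9), (-30, 25)])
    def test_noise_free_correction_is_exact(self, offset):
        _, _, m0, m1, _, _ = _pair(21, offset=offset)
        corrected, diag = two_stage_register(m0, m1, self.CFG)
        coarse = diag[diag.stage == "coarse"][["dy", "dx"]].values[0]
        assert tuple(coarse) == offset
        b = max(abs(offset[0]), abs(offset[1])) + 8
        assert np.array_equal(corrected[b:-b, b:-b], m1[b:-b, b:-b])

    def test_aligned_masks_are_left_untouched(self):
        _, _, m0, m1, _, _ = _pair(22)
        corrected, diag = two_stage_register(m0, m1, self.CFG)
        assert np.array_equal(corrected, m0)
        assert (diag[["dy", "dx"]] == 0).all().all()

    def test_salt_noise_offset_recovery_within_one_pixel(self):
        rng = np.random.default_rng(77)
        offset = (12, -9)
        _, _, m0, m1, _, _ = _pair(23, offset=offset)
        noisy0 = m0 ^ (rng.random(m0.shape) < 0.10)
        noisy1 = m1 ^ (rng.random(m1.shape) < 0.10)
        _, diag = two_stage_register(noisy0, noisy1, self.CFG)
        coarse = diag[diag.stage == "coarse"][["dy", "dx"]].values[0]
        assert abs(coarse[0] - offset[0]) <= 1
        assert abs(coarse[1] - offset[1]) <= 1

    def test_undersized_raster_rejected(self):
        with pytest.raises(ValueError):
            two_stage_register(np.zeros((32, 32), bool), np.zeros((32, 32), bool),
                               RegistrationConfig(coarse_block_px=64,
                                                  fine_block_px=64))


class TestDifferential:
    def test_identical_masks(self):
        m = np.random.default_rng(6).random((16, 16)) < 0.3
        d = build_differential(m, m)
        assert not d.current_only.any() and not d.previous_only.any()
        assert np.array_equal(d.both, m)

    def test_empty_previous(self):
        m = np.random.default_rng(7).random((16, 16)) < 0.3
        d = build_differential(m, np.zeros_like(m))
        assert np.array_equal(d.current_only, m)

    def test_two_by_two_truth_table(self):
        cur = np.array([[1, 1], [0, 0]], dtype=bool)
        prev = np.array([[1, 0], [1, 0]], dtype=bool)
        d = build_differential(cur, prev)
        assert d.both.tolist() == [[True, False], [False, False]]
        assert d.current_only.tolist() == [[False, True], [False, False]]
        assert d.previous_only.tolist() == [[False, False], [True, False]]

    def test_partition_disjoint_and_covering(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cur = rng.random((24, 24)) < 0.4
            prev = rng.random((24, 24)) < 0.4
            d = build_differential(cur, prev)
            assert not (d.current_only & d.previous_only).any()
            assert not (d.current_only & d.both).any()
            assert not (d.previous_only & d.both).any()
            union = d.current_only | d.previous_only | d.both
            assert np.array_equal(union, cur | prev)

    def test_onehot_encoding_shape(self):
        d = build_differential(np.ones((4, 4), bool), np.zeros((4, 4), bool))
        onehot = d.to_onehot()
        assert onehot.shape == (4, 4, 3)
        assert onehot[..., 0].all() and not onehot[..., 1:].any()


class TestOpening:
    def test_isolated_pixel_removed(self):
        m = np.zeros((9, 9), dtype=bool)
        m[4, 4] = True
        assert not opening_filter(m).any()

    def test_large_square_preserved(self):
        m = np.zeros((16, 16), dtype=bool)
        m[3:13, 3:13] = True
        assert np.array_equal(opening_filter(m), m)

    def test_one_pixel_line_removed(self):
        m = np.zeros((12, 12), dtype=bool)
        m[6, 1:11] = True
        assert not opening_filter(m).any()

    def test_matches_brute_force_morphology(self):
        # independent oracle: scipy opening with explicit border handling
        for seed in range(10):
            m = np.random.default_rng(seed).random((14, 14)) < 0.45
            ref = ndimage.binary_opening(m, np.ones((3, 3)))
            assert np.array_equal(opening_filter(m), ref)

    def test_idempotent_and_anti_extensive(self):
        for seed in range(20):
            m = np.random.default_rng(seed).random((20, 20)) < 0.5
            once = opening_filter(m)
            assert np.array_equal(opening_filter(once), once)
            assert not (once & ~m).any()


class TestNewTrailPipeline:
    def test_recovers_planted_new_trails(self, model2_training):
        model2, _ = model2_training
        _, _, m0, m1, new, _ = _pair(999, offset=(9, -6), n_new=3, n_trails=3)
        reg = RegistrationConfig(coarse_block_px=320, fine_block_px=64)
        pred = extract_new_trails(model2, m1, m0, reg, grid=BlockGrid(64, 32))
        assert buffered_recall(pred, new, BufferSpec(7)) >= 0.9

    def test_quiet_pair_produces_few_positives(self, model2_training):
        model2, _ = model2_training
        _, _, m0, m1, _, _ = _pair(998, offset=(4, 3), n_new=0)
        reg = RegistrationConfig(coarse_block_px=320, fine_block_px=64)
        pred = extract_new_trails(model2, m1, m0, reg, grid=BlockGrid(64, 32))
        assert pred.sum() < 0.01 * m1.sum()

    def test_pipeline_deterministic(self, model2_training):
        model2, _ = model2_training
        _, _, m0, m1, _, _ = _pair(997, size=128, offset=(2, -2), n_new=1,
                                   n_trails=2)
        reg = RegistrationConfig(coarse_block_px=128, fine_block_px=64)
        a = extract_new_trails(model2, m1, m0, reg, grid=BlockGrid(64, 32))
        b = extract_new_trails(model2, m1, m0, reg, grid=BlockGrid(64, 32))
        assert np.array_equal(a, b)


class TestMaskArea:
    def test_empty_mask_is_zero(self):
        assert mask_area(np.zeros((10, 10), bool), 0.47) == 0.0

    def test_ten_thousand_px_at_1cm_is_one_m2(self):
        m = np.zeros((200, 200), dtype=bool)
        m[:100, :100] = True
        assert mask_area(m, 1.0) == pytest.approx(1.0)

    def test_full_plot_is_900_m2(self):
        # a 30 m x 30 m ground-truth plot at 0.5 cm/px
        m = np.ones((6000, 6000), dtype=bool)
        assert mask_area(m, 0.5) == pytest.approx(900.0)

    def test_invalid_resolution_rejected(self):
        with pytest.raises(ValueError):
            mask_area(np.ones((2, 2), bool), 0.0)
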