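import numpy as np
import pytest

import dareservoir as da
from dareservoir.codec import EncoderParams, SCAN_KEYS, SpikeVideo, _window


def brute_force_wspike(p_diff, thresholds=(1, 2, 4, 8, 16, 32)):
    total = sum(thresholds)
    return sum(e for e in thresholds if p_diff >= e) / total


class TestWeightedSpikeFrame:
    def test_static_scene_no_spikes(self):
        frame = np.full((10, 10), 100, dtype=np.uint8)
        spike, wmap = da.weighted_spike_frame(frame, frame)
        assert spike.sum() == 0 and np.all(wmap == 0)

    @pytest.mark.parametrize("p_diff", [0, 1, 3, 7, 15, 31, 32, 200])
    def test_wspike_matches_threshold_sum_oracle(self, p_diff):
        prev = np.zeros((2, 2))
        curr = np.full((2, 2), float(p_diff))
        _, wmap = da.weighted_spike_frame(prev, curr)
        assert wmap[0, 0] == pytest.approx(brute_force_wspike(p_diff))

    def test_saturated_pixel_always_spikes(self):
        prev = np.zeros((1, 1))
        curr = np.full((1, 1), 32.0)
        spike, wmap = da.weighted_spike_frame(
            prev, curr, EncoderParams(binarize_theta=1.0))
        assert wmap[0, 0] == 1.0 and spike[0, 0] == 1

    def test_signed_difference_ignores_darkening(self):
        prev = np.full((1, 1), 200.0)
        curr = np.zeros((1, 1))
        spike, wmap = da.weighted_spike_frame(prev, curr)
        assert wmap[0, 0] == 0.0 and spike[0, 0] == 0

    def test_shape_mismatch_and_color_input_raise(self):
        with pytest.raises(ValueError, match="differ"):
            da.weighted_spike_frame(np.zeros((2, 2)), np.zeros((3, 3)))
        with pytest.raises(ValueError, match="grayscale"):
            da.weighted_spike_frame(np.zeros((2, 2, 3)), np.zeros((2, 2, 3)))


class TestEncodeVideo:
    def test_t_frames_give_t_minus_1_spike_frames(self):
        frames = np.random.default_rng(0).integers(0, 255, (7, 8, 8),
                                                   dtype=np.uint8)
        assert da.encode_video(frames).n_frames == 6

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            da.encode_video(np.zeros((1, 8, 8), dtype=np.uint8))

    def test_moving_square_spikes_confined_to_object_region(self):
        # 1 px/frame translation of a bright solid square on dark background
        frames = np.full((5, 30, 30), 10, dtype=np.uint8)
        for t in range(5):
            frames[t, 10:20, 5 + t:15 + t] = 200
        sv = da.encode_video(frames)
        for t in range(4):
            rows, cols = np.nonzero(sv.frames[t])
            assert rows.size > 0
            assert rows.min() >= 9 and rows.max() <= 20
            assert cols.min() >= 5 + t and cols.max() <= 15 + t + 1

    def test_reversed_video_differs_from_forward(self):
        frames = np.full((4, 20, 20), 10, dtype=np.uint8)
        for t in range(4):
            frames[t, 5:10, 5 + 2 * t:10 + 2 * t] = 200
        fwd = da.encode_video(frames)
        bwd = da.encode_video(frames[::-1])
        assert not np.array_equal(fwd.frames, bwd.frames[::-1])

    def test_temporal_order_locality(self):
        # spike frame i depends only on input frames i and i+1
        rng = np.random.default_rng(1)
        frames = rng.integers(0, 255, (6, 10, 10), dtype=np.uint8)
        sv = da.encode_video(frames)
        frames2 = frames.copy()
        frames2[5] = 0  # mutating the last frame only affects spike frame 4
        sv2 = da.encode_video(frames2)
        assert np.array_equal(sv.frames[:4], sv2.frames[:4])
        assert not np.array_equal(sv.frames[4], sv2.frames[4])


class TestCenterOfGravity:
    def test_single_pixel(self):
        frame = np.zeros((30, 40), dtype=np.uint8)
        frame[10, 20] = 1
        assert da.center_of_gravity(frame) == (10, 20)

    def test_midpoint_of_two_pixels(self):
        frame = np.zeros((20, 20), dtype=np.uint8)
        frame[0, 0] = frame[10, 10] = 1
        assert da.center_of_gravity(frame) == (5, 5)

    def test_ring_centered_via_direct_average_oracle(self):
        frame = np.zeros((41, 41), dtype=np.uint8)
        cy, cx = 20, 20
        for ang in np.linspace(0, 2 * np.pi, 100, endpoint=False):
            frame[int(round(cy + 8 * np.sin(ang))),
                  int(round(cx + 8 * np.cos(ang)))] = 1
        rows, cols = np.nonzero(frame)
        oracle = (int(np.rint(rows.mean())), int(np.rint(cols.mean())))
        assert da.center_of_gravity(frame) == oracle == (20, 20)

    def test_empty_frame_falls_back_to_center(self):
        assert da.center_of_gravity(np.zeros((30, 50))) == (15, 25)


class TestExtractScans:
    def test_default_stride_is_half_the_box_halfwidth(self):
        params = EncoderParams()
        assert params.stride == 10 == (params.bb_size - 1) // 2 // 2

    def test_windows_are_always_bb_sized(self, tiny_clip):
        sv = da.encode_video(tiny_clip.frames)
        scans = da.extract_scans(sv)
        for key in SCAN_KEYS:
            assert scans.scans[key].shape[1:] == (41, 41)

    def test_directional_windows_are_shifted_views_of_center(self):
        # activity well inside the C window: L/R/T/B see shifted subsets
        frame = np.zeros((101, 101), dtype=np.uint8)
        frame[48:53, 48:53] = 1
        scans = da.extract_scans(SpikeVideo(frame[None]))
        c = scans.scans["C"][0]
        assert np.array_equal(scans.scans["R"][0],
                              np.roll(c, -10, axis=1))
        assert np.array_equal(scans.scans["L"][0], np.roll(c, 10, axis=1))
        assert np.array_equal(scans.scans["T"][0], np.roll(c, 10, axis=0))
        assert np.array_equal(scans.scans["B"][0], np.roll(c, -10, axis=0))
        assert scans.scans["R"][0].sum() == c.sum()

    def test_empty_video_gives_zero_scans_at_image_center(self):
        sv = SpikeVideo(np.zeros((3, 80, 80), dtype=np.uint8))
        scans = da.extract_scans(sv)
        assert all(scans.scans[k].sum() == 0 for k in SCAN_KEYS)
        assert np.all(scans.cog_track == [40, 40])

    def test_translation_equivariance_of_cog_and_center_window(self):
        rng = np.random.default_rng(2)
        base = np.zeros((120, 120), dtype=np.uint8)
        base[40:60, 40:60] = (rng.random((20, 20)) < 0.5)
        shifted = np.roll(np.roll(base, 7, axis=0), 4, axis=1)
        s0 = da.extract_scans(SpikeVideo(base[None]))
        s1 = da.extract_scans(SpikeVideo(shifted[None]))
        assert tuple(s1.cog_track[0]) == (s0.cog_track[0][0] + 7,
                                          s0.cog_track[0][1] + 4)
        assert np.array_equal(s0.scans["C"][0], s1.scans["C"][0])

    def test_border_windows_are_zero_padded(self):
        frame = np.zeros((50, 50), dtype=np.uint8)
        frame[0:2, 0:2] = 1  # CoG near the corner
        scans = da.extract_scans(SpikeVideo(frame[None]))
        assert scans.scans["C"][0].shape == (41, 41)
        # zero-padding beyond the top-left border
        assert scans.scans["T"][0].sum() <= scans.scans["C"][0].sum()

    def test_window_helper_zero_pads(self):
        frame = np.arange(9, dtype=np.uint8).reshape(3, 3)
        win = _window(frame, (0, 0), 5)
        assert win.shape == (5, 5)
        assert win[:2, :].sum() == 0 and win[:, :2].sum() == 0
        assert win[2, 2] == frame[0, 0]


class TestDeleteBadFrames:
    def _scan_set(self, frames):
        sv = SpikeVideo(frames)
        return da.extract_scans(sv), sv

    def test_overactive_frame_deleted(self):
        frames = np.zeros((3, 50, 50), dtype=np.uint8)
        frames[0, :20, :20] = 1            # 16%: kept
        frames[1] = 1                      # 100% flash: rule 1
        frames[2, :20, :20] = 1
        scans, sv = self._scan_set(frames)
        out = da.delete_bad_frames(scans, sv)
        assert 1 in out.deleted_frames["C"]
        assert list(out.frame_indices["C"]) == [0, 2]

    def test_empty_frame_deleted(self):
        frames = np.zeros((2, 50, 50), dtype=np.uint8)
        frames[0, :25, :25] = 1
        scans, sv = self._scan_set(frames)
        out = da.delete_bad_frames(scans, sv)
        assert 1 in out.deleted_frames["C"]

    def test_rule2_never_touches_center_stream(self):
        rng = np.random.default_rng(3)
        frames = (rng.random((10, 60, 60)) < 0.2).astype(np.uint8)
        scans, sv = self._scan_set(frames)
        out = da.delete_bad_frames(scans, sv)
        rule1 = set(out.deleted_frames["C"])
        for k in ("R", "L", "T", "B"):
            assert rule1 <= set(out.deleted_frames[k])
        assert len(out.frame_indices["C"]) >= len(out.frame_indices["R"])

    def test_surviving_frames_match_brute_force_rules(self):
        rng = np.random.default_rng(7)
        frames = np.zeros((10, 64, 64), dtype=np.uint8)
        for t in range(10):
            # varying activity levels, some outside the [8%, 75%] band
            density = [0.0, 0.02, 0.10, 0.12, 0.30, 0.50, 0.80, 0.15,
                       0.09, 0.20][t]
            frames[t] = rng.random((64, 64)) < density
        params = EncoderParams()
        scans, sv = self._scan_set(frames)
        out = da.delete_bad_frames(scans, sv, params)

        # independent rule-by-rule reimplementation
        frac = frames.reshape(10, -1).mean(axis=1)
        keep1 = [i for i in range(10)
                 if params.min_active_frac <= frac[i] <= params.max_active_frac]
        counts = {k: scans.scans[k].reshape(10, -1).sum(axis=1).astype(float)
                  for k in SCAN_KEYS}
        mean_c = np.mean([counts["C"][i] for i in keep1])
        expected = {"C": keep1}
        for k in ("R", "L", "T", "B"):
            expected[k] = [i for i in keep1
                           if abs(counts["C"][i] - counts[k][i]) <= mean_c]
        for k in SCAN_KEYS:
            assert list(out.frame_indices[k]) == expected[k]

    def test_outputs_stay_binary_and_sorted(self, tiny_clip):
        out = da.encode_to_scans(tiny_clip.frames)
        for k in SCAN_KEYS:
            assert out.scans[k].max(initial=0) <= 1
            d = out.deleted_frames[k]
            assert d == sorted(d) and len(d) == len(set(d))


class TestEncoderParamsValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(thresholds=(4, 2, 1)),
        dict(thresholds=()),
        dict(binarize_theta=0.0),
        dict(bb_size=40),
        dict(min_active_frac=0.8, max_active_frac=0.5),
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EncoderParams(**kwargs)


def test_to_grayscale_rejects_non_rgb():
    with pytest.raises(ValueError):
        da.to_grayscale(np.zeros((3, 4, 4)))
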