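import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from avdeid import synthetic
from avdeid.videodeid import (
    STATUS_INTERPOLATED,
    STATUS_OBSERVED,
    FaceRegion,
    KeypointTrack,
    PrivacyModeParams,
    apply_gpp,
    apply_ppp,
    associate_tracks,
    face_bbox,
    interpolate_gaps,
    kalman_filter_1d,
    process_video,
    read_detections_json,
    smooth_kalman,
    write_detections_json,
)


def kp_array(x, y, conf=1.0):
    """A full 17-keypoint detection centered at (x, y)."""
    kps = np.zeros((17, 3))
    kps[:, 0] = x + synthetic._SKELETON_OFFSETS[:, 0]
    kps[:, 1] = y + synthetic._SKELETON_OFFSETS[:, 1]
    kps[:, 2] = conf
    return kps


class TestAssociate:
    def test_single_person_single_track(self):
        dets = {f: [kp_array(20 + 0.5 * f, 50)] for f in range(100)}
        tracks = associate_tracks(dets, max_match_dist_px=20)
        assert len(tracks) == 1
        assert len(tracks[0].frames) == 100

    @pytest.mark.parametrize("assignment", ["greedy", "hungarian"])
    def test_two_crossing_persons_keep_identity(self, assignment):
        """Two figures pass each other vertically separated: the fixture
        labels are the oracle for track identity."""
        dets, truth = {}, {0: [], 1: []}
        for f in range(60):
            a = kp_array(10 + f, 30)
            b = kp_array(70 - f, 90)
            dets[f] = [a, b]
            truth[0].append(a)
            truth[1].append(b)
        tracks = associate_tracks(dets, max_match_dist_px=25,
                                  assignment=assignment)
        assert len(tracks) == 2
        by_id = {t.track_id: t for t in tracks}
        for tid in (0, 1):
            for f in range(60):
                np.testing.assert_allclose(
                    by_id[tid].frames[f][:, :2], truth[tid][f][:, :2]
                )

    def test_empty_frame_leaves_gap(self):
        dets = {0: [kp_array(20, 50)], 1: [], 2: [kp_array(21, 50)]}
        tracks = associate_tracks(dets, max_match_dist_px=20)
        assert len(tracks) == 1
        assert sorted(tracks[0].frames) == [0, 2]

    def test_empty_input_gives_no_tracks(self):
        assert associate_tracks({}) == []

    def test_far_detection_starts_new_track(self):
        dets = {0: [kp_array(10, 10)], 1: [kp_array(150, 150)]}
        tracks = associate_tracks(dets, max_match_dist_px=20)
        assert len(tracks) == 2


class TestInterpolate:
    def _track_with(self, frames_xy):
        t = KeypointTrack(track_id=0)
        for f, (x, y) in frames_xy.items():
            kps = np.zeros((17, 4))
            kps[:, 0], kps[:, 1], kps[:, 2], kps[:, 3] = x, y, 1.0, STATUS_OBSERVED
            t.frames[f] = kps
        return t

    def test_linear_gap_recovery_matches_line_equation(self):
        t = self._track_with({0: (0, 0), 4: (4, 8)})
        out = interpolate_gaps(t, max_gap_frames=10)
        for f, (ex, ey) in [(1, (1, 2)), (2, (2, 4)), (3, (3, 6))]:
            np.testing.assert_allclose(out.frames[f][0, :2], [ex, ey])
            assert out.frames[f][0, 3] == STATUS_INTERPOLATED

    def test_no_gaps_is_identity(self):
        t = self._track_with({0: (1, 1), 1: (2, 2), 2: (3, 3)})
        out = interpolate_gaps(t, max_gap_frames=5)
        for f in (0, 1, 2):
            np.testing.assert_array_equal(out.frames[f], t.frames[f])
        assert out.unfilled_gaps == []

    def test_leading_gap_constant_extension(self):
        t = self._track_with({3: (5, 5)})
        out = interpolate_gaps(t, max_gap_frames=5, frame_range=(0, 3))
        for f in (0, 1, 2):
            np.testing.assert_allclose(out.frames[f][0, :2], [5, 5])
            assert out.frames[f][0, 3] == STATUS_INTERPOLATED

    def test_long_gap_left_unfilled_and_flagged(self):
        t = self._track_with({0: (0, 0), 10: (10, 10)})
        out = interpolate_gaps(t, max_gap_frames=5)
        assert out.unfilled_gaps == [(1, 9)]
        assert sorted(out.frames) == [0, 10]

    def test_empty_track_raises(self):
        with pytest.raises(ValueError):
            interpolate_gaps(KeypointTrack(track_id=0))


class TestKalman:
    def test_matches_hand_executed_recursion(self):
        """Three-step constant-velocity recursion, executed by hand with
        explicit scalar arithmetic (independent of the implementation)."""
        z = [1.0, 2.0, 4.0]
        q, r = 0.5, 2.0
        # init
        x = [z[0], 0.0]
        P = [[r, 0.0], [0.0, 1000.0]]
        expected = [x[0]]
        Q = [[0.25 * q, 0.5 * q], [0.5 * q, q]]
        for k in (1, 2):
            # predict: x = F x, P = F P F' + Q  with F = [[1,1],[0,1]]
            x = [x[0] + x[1], x[1]]
            P = [
                [P[0][0] + P[1][0] + P[0][1] + P[1][1] + Q[0][0],
                 P[0][1] + P[1][1] + Q[0][1]],
                [P[1][0] + P[1][1] + Q[1][0], P[1][1] + Q[1][1]],
            ]
            # update with H = [1, 0]
            S = P[0][0] + r
            K = [P[0][0] / S, P[1][0] / S]
            resid = z[k] - x[0]
            x = [x[0] + K[0] * resid, x[1] + K[1] * resid]
            P = [
                [(1 - K[0]) * P[0][0], (1 - K[0]) * P[0][1]],
                [P[1][0] - K[1] * P[0][0], P[1][1] - K[1] * P[0][1]],
            ]
            expected.append(x[0])
        got = kalman_filter_1d(np.array(z), q, r)
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_vanishing_measurement_noise_tracks_observations(self):
        rng = np.random.default_rng(0)
        z = np.cumsum(rng.normal(0, 1, 50))
        got = kalman_filter_1d(z, 1.0, 1e-12)
        np.testing.assert_allclose(got, z, atol=1e-6)

    def test_rmse_improvement_on_noisy_constant_velocity(self):
        rng = np.random.default_rng(1)
        truth = 0.7 * np.arange(300)
        z = truth + rng.normal(0, 2.0, 300)
        filt = kalman_filter_1d(z, 1.0, 4.0)
        rmse = lambda a: float(np.sqrt(np.mean((a - truth) ** 2)))
        assert rmse(filt) < rmse(z)

    @pytest.mark.parametrize("q,r", [(0.0, 1.0), (1.0, -1.0)])
    def test_non_positive_noise_rejected(self, q, r):
        with pytest.raises(ValueError):
            kalman_filter_1d(np.zeros(3), q, r)

    def test_smooth_kalman_preserves_frame_set(self):
        t = KeypointTrack(track_id=0)
        for f in range(10):
            kps = np.zeros((17, 4))
            kps[:, 0] = f
            kps[:, 2] = 1.0
            t.frames[f] = kps
        out = smooth_kalman(t, 1.0, 4.0)
        assert sorted(out.frames) == sorted(t.frames)

    def test_smooth_kalman_requires_contiguous_track(self):
        t = KeypointTrack(track_id=0, frames={0: np.zeros((17, 4)),
                                              2: np.zeros((17, 4))})
        with pytest.raises(ValueError, match="contiguous"):
            smooth_kalman(t, 1.0, 4.0)


class TestFaceBbox:
    def params(self, margin=0.0):
        return PrivacyModeParams(bbox_margin_frac=margin, kp_conf_threshold=0.3)

    def _kps(self, facial_xy, conf=1.0):
        kps = np.zeros((17, 3))
        kps[:5, :2] = facial_xy
        kps[:5, 2] = conf
        return kps

    def test_hull_min_max_arithmetic(self):
        kps = self._kps([(50, 40), (45, 35), (55, 35), (40, 38), (60, 38)])
        region = face_bbox(kps, self.params(margin=0.0), (200, 200))
        assert region.bbox == (40, 35, 60, 40)

    def test_all_confidences_below_threshold_gives_none(self):
        kps = self._kps([(50, 40)] * 5, conf=0.1)
        assert face_bbox(kps, self.params(), (200, 200)) is None

    def test_degenerate_hull_gives_floor_sized_box(self):
        kps = self._kps([(100, 100)] * 5)
        p = self.params(margin=0.3)
        region = face_bbox(kps, p, (300, 300))
        x0, y0, x1, y1 = region.bbox
        assert (x1 - x0) == (y1 - y0) == p.min_face_box_px
        assert (x0 + x1) / 2 == (y0 + y1) / 2 == 100

    def test_margin_expands_by_fraction_of_diagonal(self):
        kps = self._kps([(0, 0), (10, 0), (0, 10), (10, 10), (5, 5)])
        region = face_bbox(kps, self.params(margin=0.25), (100, 100))
        # diagonal sqrt(200) ~ 14.14, margin ~ 3.54 -> floor/ceil
        assert region.bbox == (0, 0, 14, 14)  # clipped at 0


class TestBlurModes:
    def checkerboard(self, h=64, w=64):
        yy, xx = np.mgrid[0:h, 0:w]
        board = ((yy // 4 + xx // 4) % 2).astype(np.uint8) * 200 + 30
        return np.repeat(board[..., None], 3, axis=2)

    def test_ppp_empty_regions_is_identity(self):
        frame = self.checkerboard()
        out = apply_ppp(frame, [], PrivacyModeParams(mode="PPP"))
        assert np.array_equal(out, frame)

    def test_ppp_constant_frame_unchanged_everywhere(self):
        frame = np.full((64, 64, 3), 77, dtype=np.uint8)
        region = FaceRegion(0, (10, 10, 40, 40), 0)
        out = apply_ppp(frame, [region], PrivacyModeParams(mode="PPP"))
        assert np.array_equal(out, frame)

    def test_ppp_matches_direct_convolution_and_is_local(self):
        frame = self.checkerboard()
        params = PrivacyModeParams(mode="PPP", blur_sigma_face=3.0)
        region = FaceRegion(0, (16, 16, 48, 48), 0)
        out = apply_ppp(frame, [region], params)
        # direct whole-frame Gaussian convolution as the oracle
        oracle = np.stack(
            [gaussian_filter(frame[:, :, c].astype(float), 3.0)
             for c in range(3)], axis=2,
        )
        oracle = np.clip(np.rint(oracle), 0, 255).astype(np.uint8)
        np.testing.assert_array_equal(out[16:48, 16:48], oracle[16:48, 16:48])
        mask = np.zeros((64, 64), bool)
        mask[16:48, 16:48] = True
        assert np.array_equal(out[~mask], frame[~mask])
        inside_var = out[16:48, 16:48].astype(float).var()
        assert inside_var < frame[16:48, 16:48].astype(float).var()

    def test_gpp_blurs_everywhere_and_draws_overlay(self):
        frame = self.checkerboard()
        params = PrivacyModeParams(mode="GPP", blur_sigma_frame=2.0)
        kps = kp_array(32, 32, conf=1.0)
        out, mask = apply_gpp(frame, [kps], params, return_mask=True)
        assert mask.any()
        # overlay pixels carry the configured color
        assert np.all(out[mask] == np.array(params.overlay.color))
        # disc centers at rounded keypoint coordinates
        for i in range(17):
            r, c = int(round(kps[i, 1])), int(round(kps[i, 0]))
            if 0 <= r < 64 and 0 <= c < 64:
                assert mask[r, c]

    def test_gpp_without_persons_is_pure_blur(self):
        frame = self.checkerboard()
        params = PrivacyModeParams(mode="GPP", blur_sigma_frame=2.0)
        out, mask = apply_gpp(frame, [], params, return_mask=True)
        assert not mask.any()
        oracle = np.stack(
            [gaussian_filter(frame[:, :, c].astype(float), 2.0)
             for c in range(3)], axis=2,
        )
        np.testing.assert_array_equal(
            out, np.clip(np.rint(oracle), 0, 255).astype(np.uint8)
        )


class TestProcessVideo:
    @pytest.fixture(scope="class")
    @staticmethod
    def clip():
        spec = synthetic.FixtureSpec(seed=21, duration_s=4.0, fps=15.0)
        return synthetic.gen_pose_clip(spec)

    def test_ppp_covers_all_facial_landmarks_despite_dropout(self, clip):
        frames, dets, gt = clip
        res = process_video(frames, dets, PrivacyModeParams(mode="PPP"))
        by_frame = {}
        for r in res.regions:
            by_frame.setdefault(r.frame_index, []).append(r.bbox)
        for f in range(len(frames)):
            for kps in gt:
                pts = kps[f][:5, :2]
                assert any(
                    all(x0 <= x < x1 and y0 <= y < y1 for x, y in pts)
                    for x0, y0, x1, y1 in by_frame.get(f, [])
                ), f"frame {f}: facial landmarks escape every blur box"

    def test_ppp_changes_nothing_outside_face_boxes(self, clip):
        frames, dets, _ = clip
        res = process_video(frames, dets, PrivacyModeParams(mode="PPP"))
        by_frame = {}
        for r in res.regions:
            by_frame.setdefault(r.frame_index, []).append(r.bbox)
        for f in range(len(frames)):
            inside = np.zeros(frames[f].shape[:2], bool)
            for x0, y0, x1, y1 in by_frame.get(f, []):
                inside[y0:y1, x0:x1] = True
            changed = (frames[f] != res.frames[f]).any(axis=2)
            assert not (changed & ~inside).any()

    def test_gpp_no_unblurred_background_pixel(self, clip):
        frames, dets, _ = clip
        res = process_video(frames, dets, PrivacyModeParams(mode="GPP"))
        f = len(frames) // 2
        same = (frames[f] == res.frames[f]).all(axis=2)
        # on a high-variance background, unchanged non-overlay pixels are
        # vanishingly rare (only where the blur happens to reproduce input)
        assert (same & ~res.overlay_masks[f]).mean() < 0.01

    def test_zero_person_clip_in_ppp_is_identity(self):
        frames = [np.full((32, 32, 3), i, dtype=np.uint8) for i in range(5)]
        res = process_video(frames, {}, PrivacyModeParams(mode="PPP"))
        for a, b in zip(frames, res.frames):
            assert np.array_equal(a, b)

    def test_detection_index_out_of_range_raises(self):
        frames = [np.zeros((32, 32, 3), dtype=np.uint8)]
        with pytest.raises(ValueError, match="frame 5"):
            process_video(frames, {5: [kp_array(10, 10)]},
                          PrivacyModeParams(mode="PPP"))

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown privacy mode"):
            process_video([], {}, PrivacyModeParams(mode="XXX"))


def test_detections_json_round_trip(tmp_path):
    dets = {0: [kp_array(10, 20)], 2: [kp_array(11, 21), kp_array(50, 60)]}
    p = tmp_path / "d.json"
    write_detections_json(dets, p)
    back = read_detections_json(p)
    assert sorted(back) == [0, 2]
    np.testing.assert_allclose(back[2][1], dets[2][1])
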