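import numpy as np
import pytest

from avdeid import synthetic
from avdeid.audioscrub import (
    AudioBuffer,
    PhiInterval,
    ToneSpec,
    insert_tones,
    transform_voice,
    VoiceTransformParams,
)
from avdeid.qc import (
    QCFinding,
    blur_coverage_metric,
    build_checklist,
    compile_report,
    residual_face_scan,
    residual_phi_scan,
    voice_transform_check,
)
from avdeid.videodeid import FaceRegion, PrivacyModeParams, apply_ppp

from conftest import make_harmonic


class TestChecklist:
    @pytest.mark.parametrize("mode,prefix", [("PPP", "ppp."), ("GPP", "gpp.")])
    def test_four_video_plus_two_audio_items(self, mode, prefix):
        items = build_checklist(mode)
        assert len(items) == 6
        assert sum(i.rule_id.startswith(prefix) for i in items) == 4
        assert sum(i.rule_id.startswith("audio.") for i in items) == 2

    def test_rule_ids_are_stable_and_usable_in_findings(self):
        for item in build_checklist("GPP"):
            QCFinding(modality="video" if "gpp" in item.rule_id else "audio",
                      rule_id=item.rule_id)

    def test_unknown_mode_errors(self):
        with pytest.raises(ValueError):
            build_checklist("ZZZ")


class TestFaceScan:
    frames = [np.zeros((8, 8, 3), dtype=np.uint8) for _ in range(20)]

    def test_silent_detector_flags_nothing(self):
        res = residual_face_scan(self.frames, lambda f: [])
        assert res.flagged_frames == []

    def test_planted_detections_flagged_exactly(self):
        hits = {3: ["face"], 17: ["face", "face"]}

        calls = iter(range(len(self.frames)))
        res = residual_face_scan(
            self.frames, lambda f, c=calls: hits.get(next(c), [])
        )
        assert res.flagged_frames == [3, 17]

    def test_duplicate_detections_give_single_flag(self):
        calls = iter(range(len(self.frames)))
        res = residual_face_scan(
            self.frames, lambda f, c=calls: ["a", "b"] if next(c) == 5 else []
        )
        assert res.flagged_frames == [5]

    def test_detector_failure_becomes_warning_and_scan_continues(self):
        calls = iter(range(len(self.frames)))

        def flaky(frame, c=calls):
            i = next(c)
            if i == 2:
                raise RuntimeError("boom")
            return ["hit"] if i == 7 else []

        res = residual_face_scan(self.frames, flaky)
        assert res.flagged_frames == [7]
        warns = [f for f in res.findings if f.severity == "warn"]
        assert len(warns) == 1 and warns[0].frame_index == 2


class TestBlurCoverage:
    def checkerboard(self):
        yy, xx = np.mgrid[0:64, 0:64]
        b = ((yy // 4 + xx // 4) % 2).astype(np.uint8) * 200 + 30
        return np.repeat(b[..., None], 3, axis=2)

    def test_identical_frames_score_zero(self):
        f = self.checkerboard()
        ratios, outside = blur_coverage_metric(
            f, f, [FaceRegion(0, (8, 8, 32, 32), 0)]
        )
        assert ratios == [0.0] and outside == 0

    def test_blurred_checkerboard_region_scores_high_no_outside_change(self):
        f = self.checkerboard()
        region = FaceRegion(0, (8, 8, 40, 40), 0)
        deid = apply_ppp(f, [region], PrivacyModeParams(mode="PPP",
                                                        blur_sigma_face=4.0))
        ratios, outside = blur_coverage_metric(f, deid, [region])
        assert ratios[0] > 0.8
        assert outside == 0

    def test_size_mismatch_raises(self):
        f = self.checkerboard()
        with pytest.raises(ValueError):
            blur_coverage_metric(f, f[:32], [])


class TestResidualPhiScan:
    def scrubbed_fixture(self):
        a = make_harmonic(120, 3.0)
        intervals = [PhiInterval(400, 900, "NAME"),
                     PhiInterval(1500, 2100, "DATE")]
        return insert_tones(a, intervals), intervals

    def test_correct_scrub_yields_zero_flags(self):
        scrubbed, intervals = self.scrubbed_fixture()
        assert residual_phi_scan(scrubbed, intervals) == []

    def test_skipped_interval_is_the_one_flagged(self):
        a = make_harmonic(120, 3.0)
        intervals = [PhiInterval(400, 900, "NAME"),
                     PhiInterval(1500, 2100, "DATE")]
        partially = insert_tones(a, intervals[:1])  # deliberately skip one
        flags = residual_phi_scan(partially, intervals)
        assert flags == [intervals[1]]

    def test_empty_interval_list_zero_flags(self):
        a = make_harmonic(120, 1.0)
        assert residual_phi_scan(a, []) == []

    def test_silence_inside_interval_is_flagged(self):
        a = AudioBuffer(np.zeros(16000 * 2), 16000)
        iv = [PhiInterval(100, 600, "NAME")]
        assert residual_phi_scan(a, iv) == iv


class TestVoiceTransformCheck:
    def test_identity_transform_detected(self):
        a = make_harmonic(120)
        finding = voice_transform_check(a, a.copy())
        assert finding is not None and finding.severity == "fail"

    def test_real_transform_passes(self):
        a = make_harmonic(120)
        out = transform_voice(a, VoiceTransformParams(f0_ratio=1.3,
                                                      envelope_warp=1.0))
        assert voice_transform_check(a, out) is None

    def test_phi_intervals_excluded_from_comparison(self):
        a = make_harmonic(120)
        toned = insert_tones(a, [PhiInterval(0, 500, "NAME")])
        # outside the interval the audio is untouched -> identity detected
        finding = voice_transform_check(a, toned, [(0, 500)])
        assert finding is not None


class TestCompileReport:
    def test_no_findings_passes(self):
        assert compile_report([], "GPP").status == "pass"

    def test_single_fail_finding_fails(self):
        r = compile_report(
            [QCFinding(modality="audio", rule_id="audio.phi_tones")], "PPP"
        )
        assert r.status == "fail"

    def test_warn_only_findings_still_pass(self):
        r = compile_report(
            [QCFinding(modality="video", rule_id="video.gap_too_long",
                       severity="warn")],
            "GPP",
        )
        assert r.status == "pass"
        assert "gap_too_long" in r.to_json()

    def test_checklist_markdown_renders_all_items(self):
        md = compile_report([], "PPP").checklist_markdown()
        assert md.count("- [") == 6


def test_fault_injection_all_defect_classes_caught(short_spec):
    """Each deliberately introduced defect — skipped tone, omitted blur
    region, identity voice transform — is caught by a machine check."""
    t, gt_spans = synthetic.gen_transcript(short_spec)
    audio = synthetic.gen_audio(short_spec, t)
    from avdeid.audioscrub import phi_intervals

    intervals = phi_intervals(t, gt_spans)

    # defect 1: one tone interval skipped
    partial = insert_tones(audio, intervals[:-1])
    assert residual_phi_scan(partial, intervals) == [intervals[-1]]

    # defect 2: identity voice transform
    toned = insert_tones(audio, intervals)
    assert voice_transform_check(
        toned, toned.copy(), [(iv.start_ms, iv.end_ms) for iv in intervals]
    ) is not None

    # defect 3: omitted face region -> coverage ratio 0 for that region
    frames, dets, gtk = synthetic.gen_pose_clip(short_spec, n_frames=5)
    region = FaceRegion(0, (10, 10, 40, 40), 0)
    ratios, _ = blur_coverage_metric(frames[0], frames[0], [region])
    assert ratios[0] == 0.0  # nothing was blurred where a region was claimed
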