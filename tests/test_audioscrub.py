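import numpy as np
import pytest

from avdeid import synthetic
from avdeid.audioscrub import (
    AudioBuffer,
    PhiInterval,
    ToneSpec,
    VoiceTransformParams,
    estimate_f0_track,
    insert_tones,
    median_f0,
    phi_intervals,
    read_wav,
    transform_voice,
    transform_voice_per_speaker,
    write_wav,
)
from avdeid.redact import PhiCategory, PhiSpan

from conftest import make_harmonic


def _span(i, j=None, cat=PhiCategory.NAME):
    return PhiSpan(word_start_index=i, word_end_index=j if j is not None else i,
                   category=cat, matched_text="x", rule_id="t")


class TestPhiIntervals:
    def test_single_word_span_maps_to_its_word_interval(self, greeting_doc):
        from avdeid.transcript import parse_diarized_transcript

        t = parse_diarized_transcript(greeting_doc)
        ivs = phi_intervals(t, [_span(4)])  # the 67358-68798 ms name word
        assert [(iv.start_ms, iv.end_ms) for iv in ivs] == [(67358, 68798)]
        assert ivs[0].category == "NAME"

    def test_empty_span_list(self, short_spec):
        t, _ = synthetic.gen_transcript(short_spec)
        assert phi_intervals(t, []) == []

    def test_unknown_word_index_raises(self, short_spec):
        t, _ = synthetic.gen_transcript(short_spec)
        with pytest.raises(KeyError):
            phi_intervals(t, [_span(10_000)])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sort_and_sweep_merge_oracle(self, seed):
        """Interval mapping equals an independent sort-and-sweep merge."""
        rng = np.random.default_rng(seed)
        spec = synthetic.FixtureSpec(seed=seed, duration_s=20.0, phi_plan=[])
        t, _ = synthetic.gen_transcript(spec)
        n = len(t.words())
        spans = []
        for _ in range(6):
            i = int(rng.integers(0, n - 2))
            spans.append(_span(i, min(n - 1, i + int(rng.integers(0, 3)))))
        merge_gap = int(rng.integers(0, 400))

        words = {w.index: w for w in t.words()}
        raw = sorted(
            (min(words[k].start_ms for k in s.indices()),
             max(words[k].end_ms for k in s.indices()))
            for s in spans
        )
        merged = []
        for s_ms, e_ms in raw:  # independent sweep
            if merged and s_ms - merged[-1][1] < merge_gap:
                merged[-1][1] = max(merged[-1][1], e_ms)
            else:
                merged.append([s_ms, e_ms])

        got = phi_intervals(t, spans, merge_gap)
        assert [(iv.start_ms, iv.end_ms) for iv in got] == \
            [tuple(m) for m in merged]
        # disjoint and sorted
        for a, b in zip(got, got[1:]):
            assert a.end_ms <= b.start_ms

    def test_two_close_spans_merge_across_small_gap(self):
        from avdeid.transcript import Segment, Transcript, Word

        words = [Word("a", 100, 200, 1.0, "A", 0), Word("b", 220, 300, 1.0, "A", 1)]
        t = Transcript([Segment(100, 300, "a b", "A", words)], "en", 400)
        got = phi_intervals(t, [_span(0), _span(1)], merge_gap_ms=50)
        assert [(iv.start_ms, iv.end_ms) for iv in got] == [(100, 300)]
        assert got[0].source_word_indices == (0, 1)


class TestInsertTones:
    def test_empty_interval_list_is_identity(self):
        a = make_harmonic(120, 0.5)
        out = insert_tones(a, [])
        assert np.array_equal(out.samples, a.samples)

    def test_direct_synthesis_inside_and_locality_outside(self):
        a = make_harmonic(120, 3.0)
        tone = ToneSpec(frequency_hz=440.0, amplitude=0.2, fade_ms=0)
        out = insert_tones(a, [PhiInterval(1000, 2000, "NAME")], tone)
        sr = a.sample_rate_hz
        n = np.arange(16000, 32000)
        expected = 0.2 * np.sin(2 * np.pi * 440.0 * n / sr)
        assert np.allclose(out.samples[16000:32000], expected, atol=0)
        assert np.array_equal(out.samples[:16000], a.samples[:16000])
        assert np.array_equal(out.samples[32000:], a.samples[32000:])
        assert len(out.samples) == len(a.samples)

    def test_full_buffer_interval_gives_pure_tone(self):
        a = make_harmonic(120, 1.0)
        tone = ToneSpec(fade_ms=0)
        out = insert_tones(a, [PhiInterval(0, 1000, "NAME")], tone)
        f0s, voiced = estimate_f0_track(out)
        assert voiced.all()
        assert np.allclose(f0s[voiced], 440.0, atol=2.0)

    def test_interval_exceeding_buffer_raises_with_interval(self):
        a = make_harmonic(120, 1.0)
        with pytest.raises(ValueError, match=r"\[500, 1500\)"):
            insert_tones(a, [PhiInterval(500, 1500, "NAME")])

    def test_fades_stay_within_tone_amplitude(self):
        a = make_harmonic(120, 1.0)
        tone = ToneSpec(amplitude=0.2, fade_ms=10)
        out = insert_tones(a, [PhiInterval(100, 900, "NAME")], tone)
        i0, i1 = 1600, 14400
        assert np.max(np.abs(out.samples[i0:i1])) <= 0.2 + 1e-12


class TestTransformVoice:
    def test_identity_parameters_reconstruct_input(self):
        a = make_harmonic(120)
        out = transform_voice(a, VoiceTransformParams(f0_ratio=1.0,
                                                      envelope_warp=1.0))
        rel = np.sqrt(np.mean((out.samples - a.samples) ** 2)) / \
            np.sqrt(np.mean(a.samples**2))
        assert rel <= 0.05

    def test_f0_scaling_within_five_percent(self):
        a = make_harmonic(120)
        out = transform_voice(a, VoiceTransformParams(f0_ratio=1.5,
                                                      envelope_warp=1.0))
        assert 171.0 <= median_f0(out) <= 189.0

    @pytest.mark.parametrize("ratio", [0.75, 1.3])
    def test_sample_count_always_preserved(self, ratio):
        a = make_harmonic(100, 1.3)
        out = transform_voice(a, VoiceTransformParams(f0_ratio=ratio,
                                                      envelope_warp=1.05))
        assert len(out.samples) == len(a.samples)

    def test_silent_input_returned_unchanged(self, caplog):
        a = AudioBuffer(np.zeros(16000), 16000)
        out = transform_voice(a, VoiceTransformParams(f0_ratio=1.3))
        assert np.array_equal(out.samples, a.samples)

    def test_randomized_mode_reproducible_and_off_unity(self):
        a = make_harmonic(120)
        p = VoiceTransformParams(seed=42)
        out1 = transform_voice(a, p)
        out2 = transform_voice(a, p)
        assert np.array_equal(out1.samples, out2.samples)
        ratio = median_f0(out1) / 120.0
        assert not (0.9 < ratio < 1.1)  # near-identity draws are excluded

    def test_inverse_ratio_does_not_restore_waveform(self):
        a = make_harmonic(120)
        fwd = transform_voice(a, VoiceTransformParams(f0_ratio=1.3,
                                                      envelope_warp=1.0))
        back = transform_voice(fwd, VoiceTransformParams(f0_ratio=1 / 1.3,
                                                         envelope_warp=1.0))
        rel = np.sqrt(np.mean((back.samples - a.samples) ** 2)) / \
            np.sqrt(np.mean(a.samples**2))
        assert rel > 0.1

    def test_per_speaker_draws_are_distinct_and_logged(self, short_spec):
        t, _ = synthetic.gen_transcript(short_spec)
        a = synthetic.gen_audio(short_spec, t)
        out, draws = transform_voice_per_speaker(
            a, t, VoiceTransformParams(seed=3)
        )
        assert set(draws) == {"SPEAKER_00", "SPEAKER_01"}
        assert len(out.samples) == len(a.samples)


class TestEstimateF0:
    def test_pure_sine_estimates_within_two_hz(self):
        sr = 16000
        t = np.arange(sr) / sr
        a = AudioBuffer(0.5 * np.sin(2 * np.pi * 200 * t), sr)
        f0s, voiced = estimate_f0_track(a)
        assert voiced.all()
        assert np.all(np.abs(f0s[voiced] - 200.0) <= 2.0)

    def test_silence_is_unvoiced(self):
        a = AudioBuffer(np.zeros(16000), 16000)
        _, voiced = estimate_f0_track(a)
        assert not voiced.any()

    def test_white_noise_voicing_fraction_low(self):
        rng = np.random.default_rng(7)
        a = AudioBuffer(0.3 * rng.standard_normal(16000), 16000)
        _, voiced = estimate_f0_track(a)
        assert voiced.mean() < 0.2


class TestWavIO:
    @pytest.mark.parametrize("subtype", ["float32", "pcm16"])
    def test_round_trip(self, tmp_path, subtype):
        a = make_harmonic(150, 0.25)
        p = tmp_path / "a.wav"
        write_wav(a, p, subtype=subtype)
        back = read_wav(p)
        assert back.sample_rate_hz == a.sample_rate_hz
        tol = 1e-4 if subtype == "pcm16" else 1e-7
        assert np.allclose(back.samples, a.samples, atol=tol)
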