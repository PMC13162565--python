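"""Synthetic fixtures: transcripts with planted PHI, voice-like audio,
stick-figure clips with known keypoint trajectories.

Every stage of the pipeline is testable against these generators without
any model weights or recordings: the generator returns the ground truth
(planted PHI spans, word intervals, true keypoint tracks) alongside the
media, so tests close the loop — run the pipeline, then check against
what was planted.

The fixtures emulate the statistical challenges of real clinical
recordings at desk scale: multi-speaker turn taking, detection dropout
runs (occlusion), jittered detections, steep trajectory segments (rapid
movement) and high-variance backgrounds. They do not model real speech,
faces, or clinical content; see the methods note for what that implies
about test coverage.

Defaults are fixed study conditions: 16 kHz mono audio, two speakers at
F0 120/180 Hz, 15 fps 160x120 video, detection jitter sigma = 0.5 px,
dropout runs of at most 5 frames. Everything is deterministic under
``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .audioscrub import AudioBuffer, write_wav
from .frames import write_frame_dir
from .redact import PhiCategory, PhiSpan, RedactionRuleSet
from .transcript import Segment, Transcript, Word, serialize_transcript
from .videodeid import COCO_LIMBS, write_detections_json

__all__ = [
    "FixtureSpec",
    "gen_transcript",
    "gen_audio",
    "gen_pose_clip",
    "ruleset_for_plan",
    "default_phi_plan",
    "write_fixture_set",
]

_VOCAB = (
    "so we are back again and today I want to talk about how you have been "
    "feeling since your last visit let us go over the plan together and see "
    "what has changed with your medication and your sleep"
).split()

# planted PHI surface forms by category (chosen to hit each rule layer)
_DEFAULT_SURFACES = {
    PhiCategory.NAME: "margaret",
    PhiCategory.LOCATION: "springfield",
    PhiCategory.DATE: "03/14/2021",
    PhiCategory.ID: "84321907",
    PhiCategory.CONTACT: "215-555-0142",
    PhiCategory.AGE: "67-year-old",
}


@dataclass
class FixtureSpec:
    """Study conditions for one fixture set. Same seed, same bytes."""

    seed: int = 0
    duration_s: float = 30.0
    fps: float = 15.0
    sample_rate_hz: int = 16000
    n_speakers: int = 2
    f0_per_speaker: tuple[float, ...] = (120.0, 180.0)
    frame_size: tuple[int, int] = (120, 160)  # (height, width)
    phi_plan: list[tuple[int, str, str]] | None = None  # (word pos, category, form)
    motion_plan: list[list[tuple[int, float, float]]] | None = None
    dropout_rate: float = 0.1
    dropout_max_gap: int = 5
    jitter_px: float = 0.5
    word_ms: int = 280
    gap_ms: int = 80
    words_per_turn: int = 5


def default_phi_plan(n_words: int) -> list[tuple[int, str, str]]:
    """One NAME, LOCATION and DATE at the 1/4, 1/2 and 3/4 word positions."""
    return [
        (max(1, n_words // 4), "NAME", _DEFAULT_SURFACES[PhiCategory.NAME]),
        (max(2, n_words // 2), "LOCATION",
         _DEFAULT_SURFACES[PhiCategory.LOCATION]),
        (max(3, 3 * n_words // 4), "DATE", _DEFAULT_SURFACES[PhiCategory.DATE]),
    ]


def gen_transcript(spec: FixtureSpec) -> tuple[Transcript, list[PhiSpan]]:
    """Deterministic transcript with planted PHI and its ground-truth spans.

    Words get contiguous non-overlapping timestamps (``word_ms`` speech +
    ``gap_ms`` pause each); speakers alternate every ``words_per_turn``
    words. Multi-token PHI surface forms occupy consecutive word slots.
    Raises on plans whose positions fall outside the transcript.
    """
    duration_ms = int(round(spec.duration_s * 1000))
    slot_ms = spec.word_ms + spec.gap_ms
    n_words = max(1, (duration_ms - spec.gap_ms) // slot_ms)
    plan = spec.phi_plan if spec.phi_plan is not None else default_phi_plan(n_words)

    texts = [_VOCAB[i % len(_VOCAB)] for i in range(n_words)]
    gt_spans: list[PhiSpan] = []
    used: set[int] = set()
    for pos, category, surface in sorted(plan):
        tokens = surface.split()
        if pos < 0 or pos + len(tokens) > n_words:
            raise ValueError(
                f"PHI plan entry at word {pos} ({surface!r}) does not fit in "
                f"{n_words} words"
            )
        slots = set(range(pos, pos + len(tokens)))
        if slots & used:
            raise ValueError(f"overlapping PHI plan entries at word {pos}")
        used |= slots
        for j, tok in enumerate(tokens):
            texts[pos + j] = tok
        gt_spans.append(
            PhiSpan(
                word_start_index=pos,
                word_end_index=pos + len(tokens) - 1,
                category=PhiCategory(category),
                matched_text=surface,
                rule_id="planted",
            )
        )

    rng = np.random.default_rng(spec.seed)
    segments: list[Segment] = []
    idx = 0
    t_ms = 0
    while idx < n_words:
        speaker = f"SPEAKER_{(len(segments) % spec.n_speakers):02d}"
        turn = min(spec.words_per_turn, n_words - idx)
        words = []
        for _ in range(turn):
            start = t_ms
            end = start + spec.word_ms
            words.append(
                Word(
                    text=texts[idx], start_ms=start, end_ms=end,
                    confidence=float(np.round(rng.uniform(0.85, 1.0), 3)),
                    speaker=speaker, index=idx,
                )
            )
            idx += 1
            t_ms = end + spec.gap_ms
        segments.append(
            Segment(
                start_ms=words[0].start_ms, end_ms=words[-1].end_ms,
                text=" ".join(w.text for w in words), speaker=speaker,
                words=words,
            )
        )
    t = Transcript(segments=segments, language="en",
                   source_audio_duration_ms=duration_ms)
    t.validate()
    return t, gt_spans


def ruleset_for_plan(
    plan: list[tuple[int, str, str]] | list[PhiSpan] | None = None,
) -> RedactionRuleSet:
    """A rule set whose lexicons/patterns recover exactly the planted forms.

    With ``plan=None`` the default surface forms are covered. Pattern
    rules cover DATE/ID/CONTACT/AGE in the generator's formats; NAME and
    LOCATION surfaces go to the lexicons.
    """
    names, locations = set(), set()
    if plan is None:
        names.add(_DEFAULT_SURFACES[PhiCategory.NAME])
        locations.add(_DEFAULT_SURFACES[PhiCategory.LOCATION])
    else:
        for entry in plan:
            if isinstance(entry, PhiSpan):
                category, surface = entry.category, entry.matched_text
            else:
                _, category, surface = entry
                category = PhiCategory(category)
            if category == PhiCategory.NAME:
                names.add(surface)
            elif category == PhiCategory.LOCATION:
                locations.add(surface)
    return RedactionRuleSet(
        name_lexicon=names,
        location_lexicon=locations,
        safe_lexicon=set(),
        patterns=_default_patterns(),
    )


def _default_patterns():
    from .redact import load_ruleset

    return load_ruleset(
        {
            "patterns": [
                {"regex": r"\d{1,2}/\d{1,2}/\d{2,4}", "category": "DATE",
                 "id": "date_slash"},
                {"regex": r"\d{3}-\d{3}-\d{4}", "category": "CONTACT",
                 "id": "phone_dashed"},
                {"regex": r"\d{1,3}-year-old", "category": "AGE",
                 "id": "age_hyphen"},
                {"regex": r"\d{7,10}", "category": "ID", "id": "record_number"},
            ]
        }
    ).patterns


def gen_audio(spec: FixtureSpec, t: Transcript) -> AudioBuffer:
    """Voice-like audio: a harmonic "vowel" at the speaker's F0 per word.

    Each word interval carries a 5-harmonic complex at that speaker's
    fundamental (5 ms edge fades); between words there is only a seeded
    noise floor. Harmonics of the default F0s stay clear of the default
    440 Hz scrub tone band, so tone-dominance checks are unambiguous.
    """
    rng = np.random.default_rng(spec.seed + 1)
    sr = spec.sample_rate_hz
    n = int(round(t.source_audio_duration_ms * sr / 1000.0))
    x = rng.normal(0.0, 5e-4, n)
    speakers = sorted({w.speaker for w in t.words()})
    f0_of = {
        spk: spec.f0_per_speaker[i % len(spec.f0_per_speaker)]
        for i, spk in enumerate(speakers)
    }
    harmonic_amps = 0.25 * 0.7 ** np.arange(5)
    for w in t.words():
        i0 = int(round(w.start_ms * sr / 1000.0))
        i1 = min(n, int(round(w.end_ms * sr / 1000.0)))
        if i1 <= i0:
            continue
        f0 = f0_of[w.speaker]
        tt = np.arange(i0, i1) / sr
        seg = np.zeros(i1 - i0)
        for k, amp in enumerate(harmonic_amps, start=1):
            seg += amp * np.sin(2.0 * np.pi * k * f0 * tt)
        n_fade = min(int(0.005 * sr), len(seg) // 2)
        if n_fade:
            ramp = np.linspace(0.0, 1.0, n_fade, endpoint=False)
            seg[:n_fade] *= ramp
            seg[-n_fade:] *= ramp[::-1]
        x[i0:i1] = seg
    return AudioBuffer(np.clip(x, -1.0, 1.0), sr)


# unit stick-figure: 17 COCO keypoint offsets (x right, y down), ~44 px tall
_SKELETON_OFFSETS = np.array(
    [
        (0.0, -20.0),           # nose
        (-2.5, -23.0), (2.5, -23.0),   # eyes
        (-5.0, -21.0), (5.0, -21.0),   # ears
        (-8.0, -12.0), (8.0, -12.0),   # shoulders
        (-11.0, -2.0), (11.0, -2.0),   # elbows
        (-12.0, 8.0), (12.0, 8.0),     # wrists
        (-5.0, 4.0), (5.0, 4.0),       # hips
        (-5.5, 14.0), (5.5, 14.0),     # knees
        (-6.0, 24.0), (6.0, 24.0),     # ankles
    ]
)


def _default_motion_plan(spec: FixtureSpec, n_frames: int):
    h, w = spec.frame_size
    return [[(0, 0.3 * w, 0.55 * h), (n_frames - 1, 0.7 * w, 0.5 * h)]]


def _center_at(plan: list[tuple[int, float, float]], f: int) -> np.ndarray:
    frames = [p[0] for p in plan]
    xs = [p[1] for p in plan]
    ys = [p[2] for p in plan]
    return np.array([np.interp(f, frames, xs), np.interp(f, frames, ys)])


# cell size kept below typical variance-probe windows so a windowed-variance
# check is informative at every pixel (no uniform patch larger than a window)
def _checkerboard(h: int, w: int, cell: int = 4) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    board = ((yy // cell + xx // cell) % 2).astype(np.uint8)
    frame = np.empty((h, w, 3), dtype=np.uint8)
    frame[:] = (board * 160 + 40)[..., None]
    return frame


def gen_pose_clip(
    spec: FixtureSpec, n_frames: int | None = None
) -> tuple[list[np.ndarray], dict[int, list[np.ndarray]], list[np.ndarray]]:
    """Stick-figure clip with jittered, dropout-afflicted detections.

    Returns ``(frames, detections, ground_truth)``: rendered uint8 RGB
    frames on a checkerboard background, per-frame detection lists
    (ground truth + seeded Gaussian jitter, with seeded dropout runs of at
    most ``dropout_max_gap`` frames), and the exact per-person keypoint
    arrays of shape (n_frames, 17, 3).
    """
    from skimage.draw import disk, line

    rng = np.random.default_rng(spec.seed + 2)
    if n_frames is None:
        n_frames = int(round(spec.duration_s * spec.fps))
    h, w = spec.frame_size
    plans = spec.motion_plan or _default_motion_plan(spec, n_frames)

    ground_truth = []
    for plan in plans:
        kps = np.empty((n_frames, 17, 3))
        for f in range(n_frames):
            center = _center_at(plan, f)
            kps[f, :, :2] = center + _SKELETON_OFFSETS
            kps[f, :, 2] = 1.0
        ground_truth.append(kps)

    frames = []
    for f in range(n_frames):
        frame = _checkerboard(h, w)
        for kps in ground_truth:
            pts = kps[f]
            for a, b in COCO_LIMBS:
                rr, cc = line(
                    int(round(pts[a, 1])), int(round(pts[a, 0])),
                    int(round(pts[b, 1])), int(round(pts[b, 0])),
                )
                keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
                frame[rr[keep], cc[keep]] = (30, 60, 200)
            for i in range(17):
                rr, cc = disk(
                    (int(round(pts[i, 1])), int(round(pts[i, 0]))), 2,
                    shape=(h, w),
                )
                frame[rr, cc] = (200, 50, 30)
        frames.append(frame)

    detections: dict[int, list[np.ndarray]] = {f: [] for f in range(n_frames)}
    for kps in ground_truth:
        dropped = np.zeros(n_frames, dtype=bool)
        f = 1  # frame 0 always observed so every track starts at clip start
        while f < n_frames:
            if rng.random() < spec.dropout_rate:
                run = int(rng.integers(1, spec.dropout_max_gap + 1))
                dropped[f : min(n_frames, f + run)] = True
                f += run + 1
            else:
                f += 1
        for f in range(n_frames):
            if dropped[f]:
                continue
            det = kps[f].copy()
            det[:, :2] += rng.normal(0.0, spec.jitter_px, (17, 2))
            det[:, 2] = rng.uniform(0.6, 1.0, 17)
            detections[f].append(det)
    return frames, detections, ground_truth


def write_fixture_set(spec: FixtureSpec, directory: str | Path) -> dict[str, Path]:
    """Write a complete fixture set in the formats the pipeline consumes.

    Produces transcript JSON, WAV audio, a PNG frame sequence, detections
    JSON, and a ground-truth JSON (planted spans + true tracks).
    """
    import json

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    t, gt_spans = gen_transcript(spec)
    audio = gen_audio(spec, t)
    frames, detections, gt_tracks = gen_pose_clip(spec)

    paths = {
        "transcript": directory / "transcript.json",
        "audio": directory / "audio.wav",
        "detections": directory / "detections.json",
        "frames": directory / "frames",
        "ground_truth": directory / "ground_truth.json",
    }
    paths["transcript"].write_text(serialize_transcript(t), encoding="utf-8")
    write_wav(audio, paths["audio"])
    write_detections_json(detections, paths["detections"])
    write_frame_dir(frames, paths["frames"])
    paths["ground_truth"].write_text(
        json.dumps(
            {
                "phi_spans": [
                    {"word_start_index": s.word_start_index,
                     "word_end_index": s.word_end_index,
                     "category": s.category.value,
                     "matched_text": s.matched_text}
                    for s in gt_spans
                ],
                "tracks": [kps.tolist() for kps in gt_tracks],
            },
            sort_keys=True,
        ),
        encoding="utf-8",
    )
    return paths
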