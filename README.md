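# avdeid — audio-video de-identification for clinical recordings

Clinical encounter recordings carry protected health information (PHI) in
every channel at once: names, dates and record numbers in the speech,
speaker identity in the voice itself, and faces and environmental detail in
the frames. `avdeid` is a six-stage pipeline for removing all of it while
keeping the recording useful for research:

1. **Transcript import** — parse a diarized, word-level-timestamped
   transcript (WhisperX-style JSON) and flatten it to one row per word.
2. **Text redaction** — a rule engine (lexicons + ordered regex patterns,
   with a safe-word exclusion list taking precedence) detects PHI word
   spans and replaces them with placeholders such as `[NAME]`, leaving
   every timestamp untouched.
3. **Audio scrubbing** — redacted spans map to millisecond intervals
   (near-adjacent ones merged); each interval is replaced by a tone rather
   than silence, because silence itself can carry clinical meaning. The
   remaining voice is disguised per speaker by scaling the fundamental
   frequency F0 and warping the spectral envelope through a pluggable
   vocoder backend — never changing the sample count.
4. **Video de-identification** — per-frame pose detections (17 COCO
   keypoints per person: 5 facial landmarks + 12 body joints, provided by
   an upstream detector) are associated into tracks, occlusion gaps are
   filled by linear interpolation, and trajectories are smoothed with a
   constant-velocity Kalman filter. Two privacy modes:
   **PPP** (precision) Gaussian-blurs only a margin-expanded box around the
   facial keypoints; **GPP** (greedy) blurs the whole frame and overlays
   the skeleton.
5. **AV resynchronization** — the net offset between streams is computed
   from stage-logged processing delays and applied before multiplexing,
   preserving the source frame rate and sample rate.
6. **QC support** — mode-specific reviewer checklists plus machine checks:
   tone-dominance scans of PHI intervals, blur-coverage and locality
   metrics, voice-transform divergence, and a pluggable residual-face scan.

Every stage execution appends a record (parameter hash, input/output
content hashes) to an artifact ledger, so a run is auditable and
reproducible bit-for-bit under a fixed seed. Heavy upstream models — ASR,
diarization, pose detection — are inputs behind documented schemas, never
dependencies, and a synthetic fixture generator (transcripts with planted
PHI, harmonic voice-like audio, stick-figure clips with known keypoints)
makes the whole pipeline testable offline.

Intended users: clinical informatics and health-services research groups
who need to share encounter recordings under HIPAA Safe Harbor-style
constraints, and engineers extending individual stages.

## The core guarantees

The pipeline is built around testable invariants rather than model
accuracy (which belongs to the upstream detectors):

- **Duration conservation** — every audio operation preserves the sample
  count exactly; the voice transform changes pitch, never speed.
- **Locality** — tone insertion is bit-exact outside its intervals; PPP
  changes no pixel outside a face box.
- **Coverage** — with detection gaps up to the interpolation limit, every
  ground-truth facial landmark stays inside the blurred box (interpolation
  + margin guarantee).
- **Tone dominance** — after scrubbing, each PHI interval's spectrum is
  dominated by the configured tone, which the QC scan verifies.
- **Sync** — the muxed container preserves fps and sample rate, with
  stream durations agreeing within one frame period.

## Worked example

```bash
python examples/02_audio_scrubbing.py
```

```
PHI intervals (ms): [(2880, 3160), (5760, 6040), (8640, 8920)]
SPEAKER_00: F0  120.1 Hz ->  170.8 Hz (drawn ratio 1.422, envelope warp 1.052)
SPEAKER_01: F0  180.0 Hz ->  133.7 Hz (drawn ratio 0.742, envelope warp 1.072)
```

The three intervals are the planted name, location and date, mapped from
word timestamps; each now contains a 440 Hz tone. Each speaker's measured
median F0 moved by the drawn ratio (120.1 x 1.422 ≈ 170.8), i.e. the
disguise applied is exactly the one logged for the audit trail. The other
examples cover transcript redaction, both video modes, and the full
pipeline with ledger verification:

```bash
python examples/04_full_pipeline.py
```

```
container: deid.avi
QC status: pass (0 findings)
ledger stages: inputs -> transcript_import -> redact -> audioscrub -> videodeid -> avsync -> qc
ledger intact: True
```

A thin CLI wraps the same library calls
(`avdeid run-all … `, `avdeid fixtures …`, `avdeid verify …`; see
`avdeid --help`).

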