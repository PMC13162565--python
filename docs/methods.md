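# Methods

This note documents the models, parameter choices and numerical decisions
behind `avdeid`, and what the synthetic-fixture tests do and do not
establish about real recordings.

## Data model and timing

All timing is integer milliseconds with half-open intervals
`[start_ms, end_ms)`. Transcript JSON carries seconds (the common ASR
convention); parsing rounds half-up to ms. The global word order is
document order: conversational audio contains overlapping speech across
speakers, so no global sort by start time is imposed — only strictly
increasing word indices and per-word `start <= end`. Segment bounds are
expanded (with a logged warning) when they fail to cover their words, a
tolerance for ASR outputs that violate the containment by a few ms;
rejecting such files outright would make the importer useless in practice.
Missing per-word confidences default to 1.0 with a warning; confidences
are carried through but gate nothing downstream.

## Text redaction

The rule engine operates on whole word rows, never sub-word character
ranges. This sacrifices a little precision (a token containing PHI is
redacted wholly) in exchange for a crucial property: the map from redacted
text to audio time is the identity on word indices, so audio scrubbing
needs no realignment. Matching normalizes tokens by Unicode case-folding
and stripping edge punctuation. Three rule layers with fixed precedence —
safe lexicon (never redact) > ordered regex patterns > name/location
lexicons — and overlap resolution by longest match first, ties broken by
rule order, then position. The resolution is deterministic and equivalent,
on bounded inputs, to an exhaustive n-gram scan (tested against one). The
six PHI categories (NAME, DATE, LOCATION, ID, CONTACT, AGE) are an
extensible enum, not a claim of Safe-Harbor completeness; institutional
deployments are expected to supply their own lexicons. The placeholder
rendering is a template (default `[{CATEGORY}]`).

## Audio scrubbing

**Interval mapping.** Each redacted span becomes
`[min word start, max word end)`; intervals closer than `merge_gap_ms`
(default 50 ms) are merged so no audible sliver of speech survives between
adjacent PHI words. No extra padding is added beyond the merge: word
timestamps are treated as precise.

**Tones.** Default 440 Hz at amplitude 0.2 with 10 ms linear fades —
audible without clipping or startling; parameters are config keys. A tone
is used instead of silence because pauses carry interactional meaning.
Insertion is bit-local: samples outside the intervals are untouched, and
inside, the signal is exactly `A sin(2*pi*f*n/sr)` shaped by the fades
(absolute sample index `n`, so the tone phase is reproducible).

**Voice transform.** The disguise scales F0 by `f0_ratio` and the spectral
envelope's frequency axis by `envelope_warp`, preserving the sample count
exactly. The reference backend is a phase vocoder: STFT (Hann, 1024
window, 256 hop) time-stretch by `f0_ratio` with per-bin phase
propagation, then resampling back to the original sample count, which
scales all frequencies by exactly `f0_ratio`; the envelope warp is applied
as a per-frame gain from a cepstrally smoothed (30-coefficient) envelope
interpolated along the warped frequency axis, with the gain clipped to
[0.05, 20]. Backends with an explicit source-filter decomposition (e.g.
WORLD) plug in behind the same interface and would decouple pitch and
formants more cleanly; the phase vocoder transposes both together, which
is acceptable for a disguise and keeps the reference implementation
dependency-free. Randomized mode draws `f0_ratio` log-uniformly from
[0.7, 0.85] ∪ [1.2, 1.45] — near-unity values are excluded so a draw never
approximates the identity — and `envelope_warp` from [0.9, 1.1] (a
deliberately conservative timbre range; larger warps degrade
intelligibility quickly). One draw is made per speaker label, giving each
speaker a consistent disguise within a file; a `per_file` switch collapses
this to a single draw. In the orchestrated pipeline the whole track is
transformed once per speaker and the speaker's word intervals are spliced
from their copy, then tones are re-inserted so PHI intervals remain pure
tone after the vocoder pass. Silent input is returned unchanged with a
warning — there is no F0 to shift, and failing would turn a degenerate
input into an outage. Reversal resistance is tested only as a weak proxy:
applying the inverse ratio leaves a relative RMS error above 0.1. This
does not constitute a speaker re-identification evaluation.

**F0 estimation** (test oracle and QC): frame-wise normalized
autocorrelation (40 ms frames, 10 ms hop, search range 60–500 Hz), voicing
where the peak exceeds 0.5 and energy is above a floor, with parabolic
interpolation of the peak lag. On pure tones this resolves F0 to well
under 1 Hz.

## Video de-identification

Detections arrive as persons × 17 COCO keypoints (x, y, confidence) per
frame; pose estimation itself is upstream. Pixel coordinates have origin
top-left; boxes are half-open in pixel index space; frame indices are
0-based.

**Track association** is greedy nearest-centroid with a distance gate
(default 50 px) over keypoints above the confidence threshold (default
0.3); a gated-out detection starts a new track. Optimal bipartite
(Hungarian) assignment is a config option. Greedy was chosen as the
simplest deterministic scheme; both are exercised in tests.

**Gap filling** precedes smoothing. Interior gaps up to `max_gap_frames`
(default 30, ≈1 s at 30 fps) are filled by per-coordinate linear
interpolation between the flanking observations; leading/trailing gaps are
filled by holding the nearest observation. Longer gaps are left unfilled
and escalated to QC rather than guessed.

**Kalman smoothing** runs a constant-velocity filter independently per
coordinate series (34 per person). State [position, velocity],
`F = [[1,1],[0,1]]`, `H = [1,0]`, `Q = q·[[1/4,1/2],[1/2,1]]` (default
q = 1 px²), `R` default 4 px²; initialization `x0 = [z0, 0]`,
`P0 = diag(R, 1000)`, so the first filtered value equals the first
observation and the velocity estimate converges within a few frames. The
defaults favour responsiveness over smoothness because the face box must
not lag a moving face; the PPP margin absorbs the residual transient.

**Face box (PPP).** The axis-aligned hull of facial keypoints above the
confidence threshold, expanded on every side by `bbox_margin_frac`
(default 0.25) of the hull diagonal, clipped to the frame. A degenerate
(single-point) hull gets a floor-sized box (default 16 px). No confident
facial keypoint → no box, and the frame is flagged to QC instead of being
silently passed. Blur sigma defaults to box-diagonal/6 (scales with
apparent face size); the blurred content equals a full-frame Gaussian blur
restricted to the box, computed on a crop padded by 4σ so truncation makes
the two identical — pixels outside boxes are bit-identical to the input.

**GPP** blurs the whole frame (sigma default frame-diagonal/100) and draws
the skeleton: discs (radius 3) at confident keypoints and 1 px segments
along the standard COCO limb pairs, in a configurable color. The rendering
style is not standardized anywhere; the COCO convention plus a flat color
was chosen for legibility and is fully configurable.

## AV resynchronization

Offsets come from the stage-logged intrinsic delays
(`offset = audio_delay − video_delay`), not from signal cross-correlation:
the delays are introduced by known processing and are therefore known.
A positive offset trims the audio head; a negative one pads it with
silence; durations are then equalized to the video (pad with silence by
default, or trim). The reference container profile is a pure-Python
lossless RIFF/AVI writer (uncompressed RGB + 16-bit PCM) with a matching
header prober, so mux post-conditions — fps preserved (stored as the
rational rate/scale with scale 1000), sample rate preserved, stream
durations within one frame period — are bit-stable and verifiable without
external tools. An FFmpeg-backed muxer implements the same narrow
interface for production MP4/H.264+AAC output and raises a remediation
error when the binary is absent.

## QC

Machine checks are pure readers and proxy the reviewer checklist items
that can be measured. The tone scan computes, per PHI interval, the
fraction of spectral energy within ±25 Hz of the tone frequency and flags
intervals below 0.6 — "adequately scrubbed" has no operational definition,
so the threshold is a config key and reports label the metric as a proxy.
Blur coverage is `1 − var(deid)/var(original)` on grayscale intensities
inside each region (0 when the original region is flat), plus an exact
count of pixels changed outside all regions. The voice check compares
original and transformed audio outside PHI intervals and fails below a
relative RMS difference of 0.1 (catches identity transforms). The residual
face scan is plumbing around a pluggable detector — detector choice for
adversarial screening is an open problem, so the harness ships with stubs,
not a model. A report passes iff it contains no fail-severity finding;
the human re-review loop is represented only as report states.

## Artifact ledger

Content hashing uses SHA-256; a directory artifact hashes the sorted
(relative-path, file-digest) pairs. Each stage appends one record with a
parameter-snapshot hash and input/output digests; verification recomputes
digests of surviving artifacts and checks that every stage input matches a
prior output or a declared external. Ledger timestamps are excluded from
all hashes, so reruns with fixed seed and inputs reproduce every output
hash (WAV/PNG/AVI writers are all deterministic). Missing intermediates
are treated as pruned, not tampered; only content mismatches and chain
breaks fail verification.

## Synthetic fixtures and what tests show

The generator plants PHI at known word positions in a two-speaker
turn-taking transcript (280 ms words, 80 ms gaps), synthesizes a
5-harmonic "vowel" at each speaker's F0 (defaults 120/180 Hz, chosen so no
harmonic falls inside the 440 ± 25 Hz tone band used by the QC scan), and
renders stick figures on a checkerboard background (4 px cells — smaller
than the 9 px windowed-variance probe, so the probe is informative at
every pixel) with seeded detection jitter (σ = 0.5 px) and dropout runs of
at most 5 frames. Clips default to 15 fps at 160×120 and the end-to-end
checks use 30 s fixtures; these sizes keep the full suite fast while
leaving every invariant's problem structure intact.

Passing fixtures establishes the pipeline's mechanical guarantees —
interval arithmetic, locality, duration conservation, coverage under
bounded dropout, reproducibility — under known ground truth. It does not
establish detection quality on real data: real ASR mis-transcribes PHI,
real lexicons leak, real pose detectors miss occluded people, and none of
those upstream error modes are modelled here. That boundary is deliberate:
upstream models are pluggable inputs, and their error rates are their own
property, measured elsewhere.

## Known limitations

- The rule engine ships with example-scale lexicons; it is a harness for
  institutional rule sets, not a complete Safe-Harbor system.
- The phase-vocoder disguise transposes formants together with pitch and
  can sound robotic at large ratios; emotional cues are not preserved.
- On-screen text (names on monitors, ID badges), tattoos and other
  non-facial identifiers are out of scope for the video stage.
- The residual-face scan is only as good as the detector plugged into it.
- QC automation supports, but does not replace, human review.
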