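"""Audio de-identification: PHI interval mapping, tone insertion, voice transform.

Three steps, each conserving the sample count exactly:

1. :func:`phi_intervals` maps redacted word spans to millisecond audio
   intervals (merging near-adjacent ones so no audible speech sliver
   survives between consecutive PHI words).
2. :func:`insert_tones` replaces each interval with a sinusoidal tone — a
   tone rather than silence, because silence itself can carry meaning in a
   clinical conversation.
3. :func:`transform_voice` disguises the remaining speech by scaling the
   fundamental frequency and warping the spectral envelope through a
   pluggable vocoder backend (see :mod:`avdeid.vocoder`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .redact import PhiSpan
from .transcript import Transcript
from .vocoder import PhaseVocoderBackend, VocoderBackend

logger = logging.getLogger(__name__)

__all__ = [
    "AudioBuffer",
    "ToneSpec",
    "VoiceTransformParams",
    "PhiInterval",
    "phi_intervals",
    "insert_tones",
    "transform_voice",
    "transform_voice_per_speaker",
    "estimate_f0_track",
    "read_wav",
    "write_wav",
]


@dataclass
class AudioBuffer:
    """Mono samples in [-1, 1] plus the sample rate."""

    samples: np.ndarray
    sample_rate_hz: int

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("AudioBuffer is mono: samples must be 1-D")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def duration_ms(self) -> int:
        return int(round(1000.0 * len(self.samples) / self.sample_rate_hz))

    def ms_to_sample(self, ms: int) -> int:
        return int(round(ms * self.sample_rate_hz / 1000.0))

    def copy(self) -> "AudioBuffer":
        return AudioBuffer(self.samples.copy(), self.sample_rate_hz)


@dataclass(frozen=True)
class ToneSpec:
    """Replacement tone: audible, non-startling, clearly non-speech."""

    frequency_hz: float = 440.0
    amplitude: float = 0.2
    fade_ms: int = 10

    def validate(self, sample_rate_hz: int) -> None:
        if not (0.0 < self.amplitude <= 1.0):
            raise ValueError("tone amplitude must be in (0, 1]")
        if self.frequency_hz >= sample_rate_hz / 2:
            raise ValueError(
                f"tone frequency {self.frequency_hz} Hz at or above Nyquist "
                f"({sample_rate_hz / 2} Hz)"
            )


@dataclass
class VoiceTransformParams:
    """Pitch/timbre transform settings.

    ``f0_ratio``/``envelope_warp`` of ``None`` select randomized mode:
    ratios are drawn per call (seeded) log-uniformly from ``ratio_ranges``,
    which exclude near-unity values so the drawn transform always departs
    from the original voice.
    """

    f0_ratio: float | None = None
    envelope_warp: float | None = None
    seed: int = 0
    ratio_ranges: tuple[tuple[float, float], ...] = ((0.7, 0.85), (1.2, 1.45))
    envelope_warp_range: tuple[float, float] = (0.9, 1.1)

    def draw(self, rng: np.random.Generator) -> tuple[float, float]:
        """One seeded draw of (f0_ratio, envelope_warp)."""
        if self.f0_ratio is not None and self.envelope_warp is not None:
            return self.f0_ratio, self.envelope_warp
        lo, hi = zip(*self.ratio_ranges)
        widths = np.log(np.asarray(hi)) - np.log(np.asarray(lo))
        band = rng.choice(len(self.ratio_ranges), p=widths / widths.sum())
        f0 = self.f0_ratio
        if f0 is None:
            f0 = float(np.exp(rng.uniform(np.log(lo[band]), np.log(hi[band]))))
        warp = self.envelope_warp
        if warp is None:
            wlo, whi = self.envelope_warp_range
            warp = float(np.exp(rng.uniform(np.log(wlo), np.log(whi))))
        return f0, warp


@dataclass(frozen=True)
class PhiInterval:
    """A half-open [start_ms, end_ms) audio interval to scrub."""

    start_ms: int
    end_ms: int
    category: str
    source_word_indices: tuple[int, ...] = ()

    def __post_init__(self):
        if self.end_ms <= self.start_ms:
            raise ValueError(
                f"interval [{self.start_ms}, {self.end_ms}) is empty or reversed"
            )


def phi_intervals(
    t: Transcript, spans: list[PhiSpan], merge_gap_ms: int = 50
) -> list[PhiInterval]:
    """Map word-index spans to sorted, disjoint millisecond intervals.

    Each span becomes ``[min start_ms, max end_ms)`` over its words;
    intervals separated by less than ``merge_gap_ms`` (or overlapping) are
    merged, keeping the earliest interval's category and the union of
    source word indices.
    """
    words = {w.index: w for w in t.words()}
    raw = []
    for span in spans:
        try:
            ws = [words[i] for i in span.indices()]
        except KeyError as exc:
            raise KeyError(
                f"span references unknown word index {exc.args[0]}"
            ) from exc
        raw.append(
            (
                min(w.start_ms for w in ws),
                max(w.end_ms for w in ws),
                span.category.value,
                tuple(span.indices()),
            )
        )
    raw.sort(key=lambda r: (r[0], r[1]))
    merged: list[list] = []
    for start, end, cat, idxs in raw:
        if merged and start - merged[-1][1] < merge_gap_ms:
            merged[-1][1] = max(merged[-1][1], end)
            merged[-1][3] = merged[-1][3] + idxs
        else:
            merged.append([start, end, cat, idxs])
    return [
        PhiInterval(start_ms=s, end_ms=e, category=c,
                    source_word_indices=tuple(sorted(set(i))))
        for s, e, c, i in merged
    ]


def insert_tones(
    a: AudioBuffer, intervals: list[PhiInterval], tone: ToneSpec = ToneSpec()
) -> AudioBuffer:
    """Replace each interval with a tone; everything else is bit-identical.

    Inside an interval the signal becomes
    ``amplitude * sin(2*pi*f*n/sr)`` (``n`` the absolute sample index),
    shaped by linear fade ramps of ``fade_ms`` at both edges. The original
    signal does not leak through the fades — only the tone's own amplitude
    ramps.
    """
    tone.validate(a.sample_rate_hz)
    out = a.copy()
    n_total = len(out.samples)
    for iv in intervals:
        i0, i1 = a.ms_to_sample(iv.start_ms), a.ms_to_sample(iv.end_ms)
        if i0 < 0 or i1 > n_total:
            raise ValueError(
                f"interval [{iv.start_ms}, {iv.end_ms}) ms exceeds buffer "
                f"duration {a.duration_ms} ms"
            )
        n = np.arange(i0, i1)
        seg = tone.amplitude * np.sin(
            2.0 * np.pi * tone.frequency_hz * n / a.sample_rate_hz
        )
        n_fade = min(a.ms_to_sample(tone.fade_ms), len(seg) // 2)
        if n_fade > 0:
            ramp = np.linspace(0.0, 1.0, n_fade, endpoint=False)
            seg[:n_fade] *= ramp
            seg[-n_fade:] *= ramp[::-1]
        out.samples[i0:i1] = seg
    return out


def transform_voice(
    a: AudioBuffer,
    p: VoiceTransformParams,
    backend: VocoderBackend | None = None,
) -> AudioBuffer:
    """Disguise the speaker; duration (sample count) is preserved exactly.

    Silent input is returned unchanged with a warning — there is no F0 to
    shift. Randomized parameters are reproducible under ``p.seed``.
    """
    if backend is None:
        backend = PhaseVocoderBackend()
    if not np.any(a.samples):
        logger.warning("transform_voice: silent input returned unchanged")
        return a.copy()
    rng = np.random.default_rng(p.seed)
    f0_ratio, warp = p.draw(rng)
    y = backend.transform(a.samples, a.sample_rate_hz, f0_ratio, warp)
    assert len(y) == len(a.samples), "vocoder backend changed sample count"
    return AudioBuffer(np.clip(y, -1.0, 1.0), a.sample_rate_hz)


def transform_voice_per_speaker(
    a: AudioBuffer,
    t: Transcript,
    p: VoiceTransformParams,
    backend: VocoderBackend | None = None,
    per_file: bool = False,
) -> tuple[AudioBuffer, dict[str, tuple[float, float]]]:
    """One parameter draw per speaker label (consistent disguise per speaker).

    The whole buffer is transformed once per distinct speaker and each
    speaker's word intervals are spliced from their transformed copy;
    regions outside any word interval take the first speaker's transform.
    With ``per_file=True`` a single draw covers the whole track. Returns
    the transformed buffer and the per-speaker (f0_ratio, envelope_warp)
    draws for the audit trail.
    """
    if backend is None:
        backend = PhaseVocoderBackend()
    if not np.any(a.samples):
        logger.warning("transform_voice_per_speaker: silent input unchanged")
        return a.copy(), {}
    speakers = sorted({w.speaker for w in t.words()}) or [""]
    if per_file:
        speakers = speakers[:1]
    rng = np.random.default_rng(p.seed)
    draws = {spk: p.draw(rng) for spk in speakers}
    transformed = {
        spk: backend.transform(a.samples, a.sample_rate_hz, f0, warp)
        for spk, (f0, warp) in draws.items()
    }
    base_spk = speakers[0]
    out = np.array(transformed[base_spk], dtype=float, copy=True)
    if not per_file:
        for w in t.words():
            spk = w.speaker if w.speaker in transformed else base_spk
            i0, i1 = a.ms_to_sample(w.start_ms), a.ms_to_sample(w.end_ms)
            i1 = min(i1, len(out))
            out[i0:i1] = transformed[spk][i0:i1]
    return AudioBuffer(np.clip(out, -1.0, 1.0), a.sample_rate_hz), draws


def estimate_f0_track(
    a: AudioBuffer,
    frame_ms: int = 40,
    hop_ms: int = 10,
    fmin_hz: float = 60.0,
    fmax_hz: float = 500.0,
    voicing_threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Autocorrelation F0 track: per-hop estimates plus voicing flags.

    A frame is voiced when its normalized autocorrelation peak in the
    [fmin, fmax] lag range exceeds ``voicing_threshold`` and its energy is
    above a floor. Peak lag is refined by parabolic interpolation, so pure
    tones resolve well below one sample of lag error. Unvoiced frames
    report F0 = 0.
    """
    sr = a.sample_rate_hz
    frame = max(16, a.ms_to_sample(frame_ms))
    hop = max(1, a.ms_to_sample(hop_ms))
    lag_min = max(2, int(sr / fmax_hz))
    lag_max = min(frame - 2, int(np.ceil(sr / fmin_hz)))
    x = a.samples
    n_frames = max(0, 1 + (len(x) - frame) // hop)
    f0 = np.zeros(n_frames)
    voiced = np.zeros(n_frames, dtype=bool)
    energy_floor = 1e-6
    for k in range(n_frames):
        seg = x[k * hop : k * hop + frame]
        seg = seg - seg.mean()
        e0 = float(np.dot(seg, seg))
        if e0 / frame < energy_floor:
            continue
        ac = np.correlate(seg, seg, mode="full")[frame - 1 :]
        ac = ac / ac[0]
        if lag_max <= lag_min:
            continue
        window = ac[lag_min : lag_max + 1]
        peak = int(np.argmax(window)) + lag_min
        if ac[peak] < voicing_threshold:
            continue
        lag = float(peak)
        if 0 < peak < len(ac) - 1:
            y0, y1, y2 = ac[peak - 1], ac[peak], ac[peak + 1]
            denom = y0 - 2 * y1 + y2
            if abs(denom) > 1e-12:
                lag += 0.5 * (y0 - y2) / denom
        voiced[k] = True
        f0[k] = sr / lag
    return f0, voiced


def median_f0(
    a: AudioBuffer, intervals_ms: list[tuple[int, int]] | None = None, **kwargs
) -> float:
    """Median voiced F0, optionally restricted to the given ms intervals."""
    if intervals_ms:
        segs = [
            a.samples[a.ms_to_sample(s) : a.ms_to_sample(e)]
            for s, e in intervals_ms
        ]
        a = AudioBuffer(np.concatenate(segs), a.sample_rate_hz)
    f0, voiced = estimate_f0_track(a, **kwargs)
    if not voiced.any():
        return 0.0
    return float(np.median(f0[voiced]))


def read_wav(path: str | Path) -> AudioBuffer:
    """Read a mono WAV (PCM 16-bit or float32) into [-1, 1] floats."""
    sr, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError("only mono WAV files are supported")
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(float)
    else:
        raise ValueError(f"unsupported WAV sample format {data.dtype}")
    return AudioBuffer(samples, int(sr))


def write_wav(a: AudioBuffer, path: str | Path, subtype: str = "float32") -> None:
    """Write mono WAV; ``subtype`` is 'float32' or 'pcm16'."""
    if subtype == "float32":
        wavfile.write(str(path), a.sample_rate_hz, a.samples.astype(np.float32))
    elif subtype == "pcm16":
        q = np.clip(np.round(a.samples * 32767.0), -32768, 32767).astype(np.int16)
        wavfile.write(str(path), a.sample_rate_hz, q)
    else:
        raise ValueError(f"unknown WAV subtype {subtype!r}")
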