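"""Diarized transcript parsing, validation, flattening and serialization.

The transcript is the spine of the whole pipeline: every downstream
operation (text redaction, audio scrubbing) is addressed through word-level
timestamps, so the data model keeps one millisecond-resolution interval per
recognized word together with its speaker label and ASR confidence.

The on-disk format is a WhisperX-compatible JSON document::

    {"language": "en", "duration_ms": 60000,
     "segments": [{"start": 50.122, "end": 51.163, "text": "...",
                   "speaker": "SPEAKER_00",
                   "words": [{"word": "So", "start": 50.122,
                              "end": 50.301, "score": 0.98}, ...]}]}

Times in the JSON are seconds; internally everything is integer
milliseconds (rounded half-up at parse time). Word intervals are half-open
``[start_ms, end_ms)``.
"""

from __future__ import annotations

import io
import json
import logging
import math
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Word",
    "Segment",
    "Transcript",
    "TranscriptValidationError",
    "parse_diarized_transcript",
    "serialize_transcript",
    "flatten_transcript",
    "unflatten_rows",
    "write_flat_csv",
    "read_flat_csv",
]

FLAT_COLUMNS = ["index", "speaker", "start_ms", "end_ms", "text", "confidence"]


class TranscriptValidationError(ValueError):
    """A transcript document violated a structural invariant."""


def _ms(seconds: float) -> int:
    """Seconds -> integer milliseconds, rounded half-up."""
    return int(math.floor(seconds * 1000.0 + 0.5))


@dataclass(frozen=True)
class Word:
    """One recognized word with its half-open time interval in ms."""

    text: str
    start_ms: int
    end_ms: int
    confidence: float = 1.0
    speaker: str = ""
    index: int = 0

    def validate(self) -> None:
        if self.start_ms < 0 or self.end_ms < 0:
            raise TranscriptValidationError(
                f"word {self.index} ({self.text!r}): negative timestamp "
                f"[{self.start_ms}, {self.end_ms})"
            )
        if self.end_ms < self.start_ms:
            raise TranscriptValidationError(
                f"word {self.index} ({self.text!r}): end {self.end_ms} ms "
                f"precedes start {self.start_ms} ms"
            )
        if not (0.0 <= self.confidence <= 1.0):
            raise TranscriptValidationError(
                f"word {self.index} ({self.text!r}): confidence "
                f"{self.confidence} outside [0, 1]"
            )


@dataclass
class Segment:
    """A diarized utterance: one speaker turn holding its words in order."""

    start_ms: int
    end_ms: int
    text: str
    speaker: str
    words: list[Word] = field(default_factory=list)


@dataclass
class Transcript:
    """Ordered segments plus global metadata.

    The global word order is document order; ``words()`` enumerates it.
    Segments of different speakers may overlap in time (overlapping speech
    is expected in conversational audio), so no cross-segment ordering is
    imposed beyond the strictly increasing global word index.
    """

    segments: list[Segment] = field(default_factory=list)
    language: str = "en"
    source_audio_duration_ms: int = 0

    def words(self) -> list[Word]:
        return [w for seg in self.segments for w in seg.words]

    def word(self, index: int) -> Word:
        words = self.words()
        if not (0 <= index < len(words)):
            raise KeyError(f"word index {index} out of range (0..{len(words) - 1})")
        return words[index]

    def validate(self) -> None:
        prev = -1
        for seg in self.segments:
            if seg.end_ms < seg.start_ms:
                raise TranscriptValidationError(
                    f"segment [{seg.start_ms}, {seg.end_ms}): reversed bounds"
                )
            for w in seg.words:
                w.validate()
                if w.index <= prev:
                    raise TranscriptValidationError(
                        f"word indices not strictly increasing at {w.index}"
                    )
                prev = w.index


def parse_diarized_transcript(json_document: str) -> Transcript:
    """Parse a WhisperX-style JSON document into a validated Transcript.

    Word indices are assigned in document order. Missing per-word
    confidence defaults to 1.0 (logged), tolerating ASR backends that do
    not emit scores. Segment bounds are expanded, if needed, to cover the
    union of their words' intervals.
    """
    try:
        doc = json.loads(json_document)
    except json.JSONDecodeError as exc:
        raise TranscriptValidationError(f"malformed JSON: {exc}") from exc
    if not isinstance(doc, dict) or "segments" not in doc:
        raise TranscriptValidationError("document missing 'segments' key")

    segments: list[Segment] = []
    idx = 0
    for raw_seg in doc["segments"]:
        speaker = str(raw_seg.get("speaker", ""))
        words: list[Word] = []
        for raw_w in raw_seg.get("words", []):
            if "score" not in raw_w:
                logger.warning(
                    "word %r has no confidence score; defaulting to 1.0",
                    raw_w.get("word"),
                )
            w = Word(
                text=str(raw_w["word"]),
                start_ms=_ms(float(raw_w["start"])),
                end_ms=_ms(float(raw_w["end"])),
                confidence=float(raw_w.get("score", 1.0)),
                speaker=str(raw_w.get("speaker", speaker)),
                index=idx,
            )
            w.validate()
            words.append(w)
            idx += 1
        start_ms = _ms(float(raw_seg["start"]))
        end_ms = _ms(float(raw_seg["end"]))
        if words:
            lo = min(w.start_ms for w in words)
            hi = max(w.end_ms for w in words)
            if lo < start_ms or hi > end_ms:
                logger.warning(
                    "segment [%d, %d) expanded to cover its words [%d, %d)",
                    start_ms, end_ms, lo, hi,
                )
                start_ms, end_ms = min(start_ms, lo), max(end_ms, hi)
        segments.append(
            Segment(
                start_ms=start_ms,
                end_ms=end_ms,
                text=str(raw_seg.get("text", "")),
                speaker=speaker,
                words=words,
            )
        )

    t = Transcript(
        segments=segments,
        language=str(doc.get("language", "en")),
        source_audio_duration_ms=int(doc.get("duration_ms", 0)),
    )
    if t.source_audio_duration_ms == 0 and segments:
        t.source_audio_duration_ms = max(s.end_ms for s in segments)
    t.validate()
    return t


def serialize_transcript(t: Transcript) -> str:
    """Render a Transcript back to the JSON document format.

    Deterministic (sorted keys, fixed separators), so repeated
    serialization of the same transcript is byte-stable, and
    ``parse_diarized_transcript(serialize_transcript(t))`` reproduces ``t``
    on the retained field set.
    """
    doc = {
        "language": t.language,
        "duration_ms": t.source_audio_duration_ms,
        "segments": [
            {
                "start": seg.start_ms / 1000.0,
                "end": seg.end_ms / 1000.0,
                "text": seg.text,
                "speaker": seg.speaker,
                "words": [
                    {
                        "word": w.text,
                        "start": w.start_ms / 1000.0,
                        "end": w.end_ms / 1000.0,
                        "score": w.confidence,
                        "speaker": w.speaker,
                    }
                    for w in seg.words
                ],
            }
            for seg in t.segments
        ],
    }
    return json.dumps(doc, sort_keys=True, separators=(",", ":"))


def flatten_transcript(t: Transcript) -> pd.DataFrame:
    """One row per word, in global word order.

    Columns: ``index, speaker, start_ms, end_ms, text, confidence``.
    Lossless with respect to those fields; this is the table the rule-based
    redactor consumes and the CSV export format.
    """
    words = t.words()
    return pd.DataFrame(
        {
            "index": [w.index for w in words],
            "speaker": [w.speaker for w in words],
            "start_ms": [w.start_ms for w in words],
            "end_ms": [w.end_ms for w in words],
            "text": [w.text for w in words],
            "confidence": [w.confidence for w in words],
        },
        columns=FLAT_COLUMNS,
    )


def unflatten_rows(rows: pd.DataFrame) -> list[Word]:
    """Inverse of :func:`flatten_transcript` at the word-list level."""
    return [
        Word(
            text=str(r.text),
            start_ms=int(r.start_ms),
            end_ms=int(r.end_ms),
            confidence=float(r.confidence),
            speaker=str(r.speaker),
            index=int(r.index),
        )
        for r in rows.itertuples(index=False)
    ]


def write_flat_csv(rows: pd.DataFrame, path_or_buf) -> None:
    """RFC-4180 CSV, UTF-8, header ``index,speaker,start_ms,end_ms,text,confidence``."""
    rows.to_csv(path_or_buf, index=False, encoding="utf-8")


def read_flat_csv(path_or_buf) -> pd.DataFrame:
    df = pd.read_csv(
        path_or_buf,
        dtype={"index": int, "speaker": str, "start_ms": int, "end_ms": int,
               "text": str, "confidence": float},
        keep_default_na=False,
    )
    missing = [c for c in FLAT_COLUMNS if c not in df.columns]
    if missing:
        raise TranscriptValidationError(f"flat CSV missing columns: {missing}")
    return df[FLAT_COLUMNS]


def flat_csv_text(rows: pd.DataFrame) -> str:
    buf = io.StringIO()
    write_flat_csv(rows, buf)
    return buf.getvalue()
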