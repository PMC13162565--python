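"""AV resynchronization: align scrubbed audio with de-identified video and mux.

Audio and video travel through the pipeline independently, and each stage
records the processing delay it introduces (a signed intrinsic delay, in
ms). Realigning the streams is therefore ledger arithmetic, not signal
cross-correlation: the net offset is the difference of the two recorded
delays. The offset is applied to the audio stream (positive offset: the
audio ran late, trim its head; negative: pad its head with silence), then
the streams are duration-equalized and multiplexed with the original frame
rate and sample rate preserved.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol

import numpy as np

from .audioscrub import AudioBuffer
from .riffavi import AviInfo, probe_avi, write_avi

__all__ = [
    "StreamTiming",
    "MuxParams",
    "Muxer",
    "RawAviMuxer",
    "FfmpegMuxer",
    "MuxerUnavailableError",
    "compute_offset",
    "apply_offset",
    "mux",
]


@dataclass(frozen=True)
class StreamTiming:
    """Per-stream timing facts recorded in the artifact ledger."""

    stream: str  # "audio" | "video"
    intrinsic_delay_ms: int = 0
    fps: float | None = None
    sample_rate_hz: int | None = None

    def __post_init__(self):
        if self.stream not in ("audio", "video"):
            raise ValueError(f"unknown stream {self.stream!r}")


@dataclass
class MuxParams:
    fps: float = 30.0
    profile: str = "lossless-avi"  # or "mp4" (external encoder)
    end_policy: str = "pad"  # duration equalization: "pad" or "trim"


class MuxerUnavailableError(RuntimeError):
    pass


class Muxer(Protocol):
    """Narrow external-muxer interface: write a container, probe it back."""

    def write(self, frames, fps: float, audio: AudioBuffer, path: Path) -> None: ...

    def probe(self, path: Path) -> AviInfo: ...


class RawAviMuxer:
    """Built-in lossless profile (uncompressed RGB + PCM16), pure Python."""

    def write(self, frames, fps, audio: AudioBuffer, path: Path) -> None:
        pcm = np.clip(np.round(audio.samples * 32767.0), -32768, 32767)
        write_avi(path, frames, fps, pcm.astype(np.int16), audio.sample_rate_hz)

    def probe(self, path: Path) -> AviInfo:
        return probe_avi(path)


class FfmpegMuxer:
    """FFmpeg-backed muxer for production containers (MP4/H.264 + AAC).

    Requires the ``ffmpeg``/``ffprobe`` executables on PATH; raises
    :class:`MuxerUnavailableError` with remediation advice otherwise.
    """

    def __init__(self, executable: str = "ffmpeg", prober: str = "ffprobe"):
        self.executable = executable
        self.prober = prober

    def _require(self, name: str) -> str:
        exe = shutil.which(name)
        if exe is None:
            raise MuxerUnavailableError(
                f"{name!r} not found on PATH; install FFmpeg or use the "
                "built-in lossless muxer (RawAviMuxer / profile 'lossless-avi')"
            )
        return exe

    def write(self, frames, fps, audio: AudioBuffer, path: Path) -> None:
        import tempfile

        from .audioscrub import write_wav
        from .frames import write_frame_dir

        exe = self._require(self.executable)
        with tempfile.TemporaryDirectory() as tmp:
            frame_dir = Path(tmp) / "frames"
            frame_dir.mkdir()
            write_frame_dir(frames, frame_dir)
            wav = Path(tmp) / "audio.wav"
            write_wav(audio, wav, subtype="pcm16")
            cmd = [
                exe, "-y", "-framerate", f"{fps}",
                "-i", str(frame_dir / "frame_%06d.png"), "-i", str(wav),
                "-c:v", "libx264", "-pix_fmt", "yuv420p", "-c:a", "aac",
                "-shortest", str(path),
            ]
            res = subprocess.run(cmd, capture_output=True)
            if res.returncode != 0:
                raise RuntimeError(
                    f"ffmpeg failed ({res.returncode}): {res.stderr.decode()[-500:]}"
                )

    def probe(self, path: Path) -> AviInfo:
        import json as _json

        exe = self._require(self.prober)
        res = subprocess.run(
            [exe, "-v", "quiet", "-print_format", "json", "-show_streams",
             str(path)],
            capture_output=True,
        )
        doc = _json.loads(res.stdout)
        fps = n_frames = width = height = sr = n_samples = None
        for st in doc.get("streams", []):
            if st["codec_type"] == "video":
                num, den = st["r_frame_rate"].split("/")
                fps = float(num) / float(den)
                n_frames = int(st.get("nb_frames", 0))
                width, height = st["width"], st["height"]
            elif st["codec_type"] == "audio":
                sr = int(st["sample_rate"])
                n_samples = int(float(st.get("duration", 0)) * sr)
        return AviInfo(fps=fps, n_frames=n_frames, width=width, height=height,
                       sample_rate_hz=sr, n_samples=n_samples)


def compute_offset(audio_timing: StreamTiming, video_timing: StreamTiming) -> int:
    """Signed ms offset between streams: audio delay minus video delay."""
    if audio_timing.stream != "audio" or video_timing.stream != "video":
        raise ValueError("timings must be (audio, video), in that order")
    return audio_timing.intrinsic_delay_ms - video_timing.intrinsic_delay_ms


def apply_offset(audio: AudioBuffer, offset_ms: int) -> AudioBuffer:
    """Shift audio by the computed offset.

    Positive offset: the audio stream accumulated that much extra delay,
    so its head is trimmed by ``offset_ms``. Negative: the audio runs
    early, so silence is prepended. Sample count changes by exactly
    ``round(|offset_ms| * sr / 1000)``.
    """
    n = audio.ms_to_sample(abs(offset_ms))
    if offset_ms == 0 or n == 0:
        return audio.copy()
    if offset_ms > 0:
        if n >= len(audio.samples):
            raise ValueError(
                f"offset {offset_ms} ms consumes the whole audio stream"
            )
        return AudioBuffer(audio.samples[n:].copy(), audio.sample_rate_hz)
    return AudioBuffer(
        np.concatenate([np.zeros(n), audio.samples]), audio.sample_rate_hz
    )


def equalize_duration(
    audio: AudioBuffer, n_frames: int, fps: float, policy: str = "pad"
) -> AudioBuffer:
    """Make audio duration match the video's, by end padding or trimming."""
    target = int(round(n_frames / fps * audio.sample_rate_hz))
    cur = len(audio.samples)
    if cur == target:
        return audio
    if cur > target:
        return AudioBuffer(audio.samples[:target].copy(), audio.sample_rate_hz)
    if policy == "trim":
        raise ValueError(
            f"audio shorter than video ({cur} < {target} samples) under "
            "policy 'trim'"
        )
    return AudioBuffer(
        np.concatenate([audio.samples, np.zeros(target - cur)]),
        audio.sample_rate_hz,
    )


def mux(
    video_frames: list[np.ndarray],
    audio: AudioBuffer,
    offset_ms: int,
    params: MuxParams,
    out_path: str | Path,
    muxer: Muxer | None = None,
) -> AviInfo:
    """Apply the offset, equalize durations, multiplex, and verify by probe.

    Post-conditions enforced by probing the written container: fps equals
    the source fps, audio sample rate equals the source rate, and the
    stream durations differ by at most one video frame period.
    """
    if len(audio.samples) == 0:
        raise ValueError("zero-length audio stream")
    if not video_frames:
        raise ValueError("zero-length video stream")
    if muxer is None:
        muxer = RawAviMuxer() if params.profile == "lossless-avi" else FfmpegMuxer()
    aligned = apply_offset(audio, offset_ms)
    aligned = equalize_duration(aligned, len(video_frames), params.fps,
                                params.end_policy)
    out_path = Path(out_path)
    muxer.write(video_frames, params.fps, aligned, out_path)
    info = muxer.probe(out_path)
    frame_period_ms = 1000.0 / params.fps
    if abs(info.fps - params.fps) > 1e-6 * params.fps:
        raise RuntimeError(
            f"container fps {info.fps} != source fps {params.fps}"
        )
    if info.sample_rate_hz != audio.sample_rate_hz:
        raise RuntimeError(
            f"container sample rate {info.sample_rate_hz} != source "
            f"{audio.sample_rate_hz}"
        )
    delta = abs(info.video_duration_ms - info.audio_duration_ms)
    if delta > frame_period_ms:
        raise RuntimeError(
            f"AV duration mismatch {delta:.2f} ms exceeds one frame period "
            f"({frame_period_ms:.2f} ms)"
        )
    return info
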