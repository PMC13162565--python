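"""Minimal lossless AVI (RIFF) writer and prober.

This is the pipeline's reference container profile: uncompressed 24-bit
RGB video ('DIB ') plus 16-bit PCM mono audio, written and probed in pure
Python. It exists so that multiplexing and its probe assertions (frame
rate, sample rate, stream durations) are bit-stable and testable without
any external binary; a general-purpose encoder (e.g. FFmpeg) sits behind
the same muxer interface for production containers.

fps is stored as the rational rate/scale with scale=1000, so non-integer
frame rates survive a write/probe round trip to 1/1000 fps.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["AviInfo", "write_avi", "probe_avi"]


@dataclass(frozen=True)
class AviInfo:
    """Header facts recovered by probing a container."""

    fps: float
    n_frames: int
    width: int
    height: int
    sample_rate_hz: int
    n_samples: int

    @property
    def video_duration_ms(self) -> float:
        return 1000.0 * self.n_frames / self.fps

    @property
    def audio_duration_ms(self) -> float:
        return 1000.0 * self.n_samples / self.sample_rate_hz


def _chunk(fourcc: bytes, payload: bytes) -> bytes:
    if len(payload) % 2:
        payload += b"\x00"
    return fourcc + struct.pack("<I", len(payload)) + payload


def _list(list_type: bytes, payload: bytes) -> bytes:
    return _chunk(b"LIST", list_type + payload)


def _frame_to_dib(frame: np.ndarray) -> bytes:
    """RGB top-down -> BGR bottom-up rows padded to 4 bytes."""
    h, w = frame.shape[:2]
    bgr = frame[::-1, :, ::-1]  # flip vertically, swap channels
    row_bytes = w * 3
    pad = (-row_bytes) % 4
    if pad:
        padded = np.zeros((h, row_bytes + pad), dtype=np.uint8)
        padded[:, :row_bytes] = bgr.reshape(h, row_bytes)
        return padded.tobytes()
    return np.ascontiguousarray(bgr).tobytes()


def write_avi(
    path: str | Path,
    frames: list[np.ndarray],
    fps: float,
    audio_pcm16: np.ndarray,
    sample_rate_hz: int,
) -> None:
    """Write uncompressed RGB frames + PCM16 mono audio to an AVI file."""
    if not frames:
        raise ValueError("cannot write a container with zero frames")
    if fps <= 0 or sample_rate_hz <= 0:
        raise ValueError("fps and sample rate must be positive")
    audio_pcm16 = np.asarray(audio_pcm16, dtype=np.int16)
    h, w = frames[0].shape[:2]
    scale, rate = 1000, int(round(fps * 1000))
    n_frames = len(frames)
    n_samples = len(audio_pcm16)
    frame_bytes = len(_frame_to_dib(frames[0]))

    avih = struct.pack(
        "<IIIIIIIIII16x",
        int(round(1_000_000 / fps)), frame_bytes * int(np.ceil(fps)), 0,
        0x10,  # AVIF_HASINDEX
        n_frames, 0, 2, frame_bytes, w, h,
    )
    vids_strh = struct.pack(
        "<4s4sIHHIIIIIIIIhhhh",
        b"vids", b"DIB ", 0, 0, 0, 0, scale, rate, 0, n_frames,
        frame_bytes, 0xFFFFFFFF, 0, 0, 0, w, h,
    )
    vids_strf = struct.pack("<IiiHHIIiiII", 40, w, h, 1, 24, 0,
                            frame_bytes, 0, 0, 0, 0)
    auds_strh = struct.pack(
        "<4s4sIHHIIIIIIIIhhhh",
        b"auds", b"\x00\x00\x00\x00", 0, 0, 0, 0, 1, sample_rate_hz, 0,
        n_samples, n_samples * 2, 0xFFFFFFFF, 2, 0, 0, 0, 0,
    )
    auds_strf = struct.pack("<HHIIHHH", 1, 1, sample_rate_hz,
                            sample_rate_hz * 2, 2, 16, 0)
    hdrl = _list(
        b"hdrl",
        _chunk(b"avih", avih)
        + _list(b"strl", _chunk(b"strh", vids_strh) + _chunk(b"strf", vids_strf))
        + _list(b"strl", _chunk(b"strh", auds_strh) + _chunk(b"strf", auds_strf)),
    )

    movi_payload = b""
    index_entries = []
    offset = 4  # relative to start of 'movi' list type
    for frame in frames:
        if frame.shape[:2] != (h, w):
            raise ValueError("all frames must share one size")
        data = _frame_to_dib(frame)
        index_entries.append((b"00db", offset, len(data)))
        movi_payload += _chunk(b"00db", data)
        offset += 8 + len(data) + (len(data) % 2)
    audio_data = audio_pcm16.tobytes()
    index_entries.append((b"01wb", offset, len(audio_data)))
    movi_payload += _chunk(b"01wb", audio_data)
    movi = _list(b"movi", movi_payload)

    idx = b"".join(
        fourcc + struct.pack("<III", 0x10, off, size)
        for fourcc, off, size in index_entries
    )
    body = b"AVI " + hdrl + movi + _chunk(b"idx1", idx)
    with open(path, "wb") as fh:
        fh.write(b"RIFF" + struct.pack("<I", len(body)) + body)


def probe_avi(path: str | Path) -> AviInfo:
    """Recover stream facts from the AVI headers (no payload decoding)."""
    data = Path(path).read_bytes()
    if data[:4] != b"RIFF" or data[8:12] != b"AVI ":
        raise ValueError(f"{path}: not a RIFF/AVI file")

    fps = n_frames = width = height = None
    sample_rate = n_samples = None

    def walk(buf: bytes, pos: int, end: int):
        nonlocal fps, n_frames, width, height, sample_rate, n_samples
        pending_type = None
        while pos + 8 <= end:
            fourcc = buf[pos : pos + 4]
            size = struct.unpack("<I", buf[pos + 4 : pos + 8])[0]
            payload = buf[pos + 8 : pos + 8 + size]
            if fourcc == b"LIST":
                if payload[:4] in (b"hdrl", b"strl"):
                    walk(buf, pos + 12, pos + 8 + size)
            elif fourcc == b"strh":
                stype = payload[:4]
                scale, rate, _start, length = struct.unpack(
                    "<IIII", payload[20:36]
                )
                if stype == b"vids":
                    fps = rate / scale
                    n_frames = length
                elif stype == b"auds":
                    n_samples = length
            elif fourcc == b"strf":
                if len(payload) >= 40 and struct.unpack("<I", payload[:4])[0] == 40:
                    width, height = struct.unpack("<ii", payload[4:12])
                    height = abs(height)
                elif len(payload) in (16, 18) and sample_rate is None:
                    sample_rate = struct.unpack("<I", payload[4:8])[0]
            pending_type = fourcc
            pos += 8 + size + (size % 2)
        return pending_type

    walk(data, 12, len(data))
    if None in (fps, n_frames, width, height, sample_rate, n_samples):
        raise ValueError(f"{path}: incomplete AVI headers")
    return AviInfo(fps=fps, n_frames=n_frames, width=width, height=height,
                   sample_rate_hz=sample_rate, n_samples=n_samples)
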