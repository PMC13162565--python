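"""Lossless frame-sequence I/O (PNG directories).

Video decoding/encoding proper is delegated to the external muxer; inside
the pipeline a video is a list of uint8 HxWx3 RGB arrays, persisted as a
zero-padded PNG sequence (``frame_000000.png`` ...) so intermediates are
lossless and content hashes are reproducible.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["write_frame_dir", "read_frame_dir"]


def write_frame_dir(frames: list[np.ndarray], directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = directory / f"frame_{i:06d}.png"
        iio.imwrite(p, np.asarray(frame, dtype=np.uint8))
        paths.append(p)
    return paths


def read_frame_dir(directory: str | Path) -> list[np.ndarray]:
    directory = Path(directory)
    paths = sorted(directory.glob("frame_*.png"))
    if not paths:
        raise FileNotFoundError(f"no frame_*.png files in {directory}")
    return [np.asarray(iio.imread(p)) for p in paths]
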