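"""Vocoder backends for voice transformation.

Voice disguise here means two independent frequency-domain edits that
leave the time axis untouched:

* fundamental-frequency (F0) scaling by ``f0_ratio`` — shifts perceived
  pitch, the strongest single cue to speaker identity;
* spectral-envelope frequency-axis scaling by ``envelope_warp`` — moves
  formants, altering perceived timbre/vocal-tract length.

Backends implement :class:`VocoderBackend`; the shipped reference backend
is a phase vocoder (STFT time-stretch with phase propagation, followed by
resampling back to the original length), with the envelope warp applied as
a per-frame cepstrally-smoothed spectral gain. Analysis/synthesis backends
with an explicit source-filter decomposition (e.g. WORLD) can be plugged
in behind the same interface.
"""

from __future__ import annotations

from typing import Protocol

import numpy as np
from scipy import signal

__all__ = ["VocoderBackend", "PhaseVocoderBackend"]


class VocoderBackend(Protocol):
    """Analysis/transformation/synthesis at a fixed sample rate.

    Implementations must preserve sample count exactly ("without changing
    speed" is a hard contract, not a goal).
    """

    def transform(
        self, samples: np.ndarray, sample_rate_hz: int,
        f0_ratio: float, envelope_warp: float,
    ) -> np.ndarray: ...


def _stft(x: np.ndarray, nperseg: int, hop: int):
    return signal.stft(
        x, window="hann", nperseg=nperseg, noverlap=nperseg - hop,
        boundary="zeros", padded=True,
    )[2]

def _istft(D: np.ndarray, nperseg: int, hop: int) -> np.ndarray:
    return signal.istft(
        D, window="hann", nperseg=nperseg, noverlap=nperseg - hop,
        boundary=True,
    )[1]


def _phase_vocoder(D: np.ndarray, rate: float, hop: int, nperseg: int) -> np.ndarray:
    """Time-stretch a complex STFT by 1/rate with phase propagation."""
    nbins, nframes = D.shape
    time_steps = np.arange(0, nframes, rate)
    phi_advance = 2.0 * np.pi * hop * np.arange(nbins) / nperseg
    out = np.empty((nbins, len(time_steps)), dtype=complex)
    phase_acc = np.angle(D[:, 0])
    Dpad = np.concatenate([D, np.zeros((nbins, 2), dtype=D.dtype)], axis=1)
    for t, step in enumerate(time_steps):
        i = int(step)
        frac = step - i
        mag = (1.0 - frac) * np.abs(Dpad[:, i]) + frac * np.abs(Dpad[:, i + 1])
        out[:, t] = mag * np.exp(1j * phase_acc)
        dphi = np.angle(Dpad[:, i + 1]) - np.angle(Dpad[:, i]) - phi_advance
        dphi -= 2.0 * np.pi * np.round(dphi / (2.0 * np.pi))
        phase_acc += phi_advance + dphi
    return out


def _fit_length(x: np.ndarray, n: int) -> np.ndarray:
    if len(x) >= n:
        return x[:n]
    return np.concatenate([x, np.zeros(n - len(x))])


class PhaseVocoderBackend:
    """Reference vocoder: phase-vocoder pitch shift + cepstral envelope warp.

    Pitch shifting stretches the signal in time by ``f0_ratio`` with a
    phase vocoder (pitch-preserving), then resamples the stretched signal
    back to the original sample count, which scales every frequency —
    hence F0 — by exactly ``f0_ratio`` while preserving duration.
    """

    def __init__(self, nperseg: int = 1024, hop: int = 256, n_cepstrum: int = 30):
        self.nperseg = nperseg
        self.hop = hop
        self.n_cepstrum = n_cepstrum

    def transform(self, samples, sample_rate_hz, f0_ratio, envelope_warp):
        if f0_ratio <= 0 or envelope_warp <= 0:
            raise ValueError("f0_ratio and envelope_warp must be positive")
        x = np.asarray(samples, dtype=float)
        n = len(x)
        y = x
        if not np.isclose(f0_ratio, 1.0):
            y = self._pitch_shift(y, f0_ratio)
        if not np.isclose(envelope_warp, 1.0):
            y = self._warp_envelope(y, envelope_warp)
        return _fit_length(y, n)

    def _pitch_shift(self, x: np.ndarray, ratio: float) -> np.ndarray:
        n = len(x)
        D = _stft(x, self.nperseg, self.hop)
        stretched = _istft(
            _phase_vocoder(D, 1.0 / ratio, self.hop, self.nperseg),
            self.nperseg, self.hop,
        )
        # read the stretched signal at speed `ratio`: frequencies scale by
        # `ratio`, and the duration returns to the original sample count
        pos = np.arange(n) * ratio
        stretched = _fit_length(stretched, int(np.ceil(pos[-1])) + 2)
        return np.interp(pos, np.arange(len(stretched)), stretched)

    def _warp_envelope(self, x: np.ndarray, warp: float) -> np.ndarray:
        n = len(x)
        D = _stft(x, self.nperseg, self.hop)
        nbins = D.shape[0]
        mag = np.abs(D)
        logmag = np.log(mag + 1e-10)
        ceps = np.fft.rfft(logmag, axis=0)
        ceps[self.n_cepstrum:, :] = 0.0
        env = np.exp(np.fft.irfft(ceps, n=nbins, axis=0).real)
        src_bins = np.arange(nbins) / warp
        warped = np.empty_like(env)
        for t in range(env.shape[1]):
            warped[:, t] = np.interp(src_bins, np.arange(nbins), env[:, t])
        gain = np.clip(warped / (env + 1e-10), 0.05, 20.0)
        return _fit_length(_istft(D * gain, self.nperseg, self.hop), n)
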