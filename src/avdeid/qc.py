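"""Quality-control support: machine checks, scan plumbing, reviewer checklists.

Human review remains the final arbiter of de-identification quality; this
module supplies everything around it: mode-specific reviewer checklists,
machine proxies for the checklist items that can be measured (tone
coverage of PHI intervals, blur coverage and locality, voice-transform
divergence), and plumbing for an adversarial residual-face scan behind a
pluggable detector. All checks are pure readers — they never modify media.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
from scipy.ndimage import uniform_filter

from .audioscrub import AudioBuffer, PhiInterval, ToneSpec
from .videodeid import FaceRegion

__all__ = [
    "ChecklistItem",
    "QCFinding",
    "QCReport",
    "build_checklist",
    "residual_face_scan",
    "FaceScanResult",
    "blur_coverage_metric",
    "residual_phi_scan",
    "voice_transform_check",
    "compile_report",
]


@dataclass(frozen=True)
class ChecklistItem:
    rule_id: str
    text: str


@dataclass(frozen=True)
class QCFinding:
    modality: str  # "audio" | "video"
    rule_id: str
    severity: str = "fail"  # "fail" | "warn"
    frame_index: int | None = None
    interval_ms: tuple[int, int] | None = None
    description: str = ""

    def __post_init__(self):
        if self.modality not in ("audio", "video"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.severity not in ("fail", "warn"):
            raise ValueError(f"unknown severity {self.severity!r}")


@dataclass
class QCReport:
    """Findings plus pass/fail status: pass iff no fail-severity finding."""

    mode: str
    findings: list[QCFinding] = field(default_factory=list)
    checklist: list[ChecklistItem] = field(default_factory=list)

    @property
    def status(self) -> str:
        return "fail" if any(f.severity == "fail" for f in self.findings) else "pass"

    def to_json(self) -> str:
        return json.dumps(
            {
                "mode": self.mode,
                "status": self.status,
                "findings": [
                    {
                        "modality": f.modality,
                        "rule_id": f.rule_id,
                        "severity": f.severity,
                        "frame_index": f.frame_index,
                        "interval_ms": list(f.interval_ms) if f.interval_ms else None,
                        "description": f.description,
                    }
                    for f in self.findings
                ],
                "checklist": [
                    {"rule_id": c.rule_id, "text": c.text} for c in self.checklist
                ],
            },
            indent=2,
            sort_keys=True,
        )

    def checklist_markdown(self) -> str:
        failed = {f.rule_id for f in self.findings if f.severity == "fail"}
        lines = [f"# QC checklist — {self.mode} mode", ""]
        for item in self.checklist:
            mark = "x" if item.rule_id not in failed else " "
            lines.append(f"- [{mark}] ({item.rule_id}) {item.text}")
        return "\n".join(lines) + "\n"


_PPP_ITEMS = [
    ChecklistItem("ppp.face_blur_adequate",
                  "the bounding-box blur adequately obscures all facial features"),
    ChecklistItem("ppp.blur_tracks_motion",
                  "the blur region properly tracks faces during movement and "
                  "occlusions"),
    ChecklistItem("ppp.environment_unaltered",
                  "environmental context remains visible and unaltered"),
    ChecklistItem("ppp.no_identifiers_outside",
                  "no identifying features are visible outside the blurred "
                  "regions"),
]
_GPP_ITEMS = [
    ChecklistItem("gpp.consistent_blur",
                  "the entire frame maintains consistent blur levels"),
    ChecklistItem("gpp.keypoints_visible",
                  "skeletal keypoints are clearly visible and accurately track "
                  "human movement"),
    ChecklistItem("gpp.no_detail_through_blur",
                  "no environmental details or identifying information can be "
                  "discerned through the blur"),
    ChecklistItem("gpp.overlay_reveals_nothing",
                  "the keypoint overlay does not reveal facial features or "
                  "other identifying characteristics"),
]
_AUDIO_ITEMS = [
    ChecklistItem("audio.phi_tones",
                  "all PHI has been replaced with tones"),
    ChecklistItem("audio.voice_transformed",
                  "voice transformation prevents speaker identification"),
]


def build_checklist(mode: str) -> list[ChecklistItem]:
    """Mode-specific reviewer criteria: 4 video items plus 2 shared audio items."""
    if mode == "PPP":
        return _PPP_ITEMS + _AUDIO_ITEMS
    if mode == "GPP":
        return _GPP_ITEMS + _AUDIO_ITEMS
    raise ValueError(f"unknown QC mode {mode!r}")


@dataclass
class FaceScanResult:
    flagged_frames: list[int]
    findings: list[QCFinding]


def residual_face_scan(
    frames: Iterable[np.ndarray],
    detector: Callable[[np.ndarray], list],
) -> FaceScanResult:
    """Adversarial second pass: any face/keypoint detection on de-identified
    frames marks those frames for additional attention.

    ``detector`` maps one frame to a list of detections (contents opaque;
    non-empty means "something face-like survived"). Detector failures on
    individual frames become warn findings and the scan continues.
    """
    flagged: set[int] = set()
    findings: list[QCFinding] = []
    for i, frame in enumerate(frames):
        try:
            hits = detector(frame)
        except Exception as exc:  # detector robustness is not our contract
            findings.append(
                QCFinding(
                    modality="video", rule_id="qc.face_scan_detector_error",
                    severity="warn", frame_index=i,
                    description=f"detector failed on frame {i}: {exc}",
                )
            )
            continue
        if hits:
            flagged.add(i)
            findings.append(
                QCFinding(
                    modality="video", rule_id="qc.residual_face",
                    severity="fail", frame_index=i,
                    description=f"{len(hits)} residual detection(s) on frame {i}",
                )
            )
    return FaceScanResult(flagged_frames=sorted(flagged), findings=findings)


def blur_coverage_metric(
    original: np.ndarray,
    deid: np.ndarray,
    regions: list[FaceRegion],
) -> tuple[list[float], int]:
    """Per-region variance-reduction ratio + count of pixels changed outside.

    The ratio is ``1 - var(deid_region) / var(original_region)`` on the
    grayscale intensities inside each box, clipped to [0, 1] and defined
    as 0 when the original region has zero variance. This is a machine
    proxy for "adequately obscures": a strong blur collapses local
    contrast. The outside-change count is the exact number of pixels
    differing outside every region — the PPP locality invariant surfaced
    as a QC number.
    """
    if original.shape != deid.shape:
        raise ValueError(
            f"frame size mismatch: {original.shape} vs {deid.shape}"
        )
    gray_o = original.astype(float).mean(axis=2)
    gray_d = deid.astype(float).mean(axis=2)
    ratios = []
    inside = np.zeros(gray_o.shape, dtype=bool)
    for region in regions:
        x0, y0, x1, y1 = region.bbox
        inside[y0:y1, x0:x1] = True
        var_o = float(gray_o[y0:y1, x0:x1].var())
        var_d = float(gray_d[y0:y1, x0:x1].var())
        if var_o == 0.0:
            ratios.append(0.0)
        else:
            ratios.append(float(np.clip(1.0 - var_d / var_o, 0.0, 1.0)))
    changed = (original != deid).any(axis=2) & ~inside
    return ratios, int(changed.sum())


def local_variance(gray: np.ndarray, size: int = 5) -> np.ndarray:
    """Windowed variance map (uniform window of ``size`` pixels)."""
    g = gray.astype(float)
    mean = uniform_filter(g, size)
    mean_sq = uniform_filter(g * g, size)
    return np.maximum(mean_sq - mean * mean, 0.0)


def residual_phi_scan(
    audio: AudioBuffer,
    intervals: list[PhiInterval],
    tone: ToneSpec = ToneSpec(),
    tone_band_hz: float = 25.0,
    energy_fraction_threshold: float = 0.6,
) -> list[PhiInterval]:
    """Flag PHI intervals whose spectrum is not dominated by the scrub tone.

    For each interval, the fraction of spectral energy within
    ``tone_band_hz`` of the tone frequency is computed; an interval whose
    fraction falls below the threshold still contains speech-like energy
    and is returned for escalation. A correctly scrubbed interval is a
    near-pure sinusoid and scores close to 1.
    """
    flagged = []
    for iv in intervals:
        i0, i1 = audio.ms_to_sample(iv.start_ms), audio.ms_to_sample(iv.end_ms)
        seg = audio.samples[i0:i1]
        if len(seg) < 8:
            continue
        spec = np.abs(np.fft.rfft(seg * np.hanning(len(seg)))) ** 2
        freqs = np.fft.rfftfreq(len(seg), 1.0 / audio.sample_rate_hz)
        total = float(spec.sum())
        if total <= 0.0:
            flagged.append(iv)  # silence, not a tone
            continue
        band = np.abs(freqs - tone.frequency_hz) <= tone_band_hz
        if float(spec[band].sum()) / total < energy_fraction_threshold:
            flagged.append(iv)
    return flagged


def voice_transform_check(
    original: AudioBuffer,
    transformed: AudioBuffer,
    phi_intervals_ms: list[tuple[int, int]] = (),
    min_relative_difference: float = 0.1,
) -> QCFinding | None:
    """Detect an identity (no-op) voice transform.

    Compares original and transformed audio outside the PHI intervals; if
    the relative RMS difference is below ``min_relative_difference`` the
    voice was effectively not transformed and a fail finding is returned.
    """
    if len(original.samples) != len(transformed.samples):
        raise ValueError("buffers must have equal length")
    keep = np.ones(len(original.samples), dtype=bool)
    for s_ms, e_ms in phi_intervals_ms:
        keep[original.ms_to_sample(s_ms) : original.ms_to_sample(e_ms)] = False
    ref = original.samples[keep]
    out = transformed.samples[keep]
    denom = float(np.sqrt(np.mean(ref**2)))
    if denom == 0.0:
        return None
    rel = float(np.sqrt(np.mean((out - ref) ** 2))) / denom
    if rel < min_relative_difference:
        return QCFinding(
            modality="audio", rule_id="qc.voice_not_transformed",
            severity="fail",
            description=f"relative RMS difference {rel:.4f} below "
                        f"{min_relative_difference}: voice transform ineffective",
        )
    return None


def compile_report(findings: list[QCFinding], mode: str) -> QCReport:
    """Assemble the QC report; pass iff no fail finding."""
    return QCReport(mode=mode, findings=list(findings),
                    checklist=build_checklist(mode))
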