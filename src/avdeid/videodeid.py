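"""Video de-identification: keypoint tracks -> PPP/GPP-obscured frames.

Pose detection is upstream (per-frame persons x 17 COCO keypoints are an
input); this module turns those detections into continuous per-person
tracks (association -> gap interpolation -> Kalman smoothing) and then
obscures identity in one of two modes:

* PPP (precision): Gaussian-blur only a margin-expanded bounding box
  around the facial keypoints; the environment stays untouched.
* GPP (greedy): Gaussian-blur the whole frame, then overlay the skeletal
  keypoints, preserving scene structure but no environmental detail.

Frames are ``uint8`` HxWx3 RGB arrays (origin top-left, x right, y down);
boxes are half-open in pixel index space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk, line

__all__ = [
    "COCO_KEYPOINT_NAMES",
    "COCO_LIMBS",
    "FACIAL_KEYPOINT_INDICES",
    "STATUS_OBSERVED",
    "STATUS_INTERPOLATED",
    "STATUS_PREDICTED",
    "KeypointTrack",
    "FaceRegion",
    "OverlaySpec",
    "PrivacyModeParams",
    "VideoDeidResult",
    "associate_tracks",
    "interpolate_gaps",
    "smooth_kalman",
    "kalman_filter_1d",
    "face_bbox",
    "apply_ppp",
    "apply_gpp",
    "process_video",
    "read_detections_json",
    "write_detections_json",
]

COCO_KEYPOINT_NAMES = (
    "nose", "left_eye", "right_eye", "left_ear", "right_ear",
    "left_shoulder", "right_shoulder", "left_elbow", "right_elbow",
    "left_wrist", "right_wrist", "left_hip", "right_hip",
    "left_knee", "right_knee", "left_ankle", "right_ankle",
)
# 5 facial landmarks (nose, eyes, ears) + 12 body joints
FACIAL_KEYPOINT_INDICES = (0, 1, 2, 3, 4)
# standard COCO limb connectivity (index pairs)
COCO_LIMBS = (
    (0, 1), (0, 2), (1, 3), (2, 4),
    (5, 6), (5, 7), (7, 9), (6, 8), (8, 10),
    (5, 11), (6, 12), (11, 12),
    (11, 13), (13, 15), (12, 14), (14, 16),
)

STATUS_OBSERVED = 0
STATUS_INTERPOLATED = 1
STATUS_PREDICTED = 2


@dataclass
class KeypointTrack:
    """One person's keypoints over time.

    ``frames`` maps frame index -> (17, 4) array of [x, y, confidence,
    status]. After gap filling, frame indices are contiguous between first
    and last; gaps longer than the interpolation limit are listed in
    ``unfilled_gaps`` for QC escalation.
    """

    track_id: int
    frames: dict[int, np.ndarray] = field(default_factory=dict)
    unfilled_gaps: list[tuple[int, int]] = field(default_factory=list)

    def frame_indices(self) -> list[int]:
        return sorted(self.frames)

    def keypoints(self, frame_index: int) -> np.ndarray:
        return self.frames[frame_index]


@dataclass(frozen=True)
class FaceRegion:
    """Half-open pixel box (x0, y0, x1, y1) around one face, one frame."""

    frame_index: int
    bbox: tuple[int, int, int, int]
    track_id: int

    def __post_init__(self):
        x0, y0, x1, y1 = self.bbox
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"degenerate bbox {self.bbox}")


@dataclass
class OverlaySpec:
    """Skeleton rendering for GPP: discs at keypoints, limb segments."""

    point_radius: int = 3
    line_width: int = 1
    color: tuple[int, int, int] = (0, 255, 0)
    limbs: tuple[tuple[int, int], ...] = COCO_LIMBS


@dataclass
class PrivacyModeParams:
    """Mode selection plus every obscuration tunable.

    ``blur_sigma_face=None`` scales the blur with face size
    (bbox diagonal / 6); ``blur_sigma_frame=None`` scales with frame size
    (frame diagonal / 100).
    """

    mode: str = "GPP"
    blur_sigma_face: float | None = None
    blur_sigma_frame: float | None = None
    bbox_margin_frac: float = 0.25
    kp_conf_threshold: float = 0.3
    min_face_box_px: int = 16
    max_gap_frames: int = 30
    max_match_dist_px: float = 50.0
    process_noise: float = 1.0
    measurement_noise: float = 4.0
    assignment: str = "greedy"  # or "hungarian"
    overlay: OverlaySpec = field(default_factory=OverlaySpec)

    def validate(self) -> None:
        if self.mode not in ("PPP", "GPP"):
            raise ValueError(f"unknown privacy mode {self.mode!r}")


def _centroid(kps: np.ndarray, conf_threshold: float) -> np.ndarray | None:
    mask = kps[:, 2] >= conf_threshold
    if not mask.any():
        mask = slice(None)  # fall back to all keypoints
    pts = kps[mask, :2] if isinstance(mask, np.ndarray) else kps[:, :2]
    return pts.mean(axis=0)


def associate_tracks(
    detections: dict[int, list[np.ndarray]],
    max_match_dist_px: float = 50.0,
    kp_conf_threshold: float = 0.3,
    assignment: str = "greedy",
) -> list[KeypointTrack]:
    """Assign per-frame detections to persistent person tracks.

    Matching is by centroid distance (over confident keypoints) between a
    detection and each live track's last known centroid, gated at
    ``max_match_dist_px``; unmatched detections start new tracks. The
    default is deterministic greedy nearest-centroid; ``assignment=
    "hungarian"`` uses optimal bipartite assignment instead.
    """
    tracks: list[KeypointTrack] = []
    last_centroid: dict[int, np.ndarray] = {}
    next_id = 0
    for frame_idx in sorted(detections):
        dets = [np.asarray(d, dtype=float) for d in detections[frame_idx]]
        for d in dets:
            if d.shape != (17, 3):
                raise ValueError(
                    f"frame {frame_idx}: detection shape {d.shape}, expected (17, 3)"
                )
        cents = [_centroid(d, kp_conf_threshold) for d in dets]
        live_ids = list(last_centroid)
        pairs: list[tuple[float, int, int]] = []  # (dist, det_idx, track_id)
        for di, c in enumerate(cents):
            for tid in live_ids:
                dist = float(np.linalg.norm(c - last_centroid[tid]))
                if dist <= max_match_dist_px:
                    pairs.append((dist, di, tid))
        assigned_det: dict[int, int] = {}
        if assignment == "hungarian" and pairs:
            from scipy.optimize import linear_sum_assignment

            big = 1e9
            cost = np.full((len(dets), len(live_ids)), big)
            for dist, di, tid in pairs:
                cost[di, live_ids.index(tid)] = dist
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                if cost[r, c] < big:
                    assigned_det[r] = live_ids[c]
        else:
            pairs.sort()
            used_tracks: set[int] = set()
            for dist, di, tid in pairs:
                if di in assigned_det or tid in used_tracks:
                    continue
                assigned_det[di] = tid
                used_tracks.add(tid)
        by_id = {t.track_id: t for t in tracks}
        for di, d in enumerate(dets):
            entry = np.column_stack([d, np.full(17, STATUS_OBSERVED, dtype=float)])
            if di in assigned_det:
                tid = assigned_det[di]
            else:
                tid = next_id
                next_id += 1
                t = KeypointTrack(track_id=tid)
                tracks.append(t)
                by_id[tid] = t
            by_id[tid].frames[frame_idx] = entry
            last_centroid[tid] = cents[di]
    return tracks


def interpolate_gaps(
    track: KeypointTrack,
    max_gap_frames: int = 30,
    frame_range: tuple[int, int] | None = None,
) -> KeypointTrack:
    """Fill detection gaps by linear interpolation, ends by constant extension.

    Interior gaps of length <= ``max_gap_frames`` get per-coordinate linear
    interpolation between the flanking observations (status=interpolated);
    longer gaps are left unfilled and recorded in ``unfilled_gaps``.
    Leading/trailing gaps relative to ``frame_range`` (default: the track's
    own observed range) are filled by holding the nearest observation.
    """
    obs = track.frame_indices()
    if not obs:
        raise ValueError("cannot interpolate an empty track")
    lo, hi = frame_range if frame_range is not None else (obs[0], obs[-1])
    out = KeypointTrack(track_id=track.track_id)
    for f in obs:
        out.frames[f] = track.frames[f].copy()
    for f in range(lo, obs[0]):  # leading: hold first observation
        entry = track.frames[obs[0]].copy()
        entry[:, 3] = STATUS_INTERPOLATED
        out.frames[f] = entry
    for f in range(obs[-1] + 1, hi + 1):  # trailing: hold last observation
        entry = track.frames[obs[-1]].copy()
        entry[:, 3] = STATUS_INTERPOLATED
        out.frames[f] = entry
    for a, b in zip(obs[:-1], obs[1:]):
        gap = b - a - 1
        if gap == 0:
            continue
        if gap > max_gap_frames:
            out.unfilled_gaps.append((a + 1, b - 1))
            continue
        ka, kb = track.frames[a], track.frames[b]
        for f in range(a + 1, b):
            w = (f - a) / (b - a)
            entry = (1.0 - w) * ka + w * kb
            entry[:, 3] = STATUS_INTERPOLATED
            out.frames[f] = entry
    return out


def kalman_filter_1d(
    z: np.ndarray, process_noise: float, measurement_noise: float
) -> np.ndarray:
    """Constant-velocity Kalman filter over one coordinate series.

    State [position, velocity], unit time step:
    F = [[1, 1], [0, 1]], H = [1, 0],
    Q = process_noise * [[1/4, 1/2], [1/2, 1]], R = measurement_noise.
    Initialization: x0 = [z[0], 0], P0 = diag(measurement_noise, 1000).
    Returns the filtered position series (same length as ``z``).
    """
    if process_noise <= 0 or measurement_noise <= 0:
        raise ValueError("noise parameters must be positive")
    z = np.asarray(z, dtype=float)
    F = np.array([[1.0, 1.0], [0.0, 1.0]])
    H = np.array([[1.0, 0.0]])
    Q = process_noise * np.array([[0.25, 0.5], [0.5, 1.0]])
    R = measurement_noise
    x = np.array([z[0], 0.0])
    P = np.diag([measurement_noise, 1000.0])
    out = np.empty_like(z)
    out[0] = x[0]
    for k in range(1, len(z)):
        x = F @ x
        P = F @ P @ F.T + Q
        S = float((H @ P @ H.T).item()) + R
        K = (P @ H.T).ravel() / S
        x = x + K * (z[k] - x[0])
        P = (np.eye(2) - np.outer(K, H.ravel())) @ P
        out[k] = x[0]
    return out


def smooth_kalman(
    track: KeypointTrack,
    process_noise: float = 1.0,
    measurement_noise: float = 4.0,
) -> KeypointTrack:
    """Filter each of the 34 coordinate series independently.

    Requires a gap-filled (contiguous) track; the output frame set equals
    the input frame set, confidences and statuses are carried through.
    """
    if process_noise <= 0 or measurement_noise <= 0:
        raise ValueError("noise parameters must be positive")
    frames = track.frame_indices()
    if not frames:
        raise ValueError("cannot smooth an empty track")
    if frames != list(range(frames[0], frames[-1] + 1)):
        raise ValueError("smooth_kalman requires a contiguous (gap-filled) track")
    stack = np.stack([track.frames[f] for f in frames])  # (T, 17, 4)
    for kp in range(17):
        for axis in (0, 1):
            stack[:, kp, axis] = kalman_filter_1d(
                stack[:, kp, axis], process_noise, measurement_noise
            )
    out = KeypointTrack(
        track_id=track.track_id, unfilled_gaps=list(track.unfilled_gaps)
    )
    for i, f in enumerate(frames):
        out.frames[f] = stack[i]
    return out


def face_bbox(
    kps: np.ndarray,
    params: PrivacyModeParams,
    frame_size: tuple[int, int],
    frame_index: int = 0,
    track_id: int = 0,
) -> FaceRegion | None:
    """Margin-expanded axis-aligned hull of the confident facial keypoints.

    Returns None when no facial keypoint reaches the confidence threshold
    (the caller escalates to QC). A degenerate hull (all points coincident)
    yields a floor-sized box centred on the points.
    """
    h, w = frame_size
    face = np.asarray(kps, dtype=float)[list(FACIAL_KEYPOINT_INDICES)]
    conf = face[:, 2] >= params.kp_conf_threshold
    if not conf.any():
        return None
    pts = face[conf, :2]
    x0, y0 = pts.min(axis=0)
    x1, y1 = pts.max(axis=0)
    diag = float(np.hypot(x1 - x0, y1 - y0))
    if diag == 0.0:
        half = params.min_face_box_px / 2.0
        x0, x1 = x0 - half, x1 + half
        y0, y1 = y0 - half, y1 + half
    else:
        margin = params.bbox_margin_frac * diag
        x0, x1 = x0 - margin, x1 + margin
        y0, y1 = y0 - margin, y1 + margin
    ix0 = max(0, int(np.floor(x0)))
    iy0 = max(0, int(np.floor(y0)))
    ix1 = min(w, int(np.ceil(x1)))
    iy1 = min(h, int(np.ceil(y1)))
    if ix0 >= ix1 or iy0 >= iy1:
        return None  # face entirely outside the frame
    return FaceRegion(frame_index=frame_index, bbox=(ix0, iy0, ix1, iy1),
                      track_id=track_id)


def _blur_rgb(frame: np.ndarray, sigma: float) -> np.ndarray:
    out = np.empty_like(frame, dtype=float)
    for c in range(frame.shape[2]):
        out[:, :, c] = gaussian_filter(frame[:, :, c].astype(float), sigma)
    return out


def apply_ppp(
    frame: np.ndarray, regions: list[FaceRegion], params: PrivacyModeParams
) -> np.ndarray:
    """Blur only the face boxes; every pixel outside them is bit-identical.

    The blur inside a box equals a full-frame Gaussian blur restricted to
    the box (computed on a padded crop wide enough that truncation makes
    the two identical).
    """
    out = frame.copy()
    h, w = frame.shape[:2]
    for region in regions:
        x0, y0, x1, y1 = region.bbox
        if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
            raise ValueError(f"region {region.bbox} outside frame {w}x{h}")
        sigma = params.blur_sigma_face
        if sigma is None:
            sigma = max(1.0, np.hypot(x1 - x0, y1 - y0) / 6.0)
        pad = int(np.ceil(4.0 * sigma)) + 1
        px0, py0 = max(0, x0 - pad), max(0, y0 - pad)
        px1, py1 = min(w, x1 + pad), min(h, y1 + pad)
        blurred = _blur_rgb(frame[py0:py1, px0:px1], sigma)
        crop = blurred[y0 - py0 : y1 - py0, x0 - px0 : x1 - px0]
        out[y0:y1, x0:x1] = np.clip(np.rint(crop), 0, 255).astype(frame.dtype)
    return out


def apply_gpp(
    frame: np.ndarray,
    tracks_at_frame: list[np.ndarray],
    params: PrivacyModeParams,
    return_mask: bool = False,
):
    """Blur the whole frame, then draw the skeleton overlay.

    A disc is drawn at every keypoint with confidence >= threshold and a
    segment along each configured limb whose endpoints are both confident.
    With ``return_mask=True`` also returns the boolean overlay mask.
    """
    h, w = frame.shape[:2]
    sigma = params.blur_sigma_frame
    if sigma is None:
        sigma = max(1.0, np.hypot(h, w) / 100.0)
    out = np.clip(np.rint(_blur_rgb(frame, sigma)), 0, 255).astype(frame.dtype)
    mask = np.zeros((h, w), dtype=bool)
    spec = params.overlay
    for kps in tracks_at_frame:
        kps = np.asarray(kps, dtype=float)
        conf = kps[:, 2] >= params.kp_conf_threshold
        for a, b in spec.limbs:
            if conf[a] and conf[b]:
                ra, ca = int(round(kps[a, 1])), int(round(kps[a, 0]))
                rb, cb = int(round(kps[b, 1])), int(round(kps[b, 0]))
                rr, cc = line(ra, ca, rb, cb)
                keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
                rr, cc = rr[keep], cc[keep]
                if spec.line_width > 1:
                    r_extra = spec.line_width / 2.0
                    for r, c in zip(rr, cc):
                        dr, dc = disk((r, c), r_extra, shape=(h, w))
                        mask[dr, dc] = True
                else:
                    mask[rr, cc] = True
        for i in range(17):
            if conf[i]:
                rr, cc = disk(
                    (int(round(kps[i, 1])), int(round(kps[i, 0]))),
                    spec.point_radius, shape=(h, w),
                )
                mask[rr, cc] = True
    out[mask] = spec.color
    return (out, mask) if return_mask else out


@dataclass
class VideoDeidResult:
    frames: list[np.ndarray]
    regions: list[FaceRegion]
    tracks: list[KeypointTrack]
    qc_flags: list[dict]
    overlay_masks: list[np.ndarray] | None = None


def process_video(
    frames: list[np.ndarray],
    detections: dict[int, list[np.ndarray]],
    params: PrivacyModeParams,
) -> VideoDeidResult:
    """Full video stage: associate -> interpolate -> Kalman -> obscure.

    Frames where a track exists but no face box can be formed (all facial
    keypoints below threshold), and gaps beyond ``max_gap_frames``, are
    flagged for QC instead of being silently passed through.
    """
    params.validate()
    n = len(frames)
    if detections and max(detections) >= n:
        raise ValueError(
            f"detections reference frame {max(detections)} but only {n} frames given"
        )
    raw_tracks = associate_tracks(
        detections, params.max_match_dist_px, params.kp_conf_threshold,
        params.assignment,
    )
    tracks = []
    qc_flags: list[dict] = []
    for t in raw_tracks:
        filled = interpolate_gaps(t, params.max_gap_frames, frame_range=(0, n - 1))
        for g0, g1 in filled.unfilled_gaps:
            qc_flags.append(
                {"rule_id": "video.gap_too_long", "track_id": t.track_id,
                 "frames": [g0, g1],
                 "description": f"track {t.track_id}: unfilled gap {g0}-{g1}"}
            )
        tracks.append(
            smooth_kalman(filled, params.process_noise, params.measurement_noise)
        )
    h, w = frames[0].shape[:2] if frames else (0, 0)
    regions: list[FaceRegion] = []
    out_frames: list[np.ndarray] = []
    overlay_masks: list[np.ndarray] = []
    for f in range(n):
        frame_regions = []
        persons_here = []
        for t in tracks:
            if f not in t.frames:
                continue
            persons_here.append(t.frames[f])
            region = face_bbox(t.frames[f], params, (h, w), f, t.track_id)
            if region is None:
                qc_flags.append(
                    {"rule_id": "video.no_face_bbox", "track_id": t.track_id,
                     "frames": [f, f],
                     "description": f"frame {f}: track {t.track_id} has no "
                                    "confident facial keypoints"}
                )
            else:
                frame_regions.append(region)
        regions.extend(frame_regions)
        if params.mode == "PPP":
            out_frames.append(apply_ppp(frames[f], frame_regions, params))
            overlay_masks.append(np.zeros((h, w), dtype=bool))
        else:
            img, mask = apply_gpp(frames[f], persons_here, params, return_mask=True)
            out_frames.append(img)
            overlay_masks.append(mask)
    return VideoDeidResult(
        frames=out_frames, regions=regions, tracks=tracks,
        qc_flags=qc_flags, overlay_masks=overlay_masks,
    )


def read_detections_json(source: str | Path) -> dict[int, list[np.ndarray]]:
    """``[{"frame": int, "persons": [{"keypoints": [[x,y,conf] x17]}]}]``."""
    doc = json.loads(Path(source).read_text(encoding="utf-8"))
    out: dict[int, list[np.ndarray]] = {}
    for entry in doc:
        out[int(entry["frame"])] = [
            np.asarray(p["keypoints"], dtype=float) for p in entry["persons"]
        ]
    return out


def write_detections_json(
    detections: dict[int, list[np.ndarray]], path: str | Path
) -> None:
    doc = [
        {"frame": f,
         "persons": [{"keypoints": np.asarray(d, dtype=float).tolist()}
                     for d in dets]}
        for f, dets in sorted(detections.items())
    ]
    Path(path).write_text(json.dumps(doc), encoding="utf-8")
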