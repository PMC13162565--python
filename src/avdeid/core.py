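"""Pipeline configuration, artifact management, and stage orchestration.

The pipeline runs six stages in a fixed order — transcript import,
transcript redaction, audio scrubbing, video de-identification, AV
resynchronization, QC — and every stage execution appends exactly one
record to a hash-chained artifact ledger: a parameter snapshot hash plus
content hashes of all inputs and outputs. The chain makes runs auditable
(each stage's inputs must match some prior stage's outputs or a declared
external input) and reproducible (fixed seed and inputs give identical
output hashes). The artifact store is a plain directory; nothing in the
pipeline ever touches the network.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import audioscrub, avsync, qc, redact, transcript, videodeid
from .frames import read_frame_dir, write_frame_dir

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineInputs",
    "PipelineResult",
    "ArtifactStore",
    "StageError",
    "LedgerVerdict",
    "run_pipeline",
    "verify_ledger",
]

STAGES = (
    "transcript_import", "redact", "audioscrub", "videodeid", "avsync", "qc",
)


@dataclass
class PipelineConfig:
    """All tunables for one run, validated before any stage executes."""

    mode: str = "GPP"
    seed: int = 0
    merge_gap_ms: int = 50
    per_file_voice: bool = False
    rules: dict | str | Path | None = None
    tone: audioscrub.ToneSpec = field(default_factory=audioscrub.ToneSpec)
    voice: audioscrub.VoiceTransformParams = field(
        default_factory=audioscrub.VoiceTransformParams
    )
    video: videodeid.PrivacyModeParams = field(
        default_factory=videodeid.PrivacyModeParams
    )
    mux: avsync.MuxParams = field(default_factory=avsync.MuxParams)
    qc_tone_band_hz: float = 25.0
    qc_tone_energy_threshold: float = 0.6
    qc_min_voice_difference: float = 0.1

    def validate(self) -> None:
        if self.mode not in ("PPP", "GPP"):
            raise ValueError(f"unknown privacy mode {self.mode!r}")
        self.video.mode = self.mode
        self.video.validate()
        if self.merge_gap_ms < 0:
            raise ValueError("merge_gap_ms must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        cfg = cls(
            mode=doc.get("mode", "GPP"),
            seed=int(doc.get("seed", 0)),
            merge_gap_ms=int(doc.get("merge_gap_ms", 50)),
            per_file_voice=bool(doc.get("per_file_voice", False)),
            rules=doc.get("rules"),
            tone=audioscrub.ToneSpec(**doc.get("tone", {})),
            voice=audioscrub.VoiceTransformParams(**doc.get("voice", {})),
            video=videodeid.PrivacyModeParams(**doc.get("video", {})),
            mux=avsync.MuxParams(**doc.get("mux", {})),
        )
        for key in ("qc_tone_band_hz", "qc_tone_energy_threshold",
                    "qc_min_voice_difference"):
            if key in doc:
                setattr(cfg, key, float(doc[key]))
        cfg.validate()
        return cfg

    def params_snapshot(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            if isinstance(obj, Path):
                return str(obj)
            return obj

        return {
            f.name: enc(getattr(self, f.name))
            for f in dataclasses.fields(self)
        }


@dataclass
class PipelineInputs:
    """Declared external inputs: the four files/directories a run consumes."""

    transcript_json: Path
    audio_wav: Path
    detections_json: Path
    frames_dir: Path

    def __post_init__(self):
        for name in ("transcript_json", "audio_wav", "detections_json",
                     "frames_dir"):
            p = Path(getattr(self, name))
            setattr(self, name, p)
            if not p.exists():
                raise FileNotFoundError(f"input {name}: {p} does not exist")


class StageError(RuntimeError):
    def __init__(self, stage: str, record_id: int, cause: Exception):
        super().__init__(f"stage {stage!r} (ledger record {record_id}) failed: "
                         f"{cause}")
        self.stage = stage
        self.record_id = record_id
        self.cause = cause


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def _sha256_tree(path: Path) -> str:
    """Digest of a directory: hash of the sorted (name, file-digest) pairs."""
    h = hashlib.sha256()
    for p in sorted(path.rglob("*")):
        if p.is_file():
            h.update(p.relative_to(path).as_posix().encode())
            h.update(bytes.fromhex(_sha256_file(p)))
    return h.hexdigest()


def _digest(path: Path) -> str:
    return _sha256_tree(path) if path.is_dir() else _sha256_file(path)


class ArtifactStore:
    """File-system artifact store with an append-only JSON-Lines ledger."""

    def __init__(self, run_dir: str | Path):
        self.run_dir = Path(run_dir)
        self.run_dir.mkdir(parents=True, exist_ok=True)
        self.ledger_path = self.run_dir / "ledger.jsonl"
        self._n = 0
        if self.ledger_path.exists():
            self._n = len(self.ledger_path.read_text().splitlines())

    def path(self, name: str) -> Path:
        return self.run_dir / name

    def append(
        self,
        stage: str,
        params_hash: str,
        inputs: dict[str, Path],
        outputs: dict[str, Path],
        status: str = "ok",
    ) -> int:
        record = {
            "record_id": self._n,
            "stage": stage,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
            "params_hash": params_hash,
            "status": status,
            "inputs": {
                n: {"path": str(p), "sha256": _digest(Path(p))}
                for n, p in inputs.items()
            },
            "outputs": {
                n: {"path": str(p), "sha256": _digest(Path(p))}
                for n, p in outputs.items()
            },
        }
        with open(self.ledger_path, "a", encoding="utf-8") as fh:
            fh.write(json.dumps(record, sort_keys=True) + "\n")
        self._n += 1
        return record["record_id"]

    def records(self) -> list[dict]:
        if not self.ledger_path.exists():
            return []
        return [
            json.loads(line)
            for line in self.ledger_path.read_text().splitlines()
            if line.strip()
        ]


@dataclass
class LedgerVerdict:
    intact: bool
    empty: bool
    breaks: list[dict] = field(default_factory=list)


def verify_ledger(run_dir: str | Path) -> LedgerVerdict:
    """Recompute artifact hashes and check the input/output chain.

    A record is flagged when a surviving artifact's recomputed digest
    disagrees with the ledger, or when a stage input hash matches neither
    a prior record's output nor a declared external input.
    """
    store = ArtifactStore(run_dir)
    records = store.records()
    if not records:
        return LedgerVerdict(intact=True, empty=True)
    breaks: list[dict] = []
    known_outputs: set[str] = set()
    for rec in records:
        for kind in ("inputs", "outputs"):
            for name, entry in rec[kind].items():
                p = Path(entry["path"])
                if not p.exists():
                    continue  # intermediates may be pruned; absence is not tampering
                actual = _digest(p)
                if actual != entry["sha256"]:
                    breaks.append(
                        {"record_id": rec["record_id"], "stage": rec["stage"],
                         "artifact": name,
                         "reason": "content hash mismatch (modified post-hoc)"}
                    )
        if rec["stage"] != "inputs":
            for name, entry in rec["inputs"].items():
                if entry["sha256"] not in known_outputs:
                    breaks.append(
                        {"record_id": rec["record_id"], "stage": rec["stage"],
                         "artifact": name,
                         "reason": "input does not match any prior output or "
                                   "declared external"}
                    )
        known_outputs.update(e["sha256"] for e in rec["outputs"].values())
    return LedgerVerdict(intact=not breaks, empty=False, breaks=breaks)


@dataclass
class PipelineResult:
    container_path: Path
    report: qc.QCReport
    ledger: list[dict]
    output_hashes: dict[str, str]


def _params_hash(config: PipelineConfig, stage: str) -> str:
    doc = {"stage": stage, "params": config.params_snapshot()}
    return hashlib.sha256(
        json.dumps(doc, sort_keys=True).encode()
    ).hexdigest()


def run_pipeline(
    config: PipelineConfig, inputs: PipelineInputs, run_dir: str | Path
) -> PipelineResult:
    """Execute all six stages, persisting every intermediate with a record.

    A failure at any stage raises :class:`StageError` after appending a
    failed record; artifacts from completed stages stay intact. Reruns
    with identical config and inputs reproduce identical output hashes
    (ledger timestamps excluded).
    """
    config.validate()
    store = ArtifactStore(run_dir)
    store.append(
        "inputs", _params_hash(config, "inputs"), {},
        {
            "transcript_json": inputs.transcript_json,
            "audio_wav": inputs.audio_wav,
            "detections_json": inputs.detections_json,
            "frames_dir": inputs.frames_dir,
        },
    )

    def run_stage(stage: str, fn, stage_inputs: dict[str, Path],
                  stage_outputs: dict[str, Path]):
        try:
            result = fn()
        except Exception as exc:
            rid = store.append(stage, _params_hash(config, stage),
                               stage_inputs, {}, status="failed")
            raise StageError(stage, rid, exc) from exc
        store.append(stage, _params_hash(config, stage), stage_inputs,
                     stage_outputs)
        return result

    # stage 1: transcript import
    flat_csv = store.path("flat.csv")
    norm_json = store.path("transcript_normalized.json")

    def s1():
        t = transcript.parse_diarized_transcript(
            inputs.transcript_json.read_text(encoding="utf-8")
        )
        rows = transcript.flatten_transcript(t)
        transcript.write_flat_csv(rows, flat_csv)
        norm_json.write_text(transcript.serialize_transcript(t),
                             encoding="utf-8")
        return t, rows

    t, rows = run_stage(
        "transcript_import", s1,
        {"transcript_json": inputs.transcript_json},
        {"flat_csv": flat_csv, "transcript_normalized": norm_json},
    )

    # stage 2: transcript redaction
    redacted_csv = store.path("redacted.csv")
    redmap_json = store.path("redaction_map.json")

    def s2():
        if config.rules is None:
            from .synthetic import ruleset_for_plan

            rules = ruleset_for_plan()
        elif isinstance(config.rules, dict):
            rules = redact.load_ruleset(config.rules)
        else:
            rules = redact.load_ruleset(Path(config.rules))
        spans = redact.detect_phi(rows, rules)
        red_rows, red_map = redact.apply_redaction(rows, spans, rules)
        transcript.write_flat_csv(red_rows, redacted_csv)
        redmap_json.write_text(redact.redaction_map_json(red_map),
                               encoding="utf-8")
        return spans

    spans = run_stage(
        "redact", s2, {"flat_csv": flat_csv},
        {"redacted_csv": redacted_csv, "redaction_map": redmap_json},
    )

    # stage 3: audio scrubbing
    scrubbed_wav = store.path("scrubbed.wav")
    intervals_json = store.path("phi_intervals.json")

    def s3():
        audio = audioscrub.read_wav(inputs.audio_wav)
        intervals = audioscrub.phi_intervals(t, spans, config.merge_gap_ms)
        toned = audioscrub.insert_tones(audio, intervals, config.tone)
        voice_params = dataclasses.replace(config.voice, seed=config.seed)
        disguised, draws = audioscrub.transform_voice_per_speaker(
            toned, t, voice_params, per_file=config.per_file_voice
        )
        # re-insert tones: the vocoder processed the whole track, tones included
        disguised = audioscrub.insert_tones(disguised, intervals, config.tone)
        audioscrub.write_wav(disguised, scrubbed_wav)
        intervals_json.write_text(
            json.dumps(
                {
                    "intervals": [
                        {"start_ms": iv.start_ms, "end_ms": iv.end_ms,
                         "category": iv.category,
                         "source_word_indices": list(iv.source_word_indices)}
                        for iv in intervals
                    ],
                    "voice_draws": {k: list(v) for k, v in draws.items()},
                },
                sort_keys=True, indent=2,
            ),
            encoding="utf-8",
        )
        return audio, intervals, disguised

    audio, intervals, scrubbed = run_stage(
        "audioscrub", s3,
        {"audio_wav": inputs.audio_wav, "redacted_csv": redacted_csv},
        {"scrubbed_wav": scrubbed_wav, "phi_intervals": intervals_json},
    )

    # stage 4: video de-identification
    deid_frames_dir = store.path("deid_frames")
    regions_jsonl = store.path("face_regions.jsonl")
    tracks_json = store.path("tracks.json")

    def s4():
        frames = read_frame_dir(inputs.frames_dir)
        detections = videodeid.read_detections_json(inputs.detections_json)
        result = videodeid.process_video(frames, detections, config.video)
        write_frame_dir(result.frames, deid_frames_dir)
        with open(regions_jsonl, "w", encoding="utf-8") as fh:
            for r in result.regions:
                fh.write(json.dumps(
                    {"frame": r.frame_index, "bbox": list(r.bbox),
                     "track_id": r.track_id}) + "\n")
        tracks_json.write_text(
            json.dumps(
                [
                    {"track_id": tr.track_id,
                     "unfilled_gaps": tr.unfilled_gaps,
                     "frames": {str(f): k.tolist()
                                for f, k in sorted(tr.frames.items())}}
                    for tr in result.tracks
                ],
                sort_keys=True,
            ),
            encoding="utf-8",
        )
        return frames, result

    frames, vresult = run_stage(
        "videodeid", s4,
        {"frames_dir": inputs.frames_dir,
         "detections_json": inputs.detections_json},
        {"deid_frames": deid_frames_dir, "face_regions": regions_jsonl,
         "tracks": tracks_json},
    )

    # stage 5: AV resynchronization
    container = store.path("deid.avi")

    def s5():
        audio_timing = avsync.StreamTiming(
            "audio", 0, sample_rate_hz=scrubbed.sample_rate_hz
        )
        video_timing = avsync.StreamTiming("video", 0, fps=config.mux.fps)
        offset = avsync.compute_offset(audio_timing, video_timing)
        return avsync.mux(vresult.frames, scrubbed, offset, config.mux,
                          container)

    run_stage(
        "avsync", s5,
        {"scrubbed_wav": scrubbed_wav, "deid_frames": deid_frames_dir},
        {"container": container},
    )

    # stage 6: QC
    report_json = store.path("qc_report.json")
    checklist_md = store.path("qc_checklist.md")

    def s6():
        findings: list[qc.QCFinding] = []
        residual = qc.residual_phi_scan(
            scrubbed, intervals, config.tone,
            tone_band_hz=config.qc_tone_band_hz,
            energy_fraction_threshold=config.qc_tone_energy_threshold,
        )
        for iv in residual:
            findings.append(qc.QCFinding(
                modality="audio", rule_id="audio.phi_tones",
                interval_ms=(iv.start_ms, iv.end_ms),
                description="speech-like energy remains inside a PHI interval",
            ))
        vt = qc.voice_transform_check(
            audio, scrubbed,
            [(iv.start_ms, iv.end_ms) for iv in intervals],
            config.qc_min_voice_difference,
        )
        if vt is not None:
            findings.append(vt)
        if config.mode == "PPP":
            regions_by_frame: dict[int, list[videodeid.FaceRegion]] = {}
            for r in vresult.regions:
                regions_by_frame.setdefault(r.frame_index, []).append(r)
            for f in range(len(frames)):
                ratios, outside = qc.blur_coverage_metric(
                    frames[f], vresult.frames[f], regions_by_frame.get(f, [])
                )
                if outside:
                    findings.append(qc.QCFinding(
                        modality="video",
                        rule_id="ppp.no_identifiers_outside",
                        frame_index=f,
                        description=f"{outside} pixels changed outside face "
                                    "regions",
                    ))
        for flag in vresult.qc_flags:
            findings.append(qc.QCFinding(
                modality="video", rule_id=flag["rule_id"], severity="warn",
                frame_index=flag["frames"][0], description=flag["description"],
            ))
        report = qc.compile_report(findings, config.mode)
        report_json.write_text(report.to_json(), encoding="utf-8")
        checklist_md.write_text(report.checklist_markdown(), encoding="utf-8")
        return report

    report = run_stage(
        "qc", s6,
        {"scrubbed_wav": scrubbed_wav, "deid_frames": deid_frames_dir,
         "container": container},
        {"qc_report": report_json, "qc_checklist": checklist_md},
    )

    hashes = {}
    for rec in store.records():
        for name, entry in rec["outputs"].items():
            hashes[f"{rec['stage']}/{name}"] = entry["sha256"]
    return PipelineResult(
        container_path=container, report=report, ledger=store.records(),
        output_hashes=hashes,
    )
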