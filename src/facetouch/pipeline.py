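"""End-to-end orchestration: simulate → ingest → extract → evaluate → report.

`PipelineConfig` is a flat configuration loadable from YAML; every run
writes the resolved configuration next to its outputs for provenance, and
each stage logs record counts (segments, windows, folds) to stderr.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .evaluation import (BINARY, FAMILIES, MULTICLASS, NestedCVReport,
                         default_model_spec, make_nested_plan, run_nested_cv,
                         window_sweep)
from .features import extract_features
from .ingest import align_and_trim, read_annotations, read_recording
from .simulate import (SimulationConfig, simulate_dataset,
                       write_annotations_csv, write_recording_csv)

logger = logging.getLogger(__name__)

TASKS = (BINARY, MULTICLASS)


@dataclass
class PipelineConfig:
    """Flat parameter surface of a full run."""

    data_dir: str | None = None        # None → simulate
    out_dir: str = "facetouch_out"
    seed: int = 0
    n_participants: int = 10
    activity_duration: float = 180.0
    sampling_rate: float = 30.0
    trim_front: float = 20.0
    trim_back: float = 5.0
    window_lengths: list[int] = field(default_factory=lambda: [5])
    tasks: list[str] = field(default_factory=lambda: [BINARY])
    families: list[str] = field(default_factory=lambda: list(FAMILIES))

    def validate(self) -> None:
        if not all(2 <= w <= 16 for w in self.window_lengths):
            raise ConfigurationError("window lengths must lie in 2..16 s")
        bad = set(self.tasks) - set(TASKS)
        if bad:
            raise ConfigurationError(f"unknown tasks {bad}")
        bad = set(self.families) - set(FAMILIES)
        if bad:
            raise ConfigurationError(f"unknown model families {bad}")

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            n_participants=self.n_participants,
            activity_duration=self.activity_duration,
            sampling_rate=self.sampling_rate, seed=self.seed,
            trim_front=self.trim_front, trim_back=self.trim_back)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def cmd_simulate(config: PipelineConfig) -> Path:
    """Write one recording CSV and one annotation CSV per participant plus a
    manifest recording the seed; returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    recordings, logs = simulate_dataset(config.simulation_config())
    files = []
    for rec, log in zip(recordings, logs):
        rec_path = out / f"{rec.participant_id}_recording.csv"
        ann_path = out / f"{rec.participant_id}_annotations.csv"
        write_recording_csv(rec, rec_path)
        write_annotations_csv(log, ann_path)
        files.append({"participant_id": rec.participant_id,
                      "recording": rec_path.name, "annotations": ann_path.name})
    manifest = {"seed": config.seed, "sampling_rate": config.sampling_rate,
                "n_participants": config.n_participants, "files": files}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    config.dump(out / "config_resolved.yaml")
    logger.info("simulated %d participants into %s", len(recordings), out)
    return out


def load_segments(config: PipelineConfig):
    """Segments from disk (data_dir with a manifest) or from the simulator."""
    if config.data_dir is None:
        recordings, logs = simulate_dataset(config.simulation_config())
    else:
        data = Path(config.data_dir)
        with open(data / "manifest.json") as fh:
            manifest = json.load(fh)
        recordings, logs = [], []
        for entry in manifest["files"]:
            recordings.append(read_recording(
                data / entry["recording"], entry["participant_id"],
                expected_rate=config.sampling_rate))
            logs.append(read_annotations(data / entry["annotations"]))
    segments = []
    for rec, log in zip(recordings, logs):
        segs = align_and_trim(rec, log, config.trim_front, config.trim_back)
        logger.info("participant %s: %d segments, %.0f s retained",
                    rec.participant_id, len(segs),
                    sum(len(s) for s in segs) / rec.sampling_rate)
        segments.extend(segs)
    return segments


def cmd_run(config: PipelineConfig) -> dict[str, NestedCVReport]:
    """Full pipeline for every (window length, task, family) combination.

    Writes one report JSON per combination under ``out_dir`` and returns the
    reports keyed by ``"<task>_<family>_<length>s"``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.dump(out / "config_resolved.yaml")
    segments = load_segments(config)
    reports: dict[str, NestedCVReport] = {}
    for length in config.window_lengths:
        matrix = extract_features(segments, length, config.sampling_rate)
        participants = sorted(matrix["participant_id"].unique())
        plan = make_nested_plan(participants, config.seed)
        logger.info("window %d s: %d windows, %d outer folds",
                    length, len(matrix), len(plan.outer_folds))
        for task in config.tasks:
            for family in config.families:
                spec = default_model_spec(family)
                report = run_nested_cv(matrix, task, spec, plan, length)
                key = f"{task}_{family}_{length}s"
                with open(out / f"report_{key}.json", "w") as fh:
                    json.dump(report.to_dict(), fh, indent=2)
                reports[key] = report
                logger.info("%s: %s", key, report.summary_formatted())
    return reports


def cmd_sweep(config: PipelineConfig, task: str):
    """Accuracy-vs-window-length table over ``config.window_lengths``."""
    config.validate()
    segments = load_segments(config)
    specs = [default_model_spec(f) for f in config.families]
    table = window_sweep(segments, config.window_lengths, task, specs,
                         config.sampling_rate, plan_seed=config.seed)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / f"sweep_{task}.csv")
    return table
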