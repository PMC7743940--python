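"""End-to-end orchestration: combine -> detect -> match -> metrics -> null.

Every stage output is written as CSV/JSON under the output directory and
recorded, with parameters, seeds and content hashes, in ``manifest.json``,
so every number in a report is traceable to its inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ethobench import combine as combine_mod
from ethobench import io as io_mod
from ethobench import matching as matching_mod
from ethobench import metrics as metrics_mod
from ethobench import nullstats as null_mod
from ethobench import smoothing as smoothing_mod

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    annotations_path: str
    scores_path: str
    movies_path: str
    out_dir: str
    smoothing: smoothing_mod.SmoothingParams = field(
        default_factory=lambda: smoothing_mod.SmoothingParams(
            threshold=0.1, max_gap=2, min_bout_len=3
        )
    )
    shuffle: null_mod.ShuffleConfig = field(default_factory=null_mod.ShuffleConfig)
    behaviors: tuple[str, ...] | None = None  # None = all present

    def validate(self) -> None:
        for p in (self.annotations_path, self.scores_path, self.movies_path):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file does not exist: {p}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


def _write_json(data, path: Path) -> None:
    path.write_text(json.dumps(_jsonable(data), indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write the report bundle.  Returns the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": _jsonable(config),
        "stages": {},
    }

    movies = io_mod.read_movies(config.movies_path)
    meta = io_mod.movies_by_id(movies)
    annotations = io_mod.read_annotations(config.annotations_path, movies=meta)
    tracks = io_mod.read_scores(config.scores_path)
    if config.behaviors:
        annotations = [a for a in annotations if str(a.behavior) in config.behaviors]
        tracks = [t for t in tracks if str(t.behavior) in config.behaviors]

    # stage 1: combined human annotations
    combined = combine_mod.combine_all(annotations)
    combined_flat = [b for group in combined.values() for b in group]
    combined_path = out / "combined_bouts.csv"
    io_mod.write_table(combined_flat, combined_path)

    # stage 2: classifier bout smoothing
    classifier = {
        io_mod.track_key(t): smoothing_mod.detect_bouts(t, config.smoothing)
        for t in tracks
    }
    classifier_flat = [b for group in classifier.values() for b in group]
    classifier_path = out / "classifier_bouts.csv"
    io_mod.write_table(classifier_flat, classifier_path)
    _write_json(config.smoothing, out / "classifier_bouts.params.json")

    # stage 3: bout matching
    records = matching_mod.match_all(combined, classifier, tracks)
    match_path = out / "match_records.csv"
    io_mod.write_table(records, match_path)

    # stage 4: metrics, per behavior and pooled
    behaviors = sorted({str(t.behavior) for t in tracks})
    metrics: dict = {"pooled": _jsonable(metrics_mod.precision_recall(records, config.smoothing))}
    for behavior in behaviors:
        sel = [r for r in records if str(r.behavior) == behavior]
        report = metrics_mod.precision_recall(sel, config.smoothing)
        entry = _jsonable(report)
        entry["fp_rate_by_pair_type"] = _jsonable(
            metrics_mod.fp_rate_by_pair_type(sel, movies)
        )
        metrics[behavior] = entry
    metrics_path = out / "metrics.json"
    _write_json(metrics, metrics_path)

    # stage 5: permutation null comparison, per behavior
    null_report: dict = {}
    for behavior in behaviors:
        sel = [r for r in records if str(r.behavior) == behavior]
        if not any(r.category in ("TP", "FN") for r in sel):
            null_report[behavior] = {"skipped": "no human-annotated bouts"}
            continue
        shuffles = null_mod.shuffle_scores(sel, config.shuffle)
        null_report[behavior] = null_mod.null_comparison(
            sel, shuffles, threshold=config.smoothing.threshold
        )
        null_report[behavior]["base_seed"] = config.shuffle.base_seed
    null_path = out / "null_report.json"
    _write_json(null_report, null_path)

    for name, path in [
        ("combined_bouts", combined_path),
        ("classifier_bouts", classifier_path),
        ("match_records", match_path),
        ("metrics", metrics_path),
        ("null_report", null_path),
    ]:
        manifest["stages"][name] = {"path": path.name, "sha256": _sha256(path)}
    _write_json(manifest, out / "manifest.json")
    return manifest
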