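"""Precision/recall metrics, confidence-stratified recall, FP rates, grid search,
and per-frame feature z-score profiles.

Precision is TP / (TP + FP) and recall is TP / (TP + FN), with the bout
counting conventions of :mod:`ethobench.matching` (TP and FN reference
human bouts, FP references classifier bouts).  An undefined ratio
(zero denominator) is reported as ``None``, never silently 0 or 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ethobench.io import MovieMeta, ScoreTrack, ValidationError, track_key
from ethobench.combine import CombinedBout
from ethobench.matching import MatchRecord, match_all
from ethobench.smoothing import SmoothingParams, detect_bouts


@dataclass
class MetricsReport:
    tp: int
    fn: int
    fp: int
    precision: float | None
    recall: float | None
    recall_by_score: dict[int, float] = field(default_factory=dict)
    params: SmoothingParams | None = None

    @property
    def objective(self) -> float | None:
        """recall x precision, the smoothing-parameter selection objective."""
        if self.precision is None or self.recall is None:
            return None
        return self.precision * self.recall


def precision_recall(
    records: Sequence[MatchRecord], params: SmoothingParams | None = None
) -> MetricsReport:
    tp = sum(1 for r in records if r.category == "TP")
    fn = sum(1 for r in records if r.category == "FN")
    fp = sum(1 for r in records if r.category == "FP")
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    return MetricsReport(
        tp=tp,
        fn=fn,
        fp=fp,
        precision=precision,
        recall=recall,
        recall_by_score=recall_by_score(records),
        params=params,
    )


def recall_by_score(records: Sequence[MatchRecord]) -> dict[int, float]:
    """Recall per combined human score (1-6).  Scores absent from the data
    are omitted rather than zero-filled."""
    out: dict[int, float] = {}
    for score in sorted({r.human_score for r in records if r.category in ("TP", "FN")}):
        sel = [r for r in records if r.category in ("TP", "FN") and r.human_score == score]
        tp = sum(1 for r in sel if r.category == "TP")
        out[score] = tp / len(sel)
    return out


def fp_rate_by_pair_type(
    records: Sequence[MatchRecord], movies: Iterable[MovieMeta]
) -> dict[str, dict[str, float]]:
    """False-positive bouts per minute of evaluated video, per pair type.

    The denominator is each movie's duration in minutes, summed over the
    movies of that pair type (a movie counts once regardless of how many
    fly tracks it contributed).  Raw FP counts and minutes are emitted
    alongside the rate.
    """
    movies = list(movies)
    meta = {m.movie_id: m for m in movies}
    for r in records:
        if r.movie_id not in meta:
            raise ValidationError(f"record references movie {r.movie_id!r} missing from metadata")
    minutes: dict[str, float] = {}
    for m in movies:
        minutes[str(m.pair_type)] = minutes.get(str(m.pair_type), 0.0) + m.minutes
    fp_counts: dict[str, int] = {}
    for r in records:
        if r.category != "FP":
            continue
        pt = str(meta[r.movie_id].pair_type)
        fp_counts[pt] = fp_counts.get(pt, 0) + 1
    out: dict[str, dict[str, float]] = {}
    for pt, mins in minutes.items():
        count = fp_counts.get(pt, 0)
        if mins <= 0:
            if count:
                raise ValidationError(f"pair type {pt} has false positives but zero evaluated time")
            continue
        out[pt] = {"fp_count": count, "minutes": mins, "fp_per_minute": count / mins}
    for pt in fp_counts:
        if pt not in out:
            raise ValidationError(f"pair type {pt} has false positives but zero evaluated time")
    return out


def parameter_grid_search(
    human: Mapping[tuple[str, str, str], Sequence[CombinedBout]],
    tracks: Iterable[ScoreTrack],
    grid: Sequence[SmoothingParams],
) -> pd.DataFrame:
    """Evaluate detect -> match -> precision/recall over a parameter grid.

    Returns one row per grid point ranked by recall x precision descending;
    points with an undefined objective sort last.  Ties break by
    (threshold, min_bout_len, max_gap) ascending.
    """
    if not grid:
        raise ValidationError("parameter grid is empty")
    tracks = list(tracks)
    rows = []
    for params in grid:
        try:
            classifier = {
                track_key(t): detect_bouts(t, params) for t in tracks
            }
            records = match_all(human, classifier, tracks)
            report = precision_recall(records, params)
        except ValidationError as exc:
            raise ValidationError(f"grid point {params}: {exc}") from exc
        rows.append(
            {
                "threshold": params.threshold,
                "max_gap": params.max_gap,
                "min_bout_len": params.min_bout_len,
                "tp": report.tp,
                "fn": report.fn,
                "fp": report.fp,
                "precision": report.precision,
                "recall": report.recall,
                "objective": report.objective,
            }
        )
    df = pd.DataFrame(rows)
    df["_defined"] = df["objective"].notna()
    df = df.sort_values(
        by=["_defined", "objective", "threshold", "min_bout_len", "max_gap"],
        ascending=[False, False, True, True, True],
    ).drop(columns="_defined")
    return df.reset_index(drop=True)


def default_grid(
    thresholds: Sequence[float] = (0.0, 0.1, 0.2, 0.3),
    max_gaps: Sequence[int] = (0, 1, 2, 4),
    min_bout_lens: Sequence[int] = (1, 2, 3, 5),
) -> list[SmoothingParams]:
    """Cartesian grid over the three smoothing axes (threshold default 0.1
    is the detection threshold used for headline metrics)."""
    return [
        SmoothingParams(threshold=t, max_gap=g, min_bout_len=m)
        for t, g, m in itertools.product(thresholds, max_gaps, min_bout_lens)
    ]


def feature_zscore_profiles(
    features: pd.DataFrame,
    annotated: np.ndarray,
    feature_columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-feature z-score distribution summaries split by annotation label.

    Each feature is z-scored over *all* frames (global mean 0, sd 1), then
    split into annotated (combined score >= 1) and unannotated frames.  For
    each label the median, quartiles, 0.5/99.5 percentiles and variance are
    reported.  A zero-variance feature is flagged and its z-summaries left
    empty instead of propagating NaN.
    """
    if feature_columns is None:
        feature_columns = [
            c for c in features.columns if c not in ("movie_id", "fly_id", "frame")
        ]
    annotated = np.asarray(annotated, dtype=bool)
    if annotated.size != len(features):
        raise ValidationError(
            f"label array has {annotated.size} entries for {len(features)} feature frames"
        )
    rows = []
    labels = {"annotated": annotated, "unannotated": ~annotated}
    if not annotated.any():
        labels = {"unannotated": ~annotated}
    for col in feature_columns:
        values = features[col].to_numpy(dtype=float)
        sd = values.std()
        zero_variance = sd == 0
        z = (values - values.mean()) / sd if not zero_variance else None
        for label, mask in labels.items():
            if not mask.any():
                continue
            row = {
                "feature": col,
                "label": label,
                "n_frames": int(mask.sum()),
                "zero_variance": zero_variance,
                "variance": float(values[mask].var()),
            }
            if not zero_variance:
                zs = z[mask]
                row.update(
                    median=float(np.median(zs)),
                    q25=float(np.percentile(zs, 25)),
                    q75=float(np.percentile(zs, 75)),
                    p005=float(np.percentile(zs, 0.5)),
                    p995=float(np.percentile(zs, 99.5)),
                )
            rows.append(row)
    return pd.DataFrame(rows)
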