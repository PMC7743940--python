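"""Combined two-observer annotations: union merge, 1-6 combined scores, summaries.

Two observers independently annotate bouts with a 1-3 confidence.  Bouts
from the two observers that overlap by at least one frame are merged via
the union operation into a single combined region.  The combined score of
a matched pair of bouts is the sum of the two confidences (1-6).  When one
observer splits a region that the other annotated as a single bout, each
sub-bout yields its own combined score record ("separate bouts"), and the
maximum of those records is the region's representative score.  Regions
annotated by a single observer pass through with that observer's
confidence as their only record.

Counting unit
-------------
Score-distribution summaries (the 4x4 observer-score grid, the 4-6
fraction, the one-observer fraction) count **score records**, not merged
regions: a split region contributes one count per record, all carrying
observer_count 2.  The raw region count is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ethobench.io import Behavior, MovieMeta, ObserverBout, PairType, ValidationError


@dataclass(frozen=True)
class CombinedBout:
    """One union-merged annotation region with its combined score record(s).

    ``grid_cells`` holds, per score record, the (observer A confidence,
    observer B confidence) pair that produced it; a one-observer region has
    0 in the absent observer's slot.
    """

    movie_id: str
    fly_id: str
    behavior: Behavior
    start_frame: int
    end_frame: int
    score_records: tuple[int, ...]
    grid_cells: tuple[tuple[int, int], ...]
    observer_count: int
    representative_score: int = 0

    def __post_init__(self) -> None:
        if not self.score_records:
            raise ValidationError("a CombinedBout needs at least one score record")
        object.__setattr__(self, "representative_score", max(self.score_records))
        if self.observer_count == 1 and (
            len(self.score_records) != 1 or self.score_records[0] > 3
        ):
            raise ValidationError(
                "a one-observer region carries exactly one record equal to that "
                "observer's 1-3 confidence"
            )

    @property
    def duration_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


def _check_single_universe(bouts: Sequence[ObserverBout]) -> None:
    keys = {(b.movie_id, b.fly_id, str(b.behavior)) for b in bouts}
    if len(keys) > 1:
        raise ValidationError(
            f"merge_observer_bouts expects bouts from one (movie, fly, behavior), got {sorted(keys)}"
        )


def _check_nonoverlapping(bouts: Sequence[ObserverBout], who: str) -> None:
    ordered = sorted(bouts, key=lambda b: b.start_frame)
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.start_frame <= prev.end_frame:
            raise ValidationError(f"observer {who}: bouts overlap, input is corrupted")


def merge_observer_bouts(
    bouts_a: Sequence[ObserverBout], bouts_b: Sequence[ObserverBout]
) -> list[CombinedBout]:
    """Union-merge two observers' bouts for one (movie, fly, behavior).

    Overlap is declared when two bouts share >= 1 frame.  Chains of
    overlaps (A1-B1-A2) collapse into one region via connected components.
    Within a two-observer region, one score record is produced per
    cross-observer overlapping pair, each the sum of the two confidences.
    """
    bouts_a, bouts_b = list(bouts_a), list(bouts_b)
    all_bouts = bouts_a + bouts_b
    if not all_bouts:
        return []
    _check_single_universe(all_bouts)
    _check_nonoverlapping(bouts_a, "A")
    _check_nonoverlapping(bouts_b, "B")
    ref = all_bouts[0]

    tagged = sorted(
        [(b, 0) for b in bouts_a] + [(b, 1) for b in bouts_b],
        key=lambda t: (t[0].start_frame, t[0].end_frame),
    )
    components: list[list[tuple[ObserverBout, int]]] = []
    comp_end = -1
    for bout, side in tagged:
        if components and bout.start_frame <= comp_end:
            components[-1].append((bout, side))
        else:
            components.append([(bout, side)])
            comp_end = -1
        comp_end = max(comp_end, bout.end_frame)

    combined: list[CombinedBout] = []
    for comp in components:
        a_side = [b for b, s in comp if s == 0]
        b_side = [b for b, s in comp if s == 1]
        start = min(b.start_frame for b, _ in comp)
        end = max(b.end_frame for b, _ in comp)
        if a_side and b_side:
            records: list[int] = []
            cells: list[tuple[int, int]] = []
            for a in sorted(a_side, key=lambda b: b.start_frame):
                for b in sorted(b_side, key=lambda b: b.start_frame):
                    if a.overlaps(b):
                        records.append(a.confidence + b.confidence)
                        cells.append((a.confidence, b.confidence))
            observer_count = 2
        else:
            only = (a_side or b_side)[0]
            records = [only.confidence]
            cells = [
                (only.confidence, 0) if a_side else (0, only.confidence)
            ]
            observer_count = 1
        combined.append(
            CombinedBout(
                movie_id=ref.movie_id,
                fly_id=ref.fly_id,
                behavior=ref.behavior,
                start_frame=start,
                end_frame=end,
                score_records=tuple(records),
                grid_cells=tuple(cells),
                observer_count=observer_count,
            )
        )
    return combined


def combine_all(
    bouts: Iterable[ObserverBout],
) -> dict[tuple[str, str, str], list[CombinedBout]]:
    """Group a mixed annotation collection by (movie, fly, behavior) and merge.

    Exactly two observer ids may appear per group (a group annotated by a
    single observer is also accepted); more than two is unsupported.
    """
    groups: dict[tuple[str, str, str], list[ObserverBout]] = {}
    for b in bouts:
        groups.setdefault((b.movie_id, b.fly_id, str(b.behavior)), []).append(b)
    out = {}
    for key, group in groups.items():
        observers = sorted({b.observer_id for b in group})
        if len(observers) > 2:
            raise ValidationError(
                f"{key}: {len(observers)} observers found; exactly two are supported"
            )
        first = [b for b in group if b.observer_id == observers[0]]
        second = [b for b in group if len(observers) == 2 and b.observer_id == observers[1]]
        out[key] = merge_observer_bouts(first, second)
    return out


def frame_combined_scores(
    bouts_a: Sequence[ObserverBout], bouts_b: Sequence[ObserverBout], n_frames: int
) -> np.ndarray:
    """Per-frame combined score: sum of each observer's confidence on frames
    inside one of their bouts, 0 elsewhere.  Returns an int array of length
    ``n_frames`` (frame f is element f-1)."""
    if bouts_a or bouts_b:
        _check_single_universe(list(bouts_a) + list(bouts_b))
    out = np.zeros(n_frames, dtype=int)
    for bouts in (bouts_a, bouts_b):
        for b in bouts:
            if b.end_frame > n_frames:
                raise ValidationError(
                    f"bout ends at frame {b.end_frame} but the track has only "
                    f"{n_frames} frames"
                )
            out[b.start_frame - 1 : b.end_frame] += b.confidence
    return out


def frame_summary(
    bouts_a: Sequence[ObserverBout], bouts_b: Sequence[ObserverBout], n_frames: int
) -> dict:
    """Frame-level agreement statistics: among annotated frames, the fraction
    with combined score 4-6 and the fraction covered by only one observer."""
    scores = frame_combined_scores(bouts_a, bouts_b, n_frames)
    cover = np.zeros(n_frames, dtype=int)
    for bouts in (bouts_a, bouts_b):
        for b in bouts:
            cover[b.start_frame - 1 : b.end_frame] += 1
    annotated = scores > 0
    n_annot = int(annotated.sum())
    return {
        "n_frames": n_frames,
        "n_annotated_frames": n_annot,
        "frac_score_4_6": float((scores >= 4).sum() / n_annot) if n_annot else 0.0,
        "frac_one_observer": float((cover[annotated] == 1).sum() / n_annot) if n_annot else 0.0,
    }


@dataclass
class AnnotationSummary:
    """Score-record-level summary of combined annotations for one behavior."""

    behavior: str
    n_combined_bouts: int = 0
    n_score_records: int = 0
    records_by_pair_type: dict[str, int] = field(default_factory=dict)
    grid: np.ndarray = field(default_factory=lambda: np.zeros((4, 4), dtype=int))
    frac_score_4_6: float = 0.0
    frac_one_observer: float = 0.0
    duration_median_frames: float = 0.0
    duration_median_ms: int = 0
    frame_frac_4_6: float | None = None


def summarize_annotations(
    combined: Mapping[tuple[str, str, str], Sequence[CombinedBout]] | Sequence[CombinedBout],
    frames: Mapping[tuple[str, str, str], np.ndarray] | None,
    movies: Mapping[str, MovieMeta],
) -> dict[str, AnnotationSummary]:
    """Per-behavior summary: score-record counts by pair type, the 4x4
    observer-score grid, 4-6 and one-observer fractions, and durations.

    ``frames`` (optional) maps track keys to frame-combined-score arrays and
    feeds the frame-level 4-6 fraction.
    """
    if isinstance(combined, Mapping):
        bouts = [b for group in combined.values() for b in group]
    else:
        bouts = list(combined)
    for b in bouts:
        if b.movie_id not in movies:
            raise ValidationError(f"movie {b.movie_id!r} missing from metadata")

    summaries: dict[str, AnnotationSummary] = {}
    for behavior in sorted({str(b.behavior) for b in bouts}):
        sel = [b for b in bouts if str(b.behavior) == behavior]
        summary = AnnotationSummary(behavior=behavior)
        summary.n_combined_bouts = len(sel)
        records = [s for b in sel for s in b.score_records]
        summary.n_score_records = len(records)
        for b in sel:
            pt = str(movies[b.movie_id].pair_type)
            summary.records_by_pair_type[pt] = (
                summary.records_by_pair_type.get(pt, 0) + len(b.score_records)
            )
            for ca, cb in b.grid_cells:
                summary.grid[ca, cb] += 1
        n = len(records)
        if n:
            summary.frac_score_4_6 = sum(1 for s in records if s >= 4) / n
            summary.frac_one_observer = (
                sum(len(b.score_records) for b in sel if b.observer_count == 1) / n
            )
            fps = movies[sel[0].movie_id].fps
            stats = bout_duration_stats(sel, fps)
            summary.duration_median_frames = stats["median_frames"]
            summary.duration_median_ms = stats["median_ms"]
        if frames:
            n_annot = 0
            n_high = 0
            for key, arr in frames.items():
                if key[2] != behavior:
                    continue
                arr = np.asarray(arr)
                n_annot += int((arr > 0).sum())
                n_high += int((arr >= 4).sum())
            if n_annot:
                summary.frame_frac_4_6 = n_high / n_annot
        summaries[behavior] = summary
    return summaries


def bout_duration_stats(combined: Sequence[CombinedBout], fps: float) -> dict:
    """Duration histogram and median of combined-bout extents.

    Durations are ``end - start + 1`` frames; milliseconds are derived as
    ``frames * 1000 / fps`` and the median is rounded to the nearest ms.
    """
    if fps <= 0:
        raise ValidationError("fps must be > 0")
    if not combined:
        raise ValidationError("bout_duration_stats needs at least one bout")
    durations = np.array([b.duration_frames for b in combined], dtype=int)
    hist: dict[int, int] = {}
    for d in durations:
        hist[int(d)] = hist.get(int(d), 0) + 1
    median_frames = float(np.median(durations))
    return {
        "durations_frames": durations,
        "histogram": dict(sorted(hist.items())),
        "median_frames": median_frames,
        "median_ms": int(round(median_frames * 1000.0 / fps)),
    }
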