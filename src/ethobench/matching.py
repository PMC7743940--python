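"""Bout- and frame-level matching of combined human annotations to classifier bouts.

A combined human bout is *matched* (true positive) when at least one
classifier bout overlaps it by one or more frames.  Matching is
human-bout-referenced:

* one human bout overlapped by several classifier bouts counts as a
  single matched bout, with its average classifier score taken over the
  union of all frames of the matched classifier bouts;
* one classifier bout overlapping several human bouts yields one matched
  bout per human bout, each inheriting that classifier bout's single
  average score (a classifier bout may therefore contribute to several
  true positives).

A human bout with no overlapping classifier bout is a false negative; a
*virtual* classifier bout spanning the human extent supplies its average
score.  A classifier bout overlapping no human bout is a false positive;
a virtual human bout (score 0) spans the classifier extent.  The human
score attached to a TP/FN record is the region's representative score
(the maximum over its split records).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from ethobench.combine import CombinedBout
from ethobench.io import Behavior, ScoreTrack, ValidationError, track_key
from ethobench.smoothing import ClassifierBout


@dataclass(frozen=True)
class MatchRecord:
    """One matched unit: TP/FN per human bout, FP per unmatched classifier bout."""

    category: str  # "TP" | "FN" | "FP"
    movie_id: str
    fly_id: str
    behavior: Behavior
    human_score: int
    avg_classifier_score: float
    human_start: int
    human_end: int
    classifier_refs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.category not in ("TP", "FN", "FP"):
            raise ValidationError(f"unknown match category {self.category!r}")
        if self.category == "FP" and self.human_score != 0:
            raise ValidationError("a false positive carries human_score 0")
        if self.category in ("TP", "FN") and self.human_score < 1:
            raise ValidationError("a TP/FN record carries human_score >= 1")


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start <= b_end and b_start <= a_end


def _bout_ref(bout: ClassifierBout) -> str:
    return f"{bout.start_frame}:{bout.end_frame}"


def match_bouts(
    human: Sequence[CombinedBout],
    classifier: Sequence[ClassifierBout],
    track: ScoreTrack,
) -> list[MatchRecord]:
    """Match one (movie, fly, behavior) universe of bouts into TP/FN/FP records."""
    keys = {track_key(x) for x in (*human, *classifier, track)}
    if len(keys) > 1:
        raise ValidationError(f"match_bouts expects one (movie, fly, behavior), got {sorted(keys)}")
    scores = track.scores
    n = scores.size
    for c in classifier:
        if c.end_frame > n:
            raise ValidationError(
                f"classifier bout [{c.start_frame},{c.end_frame}] exceeds the "
                f"{n}-frame track"
            )
    for h in human:
        if h.end_frame > n:
            raise ValidationError(
                f"human bout [{h.start_frame},{h.end_frame}] exceeds the {n}-frame track"
            )

    records: list[MatchRecord] = []
    matched_classifier: set[int] = set()
    for h in human:
        hits = [
            i
            for i, c in enumerate(classifier)
            if _overlaps(h.start_frame, h.end_frame, c.start_frame, c.end_frame)
        ]
        if hits:
            matched_classifier.update(hits)
            mask = np.zeros(n, dtype=bool)
            for i in hits:
                c = classifier[i]
                mask[c.start_frame - 1 : c.end_frame] = True
            avg = float(scores[mask].mean())
            records.append(
                MatchRecord(
                    category="TP",
                    movie_id=h.movie_id,
                    fly_id=h.fly_id,
                    behavior=h.behavior,
                    human_score=h.representative_score,
                    avg_classifier_score=avg,
                    human_start=h.start_frame,
                    human_end=h.end_frame,
                    classifier_refs=tuple(_bout_ref(classifier[i]) for i in hits),
                )
            )
        else:
            # virtual classifier bout spanning the human extent
            avg = float(scores[h.start_frame - 1 : h.end_frame].mean())
            records.append(
                MatchRecord(
                    category="FN",
                    movie_id=h.movie_id,
                    fly_id=h.fly_id,
                    behavior=h.behavior,
                    human_score=h.representative_score,
                    avg_classifier_score=avg,
                    human_start=h.start_frame,
                    human_end=h.end_frame,
                )
            )
    for i, c in enumerate(classifier):
        if i in matched_classifier:
            continue
        records.append(
            MatchRecord(
                category="FP",
                movie_id=c.movie_id,
                fly_id=c.fly_id,
                behavior=c.behavior,
                human_score=0,
                avg_classifier_score=c.avg_score,
                human_start=c.start_frame,  # virtual human bout over the classifier extent
                human_end=c.end_frame,
                classifier_refs=(_bout_ref(c),),
            )
        )
    return records


def match_all(
    human: Mapping[tuple[str, str, str], Sequence[CombinedBout]],
    classifier: Mapping[tuple[str, str, str], Sequence[ClassifierBout]],
    tracks: Iterable[ScoreTrack],
) -> list[MatchRecord]:
    """Run match_bouts over every track's universe; universes absent from
    ``human`` or ``classifier`` are treated as empty."""
    records: list[MatchRecord] = []
    for track in tracks:
        key = track_key(track)
        records.extend(
            match_bouts(list(human.get(key, ())), list(classifier.get(key, ())), track)
        )
    return records


@dataclass
class FrameMatchTable:
    """Per-frame TP/FN/FP/TN classification of one track against combined scores."""

    human_scores: np.ndarray
    classifier_scores: np.ndarray
    categories: np.ndarray  # array of 'TP'|'FN'|'FP'|'TN'
    threshold: float

    @property
    def counts(self) -> dict[str, int]:
        return {c: int((self.categories == c).sum()) for c in ("TP", "FN", "FP", "TN")}


def match_frames(
    frames: np.ndarray, track: ScoreTrack, threshold: float
) -> FrameMatchTable:
    """Frame-based matching on raw thresholded scores (no smoothing).

    A frame is TP when its score is strictly above the threshold and its
    combined human score is >= 1; FN when annotated but at/below threshold;
    FP when above threshold and unannotated; TN otherwise.
    """
    human = np.asarray(frames, dtype=int)
    scores = track.scores
    if human.size != scores.size:
        raise ValidationError(
            f"length mismatch: {human.size} human-score frames vs "
            f"{scores.size} classifier-score frames"
        )
    on = scores > threshold
    annotated = human >= 1
    categories = np.full(human.size, "TN", dtype="<U2")
    categories[on & annotated] = "TP"
    categories[~on & annotated] = "FN"
    categories[on & ~annotated] = "FP"
    return FrameMatchTable(
        human_scores=human,
        classifier_scores=scores,
        categories=categories,
        threshold=threshold,
    )
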