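"""Smoothing of per-frame classifier scores into bouts.

A frame is "on" when its score is strictly greater than the detection
threshold.  Runs of "off" frames no longer than ``max_gap`` that are
flanked on both sides by "on" frames are filled (their scores are kept
intact), and the resulting maximal "on" runs of at least
``min_bout_len`` frames become classifier bouts.  Gap filling precedes
the length filter; gaps at the track edges are never filled, and a gap
longer than ``max_gap`` is never filled even partially.

The per-bout average score is the mean of the original frame scores over
the whole bout, filled frames included.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ethobench.io import Behavior, ScoreTrack, ValidationError
from ethobench.combine import CombinedBout


@dataclass(frozen=True)
class SmoothingParams:
    """Detection threshold plus the two smoothing filter parameters (frames)."""

    threshold: float
    max_gap: int
    min_bout_len: int

    def __post_init__(self) -> None:
        if self.max_gap < 0:
            raise ValidationError("max_gap must be >= 0")
        if self.min_bout_len < 1:
            raise ValidationError("min_bout_len must be >= 1")


@dataclass(frozen=True)
class ClassifierBout:
    movie_id: str
    fly_id: str
    behavior: Behavior
    start_frame: int
    end_frame: int
    avg_score: float
    n_filled_gap_frames: int

    @property
    def duration_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """0-based inclusive (start, end) index pairs of True runs."""
    if mask.size == 0:
        return []
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def detect_bouts(track: ScoreTrack, params: SmoothingParams) -> list[ClassifierBout]:
    """Threshold, gap-fill and length-filter one score track into bouts."""
    scores = track.scores
    if scores.size == 0:
        return []
    on = scores > params.threshold

    filled = on.copy()
    n_filled_per_gap: dict[tuple[int, int], int] = {}
    if params.max_gap > 0:
        for start, end in _runs(~on):
            if start == 0 or end == on.size - 1:
                continue  # edge gaps have no flanking "on" frame on one side
            length = end - start + 1
            if length <= params.max_gap:
                filled[start : end + 1] = True
                n_filled_per_gap[(start, end)] = length

    bouts: list[ClassifierBout] = []
    for start, end in _runs(filled):
        if end - start + 1 < params.min_bout_len:
            continue
        n_filled = sum(
            n for (gs, ge), n in n_filled_per_gap.items() if gs >= start and ge <= end
        )
        bouts.append(
            ClassifierBout(
                movie_id=track.movie_id,
                fly_id=track.fly_id,
                behavior=track.behavior,
                start_frame=start + 1,
                end_frame=end + 1,
                avg_score=float(scores[start : end + 1].mean()),
                n_filled_gap_frames=n_filled,
            )
        )
    return bouts


def derive_min_bout_length(
    human_bouts: Sequence[CombinedBout], keep_fraction: float = 0.98
) -> int:
    """Largest minimum-bout-length L (frames) that keeps at least
    ``keep_fraction`` of the human-annotated bouts (those with duration >= L).

    With the default 0.98 this eliminates only bouts shorter than at least
    98% of the manually annotated bouts.
    """
    if not human_bouts:
        raise ValidationError("derive_min_bout_length needs at least one bout")
    if not 0 < keep_fraction <= 1:
        raise ValidationError("keep_fraction must be in (0, 1]")
    durations = np.sort(np.array([b.duration_frames for b in human_bouts]))
    n = durations.size
    for length in np.unique(durations)[::-1]:
        kept = (durations >= length).sum() / n
        if kept >= keep_fraction:
            return int(length)
    return int(durations[0])  # unreachable: L = min duration always keeps all
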