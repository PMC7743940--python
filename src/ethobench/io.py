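"""Tabular I/O: annotation, score, movie and feature tables in documented CSV/XLSX schemas.

Frame indexing convention
-------------------------
All in-memory frame indices are **1-based** and intervals are inclusive,
``[start_frame, end_frame]``, so a bout's length in frames is
``end - start + 1``.  Tables exported from 0-based tooling are ingested
with ``index_base=0``, which shifts both endpoints up by one.
Milliseconds are a display unit only: one frame is ``1000 / fps`` ms
(16.7 ms at the 60 fps used throughout, printed as 17 ms).

Schemas (CSV, UTF-8, header row required)
-----------------------------------------
annotations : movie_id, fly_id, behavior, observer_id, start_frame, end_frame, confidence
scores      : movie_id, fly_id, behavior, frame, score        (long format, frames contiguous from 1)
movies      : movie_id, pair_type, fps, n_frames, role, wells (wells ';'-joined, may be empty)
features    : movie_id, fly_id, frame, <13 feature columns>
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, fields, is_dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A table is missing a required column or has an unusable layout."""


class ValidationError(ValueError):
    """A row violates a domain-type invariant."""


class Behavior(enum.StrEnum):
    WING_EXTENSION = "wing_extension"
    LUNGE = "lunge"
    HEADBUTT = "headbutt"


class PairType(enum.StrEnum):
    MALE_MALE = "male_male"
    MALE_FEMALE = "male_female"
    FEMALE_FEMALE = "female_female"
    OTHER = "other"


class Role(enum.StrEnum):
    TRAINING = "training"
    EVALUATION = "evaluation"


#: Accepted spellings of pair types, lower-cased.  Includes the symbols used
#: in movie inventories exported from spreadsheets.
_PAIR_ALIASES: dict[str, PairType] = {
    "male_male": PairType.MALE_MALE,
    "mm": PairType.MALE_MALE,
    "♂ vs. ♂": PairType.MALE_MALE,
    "♂ vs ♂": PairType.MALE_MALE,
    "m vs. m": PairType.MALE_MALE,
    "male_female": PairType.MALE_FEMALE,
    "mf": PairType.MALE_FEMALE,
    "♂ vs. ♀": PairType.MALE_FEMALE,
    "♂ vs ♀": PairType.MALE_FEMALE,
    "m vs. f": PairType.MALE_FEMALE,
    "female_female": PairType.FEMALE_FEMALE,
    "ff": PairType.FEMALE_FEMALE,
    "♀ vs. ♀": PairType.FEMALE_FEMALE,
    "♀ vs ♀": PairType.FEMALE_FEMALE,
    "f vs. f": PairType.FEMALE_FEMALE,
    "other": PairType.OTHER,
}

#: The 13 per-frame tracker features (4 of them depend on both flies'
#: positions: the "relative" features).
FEATURE_NAMES: tuple[str, ...] = (
    "log_max_wing_ang",
    "facing_angle",
    "norm_mean_wing_length",
    "log_min_wing_ang",
    "dist_to_wall",
    "norm_axis_ratio",
    "log_fg_body_ratio",
    "leg_dist",
    "log_vel",
    "dist_to_other",
    "log_ang_vel",
    "norm_contrast",
    "angle_between",
)
RELATIVE_FEATURES: frozenset[str] = frozenset(
    {"facing_angle", "leg_dist", "dist_to_other", "angle_between"}
)


def parse_pair_type(value: str) -> PairType:
    key = str(value).strip().lower()
    try:
        return _PAIR_ALIASES[key]
    except KeyError:
        raise ValidationError(
            f"unknown pair type {value!r}; accepted values: "
            + ", ".join(sorted(set(_PAIR_ALIASES)))
        ) from None


def parse_behavior(value: str) -> Behavior:
    try:
        return Behavior(str(value).strip().lower())
    except ValueError:
        raise ValidationError(
            f"unknown behavior {value!r}; accepted values: "
            + ", ".join(b.value for b in Behavior)
        ) from None


@dataclass(frozen=True)
class MovieMeta:
    """One movie's metadata: sex combination, length, sampling rate, role."""

    movie_id: str
    pair_type: PairType
    fps: float = 60.0
    n_frames: int = 0
    role: Role = Role.EVALUATION
    wells: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValidationError(f"movie {self.movie_id}: fps must be > 0")
        if self.n_frames < 1:
            raise ValidationError(f"movie {self.movie_id}: n_frames must be >= 1")

    @property
    def minutes(self) -> float:
        return self.n_frames / self.fps / 60.0


@dataclass(frozen=True)
class ObserverBout:
    """One observer's annotation of one behavioral bout, graded 1-3.

    The grade is the observer's subjective certainty that the bout is the
    named behavior: 1 'maybe', 2 'probably', 3 'definitely'.
    """

    movie_id: str
    fly_id: str
    behavior: Behavior
    observer_id: str
    start_frame: int
    end_frame: int
    confidence: int

    def __post_init__(self) -> None:
        if self.start_frame > self.end_frame:
            raise ValidationError(
                f"bout {self.movie_id}/{self.fly_id}: start_frame "
                f"{self.start_frame} > end_frame {self.end_frame}"
            )
        if self.start_frame < 1:
            raise ValidationError(
                f"bout {self.movie_id}/{self.fly_id}: frame indices are 1-based, "
                f"got start_frame {self.start_frame}"
            )
        if self.confidence not in (1, 2, 3):
            raise ValidationError(
                f"bout {self.movie_id}/{self.fly_id}: confidence must be on the "
                f"1-3 scale, got {self.confidence}"
            )

    @property
    def duration_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    def overlaps(self, other: "ObserverBout") -> bool:
        return self.start_frame <= other.end_frame and other.start_frame <= self.end_frame


@dataclass(frozen=True)
class ScoreTrack:
    """Per-frame real-valued classifier confidence for one fly/behavior/movie."""

    movie_id: str
    fly_id: str
    behavior: Behavior
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 1:
            raise ValidationError("scores must be a 1-D sequence")
        if scores.size and not np.all(np.isfinite(scores)):
            bad = int(np.flatnonzero(~np.isfinite(scores))[0]) + 1
            raise ValidationError(
                f"track {self.movie_id}/{self.fly_id}/{self.behavior}: "
                f"non-finite score at frame {bad}"
            )

    @property
    def n_frames(self) -> int:
        return int(self.scores.size)

    def __eq__(self, other: object) -> bool:  # array field needs explicit comparison
        if not isinstance(other, ScoreTrack):
            return NotImplemented
        return (
            self.movie_id == other.movie_id
            and self.fly_id == other.fly_id
            and self.behavior == other.behavior
            and np.array_equal(self.scores, other.scores)
        )


TrackKey = tuple[str, str, str]


def track_key(obj) -> TrackKey:
    return (obj.movie_id, obj.fly_id, str(obj.behavior))


# ---------------------------------------------------------------------------
# readers


def _load_frame(path: str | Path, dialect: str, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if dialect == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
    elif dialect == "xlsx":
        df = pd.read_excel(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'xlsx'")
    if column_map:
        df = df.rename(columns=dict(column_map))
    return df


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing required column(s): {', '.join(missing)}")


def read_annotations(
    path: str | Path,
    dialect: str = "csv",
    *,
    index_base: int = 1,
    merge_observer_overlaps: bool = False,
    column_map: Mapping[str, str] | None = None,
    movies: Mapping[str, MovieMeta] | None = None,
) -> list[ObserverBout]:
    """Read observer bout annotations.

    ``index_base=0`` converts 0-based inclusive frame intervals to the
    package's 1-based convention.  Overlapping bouts from the same observer
    normally signal corrupted input (the annotation tool prevents them) and
    raise; ``merge_observer_overlaps=True`` instead merges each overlapping
    run into one bout keeping the maximum confidence.
    """
    df = _load_frame(path, dialect, column_map)
    required = ["movie_id", "fly_id", "behavior", "observer_id", "start_frame", "end_frame", "confidence"]
    _require_columns(df, required, "annotations")

    bouts: list[ObserverBout] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # row 1 is the header
        conf = row.confidence
        if pd.isna(conf) or int(conf) != conf or int(conf) not in (1, 2, 3):
            raise ValidationError(
                f"{path}, row {i}: confidence {conf!r} is not on the 1-3 scale"
            )
        start = int(row.start_frame) + (1 - index_base)
        end = int(row.end_frame) + (1 - index_base)
        if start > end:
            raise ValidationError(f"{path}, row {i}: start_frame {start} > end_frame {end}")
        try:
            bout = ObserverBout(
                movie_id=str(row.movie_id),
                fly_id=str(row.fly_id),
                behavior=parse_behavior(row.behavior),
                observer_id=str(row.observer_id),
                start_frame=start,
                end_frame=end,
                confidence=int(conf),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}, row {i}: {exc}") from None
        if movies is not None:
            meta = movies.get(bout.movie_id)
            if meta is None:
                raise ValidationError(f"{path}, row {i}: unknown movie {bout.movie_id!r}")
            if bout.end_frame > meta.n_frames:
                raise ValidationError(
                    f"{path}, row {i}: end_frame {bout.end_frame} exceeds "
                    f"movie length {meta.n_frames}"
                )
        bouts.append(bout)

    return _check_same_observer_overlaps(bouts, merge=merge_observer_overlaps)


def _check_same_observer_overlaps(bouts: list[ObserverBout], merge: bool) -> list[ObserverBout]:
    groups: dict[tuple, list[ObserverBout]] = {}
    order: dict[int, int] = {id(b): i for i, b in enumerate(bouts)}
    for b in bouts:
        groups.setdefault((b.movie_id, b.fly_id, str(b.behavior), b.observer_id), []).append(b)
    out: list[ObserverBout] = []
    for key, group in groups.items():
        group = sorted(group, key=lambda b: (b.start_frame, b.end_frame))
        merged: list[ObserverBout] = []
        for b in group:
            if merged and b.start_frame <= merged[-1].end_frame:
                if not merge:
                    raise ValidationError(
                        f"observer {key[3]} has overlapping bouts "
                        f"[{merged[-1].start_frame},{merged[-1].end_frame}] and "
                        f"[{b.start_frame},{b.end_frame}] for {key[0]}/{key[1]}/{key[2]}; "
                        "pass merge_observer_overlaps=True to union them"
                    )
                prev = merged.pop()
                merged.append(
                    replace(
                        prev,
                        end_frame=max(prev.end_frame, b.end_frame),
                        confidence=max(prev.confidence, b.confidence),
                    )
                )
            else:
                merged.append(b)
        out.extend(merged)
    # preserve input row order for untouched bouts
    out.sort(key=lambda b: order.get(id(b), len(order)))
    return out


def read_scores(
    path: str | Path,
    dialect: str = "csv",
    *,
    column_map: Mapping[str, str] | None = None,
) -> list[ScoreTrack]:
    """Read long-format per-frame classifier scores into one track per
    (movie, fly, behavior).  Frames must be contiguous from 1."""
    df = _load_frame(path, dialect, column_map)
    _require_columns(df, ["movie_id", "fly_id", "behavior", "frame", "score"], "scores")

    tracks: list[ScoreTrack] = []
    for (movie, fly, behavior), grp in df.groupby(
        ["movie_id", "fly_id", "behavior"], sort=False
    ):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy(dtype=int)
        expected = np.arange(1, len(frames) + 1)
        if not np.array_equal(frames, expected):
            first_missing = int(expected[frames != expected][0]) if len(frames) else 1
            # frames could also repeat or start late; report the first deviation
            present = set(frames.tolist())
            gap = next((f for f in range(1, int(frames.max()) + 2) if f not in present), 1)
            raise ValidationError(
                f"track {movie}/{fly}/{behavior}: frames are not contiguous from 1 "
                f"(first missing frame: {gap})"
            )
        scores = grp["score"].to_numpy(dtype=float)
        if not np.all(np.isfinite(scores)):
            bad = int(np.flatnonzero(~np.isfinite(scores))[0]) + 1
            raise ValidationError(
                f"track {movie}/{fly}/{behavior}: non-finite score at frame {bad}"
            )
        tracks.append(
            ScoreTrack(str(movie), str(fly), parse_behavior(behavior), scores)
        )
    return tracks


def read_movies(
    path: str | Path,
    dialect: str = "csv",
    *,
    column_map: Mapping[str, str] | None = None,
) -> list[MovieMeta]:
    df = _load_frame(path, dialect, column_map)
    _require_columns(df, ["movie_id", "pair_type", "n_frames"], "movies")
    movies: list[MovieMeta] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        movie_id = str(row.movie_id)
        if movie_id in seen:
            raise ValidationError(f"{path}, row {i}: duplicate movie_id {movie_id!r}")
        seen.add(movie_id)
        fps = getattr(row, "fps", None)
        if fps is None or (isinstance(fps, float) and math.isnan(fps)):
            logger.info("movie %s: fps not given, defaulting to 60", movie_id)
            fps = 60.0
        role = getattr(row, "role", None)
        if role is None or (isinstance(role, float) and math.isnan(role)):
            role = Role.EVALUATION
        else:
            role = Role(str(role).strip().lower())
        wells_raw = getattr(row, "wells", None)
        if wells_raw is None or (isinstance(wells_raw, float) and math.isnan(wells_raw)):
            wells: tuple[str, ...] = ()
        else:
            wells = tuple(w for w in str(wells_raw).split(";") if w)
        try:
            movies.append(
                MovieMeta(
                    movie_id=movie_id,
                    pair_type=parse_pair_type(row.pair_type),
                    fps=float(fps),
                    n_frames=int(row.n_frames),
                    role=role,
                    wells=wells,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}, row {i}: {exc}") from None
    return movies


def movies_by_id(movies: Iterable[MovieMeta]) -> dict[str, MovieMeta]:
    return {m.movie_id: m for m in movies}


# ---------------------------------------------------------------------------
# writer


def _flatten(value):
    """Serialize list-like record fields as ';'-joined strings."""
    if isinstance(value, (list, tuple)):
        return ";".join(str(v) for v in value)
    if isinstance(value, enum.Enum):
        return value.value
    return value


def _exact_floats(df: pd.DataFrame) -> pd.DataFrame:
    """Render float columns with Python's shortest round-trippable repr
    (pandas' CSV writer truncates to 15 significant digits)."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(repr)
    return out


_SCHEMAS = {
    "annotations": ["movie_id", "fly_id", "behavior", "observer_id", "start_frame", "end_frame", "confidence"],
    "scores": ["movie_id", "fly_id", "behavior", "frame", "score"],
    "movies": ["movie_id", "pair_type", "fps", "n_frames", "role", "wells"],
}


def write_table(records, path: str | Path, *, kind: str | None = None) -> None:
    """Write a homogeneous collection of records to CSV (UTF-8, stable column order).

    ScoreTracks are exploded to the long scores schema.  List-valued fields
    (``score_records``, ``wells``, ``classifier_refs``) are ';'-joined.
    An empty collection writes a header-only file; pass ``kind`` (one of
    ``annotations``/``scores``/``movies``) to choose its header.
    """
    records = list(records)
    path = Path(path)
    if not records:
        columns = _SCHEMAS.get(kind or "", [])
        pd.DataFrame(columns=columns).to_csv(path, index=False, encoding="utf-8")
        return
    first = records[0]
    if isinstance(first, ScoreTrack):
        parts = []
        for t in records:
            parts.append(
                pd.DataFrame(
                    {
                        "movie_id": t.movie_id,
                        "fly_id": t.fly_id,
                        "behavior": str(t.behavior),
                        "frame": np.arange(1, t.n_frames + 1),
                        "score": t.scores,
                    }
                )
            )
        _exact_floats(pd.concat(parts, ignore_index=True)).to_csv(
            path, index=False, encoding="utf-8"
        )
        return
    if not is_dataclass(first):
        raise TypeError(f"cannot serialize records of type {type(first).__name__}")
    cols = [f.name for f in fields(first)]
    rows = [{c: _flatten(getattr(r, c)) for c in cols} for r in records]
    _exact_floats(pd.DataFrame(rows, columns=cols)).to_csv(
        path, index=False, encoding="utf-8"
    )
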