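"""Generative model of a two-observer behavior-annotation study.

The generator emulates the statistical structure the evaluation pipeline
assumes, so every stage is testable without any recorded video:

* movies of fly pairs in several sex combinations, 60 fps;
* ground-truth behavior bouts with behavior-specific prevalence per pair
  type and log-normal bout durations (lunges ~5 frames / 83 ms median,
  headbutts ~4 frames / 67 ms, wing extensions heavy-tailed);
* a latent per-bout *salience* S ~ Uniform(0,1) that drives both observer
  behavior and classifier scores, encoding the premise that variability in
  the behavior itself is what both humans and classifiers respond to;
* two observers who each detect a bout with probability
  logistic(a0 + a1*S), grade it 1-3 by thresholding S plus per-observer
  Gaussian noise, and jitter the bout boundaries (defaults calibrated so
  ~27% of combined bouts are seen by a single observer, inside the
  25-35% range typical of trained annotators);
* per-frame classifier score tracks whose on-bout level is b0 + b1*S with
  AR(1) noise, plus an off-bout baseline and occasional distractor bumps
  that create controllable false-positive pressure.  b1 is the
  score-salience coupling; b1 = 0 generates data with no association
  between human confidence and classifier score.

Four independent RNG streams (truth / observer A / observer B / scores)
are spawned from the single seed, so changing one component's parameters
leaves the other components' draws identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal, special

from ethobench.io import (
    Behavior,
    MovieMeta,
    ObserverBout,
    PairType,
    Role,
    ScoreTrack,
    ValidationError,
)


@dataclass(frozen=True)
class DurationModel:
    """Log-normal bout duration in frames (median = exp(mu), dispersion sigma)."""

    median_frames: float
    sigma: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        draws = rng.lognormal(math.log(self.median_frames), self.sigma, size=n)
        return np.maximum(1, np.rint(draws)).astype(int)


@dataclass(frozen=True)
class BehaviorModel:
    duration: DurationModel
    prevalence: Mapping[str, float]  # bouts per minute, keyed by pair type


@dataclass(frozen=True)
class ObserverModel:
    a0: float = 0.3
    a1: float = 3.0
    conf_noise_sd: float = 0.15
    conf_thresholds: tuple[float, float] = (1 / 3, 2 / 3)
    threshold_offsets: tuple[float, float] = (0.0, 0.0)  # per-observer shift on S+noise
    boundary_jitter_sd: float = 1.0  # frames

    def detection_prob(self, salience: np.ndarray) -> np.ndarray:
        return special.expit(self.a0 + self.a1 * np.asarray(salience))


@dataclass(frozen=True)
class ScoreModel:
    b0: float = 0.02
    b1: float = 0.35  # score-salience coupling
    ar_phi: float = 0.8
    ar_sd: float = 0.05
    baseline_mean: float = 0.02
    baseline_sd: float = 0.01
    distractor_rate_per_min: float = 0.4
    distractor_amp: float = 0.35
    distractor_len: int = 4


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int
    movies: tuple[tuple[str, int, float], ...]  # (pair_type, n_frames, fps)
    behaviors: Mapping[str, BehaviorModel]
    observer: ObserverModel = ObserverModel()
    score: ScoreModel = ScoreModel()
    salience: str = "uniform"  # or "beta"
    beta_params: tuple[float, float] = (2.0, 2.0)
    n_flies_per_movie: int = 2

    def sample_salience(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.salience == "uniform":
            return rng.uniform(size=n)
        if self.salience == "beta":
            return rng.beta(*self.beta_params, size=n)
        raise ValidationError(f"unknown salience model {self.salience!r}")


def default_config(
    seed: int,
    *,
    minutes_per_movie: float = 5.0,
    n_movies_per_type: int = 2,
    coupling: float | None = None,
    fps: float = 60.0,
) -> SyntheticConfig:
    """Study-shaped default configuration.

    Movies of male-male, male-female and female-female pairs at 60 fps;
    lunges only in male-male pairs, headbutts predominantly in
    female-female pairs, wing extensions mostly male-to-female.  Duration
    medians: 5 frames (83 ms) for lunges, 4 frames (67 ms) for headbutts,
    30 frames for the heavy-tailed wing extensions.
    """
    n_frames = int(round(minutes_per_movie * 60 * fps))
    movies = []
    for pt in ("male_male", "male_female", "female_female"):
        for i in range(n_movies_per_type):
            movies.append((pt, n_frames, fps))
    behaviors = {
        "wing_extension": BehaviorModel(
            duration=DurationModel(median_frames=30.0, sigma=1.1),
            prevalence={"male_male": 0.5, "male_female": 4.0, "female_female": 0.0, "other": 1.0},
        ),
        "lunge": BehaviorModel(
            duration=DurationModel(median_frames=5.0, sigma=0.35),
            prevalence={"male_male": 3.0, "male_female": 0.0, "female_female": 0.0, "other": 0.0},
        ),
        "headbutt": BehaviorModel(
            duration=DurationModel(median_frames=4.0, sigma=0.35),
            prevalence={"male_male": 0.0, "male_female": 0.0, "female_female": 3.0, "other": 0.3},
        ),
    }
    score = ScoreModel() if coupling is None else ScoreModel(b1=coupling)
    return SyntheticConfig(seed=seed, movies=tuple(movies), behaviors=behaviors, score=score)


@dataclass(frozen=True)
class TruthBout:
    movie_id: str
    fly_id: str
    behavior: str
    start_frame: int
    end_frame: int
    salience: float
    bout_id: int


@dataclass
class SyntheticTruth:
    """A complete generated dataset with full provenance."""

    config: SyntheticConfig
    movies: list[MovieMeta]
    truth: list[TruthBout]
    annotations: list[ObserverBout]
    tracks: list[ScoreTrack]
    #: maps each observer bout (its index in ``annotations``) to its truth bout_id
    annotation_provenance: list[int] = field(default_factory=list)

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "bout_id": t.bout_id,
                    "movie_id": t.movie_id,
                    "fly_id": t.fly_id,
                    "behavior": t.behavior,
                    "start_frame": t.start_frame,
                    "end_frame": t.end_frame,
                    "salience": t.salience,
                }
                for t in self.truth
            ],
            columns=[
                "bout_id", "movie_id", "fly_id", "behavior",
                "start_frame", "end_frame", "salience",
            ],
        )


def _place_bouts(
    rng: np.random.Generator, durations: np.ndarray, n_frames: int, min_sep: int = 2
) -> list[tuple[int, int]]:
    """Place bouts of the given durations uniformly at random without overlap,
    keeping ``min_sep`` empty frames between neighbors.  1-based intervals."""
    n = durations.size
    if n == 0:
        return []
    occupied = int(durations.sum()) + min_sep * (n - 1)
    free = n_frames - occupied
    if free < 0:
        raise ValidationError(
            f"cannot place {n} bouts totalling {occupied} frames in a "
            f"{n_frames}-frame track"
        )
    # split the free space into n+1 gaps via an ordered uniform draw
    cuts = np.sort(rng.integers(0, free + 1, size=n))
    gaps = np.diff(np.concatenate(([0], cuts)))
    order = rng.permutation(n)  # durations in random order along the track
    starts = []
    pos = 1
    for gap, idx in zip(gaps, order):
        pos += int(gap)
        starts.append((pos, pos + int(durations[idx]) - 1, idx))
        pos += int(durations[idx]) + min_sep
    # return in the original duration order
    placed = [(0, 0)] * n
    for start, end, idx in starts:
        placed[idx] = (start, end)
    return placed


def generate_truth(config: SyntheticConfig, rng: np.random.Generator) -> tuple[list[MovieMeta], list[TruthBout]]:
    movies: list[MovieMeta] = []
    truth: list[TruthBout] = []
    bout_id = 0
    for i, (pair_type, n_frames, fps) in enumerate(config.movies):
        movie_id = f"synthetic_movie_{i:02d}"
        movies.append(
            MovieMeta(
                movie_id=movie_id,
                pair_type=PairType(pair_type),
                fps=fps,
                n_frames=n_frames,
                role=Role.EVALUATION,
            )
        )
        minutes = n_frames / fps / 60.0
        for f in range(config.n_flies_per_movie):
            fly_id = f"fly{f + 1}"
            for behavior, model in config.behaviors.items():
                rate = model.prevalence.get(pair_type, 0.0)
                expected_frames = rate * minutes * model.duration.median_frames
                if expected_frames > 0.5 * n_frames:
                    raise ValidationError(
                        f"infeasible config: behavior {behavior} at {rate}/min expects "
                        f"{expected_frames:.0f} bout frames in a {n_frames}-frame track"
                    )
                n = rng.poisson(rate * minutes)
                durations = model.duration.sample(rng, n)
                salience = config.sample_salience(rng, n)
                for (start, end), s in zip(
                    _place_bouts(rng, durations, n_frames), salience
                ):
                    truth.append(
                        TruthBout(movie_id, fly_id, behavior, start, end, float(s), bout_id)
                    )
                    bout_id += 1
    return movies, truth


def generate_observer_annotations(
    truth: Sequence[TruthBout],
    observer: ObserverModel,
    rng: np.random.Generator,
    observer_id: str,
    observer_index: int,
    movies: Mapping[str, MovieMeta],
) -> tuple[list[ObserverBout], list[int]]:
    """One observer's noisy annotation of the ground truth.

    Detection is Bernoulli(logistic(a0 + a1*S)); confidence thresholds the
    latent salience plus Gaussian noise; boundaries are jittered but
    clipped so the annotated bout always overlaps its truth bout, stays in
    the track, and never overlaps the observer's neighboring annotations.
    """
    t1, t2 = observer.conf_thresholds
    offset = observer.threshold_offsets[observer_index]
    bouts: list[ObserverBout] = []
    provenance: list[int] = []
    by_track: dict[tuple[str, str, str], list[TruthBout]] = {}
    for t in truth:
        by_track.setdefault((t.movie_id, t.fly_id, t.behavior), []).append(t)
    for key, group in by_track.items():
        group = sorted(group, key=lambda t: t.start_frame)
        n_frames = movies[key[0]].n_frames
        prev_end = 0
        for i, t in enumerate(group):
            detect = rng.uniform() < observer.detection_prob(np.array(t.salience))
            # draw jitters and the confidence noise unconditionally so the
            # stream stays aligned whether or not the bout is detected
            noise = rng.normal(0.0, observer.conf_noise_sd)
            j_start = int(round(rng.normal(0.0, observer.boundary_jitter_sd)))
            j_end = int(round(rng.normal(0.0, observer.boundary_jitter_sd)))
            if not detect:
                continue
            graded = t.salience + noise + offset
            confidence = 1 if graded < t1 else (2 if graded < t2 else 3)
            start = t.start_frame + j_start
            end = t.end_frame + j_end
            start, end = min(start, t.end_frame), max(end, t.start_frame)  # keep overlap
            start = max(start, 1, prev_end + 1)
            end = min(end, n_frames)
            next_start = group[i + 1].start_frame if i + 1 < len(group) else n_frames + 1
            end = min(end, next_start - 1)
            if start > end:
                continue  # jitter squeezed the bout away entirely
            bouts.append(
                ObserverBout(
                    movie_id=t.movie_id,
                    fly_id=t.fly_id,
                    behavior=Behavior(t.behavior),
                    observer_id=observer_id,
                    start_frame=start,
                    end_frame=end,
                    confidence=confidence,
                )
            )
            provenance.append(t.bout_id)
            prev_end = end
    return bouts, provenance


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary-variance AR(1) noise: x_t = phi x_{t-1} + sqrt(1-phi^2) e_t."""
    innovations = rng.normal(0.0, sd, size=n)
    scale = math.sqrt(max(1e-12, 1.0 - phi**2))
    return signal.lfilter([scale], [1.0, -phi], innovations)


def generate_score_track(
    truth: Sequence[TruthBout],
    score: ScoreModel,
    rng: np.random.Generator,
    movie_id: str,
    fly_id: str,
    behavior: str,
    n_frames: int,
    fps: float,
) -> ScoreTrack:
    """Per-frame classifier confidence for one (movie, fly, behavior).

    Off-bout frames follow a low AR(1) baseline with Poisson-placed
    distractor bumps; on-bout frames sit at b0 + b1*S plus AR(1) noise.
    Scores are clipped to [0, 1].
    """
    base = score.baseline_mean + _ar1(rng, n_frames, score.ar_phi, score.baseline_sd)
    level = np.zeros(n_frames)
    on = np.zeros(n_frames, dtype=bool)
    for t in truth:
        level[t.start_frame - 1 : t.end_frame] = score.b0 + score.b1 * t.salience
        on[t.start_frame - 1 : t.end_frame] = True
    noise_on = _ar1(rng, n_frames, score.ar_phi, score.ar_sd)
    scores = np.where(on, level + noise_on, base)
    minutes = n_frames / fps / 60.0
    n_bumps = rng.poisson(score.distractor_rate_per_min * minutes)
    for _ in range(n_bumps):
        pos = int(rng.integers(0, max(1, n_frames - score.distractor_len)))
        bump = score.distractor_amp * np.sin(
            np.linspace(0, math.pi, score.distractor_len)
        )
        scores[pos : pos + score.distractor_len] += bump
    return ScoreTrack(movie_id, fly_id, Behavior(behavior), np.clip(scores, 0.0, 1.0))


def generate_dataset(config: SyntheticConfig) -> SyntheticTruth:
    """Generate the full dataset: movies, ground truth, two observers' graded
    annotations, and classifier score tracks.  Deterministic given the seed."""
    ss = np.random.SeedSequence(config.seed)
    rng_truth, rng_a, rng_b, rng_scores = [np.random.default_rng(c) for c in ss.spawn(4)]
    movies, truth = generate_truth(config, rng_truth)
    meta = {m.movie_id: m for m in movies}

    bouts_a, prov_a = generate_observer_annotations(truth, config.observer, rng_a, "obsA", 0, meta)
    bouts_b, prov_b = generate_observer_annotations(truth, config.observer, rng_b, "obsB", 1, meta)

    truth_by_track: dict[tuple[str, str, str], list[TruthBout]] = {}
    for t in truth:
        truth_by_track.setdefault((t.movie_id, t.fly_id, t.behavior), []).append(t)
    tracks: list[ScoreTrack] = []
    for m in movies:
        for f in range(config.n_flies_per_movie):
            fly_id = f"fly{f + 1}"
            for behavior in config.behaviors:
                tracks.append(
                    generate_score_track(
                        truth_by_track.get((m.movie_id, fly_id, behavior), []),
                        config.score,
                        rng_scores,
                        m.movie_id,
                        fly_id,
                        behavior,
                        m.n_frames,
                        m.fps,
                    )
                )
    return SyntheticTruth(
        config=config,
        movies=movies,
        truth=truth,
        annotations=bouts_a + bouts_b,
        tracks=tracks,
        annotation_provenance=prov_a + prov_b,
    )
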