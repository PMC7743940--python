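"""The generative model: determinism, calibration, and coupling behavior."""

import numpy as np
import pytest

from ethobench.combine import combine_all
from ethobench.io import ValidationError, write_table, read_annotations, read_movies, read_scores
from ethobench.synth import (
    BehaviorModel,
    DurationModel,
    ObserverModel,
    ScoreModel,
    SyntheticConfig,
    TruthBout,
    default_config,
    generate_dataset,
    generate_observer_annotations,
    generate_score_track,
    generate_truth,
)


def tiny_config(seed, **overrides):
    base = default_config(seed, minutes_per_movie=1.0, n_movies_per_type=1)
    return SyntheticConfig(**{**base.__dict__, **overrides})


class TestDeterminism:
    def test_same_seed_identical_csvs(self, tmp_path):
        for d in ("run1", "run2"):
            data = generate_dataset(default_config(5, minutes_per_movie=0.5, n_movies_per_type=1))
            out = tmp_path / d
            out.mkdir()
            write_table(data.annotations, out / "annotations.csv", kind="annotations")
            write_table(data.tracks, out / "scores.csv", kind="scores")
            write_table(data.movies, out / "movies.csv", kind="movies")
        for name in ("annotations.csv", "scores.csv", "movies.csv"):
            assert (tmp_path / "run1" / name).read_bytes() == (
                tmp_path / "run2" / name
            ).read_bytes()

    def test_different_seed_different_dataset(self):
        a = generate_dataset(default_config(1, minutes_per_movie=0.5, n_movies_per_type=1))
        b = generate_dataset(default_config(2, minutes_per_movie=0.5, n_movies_per_type=1))
        assert a.truth != b.truth


class TestTruth:
    def test_zero_prevalence_empty_annotations(self):
        config = tiny_config(
            3,
            behaviors={
                "lunge": BehaviorModel(
                    duration=DurationModel(5.0, 0.35),
                    prevalence={"male_male": 0.0, "male_female": 0.0, "female_female": 0.0},
                )
            },
        )
        data = generate_dataset(config)
        assert data.truth == []
        assert data.annotations == []
        assert all(t.scores.max() < 0.5 for t in data.tracks)  # pure noise + bumps

    def test_duration_model_median_83_ms(self):
        model = DurationModel(median_frames=5.0, sigma=0.35)
        rng = np.random.default_rng(0)
        durations = model.sample(rng, 10_000)
        median_ms = np.median(durations) * 1000 / 60
        assert abs(median_ms - 83.3) <= 1000 / 60  # within one frame

    def test_truth_bouts_disjoint_and_in_range(self):
        config = default_config(4, minutes_per_movie=1.0, n_movies_per_type=1)
        movies, truth = generate_truth(config, np.random.default_rng(4))
        n_frames = {m.movie_id: m.n_frames for m in movies}
        by_track = {}
        for t in truth:
            assert 1 <= t.start_frame <= t.end_frame <= n_frames[t.movie_id]
            by_track.setdefault((t.movie_id, t.fly_id, t.behavior), []).append(t)
        for group in by_track.values():
            group.sort(key=lambda t: t.start_frame)
            for prev, nxt in zip(group, group[1:]):
                assert prev.end_frame < nxt.start_frame

    def test_infeasible_prevalence_rejected(self):
        config = tiny_config(
            5,
            behaviors={
                "lunge": BehaviorModel(
                    duration=DurationModel(500.0, 0.1),
                    prevalence={"male_male": 50.0, "male_female": 0.0, "female_female": 0.0},
                )
            },
        )
        with pytest.raises(ValidationError, match="infeasible"):
            generate_dataset(config)


class TestObservers:
    def make_truth(self, n, rng, duration=10, spacing=30):
        return [
            TruthBout("m0", "fly1", "lunge", 1 + i * spacing, i * spacing + duration,
                      float(rng.uniform()), i)
            for i in range(n)
        ]

    def movies_meta(self, n_frames):
        from ethobench.io import MovieMeta, PairType

        return {"m0": MovieMeta("m0", PairType.MALE_MALE, 60, n_frames)}

    def test_step_detection_never_annotates_low_salience(self):
        rng = np.random.default_rng(0)
        truth = self.make_truth(500, rng)
        observer = ObserverModel(a0=-1e6, a1=2e6)  # step at S = 0.5
        bouts, prov = generate_observer_annotations(
            truth, observer, np.random.default_rng(1), "obsA", 0,
            self.movies_meta(truth[-1].end_frame + 10),
        )
        detected_salience = {truth[i].salience for i in (t for t in prov)}
        assert all(s >= 0.5 for s in detected_salience)

    def test_perfect_observer_reproduces_truth(self):
        rng = np.random.default_rng(1)
        truth = self.make_truth(50, rng)
        observer = ObserverModel(a0=1000.0, a1=0.0, conf_noise_sd=0.0, boundary_jitter_sd=0.0)
        meta = self.movies_meta(truth[-1].end_frame + 10)
        bouts_a, _ = generate_observer_annotations(truth, observer, np.random.default_rng(2), "obsA", 0, meta)
        bouts_b, _ = generate_observer_annotations(truth, observer, np.random.default_rng(3), "obsB", 1, meta)
        assert [(b.start_frame, b.end_frame) for b in bouts_a] == [
            (t.start_frame, t.end_frame) for t in truth
        ]
        combined = combine_all(bouts_a + bouts_b)
        flat = [c for g in combined.values() for c in g]
        assert all(c.observer_count == 2 for c in flat)

    def test_default_single_observer_fraction_calibrated(self):
        """Monte-Carlo check of the analytic ~27% single-observer calibration."""
        rng = np.random.default_rng(2)
        truth = self.make_truth(10_000, rng)
        observer = ObserverModel()
        meta = self.movies_meta(truth[-1].end_frame + 10)
        bouts_a, _ = generate_observer_annotations(truth, observer, np.random.default_rng(3), "obsA", 0, meta)
        bouts_b, _ = generate_observer_annotations(truth, observer, np.random.default_rng(4), "obsB", 1, meta)
        combined = combine_all(bouts_a + bouts_b)
        flat = [c for g in combined.values() for c in g]
        records = [s for c in flat for s in c.score_records]
        one_obs = sum(len(c.score_records) for c in flat if c.observer_count == 1)
        fraction = one_obs / len(records)
        assert abs(fraction - 0.272) < 0.03

    def test_observer_bouts_overlap_their_truth(self, small_dataset):
        truth_by_id = {t.bout_id: t for t in small_dataset.truth}
        for b, bout_id in zip(small_dataset.annotations, small_dataset.annotation_provenance):
            t = truth_by_id[bout_id]
            assert b.start_frame <= t.end_frame and t.start_frame <= b.end_frame


class TestScoreTracks:
    def make_truth(self, n, rng, duration=8, spacing=20):
        return [
            TruthBout("m0", "fly1", "lunge", 1 + i * spacing, i * spacing + duration,
                      float(rng.uniform()), i)
            for i in range(n)
        ]

    def bout_means(self, truth, track):
        return np.array(
            [track.scores[t.start_frame - 1 : t.end_frame].mean() for t in truth]
        )

    def test_zero_coupling_uncorrelated_with_salience(self):
        rng = np.random.default_rng(0)
        truth = self.make_truth(10_000, rng)
        model = ScoreModel(b1=0.0)
        track = generate_score_track(
            truth, model, np.random.default_rng(1), "m0", "fly1", "lunge",
            truth[-1].end_frame + 10, 60.0,
        )
        salience = np.array([t.salience for t in truth])
        r = np.corrcoef(salience, self.bout_means(truth, track))[0, 1]
        assert abs(r) < 0.05

    def test_strong_coupling_rank_correlates(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(1)
        truth = self.make_truth(10_000, rng)
        model = ScoreModel(b1=0.7, ar_sd=0.02)
        track = generate_score_track(
            truth, model, np.random.default_rng(2), "m0", "fly1", "lunge",
            truth[-1].end_frame + 10, 60.0,
        )
        salience = np.array([t.salience for t in truth])
        rho, _ = spearmanr(salience, self.bout_means(truth, track))
        assert rho > 0.8

    def test_no_distractors_low_baseline_zero_fp(self):
        from ethobench.io import track_key
        from ethobench.matching import match_all
        from ethobench.smoothing import SmoothingParams, detect_bouts

        rng = np.random.default_rng(2)
        truth = self.make_truth(30, rng)
        model = ScoreModel(distractor_rate_per_min=0.0, baseline_mean=0.01, baseline_sd=0.002)
        track = generate_score_track(
            truth, model, np.random.default_rng(3), "m0", "fly1", "lunge",
            truth[-1].end_frame + 10, 60.0,
        )
        bouts = detect_bouts(track, SmoothingParams(0.1, 2, 3))
        truth_intervals = [(t.start_frame, t.end_frame) for t in truth]
        for b in bouts:
            assert any(b.start_frame <= e and s <= b.end_frame for s, e in truth_intervals)


class TestEmittedTables:
    def test_round_trip_through_io_validation(self, small_dataset, tmp_path):
        write_table(small_dataset.annotations, tmp_path / "a.csv", kind="annotations")
        write_table(small_dataset.tracks, tmp_path / "s.csv", kind="scores")
        write_table(small_dataset.movies, tmp_path / "m.csv", kind="movies")
        movies = read_movies(tmp_path / "m.csv")
        meta = {m.movie_id: m for m in movies}
        annotations = read_annotations(tmp_path / "a.csv", movies=meta)
        tracks = read_scores(tmp_path / "s.csv")
        assert annotations == small_dataset.annotations
        assert tracks == small_dataset.tracks
        assert movies == small_dataset.movies
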