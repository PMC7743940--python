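import numpy as np
import pytest

from ethobench.io import Behavior, MovieMeta, ObserverBout, PairType, ScoreTrack
from ethobench.synth import default_config, generate_dataset


def bout(start, end, conf, observer="obsA", movie="m1", fly="fly1", behavior="lunge"):
    """Shorthand ObserverBout constructor for fixtures."""
    return ObserverBout(
        movie_id=movie,
        fly_id=fly,
        behavior=Behavior(behavior),
        observer_id=observer,
        start_frame=start,
        end_frame=end,
        confidence=conf,
    )


def track(scores, movie="m1", fly="fly1", behavior="lunge"):
    return ScoreTrack(movie, fly, Behavior(behavior), np.asarray(scores, dtype=float))


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic study (1 movie per pair type, 2 min)."""
    config = default_config(20240, minutes_per_movie=2.0, n_movies_per_type=1)
    return generate_dataset(config)


@pytest.fixture
def movie_meta():
    return MovieMeta(movie_id="m1", pair_type=PairType.MALE_MALE, fps=60, n_frames=2000)
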