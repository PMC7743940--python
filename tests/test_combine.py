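"""Union merging of two observers' bouts, combined 1-6 scores, and summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ethobench.combine import (
    bout_duration_stats,
    combine_all,
    frame_combined_scores,
    frame_summary,
    merge_observer_bouts,
    summarize_annotations,
)
from ethobench.io import MovieMeta, PairType, ValidationError
from tests.conftest import bout


class TestMergeObserverBouts:
    def test_simple_overlap_sums_confidences(self):
        (c,) = merge_observer_bouts([bout(100, 130, 3)], [bout(110, 140, 2, "obsB")])
        assert (c.start_frame, c.end_frame) == (100, 140)
        assert c.score_records == (5,)
        assert c.observer_count == 2

    def test_split_bout_produces_one_record_per_sub_bout(self):
        a = [bout(100, 110, 3), bout(120, 130, 2)]
        b = [bout(95, 135, 3, "obsB")]
        (c,) = merge_observer_bouts(a, b)
        assert (c.start_frame, c.end_frame) == (95, 135)
        assert c.score_records == (6, 5)
        assert c.representative_score == 6
        assert c.observer_count == 2

    def test_single_observer_bout_passes_through(self):
        (c,) = merge_observer_bouts([bout(100, 110, 2)], [])
        assert (c.start_frame, c.end_frame) == (100, 110)
        assert c.score_records == (2,)
        assert c.observer_count == 1

    def test_one_frame_overlap_counts_as_matched(self):
        (c,) = merge_observer_bouts([bout(100, 110, 1)], [bout(110, 120, 1, "obsB")])
        assert c.observer_count == 2
        assert c.score_records == (2,)

    def test_adjacent_but_disjoint_bouts_stay_separate(self):
        c = merge_observer_bouts([bout(100, 110, 1)], [bout(111, 120, 1, "obsB")])
        assert len(c) == 2
        assert all(x.observer_count == 1 for x in c)

    def test_chained_overlap_is_one_region(self):
        # A1-B1-A2 chain: one region via connected components
        a = [bout(100, 110, 3), bout(118, 125, 2)]
        b = [bout(108, 120, 1, "obsB")]
        (c,) = merge_observer_bouts(a, b)
        assert (c.start_frame, c.end_frame) == (100, 125)
        assert sorted(c.score_records) == [3, 4]

    def test_mixed_universes_rejected(self):
        with pytest.raises(ValidationError, match="one \\(movie, fly, behavior\\)"):
            merge_observer_bouts([bout(1, 5, 1)], [bout(1, 5, 1, "obsB", movie="m2")])

    def test_three_observers_unsupported(self):
        bouts = [bout(1, 5, 1, o) for o in ("obsA", "obsB", "obsC")]
        with pytest.raises(ValidationError, match="two"):
            combine_all(bouts)


@st.composite
def observer_bouts(draw, max_bouts=10, n_frames=120):
    """Non-overlapping bouts for one observer on a short track."""
    n = draw(st.integers(0, max_bouts))
    edges = sorted(draw(st.lists(st.integers(1, n_frames), min_size=2 * n, max_size=2 * n, unique=True)))
    confs = draw(st.lists(st.integers(1, 3), min_size=n, max_size=n))
    return [
        bout(edges[2 * i], edges[2 * i + 1] - 1, confs[i])
        for i in range(n)
        if edges[2 * i] <= edges[2 * i + 1] - 1
    ]


def retag(bouts, observer):
    from dataclasses import replace

    return [replace(b, observer_id=observer) for b in bouts]


class TestMergeProperties:
    @given(observer_bouts(), observer_bouts())
    @settings(max_examples=120, deadline=None)
    def test_symmetry_and_conservation(self, a, b):
        b = retag(b, "obsB")
        merged_ab = merge_observer_bouts(a, b)
        merged_ba = merge_observer_bouts(b, a)
        # identical extents and observer counts either way
        assert [(c.start_frame, c.end_frame, c.observer_count) for c in merged_ab] == [
            (c.start_frame, c.end_frame, c.observer_count) for c in merged_ba
        ]
        # identical score-record multisets
        assert sorted(s for c in merged_ab for s in c.score_records) == sorted(
            s for c in merged_ba for s in c.score_records
        )
        # every input bout is covered by exactly one combined extent
        for x in a + b:
            covering = [
                c
                for c in merged_ab
                if c.start_frame <= x.start_frame and x.end_frame <= c.end_frame
            ]
            assert len(covering) == 1

    @given(observer_bouts())
    @settings(max_examples=60, deadline=None)
    def test_merge_with_empty_observer_is_identity(self, a):
        merged = merge_observer_bouts(a, [])
        assert [(c.start_frame, c.end_frame) for c in merged] == sorted(
            (x.start_frame, x.end_frame) for x in a
        )
        assert all(c.score_records == (x.confidence,) for c, x in zip(
            merged, sorted(a, key=lambda b: b.start_frame)))

    @given(observer_bouts(), observer_bouts())
    @settings(max_examples=120, deadline=None)
    def test_extents_match_brute_force_interval_graph(self, a, b):
        """Oracle: combined extents are the connected components of the
        brute-force pairwise-overlap graph (frame-set intersections)."""
        b = retag(b, "obsB")
        bouts = a + b
        n = len(bouts)
        frames = [set(range(x.start_frame, x.end_frame + 1)) for x in bouts]
        adjacency = {
            i: {j for j in range(n) if j != i and frames[i] & frames[j]}
            for i in range(n)
        }
        seen: set[int] = set()
        components = []
        for i in range(n):
            if i in seen:
                continue
            stack, comp = [i], set()
            while stack:
                k = stack.pop()
                if k in comp:
                    continue
                comp.add(k)
                stack.extend(adjacency[k] - comp)
            seen |= comp
            components.append(
                (
                    min(bouts[k].start_frame for k in comp),
                    max(bouts[k].end_frame for k in comp),
                )
            )
        merged = merge_observer_bouts(a, b)
        assert sorted((c.start_frame, c.end_frame) for c in merged) == sorted(components)

    @given(observer_bouts(), observer_bouts())
    @settings(max_examples=60, deadline=None)
    def test_frame_bout_consistency(self, a, b):
        """A frame has combined score > 0 iff it lies in some combined extent."""
        b = retag(b, "obsB")
        scores = frame_combined_scores(a, b, 130)
        merged = merge_observer_bouts(a, b)
        inside = np.zeros(130, dtype=bool)
        for c in merged:
            inside[c.start_frame - 1 : c.end_frame] = True
        assert np.array_equal(scores > 0, inside)


class TestFrameCombinedScores:
    def test_staggered_overlap(self):
        a = [bout(100, 110, 3)]
        b = [bout(105, 115, 2, "obsB")]
        scores = frame_combined_scores(a, b, 120)
        assert (scores[104:110] == 5).all()
        assert (scores[99:104] == 3).all()
        assert (scores[110:115] == 2).all()
        assert scores.sum() == 6 * 5 + 5 * 3 + 5 * 2

    def test_no_bouts_all_zero(self):
        assert frame_combined_scores([], [], 50).sum() == 0

    def test_bout_past_track_end_rejected(self):
        with pytest.raises(ValidationError, match="40 frames"):
            frame_combined_scores([bout(30, 45, 1)], [], 40)

    def test_frame_summary_fractions(self):
        a = [bout(1, 10, 3)]
        b = [bout(6, 15, 2, "obsB")]
        s = frame_summary(a, b, 20)
        assert s["n_annotated_frames"] == 15
        assert s["frac_score_4_6"] == pytest.approx(5 / 15)
        assert s["frac_one_observer"] == pytest.approx(10 / 15)


class TestSummaries:
    def make_movies(self):
        return {
            "m1": MovieMeta("m1", PairType.MALE_MALE, 60, 2000),
        }

    def test_empty_input_all_zero(self):
        out = summarize_annotations({}, None, self.make_movies())
        assert out == {}

    def test_hand_enumerated_record_counts(self):
        """3 regions with records {5}, {2}, {6,3}: 4 records, half score 4-6,
        a quarter one-observer (score-record basis)."""
        # region1 A(10,20,3)+B(15,25,2) -> {5}; region2 A(100,110,2) alone -> {2};
        # region3 A(200,210,3)+A(220,230,3) split over B(195,232,3) -> {6,6}
        a = [bout(10, 20, 3), bout(100, 110, 2), bout(200, 210, 3), bout(220, 230, 3)]
        b = [bout(15, 25, 2, "obsB"), bout(195, 232, 3, "obsB")]
        merged = combine_all(a + b)
        flat = [c for g in merged.values() for c in g]
        summary = summarize_annotations(flat, None, self.make_movies())["lunge"]
        assert summary.n_combined_bouts == 3
        assert summary.n_score_records == 4
        records = sorted(s for c in flat for s in c.score_records)
        assert records == [2, 5, 6, 6]
        assert summary.frac_score_4_6 == pytest.approx(3 / 4)
        assert summary.frac_one_observer == pytest.approx(1 / 4)
        assert summary.grid.sum() == 4
        assert summary.grid[0, 0] == 0  # structurally empty cell

    def test_grid_total_equals_record_count(self, small_dataset):
        from ethobench.io import movies_by_id

        combined = combine_all(small_dataset.annotations)
        flat = [c for g in combined.values() for c in g]
        summaries = summarize_annotations(flat, None, movies_by_id(small_dataset.movies))
        for s in summaries.values():
            assert s.grid.sum() == s.n_score_records
            assert s.grid[0, 0] == 0
            assert 0 <= s.frac_one_observer <= 1
            assert 0 <= s.frac_score_4_6 <= 1


class TestDurationStats:
    def test_single_bout_arithmetic(self):
        (c,) = merge_observer_bouts([bout(100, 104, 3)], [])
        stats = bout_duration_stats([c], fps=60)
        assert stats["median_frames"] == 5
        assert stats["median_ms"] == 83

    def test_four_frames_is_67_ms(self):
        (c,) = merge_observer_bouts([bout(100, 103, 3)], [])
        assert bout_duration_stats([c], fps=60)["median_ms"] == 67

    def test_empty_input_errors(self):
        with pytest.raises(ValidationError):
            bout_duration_stats([], fps=60)
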