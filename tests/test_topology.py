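"""Lineage graph construction, track inference, events, motility stats."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from biotracks import (
    BiotracksPackage,
    Link,
    TrackedObject,
    build_lineage_graph,
    detect_events,
    infer_tracks,
    track_stats,
)
from biotracks.topology import InvalidInputError
from conftest import brute_force_components, make_objects


def random_instance(rng, n_objects=60, n_links=25):
    """A random valid objects+links instance: chains over a frame grid."""
    objects = [TrackedObject(i, rng.randrange(0, 30), rng.uniform(-5, 5),
                             rng.uniform(-5, 5)) for i in range(n_objects)]
    by_frame = sorted(objects, key=lambda o: (o.frame, o.object_id))
    links = []
    for lid in range(n_links):
        length = rng.randrange(2, 6)
        start = rng.randrange(0, max(1, len(by_frame) - length))
        chain, last_frame = [], -1
        for obj in by_frame[start:]:
            if obj.frame > last_frame:
                chain.append(obj.object_id)
                last_frame = obj.frame
            if len(chain) == length:
                break
        if len(chain) >= 2:
            links.append(Link(lid, tuple(chain)))
    return objects, links


class TestLineageGraph:
    def test_simple_chain_edges(self):
        objects = make_objects([(0, 0, 0), (1, 1, 1), (2, 2, 2)])
        graph = build_lineage_graph(objects, [Link(0, (0, 1)), Link(1, (1, 2))])
        assert set(graph.edges) == {(0, 1), (1, 2)}

    def test_branching_outdegree(self):
        objects = make_objects([(0, 0, 0), (1, 1, 1), (1, 2, 2)])
        graph = build_lineage_graph(objects, [Link(0, (0, 1)), Link(1, (0, 2))])
        assert graph.out_degree(0) == 2

    def test_duplicate_edges_collapse_with_multilabel(self):
        objects = make_objects([(0, 0, 0), (1, 1, 1)])
        graph = build_lineage_graph(objects, [Link(0, (0, 1)), Link(1, (0, 1))])
        assert graph.number_of_edges() == 1
        assert graph.edges[0, 1]["links"] == [0, 1]

    def test_edge_count_matches_pair_enumeration(self):
        # oracle: enumerate every consecutive pair of every link, deduplicate
        rng = random.Random(7)
        objects, links = random_instance(rng, n_objects=120, n_links=100)
        graph = build_lineage_graph(objects, links)
        expected = {(a, b) for ln in links
                    for a, b in zip(ln.object_ids, ln.object_ids[1:])}
        assert set(graph.edges) == expected

    def test_invalid_input_rejected(self):
        objects = make_objects([(0, 0, 0)])
        with pytest.raises(InvalidInputError) as err:
            build_lineage_graph(objects, [Link(0, (0, 99))])
        assert "dangling_reference" in err.value.report.codes()


class TestInferTracks:
    def test_shared_object_joins_links(self):
        objects = make_objects([(0, 0, 0), (1, 1, 1), (2, 2, 2), (3, 3, 3)])
        tracks = infer_tracks(objects, [Link(0, (0, 1, 2)), Link(1, (2, 3))])
        assert len(tracks) == 1 and tracks[0].link_ids == frozenset({0, 1})

    def test_disjoint_links_separate(self):
        objects = make_objects([(0, 0, 0), (1, 1, 1), (0, 5, 5), (1, 6, 6)])
        tracks = infer_tracks(objects, [Link(0, (0, 1)), Link(1, (2, 3))])
        assert len(tracks) == 2

    def test_matches_bruteforce_dfs_on_random_instances(self):
        rng = random.Random(1234)
        for _ in range(25):
            objects, links = random_instance(rng, n_objects=120, n_links=60)
            tracks = infer_tracks(objects, links)
            assert sorted((t.link_ids for t in tracks), key=min) == \
                brute_force_components(links)

    def test_numbering_is_input_order_invariant(self):
        rng = random.Random(5)
        objects, links = random_instance(rng)
        reference = infer_tracks(objects, links)
        shuffled = list(links)
        rng.shuffle(shuffled)
        assert infer_tracks(objects, shuffled) == reference

    def test_linear_forest_has_one_track_per_link(self):
        objects = make_objects([(0, 0, 0), (1, 1, 1), (0, 5, 5), (1, 6, 6),
                                (0, 9, 9), (1, 10, 10)])
        links = [Link(0, (0, 1)), Link(1, (2, 3)), Link(2, (4, 5))]
        assert len(infer_tracks(objects, links)) == len(links)


class TestDetectEvents:
    def test_split_semantics(self, split_package):
        events = detect_events(split_package.objects, split_package.links)
        assert [(e.kind.value, e.pivot_object_id) for e in events] == [("split", 1)]
        assert events[0].downstream_object_ids == {2, 4}

    def test_merge_semantics(self):
        objects = make_objects([(0, 0, 0), (0, 2, 2), (1, 1, 1), (2, 2, 2)])
        links = [Link(0, (0, 2)), Link(1, (1, 2)), Link(2, (2, 3))]
        events = detect_events(objects, links)
        assert [(e.kind.value, e.pivot_object_id) for e in events] == [("merge", 2)]
        assert events[0].upstream_object_ids == {0, 1}

    def test_branch_free_package_has_no_events(self):
        rng = random.Random(9)
        objects = make_objects([(f, f, c) for c in range(3) for f in range(6)])
        links = [Link(c, tuple(range(c * 6, c * 6 + 6))) for c in range(3)]
        assert detect_events(objects, links) == []


class TestTrackStats:
    def test_three_four_five(self, straight_line_package):
        pkg = straight_line_package
        stats = track_stats(pkg.tracks[0], pkg.objects, pkg.links, frame_interval=1.0)
        assert stats.path_length == pytest.approx(5.0)
        assert stats.net_displacement == pytest.approx(5.0)
        assert stats.mean_speed == pytest.approx(5.0)
        assert stats.confinement_ratio == pytest.approx(1.0)

    def test_closed_loop_confinement_zero(self, square_loop_package):
        pkg = square_loop_package
        stats = track_stats(pkg.tracks[0], pkg.objects, pkg.links)
        assert stats.net_displacement == pytest.approx(0.0)
        assert stats.confinement_ratio == pytest.approx(0.0)

    def test_random_walk_path_length_matches_direct_sum(self):
        rng = random.Random(3)
        points = [(i, rng.uniform(-10, 10), rng.uniform(-10, 10))
                  for i in range(51)]
        objects = make_objects(points)
        links = [Link(0, tuple(range(51)))]
        expected = sum(math.dist((objects[i].x, objects[i].y),
                                 (objects[i + 1].x, objects[i + 1].y))
                       for i in range(50))
        stats = track_stats(infer_tracks(objects, links)[0], objects, links)
        assert stats.path_length == pytest.approx(expected, rel=1e-9)

    def test_frame_interval_scales_speed(self, straight_line_package):
        pkg = straight_line_package
        stats = track_stats(pkg.tracks[0], pkg.objects, pkg.links, frame_interval=2.0)
        assert stats.mean_speed == pytest.approx(2.5)

    def test_branching_track_uses_longest_frame_span_path(self, split_package):
        pkg = split_package
        stats = track_stats(pkg.tracks[0], pkg.objects, pkg.links)
        # principal path runs root 0 -> leaf over frames 0..3
        assert stats.duration_frames == 3

    def test_rejects_nonpositive_frame_interval(self, straight_line_package):
        pkg = straight_line_package
        with pytest.raises(ValueError):
            track_stats(pkg.tracks[0], pkg.objects, pkg.links, frame_interval=0.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
                    min_size=2, max_size=30))
    def test_confinement_bounds_hold_for_any_polyline(self, coords):
        objects = [TrackedObject(i, i, x, y) for i, (x, y) in enumerate(coords)]
        links = [Link(0, tuple(range(len(coords))))]
        stats = track_stats(infer_tracks(objects, links)[0], objects, links)
        assert stats.path_length + 1e-9 >= stats.net_displacement >= 0.0
        if stats.path_length > 0:
            assert 0.0 <= stats.confinement_ratio <= 1.0 + 1e-12
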