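"""Lineage topology: track inference, split/merge detection, motility stats.

Links linearly connect objects; the *lineage graph* is the directed graph
whose edges are the consecutive object pairs of every link, pointing
forward in time. Tracks are its weakly connected components mapped back
to link sets — weak connectivity keeps splits and merges inside one
lineage. Splits are nodes with out-degree >= 2, merges nodes with
in-degree >= 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx

from .model import (
    BiotracksPackage,
    EventKind,
    LineageEvent,
    Link,
    Track,
    TrackedObject,
    ValidationReport,
    validate_links,
    validate_objects,
)

__all__ = [
    "InvalidInputError",
    "TrackStats",
    "build_lineage_graph",
    "infer_tracks",
    "detect_events",
    "track_stats",
    "package_stats",
]


class InvalidInputError(ValueError):
    """Raised when inputs fail core-model validation; carries the report."""

    def __init__(self, report: ValidationReport):
        self.report = report
        super().__init__(str(report))


def _check(objects: Sequence[TrackedObject], links: Sequence[Link]) -> None:
    report = validate_objects(objects)
    report.extend(validate_links(objects, links))
    if not report.ok:
        raise InvalidInputError(report)


def build_lineage_graph(objects: Sequence[TrackedObject],
                        links: Sequence[Link]) -> nx.DiGraph:
    """Directed graph of parent→child object pairs contributed by links.

    Nodes are the object ids referenced by at least one link; each edge
    carries a sorted ``links`` label listing every link contributing that
    consecutive pair (duplicate edges across links are collapsed).
    Node attribute ``frame`` holds the object's frame index.
    """
    _check(objects, links)
    frames = {o.object_id: o.frame for o in objects}
    graph = nx.DiGraph()
    for link in links:
        for oid in link.object_ids:
            if oid not in graph:
                graph.add_node(oid, frame=frames[oid])
        for a, b in zip(link.object_ids, link.object_ids[1:]):
            if graph.has_edge(a, b):
                labels = set(graph.edges[a, b]["links"])
                labels.add(link.link_id)
                graph.edges[a, b]["links"] = sorted(labels)
            else:
                graph.add_edge(a, b, links=[link.link_id])
    return graph


def infer_tracks(objects: Sequence[TrackedObject],
                 links: Sequence[Link]) -> list[Track]:
    """Tracks as weakly connected components of the lineage graph.

    Components are mapped back to the link sets that touch them, sorted
    by their minimum contained link id, and numbered from 0 — the
    numbering is deterministic and independent of link input order.
    """
    graph = build_lineage_graph(objects, links)
    component_of: dict[int, int] = {}
    for cid, component in enumerate(nx.weakly_connected_components(graph)):
        for oid in component:
            component_of[oid] = cid
    groups: dict[int, set[int]] = {}
    for link in links:
        cid = component_of[link.object_ids[0]]
        groups.setdefault(cid, set()).add(link.link_id)
    ordered = sorted(groups.values(), key=min)
    return [Track(track_id=i, link_ids=frozenset(g)) for i, g in enumerate(ordered)]


def detect_events(objects: Sequence[TrackedObject],
                  links: Sequence[Link]) -> list[LineageEvent]:
    """Splits (out-degree >= 2) and merges (in-degree >= 2) in the lineage graph.

    Events are sorted by pivot frame, then pivot object id, with splits
    before merges on the same pivot.
    """
    graph = build_lineage_graph(objects, links)
    events: list[LineageEvent] = []
    for node in graph.nodes:
        succ = frozenset(graph.successors(node))
        pred = frozenset(graph.predecessors(node))
        if len(succ) >= 2:
            events.append(LineageEvent(EventKind.SPLIT, node, pred, succ))
        if len(pred) >= 2:
            events.append(LineageEvent(EventKind.MERGE, node, pred, succ))
    frames = {o.object_id: o.frame for o in objects}
    events.sort(key=lambda e: (frames[e.pivot_object_id], e.pivot_object_id,
                               e.kind is EventKind.MERGE))
    return events


@dataclass(frozen=True)
class TrackStats:
    """Motility summary of one track's principal path.

    path_length is the summed Euclidean step distance, net_displacement
    the start-to-end distance, mean_speed = path_length / elapsed time,
    confinement_ratio = net_displacement / path_length (1 for straight
    motion, 0 for a closed loop).
    """

    track_id: int
    n_objects: int
    duration_frames: int
    path_length: float
    net_displacement: float
    mean_speed: float
    confinement_ratio: float
    spatial_unit: str = "pixel"


def _principal_path(graph: nx.DiGraph) -> list[int]:
    """Longest root-to-leaf path by frame span; ties → smaller leaf, then root id.

    Memoised DP over the (acyclic, time-ordered) lineage graph: for each
    node the best continuation maximises the leaf frame, breaking ties on
    the smaller leaf id and then the smaller successor id.
    """
    frames = nx.get_node_attributes(graph, "frame")
    best: dict[int, tuple[int, int, Optional[int]]] = {}  # node -> (leaf_frame, leaf_id, next)

    for node in sorted(graph.nodes, key=lambda n: (-frames[n], n)):
        succs = list(graph.successors(node))
        if not succs:
            best[node] = (frames[node], node, None)
        else:
            choice = min(succs, key=lambda s: (-best[s][0], best[s][1], s))
            leaf_frame, leaf_id, _ = best[choice]
            best[node] = (leaf_frame, leaf_id, choice)

    roots = [n for n in graph.nodes if graph.in_degree(n) == 0]
    root = min(roots, key=lambda r: (-(best[r][0] - frames[r]), best[r][1], r))
    path = [root]
    while best[path[-1]][2] is not None:
        path.append(best[path[-1]][2])
    return path


def _distance(a: TrackedObject, b: TrackedObject) -> float:
    pa, pb = a.position(), b.position()
    if len(pa) != len(pb):  # mixed 2D/3D: treat missing z as 0
        pa = (a.x, a.y, a.z or 0.0)
        pb = (b.x, b.y, b.z or 0.0)
    return math.dist(pa, pb)


def track_stats(track: Track,
                objects: Sequence[TrackedObject],
                links: Sequence[Link],
                frame_interval: float = 1.0,
                spatial_unit: str = "pixel") -> TrackStats:
    """Motility statistics for one track.

    Branching tracks have no single trajectory; statistics follow the
    principal (longest frame-span) root-to-leaf path. ``frame_interval``
    converts frame counts to elapsed time for the mean speed, using the
    frame span of the chosen path so gap-closed links are timed correctly.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    link_map = {ln.link_id: ln for ln in links}
    track_links = [link_map[lid] for lid in sorted(track.link_ids)]
    member_ids = {oid for ln in track_links for oid in ln.object_ids}
    obj_map = {o.object_id: o for o in objects if o.object_id in member_ids}
    sub_objects = [obj_map[oid] for oid in sorted(member_ids)]
    graph = build_lineage_graph(sub_objects, track_links)

    if len(member_ids) < 2:
        return TrackStats(track.track_id, len(member_ids), 0, 0.0, 0.0, 0.0, 0.0,
                          spatial_unit)

    path = _principal_path(graph)
    points = [obj_map[oid] for oid in path]
    path_length = sum(_distance(a, b) for a, b in zip(points, points[1:]))
    net = _distance(points[0], points[-1])
    duration = points[-1].frame - points[0].frame
    speed = path_length / (duration * frame_interval) if duration > 0 else 0.0
    confinement = net / path_length if path_length > 0 else 0.0
    return TrackStats(track.track_id, len(member_ids), duration, path_length,
                      net, speed, confinement, spatial_unit)


def package_stats(pkg: BiotracksPackage,
                  frame_interval: float = 1.0,
                  spatial_unit: str = "pixel") -> list[TrackStats]:
    """Per-track statistics for a whole package, ordered by track id."""
    tracks = pkg.tracks if pkg.tracks is not None else infer_tracks(pkg.objects, pkg.links)
    return [track_stats(t, pkg.objects, pkg.links, frame_interval, spatial_unit)
            for t in sorted(tracks, key=lambda t: t.track_id)]
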