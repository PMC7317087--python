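"""Core data model for tracked objects, links, tracks, and lineage events.

The model has three levels:

* **objects** — one detection per frame, with coordinates and optional
  numeric features (area, intensity, ...);
* **links** — ordered linear chains of object ids across strictly
  increasing frames, as produced by a frame-to-frame linker;
* **tracks** — sets of links joined through shared objects, i.e. one
  weakly connected lineage component spanning split/merge events.

Validation never raises on malformed content; it returns a
:class:`ValidationReport` listing every problem found, so that callers
(converters, the CLI) can surface all issues at once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "TrackedObject",
    "Link",
    "Track",
    "LineageEvent",
    "Issue",
    "ValidationReport",
    "BiotracksPackage",
    "validate_objects",
    "validate_links",
    "validate_tracks",
    "validate_package",
]


@dataclass(frozen=True)
class TrackedObject:
    """One detection in one frame.

    Coordinates are stored exactly as given by the source tool (pixels or
    calibrated units); the package descriptor records the spatial unit.
    ``features`` maps feature names to numeric values.
    """

    object_id: int
    frame: int
    x: float
    y: float
    z: Optional[float] = None
    features: Mapping[str, float] = field(default_factory=dict)

    def position(self) -> tuple[float, ...]:
        if self.z is None:
            return (self.x, self.y)
        return (self.x, self.y, self.z)


@dataclass(frozen=True)
class Link:
    """An ordered linear chain of object ids across strictly increasing frames.

    Frames need not be consecutive: gap-closing trackers emit links with
    within-link frame gaps, which are permitted.
    """

    link_id: int
    object_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "object_ids", tuple(self.object_ids))


@dataclass(frozen=True)
class Track:
    """A set of link ids forming one weakly connected lineage component."""

    track_id: int
    link_ids: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "link_ids", frozenset(self.link_ids))


class EventKind(str, Enum):
    SPLIT = "split"
    MERGE = "merge"


@dataclass(frozen=True)
class LineageEvent:
    """A split (parent with >1 child) or merge (child with >1 parent).

    ``pivot_object_id`` is the shared object; for a split the downstream
    set holds its successor objects, for a merge the upstream set holds
    its predecessor objects.
    """

    kind: EventKind
    pivot_object_id: int
    upstream_object_ids: frozenset[int]
    downstream_object_ids: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "upstream_object_ids", frozenset(self.upstream_object_ids))
        object.__setattr__(self, "downstream_object_ids", frozenset(self.downstream_object_ids))
        if self.kind is EventKind.SPLIT and len(self.downstream_object_ids) < 2:
            raise ValueError("a split event needs at least two downstream objects")
        if self.kind is EventKind.MERGE and len(self.upstream_object_ids) < 2:
            raise ValueError("a merge event needs at least two upstream objects")


@dataclass(frozen=True)
class Issue:
    severity: str  # "error" | "warning"
    code: str
    message: str
    location: str = ""


@dataclass
class ValidationReport:
    issues: list[Issue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    @property
    def errors(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "warning"]

    def error(self, code: str, message: str, location: str = "") -> None:
        self.issues.append(Issue("error", code, message, location))

    def warning(self, code: str, message: str, location: str = "") -> None:
        self.issues.append(Issue("warning", code, message, location))

    def extend(self, other: "ValidationReport") -> None:
        self.issues.extend(other.issues)

    def codes(self) -> list[str]:
        return [i.code for i in self.issues]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if not self.issues:
            return "OK (no issues)"
        lines = [f"{'OK' if self.ok else 'INVALID'} ({len(self.errors)} errors, "
                 f"{len(self.warnings)} warnings)"]
        lines += [f"  [{i.severity}] {i.code}: {i.message}"
                  + (f" ({i.location})" if i.location else "")
                  for i in self.issues]
        return "\n".join(lines)


@dataclass
class BiotracksPackage:
    """In-memory package: descriptor metadata plus the three tables.

    ``descriptor`` is the JSON-serialisable descriptor dict (see
    :mod:`biotracks.package_io`); ``tracks`` is optional because the
    tracks table is derivable from objects and links.
    """

    objects: list[TrackedObject]
    links: list[Link]
    tracks: Optional[list[Track]] = None
    descriptor: dict = field(default_factory=dict)

    def object_index(self) -> dict[int, TrackedObject]:
        return {o.object_id: o for o in self.objects}

    def link_index(self) -> dict[int, Link]:
        return {ln.link_id: ln for ln in self.links}


def _is_finite(value: object) -> bool:
    return isinstance(value, (int, float)) and math.isfinite(value)


def validate_objects(objects: Iterable[TrackedObject]) -> ValidationReport:
    """Check object ids for uniqueness and coordinates/features for sanity."""
    report = ValidationReport()
    seen: set[int] = set()
    for idx, obj in enumerate(objects):
        loc = f"objects[{idx}]"
        if obj.object_id < 0:
            report.error("negative_object_id", f"object id {obj.object_id} is negative", loc)
        if obj.object_id in seen:
            report.error("duplicate_object_id",
                         f"object id {obj.object_id} occurs more than once", loc)
        seen.add(obj.object_id)
        if obj.frame < 0:
            report.error("negative_frame",
                         f"object {obj.object_id} has negative frame {obj.frame}", loc)
        for axis, value in (("x", obj.x), ("y", obj.y)):
            if not _is_finite(value):
                report.error("nonfinite_coordinate",
                             f"object {obj.object_id} has non-finite {axis}={value!r}", loc)
        if obj.z is not None and not _is_finite(obj.z):
            report.error("nonfinite_coordinate",
                         f"object {obj.object_id} has non-finite z={obj.z!r}", loc)
        for name, value in obj.features.items():
            if not isinstance(name, str) or not name:
                report.error("bad_feature_name",
                             f"object {obj.object_id} has an empty feature name", loc)
            elif not _is_finite(value):
                report.error("nonfinite_feature",
                             f"object {obj.object_id} feature {name!r} = {value!r}", loc)
    return report


def validate_links(objects: Iterable[TrackedObject], links: Iterable[Link]) -> ValidationReport:
    """Check links for dangling references, frame order, and linearity.

    Frames must strictly increase along each link but gaps are allowed.
    An object may appear in several links (that is how splits and merges
    are represented) but at most once within a single link.
    """
    report = ValidationReport()
    frames = {o.object_id: o.frame for o in objects}
    seen_ids: set[int] = set()
    for idx, link in enumerate(links):
        loc = f"links[{idx}]"
        if link.link_id < 0:
            report.error("negative_link_id", f"link id {link.link_id} is negative", loc)
        if link.link_id in seen_ids:
            report.error("duplicate_link_id",
                         f"link id {link.link_id} occurs more than once", loc)
        seen_ids.add(link.link_id)
        if len(link.object_ids) < 2:
            report.error("short_link",
                         f"link {link.link_id} has {len(link.object_ids)} object(s); "
                         "a link connects at least two", loc)
        if len(set(link.object_ids)) != len(link.object_ids):
            report.error("repeated_object",
                         f"link {link.link_id} references an object more than once", loc)
        dangling = [oid for oid in link.object_ids if oid not in frames]
        for oid in dangling:
            report.error("dangling_reference",
                         f"link {link.link_id} references unknown object {oid}", loc)
        if not dangling:
            seq = [frames[oid] for oid in link.object_ids]
            if any(b <= a for a, b in zip(seq, seq[1:])):
                report.error("frame_order",
                             f"link {link.link_id} frames {seq} are not strictly increasing",
                             loc)
    return report


def _track_connected(link_ids: frozenset[int], link_map: Mapping[int, Link]) -> bool:
    """Brute check: is the object-sharing graph over these links connected?"""
    ids = [lid for lid in link_ids if lid in link_map]
    if len(ids) <= 1:
        return True
    members = {lid: set(link_map[lid].object_ids) for lid in ids}
    visited = {ids[0]}
    frontier = [ids[0]]
    while frontier:
        current = frontier.pop()
        for other in ids:
            if other not in visited and members[current] & members[other]:
                visited.add(other)
                frontier.append(other)
    return len(visited) == len(ids)


def validate_tracks(links: Iterable[Link], tracks: Iterable[Track]) -> ValidationReport:
    """Check that tracks partition the links and are internally connected."""
    report = ValidationReport()
    link_map = {ln.link_id: ln for ln in links}
    assigned: dict[int, int] = {}
    seen_tracks: set[int] = set()
    for idx, track in enumerate(tracks):
        loc = f"tracks[{idx}]"
        if track.track_id < 0:
            report.error("negative_track_id", f"track id {track.track_id} is negative", loc)
        if track.track_id in seen_tracks:
            report.error("duplicate_track_id",
                         f"track id {track.track_id} occurs more than once", loc)
        seen_tracks.add(track.track_id)
        if not track.link_ids:
            report.error("empty_track", f"track {track.track_id} contains no links", loc)
        for lid in sorted(track.link_ids):
            if lid not in link_map:
                report.error("dangling_link_reference",
                             f"track {track.track_id} references unknown link {lid}", loc)
            elif lid in assigned:
                report.error("link_in_multiple_tracks",
                             f"link {lid} assigned to tracks {assigned[lid]} and "
                             f"{track.track_id}", loc)
            else:
                assigned[lid] = track.track_id
        if not _track_connected(track.link_ids, link_map):
            report.error("track_disconnected",
                         f"track {track.track_id} is not connected through shared objects",
                         loc)
    for lid in sorted(link_map):
        if lid not in assigned:
            report.error("unassigned_link",
                         f"link {lid} is not assigned to any track", "tracks")
    return report


def validate_package(pkg: BiotracksPackage) -> ValidationReport:
    """Run object, link, and (when present) track checks and aggregate issues."""
    report = validate_objects(pkg.objects)
    report.extend(validate_links(pkg.objects, pkg.links))
    if pkg.tracks is not None:
        report.extend(validate_tracks(pkg.links, pkg.tracks))
    return report
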