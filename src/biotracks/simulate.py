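"""Synthetic time-lapse tracking data with a known ground truth.

The simulator emulates the output of a segmentation + linking pipeline
on a single-cell migration movie: per-frame detections moving as a
biased 2D random walk (isotropic Gaussian steps of scale sigma plus an
optional drift), cell divisions (splits: the parent's last object gains
two children), cell coalescence (merges: two cells within a capture
radius fuse into one object stream), and detection dropout (creating
within-link frame gaps). Every run returns both the biotracks package
and a :class:`GroundTruthLedger` recording the true lineage events and
track partition, so detectors can be scored exactly.

It also provides fixture emitters for the tool dialects
(:func:`emit_trackmate`, :func:`emit_cellprofiler`) that invert the
converters for round-trip testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import yaml
from lxml import etree

from .model import (
    BiotracksPackage,
    EventKind,
    Link,
    LineageEvent,
    TrackedObject,
)
from .topology import detect_events, infer_tracks

__all__ = [
    "SimulationConfig",
    "GroundTruthLedger",
    "UnexpressibleTopologyError",
    "simulate_tracks",
    "emit_trackmate",
    "emit_cellprofiler",
]


class UnexpressibleTopologyError(ValueError):
    """Target dialect cannot represent the package's topology."""


@dataclass
class SimulationConfig:
    """Parameters of one simulated movie.

    sigma is the per-axis Gaussian step scale in spatial units per
    frame; drift a constant displacement added each frame. Split and
    merge probabilities apply per cell (resp. per in-radius cell pair)
    per frame; ``split_schedule`` / ``merge_schedule`` override the
    scalar rate at specific frames (e.g. ``{1: 1.0}`` forces the event
    at frame 1 and nowhere else). Merges require the pair to lie within
    ``merge_radius`` (default 3*sigma, floor 1.0). Dropout removes
    interior detections of a segment, producing frame gaps inside
    links. ``area_lognormal`` gives (mean, sigma) of log area for the
    per-object area feature.
    """

    n_initial_cells: int = 5
    n_frames: int = 20
    sigma: float = 1.0
    drift: tuple[float, float] = (0.0, 0.0)
    split_prob: float = 0.0
    merge_prob: float = 0.0
    dropout_prob: float = 0.0
    split_schedule: Optional[Mapping[int, float]] = None
    merge_schedule: Optional[Mapping[int, float]] = None
    merge_radius: Optional[float] = None
    initial_spacing: float = 5.0
    area_lognormal: tuple[float, float] = (math.log(100.0), 0.25)
    max_cells: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("split_prob", "merge_prob", "dropout_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.n_frames < 2:
            raise ValueError(f"n_frames must be >= 2, got {self.n_frames}")
        if self.n_initial_cells < 1:
            raise ValueError("n_initial_cells must be >= 1")

    @property
    def capture_radius(self) -> float:
        if self.merge_radius is not None:
            return self.merge_radius
        return max(3.0 * self.sigma, 1.0)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        for key in ("drift", "area_lognormal"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        if "split_schedule" in data and data["split_schedule"] is not None:
            data["split_schedule"] = {int(k): float(v)
                                      for k, v in data["split_schedule"].items()}
        if "merge_schedule" in data and data["merge_schedule"] is not None:
            data["merge_schedule"] = {int(k): float(v)
                                      for k, v in data["merge_schedule"].items()}
        return cls(**data)


@dataclass
class GroundTruthLedger:
    """What the simulator actually did: paths, events, track partition."""

    paths: dict[int, list[int]]  # cell id -> object ids along its segment
    events: list[LineageEvent]
    event_frames: dict[tuple[str, int], int]  # (kind, pivot) -> frame
    track_partition: list[frozenset[int]]  # sets of link ids

    @property
    def n_splits(self) -> int:
        return sum(1 for e in self.events if e.kind is EventKind.SPLIT)

    @property
    def n_merges(self) -> int:
        return sum(1 for e in self.events if e.kind is EventKind.MERGE)


class _Cell:
    __slots__ = ("cell_id", "pos", "objects", "frames", "parent_link_tail")

    def __init__(self, cell_id: int, pos: np.ndarray,
                 seed_object: Optional[tuple[int, int]] = None):
        self.cell_id = cell_id
        self.pos = pos
        # (object_id, frame) pairs making up this cell's link
        self.objects: list[int] = []
        self.frames: list[int] = []
        if seed_object is not None:
            self.objects.append(seed_object[0])
            self.frames.append(seed_object[1])


def _rate(scalar: float, schedule: Optional[Mapping[int, float]], frame: int) -> float:
    if schedule is not None:
        return float(schedule.get(frame, 0.0))
    return scalar


def simulate_tracks(config: SimulationConfig) -> tuple[BiotracksPackage, GroundTruthLedger]:
    """Simulate one movie; returns (package, ground-truth ledger).

    The package always passes validation and the ledger's track
    partition equals :func:`biotracks.topology.infer_tracks` on it.
    Identical configs (including seed) give identical output.
    """
    rng = np.random.default_rng(config.seed)
    next_object = 0
    next_cell = 0
    objects: list[TrackedObject] = []
    drift = np.asarray(config.drift, dtype=float)

    # cell lineage bookkeeping: which cells are related through events
    cell_relations: list[tuple[int, int]] = []
    event_records: list[tuple[str, int]] = []  # (kind, pivot object id)
    event_frames: dict[tuple[str, int], int] = {}

    def new_object(cell: _Cell, frame: int) -> int:
        nonlocal next_object
        oid = next_object
        next_object += 1
        area = float(rng.lognormal(*config.area_lognormal))
        objects.append(TrackedObject(
            object_id=oid, frame=frame,
            x=float(cell.pos[0]), y=float(cell.pos[1]),
            features={"area": area}))
        cell.objects.append(oid)
        cell.frames.append(frame)
        return oid

    # initial placement: a row of cells spaced initial_spacing apart
    active: list[_Cell] = []
    for i in range(config.n_initial_cells):
        cell = _Cell(next_cell, np.array([i * config.initial_spacing, 0.0]))
        next_cell += 1
        new_object(cell, 0)
        active.append(cell)

    finished: list[_Cell] = []
    # merges decided at frame f resolve at f+1 when the fused cell emits
    # its first detection (the pivot): (parent_a, parent_b, fused)
    pending_merges: list[tuple[_Cell, _Cell, _Cell]] = []

    for frame in range(1, config.n_frames):
        # move every active cell and emit its detection for this frame
        for cell in active:
            step = rng.normal(0.0, config.sigma, size=2) if config.sigma > 0 \
                else np.zeros(2)
            cell.pos = cell.pos + step + drift
            new_object(cell, frame)

        # resolve merges decided last frame: the fused cell's first
        # detection terminates both parent links (shared pivot, in-degree 2)
        for a, b, fused in pending_merges:
            pivot = fused.objects[0]
            upstream = frozenset({a.objects[-1], b.objects[-1]})
            for parent in (a, b):
                parent.objects.append(pivot)
                parent.frames.append(frame)
            event_records.append(("merge", pivot))
            event_frames[("merge", pivot)] = frame
        pending_merges = []

        if frame == config.n_frames - 1:
            break  # no events decided at the last frame: no room to resolve

        def emitted_this_frame(cell: _Cell) -> bool:
            return bool(cell.frames) and cell.frames[-1] == frame

        # decide merges: in-radius pairs coalesce starting next frame
        merge_rate = _rate(config.merge_prob, config.merge_schedule, frame)
        if merge_rate > 0 and len(active) >= 2:
            merged_away: set[int] = set()
            for i in range(len(active)):
                for j in range(i + 1, len(active)):
                    a, b = active[i], active[j]
                    if (a.cell_id in merged_away or b.cell_id in merged_away
                            or not emitted_this_frame(a)
                            or not emitted_this_frame(b)
                            or a.objects[-1] == b.objects[-1]):
                        continue
                    if float(np.linalg.norm(a.pos - b.pos)) > config.capture_radius:
                        continue
                    if rng.random() >= merge_rate:
                        continue
                    fused = _Cell(next_cell, (a.pos + b.pos) / 2.0)
                    next_cell += 1
                    cell_relations += [(a.cell_id, fused.cell_id),
                                       (b.cell_id, fused.cell_id)]
                    pending_merges.append((a, b, fused))
                    merged_away.update({a.cell_id, b.cell_id})
                    finished.extend([a, b])
            if merged_away:
                active = [c for c in active if c.cell_id not in merged_away]
                active.extend(fused for _, _, fused in pending_merges)

        # decide splits: the parent's current detection becomes the pivot
        # shared with two daughter links
        split_rate = _rate(config.split_prob, config.split_schedule, frame)
        if split_rate > 0:
            total = len(active)
            still_active: list[_Cell] = []
            for cell in active:
                if (not emitted_this_frame(cell) or total >= config.max_cells
                        or rng.random() >= split_rate):
                    still_active.append(cell)
                    continue
                pivot = cell.objects[-1]
                for _ in range(2):
                    d = _Cell(next_cell, cell.pos.copy(),
                              seed_object=(pivot, frame))
                    next_cell += 1
                    cell_relations.append((cell.cell_id, d.cell_id))
                    still_active.append(d)
                finished.append(cell)
                total += 1
                event_records.append(("split", pivot))
                event_frames[("split", pivot)] = frame
            active = still_active

    finished.extend(active)
    finished.sort(key=lambda c: c.cell_id)

    # daughters/fused cells seeded with the pivot already carry it; ensure
    # every segment is a real link (>= 2 objects)
    cells_with_links = [c for c in finished if len(c.objects) >= 2]
    link_of_cell = {c.cell_id: lid for lid, c in enumerate(cells_with_links)}

    # dropout: remove interior, non-shared detections (keeps pivots and ends)
    shared: set[int] = set()
    counts: dict[int, int] = {}
    for cell in cells_with_links:
        for oid in cell.objects:
            counts[oid] = counts.get(oid, 0) + 1
    shared = {oid for oid, n in counts.items() if n > 1}

    dropped: set[int] = set()
    if config.dropout_prob > 0:
        for cell in cells_with_links:
            interior = cell.objects[1:-1]
            for oid in interior:
                if oid in shared or oid in dropped:
                    continue
                if rng.random() < config.dropout_prob:
                    dropped.add(oid)

    links: list[Link] = []
    paths: dict[int, list[int]] = {}
    for cell in cells_with_links:
        kept = tuple(oid for oid in cell.objects if oid not in dropped)
        links.append(Link(link_of_cell[cell.cell_id], kept))
        paths[cell.cell_id] = list(kept)
    objects = [o for o in objects if o.object_id not in dropped]

    # fill event upstream/downstream sets from the final link structure
    succ: dict[int, set[int]] = {}
    pred: dict[int, set[int]] = {}
    for link in links:
        for a, b in zip(link.object_ids, link.object_ids[1:]):
            succ.setdefault(a, set()).add(b)
            pred.setdefault(b, set()).add(a)
    final_events = [
        LineageEvent(EventKind.SPLIT if kind == "split" else EventKind.MERGE,
                     pivot,
                     frozenset(pred.get(pivot, set())),
                     frozenset(succ.get(pivot, set())))
        for kind, pivot in event_records]

    # true track partition: union cells related through events
    parent_of: dict[int, int] = {}

    def find(x: int) -> int:
        while parent_of.get(x, x) != x:
            parent_of[x] = parent_of.get(parent_of[x], parent_of[x])
            x = parent_of[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent_of[max(ra, rb)] = min(ra, rb)

    # union through every related cell, including link-less intermediates
    # (e.g. a fused cell that split immediately), then project onto
    # link-bearing cells
    for a, b in cell_relations:
        union(a, b)
    partition: dict[int, set[int]] = {}
    for cid, lid in link_of_cell.items():
        partition.setdefault(find(cid), set()).add(lid)
    track_partition = sorted((frozenset(s) for s in partition.values()), key=min)

    ledger = GroundTruthLedger(paths=paths, events=final_events,
                               event_frames=event_frames,
                               track_partition=track_partition)
    pkg = BiotracksPackage(objects=objects, links=links,
                           descriptor={"simulation": {"seed": config.seed}})
    pkg.tracks = infer_tracks(objects, links)
    return pkg, ledger


# ---------------------------------------------------------------------------
# fixture emitters (inverse of the dialect readers, for round-trip testing)
# ---------------------------------------------------------------------------

def emit_trackmate(pkg: BiotracksPackage) -> bytes:
    """Render a package as TrackMate-style XML (spots + per-track edges)."""
    tracks = pkg.tracks if pkg.tracks is not None \
        else infer_tracks(pkg.objects, pkg.links)
    root = etree.Element("TrackMate", version="synthetic")
    model = etree.SubElement(root, "Model", spatialunits="pixel", timeunits="frame")
    all_spots = etree.SubElement(model, "AllSpots")
    by_frame: dict[int, list[TrackedObject]] = {}
    for obj in pkg.objects:
        by_frame.setdefault(obj.frame, []).append(obj)
    for frame in sorted(by_frame):
        holder = etree.SubElement(all_spots, "SpotsInFrame", frame=str(frame))
        for obj in sorted(by_frame[frame], key=lambda o: o.object_id):
            attrs = {"ID": str(obj.object_id), "FRAME": str(obj.frame),
                     "POSITION_X": repr(float(obj.x)),
                     "POSITION_Y": repr(float(obj.y))}
            if obj.z is not None:
                attrs["POSITION_Z"] = repr(float(obj.z))
            for name in sorted(obj.features):
                attrs[name.upper()] = repr(float(obj.features[name]))
            etree.SubElement(holder, "Spot", **attrs)
    all_tracks = etree.SubElement(model, "AllTracks")
    link_map = pkg.link_index()
    for track in sorted(tracks, key=lambda t: t.track_id):
        track_el = etree.SubElement(all_tracks, "Track", TRACK_ID=str(track.track_id))
        pairs = sorted({(a, b)
                        for lid in sorted(track.link_ids)
                        for a, b in zip(link_map[lid].object_ids,
                                        link_map[lid].object_ids[1:])})
        for a, b in pairs:
            etree.SubElement(track_el, "Edge", SPOT_SOURCE_ID=str(a),
                             SPOT_TARGET_ID=str(b))
    return etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="utf-8")


def emit_cellprofiler(pkg: BiotracksPackage) -> str:
    """Render a branch-free package as a CellProfiler-style tracking CSV.

    The label-column dialect can only express disjoint linear tracks:
    packages with splits/merges, links sharing objects, or within-link
    frame gaps are refused with :class:`UnexpressibleTopologyError`.
    Frames are written 1-based (ImageNumber), matching the default
    read-back mapping.
    """
    if detect_events(pkg.objects, pkg.links):
        raise UnexpressibleTopologyError(
            "unexpressible_topology: package contains split/merge events, "
            "which the label-column dialect cannot represent")
    counts: dict[int, int] = {}
    for link in pkg.links:
        for oid in link.object_ids:
            counts[oid] = counts.get(oid, 0) + 1
    if any(n > 1 for n in counts.values()):
        raise UnexpressibleTopologyError(
            "unexpressible_topology: links share objects; the label-column "
            "dialect would fuse them into one run")
    frames = {o.object_id: o.frame for o in pkg.objects}
    for link in pkg.links:
        seq = [frames[oid] for oid in link.object_ids]
        if any(b != a + 1 for a, b in zip(seq, seq[1:])):
            raise UnexpressibleTopologyError(
                "unexpressible_topology: link contains frame gaps; the "
                "label-column dialect cannot distinguish a gap from a track end")

    feat_cols = sorted({name for o in pkg.objects for name in o.features})
    label_of: dict[int, int] = {}
    for label, link in enumerate(sorted(pkg.links, key=lambda l: l.link_id), start=1):
        for oid in link.object_ids:
            label_of[oid] = label

    rows = ["ImageNumber,ObjectNumber,Location_Center_X,Location_Center_Y,"
            "TrackObjects_Label" + ("," + ",".join(feat_cols) if feat_cols else "")]
    by_frame: dict[int, list[TrackedObject]] = {}
    for obj in pkg.objects:
        if obj.object_id in label_of:  # unlinked objects are not expressible rows
            by_frame.setdefault(obj.frame, []).append(obj)
    for frame in sorted(by_frame):
        for number, obj in enumerate(sorted(by_frame[frame],
                                            key=lambda o: o.object_id), start=1):
            cells = [str(frame + 1), str(number), repr(float(obj.x)),
                     repr(float(obj.y)), str(label_of[obj.object_id])]
            cells += [repr(float(obj.features[c])) if c in obj.features else ""
                      for c in feat_cols]
            rows.append(",".join(cells))
    return "\n".join(rows) + "\n"
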