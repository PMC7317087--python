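"""Converters from tracking-tool outputs to validated biotracks packages.

Three dialects are implemented: TrackMate-style XML (spots + edges),
CellProfiler-style tracking CSV (per-object rows with a tracking label
column), and a generic per-object CSV driven entirely by a user-supplied
column mapping. Icy and MosaicSuite are declared plugin points (see
:data:`PLUGIN_DIALECTS`) without core implementations.

All converters normalise frames to 0-based, remap source ids to dense
non-negative integers (mapping recorded in the descriptor), and return
packages that pass :func:`biotracks.model.validate_package`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml
from lxml import etree

from .model import BiotracksPackage, Link, TrackedObject, validate_package
from .package_io import PackageValidationError
from .topology import infer_tracks

__all__ = [
    "ColumnMapping",
    "DialectError",
    "PLUGIN_DIALECTS",
    "read_trackmate",
    "read_cellprofiler",
    "read_generic_csv",
]

#: dialects declared but not implemented in the core
PLUGIN_DIALECTS = ("icy", "mosaicsuite")


class DialectError(ValueError):
    """Raised for malformed or unconvertible source documents."""


@dataclass
class ColumnMapping:
    """Maps source CSV columns onto the biotracks model.

    ``object_id`` may be omitted, in which case dense ids are
    synthesised in (frame, row) order. ``frame_base`` declares whether
    the source counts frames from 0 or 1 (normalised to 0-based).
    ``features`` lists passthrough columns; when None, every unmapped
    numeric column becomes a feature. ``gap_policy`` controls what a
    frame gap within one label does: ``"split"`` closes the link and
    opens a new one, ``"bridge"`` keeps one gap-containing link.
    """

    frame: str
    x: str
    y: str
    z: Optional[str] = None
    object_id: Optional[str] = None
    label: Optional[str] = None
    frame_base: int = 0
    features: Optional[list[str]] = None
    gap_policy: str = "split"

    def __post_init__(self) -> None:
        if self.frame_base not in (0, 1):
            raise DialectError(f"frame_base must be 0 or 1, got {self.frame_base}")
        if self.gap_policy not in ("split", "bridge"):
            raise DialectError(f"gap_policy must be 'split' or 'bridge', "
                               f"got {self.gap_policy!r}")
        mapped = [c for c in (self.frame, self.x, self.y, self.z,
                              self.object_id, self.label) if c is not None]
        if len(set(mapped)) != len(mapped):
            raise DialectError(f"mapped source columns must be distinct: {mapped}")

    @classmethod
    def from_dict(cls, data: dict) -> "ColumnMapping":
        known = {f for f in cls.__dataclass_fields__}  # noqa: F821
        unknown = set(data) - known
        if unknown:
            raise DialectError(f"unknown mapping keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "ColumnMapping":
        """Load a mapping from a YAML or JSON file (YAML is a JSON superset)."""
        with open(path, encoding="utf-8") as handle:
            data = yaml.safe_load(handle)
        if not isinstance(data, dict):
            raise DialectError(f"mapping file {path} must hold a mapping object")
        return cls.from_dict(data)


def _finalise(objects: list[TrackedObject], links: list[Link],
              descriptor: dict, with_tracks: bool = True) -> BiotracksPackage:
    pkg = BiotracksPackage(objects=objects, links=links, descriptor=descriptor)
    report = validate_package(pkg)
    if not report.ok:
        raise PackageValidationError("conversion produced an invalid package", report)
    if with_tracks and links:
        pkg.tracks = infer_tracks(objects, links)
    elif with_tracks:
        pkg.tracks = []
    return pkg


# ---------------------------------------------------------------------------
# TrackMate-style XML
# ---------------------------------------------------------------------------

_SPOT_POSITION_ATTRS = {"POSITION_X", "POSITION_Y", "POSITION_Z", "FRAME",
                        "POSITION_T", "ID", "name"}


def _chain_decomposition(edges: list[tuple[int, int]]) -> list[list[int]]:
    """Decompose a directed edge set into maximal linear chains.

    A chain is a maximal path whose interior nodes have in-degree =
    out-degree = 1; branch and terminal nodes are chain endpoints, so
    splits/merges surface as objects shared across chains.
    """
    out_edges: dict[int, list[int]] = {}
    in_deg: dict[int, int] = {}
    nodes: set[int] = set()
    for a, b in sorted(set(edges)):
        out_edges.setdefault(a, []).append(b)
        in_deg[b] = in_deg.get(b, 0) + 1
        nodes.update((a, b))

    def is_break(node: int) -> bool:
        return in_deg.get(node, 0) != 1 or len(out_edges.get(node, ())) != 1

    chains: list[list[int]] = []
    for start in sorted(nodes):
        if not is_break(start):
            continue
        for nxt in out_edges.get(start, ()):
            chain = [start, nxt]
            while not is_break(chain[-1]):
                chain.append(out_edges[chain[-1]][0])
            chains.append(chain)
    return chains


def read_trackmate(source: Union[str, Path, bytes]) -> BiotracksPackage:
    """Convert a TrackMate-style XML document into a biotracks package.

    Spots become objects (position/frame attributes bound, remaining
    numeric spot attributes kept as features); the per-track edge lists
    are decomposed into maximal linear chains which become links.
    ``source`` is a path or raw XML bytes/string.
    """
    try:
        if isinstance(source, bytes):
            root = etree.fromstring(source)
        elif isinstance(source, str) and source.lstrip().startswith("<"):
            root = etree.fromstring(source.encode("utf-8"))
        else:
            root = etree.parse(str(source)).getroot()
    except etree.XMLSyntaxError as exc:
        raise DialectError(f"malformed XML: {exc}") from exc

    model = root if root.tag == "Model" else root.find("Model")
    if model is None:
        raise DialectError("document has no <Model> element")

    spots: dict[int, dict] = {}
    for frame_el in model.iterfind(".//AllSpots/SpotsInFrame"):
        frame_attr = frame_el.get("frame")
        for spot in frame_el.iterfind("Spot"):
            sid = int(spot.get("ID"))
            frame = int(float(spot.get("FRAME", frame_attr)))
            features = {}
            for key, value in spot.attrib.items():
                if key in _SPOT_POSITION_ATTRS:
                    continue
                try:
                    features[key.lower()] = float(value)
                except ValueError:
                    pass  # non-numeric attributes are dropped (features are numeric)
            zraw = spot.get("POSITION_Z")
            spots[sid] = {
                "frame": frame,
                "x": float(spot.get("POSITION_X")),
                "y": float(spot.get("POSITION_Y")),
                "z": float(zraw) if zraw is not None else None,
                "features": features,
            }
    if not spots:
        raise DialectError("document contains no spots")

    edges: list[tuple[int, int]] = []
    source_track_count = 0
    for track in model.iterfind(".//AllTracks/Track"):
        source_track_count += 1
        for edge in track.iterfind("Edge"):
            a = int(edge.get("SPOT_SOURCE_ID"))
            b = int(edge.get("SPOT_TARGET_ID"))
            for sid in (a, b):
                if sid not in spots:
                    raise DialectError(f"edge references unknown spot {sid}")
            edges.append((a, b))

    id_map = {sid: i for i, sid in enumerate(sorted(spots))}
    objects = [TrackedObject(object_id=id_map[sid], frame=s["frame"], x=s["x"],
                             y=s["y"], z=s["z"], features=s["features"])
               for sid, s in sorted(spots.items())]
    chains = _chain_decomposition(edges)
    links = [Link(i, tuple(id_map[sid] for sid in chain))
             for i, chain in enumerate(chains)]

    descriptor = {"conversion": {
        "dialect": "trackmate",
        "source_id_map": {str(k): v for k, v in sorted(id_map.items())},
    }}
    pkg = _finalise(objects, links, descriptor)
    if source_track_count and pkg.tracks is not None \
            and len(pkg.tracks) != source_track_count:
        pkg.descriptor["conversion"]["warning"] = (
            f"source groups edges into {source_track_count} tracks; "
            f"recomputed components give {len(pkg.tracks)}")
    return pkg


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

def _load_table(source: Union[str, Path, pd.DataFrame]) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source.copy()
    try:
        return pd.read_csv(source)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise DialectError(f"cannot read table {source}: {exc}") from exc


def _segment_runs(frames: Sequence[int], gap_policy: str) -> list[list[int]]:
    """Indices of ``frames`` grouped into link segments per the gap policy."""
    runs: list[list[int]] = [[0]]
    for i in range(1, len(frames)):
        if gap_policy == "split" and frames[i] != frames[i - 1] + 1:
            runs.append([i])
        else:
            runs[-1].append(i)
    return runs


def _csv_to_package(table: pd.DataFrame, mapping: ColumnMapping,
                    dialect: str) -> BiotracksPackage:
    required = [mapping.frame, mapping.x, mapping.y]
    if mapping.z:
        required.append(mapping.z)
    if mapping.object_id:
        required.append(mapping.object_id)
    if mapping.label:
        required.append(mapping.label)
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise DialectError(f"mapping names columns absent from the table: {missing}")

    if mapping.object_id is not None:
        dupes = table.duplicated(subset=[mapping.frame, mapping.object_id])
        if dupes.any():
            raise DialectError(
                f"duplicate (frame, object id) rows at indices "
                f"{table.index[dupes].tolist()}")

    if mapping.features is not None:
        feat_cols = list(mapping.features)
        missing_feats = [c for c in feat_cols if c not in table.columns]
        if missing_feats:
            raise DialectError(f"feature columns absent from table: {missing_feats}")
    else:
        mapped = {mapping.frame, mapping.x, mapping.y, mapping.z,
                  mapping.object_id, mapping.label}
        feat_cols = [c for c in table.columns
                     if c not in mapped and pd.api.types.is_numeric_dtype(table[c])]

    work = table.copy()
    work["__frame"] = work[mapping.frame].astype(int) - mapping.frame_base
    if mapping.object_id is not None:
        order_keys = ["__frame", mapping.object_id]
    else:
        work["__row"] = range(len(work))
        order_keys = ["__frame", "__row"]
    work = work.sort_values(order_keys, kind="stable").reset_index(drop=True)

    objects: list[TrackedObject] = []
    for oid, row in enumerate(work.itertuples(index=False)):
        record = dict(zip(work.columns, row))
        features = {c: float(record[c]) for c in feat_cols
                    if pd.notna(record[c])}
        objects.append(TrackedObject(
            object_id=oid,
            frame=int(record["__frame"]),
            x=float(record[mapping.x]),
            y=float(record[mapping.y]),
            z=float(record[mapping.z]) if mapping.z else None,
            features=features))

    links: list[Link] = []
    warning = None
    if mapping.label is not None:
        labels = work[mapping.label]
        chains: list[tuple] = []
        for label in sorted(labels.dropna().unique()):
            member_rows = work.index[labels == label].tolist()
            member_rows.sort(key=lambda i: work.at[i, "__frame"])
            frames = [int(work.at[i, "__frame"]) for i in member_rows]
            if len(set(frames)) != len(frames):
                raise DialectError(
                    f"label {label!r} appears more than once in one frame")
            for run in _segment_runs(frames, mapping.gap_policy):
                if len(run) >= 2:
                    chains.append((label, tuple(member_rows[i] for i in run)))
        links = [Link(lid, rows) for lid, (_, rows) in enumerate(chains)]
    else:
        warning = ("no_linking_column: mapping declares no label column; "
                   "emitting an objects-only package")

    descriptor: dict = {"conversion": {"dialect": dialect,
                                       "frame_base": mapping.frame_base}}
    if warning:
        descriptor["conversion"]["warning"] = warning
    return _finalise(objects, links, descriptor)


#: default mapping for CellProfiler TrackObjects exports (1-based frames)
CELLPROFILER_DEFAULT = ColumnMapping(
    frame="ImageNumber", object_id="ObjectNumber",
    x="Location_Center_X", y="Location_Center_Y",
    label="TrackObjects_Label", frame_base=1)


def read_cellprofiler(source: Union[str, Path, pd.DataFrame],
                      mapping: Optional[ColumnMapping] = None) -> BiotracksPackage:
    """Convert a CellProfiler-style tracking CSV into a biotracks package.

    One row per object per frame; objects sharing a tracking label are
    connected in consecutive-frame order into linear links. A frame gap
    within one label closes the link and opens a new one (gap policy
    ``"split"``, the default) or is bridged into one gap-containing link
    (``"bridge"``). Frames are normalised from the source's frame base
    (1-based by default for CellProfiler).
    """
    if mapping is None:
        mapping = CELLPROFILER_DEFAULT
    return _csv_to_package(_load_table(source), mapping, "cellprofiler")


def read_generic_csv(source: Union[str, Path, pd.DataFrame],
                     mapping: ColumnMapping) -> BiotracksPackage:
    """Convert an arbitrary per-object CSV via an explicit column mapping.

    Without a label column the result is a valid objects-only package
    (links empty) and the descriptor carries a ``no_linking_column``
    warning.
    """
    return _csv_to_package(_load_table(source), mapping, "generic")
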