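"""Read/write biotracks packages as a Tabular Data Package.

Layout on disk::

    <dir>/datapackage.json   descriptor: general metadata + per-table schemas
    <dir>/objects.csv        one row per detection
    <dir>/links.csv          long form: one row per (link_id, object_id), ordered
    <dir>/tracks.csv         long form: one row per (track_id, link_id); optional

Column names carry a ``cmso_`` prefix (cmso_object_id, cmso_frame_id,
cmso_x_coord, ...) so that tool-specific feature columns can never
collide with the bound columns. CSVs are UTF-8, comma-delimited, LF
terminated, RFC 4180 quoted; floats use the shortest round-trip
representation and the descriptor JSON is written with sorted keys, so
writing the same package twice is byte-identical.
"""

from __future__ import annotations

import csv
import io
import json
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import jsonschema

from .model import (
    BiotracksPackage,
    Link,
    Track,
    TrackedObject,
    ValidationReport,
    validate_package,
)

__all__ = [
    "FORMAT_VERSION",
    "COL",
    "PackageValidationError",
    "build_descriptor",
    "validate_descriptor",
    "write_package",
    "read_package",
]

FORMAT_VERSION = "0.1"
PROFILE = "tabular-data-package"

#: canonical bound column names
COL = {
    "object_id": "cmso_object_id",
    "frame": "cmso_frame_id",
    "x": "cmso_x_coord",
    "y": "cmso_y_coord",
    "z": "cmso_z_coord",
    "link_id": "cmso_link_id",
    "track_id": "cmso_track_id",
}


class PackageValidationError(ValueError):
    """Raised when reading or writing a package that fails validation."""

    def __init__(self, message: str, report: Optional[ValidationReport] = None):
        self.report = report
        if report is not None:
            message = f"{message}\n{report}"
        super().__init__(message)


def _fmt(value: object) -> str:
    """Deterministic cell formatting: ints plain, floats shortest round-trip."""
    if isinstance(value, bool):
        raise TypeError("boolean table cells are not supported")
    if isinstance(value, int):
        return str(value)
    if isinstance(value, float):
        if value.is_integer() and abs(value) < 1e16:
            return f"{value:.1f}"
        return repr(value)
    return str(value)


def _feature_columns(objects: list[TrackedObject]) -> list[str]:
    names: set[str] = set()
    for obj in objects:
        names.update(obj.features)
    return sorted(names)


def build_descriptor(pkg: BiotracksPackage,
                     name: str = "biotracks-package",
                     spatial_unit: str = "pixel",
                     frame_interval: float = 1.0) -> dict:
    """Descriptor dict for a package: resources, schemas, biotracks block.

    Existing non-resource entries of ``pkg.descriptor`` (e.g. an embedded
    ``miacme`` block, an id-remapping record) are carried over.
    """
    has_z = any(o.z is not None for o in pkg.objects)
    feat_cols = _feature_columns(pkg.objects)

    object_fields = [
        {"name": COL["object_id"], "type": "integer", "constraints": {"required": True}},
        {"name": COL["frame"], "type": "integer", "constraints": {"required": True}},
        {"name": COL["x"], "type": "number", "constraints": {"required": True}},
        {"name": COL["y"], "type": "number", "constraints": {"required": True}},
    ]
    if has_z:
        object_fields.append({"name": COL["z"], "type": "number"})
    object_fields += [{"name": c, "type": "number"} for c in feat_cols]

    resources = [
        {
            "name": "objects",
            "path": "objects.csv",
            "format": "csv",
            "mediatype": "text/csv",
            "schema": {"fields": object_fields},
        },
        {
            "name": "links",
            "path": "links.csv",
            "format": "csv",
            "mediatype": "text/csv",
            "schema": {"fields": [
                {"name": COL["link_id"], "type": "integer",
                 "constraints": {"required": True}},
                {"name": COL["object_id"], "type": "integer",
                 "constraints": {"required": True}},
            ]},
        },
    ]
    if pkg.tracks is not None:
        resources.append({
            "name": "tracks",
            "path": "tracks.csv",
            "format": "csv",
            "mediatype": "text/csv",
            "schema": {"fields": [
                {"name": COL["track_id"], "type": "integer",
                 "constraints": {"required": True}},
                {"name": COL["link_id"], "type": "integer",
                 "constraints": {"required": True}},
            ]},
        })

    bindings = {"object_id": COL["object_id"], "frame": COL["frame"],
                "x": COL["x"], "y": COL["y"]}
    if has_z:
        bindings["z"] = COL["z"]

    descriptor = {k: v for k, v in pkg.descriptor.items() if k != "resources"}
    descriptor.update({
        "name": name if "name" not in descriptor else descriptor["name"],
        "profile": PROFILE,
        "resources": resources,
        "biotracks": {
            "format_version": FORMAT_VERSION,
            "bindings": bindings,
            "spatial_unit": spatial_unit,
            "frame_interval": frame_interval,
        },
    })
    # preserve a previously configured biotracks block's units/interval
    previous = pkg.descriptor.get("biotracks", {})
    for key in ("spatial_unit", "frame_interval"):
        if key in previous:
            descriptor["biotracks"][key] = previous[key]
    return descriptor


def _descriptor_schema() -> dict:
    text = resources.files("biotracks.data").joinpath("descriptor_schema.json").read_text()
    return json.loads(text)


def validate_descriptor(descriptor: dict) -> ValidationReport:
    """Structural check of a descriptor document.

    Reports schema violations, an unknown profile, missing objects/links
    resources, and bindings that point at columns absent from the bound
    resource's schema.
    """
    report = ValidationReport()
    validator = jsonschema.Draft7Validator(_descriptor_schema())
    for err in sorted(validator.iter_errors(descriptor), key=lambda e: list(e.absolute_path)):
        path = "/".join(str(p) for p in err.absolute_path) or "<root>"
        report.error("descriptor_schema", err.message, path)
    if not isinstance(descriptor, dict):
        return report

    if descriptor.get("profile") != PROFILE:
        report.error("unknown_profile",
                     f"profile {descriptor.get('profile')!r} is not {PROFILE!r}",
                     "profile")
    by_name = {r.get("name"): r for r in descriptor.get("resources", [])
               if isinstance(r, dict)}
    if "objects" not in by_name:
        report.error("missing_objects_resource", "no resource named 'objects'",
                     "resources")
    if "links" not in by_name:
        report.error("missing_links_resource", "no resource named 'links'",
                     "resources")
    bindings = descriptor.get("biotracks", {}).get("bindings", {})
    obj_res = by_name.get("objects")
    if obj_res is not None and isinstance(bindings, dict):
        columns = {f.get("name") for f in obj_res.get("schema", {}).get("fields", [])}
        for role, column in sorted(bindings.items()):
            if column not in columns:
                report.error("dangling_binding",
                             f"binding {role!r} -> {column!r} names a column absent "
                             "from the objects schema", "biotracks/bindings")
    return report


def _write_csv(path: Path, header: list[str], rows: list[list[object]]) -> None:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(header)
    for row in rows:
        writer.writerow([_fmt(v) for v in row])
    path.write_text(buf.getvalue(), encoding="utf-8")


def write_package(pkg: BiotracksPackage, directory: Union[str, Path],
                  name: str = "biotracks-package",
                  spatial_unit: str = "pixel",
                  frame_interval: float = 1.0) -> list[Path]:
    """Serialise a valid package to ``directory``; returns the written files.

    Refuses invalid packages (raises :class:`PackageValidationError` with
    the report attached).
    """
    report = validate_package(pkg)
    if not report.ok:
        raise PackageValidationError("refusing to write an invalid package", report)

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    descriptor = build_descriptor(pkg, name=name, spatial_unit=spatial_unit,
                                  frame_interval=frame_interval)
    written: list[Path] = []

    has_z = "z" in descriptor["biotracks"]["bindings"]
    feat_cols = _feature_columns(pkg.objects)
    header = [COL["object_id"], COL["frame"], COL["x"], COL["y"]]
    if has_z:
        header.append(COL["z"])
    header += feat_cols
    rows = []
    for obj in sorted(pkg.objects, key=lambda o: o.object_id):
        row: list[object] = [obj.object_id, obj.frame, float(obj.x), float(obj.y)]
        if has_z:
            row.append(float(obj.z) if obj.z is not None else "")
        row += [float(obj.features[c]) if c in obj.features else "" for c in feat_cols]
        rows.append(row)
    objects_path = directory / "objects.csv"
    _write_csv(objects_path, header, rows)
    written.append(objects_path)

    links_path = directory / "links.csv"
    link_rows = [[ln.link_id, oid]
                 for ln in sorted(pkg.links, key=lambda l: l.link_id)
                 for oid in ln.object_ids]
    _write_csv(links_path, [COL["link_id"], COL["object_id"]], link_rows)
    written.append(links_path)

    if pkg.tracks is not None:
        tracks_path = directory / "tracks.csv"
        track_rows = [[t.track_id, lid]
                      for t in sorted(pkg.tracks, key=lambda t: t.track_id)
                      for lid in sorted(t.link_ids)]
        _write_csv(tracks_path, [COL["track_id"], COL["link_id"]], track_rows)
        written.append(tracks_path)

    desc_path = directory / "datapackage.json"
    desc_path.write_text(json.dumps(descriptor, sort_keys=True, indent=2) + "\n",
                         encoding="utf-8")
    written.append(desc_path)
    return written


def _parse_cell(text: str, ftype: str) -> Optional[float]:
    if text == "":
        return None
    return int(text) if ftype == "integer" else float(text)


def read_package(directory: Union[str, Path],
                 infer_tracks_if_absent: bool = False) -> BiotracksPackage:
    """Read a package directory back into memory.

    Tables are parsed per the descriptor's schemas and column bindings.
    The result must pass validation, otherwise
    :class:`PackageValidationError` is raised with the report attached.
    A missing tracks table stays absent unless ``infer_tracks_if_absent``
    (never materialised silently).
    """
    directory = Path(directory)
    desc_path = directory / "datapackage.json"
    if not desc_path.is_file():
        raise PackageValidationError(f"no descriptor at {desc_path}")
    descriptor = json.loads(desc_path.read_text(encoding="utf-8"))

    desc_report = validate_descriptor(descriptor)
    if not desc_report.ok:
        raise PackageValidationError(f"invalid descriptor at {desc_path}", desc_report)

    by_name = {r["name"]: r for r in descriptor["resources"]}
    for rname, res in by_name.items():
        if not (directory / res["path"]).is_file():
            raise PackageValidationError(
                f"missing_resource: resource {rname!r} file {res['path']!r} "
                f"is absent from {directory}")

    def load(resource: dict) -> tuple[list[str], list[dict[str, Optional[float]]]]:
        path = directory / resource["path"]
        types = {f["name"]: f.get("type", "number")
                 for f in resource["schema"]["fields"]}
        with path.open(newline="", encoding="utf-8") as handle:
            reader = csv.reader(handle)
            header = next(reader)
            unknown = [c for c in header if c not in types]
            if unknown:
                raise PackageValidationError(
                    f"columns {unknown} in {path.name} are not declared in the "
                    "descriptor schema")
            parsed = []
            for lineno, row in enumerate(reader, start=2):
                try:
                    parsed.append({c: _parse_cell(v, types[c])
                                   for c, v in zip(header, row)})
                except ValueError as exc:
                    raise PackageValidationError(
                        f"{path.name}:{lineno}: {exc}") from exc
        return header, parsed

    bindings = descriptor["biotracks"]["bindings"]
    header, rows = load(by_name["objects"])
    bound = set(bindings.values())
    feat_cols = [c for c in header if c not in bound]
    objects = []
    for row in rows:
        features = {c: row[c] for c in feat_cols if row.get(c) is not None}
        zval = row.get(bindings["z"]) if "z" in bindings else None
        objects.append(TrackedObject(
            object_id=int(row[bindings["object_id"]]),
            frame=int(row[bindings["frame"]]),
            x=row[bindings["x"]], y=row[bindings["y"]], z=zval,
            features=features))

    _, link_rows = load(by_name["links"])
    chains: dict[int, list[int]] = {}
    for row in link_rows:
        chains.setdefault(int(row[COL["link_id"]]), []).append(int(row[COL["object_id"]]))
    links = [Link(lid, tuple(chains[lid])) for lid in sorted(chains)]

    tracks: Optional[list[Track]] = None
    if "tracks" in by_name:
        _, track_rows = load(by_name["tracks"])
        grouping: dict[int, set[int]] = {}
        for row in track_rows:
            grouping.setdefault(int(row[COL["track_id"]]), set()).add(
                int(row[COL["link_id"]]))
        tracks = [Track(tid, frozenset(grouping[tid])) for tid in sorted(grouping)]

    pkg = BiotracksPackage(objects=objects, links=links, tracks=tracks,
                           descriptor=descriptor)
    report = validate_package(pkg)
    if not report.ok:
        raise PackageValidationError(f"package at {directory} failed validation",
                                     report)
    if tracks is None and infer_tracks_if_absent:
        from .topology import infer_tracks
        pkg.tracks = infer_tracks(objects, links)
    return pkg
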