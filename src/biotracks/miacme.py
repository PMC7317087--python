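"""MIACME metadata: validation and embedding into a package descriptor.

MIACME (Minimum Information About a Cell Migration Experiment)
organises experiment metadata into three conceptual domains —
experimental set-up (assay, cell model, environment, perturbations),
imaging condition (modality, instrument, channel/time settings), and
data (raw image summary, replicates, processed/analysis outputs) — plus
generic investigation information.

Validation is two-layered: a JSON-schema structural check (shape of
term annotations, positive counts, value types) followed by a
declarative requirement table mapping field paths to MUST/SHOULD
levels. A missing MUST field is an error, a missing SHOULD field a
warning. Term annotations are shape-checked offline only (label /
source / accession); no ontology lookup is ever performed.
"""

from __future__ import annotations

import copy
import json
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import jsonschema
import yaml

from .model import BiotracksPackage, ValidationReport

__all__ = [
    "SUPPORTED_VERSIONS",
    "load_example_document",
    "load_requirement_table",
    "validate_miacme",
    "embed_miacme",
    "MiacmeError",
]

SUPPORTED_VERSIONS = ("1.1",)


class MiacmeError(ValueError):
    """Raised when embedding a document with MUST-level errors."""

    def __init__(self, message: str, report: Optional[ValidationReport] = None):
        self.report = report
        if report is not None:
            message = f"{message}\n{report}"
        super().__init__(message)


def _data_text(filename: str) -> str:
    return resources.files("biotracks.data").joinpath(filename).read_text()


def load_example_document() -> dict:
    """The shipped complete example document (synthetic, schema-complete)."""
    return json.loads(_data_text("miacme_example_synthetic.json"))


def load_requirement_table(version: str = "1.1",
                           path: Optional[Union[str, Path]] = None) -> dict[str, str]:
    """Requirement levels (field path -> MUST/SHOULD) for a MIACME version.

    The table ships as YAML and can be overridden with ``path``.
    """
    if path is not None:
        tables = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    else:
        tables = yaml.safe_load(_data_text("miacme_requirements.yaml"))
    if version not in tables:
        raise KeyError(f"no requirement table for MIACME version {version!r}")
    return dict(tables[version])


def _schema(version: str) -> dict:
    return json.loads(_data_text(f"miacme_schema_{version}.json"))


def _lookup(document: dict, dotted: str) -> tuple[bool, object]:
    node: object = document
    for part in dotted.split("."):
        if not isinstance(node, dict) or part not in node:
            return False, None
        node = node[part]
    return True, node


def _is_empty(value: object) -> bool:
    return value is None or value == "" or value == [] or value == {}


def validate_miacme(document: object,
                    requirement_table: Optional[dict[str, str]] = None) -> ValidationReport:
    """Validate a MIACME document; returns a report, never raises.

    Unknown extra fields are preserved and never flagged (open world);
    validation is independent of field order. The document must declare
    ``miacme_version``; unknown versions are an error. When a MUST-level
    parent section is missing, only the parent is reported, not its
    missing children.
    """
    report = ValidationReport()
    if not isinstance(document, dict):
        report.error("not_an_object", "MIACME document must be a JSON object")
        return report
    version = document.get("miacme_version")
    if version is None:
        report.error("missing_version", "document lacks 'miacme_version'")
        return report
    if version not in SUPPORTED_VERSIONS:
        report.error("unknown_version",
                     f"miacme_version {version!r} not in {SUPPORTED_VERSIONS}")
        return report

    validator = jsonschema.Draft7Validator(_schema(version))
    for err in sorted(validator.iter_errors(document),
                      key=lambda e: list(map(str, e.absolute_path))):
        path = ".".join(str(p) for p in err.absolute_path) or "<root>"
        report.error("schema_violation", err.message, path)

    if requirement_table is None:
        requirement_table = load_requirement_table(version)
    missing_reported: list[str] = []
    for dotted in sorted(requirement_table):
        level = requirement_table[dotted].upper()
        present, value = _lookup(document, dotted)
        if present and not _is_empty(value):
            continue
        if any(dotted.startswith(parent + ".") for parent in missing_reported):
            continue  # parent already reported; avoid cascading duplicates
        missing_reported.append(dotted)
        if level == "MUST":
            report.error("missing_required_field",
                         f"MUST-level field {dotted!r} is missing or empty", dotted)
        elif level == "SHOULD":
            report.warning("missing_recommended_field",
                           f"SHOULD-level field {dotted!r} is missing or empty", dotted)
    return report


def embed_miacme(pkg: BiotracksPackage, document: dict,
                 requirement_table: Optional[dict[str, str]] = None) -> BiotracksPackage:
    """Attach a MIACME document to a package descriptor.

    The document is validated first; MUST-level errors make the embed
    refuse with :class:`MiacmeError`. The descriptor gains a ``miacme``
    block carrying the document verbatim plus its version; a second
    embed replaces the block (last write wins) and leaves a warning
    note in the block. Returns ``pkg`` (mutated in place).
    """
    report = validate_miacme(document, requirement_table)
    if not report.ok:
        raise MiacmeError("refusing to embed a MIACME document with MUST-level "
                          "errors", report)
    block = {"miacme_version": document["miacme_version"],
             "document": copy.deepcopy(document)}
    if "miacme" in pkg.descriptor:
        block["note"] = "replaced a previously embedded MIACME document"
    pkg.descriptor["miacme"] = block
    return pkg
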