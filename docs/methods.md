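# Methods

## The three-level model and its conventions

Objects, links, and tracks form a strict hierarchy: links reference
objects, tracks reference links. The conventions this package fixes where
the format itself leaves room:

- **Frames are 0-based integers.** Converters normalise source
  conventions (CellProfiler's `ImageNumber` is 1-based) to 0-based.
- **Identifiers are non-negative integers.** Converters that meet
  arbitrary source ids remap them to dense integers in sorted source-id
  order and record the mapping in the descriptor
  (`conversion.source_id_map`), so identity across a conversion is always
  recoverable.
- **Coordinates are stored as given by the source** — no rescaling. The
  descriptor records the spatial unit and the frame interval; statistics
  take the frame interval as a parameter.
- **Frame gaps inside a link are legal** (frames strictly increasing, not
  necessarily consecutive): gap-closing trackers produce such links, and
  the simulator's dropout exercises them.
- **An object may appear in several links but at most once per link.**
  This is how splits and merges are representable with purely linear
  links: a division is a parent link ending at a pivot object that two
  daughter links begin with.
- **Tracks partition the links** and each track must be connected through
  shared objects. Whether lineages should instead separate at merges
  (collision vs. fusion semantics) is left to downstream analysis; the
  track keeps one component and the split/merge events are reported
  separately.

Validation never raises on malformed content: every violation becomes a
coded issue (`duplicate_object_id`, `frame_order`, `dangling_reference`,
`unassigned_link`, `track_disconnected`, ...) in a report, so a package
with ten problems surfaces all ten at once. Validation is pure and
idempotent.

## Topology

The lineage graph has one node per linked object and one directed edge
per consecutive pair within a link; duplicate edges contributed by
several links collapse into one edge carrying all contributing link ids.
Tracks are the weakly connected components (direction ignored, so splits
and merges stay within one lineage), numbered deterministically: sort
components by their minimum contained link id, number from 0. This makes
`infer_tracks` invariant to link input order.

Splits are nodes with out-degree ≥ 2, merges nodes with in-degree ≥ 2;
events are reported sorted by pivot frame, then pivot id.

Branching tracks have no single trajectory, so per-track statistics
follow a **principal path**: the root-to-leaf path with the largest frame
span, ties broken by the smaller terminal (leaf, then root) object id.
The choice is computed by dynamic programming over the acyclic lineage
graph, so it is deterministic and linear-time. Elapsed time for the mean
speed uses the frame span of that path — not the object count — so
gap-closed links are timed correctly. Degenerate cases: a single-object
component gets all-zero statistics; a zero-length path (stationary cell)
reports confinement ratio 0 by convention.

## Serialisation

One directory per dataset: `datapackage.json` + `objects.csv` +
`links.csv` (+ `tracks.csv`). Link and track tables are long-form (one
row per membership, ordered), which keeps them trivially parseable by any
CSV reader. Byte-stability — writing the same package twice yields
byte-identical files — is guaranteed by fixed conventions: UTF-8, comma
delimiter, LF line endings, RFC 4180 quoting, rows sorted by id,
descriptor keys sorted, integers printed without a decimal point, floats
via Python's shortest round-trip `repr` (which also makes coordinate
round-trips exact, well inside the 1e-12 tolerance the tests assert).
The descriptor is validated against a JSON schema shipped with the
package; binding errors (a bound column absent from its schema) and
missing resources are reported with dedicated codes. A missing tracks
table is never materialised silently — only via an explicit flag.

## Converters

*TrackMate-style XML*: spots become objects (bound position/frame
attributes; remaining numeric spot attributes kept as features,
non-numeric ones dropped with the numeric-features contract). The edge
list is decomposed into **maximal linear chains** — paths whose interior
nodes have in-degree = out-degree = 1 — so branch nodes terminate chains
and lineage survives as shared endpoint objects. Components are
recomputed from the edges; if the source's own track grouping disagrees
in count, a warning is recorded in the descriptor rather than trusting
either side silently.

*CellProfiler-style CSV*: one row per object per frame; rows sharing a
tracking label connect in consecutive-frame order. A frame gap within a
label either closes the link and opens a new one (`split`, the default —
gap semantics differ across tracker configurations, and splitting is the
conservative reading) or bridges into one gap-containing link
(`bridge`). The label dialect cannot express branching, shared objects,
or (under the default policy) within-link gaps; the matching emitter
refuses such packages with `unexpressible_topology` instead of writing a
file that would not round-trip.

*Generic CSV*: the CellProfiler engine without tool assumptions, driven
entirely by a user-supplied column mapping (YAML/JSON); with no label
column it produces a valid objects-only package and a
`no_linking_column` warning. Icy and MosaicSuite are declared plugin
dialects without core implementations.

## MIACME metadata

Documents are JSON with three cell-migration domains (experimental
set-up, imaging condition, data) plus investigation information.
Validation layers a JSON-schema shape check (term annotations are
label/source/accession triples, accession requires a source, counts are
positive integers) under a **declarative requirement table** shipped as
YAML: field path → MUST/SHOULD. Missing MUST fields are errors, missing
SHOULD fields warnings; when a whole MUST section is absent only the
section is reported, not each missing child, so one deletion maps to one
error. The table is a working approximation of the full MIACME 1.1 field
list and is deliberately editable as data. Validation is open-world
(unknown fields pass through untouched) and fully offline — term
annotations are shape-checked, never resolved against an ontology
service. Embedding copies the document verbatim into the descriptor's
`miacme` block; documents with MUST-level errors are refused, and a
re-embed replaces the block with a note.

## The simulator

`simulate_tracks` emulates a segmentation + linking pipeline on a
single-cell migration movie, and every dataset ships with a ground-truth
ledger (true paths, true events with pivot frames, true track
partition), so detectors are scored exactly rather than approximately.

Model and defaults:

- **Motility**: 2D random walk, isotropic Gaussian steps with per-axis
  scale `sigma` (default 1.0 units/frame) plus an optional constant
  drift. Step lengths are therefore Rayleigh with mean
  `sigma * sqrt(pi/2)` — the statistical contract the tests check over
  ≥ 10⁴ steps within 3 standard errors.
- **Scale**: 5 initial cells, 20 frames by default — the size of a small
  field of view; acceptance runs use 4 cells × 12 frames across many
  seeds and event regimes, and 50 cells × 201 frames for the step-length
  statistic.
- **Divisions**: per cell per frame with probability `split_prob`; the
  parent's current detection becomes the pivot shared with two daughter
  links. `split_schedule` forces exact frames (`{1: 1.0}` → exactly one
  division at frame 1).
- **Merges**: two cells within a capture radius (default `3*sigma`,
  floor 1.0) coalesce with probability `merge_prob` per pair per frame;
  the fused stream's first detection is the pivot terminating both
  parent links. Initial cells are placed `initial_spacing` apart
  (default 5.0 units), so merge-heavy scenarios use smaller spacing to
  put pairs in radius.
- **Dropout**: each interior, non-pivot detection of a segment is removed
  with probability `dropout_prob`, creating within-link frame gaps
  without ever deleting an event pivot or a segment endpoint.
- **Features**: per-object area drawn lognormal(log 100, 0.25) —
  a plausible cell-area distribution in square pixels.
- **Randomness**: one `numpy` generator seeded from the config; identical
  configs give byte-identical packages.

What the simulator does **not** emulate: detection noise on positions
(objects are the true walk positions), false positives, identity-switch
linking errors, realistic biophysical motility (persistence, contact
inhibition), or pixel data. Passing tests therefore demonstrate that the
format, topology, converters, and statistics are correct on clean,
well-formed tracking output — not that any upstream tracker is accurate.

## Numerical and design choices

- Distances are Euclidean (`math.dist`); mixed 2D/3D tracks treat a
  missing z as 0.
- Floats survive round trips exactly (shortest-repr); the 1e-12 relative
  tolerance in round-trip checks is therefore slack, not a requirement.
- Exit codes in the CLI: 0 success, 1 validation failure, 2 usage/I-O
  error; logs go to stderr, machine-readable JSON to stdout with
  `--json`.
- Problem sizes in tests and the acceptance script (≤ 400 objects,
  ≤ 200 links per random instance; 20 seeds; 10⁴ steps) are desk-scale
  choices: large enough to exercise every code path and give the
  statistical checks power, small enough to run in seconds.

## Known limitations

- One objects table (one field of view) per package; multi-FOV bundling
  is out of scope.
- Objects are points with features; masks/ROI geometry are not stored.
- The MIACME requirement table approximates the specification's full
  field list; deployments can replace the YAML.
- No MSD/diffusion fitting or chemotaxis indices — the statistics stop at
  speed, displacement, and confinement.
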