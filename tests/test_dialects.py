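"""Tracking-tool dialect converters: TrackMate XML, CellProfiler CSV, generic CSV."""

import io

import pandas as pd
import pytest

from biotracks import (
    ColumnMapping,
    DialectError,
    SimulationConfig,
    build_lineage_graph,
    detect_events,
    emit_trackmate,
    read_cellprofiler,
    read_generic_csv,
    read_trackmate,
    simulate_tracks,
    validate_package,
)

TRACKMATE_LINEAR = b"""<?xml version="1.0"?>
<TrackMate version="7">
  <Model>
    <AllSpots>
      <SpotsInFrame frame="0">
        <Spot ID="10" FRAME="0" POSITION_X="1.0" POSITION_Y="2.0" MEAN_INTENSITY="30.0" name="s10"/>
      </SpotsInFrame>
      <SpotsInFrame frame="1">
        <Spot ID="11" FRAME="1" POSITION_X="1.5" POSITION_Y="2.5" MEAN_INTENSITY="31.0" name="s11"/>
      </SpotsInFrame>
      <SpotsInFrame frame="2">
        <Spot ID="12" FRAME="2" POSITION_X="2.0" POSITION_Y="3.0" MEAN_INTENSITY="32.0" name="s12"/>
      </SpotsInFrame>
    </AllSpots>
    <AllTracks>
      <Track TRACK_ID="0">
        <Edge SPOT_SOURCE_ID="10" SPOT_TARGET_ID="11"/>
        <Edge SPOT_SOURCE_ID="11" SPOT_TARGET_ID="12"/>
      </Track>
    </AllTracks>
  </Model>
</TrackMate>
"""

TRACKMATE_SPLIT = TRACKMATE_LINEAR.replace(
    b'</SpotsInFrame>\n      <SpotsInFrame frame="2">',
    b'</SpotsInFrame>\n      <SpotsInFrame frame="2">\n        '
    b'<Spot ID="13" FRAME="2" POSITION_X="0.5" POSITION_Y="1.5" '
    b'MEAN_INTENSITY="29.0" name="s13"/>').replace(
    b'<Edge SPOT_SOURCE_ID="11" SPOT_TARGET_ID="12"/>',
    b'<Edge SPOT_SOURCE_ID="11" SPOT_TARGET_ID="12"/>\n        '
    b'<Edge SPOT_SOURCE_ID="11" SPOT_TARGET_ID="13"/>')


class TestTrackMate:
    def test_linear_chain(self):
        pkg = read_trackmate(TRACKMATE_LINEAR)
        assert len(pkg.objects) == 3
        assert len(pkg.links) == 1 and pkg.links[0].object_ids == (0, 1, 2)
        assert len(pkg.tracks) == 1

    def test_spot_attributes_become_features(self):
        pkg = read_trackmate(TRACKMATE_LINEAR)
        assert pkg.objects[0].features == {"mean_intensity": 30.0}

    def test_branch_decomposes_into_shared_links(self):
        pkg = read_trackmate(TRACKMATE_SPLIT)
        assert len(pkg.links) == 3
        events = detect_events(pkg.objects, pkg.links)
        assert [(e.kind.value, e.pivot_object_id) for e in events] == [("split", 1)]
        assert len(pkg.tracks) == 1

    def test_converter_output_validates(self):
        for doc in (TRACKMATE_LINEAR, TRACKMATE_SPLIT):
            assert validate_package(read_trackmate(doc)).ok

    def test_malformed_xml_rejected(self):
        with pytest.raises(DialectError, match="malformed"):
            read_trackmate(b"<TrackMate><Model>")

    def test_edge_to_unknown_spot_rejected(self):
        bad = TRACKMATE_LINEAR.replace(b'SPOT_TARGET_ID="12"',
                                       b'SPOT_TARGET_ID="99"')
        with pytest.raises(DialectError, match="unknown spot"):
            read_trackmate(bad)

    @pytest.mark.parametrize("seed", range(6))
    def test_simulator_roundtrip_preserves_lineage_graph(self, seed):
        pkg, _ = simulate_tracks(SimulationConfig(
            n_initial_cells=3, n_frames=10, split_prob=0.1, merge_prob=0.05,
            dropout_prob=0.1, initial_spacing=2.0, seed=seed))
        back = read_trackmate(emit_trackmate(pkg))
        inverse = {new: int(old) for old, new
                   in back.descriptor["conversion"]["source_id_map"].items()}
        g_orig = build_lineage_graph(pkg.objects, pkg.links)
        g_back = build_lineage_graph(back.objects, back.links)
        assert {inverse[n] for n in g_back.nodes} == set(g_orig.nodes)
        assert {(inverse[a], inverse[b]) for a, b in g_back.edges} == \
            set(g_orig.edges)

    def test_edge_count_preserved(self):
        pkg, _ = simulate_tracks(SimulationConfig(
            n_initial_cells=3, n_frames=8, split_prob=0.2, seed=4))
        back = read_trackmate(emit_trackmate(pkg))
        n_edges = sum(len(ln.object_ids) - 1 for ln in pkg.links)
        assert sum(len(ln.object_ids) - 1 for ln in back.links) == n_edges


CP_CSV = """ImageNumber,ObjectNumber,Location_Center_X,Location_Center_Y,TrackObjects_Label,AreaShape_Area
1,1,0.0,0.0,1,100
2,1,1.0,0.5,1,101
3,1,2.0,1.0,1,102
4,1,3.0,1.5,1,103
"""


class TestCellProfiler:
    def test_frames_normalised_to_zero_based(self):
        pkg = read_cellprofiler(io.StringIO(CP_CSV))
        assert sorted(o.frame for o in pkg.objects) == [0, 1, 2, 3]
        assert len(pkg.links) == 1 and len(pkg.links[0].object_ids) == 4

    def test_two_interleaved_labels_give_two_tracks(self):
        rows = ["ImageNumber,ObjectNumber,Location_Center_X,Location_Center_Y,"
                "TrackObjects_Label"]
        for frame in (1, 2, 3):
            rows.append(f"{frame},1,{frame}.0,0.0,1")
            rows.append(f"{frame},2,{frame}.0,5.0,2")
        pkg = read_cellprofiler(io.StringIO("\n".join(rows) + "\n"))
        assert len(pkg.links) == 2 and len(pkg.tracks) == 2

    def test_gap_policy_split_vs_bridge(self):
        rows = ["ImageNumber,ObjectNumber,Location_Center_X,Location_Center_Y,"
                "TrackObjects_Label"]
        for frame in (1, 2, 6, 7):  # gap between source frames 2 and 6
            rows.append(f"{frame},1,{frame}.0,0.0,1")
        text = "\n".join(rows) + "\n"
        split_pkg = read_cellprofiler(io.StringIO(text))
        assert len(split_pkg.links) == 2
        mapping = ColumnMapping(frame="ImageNumber", object_id="ObjectNumber",
                                x="Location_Center_X", y="Location_Center_Y",
                                label="TrackObjects_Label", frame_base=1,
                                gap_policy="bridge")
        bridge_pkg = read_cellprofiler(io.StringIO(text), mapping)
        assert len(bridge_pkg.links) == 1

    def test_gap_segmentation_matches_bruteforce_runs(self):
        frames = [0, 1, 5, 6, 10]
        rows = ["f,x,y,label"] + [f"{fr},0.0,0.0,1" for fr in frames]
        mapping = ColumnMapping(frame="f", x="x", y="y", label="label")
        pkg = read_generic_csv(io.StringIO("\n".join(rows) + "\n"), mapping)
        # brute force: consecutive-frame runs of length >= 2
        runs, current = [], [frames[0]]
        for fr in frames[1:]:
            if fr == current[-1] + 1:
                current.append(fr)
            else:
                runs.append(current)
                current = [fr]
        runs.append(current)
        assert len(pkg.links) == sum(1 for r in runs if len(r) >= 2)

    def test_duplicate_frame_object_rows_rejected(self):
        text = CP_CSV + "1,1,9.0,9.0,1,99\n"
        with pytest.raises(DialectError, match="duplicate"):
            read_cellprofiler(io.StringIO(text))

    def test_unresolvable_mapping_rejected(self):
        mapping = ColumnMapping(frame="NoSuchColumn", x="Location_Center_X",
                                y="Location_Center_Y")
        with pytest.raises(DialectError, match="absent"):
            read_cellprofiler(io.StringIO(CP_CSV), mapping)


class TestGenericCsv:
    def test_objects_only_with_warning(self):
        table = pd.DataFrame({"t": range(10), "px": range(10), "py": range(10)})
        pkg = read_generic_csv(table, ColumnMapping(frame="t", x="px", y="py"))
        assert len(pkg.objects) == 10 and pkg.links == []
        assert "no_linking_column" in pkg.descriptor["conversion"]["warning"]

    def test_frame_base_normalisation_invariant(self):
        zero = pd.DataFrame({"t": [0, 1, 2], "px": [0., 1., 2.],
                             "py": [0., 0., 0.], "lab": [1, 1, 1]})
        one = zero.assign(t=zero["t"] + 1)
        pkg0 = read_generic_csv(zero, ColumnMapping(frame="t", x="px", y="py",
                                                    label="lab", frame_base=0))
        pkg1 = read_generic_csv(one, ColumnMapping(frame="t", x="px", y="py",
                                                   label="lab", frame_base=1))
        assert [o.frame for o in pkg0.objects] == [o.frame for o in pkg1.objects]
        assert [l.object_ids for l in pkg0.links] == \
            [l.object_ids for l in pkg1.links]

    def test_nonnumeric_columns_dropped_from_features(self):
        table = pd.DataFrame({"t": [0, 1], "px": [0., 1.], "py": [0., 0.],
                              "lab": [1, 1], "note": ["a", "b"],
                              "score": [0.5, 0.6]})
        pkg = read_generic_csv(table, ColumnMapping(frame="t", x="px", y="py",
                                                    label="lab"))
        assert set(pkg.objects[0].features) == {"score"}

    def test_mapping_file_loading(self, tmp_path):
        path = tmp_path / "mapping.yaml"
        path.write_text("frame: t\nx: px\ny: py\nlabel: lab\nframe_base: 1\n")
        mapping = ColumnMapping.from_file(path)
        assert mapping.label == "lab" and mapping.frame_base == 1

    def test_mapping_rejects_duplicates_and_bad_values(self):
        with pytest.raises(DialectError):
            ColumnMapping(frame="a", x="a", y="b")
        with pytest.raises(DialectError):
            ColumnMapping(frame="a", x="b", y="c", frame_base=2)
        with pytest.raises(DialectError):
            ColumnMapping.from_dict({"frame": "a", "x": "b", "y": "c",
                                     "bogus": 1})
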