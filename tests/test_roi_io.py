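"""ImageJ ROI codec, trace model and manifest loading."""

import struct

import numpy as np
import pytest

from woundmetrics.errors import (
    RoiFormatError,
    UnsupportedRoiTypeError,
    ValidationError,
)
from woundmetrics.roi_io import (
    Canvas,
    Polygon,
    Trace,
    load_manifest,
    read_mask,
    read_roi,
    write_manifest,
    write_mask,
    write_roi,
    write_roi_file,
)


class TestRoiCodec:
    @pytest.mark.parametrize(
        "verts",
        [
            ((0, 0), (10, 0), (0, 10)),
            ((5, 7), (9, 7), (9, 11), (5, 11)),
            ((100, 200), (150, 200), (150, 260), (120, 280), (100, 260)),
        ],
    )
    def test_integer_round_trip_bit_exact(self, verts):
        poly = Polygon(verts)
        assert read_roi(write_roi(poly)).vertices == poly.vertices

    @pytest.mark.parametrize("roi_type", [0, 7, 8])
    def test_round_trip_preserves_supported_types(self, roi_type):
        poly = Polygon(((1, 1), (20, 3), (12, 25)))
        data = write_roi(poly, roi_type=roi_type)
        assert data[6] == roi_type
        assert read_roi(data).vertices == poly.vertices

    def test_subpixel_round_trip_preserves_floats(self):
        poly = Polygon(((0.5, 0.25), (10.75, 0.0), (3.0, 9.5)))
        data = write_roi(poly)
        options = struct.unpack(">H", data[50:52])[0]
        assert options & 128  # subpixel flag set
        # coordinates chosen exactly representable in float32
        assert read_roi(data).vertices == poly.vertices

    def test_offset_arithmetic_on_hand_built_record(self):
        # record built by hand, independent of write_roi: left=5, top=7,
        # relative vertices (0,0),(4,0),(4,4) -> absolute (5,7),(9,7),(9,11)
        header = bytearray(64)
        header[0:4] = b"Iout"
        struct.pack_into(">h", header, 4, 227)
        header[6] = 0  # polygon
        struct.pack_into(">4h", header, 8, 7, 5, 11, 9)  # top,left,bottom,right
        struct.pack_into(">H", header, 16, 3)
        body = struct.pack(">3h", 0, 4, 4) + struct.pack(">3h", 0, 0, 4)
        poly = read_roi(bytes(header) + body)
        assert poly.vertices == ((5.0, 7.0), (9.0, 7.0), (9.0, 11.0))

    def test_bad_magic_rejected(self):
        with pytest.raises(RoiFormatError, match="magic"):
            read_roi(b"Nope" + bytes(100))

    @pytest.mark.parametrize("code,name", [(10, "point"), (3, "line"), (2, "oval"), (1, "rect")])
    def test_unsupported_types_rejected_by_name_and_code(self, code, name):
        data = bytearray(write_roi(Polygon(((0, 0), (4, 0), (4, 4)))))
        data[6] = code
        with pytest.raises(UnsupportedRoiTypeError, match=str(code)) as exc:
            read_roi(bytes(data))
        assert exc.value.type_name == name

    def test_truncated_stream_rejected(self):
        data = write_roi(Polygon(((0, 0), (4, 0), (4, 4))))
        with pytest.raises(RoiFormatError):
            read_roi(data[:60])

    def test_too_few_vertices_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            Polygon(((0, 0), (1, 1)))
        with pytest.raises(ValidationError):
            Polygon(())


class TestTraceModel:
    def test_absent_iff_no_regions_and_no_mask(self):
        assert Trace("p", "AI").status == "absent"
        t = Trace("p", "AI", regions=(Polygon(((0, 0), (4, 0), (4, 4))),))
        assert t.status == "present"
        assert Trace("p", "AI", mask=np.ones((4, 4), bool)).status == "present"

    def test_polygon_and_mask_are_mutually_exclusive(self):
        with pytest.raises(ValidationError):
            Trace("p", "AI", regions=(Polygon(((0, 0), (4, 0), (4, 4))),),
                  mask=np.ones((4, 4), bool))

    def test_out_of_canvas_vertices_warn_not_fail(self):
        canvas = Canvas(10, 10)
        with pytest.warns(UserWarning, match="outside canvas"):
            canvas.check_bounds(Polygon(((0, 0), (40, 0), (40, 40))))

    def test_invalid_canvas_rejected(self):
        with pytest.raises(ValidationError):
            Canvas(0, 10)


class TestManifest:
    def _write_study(self, tmp_path, rows):
        for i, row in enumerate(rows):
            if row["path"] and row["path"].endswith(".roi"):
                write_roi_file(tmp_path / row["path"],
                               Polygon(((0, 0), (8 + i, 0), (8 + i, 8))))
        manifest = tmp_path / "manifest.csv"
        write_manifest(manifest, rows)
        return manifest

    def _row(self, photo, tracer, path, kind="wound_area"):
        return {"photo_id": photo, "tracer_id": tracer, "kind": kind,
                "path": path, "canvas_width": 64, "canvas_height": 64}

    def test_grouping_and_counts(self, tmp_path):
        rows = [
            self._row(p, t, f"{p}_{t}.roi")
            for p in ("ph1", "ph2") for t in ("AI", "H1", "H2")
        ]
        manifest = self._write_study(tmp_path, rows)
        groups = load_manifest(manifest)
        assert set(groups) == {"wound_area"}
        assert set(groups["wound_area"]) == {"ph1", "ph2"}
        assert all(len(g.traces) == 3 for g in groups["wound_area"].values())

    def test_empty_path_is_absent_trace(self, tmp_path):
        rows = [self._row("ph1", "AI", ""), self._row("ph1", "H1", "a.roi")]
        groups = load_manifest(self._write_study(tmp_path, rows))
        traces = groups["wound_area"]["ph1"].traces
        assert traces["AI"].is_absent and not traces["H1"].is_absent

    def test_duplicate_key_rejected_with_key_in_message(self, tmp_path):
        rows = [self._row("ph1", "AI", "a.roi"), self._row("ph1", "AI", "b.roi")]
        with pytest.raises(ValidationError, match="ph1.*AI"):
            load_manifest(self._write_study(tmp_path, rows))

    def test_missing_file_rejected_with_path(self, tmp_path):
        manifest = tmp_path / "manifest.csv"
        write_manifest(manifest, [self._row("ph1", "AI", "absent.roi")])
        with pytest.raises(ValidationError, match="absent.roi"):
            load_manifest(manifest)

    def test_multi_roi_path_becomes_multi_region_trace(self, tmp_path):
        write_roi_file(tmp_path / "a.roi", Polygon(((0, 0), (8, 0), (8, 8))))
        write_roi_file(tmp_path / "b.roi", Polygon(((20, 20), (28, 20), (28, 28))))
        manifest = tmp_path / "manifest.csv"
        write_manifest(manifest, [self._row("ph1", "AI", "a.roi;b.roi")])
        groups = load_manifest(manifest)
        assert len(groups["wound_area"]["ph1"].traces["AI"].regions) == 2

    def test_mask_file_accepted(self, tmp_path):
        mask = np.zeros((64, 64), bool)
        mask[10:20, 10:30] = True
        write_mask(tmp_path / "m.png", mask)
        assert np.array_equal(read_mask(tmp_path / "m.png"), mask)
        manifest = tmp_path / "manifest.csv"
        write_manifest(manifest, [self._row("ph1", "AI", "m.png")])
        groups = load_manifest(manifest)
        assert groups["wound_area"]["ph1"].traces["AI"].mask.sum() == 200

    def test_empty_manifest_rejected(self, tmp_path):
        manifest = tmp_path / "manifest.csv"
        manifest.write_text("photo_id,tracer_id,kind,path,canvas_width,canvas_height\n")
        with pytest.raises(ValidationError, match="no rows"):
            load_manifest(manifest)
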