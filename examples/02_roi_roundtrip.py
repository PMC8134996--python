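"""Write and read ImageJ .roi files, including multi-region (satellite) traces.

Shows the codec round-trip, subpixel coordinates, and how a manifest ties
.roi files to photographs and tracers.
"""

import tempfile
from pathlib import Path

from woundmetrics import Polygon, load_manifest, read_roi_file, write_manifest, write_roi_file

tmp = Path(tempfile.mkdtemp())

# a freehand outline with subpixel vertices (float coordinates survive)
outline = Polygon(((10.25, 12.5), (40.75, 11.0), (44.5, 38.25), (12.0, 36.5)))
write_roi_file(tmp / "wound_main.roi", outline, roi_type=7)
back = read_roi_file(tmp / "wound_main.roi")
print(f"round-trip vertices equal: {back.vertices == outline.vertices}")

# a satellite lesion in its own file; the manifest joins them with ';'
satellite = Polygon(((60.0, 20.0), (70.0, 20.0), (70.0, 30.0), (60.0, 30.0)))
write_roi_file(tmp / "wound_sat.roi", satellite, roi_type=0)

write_manifest(
    tmp / "manifest.csv",
    [
        {"photo_id": "p1", "tracer_id": "H1", "kind": "wound_area",
         "path": "wound_main.roi;wound_sat.roi",
         "canvas_width": 96, "canvas_height": 64},
        # empty path = absent trace (wound judged fully epithelialized)
        {"photo_id": "p1", "tracer_id": "AI", "kind": "wound_area",
         "path": "", "canvas_width": 96, "canvas_height": 64},
    ],
)
groups = load_manifest(tmp / "manifest.csv")
photo = groups["wound_area"]["p1"]
h1 = photo.traces["H1"]
ai = photo.traces["AI"]
print(f"H1 trace has {len(h1.regions)} regions (main wound + satellite)")
print(f"AI trace absent (epithelialized call): {ai.is_absent}")
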