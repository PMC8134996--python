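"""Trace data model, ImageJ .roi codec, mask files and the study manifest.

Coordinates are ImageJ-style: 0-based, x rightward, y downward, origin at the
top-left corner, vertices at pixel corners.  An axis-aligned W x H rectangle
therefore encloses exactly W*H pixels when rasterized (see :mod:`.metrics`).

Only the polygon-like subset of the ImageJ ROI format is supported: type codes
polygon (0), freehand (7) and traced (8), with optional subpixel (float)
coordinates.  Satellite lesions are stored as separate .roi files and
aggregated into a single multi-region trace through the manifest.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from PIL import Image

from .errors import RoiFormatError, UnsupportedRoiTypeError, ValidationError

__all__ = [
    "Polygon",
    "Canvas",
    "Trace",
    "PhotoTraces",
    "read_roi",
    "write_roi",
    "read_roi_file",
    "write_roi_file",
    "read_mask",
    "write_mask",
    "load_manifest",
    "WOUND_AREA",
    "GRANULATION",
]

WOUND_AREA = "wound_area"
GRANULATION = "granulation"
KINDS = (WOUND_AREA, GRANULATION)

_MAGIC = b"Iout"
_VERSION = 228  # any version >= 222 understands subpixel coordinates

# ImageJ ROI type codes (RoiDecoder.java)
_TYPE_NAMES = {
    0: "polygon",
    1: "rect",
    2: "oval",
    3: "line",
    4: "freeline",
    5: "polyline",
    6: "noRoi",
    7: "freehand",
    8: "traced",
    9: "angle",
    10: "point",
}
_SUPPORTED_TYPES = (0, 7, 8)
_OPT_SUBPIXEL = 128  # options bit at header offset 50


@dataclass(frozen=True)
class Polygon:
    """A closed polygon given by its ordered vertices in pixel units.

    The polygon is implicitly closed (last vertex connects back to the
    first).  At least 3 vertices are required; self-intersection is allowed
    and resolved at rasterization time by the even-odd rule, matching how
    ImageJ fills freehand tracings.
    """

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if len(self.vertices) < 3:
            raise ValidationError(
                f"polygon needs at least 3 vertices, got {len(self.vertices)}"
            )
        object.__setattr__(
            self, "vertices", tuple((float(x), float(y)) for x, y in self.vertices)
        )

    @property
    def xy(self) -> np.ndarray:
        """Vertices as an (n, 2) float array."""
        return np.asarray(self.vertices, dtype=float)


@dataclass(frozen=True)
class Canvas:
    """Pixel frame shared by all tracings of one photograph."""

    width: int
    height: int

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValidationError("canvas dimensions must be positive")

    def check_bounds(self, polygon: Polygon, context: str = "") -> None:
        """Warn (never fail) when vertices fall outside the canvas."""
        xy = polygon.xy
        if (
            (xy[:, 0] < 0).any()
            or (xy[:, 0] > self.width).any()
            or (xy[:, 1] < 0).any()
            or (xy[:, 1] > self.height).any()
        ):
            warnings.warn(
                f"trace vertices outside canvas {self.width}x{self.height}"
                + (f" ({context})" if context else ""),
                stacklevel=3,
            )


@dataclass
class Trace:
    """One tracer's annotation of one photograph.

    A trace is either *present* (one or more polygon regions, or a pixel
    mask) or *absent*, meaning the tracer judged the wound completely
    epithelialized (or found no granulation tissue).  Multiple regions
    represent satellite lesions; their area is the area of the union.
    """

    photo_id: str
    tracer_id: str
    kind: str = WOUND_AREA
    regions: tuple[Polygon, ...] = ()
    mask: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValidationError(f"unknown trace kind {self.kind!r}")
        self.regions = tuple(self.regions)
        if self.mask is not None and self.regions:
            raise ValidationError("a trace holds polygons or a mask, not both")

    @property
    def status(self) -> str:
        return "present" if (self.regions or self.mask is not None) else "absent"

    @property
    def is_absent(self) -> bool:
        return self.status == "absent"


@dataclass
class PhotoTraces:
    """All traces of one kind for one photograph, with the shared canvas."""

    photo_id: str
    canvas: Canvas
    traces: dict[str, Trace] = field(default_factory=dict)  # tracer_id -> Trace


# ---------------------------------------------------------------------------
# ImageJ .roi codec
# ---------------------------------------------------------------------------

def read_roi(data: bytes) -> Polygon:
    """Decode one ImageJ .roi record into a polygon in absolute coordinates.

    The header stores the bounding box (top, left, bottom, right) and the
    vertices as 16-bit integers relative to (left, top); absolute integer
    coordinates are recovered by adding the offset.  When the subpixel-
    resolution option bit is set (and the version supports it), float
    coordinates follow the integer block and take precedence.

    Raises
    ------
    RoiFormatError
        If the magic bytes are wrong or the record is truncated.
    UnsupportedRoiTypeError
        For valid records of a type outside {polygon, freehand, traced}.
    """
    if len(data) < 64:
        raise RoiFormatError(f"ROI record too short ({len(data)} bytes)")
    if data[:4] != _MAGIC:
        raise RoiFormatError(f"bad magic bytes {data[:4]!r}, expected b'Iout'")
    version = struct.unpack(">h", data[4:6])[0]
    roi_type = data[6]
    if roi_type not in _SUPPORTED_TYPES:
        raise UnsupportedRoiTypeError(roi_type, _TYPE_NAMES.get(roi_type, "unknown"))
    top, left, _bottom, _right = struct.unpack(">4h", data[8:16])
    n = struct.unpack(">H", data[16:18])[0]
    if n < 3:
        raise RoiFormatError(f"polygon ROI with {n} coordinates")
    options = struct.unpack(">H", data[50:52])[0]
    subpixel = bool(options & _OPT_SUBPIXEL) and version >= 222

    base = 64
    need = base + 4 * n + (8 * n if subpixel else 0)
    if len(data) < need:
        raise RoiFormatError("ROI record truncated before coordinate block")

    if subpixel:
        off = base + 4 * n
        xs = struct.unpack(f">{n}f", data[off : off + 4 * n])
        ys = struct.unpack(f">{n}f", data[off + 4 * n : off + 8 * n])
        verts = tuple(zip(xs, ys))
    else:
        xs = struct.unpack(f">{n}h", data[base : base + 2 * n])
        ys = struct.unpack(f">{n}h", data[base + 2 * n : base + 4 * n])
        verts = tuple((float(x + left), float(y + top)) for x, y in zip(xs, ys))
    return Polygon(verts)


def write_roi(polygon: Polygon, roi_type: int = 0, name: str | None = None) -> bytes:
    """Encode a polygon as a big-endian ImageJ .roi record.

    Integer-valued vertices round-trip bit-exactly through the 16-bit
    relative-coordinate block; fractional vertices additionally get the
    subpixel float block (option bit 128) which readers prefer.
    """
    if roi_type not in _SUPPORTED_TYPES:
        raise ValidationError(f"refusing to write ROI type {roi_type}")
    xy = polygon.xy
    n = len(xy)
    integral = bool(np.all(xy == np.round(xy)))
    left = int(np.floor(xy[:, 0].min()))
    top = int(np.floor(xy[:, 1].min()))
    right = int(np.ceil(xy[:, 0].max()))
    bottom = int(np.ceil(xy[:, 1].max()))
    options = 0 if integral else _OPT_SUBPIXEL

    header = bytearray(64)
    header[0:4] = _MAGIC
    struct.pack_into(">h", header, 4, _VERSION)
    header[6] = roi_type
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">H", header, 16, n)
    struct.pack_into(">H", header, 50, options)

    rel_x = np.round(xy[:, 0]).astype(int) - left
    rel_y = np.round(xy[:, 1]).astype(int) - top
    body = struct.pack(f">{n}h", *rel_x) + struct.pack(f">{n}h", *rel_y)
    if not integral:
        body += struct.pack(f">{n}f", *xy[:, 0]) + struct.pack(f">{n}f", *xy[:, 1])
    return bytes(header) + body


def read_roi_file(path: str | Path) -> Polygon:
    return read_roi(Path(path).read_bytes())


def write_roi_file(path: str | Path, polygon: Polygon, roi_type: int = 0) -> None:
    Path(path).write_bytes(write_roi(polygon, roi_type=roi_type))


# ---------------------------------------------------------------------------
# Pixel-mask files
# ---------------------------------------------------------------------------

def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel image as a boolean mask (nonzero = inside)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return arr > 0


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    Image.fromarray((np.asarray(mask, bool) * 255).astype(np.uint8)).save(path)


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = [
    "photo_id",
    "tracer_id",
    "kind",
    "path",
    "canvas_width",
    "canvas_height",
]
_MASK_SUFFIXES = {".png", ".tif", ".tiff"}


def load_manifest(csv_path: str | Path) -> dict[str, dict[str, PhotoTraces]]:
    """Load a study manifest into traces grouped per photograph and kind.

    The manifest is a UTF-8 CSV with header ``photo_id, tracer_id, kind,
    path, canvas_width, canvas_height``.  ``path`` is resolved relative to
    the manifest location; an empty path marks an absent trace (the tracer
    judged the wound epithelialized).  Multiple .roi files for one trace
    (satellite lesions) are given as a ';'-separated list and become the
    regions of one trace.

    Returns a mapping ``kind -> photo_id -> PhotoTraces``.
    """
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, dtype=str, comment="#", keep_default_na=False)
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest is missing columns {missing}")
    if df.empty:
        raise ValidationError("manifest contains no rows")

    keys = list(zip(df.photo_id, df.tracer_id, df.kind))
    seen: set = set()
    for key in keys:
        if key in seen:
            raise ValidationError(f"duplicate manifest key {key}")
        seen.add(key)

    out: dict[str, dict[str, PhotoTraces]] = {k: {} for k in KINDS}
    base = csv_path.parent
    for row in df.itertuples(index=False):
        kind = row.kind
        if kind not in KINDS:
            raise ValidationError(f"unknown kind {kind!r} in manifest")
        canvas = Canvas(int(row.canvas_width), int(row.canvas_height))
        group = out[kind].setdefault(row.photo_id, PhotoTraces(row.photo_id, canvas))
        if group.canvas != canvas:
            raise ValidationError(
                f"conflicting canvas sizes for photo {row.photo_id!r}"
            )
        path_field = row.path.strip()
        if not path_field:
            trace = Trace(row.photo_id, row.tracer_id, kind)
        else:
            parts = [p.strip() for p in path_field.split(";") if p.strip()]
            paths = [base / p for p in parts]
            for p in paths:
                if not p.exists():
                    raise ValidationError(f"trace file not found: {p}")
            if paths[0].suffix.lower() in _MASK_SUFFIXES:
                if len(paths) > 1:
                    raise ValidationError(
                        "a trace is one mask file or several .roi files, not both"
                    )
                trace = Trace(row.photo_id, row.tracer_id, kind, mask=read_mask(paths[0]))
                if trace.mask.shape != (canvas.height, canvas.width):
                    raise ValidationError(
                        f"mask {paths[0]} does not match canvas "
                        f"{canvas.width}x{canvas.height}"
                    )
            else:
                regions = tuple(read_roi_file(p) for p in paths)
                for poly in regions:
                    canvas.check_bounds(poly, context=str(row.photo_id))
                trace = Trace(row.photo_id, row.tracer_id, kind, regions=regions)
        group.traces[row.tracer_id] = trace
    return {k: v for k, v in out.items() if v}


def write_manifest(
    csv_path: str | Path, rows: Iterable[Mapping[str, object]]
) -> None:
    """Write manifest rows (dicts with the manifest columns) to CSV."""
    pd.DataFrame(list(rows), columns=_MANIFEST_COLUMNS).to_csv(csv_path, index=False)
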