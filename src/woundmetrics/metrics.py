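"""Rasterization and reference/test overlap error measures.

Areas are measured in pixels on rasterized traces, mirroring planimetry
practice in ImageJ where the overlap region is built with the ROI AND
command and all three areas (reference R, test T, overlap O) are pixel
counts.  Exact polygon clipping (via shapely) is deliberately *not* the
canonical path; it serves only as an independent oracle in the test suite.

Fill convention (fixed so areas are bit-reproducible): a pixel (row i,
column j) belongs to a polygon when its center (j + 0.5, i + 0.5) is inside
by the even-odd rule.  Vertices are pixel-corner coordinates, so an
axis-aligned W x H rectangle covers exactly W*H pixels.  Self-intersecting
freehand outlines are filled even-odd without repair, as ImageJ does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedReferenceError, ValidationError
from .roi_io import Canvas, Polygon, Trace

__all__ = [
    "AreaTriple",
    "ErrorMeasures",
    "fill_polygon",
    "rasterize",
    "area_triple",
    "error_measures",
    "dice",
    "jaccard",
]


@dataclass(frozen=True)
class AreaTriple:
    """Reference, test and overlap areas of one trace comparison, in pixels."""

    R: int
    T: int
    O: int

    def __post_init__(self):
        if min(self.R, self.T, self.O) < 0:
            raise ValidationError("areas must be nonnegative")
        if self.O > min(self.R, self.T):
            raise ValidationError("overlap cannot exceed either trace area")


@dataclass(frozen=True)
class ErrorMeasures:
    """Reference-normalized error measures between a test and reference trace.

    FNA
        False-negative area (R - O)/R: the fraction of the reference missed
        by the test trace.  Always in [0, 1].
    FPA
        False-positive area (T - O)/R: test area outside the reference,
        normalized by the *reference* area.  May exceed 1 when the test
        trace is much larger than the reference.
    RE / ARE
        Signed and absolute relative area error (T - R)/R and |T - R|/R.
        ARE compares only sizes: it can be zero for completely disjoint
        traces of equal area.  Algebraically RE = FPA - FNA.
    """

    FNA: float
    FPA: float
    RE: float
    ARE: float


def fill_polygon(polygon: Polygon, width: int, height: int) -> np.ndarray:
    """Even-odd scanline fill of one polygon onto a boolean (height, width) grid.

    A pixel is inside when the horizontal ray from its center crosses the
    polygon boundary an odd number of times.
    """
    xy = polygon.xy
    x1, y1 = xy[:, 0], xy[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    keep = y1 != y2  # horizontal edges never cross a half-integer scanline test
    x1, y1, x2, y2 = x1[keep], y1[keep], x2[keep], y2[keep]
    mask = np.zeros((height, width), dtype=bool)
    if x1.size == 0:
        return mask

    ylo = np.minimum(y1, y2)
    yhi = np.maximum(y1, y2)
    centers = np.arange(width) + 0.5
    row_lo = max(0, int(np.floor(ylo.min() - 0.5)))
    row_hi = min(height - 1, int(np.ceil(yhi.max() - 0.5)))
    for i in range(row_lo, row_hi + 1):
        yc = i + 0.5
        hit = (ylo <= yc) & (yc < yhi)
        if not hit.any():
            continue
        t = (yc - y1[hit]) / (y2[hit] - y1[hit])
        xs = np.sort(x1[hit] + t * (x2[hit] - x1[hit]))
        # crossings strictly to the right of each pixel center
        n_right = xs.size - np.searchsorted(xs, centers, side="right")
        mask[i] = (n_right & 1).astype(bool)
    return mask


def rasterize(trace: Trace, canvas: Canvas) -> np.ndarray:
    """Rasterize a present trace to a boolean mask on the photograph's canvas.

    Multiple regions (satellite lesions) are combined by union, so listing a
    region twice never double-counts area.  Absent traces are rejected: the
    missing-trace rules of the comparison design must be applied first.
    """
    if trace.is_absent:
        raise ValidationError(
            f"cannot rasterize absent trace ({trace.photo_id}/{trace.tracer_id}); "
            "apply the missing-trace rules first"
        )
    if trace.mask is not None:
        if trace.mask.shape != (canvas.height, canvas.width):
            raise ValidationError("trace mask does not match canvas dimensions")
        return np.asarray(trace.mask, dtype=bool)
    mask = np.zeros((canvas.height, canvas.width), dtype=bool)
    for region in trace.regions:
        mask |= fill_polygon(region, canvas.width, canvas.height)
    return mask


def area_triple(ref_mask: np.ndarray, test_mask: np.ndarray) -> AreaTriple:
    """Pixel counts of the reference, test and overlap (logical AND) regions."""
    ref_mask = np.asarray(ref_mask, dtype=bool)
    test_mask = np.asarray(test_mask, dtype=bool)
    if ref_mask.shape != test_mask.shape:
        raise ValidationError(
            f"mask dimensions differ: {ref_mask.shape} vs {test_mask.shape}"
        )
    return AreaTriple(
        R=int(ref_mask.sum()),
        T=int(test_mask.sum()),
        O=int((ref_mask & test_mask).sum()),
    )


def error_measures(triple: AreaTriple) -> ErrorMeasures:
    """FNA, FPA, RE and ARE for one area triple; requires R > 0."""
    R, T, O = triple.R, triple.T, triple.O
    if R <= 0:
        raise UndefinedReferenceError(
            "reference area is zero; reference-normalized errors are undefined"
        )
    return ErrorMeasures(
        FNA=(R - O) / R,
        FPA=(T - O) / R,
        RE=(T - R) / R,
        ARE=abs(T - R) / R,
    )


def jaccard(triple: AreaTriple) -> float:
    """Auxiliary Jaccard index O / (R + T - O); not part of the core analysis."""
    union = triple.R + triple.T - triple.O
    return triple.O / union if union else float("nan")


def dice(triple: AreaTriple) -> float:
    """Auxiliary Dice coefficient 2O / (R + T); not part of the core analysis."""
    tot = triple.R + triple.T
    return 2 * triple.O / tot if tot else float("nan")
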