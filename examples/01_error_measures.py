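"""Overlap error measures between two wound tracings.

Builds two rectangular tracings of the same wound, rasterizes them on a
shared canvas and prints the reference/test/overlap areas and the
reference-normalized error measures.
"""

from woundmetrics import (
    Canvas,
    Polygon,
    Trace,
    area_triple,
    error_measures,
    rasterize,
)

canvas = Canvas(64, 64)
# reference tracing: 20 x 10 wound; test tracing shifted right by 5 px
reference = Trace("photo-1", "H1", regions=(Polygon(((10, 10), (30, 10), (30, 20), (10, 20))),))
test = Trace("photo-1", "AI", regions=(Polygon(((15, 10), (35, 10), (35, 20), (15, 20))),))

triple = area_triple(rasterize(reference, canvas), rasterize(test, canvas))
e = error_measures(triple)

print(f"areas (pixels): reference R={triple.R}, test T={triple.T}, overlap O={triple.O}")
print(f"FNA = (R-O)/R = {e.FNA:.3f}   fraction of the reference the test missed")
print(f"FPA = (T-O)/R = {e.FPA:.3f}   test area outside the reference, per reference area")
print(f"RE  = (T-R)/R = {e.RE:+.3f}   signed relative area difference")
print(f"ARE = |T-R|/R = {e.ARE:.3f}   size error only; blind to location")
# Both tracings are 200 px, so ARE is 0 even though a quarter of each
# tracing does not overlap the other (FNA = FPA = 0.25).
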