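# Methods

This note records what `woundmetrics` computes, why each default is what it
is, and where the numerical conventions come from. The package evaluates an
automated wound-tracing tool against human annotators; it does not segment
images itself.

## Measurement model

Every annotation is a *trace*: one or more closed polygons (main wound plus
satellite lesions) on a photograph's pixel canvas, or an explicit *absent*
trace when the annotator judged the wound fully epithelialized. Traces are
compared pairwise after rasterization:

- **R** — reference trace area (pixels), **T** — test trace area,
  **O** — overlap area (logical AND of the two masks).
- **FNA** = (R − O)/R: fraction of the reference missed by the test trace.
- **FPA** = (T − O)/R: test area outside the reference, normalized by the
  *reference* area (so FPA can exceed 1).
- **RE** = (T − R)/R and **ARE** = |T − R|/R: signed and absolute relative
  area error. Algebraically RE = FPA − FNA and ARE = |FPA − FNA|; ARE is
  blind to location (disjoint equal-area traces have ARE = 0).

### Comparison design

Each photograph has one AI trace and two human traces (H1, H2). Each human
trace serves as both reference and test; the AI trace is never the
reference. A fully annotated photograph yields 4 records (AI vs H1, AI vs
H2, H1 vs H2, H2 vs H1). Missing-trace rules: AI absent → the 2
human-vs-human records; one human absent → the 1 AI-vs-remaining-human
record (the AI cannot replace the lost reference); two or more absent → 0.
Group distributions are summarized as median [IQR] with linearly
interpolated quantiles (`numpy.quantile(..., method="linear")`).

### Rasterization convention

Pixel (row *i*, column *j*) belongs to a polygon when its center
(*j* + 0.5, *i* + 0.5) is inside by the even-odd rule, evaluated by scanline
counting of edge crossings strictly right of the center. Consequences,
fixed deliberately so areas are bit-reproducible:

- vertices are pixel-corner coordinates: an axis-aligned W×H rectangle
  covers exactly W·H pixels;
- the overlap of two polygons rasterized separately equals the
  rasterization of their exact intersection (a center is in both iff it is
  in the intersection), so raster overlap differs from the exact
  intersection area only by boundary discretization, which for convex
  regions is bounded by a constant times the perimeter;
- self-intersecting freehand outlines are filled even-odd without repair,
  matching ImageJ behavior.

Exact polygon clipping (shapely) is used only as an independent oracle in
the test suite, never as the measurement path.

## Statistics

All four procedures are implemented from first principles; scipy supplies
only distribution tail functions (`chi2.sf`, `t.sf`, `norm.sf`,
`hypergeom.pmf`).

- **Wilcoxon matched-pairs signed-rank**, two-tailed. Zero differences are
  discarded; ties in |d| receive midranks. For n ≤ 25 retained pairs the
  null distribution of W+ is computed exactly by dynamic programming over
  doubled ranks (equivalent to enumerating all 2ⁿ sign patterns);
  p = 2·min(lower tail, upper tail), capped at 1. Beyond n = 25 a normal
  approximation with tie and continuity corrections is used.
- **Fisher exact (2×2)**, two-sided by the probability-mass method: sum of
  hypergeometric probabilities over all tables with the observed margins
  that are no more probable than the observed table (relative tolerance
  1e-7 on the comparison, as the literature standard implementations use).
- **Chi-square goodness of fit** against uniform selection over the k
  annotators (df = k − 1), for the "which tracing is the AI's / most
  accurate" survey questions.
- **Paired t** (two-tailed, sample SD with n − 1 denominator) for the PGT
  comparisons.

P-values are reported journal-style: `<.001` below 0.001, otherwise three
significant figures without a leading zero.

### Matched-pairs testing of AI-vs-human against human-vs-human

`paired_error_table` pairs the AI-vs-h error with the other-human-vs-h
error for every human reference h, so a complete photograph yields two
pairs. For *testing*, the pipeline's `wilcoxon_table` keeps only one
shared-reference pair per photograph (the first reference in sorted order).
Reason: the two pairs of one photograph share the same AI trace and are
strongly positively correlated; treating them as independent pairs inflates
the signed-rank type-I error to ~0.15 at nominal 0.05 in simulation.
Averaging the two pairs also fails (~0.12) because the averaged difference
is not symmetric about zero under the null. With a single shared reference,
exchanging the AI and the other human negates the paired difference
exactly, so the symmetric-null assumption of the signed-rank test holds by
construction; 400 equal-accuracy simulated studies show a rejection rate of
0.07 ± 0.013 with near-uniform p-values.

## Survey and PGT analyses

**Survey (masked review).** Q1 (does the tracing meet the standardized
wound-area definition) is aggregated per reviewer and pooled per annotator
class; each reviewer gets a Fisher exact test on [[AI yes, AI no],
[human yes, human no]] with the two humans pooled. Q2 (which tracing is the
AI's) and Q3 (most accurate) are tested per reviewer against uniform random
selection with the chi-square test. Missing answers are excluded listwise
per question; denominators therefore vary.

**PGT (percent granulation tissue).** Three reviewers estimate PGT visually
to the nearest 10%; the tool reports a continuous value from its own
granulation and wound areas. Per photograph the analysis computes |AI −
mean reviewer estimate| and the reviewers' own disagreement (range and
sample SD of the three estimates), compares them with paired t tests, and
tallies a 10%-bin range histogram.

## Synthetic studies

Clinical photographs cannot ship with the package, so every stage is
exercised on generated data with known truth.

**Phantom** (`PhantomParams`): the main wound is a radial Fourier-harmonic
blob (72 vertices, relative radius noise 0.22) on a 160×160 canvas with
mean radius 40 px; 0–3 satellite blobs (radius 7 px) are placed disjointly
within `satellite_reach_px = 40` of the main boundary — a plain pixel
stand-in for the clinical "within 2 cm" inclusion rule, with no physical
calibration; a granulation sub-blob is scaled by bisection until it covers
`granulation_fraction = 0.5` of the wound.

**Annotator** (`AnnotatorModel`): each boundary is perturbed radially with
SD `boundary_jitter_sigma` (default 3 px), mixing a constant per-trace
offset (weight 0.75 of the SD) with smooth along-boundary wiggle
(correlation length 20 px). The offset dominance is deliberate: real
tracers disagree mostly about *where the wound edge is* as a whole, which
makes the size error (ARE) comparable to or larger than the overlap errors
(FNA/FPA) — the pattern observed in clinical tracing comparisons. At the
defaults the wound-area medians land near FNA ≈ 8%, ARE ≈ 10%, the scale
reported for careful human tracers. The annotator also calls the wound
epithelialized with probability `epithelialized_prob` (absent trace) and
misses each satellite with `satellite_miss_prob`.

**Reviewer** (`ReviewerModel`): PGT estimate = truth + N(0, `noise_sd`=20),
clipped to [0, 100] and rounded to the nearest 10; at this noise the mean
per-photo reviewer range is ~33% and the mean SD ~17%, matching the
disagreement scale reported for visual granulation estimates. Q1 answers
yes when the tracing's true ARE is below the reviewer's personal threshold
(0.05 / 0.10 / 0.15 across the three reviewers); Q2 and Q3 choices are
softmax draws (temperature 0.1) over the tracings' true AREs, worse traces
"looking more AI" and better traces "looking more accurate".

All randomness flows from one seedable `numpy` Generator; a study is fully
reproducible from (parameters, seed).

**What the generator does not emulate:** photograph color and texture,
lighting, camera geometry, ruler-based physical scale, systematic annotator
bias (all noise is zero-mean), inter-photo correlation within a patient,
and reviewer learning effects. Passing tests therefore demonstrate
correctness of the *measurement pipeline*, not clinical performance of any
tracing tool.

## Limitations

- Areas are pixel counts; there is no conversion to cm². Reference-
  normalized measures are scale-free, so this only matters for absolute
  area reporting.
- The .roi codec supports the polygon, freehand and traced ROI types (with
  subpixel coordinates); composite/shape ROIs, lines, points and ovals are
  rejected explicitly.
- The missing-trace rules yield 1 record when a *human* trace is absent
  (the AI cannot serve as reference); distribution summaries over groups
  with many absent humans are correspondingly thinner on the
  human-vs-human side.
- The exact Wilcoxon path is O(n²·max rank) and switches to the corrected
  normal approximation above n = 25; at that boundary the two paths agree
  to about 0.02 in p.
- Synthetic calibrations (jitter 3 px, reviewer noise 20%) are study
  conditions chosen to land in the ranges reported for human tracers and
  reviewers; they are not fitted to any dataset.
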