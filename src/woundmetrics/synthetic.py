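"""Synthetic wound phantoms, annotator models and reviewer simulation.

Real wound photographs cannot ship with the package, so every pipeline stage
is exercised on synthetic studies instead: a *phantom* is a known-truth
wound geometry (a main blob from a smoothed random radial function, up to a
few disjoint satellite lesions nearby, and a granulation sub-region inside
the wound); an *annotator model* perturbs the true boundary with smooth
correlated radial noise, occasionally misses satellites, and occasionally
calls the wound epithelialized (producing an absent trace); a *reviewer
model* produces visual PGT estimates (truth plus Gaussian noise, clipped and
rounded to the nearest 10%) and survey answers driven by each tracing's true
accuracy.

All randomness flows from one seedable numpy Generator, so studies are
reproducible from (parameters, seed).  The satellite-inclusion radius is a
plain pixel parameter (default 40 px standing in for the 2 cm clinical
rule); there is no physical calibration anywhere.

What this generator does NOT emulate: photograph color/texture, lighting,
ruler-based scale, or systematic annotator bias (noise is zero-mean), so
passing tests demonstrate correctness of the measurement pipeline, not
clinical performance of any tracing tool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import cached_property
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon as ShapelyPolygon

from .errors import ValidationError, WoundMetricsError
from .metrics import rasterize
from .pgt import PGTRecord
from .qualitative import SurveyResponse
from .roi_io import (
    GRANULATION,
    WOUND_AREA,
    Canvas,
    PhotoTraces,
    Polygon,
    Trace,
    write_manifest,
    write_roi_file,
)

__all__ = [
    "GenerationError",
    "PhantomParams",
    "AnnotatorModel",
    "ReviewerModel",
    "WoundPhantom",
    "generate_phantom",
    "simulate_annotation",
    "simulate_reviewers",
    "SimulatedStudy",
    "simulate_study",
    "write_study",
]


class GenerationError(WoundMetricsError):
    """Phantom geometry could not be realized within bounded retries."""


@dataclass(frozen=True)
class PhantomParams:
    """Geometry of one synthetic wound.

    ``satellite_reach_px`` is the maximal gap between a satellite lesion and
    the main wound edge (default 40 px, the stand-in for the 2 cm clinical
    inclusion rule).  ``granulation_fraction`` is the target fraction of the
    wound area covered by granulation tissue.
    """

    canvas: tuple[int, int] = (160, 160)  # (width, height)
    main_radius: float = 40.0
    radius_jitter: float = 0.22  # relative amplitude of the radial profile noise
    n_vertices: int = 72
    satellite_count: int | None = None  # None = draw uniformly from 0..3
    satellite_radius: float = 7.0
    satellite_reach_px: float = 40.0
    granulation_fraction: float = 0.5

    def __post_init__(self):
        if min(self.canvas) < 64:
            raise ValidationError("canvas must be at least 64x64")
        if self.main_radius < 4 or self.satellite_radius < 4:
            raise ValidationError("blob radii must be at least 4 px")
        if not 0 <= self.granulation_fraction <= 1:
            raise ValidationError("granulation fraction must lie in [0, 1]")


@dataclass(frozen=True)
class AnnotatorModel:
    """Stochastic tracing behavior of one annotator (human or AI).

    ``boundary_jitter_sigma`` is the SD, in pixels, of the radial
    perturbation applied to each region boundary.  The perturbation mixes a
    constant per-trace offset (the annotator drawing systematically wider or
    tighter than the truth) with smooth wiggle along the boundary whose
    correlation length is ``smoothing_scale_px``; ``offset_weight`` sets the
    share of variance carried by the constant component.  Human tracing
    disagreement is dominated by such whole-boundary size differences — two
    careful tracers disagree about where the wound edge *is*, not by jagged
    local error — which is what makes relative-area error comparable to, or
    larger than, the overlap-based errors on real tracings.
    """

    tracer_id: str
    boundary_jitter_sigma: float = 3.0
    smoothing_scale_px: float = 20.0
    offset_weight: float = 0.75
    epithelialized_prob: float = 0.0
    satellite_miss_prob: float = 0.0

    def __post_init__(self):
        if self.boundary_jitter_sigma < 0:
            raise ValidationError("jitter sigma must be nonnegative")
        if not 0 <= self.offset_weight <= 1:
            raise ValidationError("offset weight must lie in [0, 1]")
        for p in (self.epithelialized_prob, self.satellite_miss_prob):
            if not 0 <= p <= 1:
                raise ValidationError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class ReviewerModel:
    """Visual-estimation behavior of the masked reviewer panel.

    Reviewer PGT = true PGT + N(0, noise_sd), clipped to [0, 100] and rounded
    to the nearest 10%.  Q1 (meets the area definition) answers yes when the
    tracing's true ARE is below the reviewer's personal threshold; Q2 (which
    is AI) and Q3 (most accurate) are sampled from softmax distributions over
    the tracings' true errors.
    """

    noise_sd: float = 20.0
    q1_thresholds: tuple[float, float, float] = (0.05, 0.10, 0.15)
    softmax_temperature: float = 0.1


@dataclass
class WoundPhantom:
    """Known-truth wound geometry: main blob, satellites, granulation region."""

    canvas: Canvas
    wound_polygons: tuple[Polygon, ...]  # main blob first, then satellites
    granulation_polygons: tuple[Polygon, ...]
    seed: int

    @property
    def satellite_count(self) -> int:
        return len(self.wound_polygons) - 1

    def _trace(self, kind: str) -> Trace:
        regions = self.wound_polygons if kind == WOUND_AREA else self.granulation_polygons
        return Trace("truth", "truth", kind, regions=regions)

    @cached_property
    def wound_mask(self) -> np.ndarray:
        return rasterize(self._trace(WOUND_AREA), self.canvas)

    @cached_property
    def granulation_mask(self) -> np.ndarray:
        # enforce granulation ⊆ wound at pixel level
        return rasterize(self._trace(GRANULATION), self.canvas) & self.wound_mask

    @property
    def true_pgt(self) -> float:
        """True percent granulation tissue, from the rasterized truth masks."""
        wound = int(self.wound_mask.sum())
        if wound == 0:
            return 0.0
        return 100.0 * int(self.granulation_mask.sum()) / wound


def _smooth_radial_noise(n: int, rng: np.random.Generator, harmonics: int) -> np.ndarray:
    """Unit-SD smooth periodic noise over n boundary vertices (random Fourier sum)."""
    theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    z = np.zeros(n)
    for m in range(1, max(1, harmonics) + 1):
        a, b = rng.normal(size=2)
        z += (a * np.cos(m * theta) + b * np.sin(m * theta)) / m
    sd = z.std()
    return z / sd if sd > 0 else z


def _blob(
    center: tuple[float, float],
    radius: float,
    rel_jitter: float,
    n_vertices: int,
    rng: np.random.Generator,
    harmonics: int = 4,
) -> Polygon:
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    r = radius * (1.0 + rel_jitter * _smooth_radial_noise(n_vertices, rng, harmonics))
    r = np.maximum(r, 2.0)
    xs = center[0] + r * np.cos(theta)
    ys = center[1] + r * np.sin(theta)
    return Polygon(tuple(zip(xs, ys)))


def _shapely(poly: Polygon) -> ShapelyPolygon:
    return ShapelyPolygon(poly.vertices)


def generate_phantom(params: PhantomParams | None = None, seed: int = 0) -> WoundPhantom:
    """Generate one reproducible wound phantom.

    The main blob sits near the canvas center; each satellite is placed in
    the annulus within ``satellite_reach_px`` of the main boundary, disjoint
    from the main blob and from other satellites (bounded retries, then
    :class:`GenerationError`).  The granulation sub-blob is scaled by
    bisection so its area inside the main blob hits the requested fraction
    of the total wound area.
    """
    params = params or PhantomParams()
    rng = np.random.default_rng(seed)
    width, height = params.canvas
    canvas = Canvas(width, height)
    cx = width / 2 + rng.uniform(-0.05, 0.05) * width
    cy = height / 2 + rng.uniform(-0.05, 0.05) * height

    main = _blob((cx, cy), params.main_radius, params.radius_jitter,
                 params.n_vertices, rng)
    main_s = _shapely(main)

    n_sat = (
        int(rng.integers(0, 4)) if params.satellite_count is None
        else params.satellite_count
    )
    satellites: list[Polygon] = []
    placed: list[ShapelyPolygon] = []
    for _ in range(n_sat):
        ok = False
        for _attempt in range(200):
            phi = rng.uniform(0, 2 * np.pi)
            gap = rng.uniform(4.0, params.satellite_reach_px)
            # distance from main centroid: local main radius + gap + satellite radius
            ray = np.array([math.cos(phi), math.sin(phi)])
            local_r = _local_radius(main, (cx, cy), phi)
            center = (cx + ray[0] * (local_r + gap + params.satellite_radius),
                      cy + ray[1] * (local_r + gap + params.satellite_radius))
            if not (params.satellite_radius * 2 < center[0] < width - 2 * params.satellite_radius
                    and params.satellite_radius * 2 < center[1] < height - 2 * params.satellite_radius):
                continue
            sat = _blob(center, params.satellite_radius, 0.15, 24, rng, harmonics=2)
            sat_s = _shapely(sat)
            if sat_s.distance(main_s) < 2.0:
                continue
            if any(sat_s.distance(p) < 2.0 for p in placed):
                continue
            satellites.append(sat)
            placed.append(sat_s)
            ok = True
            break
        if not ok:
            raise GenerationError(
                f"could not place satellite {len(satellites) + 1} of {n_sat} "
                f"on a {width}x{height} canvas"
            )

    granulation = _granulation_polygons(
        main, main_s, placed, params, rng, (cx, cy)
    )
    return WoundPhantom(
        canvas=canvas,
        wound_polygons=(main, *satellites),
        granulation_polygons=granulation,
        seed=seed,
    )


def _local_radius(poly: Polygon, center: tuple[float, float], phi: float) -> float:
    xy = poly.xy - np.asarray(center)
    angles = np.arctan2(xy[:, 1], xy[:, 0]) % (2 * np.pi)
    k = int(np.argmin(np.abs((angles - phi + np.pi) % (2 * np.pi) - np.pi)))
    return float(np.hypot(*xy[k]))


def _granulation_polygons(
    main: Polygon,
    main_s: ShapelyPolygon,
    satellites: list[ShapelyPolygon],
    params: PhantomParams,
    rng: np.random.Generator,
    center: tuple[float, float],
) -> tuple[Polygon, ...]:
    frac = params.granulation_fraction
    if frac == 0:
        return ()
    total_area = main_s.area + sum(p.area for p in satellites)
    target = min(frac * total_area, 0.95 * main_s.area)

    # fixed sub-blob shape, scaled about an interior anchor by bisection
    shape = _blob(center, params.main_radius, params.radius_jitter * 1.2,
                  params.n_vertices, rng)
    base = shape.xy - np.asarray(center)

    def realized(scale: float) -> tuple[float, ShapelyPolygon]:
        pts = np.asarray(center) + scale * base
        g = ShapelyPolygon(pts)
        inter = g.intersection(main_s)
        return inter.area, g

    lo, hi = 0.01, 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        area, _g = realized(mid)
        if area < target:
            lo = mid
        else:
            hi = mid
    scale = 0.5 * (lo + hi)
    _area, g = realized(scale)
    inter = g.intersection(main_s)
    if inter.is_empty:
        return ()
    geoms = getattr(inter, "geoms", [inter])
    polys = []
    for geom in geoms:
        coords = list(geom.exterior.coords)[:-1]
        if len(coords) >= 3:
            polys.append(Polygon(tuple(coords)))
    return tuple(polys)


# ---------------------------------------------------------------------------
# Annotator simulation
# ---------------------------------------------------------------------------

def _jitter_region(
    poly: Polygon, model: AnnotatorModel, rng: np.random.Generator
) -> Polygon:
    """Perturb a region boundary with offset-plus-wiggle radial noise."""
    sigma = model.boundary_jitter_sigma
    xy = poly.xy
    center = xy.mean(axis=0)
    rel = xy - center
    r = np.hypot(rel[:, 0], rel[:, 1])
    if sigma > 0:
        circumference = 2 * np.pi * max(r.mean(), 1.0)
        harmonics = max(1, int(round(circumference / max(model.smoothing_scale_px, 1.0))))
        w0 = model.offset_weight
        noise = (
            w0 * rng.normal()
            + np.sqrt(1 - w0**2) * _smooth_radial_noise(len(r), rng, harmonics)
        )
        r = np.maximum(r + sigma * noise, 1.0)
    unit = rel / np.maximum(np.hypot(rel[:, 0], rel[:, 1]), 1e-9)[:, None]
    pts = center + unit * r[:, None]
    return Polygon(tuple(map(tuple, pts)))


def simulate_annotation(
    phantom: WoundPhantom,
    model: AnnotatorModel,
    rng: np.random.Generator,
    kind: str = WOUND_AREA,
    photo_id: str = "photo",
) -> Trace:
    """One annotator's trace of one phantom.

    The whole trace is absent with ``epithelialized_prob``; each satellite
    (every region after the first) is independently dropped with
    ``satellite_miss_prob``; every kept boundary is perturbed radially with
    SD ``boundary_jitter_sigma``.
    """
    if rng.random() < model.epithelialized_prob:
        return Trace(photo_id, model.tracer_id, kind)
    truth = (
        phantom.wound_polygons if kind == WOUND_AREA else phantom.granulation_polygons
    )
    if not truth:
        return Trace(photo_id, model.tracer_id, kind)
    regions = []
    for i, region in enumerate(truth):
        if i > 0 and rng.random() < model.satellite_miss_prob:
            continue
        regions.append(_jitter_region(region, model, rng))
    return Trace(photo_id, model.tracer_id, kind, regions=tuple(regions))


# ---------------------------------------------------------------------------
# Reviewer simulation
# ---------------------------------------------------------------------------

def _trace_are(trace: Trace, phantom: WoundPhantom) -> float | None:
    """True ARE of a wound trace against the phantom truth (None when absent)."""
    from .metrics import area_triple, error_measures

    if trace.is_absent:
        return None
    mask = rasterize(trace, phantom.canvas)
    triple = area_triple(phantom.wound_mask, mask)
    if triple.R == 0:
        return None
    return error_measures(triple).ARE


def simulate_reviewers(
    phantom: WoundPhantom,
    traces: dict[str, Trace],
    rng: np.random.Generator,
    reviewer_model: ReviewerModel | None = None,
    photo_id: str = "photo",
    site: str = "S1",
    ai_id: str = "AI",
    ai_pgt: float | None = None,
) -> tuple[list[SurveyResponse], PGTRecord | None]:
    """Simulate the three-reviewer panel for one photograph.

    Returns the three survey responses plus the PGT record (None when no AI
    PGT measurement is available, e.g. the AI wound trace is absent).
    ``traces`` maps annotator -> wound-area trace.
    """
    model = reviewer_model or ReviewerModel()
    true_pgt = phantom.true_pgt
    ares = {ann: _trace_are(tr, phantom) for ann, tr in traces.items()}
    annotators = sorted(traces)

    responses = []
    estimates = []
    for j, thr in enumerate(model.q1_thresholds, start=1):
        est = float(np.clip(true_pgt + rng.normal(0, model.noise_sd), 0, 100))
        estimates.append(round(est / 10) * 10)

        # an absent tracing cannot be reviewed: that Q1 answer stays missing
        q1 = {ann: ares[ann] <= thr for ann in annotators if ares[ann] is not None}
        scored = [a for a in annotators if ares[a] is not None]
        if scored:
            errs = np.array([ares[a] for a in scored])
            t = model.softmax_temperature
            p_ai = np.exp(errs / t - (errs / t).max())       # worse trace: more "looks AI"
            p_acc = np.exp(-errs / t - (-errs / t).max())    # better trace: more "accurate"
            q2 = str(rng.choice(scored, p=p_ai / p_ai.sum()))
            q3 = str(rng.choice(scored, p=p_acc / p_acc.sum()))
        else:
            q2 = q3 = None
        responses.append(
            SurveyResponse(site=site, reviewer_id=f"R{j}", photo_id=photo_id,
                           q1=q1, q2_choice=q2, q3_choice=q3)
        )

    if ai_pgt is None and ai_id in traces and not traces[ai_id].is_absent:
        # no explicit measurement given: fall back to the truth-derived value
        ai_pgt = true_pgt
    record = None
    if ai_pgt is not None:
        record = PGTRecord(
            photo_id=photo_id,
            reviewer_estimates=tuple(estimates),
            ai_pgt=float(np.clip(ai_pgt, 0, 100)),
        )
    return responses, record


# ---------------------------------------------------------------------------
# Whole-study simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    """In-memory synthetic study: phantoms, traces, survey and PGT inputs."""

    phantoms: dict[str, WoundPhantom]
    photos: dict[str, dict[str, PhotoTraces]]  # kind -> photo_id -> PhotoTraces
    survey: list[SurveyResponse] = field(default_factory=list)
    pgt_records: list[PGTRecord] = field(default_factory=list)
    seed: int = 0


def simulate_study(
    n_photos: int = 40,
    params: PhantomParams | None = None,
    ai_model: AnnotatorModel | None = None,
    human_models: tuple[AnnotatorModel, AnnotatorModel] | None = None,
    reviewer_model: ReviewerModel | None = None,
    granulation_photo_fraction: float = 0.25,
    seed: int = 0,
    site: str = "S1",
) -> SimulatedStudy:
    """Simulate a full evaluation study.

    Defaults mirror the shape of a two-site tracing study: one AI and two
    human annotators per photograph, all with equal boundary noise
    (3 px SD), a small epithelialized-call rate (3%), granulation traced for
    a quarter of the photographs, and a 3-reviewer panel estimating PGT with
    20% visual noise.  Every quantity is reproducible from the seed.
    """
    params = params or PhantomParams()
    ai_model = ai_model or AnnotatorModel("AI", epithelialized_prob=0.03,
                                          satellite_miss_prob=0.15)
    if human_models is None:
        human_models = (
            replace(ai_model, tracer_id="H1"),
            replace(ai_model, tracer_id="H2"),
        )
    models = (ai_model, *human_models)
    rng = np.random.default_rng(seed)

    phantoms: dict[str, WoundPhantom] = {}
    photos: dict[str, dict[str, PhotoTraces]] = {WOUND_AREA: {}, GRANULATION: {}}
    survey: list[SurveyResponse] = []
    pgt_records: list[PGTRecord] = []

    n_gran = int(round(granulation_photo_fraction * n_photos))
    for i in range(n_photos):
        photo_id = f"{site}-{i + 1:03d}"
        phantom = generate_phantom(params, seed=int(rng.integers(0, 2**31 - 1)))
        phantoms[photo_id] = phantom

        wound_group = PhotoTraces(photo_id, phantom.canvas)
        for m in models:
            wound_group.traces[m.tracer_id] = simulate_annotation(
                phantom, m, rng, WOUND_AREA, photo_id
            )
        photos[WOUND_AREA][photo_id] = wound_group

        ai_pgt = None
        if i < n_gran:
            gran_group = PhotoTraces(photo_id, phantom.canvas)
            for m in models:
                gran_group.traces[m.tracer_id] = simulate_annotation(
                    phantom, m, rng, GRANULATION, photo_id
                )
            photos[GRANULATION][photo_id] = gran_group
            ai_pgt = _ai_pgt(wound_group, gran_group, phantom.canvas)

        resp, rec = simulate_reviewers(
            phantom, wound_group.traces, rng, reviewer_model,
            photo_id=photo_id, site=site, ai_pgt=ai_pgt,
        )
        survey.extend(resp)
        # PGT comparison exists only where the tool produced a granulation
        # tracing (and hence its own PGT measurement)
        if rec is not None and ai_pgt is not None:
            pgt_records.append(rec)

    return SimulatedStudy(phantoms, photos, survey, pgt_records, seed)


def _ai_pgt(wound_group: PhotoTraces, gran_group: PhotoTraces, canvas: Canvas,
            ai_id: str = "AI") -> float | None:
    """AI PGT from the AI's own wound and granulation traces, in percent."""
    w = wound_group.traces.get(ai_id)
    g = gran_group.traces.get(ai_id)
    if w is None or g is None or w.is_absent:
        return None
    wa = int(rasterize(w, canvas).sum())
    if wa == 0:
        return None
    ga = 0 if g.is_absent else int((rasterize(g, canvas) & rasterize(w, canvas)).sum())
    return 100.0 * ga / wa


def write_study(study: SimulatedStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated study to disk in the formats the pipeline consumes.

    Produces ``manifest.csv`` (+ per-trace .roi files under ``roi/``),
    ``survey.csv`` and ``pgt.csv``.  Returns the paths.
    """
    out = Path(out_dir)
    roi_dir = out / "roi"
    roi_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for kind, groups in study.photos.items():
        for photo_id, group in groups.items():
            for tracer_id, trace in group.traces.items():
                if trace.is_absent:
                    path_field = ""
                else:
                    parts = []
                    for k, region in enumerate(trace.regions):
                        fname = f"{photo_id}_{tracer_id}_{kind}_{k}.roi"
                        write_roi_file(roi_dir / fname, region, roi_type=7)
                        parts.append(f"roi/{fname}")
                    path_field = ";".join(parts)
                rows.append(
                    {"photo_id": photo_id, "tracer_id": tracer_id, "kind": kind,
                     "path": path_field,
                     "canvas_width": group.canvas.width,
                     "canvas_height": group.canvas.height}
                )
    manifest = out / "manifest.csv"
    write_manifest(manifest, rows)

    survey = out / "survey.csv"
    pd.DataFrame(
        [
            {"site": r.site, "reviewer_id": r.reviewer_id, "photo_id": r.photo_id,
             "q1_AI": _yn(r.q1.get("AI")), "q1_H1": _yn(r.q1.get("H1")),
             "q1_H2": _yn(r.q1.get("H2")),
             "q2_choice": r.q2_choice or "", "q3_choice": r.q3_choice or ""}
            for r in study.survey
        ]
    ).to_csv(survey, index=False)

    pgt = out / "pgt.csv"
    pd.DataFrame(
        [
            {"photo_id": r.photo_id, "r1": r.reviewer_estimates[0],
             "r2": r.reviewer_estimates[1], "r3": r.reviewer_estimates[2],
             "ai_pgt": r.ai_pgt}
            for r in study.pgt_records
        ],
        columns=["photo_id", "r1", "r2", "r3", "ai_pgt"],
    ).to_csv(pgt, index=False)

    return {"manifest": manifest, "survey": survey, "pgt": pgt}


def _yn(v) -> str:
    if v is None:
        return ""
    return "Y" if v else "N"
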