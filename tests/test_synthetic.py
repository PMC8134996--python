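"""Phantom generation, annotator jitter and reviewer simulation."""

import numpy as np
import pytest

from woundmetrics.errors import ValidationError
from woundmetrics.metrics import area_triple, error_measures, rasterize
from woundmetrics.roi_io import GRANULATION, WOUND_AREA
from woundmetrics.synthetic import (
    AnnotatorModel,
    PhantomParams,
    ReviewerModel,
    generate_phantom,
    simulate_annotation,
    simulate_reviewers,
    simulate_study,
    write_study,
)


class TestPhantom:
    def test_identical_seed_gives_byte_identical_masks(self):
        params = PhantomParams(satellite_count=3)
        a = generate_phantom(params, seed=5)
        b = generate_phantom(params, seed=5)
        assert np.array_equal(a.wound_mask, b.wound_mask)
        assert np.array_equal(a.granulation_mask, b.granulation_mask)

    def test_zero_satellites_single_connected_component(self):
        from scipy import ndimage

        phantom = generate_phantom(PhantomParams(satellite_count=0), seed=2)
        _, n_components = ndimage.label(phantom.wound_mask)
        assert n_components == 1

    def test_satellites_disjoint_from_main_blob(self):
        from scipy import ndimage

        phantom = generate_phantom(PhantomParams(satellite_count=3), seed=9)
        _, n_components = ndimage.label(phantom.wound_mask)
        assert n_components == 4

    @pytest.mark.parametrize("frac", [0.3, 0.5, 0.7])
    def test_granulation_fraction_realized_within_tolerance(self, frac):
        params = PhantomParams(granulation_fraction=frac, satellite_count=1)
        realized = [
            generate_phantom(params, seed=s).true_pgt / 100 for s in range(30)
        ]
        assert abs(np.mean(realized) - frac) < 0.1
        assert max(abs(r - frac) for r in realized) < 0.15

    def test_granulation_inside_wound(self):
        phantom = generate_phantom(PhantomParams(satellite_count=2), seed=11)
        assert not (phantom.granulation_mask & ~phantom.wound_mask).any()

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(ValidationError):
            PhantomParams(canvas=(32, 32))
        with pytest.raises(ValidationError):
            PhantomParams(main_radius=2)


class TestAnnotation:
    def test_noise_free_annotator_reproduces_truth(self, small_phantom, rng):
        model = AnnotatorModel("H1", boundary_jitter_sigma=0,
                               satellite_miss_prob=0, epithelialized_prob=0)
        trace = simulate_annotation(small_phantom, model, rng)
        mask = rasterize(trace, small_phantom.canvas)
        e = error_measures(area_triple(small_phantom.wound_mask, mask))
        assert (e.FNA, e.FPA, e.ARE) == (0, 0, 0)

    def test_always_epithelialized_gives_absent_trace(self, small_phantom, rng):
        model = AnnotatorModel("H1", epithelialized_prob=1.0)
        assert simulate_annotation(small_phantom, model, rng).is_absent

    def test_certain_satellite_miss_keeps_only_main_region(self, small_phantom, rng):
        model = AnnotatorModel("H1", boundary_jitter_sigma=0, satellite_miss_prob=1.0)
        trace = simulate_annotation(small_phantom, model, rng)
        assert len(trace.regions) == 1

    def test_error_grows_monotonically_with_jitter(self):
        params = PhantomParams(satellite_count=0, main_radius=40)
        medians = []
        for sigma in (1.5, 3.0, 6.0):
            ares = []
            for seed in range(40):
                phantom = generate_phantom(params, seed=seed)
                rng = np.random.default_rng(1000 + seed)
                model = AnnotatorModel("H1", boundary_jitter_sigma=sigma)
                trace = simulate_annotation(phantom, model, rng)
                mask = rasterize(trace, phantom.canvas)
                ares.append(error_measures(area_triple(phantom.wound_mask, mask)).ARE)
            medians.append(np.median(ares))
        assert medians[0] < medians[1] < medians[2]

    def test_granulation_kind_traces_granulation_region(self, small_phantom, rng):
        model = AnnotatorModel("H1", boundary_jitter_sigma=0)
        trace = simulate_annotation(small_phantom, model, rng, kind=GRANULATION)
        mask = rasterize(trace, small_phantom.canvas)
        assert mask.sum() == small_phantom.granulation_mask.sum()


class TestReviewers:
    def test_zero_noise_estimates_equal_rounded_truth(self, small_phantom, rng):
        model = AnnotatorModel("AI", boundary_jitter_sigma=0)
        traces = {"AI": simulate_annotation(small_phantom, model, rng)}
        responses, record = simulate_reviewers(
            small_phantom, traces, rng, ReviewerModel(noise_sd=0),
        )
        expected = round(small_phantom.true_pgt / 10) * 10
        assert record.reviewer_estimates == (expected,) * 3
        assert len(responses) == 3

    def test_rounding_to_nearest_ten(self, rng):
        # force a truth PGT near 47%: estimates must land on 50
        params = PhantomParams(granulation_fraction=0.47, satellite_count=0)
        phantom = generate_phantom(params, seed=3)
        assert 42 < phantom.true_pgt < 52
        model = AnnotatorModel("AI", boundary_jitter_sigma=0)
        traces = {"AI": simulate_annotation(phantom, model, rng)}
        _, record = simulate_reviewers(phantom, traces, rng, ReviewerModel(noise_sd=0))
        assert record.reviewer_estimates[0] % 10 == 0
        assert abs(record.reviewer_estimates[0] - phantom.true_pgt) <= 5

    def test_reviewer_spread_grows_with_noise(self):
        from woundmetrics.pgt import pgt_variability

        mean_ranges = []
        for noise in (5.0, 20.0):
            records = []
            for seed in range(120):
                phantom = generate_phantom(PhantomParams(satellite_count=0), seed=seed)
                rng = np.random.default_rng(2000 + seed)
                model = AnnotatorModel("AI", boundary_jitter_sigma=0)
                traces = {"AI": simulate_annotation(phantom, model, rng)}
                _, record = simulate_reviewers(
                    phantom, traces, rng, ReviewerModel(noise_sd=noise)
                )
                records.append(record)
            ranges, _ = pgt_variability(records)
            mean_ranges.append(ranges.mean())
        assert mean_ranges[0] < mean_ranges[1]


class TestStudy:
    def test_study_reproducible_and_writable(self, tmp_path):
        study = simulate_study(n_photos=6, seed=21)
        study2 = simulate_study(n_photos=6, seed=21)
        ids = sorted(study.photos[WOUND_AREA])
        assert ids == sorted(study2.photos[WOUND_AREA])
        paths = write_study(study, tmp_path)
        assert paths["manifest"].exists()
        from woundmetrics.roi_io import load_manifest

        groups = load_manifest(paths["manifest"])
        assert set(groups[WOUND_AREA]) == set(ids)
        # round trip: reloaded traces rasterize identically to the originals
        for pid in ids:
            orig = study.photos[WOUND_AREA][pid]
            loaded = groups[WOUND_AREA][pid]
            for tracer, trace in orig.traces.items():
                if trace.is_absent:
                    assert loaded.traces[tracer].is_absent
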