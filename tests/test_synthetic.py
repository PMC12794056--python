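import numpy as np
import pandas as pd
import pytest

from afm.errors import PlacementError
from afm.imaging import FibrosisParams
from afm.metrics import compute_tile_metrics, records_to_frame
from afm.synthetic import (
    SyntheticSlideSpec,
    effect_spec,
    expected_tile_fraction,
    generate_slide,
    reduced_spec,
)


def _metric_frame(slide, tile_size=64):
    recs = compute_tile_metrics(
        slide.image, slide.annotations, FibrosisParams(), nominal_size=tile_size
    )
    return records_to_frame(recs)


class TestSpecValidation:
    def test_overlap_guard(self):
        with pytest.raises(ValueError, match="min_center_spacing"):
            SyntheticSlideSpec(tubule_radius_range=(30, 60), min_center_spacing=50)

    def test_density_bounds(self):
        with pytest.raises(ValueError):
            SyntheticSlideSpec(p0=0.9, delta=0.2)

    def test_unplaceable_spec(self):
        with pytest.raises(PlacementError):
            generate_slide(
                reduced_spec(width=80, height=80, n_distal=60, n_proximal=120)
            )


class TestGenerateSlide:
    def test_zero_density_slide_has_no_fibrotic_pixels(self):
        spec = reduced_spec(seed=9, p0=0.0, delta=0.0)
        slide = generate_slide(spec)
        frame = _metric_frame(slide)
        assert (frame["fibrotic_fraction"] == 0.0).all()
        assert (slide.ground_truth["expected_fraction"] == 0.0).all()

    def test_determinism_same_seed(self):
        spec = reduced_spec(seed=33, p0=0.2, delta=0.05)
        s1 = generate_slide(spec)
        s2 = generate_slide(spec)
        assert np.array_equal(s1.image.pixels, s2.image.pixels)
        assert [a.vertices for a in s1.annotations] == [a.vertices for a in s2.annotations]
        assert [a.tubule_class for a in s1.annotations] == [
            a.tubule_class for a in s2.annotations
        ]
        pd.testing.assert_frame_equal(s1.ground_truth, s2.ground_truth)

    def test_different_seeds_differ(self):
        s1 = generate_slide(reduced_spec(seed=1), ground_truth=False)
        s2 = generate_slide(reduced_spec(seed=2), ground_truth=False)
        assert not np.array_equal(s1.image.pixels, s2.image.pixels)

    def test_class_counts_match_spec(self, small_slide):
        classes = [a.tubule_class for a in small_slide.annotations]
        assert classes.count("distal") == 60 and classes.count("proximal") == 120

    def test_tubules_do_not_overlap(self, small_slide):
        from shapely.geometry import Polygon

        polys = [Polygon(a.vertices) for a in small_slide.annotations]
        for i in range(0, len(polys), 7):  # spot-check pairs
            for j in range(i + 1, len(polys), 13):
                assert not polys[i].intersects(polys[j])

    def test_flat_field_calibration(self, small_slide):
        """p0=0.25, delta=0: mean pipeline metric tracks p0 and the per-tubule
        ground truth within the Monte-Carlo band."""
        frame = _metric_frame(small_slide)
        merged = frame.merge(
            small_slide.ground_truth[["tubule_id", "expected_fraction"]], on="tubule_id"
        )
        assert merged["fibrotic_fraction"].mean() == pytest.approx(0.25, abs=0.02)
        bias = (merged["fibrotic_fraction"] - merged["expected_fraction"]).mean()
        assert -0.02 <= bias <= 0.02


class TestExpectedTileFraction:
    def test_zero_delta_returns_p0_less_interiors(self, small_slide):
        gt = small_slide.ground_truth
        # interiors are tiny (3-5 px radius tubules in 64 px tiles): expectation
        # sits just below p0 and never above
        assert (gt["expected_fraction"] <= 0.25 + 1e-12).all()
        assert gt["expected_fraction"].mean() == pytest.approx(0.25, abs=0.02)

    def test_fully_enriched_distal_tile_reaches_p0_plus_delta(self):
        spec = reduced_spec(seed=5, p0=0.10, delta=0.08, enrichment_radius=200.0)
        slide = generate_slide(spec)
        gt = slide.ground_truth
        distal = gt[gt["tubule_class"] == "distal"]["expected_fraction"]
        # r=200 covers every 64-px tile entirely: expectation = p0 + delta
        # minus the small tubule-interior correction
        assert (distal <= 0.18 + 1e-12).all()
        assert distal.mean() == pytest.approx(0.18, abs=0.01)

    def test_half_covered_tile_mixes_linearly(self):
        """A tile half inside the enrichment disk: numeric integration oracle."""
        from afm.annotations import TubuleAnnotation

        spec = SyntheticSlideSpec(
            width=4000, height=4000, n_distal=1, n_proximal=0,
            tubule_radius_range=(30.0, 60.0), min_center_spacing=125.0,
            p0=0.10, delta=0.08, enrichment_radius=600.0, tile_size=512,
        )
        # proximal-style probe tubule centered so the disk edge bisects its tile;
        # the tubule is placed far away, so no interior correction applies here
        distal_center = np.array([2000.0, 2000.0])
        probe_center = (2000.0 + 600.0, 2000.0)  # on the disk boundary
        half_plane_center = np.array([2600.0 - 20000.0, 2000.0])  # huge disk
        probe = TubuleAnnotation(
            "probe",
            [
                (probe_center[0] - 3, probe_center[1] - 3),
                (probe_center[0] + 3, probe_center[1] - 3),
                (probe_center[0] + 3, probe_center[1] + 3),
                (probe_center[0] - 3, probe_center[1] + 3),
            ],
            "proximal",
        )
        got = expected_tile_fraction(
            spec, probe, distal_centroids=distal_center.reshape(1, 2), all_polygons=[]
        )
        # numeric integration over the tile of p0 + delta * 1[inside disk]
        win = 512
        xs = np.linspace(probe_center[0] - win / 2, probe_center[0] + win / 2, 600)
        ys = np.linspace(probe_center[1] - win / 2, probe_center[1] + win / 2, 600)
        gx, gy = np.meshgrid(xs, ys)
        inside = (gx - 2000.0) ** 2 + (gy - 2000.0) ** 2 <= 600.0**2
        oracle = 0.10 + 0.08 * inside.mean()
        assert got == pytest.approx(oracle, abs=1e-3)
        # with a near-flat disk boundary through the tile center the covered
        # share is an exact half, so the mix collapses to p0 + delta/2
        spec_flat = SyntheticSlideSpec(
            width=4000, height=4000, n_distal=1, n_proximal=0,
            tubule_radius_range=(30.0, 60.0), min_center_spacing=125.0,
            p0=0.10, delta=0.08, enrichment_radius=20000.0, tile_size=512,
        )
        got_flat = expected_tile_fraction(
            spec_flat, probe, distal_centroids=half_plane_center.reshape(1, 2),
            all_polygons=[],
        )
        assert got_flat == pytest.approx(0.10 + 0.08 / 2, abs=2e-3)

    def test_monotone_in_delta(self):
        """Expected distal-minus-proximal separation grows with delta."""
        diffs = []
        for delta in (0.0, 0.04, 0.08):
            spec = effect_spec(seed=21, p0=0.15, delta=delta)
            slide = generate_slide(spec)
            gt = slide.ground_truth
            by = gt.groupby("tubule_class")["expected_fraction"].mean()
            diffs.append(by["distal"] - by["proximal"])
        # delta=0: only the (class-blind) interior correction distinguishes
        # the groups, so the expected separation is essentially zero
        assert diffs[0] == pytest.approx(0.0, abs=1e-3)
        assert diffs[0] < diffs[1] < diffs[2]
        assert diffs[2] > 0.04

    def test_observed_separation_grows_with_delta(self):
        observed = []
        for delta in (0.0, 0.10):
            vals = []
            for seed in (60, 61, 62):
                spec = effect_spec(seed=seed, p0=0.15, delta=delta)
                frame = _metric_frame(generate_slide(spec, ground_truth=False))
                by = frame.groupby("tubule_class")["fibrotic_fraction"].mean()
                vals.append(by["distal"] - by["proximal"])
            observed.append(np.mean(vals))
        assert observed[1] > observed[0] + 0.03

    def test_class_exchangeability_under_null(self, small_slide):
        """delta=0: permuting class labels leaves the metric distribution alone."""
        frame = _metric_frame(small_slide)
        rng = np.random.default_rng(8)
        obs = np.abs(
            frame.groupby("tubule_class")["fibrotic_fraction"].mean().diff().iloc[-1]
        )
        vals = frame["fibrotic_fraction"].to_numpy()
        n_d = (frame["tubule_class"] == "distal").sum()
        perm_stats = []
        for _ in range(500):
            perm = rng.permutation(vals)
            perm_stats.append(abs(perm[:n_d].mean() - perm[n_d:].mean()))
        p_perm = np.mean(np.asarray(perm_stats) >= obs)
        assert p_perm > 0.01  # observed labelling is unremarkable under permutation
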