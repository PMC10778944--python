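import numpy as np
import pytest

from powderdiff.segmentation import (
    otsu_threshold, segment_frame, segment_series, equivalent_diameter,
    regions_from_masks,
)
from powderdiff.reference import REFERENCE_PARTICLES
from conftest import match_truth
from oracles import otsu_bruteforce


class TestOtsuThreshold:
    def test_binary_image_separates_classes(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        img[:5] = 255
        hist = np.bincount(img.ravel(), minlength=256)
        t = otsu_threshold(hist)
        assert 0 <= t <= 254
        assert (img > t).sum() == 50

    def test_bimodal_histogram_foreground_count(self):
        hist = np.zeros(256)
        hist[10] = 100
        hist[200] = 100
        t = otsu_threshold(hist)
        assert 10 <= t < 200  # the 200-class is foreground

    def test_single_valued_image_rejected(self):
        hist = np.zeros(256)
        hist[42] = 1000
        with pytest.raises(ValueError, match="single"):
            otsu_threshold(hist)

    def test_matches_exhaustive_search_on_random_histograms(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            hist = rng.integers(0, 50, 256)
            while np.count_nonzero(hist) < 2:
                hist = rng.integers(0, 50, 256)
            assert otsu_threshold(hist) == otsu_bruteforce(hist)


class TestEquivalentDiameter:
    @pytest.mark.parametrize(
        "particle", REFERENCE_PARTICLES, ids=lambda p: f"p{p.particle_id}"
    )
    def test_benchmark_diameters_from_areas(self, particle):
        d_um = equivalent_diameter(particle.area_m2) * 1e6
        assert d_um == pytest.approx(particle.diameter_um, abs=0.01)

    def test_closed_form_unit_case(self):
        assert equivalent_diameter(np.pi / 4) == pytest.approx(1.0)

    def test_non_positive_area_rejected(self):
        with pytest.raises(ValueError):
            equivalent_diameter(0.0)


def _disc_frame(shape=(64, 64), centre=(32, 32), radius=10,
                fg=200, bg=20, hole=None):
    img = np.full(shape, bg, dtype=np.uint8)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    mask = (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2 <= radius**2
    img[mask] = fg
    if hole is not None:
        hmask = (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2 <= hole**2
        img[hmask] = bg
    return img, mask


class TestSegmentFrame:
    def test_single_disc_area(self):
        img, mask = _disc_frame()
        regions = segment_frame(img, pixel_size_m=1e-6)
        assert len(regions) == 1
        assert regions[0].area_px == pytest.approx(np.pi * 100, rel=0.04)
        assert regions[0].area_px == mask.sum()

    def test_dark_hole_is_filled(self):
        img, mask = _disc_frame(hole=4)
        regions = segment_frame(img, pixel_size_m=1e-6)
        assert len(regions) == 1
        assert regions[0].area_px == mask.sum()

    def test_constant_frame_yields_no_regions(self):
        assert segment_frame(np.full((32, 32), 7, np.uint8), 1e-6) == []

    def test_border_touching_particle_discarded(self):
        img, _ = _disc_frame(centre=(2, 32), radius=10)
        assert segment_frame(img, 1e-6) == []

    def test_small_specks_filtered(self):
        img = np.full((32, 32), 10, dtype=np.uint8)
        img[5:7, 5:7] = 200  # 4 px speck
        assert segment_frame(img, 1e-6, min_area_px=20) == []
        assert len(segment_frame(img, 1e-6, min_area_px=2)) == 1

    def test_morphology_fields_consistent(self):
        img, _ = _disc_frame()
        r = segment_frame(img, pixel_size_m=2e-6)[0]
        assert r.area_m2 == pytest.approx(r.area_px * (2e-6) ** 2)
        assert r.equivalent_diameter_m == pytest.approx(
            2 * np.sqrt(r.area_m2 / np.pi)
        )
        r0, c0, h, w = r.bbox
        rows, cols = np.nonzero(r.mask)
        assert (r0, c0) == (rows.min(), cols.min())
        assert (h, w) == (rows.max() - r0 + 1, cols.max() - c0 + 1)
        assert r.centroid_px == pytest.approx((32.0, 32.0), abs=0.1)

    def test_labels_ordered_by_decreasing_area(self):
        img = np.full((96, 96), 10, dtype=np.uint8)
        rr, cc = np.mgrid[0:96, 0:96]
        img[(rr - 25) ** 2 + (cc - 25) ** 2 <= 36] = 200    # small
        img[(rr - 65) ** 2 + (cc - 65) ** 2 <= 144] = 200   # large
        regions = segment_frame(img, 1e-6)
        assert [r.label for r in regions] == [1, 2]
        assert regions[0].area_px > regions[1].area_px

    def test_regions_pairwise_disjoint(self, noiseless_scene):
        _, series, _ = noiseless_scene
        regions = segment_frame(series.frames[0], series.pixel_size_m)
        total = np.zeros(series.shape, dtype=int)
        for r in regions:
            total += r.mask
        assert total.max() <= 1
        assert sum(r.area_px for r in regions) <= total.size


class TestDiameterRecovery:
    def test_noiseless_scene_diameters_within_5pct(self, noiseless_scene):
        _, series, truth = noiseless_scene
        regions = segment_frame(series.frames[0], series.pixel_size_m)
        assert len(regions) == len(truth.particles)
        for r in regions:
            p = min(
                truth.particles,
                key=lambda q: (q.centre_px[0] - r.centroid_px[0]) ** 2
                + (q.centre_px[1] - r.centroid_px[1]) ** 2,
            )
            assert r.equivalent_diameter_m == pytest.approx(
                2 * p.radius_m, rel=0.05
            )


class TestRegionsFromMasks:
    def test_external_masks_respect_filters(self):
        big = np.zeros((32, 32), dtype=bool)
        big[5:15, 5:15] = True
        tiny = np.zeros((32, 32), dtype=bool)
        tiny[20:22, 20:22] = True
        per_frame = regions_from_masks([[big, tiny]], pixel_size_m=1e-6)
        assert len(per_frame[0]) == 1
        assert per_frame[0][0].area_px == 100
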