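"""Histological quantification against ground truth and a brute-force
per-pixel distance oracle."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from pbmstudy import histology as hi
from pbmstudy import synthdata as sd


def _section(**kw):
    defaults = dict(image_shape=(400, 400), plaque_count=4, noise_sd=0.0,
                    min_separation_um=95.0, seed=4)
    defaults.update(kw)
    params = sd.HistoSimParams(**defaults)
    images, truth = sd.simulate_histology_image(params)
    region = hi.RegionAnnotation.full_frame(params.image_shape,
                                            pixel_size_um=params.pixel_size_um)
    return params, images, truth, region


class TestSegmentPlaques:
    def test_blank_image_yields_no_plaques(self, full_region):
        img = np.full((100, 100), 50.0)
        labels, table = hi.segment_plaques(img, full_region((100, 100)))
        assert labels.max() == 0 and len(table) == 0

    def test_recovers_ground_truth_disks(self):
        _, images, truth, region = _section(plaque_count=5, image_shape=(512, 512))
        labels, table = hi.segment_plaques(images["plaque_channel"], region)
        assert len(table) == 5
        got = table[["centroid_row_px", "centroid_col_px"]].to_numpy()
        d = cdist(got, truth.plaque_centers_px)
        assert (d.min(axis=1) <= 1.0).all()  # centroids within 1 pixel

    def test_equivalent_radius_definition(self):
        _, images, truth, region = _section(plaque_count=3)
        _, table = hi.segment_plaques(images["plaque_channel"], region)
        expected = np.sqrt(table["area_um2"] / np.pi)
        assert np.allclose(table["equivalent_radius_um"], expected)
        # and close to the generated disk radii
        assert np.allclose(
            np.sort(table["equivalent_radius_um"]), np.sort(truth.plaque_radii_um), atol=1.0
        )

    def test_min_area_filter(self):
        img = np.full((100, 100), 50.0)
        img[10:12, 10:12] = 5000.0   # 4 px = 1.44 μm²
        img[40:60, 40:60] = 5000.0   # 400 px = 144 μm²
        region = hi.RegionAnnotation.full_frame((100, 100))
        _, table = hi.segment_plaques(img, region, min_area_um2=20.0,
                                      threshold_method=1000.0)
        assert len(table) == 1

    def test_exclusion_polygon_removes_plaques(self):
        _, images, truth, region = _section(plaque_count=4)
        r0, c0 = truth.plaque_centers_px[0]
        excl = np.array([[r0 - 30, c0 - 30], [r0 - 30, c0 + 30],
                         [r0 + 30, c0 + 30], [r0 + 30, c0 - 30]])
        region.exclude_polygons = [excl]
        _, table = hi.segment_plaques(images["plaque_channel"], region)
        assert len(table) < 4


class TestPlaqueLoad:
    def test_empty_and_full_masks(self, full_region):
        region = full_region((50, 50))
        assert hi.plaque_load(np.zeros((50, 50), bool), region) == 0.0
        assert hi.plaque_load(np.ones((50, 50), bool), region) == 1.0

    def test_fraction_arithmetic(self, full_region):
        mask = np.zeros((1000, 1000), bool)
        mask[:100, :100] = True  # 10,000 of 1,000,000 pixels
        assert hi.plaque_load(mask, full_region((1000, 1000))) == pytest.approx(0.01)

    def test_zero_area_region_raises(self):
        region = hi.RegionAnnotation.from_mask(np.zeros((10, 10), bool))
        with pytest.raises(ValueError, match="zero area"):
            hi.plaque_load(np.zeros((10, 10), bool), region)

    def test_pixel_size_invariance_under_upsampling(self):
        params, images, truth, region = _section(plaque_count=3)
        labels, _ = hi.segment_plaques(images["plaque_channel"], region)
        load1 = hi.plaque_load(labels, region)
        up = np.kron(labels > 0, np.ones((2, 2), dtype=bool))
        region2 = hi.RegionAnnotation.full_frame(up.shape, pixel_size_um=0.3)
        load2 = hi.plaque_load(up, region2)
        assert load2 == pytest.approx(load1, rel=0.01)


class TestMicrogliaResponse:
    def test_uniform_channel_gives_ratio_one(self):
        _, images, _, region = _section(enrichment_factor=1.0, plaque_count=5,
                                        image_shape=(512, 512))
        labels, _ = hi.segment_plaques(images["plaque_channel"], region)
        resp = hi.microglia_response(images["microglia_channel"], labels, region)
        assert len(resp.per_plaque) == 5
        assert np.allclose(resp.per_plaque["ratio"], 1.0, atol=1e-6)

    def test_near_annulus_enrichment_doubles_ratio(self):
        _, images, _, region = _section(enrichment_factor=2.0)
        labels, _ = hi.segment_plaques(images["plaque_channel"], region)
        resp = hi.microglia_response(images["microglia_channel"], labels, region)
        assert np.allclose(resp.per_plaque["ratio"], 2.0, atol=0.05)
        assert (resp.per_plaque["ratio"] > 1.0).all()

    def test_matches_brute_force_pixel_oracle(self):
        """Annulus means must equal an explicit per-pixel distance
        enumeration (no geometry shortcuts) on a small decaying field."""
        params, images, truth, region = _section(
            image_shape=(220, 220), plaque_count=2, enrichment_factor=1.8,
            falloff_um=30.0, min_separation_um=40.0, seed=9,
        )
        labels, _ = hi.segment_plaques(images["plaque_channel"], region)
        mg = images["microglia_channel"]
        resp = hi.microglia_response(mg, labels, region)
        px = params.pixel_size_um
        coords = np.argwhere(np.ones_like(labels, dtype=bool))
        any_plaque = labels > 0
        for _, row in resp.per_plaque.iterrows():
            pid = int(row["plaque_id"])
            plaque_px = np.argwhere(labels == pid)
            d = cdist(coords, plaque_px).min(axis=1).reshape(labels.shape) * px
            d[labels == pid] = 0.0
            near = (d > 0) & (d <= 12.0) & ~any_plaque
            far = (d >= 18.0) & (d <= 60.0) & ~any_plaque
            assert row["mean_intensity_near"] == pytest.approx(mg[near].mean(), abs=1e-9)
            assert row["mean_intensity_far"] == pytest.approx(mg[far].mean(), abs=1e-9)

    def test_ratio_invariant_to_intensity_scaling(self):
        _, images, _, region = _section(enrichment_factor=1.6, noise_sd=25.0)
        labels, _ = hi.segment_plaques(images["plaque_channel"], region)
        r1 = hi.microglia_response(images["microglia_channel"], labels, region)
        r2 = hi.microglia_response(images["microglia_channel"] * 7.3, labels, region)
        assert np.allclose(r1.per_plaque["ratio"], r2.per_plaque["ratio"])

    def test_plaque_interiors_excluded_from_annuli(self):
        """Pixels of a neighbouring plaque never contribute to an annulus:
        inflate one plaque's interior intensity and check no ratio moves."""
        _, images, truth, region = _section(plaque_count=3, enrichment_factor=1.0,
                                            min_separation_um=20.0)
        labels, _ = hi.segment_plaques(images["plaque_channel"], region)
        mg = images["microglia_channel"].copy()
        mg[labels > 0] = 1e9
        resp = hi.microglia_response(mg, labels, region)
        assert np.allclose(resp.per_plaque["ratio"], 1.0, atol=1e-6)

    def test_border_plaque_dropped_and_logged(self):
        img = np.full((80, 300), 50.0)
        img[2:8, 2:8] = 5000.0       # tiny corner plaque: far annulus clipped
        img[30:60, 150:180] = 5000.0
        region = hi.RegionAnnotation.from_mask(np.zeros((80, 300), bool))
        region._mask[:, :] = False
        region._mask[0:80, 100:300] = True  # corner plaque outside region
        labels, _ = hi.segment_plaques(img, region, threshold_method=1000.0)
        mgc = np.full((80, 300), 100.0)
        resp = hi.microglia_response(mgc, labels, region)
        assert len(resp.per_plaque) == 1

    def test_monotone_in_generated_enrichment(self):
        means = []
        for ef in (1.0, 1.5, 2.0, 3.0):
            _, images, _, region = _section(enrichment_factor=ef, noise_sd=30.0,
                                            image_shape=(400, 400), plaque_count=3,
                                            seed=11)
            labels, _ = hi.segment_plaques(images["plaque_channel"], region)
            resp = hi.microglia_response(images["microglia_channel"], labels, region)
            means.append(resp.summary_mean)
        assert all(a < b for a, b in zip(means, means[1:]))


class TestCountNeurons:
    def test_counts_and_exclusions(self):
        _, images, truth, region = _section(plaque_count=0, nucleus_count=40,
                                            image_shape=(300, 300))
        n, dens = hi.count_neurons(images["nucleus_labels"], region)
        assert n == 40
        assert dens == pytest.approx(40 / (300 * 300 * 0.6**2))
        # exclude a polygon around one nucleus centroid
        r0, c0 = truth.nucleus_centers_px[0]
        excl = np.array([[r0 - 9, c0 - 9], [r0 - 9, c0 + 9],
                         [r0 + 9, c0 + 9], [r0 + 9, c0 - 9]])
        region.exclude_polygons = [excl]
        n2, _ = hi.count_neurons(images["nucleus_labels"], region)
        assert n2 == 39

    def test_empty_mask(self, full_region):
        n, dens = hi.count_neurons(np.zeros((50, 50), np.int32), full_region((50, 50)))
        assert n == 0 and dens == 0.0

    def test_binary_mask_rejected_with_guidance(self, full_region):
        mask = np.zeros((60, 60), np.int32)
        mask[5:10, 5:10] = 1
        mask[40:45, 40:45] = 1  # two components, one label: binary, not instances
        with pytest.raises(ValueError, match="instance label mask"):
            hi.count_neurons(mask, full_region((60, 60)))
        with pytest.raises(ValueError, match="instance label mask"):
            hi.count_neurons(mask.astype(bool), full_region((60, 60)))
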