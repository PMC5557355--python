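"""Segmentation and pairing contracts, with brute-force oracles."""

import itertools
import math

import numpy as np
import pytest

from synaptoquant import puncta
from synaptoquant.puncta import DetectionConfig, PairingConfig, Punctum
from synaptoquant.synthgen import PunctaFieldSpec, generate_puncta_field

PX = 0.07


def make_punctum(pid, channel, pixels, shape=(64, 64)):
    pixels = frozenset(pixels)
    rows = [r for r, _ in pixels]
    cols = [c for _, c in pixels]
    return Punctum(
        id=pid, channel=channel, pixel_set=pixels, area_px=len(pixels),
        area_um2=len(pixels) * PX**2,
        centroid_um=(float(np.mean(cols)) * PX, float(np.mean(rows)) * PX),
        mean_intensity=100.0, snr=10.0, image_shape=shape,
    )


def rect(r0, c0, h, w):
    return {(r, c) for r in range(r0, r0 + h) for c in range(c0, c0 + w)}


FULL_ROI = [(0.0, 0.0), (63 * PX, 0.0), (63 * PX, 63 * PX), (0.0, 63 * PX)]


class TestSegmentPuncta:
    def test_isolated_single_pixels_removed(self):
        img = np.zeros((64, 64))
        for r, c in [(5, 5), (20, 40), (50, 10)]:
            img[r, c] = 100.0
        cfg = DetectionConfig(threshold_method="fixed", fixed_threshold=50.0)
        assert puncta.segment_puncta(img, cfg) == []

    def test_apparent_diameter_cutoff(self):
        # disks straddling the 0.335 um apparent-diameter rule; rasterized
        # areas verified against a direct pixel count
        img = np.zeros((200, 200))
        planted = [(0.30, 50, 100), (0.45, 150, 100)]
        for d_um, cy, cx in planted:
            r = d_um / 2 / PX
            rr, cc = np.ogrid[:200, :200]
            img[(rr - cy) ** 2 + (cc - cx) ** 2 <= r * r] = 100.0
        for d_um, cy, cx in planted:
            r = d_um / 2 / PX
            span = np.arange(-6, 7)
            area = int(np.sum(span[:, None] ** 2 + span[None, :] ** 2 <= r * r))
            side = 2 * math.sqrt(area * PX * PX / math.pi)
            assert (side < 0.335) == (d_um < 0.335)
        cfg = DetectionConfig(threshold_method="fixed", fixed_threshold=50.0)
        objs = puncta.segment_puncta(img, cfg)
        assert len(objs) == 1
        assert objs[0].equivalent_diameter_um >= 0.335

    def test_small_object_survives_with_finite_snr_gate(self):
        img = np.zeros((100, 100))
        rr, cc = np.ogrid[:100, :100]
        img[(rr - 50) ** 2 + (cc - 50) ** 2 <= (0.15 / PX) ** 2] = 100.0
        img += np.random.default_rng(0).normal(0, 1.0, size=img.shape)
        img = np.clip(img, 0, None)
        strict = DetectionConfig(threshold_method="fixed", fixed_threshold=50.0)
        lax = DetectionConfig(threshold_method="fixed", fixed_threshold=50.0,
                              snr_min=5.0)
        assert puncta.segment_puncta(img, strict) == []
        assert len(puncta.segment_puncta(img, lax)) == 1

    def test_noiseless_field_fully_recovered(self, noiseless_field_spec):
        red, _, truth = generate_puncta_field(noiseless_field_spec)
        objs = puncta.segment_puncta(red, DetectionConfig(), "red")
        assert len(objs) == len(truth.red_centers)
        got = np.array([o.centroid_um for o in objs])
        for x, y, _ in truth.red_centers:
            d = np.hypot(got[:, 0] - x, got[:, 1] - y).min()
            assert d < PX  # centroid within one pixel of ground truth

    def test_empty_image_gives_empty_list(self):
        cfg = DetectionConfig(threshold_method="fixed", fixed_threshold=10.0)
        assert puncta.segment_puncta(np.zeros((32, 32)), cfg) == []

    def test_labels_in_raster_order(self):
        img = np.zeros((64, 64))
        img[40:46, 5:11] = 100.0
        img[10:16, 50:56] = 100.0
        cfg = DetectionConfig(threshold_method="fixed", fixed_threshold=50.0)
        objs = puncta.segment_puncta(img, cfg)
        assert [o.id for o in objs] == [1, 2]
        assert objs[0].centroid_um[1] < objs[1].centroid_um[1]


class TestPairPuncta:
    def test_sixty_pixel_boundary_is_strict(self):
        red = [make_punctum(1, "red", rect(10, 10, 10, 10))]
        for overlap_cols, expected in [(6, 0), (7, 1)]:  # 60 px vs 70 px
            green = [make_punctum(1, "green", rect(10, 10, 10, overlap_cols)
                                  | rect(30, 30, 5, 5))]
            res = puncta.pair_puncta(red, green, FULL_ROI, PairingConfig())
            assert len(res.overlap_objects) == expected
        # exactly 61 shared pixels -> paired
        green = [make_punctum(1, "green",
                              rect(10, 10, 6, 10) | {(16, 10)})]
        res = puncta.pair_puncta(red, green, FULL_ROI, PairingConfig())
        assert len(res.overlap_objects) == 1
        assert res.overlap_objects[0][2] == 61

    def test_disjoint_channels_all_single(self):
        red = [make_punctum(1, "red", rect(5, 5, 9, 9))]
        green = [make_punctum(1, "green", rect(40, 40, 9, 9))]
        res = puncta.pair_puncta(red, green, FULL_ROI, PairingConfig())
        assert res.paired_red == res.paired_green == 0
        assert res.singles_red == res.singles_green == 1
        assert res.densities_per_um2["overlap"] == 0.0

    def test_channel_symmetry_and_count_conservation(self, rng):
        red, green = _random_objects(rng, seed_offset=0)
        res_rg = puncta.pair_puncta(red, green, FULL_ROI, PairingConfig(overlap_min_px=10))
        res_gr = puncta.pair_puncta(green, red, FULL_ROI, PairingConfig(overlap_min_px=10))
        assert {(r, g, n) for r, g, n, _ in res_rg.overlap_objects} == \
               {(g, r, n) for r, g, n, _ in res_gr.overlap_objects}
        assert res_rg.singles_red + res_rg.paired_red == res_rg.total_red
        assert res_rg.singles_green + res_rg.paired_green == res_rg.total_green

    def test_matches_brute_force_intersection(self, rng):
        for trial in range(20):
            red, green = _random_objects(rng, seed_offset=trial)
            cfg = PairingConfig(overlap_min_px=int(rng.integers(1, 40)))
            res = puncta.pair_puncta(red, green, FULL_ROI, cfg)
            expected = {
                (a.id, b.id, len(a.pixel_set & b.pixel_set))
                for a, b in itertools.product(red, green)
                if len(a.pixel_set & b.pixel_set) > cfg.overlap_min_px
            }
            assert {(r, g, n) for r, g, n, _ in res.overlap_objects} == expected

    def test_more_overlap_required_never_more_pairs(self, rng):
        red, green = _random_objects(rng, seed_offset=99)
        prev = None
        for k in [1, 5, 10, 20, 40, 80]:
            res = puncta.pair_puncta(red, green, FULL_ROI,
                                     PairingConfig(overlap_min_px=k))
            if prev is not None:
                assert len(res.overlap_objects) <= prev
            prev = len(res.overlap_objects)

    def test_multisynaptic_participation_counted_once_as_paired(self):
        red = [make_punctum(1, "red", rect(10, 10, 20, 20))]
        green = [make_punctum(1, "green", rect(10, 10, 9, 9)),
                 make_punctum(2, "green", rect(20, 20, 9, 9))]
        res = puncta.pair_puncta(red, green, FULL_ROI,
                                 PairingConfig(overlap_min_px=60))
        assert len(res.overlap_objects) == 2
        assert res.paired_red == 1
        assert res.multisynaptic_contacts == 1  # the red punctum

    def test_roi_membership_by_centroid(self):
        red = [make_punctum(1, "red", rect(10, 10, 10, 10))]
        green = [make_punctum(1, "green", rect(10, 10, 10, 10))]
        far_roi = [(3.0, 3.0), (4.0, 3.0), (4.0, 4.0), (3.0, 4.0)]
        res = puncta.pair_puncta(red, green, far_roi, PairingConfig())
        assert res.total_red == res.total_green == 0

    def test_degenerate_roi_rejected(self):
        red = [make_punctum(1, "red", rect(10, 10, 5, 5))]
        line = [(0.0, 0.0), (1.0, 0.0), (2.0, 0.0)]
        with pytest.raises(ValueError):
            puncta.pair_puncta(red, [], line, PairingConfig())

    def test_unregistered_channels_rejected(self):
        red = [make_punctum(1, "red", rect(10, 10, 5, 5), shape=(64, 64))]
        green = [make_punctum(1, "green", rect(10, 10, 5, 5), shape=(128, 128))]
        with pytest.raises(ValueError):
            puncta.pair_puncta(red, green, FULL_ROI, PairingConfig())


def _random_objects(rng, seed_offset=0):
    """Random rectangles per channel, non-overlapping within a channel."""
    local = np.random.default_rng(1000 + seed_offset)
    out = []
    for channel in ("red", "green"):
        objs = []
        taken = set()
        pid = 1
        for _ in range(6):
            h, w = local.integers(3, 12, size=2)
            r0 = int(local.integers(0, 64 - h))
            c0 = int(local.integers(0, 64 - w))
            pix = rect(r0, c0, int(h), int(w))
            if pix & taken:
                continue
            taken |= pix
            objs.append(make_punctum(pid, channel, pix))
            pid += 1
        out.append(objs)
    return out


class TestDistributionsAndDensities:
    def test_equal_areas_fill_single_bin(self):
        dist = puncta.cluster_area_distribution(np.full(5, 0.12), 0.1)
        assert dist.frequencies.sum() == 5
        assert (dist.frequencies > 0).sum() == 1

    def test_three_areas_three_bins(self):
        dist = puncta.cluster_area_distribution(
            np.array([0.05, 0.15, 0.25]), 0.1)
        assert dist.frequencies.tolist() == [1, 1, 1]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            puncta.cluster_area_distribution([], 0.1)

    def test_linear_density(self):
        assert puncta.linear_density(10, 20.0) == 0.5
        assert puncta.linear_density(0, 20.0) == 0.0
        with pytest.raises(ValueError):
            puncta.linear_density(3, 0.0)

    def test_poisson_placed_clusters_density_estimate(self, rng):
        lam, length = 0.8, 100.0
        estimates = [
            puncta.linear_density(int(rng.poisson(lam * length)), length)
            for _ in range(50)
        ]
        se = math.sqrt(lam / length) / math.sqrt(50)
        assert abs(np.mean(estimates) - lam) < 3 * se


class TestIntensityPerArea:
    def test_uniform_signal_returns_its_value(self):
        mask_src = np.zeros((64, 64))
        mask_src[20:40, 20:40] = 100.0
        signal = np.full((64, 64), 7.5)
        assert puncta.intensity_per_area(signal, mask_src) == pytest.approx(7.5)

    def test_linear_in_signal(self, rng):
        mask_src = np.zeros((64, 64))
        mask_src[10:50, 10:50] = 100.0
        signal = rng.uniform(0, 50, size=(64, 64))
        v1 = puncta.intensity_per_area(signal, mask_src)
        v2 = puncta.intensity_per_area(2.0 * signal, mask_src)
        assert v2 == pytest.approx(2.0 * v1)

    def test_known_mean_recovered_over_triangle_mask(self, rng):
        mask_src = np.zeros((128, 128))
        rr, cc = np.ogrid[:128, :128]
        cell = (rr - 64) ** 2 + (cc - 64) ** 2 <= 40**2
        mask_src[cell] = 200.0
        mask_src += rng.normal(5, 1, size=mask_src.shape)
        signal = np.where(cell, 100.0, 0.0)
        v = puncta.intensity_per_area(np.clip(signal, 0, None),
                                      np.clip(mask_src, 0, None))
        assert v == pytest.approx(100.0, rel=0.02)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            puncta.intensity_per_area(np.zeros((8, 8)), np.zeros((9, 9)))
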