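import numpy as np
import pytest
from skimage.draw import disk as draw_disk
from skimage.measure import label

from myofuse import make_boundary_case, make_culture
from myofuse.errors import ParameterError
from myofuse.image_io import select_channel
from myofuse.nucleus_segmentation import (
    binarize_and_clean_nuclei,
    denoise_nuclei,
    detect_nuclei,
    hough_round_nuclei,
    remove_round_nuclei,
    watershed_split_remaining,
)


def disc_mask(shape, centres, radii):
    m = np.zeros(shape, bool)
    for c, r in zip(centres, radii):
        rr, cc = draw_disk(c, r + 0.5, shape=shape)
        m[rr, cc] = True
    return m


class TestDenoise:
    def test_constant_image_unchanged(self):
        im = np.full((40, 40), 0.37)
        np.testing.assert_allclose(denoise_nuclei(im), im)

    def test_reduces_gaussian_noise_rmse(self):
        rng = np.random.default_rng(1)
        clean = np.full((120, 120), 0.05)
        rr, cc = draw_disk((60, 60), 20.5, shape=clean.shape)
        clean[rr, cc] = 0.8
        noisy = np.clip(clean + rng.normal(0, 0.05, clean.shape), 0, 1)
        den = denoise_nuclei(noisy)
        rmse = lambda a: float(np.sqrt(((a - clean) ** 2).mean()))
        assert rmse(den) < rmse(noisy)

    def test_attenuates_impulse(self):
        im = np.full((30, 30), 0.1)
        im[15, 15] = 1.0
        assert denoise_nuclei(im)[15, 15] < 1.0


class TestBinarizeAndClean:
    def test_size_floor_boundary_exact(self, params):
        img299, _ = make_boundary_case("nucleus_area_299")
        img300, _ = make_boundary_case("nucleus_area_300")
        gone = binarize_and_clean_nuclei(select_channel(img299, 3), params)
        kept = binarize_and_clean_nuclei(select_channel(img300, 3), params)
        assert gone.sum() == 0
        assert kept.sum() == 300

    def test_oversize_blob_discarded(self, params):
        image, truth = make_boundary_case("oversize_nucleus")
        assert truth.structure_areas[1] == 11_000  # > 1% of the 1000x1000 field
        mask = binarize_and_clean_nuclei(select_channel(image, 3), params)
        assert mask.sum() == 0

    def test_blank_stays_blank(self, params):
        assert binarize_and_clean_nuclei(np.zeros((50, 50)), params).sum() == 0


class TestHough:
    def test_single_disc_radius_20(self):
        m = disc_mask((120, 120), [(60, 60)], [20])
        dets = hough_round_nuclei(m, m.astype(float), 15, 40)
        assert len(dets) == 1
        (r, c), rad = dets[0]
        assert abs(r - 60) <= 2 and abs(c - 60) <= 2
        assert abs(rad - 20) <= 3

    def test_disc_below_radius_floor_ignored(self):
        m = disc_mask((120, 120), [(60, 60)], [10])
        assert hough_round_nuclei(m, m.astype(float), 15, 40) == []

    def test_two_discs_both_found(self):
        m = disc_mask((150, 150), [(75, 50), (75, 100)], [18, 18])
        dets = hough_round_nuclei(m, m.astype(float), 15, 40)
        assert len(dets) == 2

    def test_degenerate_radius_range_rejected(self):
        with pytest.raises(ParameterError):
            hough_round_nuclei(np.ones((10, 10), bool), np.ones((10, 10)), 20, 20)


class TestRemoveRound:
    def test_matching_detection_leaves_small_residual(self):
        m = disc_mask((120, 120), [(60, 60)], [20])
        rem = remove_round_nuclei(m, [((60, 60), 20)])
        assert rem.sum() / m.sum() < 0.15

    def test_no_detections_identity(self):
        m = disc_mask((80, 80), [(40, 40)], [15])
        np.testing.assert_array_equal(remove_round_nuclei(m, []), m)

    def test_clump_minus_one_detection_leaves_other_lobe(self):
        centres, radii = [(75, 60), (75, 95)], [18, 18]
        m = disc_mask((150, 150), centres, radii)
        rem = remove_round_nuclei(m, [((75, 60), 18)])
        # the remaining pixels sit around the non-detected lobe
        ys, xs = np.nonzero(rem)
        assert xs.mean() > 85
        lone = disc_mask((150, 150), [(75, 95)], [18])
        assert rem.sum() < lone.sum() * 1.1


class TestWatershed:
    def test_overlapping_pair_split_into_two(self, params):
        m = disc_mask((150, 150), [(75, 60), (75, 90)], [20, 20])
        frags = watershed_split_remaining(m, params)
        assert len(frags) == 2
        for (r, c), _ in frags:
            assert min(np.hypot(r - 75, c - 60), np.hypot(r - 75, c - 90)) < 5

    def test_empty_remainder(self, params):
        assert watershed_split_remaining(np.zeros((40, 40), bool), params) == []

    def test_single_convex_blob_not_split(self, params):
        m = disc_mask((150, 150), [(75, 75)], [28])  # ~2x typical nucleus area
        frags = watershed_split_remaining(m, params)
        assert len(frags) == 1


class TestDetectNuclei:
    def test_recovers_all_separated_discs(self, params):
        image, truth = make_culture(
            height=512, width=512, n_tubes=0, n_myoblasts=0,
            n_free_nuclei=12, noise_sigma=0.03, seed=21,
        )
        nuclei = detect_nuclei(select_channel(image, 3), params)
        assert nuclei.count == truth.total_nuclei == 12

    def test_touching_pairs_counted_exactly(self, params):
        image, truth = make_culture(
            height=768, width=768, n_tubes=0, n_myoblasts=0,
            n_free_nuclei=10, touching_pairs=5, noise_sigma=0.03, seed=23,
        )
        nuclei = detect_nuclei(select_channel(image, 3), params)
        assert nuclei.count == truth.total_nuclei == 20

    def test_blank_channel_zero_nuclei(self, params):
        nuclei = detect_nuclei(np.zeros((64, 64)), params)
        assert nuclei.count == 0

    def test_determinism_and_invariants(self, params, culture512_analysis):
        image = culture512_analysis["image"]
        a = culture512_analysis["nuclei"]
        b = detect_nuclei(select_channel(image, 3), params)
        assert a.centres == b.centres
        assert a.provenance == b.provenance
        # every centre lies inside the accepted nuclear mask
        for (r, c), size, tag in zip(a.centres, a.sizes, a.provenance):
            assert a.mask[int(round(r)), int(round(c))]
            if tag == "hough":
                assert params.min_circle_rad <= size <= params.max_circle_rad
            else:
                assert size >= params.smallest_nucleus_pixel_count
        # no coinciding centres; canonical row-major ordering
        assert len(set(a.centres)) == a.count
        assert a.centres == sorted(a.centres)

    def test_hough_and_watershed_pixels_partition_mask(self, params):
        # explicit partition check: pixels claimed by circles are erased
        # before watershed, so the two detection routes cannot overlap
        m = disc_mask((200, 200), [(60, 60), (140, 120), (140, 152)], [20, 19, 19])
        dets = hough_round_nuclei(m, m.astype(float), 15, 40)
        rem = remove_round_nuclei(m, dets)
        claimed = m & ~rem
        assert not (claimed & rem).any()
        assert (claimed | rem).sum() == m.sum()
        frags = watershed_split_remaining(rem, params)
        total = len(dets) + len(frags)
        assert total == 3
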