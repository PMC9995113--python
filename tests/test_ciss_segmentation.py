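"""CSF-segmentation unit tests: statistics, seeding, region growing
(with an independent brute-force oracle), and volumetry arithmetic."""

import numpy as np
import pytest

from glymphokit.ciss import (
    IntensityStats,
    RegionGrowParams,
    boundary_contrast,
    compartment_report,
    compute_bounding_box,
    compute_intensity_stats,
    csf_ratio_pct,
    dice,
    region_grow_dilate,
    region_grow_erode,
    remove_solitary_regions,
    rescale_intensities,
    seed_csf,
    segment_csf,
)


class TestIntensityStats:
    def test_direct_substitution(self):
        vol = np.zeros((4, 4, 4))
        vol[0, 0, :2] = [2.0, 4.0]  # mean 3, population SD 1
        mask = vol > 0
        st = compute_intensity_stats(vol, mask)
        assert st.mu_d == 3.0 and st.sigma_d == 1.0
        assert st.f_c == pytest.approx(0.25)
        assert st.snr == pytest.approx(3.0)

    def test_degenerate_and_symmetric_cases(self):
        assert IntensityStats(3.0, 0.0).f_c == 0.0
        assert IntensityStats(3.0, 3.0).f_c == pytest.approx(0.5)
        with pytest.raises(ValueError):
            compute_intensity_stats(np.zeros((3, 3, 3)), np.ones((3, 3, 3), bool))


class TestBoundingBox:
    def test_content_slices_recovered(self):
        vol = np.zeros((32, 32, 32))
        rng = np.random.default_rng(0)
        vol[10:21, 10:21, 10:21] = rng.uniform(1, 2, (11, 11, 11))
        assert compute_bounding_box(vol) == ((10, 20), (10, 20), (10, 20))

    def test_flat_volume_full_extent(self):
        with pytest.warns(UserWarning):
            box = compute_bounding_box(np.ones((8, 8, 8)))
        assert box == ((0, 7), (0, 7), (0, 7))

    def test_phantom_box_contains_all_csf(self, small_noiseless_phantom):
        vol, truth = small_noiseless_phantom
        box = compute_bounding_box(np.where(truth.brain_mask, vol.data, 0.0))
        from glymphokit.ciss import box_to_mask

        inside = box_to_mask(box, vol.data.shape)
        assert np.all(inside[truth.csf_mask])


class TestSolitaryRegions:
    def test_empty_mask_passthrough(self):
        out = remove_solitary_regions(np.zeros((4, 16, 16), bool), 10**7)
        assert not out.any()

    def test_small_round_elongated_blob_removed(self):
        # 2x4 blob: eccentricity ~0.87, roundness >> 0.5, tiny perimeter
        mask = np.zeros((1, 32, 32), bool)
        mask[0, 10:12, 10:14] = True
        out = remove_solitary_regions(mask, 10**7)
        assert not out[0, 10:12, 10:14].any()

    def test_thin_strip_retained_roundness_fails(self):
        # 3x30 strip: eccentricity ~1 but roundness 4*pi*A/P^2 << 0.5
        mask = np.zeros((1, 40, 40), bool)
        mask[0, 5:8, 5:35] = True
        out = remove_solitary_regions(mask, 10**7)
        assert out[0, 6, 20]

    def test_large_perimeter_blob_retained(self):
        mask = np.zeros((1, 64, 64), bool)
        mask[0, 8:56, 8:56] = True  # perimeter ~188 >= 0.005% of 1e6 = 50
        out = remove_solitary_regions(mask, 10**6)
        assert out[0, 30, 30]


class TestRescaleAndSeed:
    def test_rescale_identities(self):
        st = IntensityStats(mu_d=4.0, sigma_d=1.0)
        vol = np.array([[[1.33, 0.0, 2.33]]])
        out = rescale_intensities(vol, st)
        np.testing.assert_allclose(out[0, 0], [0.0, -1.33, 1.0])
        st2 = IntensityStats(mu_d=4.0, sigma_d=2.0)
        assert rescale_intensities(np.array([[[4.66]]]), st2)[0, 0, 0] == pytest.approx(1.0)
        with pytest.raises(ValueError):
            rescale_intensities(vol, IntensityStats(4.0, 0.0))

    def test_seed_keeps_top_45_of_1000(self):
        rng = np.random.default_rng(1)
        vals = rng.permutation(np.linspace(0.5, 10, 1000))
        rescaled = np.zeros((10, 10, 10))
        rescaled.flat[:1000] = vals
        st = IntensityStats(3.0, 1.0)  # SNR 3 -> no f_c boost
        seed, thr = seed_csf(rescaled, st)
        order = np.sort(vals)
        assert seed.sum() == 45  # strictly above the 95.5th percentile
        assert set(rescaled[seed]) == set(order[-45:])

    def test_all_equal_gives_empty_seed(self):
        rescaled = np.full((5, 5, 5), 2.0)
        with pytest.warns(UserWarning):
            seed, _ = seed_csf(rescaled, IntensityStats(3.0, 1.0))
        assert not seed.any()

    def test_snr_boost_shifts_percentile(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0.1, 5, 2000)
        rescaled = np.zeros((20, 10, 10))
        rescaled.flat[:2000] = vals
        st = IntensityStats(5.0, 1.0)  # SNR 5 > 4, f_c = 1/6
        _, thr = seed_csf(rescaled, st)
        assert thr == pytest.approx(np.percentile(vals, 95.5 + 1 / 6))


class TestBoundaryContrast:
    def test_hand_traced_row(self):
        img = np.array([[8, 9, 10, 10, 10]], dtype=float).T  # column layout
        c = boundary_contrast(img, (2, 0), (1, 0), 2)
        assert c == pytest.approx(7.5)

    def test_identity_zero(self):
        img = np.full((7, 7), 5.0)
        assert boundary_contrast(img, (3, 3), (0, 1), 2) == 0.0

    def test_window_leaving_grid_skipped(self):
        img = np.ones((5, 5))
        assert boundary_contrast(img, (0, 2), (1, 0), 2) is None

    def test_arithmetic_example(self):
        # I_b = 10, preceding mean 9.9, following mean 10 -> 0.1/20 = 0.5%
        img = np.array([[9.9, 9.9, 10.0, 10.0, 10.0]])
        c = boundary_contrast(img, (0, 2), (0, 1), 2)
        assert c == pytest.approx(0.5)


# --------------------------------------------------------------------------
# brute-force oracle for the region-growing rules (independent re-statement)
# --------------------------------------------------------------------------

def _oracle_contrast(img, v, d, n):
    h, w = img.shape
    prev, nxt = [], []
    for k in range(1, n + 1):
        pr = (v[0] - k * d[0], v[1] - k * d[1])
        nx = (v[0] + k * d[0], v[1] + k * d[1])
        for (r, c), acc in ((pr, prev), (nx, nxt)):
            if not (0 <= r < h and 0 <= c < w):
                return None
        prev.append(img[pr])
        nxt.append(img[nx])
    denom = img[v] + np.mean(nxt)
    if denom == 0:
        return None
    return abs(img[v] - np.mean(prev)) / denom * 100.0


def _oracle_boundary(mask):
    h, w = mask.shape
    out = []
    for r, c in zip(*np.nonzero(mask)):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                    out.append((r, c))
                    break
            else:
                continue
            break
    return out


def _oracle_dilate(img, mask, thr_boundary, n_range):
    out = mask.copy()
    for b in _oracle_boundary(mask):
        if img[b] < thr_boundary:
            continue
        for u in ((0, 1), (1, 0), (1, 1)):
            for n in range(n_range[0], n_range[1] + 1):
                for s in (-1, 1):
                    v = (b[0] + s * n * u[0], b[1] + s * n * u[1])
                    if not (0 <= v[0] < img.shape[0] and 0 <= v[1] < img.shape[1]):
                        continue
                    if mask[v]:
                        continue
                    c = _oracle_contrast(img, v, (s * u[0], s * u[1]), n)
                    if c is not None and c < 2.0:
                        out[v] = True
    return out


def _oracle_erode(img, mask, thr_int, n_range, strict):
    out = mask.copy()
    for b in _oracle_boundary(mask):
        for u in ((0, 1), (1, 0), (1, 1)):
            for n in range(n_range[0], n_range[1] + 1):
                for s in (-1, 1):
                    v = (b[0] + s * n * u[0], b[1] + s * n * u[1])
                    if not (0 <= v[0] < img.shape[0] and 0 <= v[1] < img.shape[1]):
                        continue
                    if not mask[v]:
                        continue
                    low = img[v] <= thr_int if strict else img[v] < thr_int
                    if not low:
                        continue
                    c = _oracle_contrast(img, v, (s * u[0], s * u[1]), n)
                    if c is None:
                        continue
                    if (strict and c > 2.5) or (not strict and c >= 2.5):
                        out[v] = False
    return out


class TestRegionGrowOracleEquivalence:
    def _toy_slice(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(2.5, 3.5, (32, 32))
        img[10:20, 10:20] = rng.uniform(8.5, 9.5, (10, 10))
        img[12:18, 20:24] = rng.uniform(8.3, 8.6, (6, 4))  # smooth shoulder
        mask = np.zeros((32, 32), bool)
        mask[11:19, 11:19] = True
        return img, mask

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_dilation_matches_brute_force(self, seed):
        img, mask = self._toy_slice(seed)
        stats = IntensityStats(float(img.mean()), float(img.std()))
        thr = stats.mu_d + 2 * stats.sigma_d
        vol = img[None, :, :]
        got = region_grow_dilate(mask[None], vol, stats, "sagittal")
        expected = _oracle_dilate(img, mask, thr, (1, 4))
        np.testing.assert_array_equal(got[0], expected)
        assert np.all(got[0] | ~mask)  # monotone: mask only grows

    @pytest.mark.parametrize("seed,plane,strict", [(0, "sagittal", True), (3, "axial", False)])
    def test_erosion_matches_brute_force(self, seed, plane, strict):
        img, mask = self._toy_slice(seed)
        # dim fringe well below the CSF intensities
        img[18, 11:19] = 3.1
        stats = IntensityStats(float(img.mean()), float(img.std()))
        thr_int = float(np.percentile(img[img > 0], 95.5 - stats.f_c))
        if plane == "sagittal":
            vol, m3 = img[None, :, :], mask[None]
            axis = 0
        else:
            vol, m3 = img[:, :, None], mask[..., None]
            axis = 2
        got = region_grow_erode(m3, vol, stats, plane)
        expected = _oracle_erode(img, mask, thr_int, (1, 2) if strict else (1, 3), strict)
        np.testing.assert_array_equal(np.take(got, 0, axis=axis), expected)
        assert not np.any(got & ~m3)  # monotone: mask only shrinks

    def test_sharp_edge_blocks_dilation(self):
        img = np.full((1, 16, 16), 3.0)
        img[0, 5:11, 5:11] = 9.0
        mask = np.zeros((1, 16, 16), bool)
        mask[0, 5:11, 5:11] = True
        stats = IntensityStats(float(img.mean()), float(img.std()))
        out = region_grow_dilate(mask, img, stats, "sagittal")
        np.testing.assert_array_equal(out, mask)

    def test_pure_bright_mask_survives_erosion(self):
        img = np.full((1, 16, 16), 3.0)
        img[0, 5:11, 5:11] = 9.0
        mask = np.zeros((1, 16, 16), bool)
        mask[0, 5:11, 5:11] = True
        stats = IntensityStats(float(img.mean()), float(img.std()))
        out = region_grow_erode(mask, img, stats, "sagittal")
        np.testing.assert_array_equal(out, mask)


class TestSegmentCSF:
    def test_noiseless_phantom_recovered(self, small_noiseless_phantom):
        vol, truth = small_noiseless_phantom
        seg = segment_csf(vol, truth.brain_mask)
        assert dice(seg.final_mask, truth.csf_mask) >= 0.90
        assert np.all(truth.brain_mask[seg.final_mask])  # final within brain

    def test_no_csf_phantom_low_false_positive_rate(self):
        """Specificity floor: all-parenchyma phantom segments < 1% of brain."""
        from glymphokit.synthetic import _ellipsoid_mask, rician

        rng = np.random.default_rng(11)
        shape = (64, 64, 64)
        brain = _ellipsoid_mask(shape, (31.5, 31.5, 31.5), (25, 24, 23))
        clean = np.where(brain, 3.0, 0.0)
        vol = rician(rng, clean, 3.0 / 3.5)
        seg = segment_csf(vol, brain)
        assert seg.final_mask.sum() < 0.01 * brain.sum()


class TestVolumetry:
    def test_ratio_arithmetic(self):
        assert csf_ratio_pct(0.0, 477.0, 17.7) == 0.0
        assert csf_ratio_pct(1.0, 2.0, 1.0) == pytest.approx(100.0)
        assert csf_ratio_pct(17.7, 477.0, 17.7) == pytest.approx(3.85, abs=0.005)

    def test_ratio_voxel_size_invariance(self, small_noiseless_phantom):
        vol, truth = small_noiseless_phantom
        seg = segment_csf(vol, truth.brain_mask)
        v1, r1 = compartment_report(seg, truth.compartment_labels, (0.1, 0.1, 0.1))
        v2, r2 = compartment_report(seg, truth.compartment_labels, (0.2, 0.2, 0.2))
        for key in r1:
            assert r1[key] == pytest.approx(r2[key], rel=1e-12)
        assert v2["brain"] == pytest.approx(8 * v1["brain"])
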