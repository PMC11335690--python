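"""ePVS pipeline: normalization, EPC, vesselness, segmentation, burden."""

import numpy as np
import pytest

import glymkit as gk
from glymkit.epvs import FrangiParams, SegmentationParams
from glymkit.volume import Volume


# ---------------------------------------------------------------------------
# independent oracles


def bfs_connected_components(supra: np.ndarray, connectivity: int) -> list[set]:
    """Brute-force flood fill, independent of scipy.ndimage.label."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    shape = supra.shape
    seen = np.zeros(shape, dtype=bool)
    comps = []
    for start in zip(*np.nonzero(supra)):
        if seen[start]:
            continue
        comp = set()
        stack = [start]
        seen[start] = True
        while stack:
            p = stack.pop()
            comp.add(p)
            for dx, dy, dz in offsets:
                q = (p[0] + dx, p[1] + dy, p[2] + dz)
                if (
                    0 <= q[0] < shape[0]
                    and 0 <= q[1] < shape[1]
                    and 0 <= q[2] < shape[2]
                    and supra[q]
                    and not seen[q]
                ):
                    seen[q] = True
                    stack.append(q)
        comps.append(comp)
    return comps


def oracle_segment(vmap, region, h, min_size, connectivity=26):
    supra = (vmap >= h) & region
    mask = np.zeros_like(supra)
    for comp in bfs_connected_components(supra, connectivity):
        if len(comp) >= min_size:
            for p in comp:
                mask[p] = True
    return mask


def gaussian_tube(shape=(31, 31, 31), r0=2.0, axis=2, depth=0.8):
    """Dark tube with Gaussian cross-section profile, axis along ``axis``."""
    idx = np.indices(shape, dtype=float)
    c = (np.asarray(shape) - 1) / 2.0
    perp = [i for i in range(3) if i != axis]
    r2 = (idx[perp[0]] - c[perp[0]]) ** 2 + (idx[perp[1]] - c[perp[1]]) ** 2
    return 1.0 - depth * np.exp(-r2 / (2 * r0**2))


def gaussian_blob(shape=(31, 31, 31), r0=2.0, depth=0.8):
    idx = np.indices(shape, dtype=float)
    c = (np.asarray(shape) - 1) / 2.0
    r2 = sum((idx[i] - c[i]) ** 2 for i in range(3))
    return 1.0 - depth * np.exp(-r2 / (2 * r0**2))


def gaussian_plate(shape=(31, 31, 31), r0=2.0, depth=0.8):
    idx = np.indices(shape, dtype=float)
    c = (np.asarray(shape) - 1) / 2.0
    return 1.0 - depth * np.exp(-((idx[0] - c[0]) ** 2) / (2 * r0**2))


# ---------------------------------------------------------------------------


class TestNormalization:
    def test_wm_median_two_halves_values(self, rng):
        data = rng.uniform(1.9, 2.1, size=(10, 10, 10))
        wm = np.zeros((10, 10, 10), dtype=bool)
        wm[2:8, 2:8, 2:8] = True
        data[wm] = 2.0
        v = Volume(data)
        out = gk.normalize_intensity(v, wm)
        assert np.allclose(out.data[wm], 1.0, atol=1e-12)
        assert np.allclose(out.data, data / 2.0)

    def test_constant_one_unchanged(self):
        v = Volume(np.ones((6, 6, 6)))
        out = gk.normalize_intensity(v, np.ones((6, 6, 6), dtype=bool))
        assert np.allclose(out.data, 1.0)

    def test_empty_mask_rejected(self):
        v = Volume(np.ones((4, 4, 4)))
        with pytest.raises(ValueError, match="empty"):
            gk.normalize_intensity(v, np.zeros((4, 4, 4), dtype=bool))


class TestEpc:
    def test_equal_inputs_give_unity(self, rng):
        d = rng.uniform(0.5, 1.5, size=(6, 6, 6))
        v = Volume(d)
        out = gk.compute_epc(v, Volume(d.copy()))
        assert np.allclose(out.data, 1.0, atol=1e-12)

    def test_pvs_voxel_lower_than_wm(self):
        t1 = np.ones((4, 4, 4))
        t2 = np.ones((4, 4, 4))
        t1[1, 1, 1], t2[1, 1, 1] = 0.2, 2.0  # PVS-like voxel
        out = gk.compute_epc(Volume(t1), Volume(t2))
        assert out.data[1, 1, 1] == pytest.approx(0.1)
        assert out.data[1, 1, 1] < out.data[0, 0, 0]

    def test_zero_t2_guarded(self):
        t1 = np.ones((4, 4, 4))
        t2 = np.ones((4, 4, 4))
        t2[0, 0, 0] = 0.0
        out = gk.compute_epc(Volume(t1), Volume(t2))
        assert np.all(np.isfinite(out.data))

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="same grid"):
            gk.compute_epc(Volume(np.ones((4, 4, 4))), Volume(np.ones((5, 5, 5))))


class TestFrangi:
    def test_constant_volume_zero_everywhere(self):
        out = gk.frangi_vesselness(Volume(np.full((16, 16, 16), 3.0)))
        assert np.all(out.data == 0.0)

    def test_output_nonnegative(self, rng):
        out = gk.frangi_vesselness(Volume(rng.normal(size=(16, 16, 16))))
        assert out.data.min() >= 0.0

    def test_tube_beats_blob_beats_plate(self):
        # dark tube / blob / plate of equal peak contrast; fixed c for
        # comparability across images
        p = FrangiParams(scales_mm=(1.0, 2.0, 3.0), c=0.1)
        center = (15, 15, 15)
        v_tube = gk.frangi_vesselness(Volume(gaussian_tube()), p).data[center]
        v_blob = gk.frangi_vesselness(Volume(gaussian_blob()), p).data[center]
        v_plate = gk.frangi_vesselness(Volume(gaussian_plate()), p).data[center]
        assert v_tube > v_blob
        assert v_plate < 0.05 * v_tube

    def test_axis_rotation_equivariance(self):
        # rotating a tube by 90 deg about a grid axis permutes the map
        p = FrangiParams(scales_mm=(1.0, 2.0), c=0.1)
        img = gaussian_tube(axis=2)
        v_z = gk.frangi_vesselness(Volume(img), p).data
        img_x = np.transpose(img, (2, 1, 0))  # tube now along x
        v_x = gk.frangi_vesselness(Volume(img_x), p).data
        assert np.max(np.abs(v_x - np.transpose(v_z, (2, 1, 0)))) < 1e-6

    def test_against_skimage_reference(self):
        # independent implementation cross-check on a dark tube
        from skimage.filters import frangi as sk_frangi

        img = gaussian_tube(shape=(25, 25, 25), r0=2.0)
        p = FrangiParams(scales_mm=(2.0,), c=None)  # type: ignore[arg-type]
        p.c = "auto"
        ours = gk.frangi_vesselness(Volume(img), p).data
        theirs = sk_frangi(
            img, sigmas=[2.0], alpha=0.5, beta=0.5, black_ridges=True
        )
        # same tube support: both rank the interior axis far above background
        axis = ours[12, 12, 6:19]
        bg = ours[2, 2, 6:19]
        assert axis.min() > 10 * bg.max()
        axis_t = theirs[12, 12, 6:19]
        bg_t = theirs[2, 2, 6:19]
        assert axis_t.min() > 10 * bg_t.max()
        # and the two maps agree on ordering (Spearman over the volume)
        from scipy.stats import spearmanr

        fired = ours > 0  # our polarity gate zeroes non-ridge voxels exactly
        rho = spearmanr(ours[fired], theirs[fired]).statistic
        assert rho > 0.9

    def test_anisotropic_spacing_rejected_in_strict_mode(self):
        v = Volume(np.zeros((8, 8, 8)), spacing=(1.0, 1.0, 2.0))
        with pytest.raises(ValueError, match="anisotropic"):
            gk.frangi_vesselness(v)


class TestSegmentation:
    def test_min_cluster_size_boundary(self):
        # an 8-voxel and a 9-voxel supra-threshold cluster; min 9 keeps one
        vmap = np.zeros((20, 20, 20))
        vmap[2:4, 2:4, 2:4] = 1.0  # 8 voxels
        vmap[10:13, 10:13, 10] = 1.0  # 9 voxels
        region = np.ones((20, 20, 20), dtype=bool)
        res = gk.segment_epvs(Volume(vmap), region, SegmentationParams(h=0.5))
        assert res.n_clusters == 1
        assert res.cluster_sizes.tolist() == [9]
        assert res.mask.sum() == 9
        assert res.mask[11, 11, 10]

    def test_no_supra_threshold_voxels(self):
        res = gk.segment_epvs(
            Volume(np.zeros((8, 8, 8))), np.ones((8, 8, 8), dtype=bool),
            SegmentationParams(h=0.5),
        )
        assert res.n_clusters == 0
        assert not res.mask.any()
        assert res.burden_pct == 0.0

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        for _ in range(10):
            vmap = rng.random((32, 32, 32))
            vmap[vmap < 0.97] = 0.0  # sparse supra-threshold set
            region = np.ones((32, 32, 32), dtype=bool)
            p = SegmentationParams(h=0.5, min_cluster_voxels=3, connectivity=connectivity)
            res = gk.segment_epvs(Volume(vmap), region, p)
            oracle = oracle_segment(vmap, region, 0.5, 3, connectivity)
            assert np.array_equal(res.mask, oracle)

    def test_threshold_homogeneity(self, rng):
        vmap = rng.random((24, 24, 24)) ** 4
        region = np.ones((24, 24, 24), dtype=bool)
        a = gk.segment_epvs(Volume(vmap), region, SegmentationParams(h=0.3))
        b = gk.segment_epvs(Volume(10.0 * vmap), region, SegmentationParams(h=3.0))
        assert np.array_equal(a.mask, b.mask)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gk.segment_epvs(
                Volume(np.zeros((4, 4, 4))), np.zeros((4, 4, 4), dtype=bool)
            )


class TestBurden:
    def test_simple_count_ratio(self):
        region = np.zeros((10, 10, 10), dtype=bool)
        region[:10, :10, :10] = True
        mask = np.zeros_like(region)
        mask[0, 0, :5] = True
        assert gk.compute_burden(mask, region) == pytest.approx(0.5)

    def test_full_region_is_100(self):
        region = np.ones((5, 5, 5), dtype=bool)
        assert gk.compute_burden(region, region) == 100.0

    def test_random_masks_match_count_oracle(self, rng):
        for _ in range(50):
            region = rng.random((12, 12, 12)) < 0.6
            if not region.any():
                continue
            mask = (rng.random((12, 12, 12)) < 0.1) & region
            expect = 100.0 * (mask & region).sum() / region.sum()
            assert gk.compute_burden(mask, region) == expect

    def test_additive_over_disjoint_clusters(self, rng):
        region = np.ones((10, 10, 10), dtype=bool)
        a = np.zeros_like(region)
        b = np.zeros_like(region)
        a[1, 1, 1:4] = True
        b[7, 7, 2:8] = True
        assert gk.compute_burden(a | b, region) == pytest.approx(
            gk.compute_burden(a, region) + gk.compute_burden(b, region)
        )

    def test_empty_region_is_error_not_zero(self):
        with pytest.raises(ValueError, match="empty"):
            gk.compute_burden(np.zeros((4, 4, 4), bool), np.zeros((4, 4, 4), bool))


class TestEndToEnd:
    def test_zero_pvs_zero_burden(self):
        spec = gk.StructuralPhantomSpec(
            shape=(32, 32, 32), pvs_count={"WM": 0, "BG": 0}, noise_sigma=(0.0, 0.0), seed=1
        )
        ph = gk.make_structural_phantom(spec)
        results = gk.run_epvs(ph.t1w, ph.t2w, ph.labels)
        assert results["WM"].burden_pct == 0.0
        assert results["BG"].burden_pct == 0.0

    def test_calibrated_threshold_recovers_burden(self, noise_free_phantom):
        from glymkit.io import resample_labels, resample_volume

        ph = noise_free_phantom
        target = (0.7,) * 3
        t1r = resample_volume(ph.t1w, target)
        t2r = resample_volume(ph.t2w, target)
        labr = resample_labels(ph.labels, target)
        wm = labr.region_mask("WM")
        epc = gk.compute_epc(
            gk.normalize_intensity(t1r, wm), gk.normalize_intensity(t2r, wm)
        )
        vness = gk.region_vesselness(epc, wm)
        h = gk.calibrate_threshold(vness, wm, ph.true_burden["WM"])
        res = gk.segment_epvs(vness, wm, SegmentationParams(h=h))
        rel = abs(res.burden_pct - ph.true_burden["WM"]) / ph.true_burden["WM"]
        assert rel < 0.30
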