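"""Per-channel fiber morphometry: denoise, binarize, skeleton, features."""

import math

import numpy as np
import pytest
from scipy import ndimage

from ecmorph.deconvolution import deconvolve, rgb_to_absorbance
from ecmorph.morphometry import (
    FEATURE_NAMES,
    BinaryFiberMask,
    MorphometryConfig,
    binarize,
    channel_features,
    extract_features,
    morphological_fiber_select,
    simple_fiber_metrics,
    skeletonize_network,
    wiener_denoise,
)
from ecmorph.synthetic import FiberSpec, render_image, simulate_image


def brute_force_wiener(image, window):
    """Independent sliding-window recomputation of the adaptive filter."""
    h, w = image.shape
    r = window // 2
    padded = np.pad(image, r, mode="symmetric")  # edge-inclusive reflection
    mean = np.empty_like(image, dtype=float)
    var = np.empty_like(image, dtype=float)
    for i in range(h):
        for j in range(w):
            block = padded[i : i + window, j : j + window]
            mean[i, j] = block.mean()
            var[i, j] = block.var()
    noise = var.mean()
    out = np.empty_like(mean)
    for i in range(h):
        for j in range(w):
            if var[i, j] > 0:
                g = max(var[i, j] - noise, 0.0) / var[i, j]
            else:
                g = 0.0
            out[i, j] = mean[i, j] + g * (image[i, j] - mean[i, j])
    return out


class TestWiener:
    def test_constant_image_unchanged(self):
        img = np.full((16, 16), 0.7)
        assert np.allclose(wiener_denoise(img, 3), img)

    def test_matches_brute_force_oracle(self, rng):
        img = rng.uniform(0, 1, size=(20, 20))
        assert np.allclose(wiener_denoise(img, 3), brute_force_wiener(img, 3), atol=1e-9)

    def test_matches_brute_force_window5(self, rng):
        img = rng.uniform(0, 1, size=(15, 17))
        assert np.allclose(wiener_denoise(img, 5), brute_force_wiener(img, 5), atol=1e-9)

    def test_step_edge_mostly_retained(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 1.0
        out = wiener_denoise(img, 3)
        contrast = out[:, 20].mean() - out[:, 12].mean()
        assert contrast > 0.8

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            wiener_denoise(np.zeros((8, 8)), 4)
        with pytest.raises(ValueError):
            wiener_denoise(np.zeros((8, 8)), 9)


class TestBinarize:
    def test_all_zero_channel_gives_empty_mask(self):
        mask = binarize(np.zeros((8, 8)))
        assert not mask.mask.any()

    def test_two_level_image_thresholds_at_half_max(self):
        img = np.full((10, 10), 0.2)
        img[3:6, 3:6] = 0.8
        mask = binarize(img, threshold=0.5)
        assert np.array_equal(mask.mask, img == 0.8)

    def test_matches_elementwise_comparison(self, rng):
        img = rng.uniform(0, 2, size=(12, 12))
        mask = binarize(img, threshold=0.4)
        assert np.array_equal(mask.mask, img / img.max() > 0.4)

    def test_threshold_range_enforced(self):
        with pytest.raises(ValueError):
            binarize(np.ones((4, 4)), threshold=1.5)


class TestFiberSelect:
    def test_isolated_pixel_removed(self):
        m = np.zeros((20, 20), bool)
        m[10, 10] = True
        out = morphological_fiber_select(BinaryFiberMask(m, 1.0), 5, 1)
        assert not out.mask.any()

    def test_straight_fiber_retained(self):
        m = np.zeros((20, 70), bool)
        m[9:12, 10:60] = True
        out = morphological_fiber_select(BinaryFiberMask(m, 1.0), 5, 1)
        assert out.mask[m].sum() >= 0.9 * m.sum()

    def test_empty_mask_stays_empty(self):
        out = morphological_fiber_select(BinaryFiberMask(np.zeros((8, 8), bool), 1.0), 5, 1)
        assert not out.mask.any()


class TestSkeleton:
    def test_rectangle_single_segment(self):
        m = np.zeros((40, 120), bool)
        m[18:23, 10:110] = True  # 100x5 px at 0.5 um/px
        g = skeletonize_network(BinaryFiberMask(m, 0.5))
        assert len(g.segments) == 1
        assert g.n_branchpoints == 0
        assert g.segments[0].geodesic_um == pytest.approx(50.0, rel=0.10)
        assert g.segments[0].orientation == pytest.approx(0.0, abs=0.05)

    def test_plus_sign_one_junction_four_segments(self):
        m = np.zeros((60, 60), bool)
        m[29:32, 10:50] = True
        m[10:50, 29:32] = True
        g = skeletonize_network(BinaryFiberMask(m, 0.5))
        junctions = [n for n in g.nodes if n["kind"] == "junction"]
        assert len(junctions) == 1
        assert junctions[0]["degree"] == 4
        assert len(g.segments) == 4

    def test_empty_mask_empty_graph(self):
        g = skeletonize_network(BinaryFiberMask(np.zeros((10, 10), bool), 0.5))
        assert g.nodes == [] and g.segments == []

    def test_geodesic_at_least_chord(self, rng):
        img, _ = simulate_image("control", seed=17, shape=(192, 192))
        od = rgb_to_absorbance(img.rgb)
        mask = binarize(deconvolve(od).mature, pixel_size_um=0.5)
        g = skeletonize_network(mask)
        assert g.segments
        for s in g.segments:
            assert s.geodesic_um >= s.chord_um - 1e-9
            assert 0.0 <= s.orientation < math.pi

    def test_skeleton_subset_of_mask(self):
        img, _ = simulate_image("degradation", seed=4, shape=(160, 160))
        od = rgb_to_absorbance(img.rgb)
        mask = binarize(deconvolve(od).mature, pixel_size_um=0.5)
        g = skeletonize_network(mask)
        assert not (g.skeleton & ~mask.mask).any()


class TestChannelFeatures:
    def test_single_straight_fiber(self, single_fiber_image):
        img, _ = single_fiber_image
        od = rgb_to_absorbance(img.rgb, i0=1.0)
        ch = deconvolve(od).mature
        mask = binarize(wiener_denoise(ch, 3).clip(min=0), pixel_size_um=0.5)
        mask = morphological_fiber_select(mask, 5, 1)
        g = skeletonize_network(mask)
        feats = channel_features(g, mask, ch)
        assert feats["NumberOfFibers"] == 1
        assert feats["Branchpoints"] == 0
        assert feats["EulerNumber"] == 1
        assert feats["Persistence"] >= 0.95

    def test_identical_orientations_zero_randomness(self):
        # two parallel horizontal strokes -> zero circular variance
        m = np.zeros((40, 60), bool)
        m[10:13, 5:55] = True
        m[30:33, 5:55] = True
        g = skeletonize_network(BinaryFiberMask(m, 1.0))
        feats = channel_features(g, BinaryFiberMask(m, 1.0), m.astype(float))
        assert feats["AngleRandomness"] == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_equal_lengths_full_randomness(self):
        # doubled angles 0 and pi cancel exactly for equal weights
        from ecmorph.morphometry import SkeletonGraph, SkeletonSegment

        m = np.zeros((10, 10), bool)
        m[2, 2] = m[7, 7] = True
        segs = [
            SkeletonSegment(
                path=np.array([[2, 2]]), geodesic_um=10.0, chord_um=10.0,
                half_width_um=1.0, orientation=0.0, endpoints=(-1, -1),
            ),
            SkeletonSegment(
                path=np.array([[7, 7]]), geodesic_um=10.0, chord_um=10.0,
                half_width_um=1.0, orientation=math.pi / 2, endpoints=(-1, -1),
            ),
        ]
        g = SkeletonGraph(nodes=[], segments=segs, skeleton=m, pixel_size_um=1.0)
        feats = channel_features(g, BinaryFiberMask(m, 1.0), m.astype(float))
        assert feats["AngleRandomness"] == pytest.approx(1.0, abs=1e-12)

    def test_empty_mask_all_zero(self):
        m = BinaryFiberMask(np.zeros((8, 8), bool), 0.5)
        g = skeletonize_network(m)
        feats = channel_features(g, m, np.zeros((8, 8)))
        assert all(v == 0.0 for v in feats.values())

    def test_extra_isolated_fiber_increments_counts(self):
        f1 = FiberSpec((40.0, 40.0), 0.2, 30.0, 3.0)
        f2 = FiberSpec((120.0, 120.0), 1.2, 30.0, 3.0)
        feats = {}
        for key, fibers in {"one": [f1], "two": [f1, f2]}.items():
            img, _ = render_image(fibers, pixel_size_um=0.5, shape=(320, 320), noise_sigma=0.0)
            od = rgb_to_absorbance(img.rgb, i0=1.0)
            ch = deconvolve(od).mature
            mask = binarize(ch, pixel_size_um=0.5)
            g = skeletonize_network(mask)
            feats[key] = channel_features(g, mask, ch)
        assert feats["two"]["NumberOfFibers"] == feats["one"]["NumberOfFibers"] + 1
        assert feats["two"]["EulerNumber"] == feats["one"]["EulerNumber"] + 1


class TestExtractFeatures:
    def test_vector_has_26_canonical_entries(self):
        img, _ = simulate_image("control", seed=2, shape=(160, 160))
        fv = extract_features(img)
        assert len(fv) == 26
        assert list(fv.index) == list(FEATURE_NAMES)

    def test_blank_image_all_zero(self):
        fv = extract_features(np.ones((64, 64, 3)), pixel_size_um=0.5)
        assert (fv == 0.0).all()

    def test_deterministic_for_fixed_image(self):
        img, _ = simulate_image("degradation", seed=8, shape=(160, 160))
        a = extract_features(img)
        b = extract_features(img)
        assert (a == b).all()

    def test_bounded_features_in_unit_interval(self):
        img, _ = simulate_image("control", seed=6, shape=(192, 192))
        fv = extract_features(img)
        for name in ("Persistence", "AngleRandomness", "Extent", "Solidity", "Eccentricity"):
            for ch in ("mature", "immature"):
                assert 0.0 <= fv[f"{name}_{ch}"] <= 1.0

    def test_deposition_has_longer_mature_fibers(self):
        # the fibrotic state lays down longer fibers than homeostatic dermis
        means = {}
        for preset in ("control", "deposition"):
            vals = [
                extract_features(simulate_image(preset, seed=300 + s, shape=(256, 256))[0])[
                    "FiberLength_mature"
                ]
                for s in range(8)
            ]
            means[preset] = np.mean(vals)
        assert means["deposition"] > means["control"]


class TestSimpleMetrics:
    def test_blank_image_full_porosity(self):
        m = simple_fiber_metrics(np.ones((64, 64, 3)), pixel_size_um=0.5)
        assert m["porosity_pct"] == 100.0
        assert m["fiber_length_um"] == 0.0

    def test_porosity_complements_mask_area(self):
        m = np.zeros((20, 20), bool)
        m[:10, :10] = True  # exactly 25 % coverage
        porosity = 100.0 * (1.0 - BinaryFiberMask(m, 1.0).area_fraction)
        assert porosity == 75.0

    def test_degradation_shorter_and_more_porous_than_control(self):
        res = {}
        for preset in ("control", "degradation"):
            lengths, poros = [], []
            for s in range(8):
                img, _ = simulate_image(preset, seed=700 + s, shape=(256, 256))
                m = simple_fiber_metrics(img)
                lengths.append(m["fiber_length_um"])
                poros.append(m["porosity_pct"])
            res[preset] = (np.mean(lengths), np.mean(poros))
        assert res["degradation"][0] < res["control"][0]
        assert res["degradation"][1] > res["control"][1]
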