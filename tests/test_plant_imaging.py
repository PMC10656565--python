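"""Vegetation indices, correlated-index pruning, the noise-filter cascade and
plant centering/cropping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uavpheno.plant_imaging import (
    VI_ORDER,
    VI_REGISTRY,
    MaskLayer,
    center_and_crop,
    compute_vi_image,
    contour_filter,
    equalize_rgb,
    hull_center,
    noise_filter_cascade,
    prune_correlated_vis,
    soil_mask_kmeans,
)
from uavpheno.raster_processing import PlantImageStack


def _img(v):
    return np.full((2, 2), float(v))


class TestVegetationIndices:
    def test_registry_is_complete_and_ordered(self):
        assert set(VI_ORDER) == set(VI_REGISTRY)
        assert len(VI_ORDER) == 11

    @pytest.mark.parametrize(
        "name, layers, expected",
        [
            ("NDVI", {"NIR": 0.8, "red": 0.2}, pytest.approx(0.6)),
            ("SAVI", {"NIR": 0.8, "red": 0.2}, pytest.approx(0.6)),
            ("RECI", {"NIR": 0.6, "red_edge": 0.3}, pytest.approx(1.0)),
            ("GRVI-MS", {"green": 0.3, "red": 0.3}, pytest.approx(0.0)),
            ("GRVI-RGB", {"G": 0.4, "R": 0.2}, pytest.approx(1 / 3)),
            ("MGRVI-MS", {"green": 0.4, "red": 0.2}, pytest.approx(0.6)),
            ("RGBVI-MS", {"green": 0.4, "blue": 0.2, "red": 0.2},
             pytest.approx(0.12 / 0.20)),
            ("GNDVI", {"NIR": 0.8, "green": 0.2}, pytest.approx(0.6)),
            ("NDRE", {"NIR": 0.75, "red_edge": 0.25}, pytest.approx(0.5)),
        ],
    )
    def test_hand_evaluated_formulas(self, name, layers, expected):
        out = compute_vi_image({k: _img(v) for k, v in layers.items()}, name)
        assert out[0, 0] == expected

    def test_zero_denominator_becomes_missing(self):
        out = compute_vi_image({"NIR": _img(0.0), "red": _img(0.0)}, "NDVI")
        assert np.isnan(out).all()

    def test_unknown_index_rejected(self):
        with pytest.raises(KeyError):
            compute_vi_image({"NIR": _img(1)}, "EVI")

    @given(
        nir=st.floats(0, 1), red=st.floats(0, 1), green=st.floats(0, 1),
        blue=st.floats(0, 1), red_edge=st.floats(0, 1),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_normalized_difference_indices_bounded(
        self, nir, red, green, blue, red_edge
    ):
        layers = {
            "NIR": _img(nir), "red": _img(red), "green": _img(green),
            "blue": _img(blue), "red_edge": _img(red_edge),
            "R": _img(red), "G": _img(green), "B": _img(blue),
        }
        for name in ("NDVI", "GNDVI", "NDRE", "GRVI-MS", "MGRVI-MS",
                     "RGBVI-MS", "GRVI-RGB", "MGRVI-RGB", "RGBVI-RGB"):
            out = compute_vi_image(layers, name)
            finite = out[np.isfinite(out)]
            assert (np.abs(finite) <= 1 + 1e-12).all()


class TestPruneCorrelated:
    def test_uncorrelated_all_retained(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(50, 3)), columns=["NDVI", "SAVI", "RECI"])
        df["SAVI"] = rng.normal(size=50)  # independent draws
        assert prune_correlated_vis(df) == ["NDVI", "RECI", "SAVI"]

    def test_duplicate_column_dropped(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        df = pd.DataFrame({"NDVI": x, "SAVI": x.copy(), "RECI": rng.normal(size=40)})
        assert prune_correlated_vis(df) == ["NDVI", "RECI"]

    def test_three_identical_keep_first_in_order(self):
        x = np.arange(30.0)
        df = pd.DataFrame({"GNDVI": x, "NDVI": x.copy(), "SAVI": x.copy()})
        assert prune_correlated_vis(df) == ["GNDVI"]

    def test_constant_column_retained(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"NDVI": rng.normal(size=20), "RECI": np.ones(20)})
        assert prune_correlated_vis(df) == ["NDVI", "RECI"]


def _two_population_field(rng, shape=(40, 40), n_vi=7):
    """Vegetation blob (high NDVI) on soil (low NDVI), Gaussian VI noise."""
    labels = np.zeros(shape, dtype=bool)
    labels[10:30, 10:30] = True
    vis = {}
    for i in range(n_vi):
        base = np.where(labels, 0.7, 0.05)
        vis[f"vi{i}"] = base + rng.normal(0, 0.04, size=shape)
    ndvi = np.where(labels, 0.8, -0.05) + rng.normal(0, 0.04, size=shape)
    return labels, vis, ndvi


class TestSoilMask:
    def test_two_population_agreement(self):
        rng = np.random.default_rng(0)
        labels, vis, ndvi = _two_population_field(rng)
        mask = soil_mask_kmeans(vis, ndvi, seed=0)
        assert (mask.values == labels).mean() >= 0.99

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        _, vis, ndvi = _two_population_field(rng)
        m1 = soil_mask_kmeans(vis, ndvi, seed=3)
        m2 = soil_mask_kmeans(vis, ndvi, seed=3)
        np.testing.assert_array_equal(m1.values, m2.values)

    def test_labeling_by_ndvi_not_cluster_index(self):
        rng = np.random.default_rng(2)
        labels, vis, ndvi = _two_population_field(rng)
        masks = [soil_mask_kmeans(vis, ndvi, seed=s).values for s in range(5)]
        for m in masks[1:]:
            assert (m == masks[0]).mean() > 0.99

    def test_identical_pixels_rejected(self):
        with pytest.raises(ValueError):
            soil_mask_kmeans({"a": np.ones((4, 4))}, np.ones((4, 4)), seed=0)


class TestContourFilter:
    def test_single_component_unchanged(self):
        m = np.zeros((20, 20), dtype=bool)
        m[5:15, 5:15] = True
        out = contour_filter(MaskLayer(m))
        np.testing.assert_array_equal(out.values, m)

    def test_small_component_removed(self):
        m = np.zeros((60, 60), dtype=bool)
        m[5:45, 5:30] = True  # 1000 px
        m[55:56, 50:55] = True  # 5 px, 0.005 < 0.05
        out = contour_filter(MaskLayer(m))
        assert out.values[10, 10]
        assert not out.values[55, 52]

    def test_empty_mask_passes_through(self):
        out = contour_filter(MaskLayer(np.zeros((5, 5), dtype=bool)))
        assert not out.values.any()

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = rng.random((50, 50)) > 0.7
        once = contour_filter(MaskLayer(m))
        twice = contour_filter(once)
        np.testing.assert_array_equal(once.values, twice.values)


class TestEqualizeRGB:
    def test_constant_layer_stays_constant(self):
        rgb = np.stack([np.full((8, 8), 0.4)] * 3)
        out = equalize_rgb(rgb)
        for ch in out:
            assert len(np.unique(ch)) == 1

    def test_two_level_cdf_mapping(self):
        layer = np.zeros((20, 20))
        layer.ravel()[:100] = 255.0  # 25% at level 255, 75% at 0
        out = equalize_rgb(np.stack([layer] * 3))
        assert set(np.unique(out[0])) == {191.0, 255.0}

    def test_gradient_histogram_near_uniform(self):
        layer = np.linspace(0, 1, 64 * 64).reshape(64, 64)
        out = equalize_rgb(np.stack([layer] * 3))[0]
        hist, _ = np.histogram(out, bins=16, range=(0, 255))
        assert hist.max() - hist.min() <= 0.05 * out.size


def _blob_stack(shift=(0, 0), size=41, tps=(12, 40), noise_sd=0.01):
    """Two-TP stack with one square vegetation blob and realistic bands."""
    veg = {"R": 0.1, "G": 0.35, "B": 0.08, "blue": 0.05, "green": 0.12,
           "red": 0.1, "red_edge": 0.35, "NIR": 0.8}
    soil = {"R": 0.35, "G": 0.3, "B": 0.22, "blue": 0.18, "green": 0.22,
            "red": 0.3, "red_edge": 0.27, "NIR": 0.25}
    names = list(veg) + ["height"]
    mask = np.zeros((size, size), dtype=bool)
    c = size // 2
    mask[
        c - 8 + shift[0] : c + 9 + shift[0], c - 8 + shift[1] : c + 9 + shift[1]
    ] = True
    rng = np.random.default_rng(0)
    values = np.empty((len(tps), len(names), size, size))
    for ti in range(len(tps)):
        for li, n in enumerate(names):
            if n == "height":
                values[ti, li] = np.where(mask, 0.2, 0.0)
            else:
                base = np.where(mask, veg[n], soil[n])
                values[ti, li] = base + rng.normal(0, noise_sd, size=(size, size))
    return PlantImageStack(values=values, tp_dat=list(tps), layer_names=names,
                           pixel_area_cm2=1.0), mask


class TestCascade:
    def test_cascade_recovers_blob(self):
        stack, truth = _blob_stack()
        masks = noise_filter_cascade(stack, ["NDVI", "GNDVI", "SAVI"], seed=0)
        for m in masks:
            assert (m.values == truth).mean() >= 0.99

    def test_cascade_idempotent(self):
        stack, _ = _blob_stack()
        masks1 = noise_filter_cascade(stack, ["NDVI", "GNDVI", "SAVI"], seed=0)
        stack.mask = np.stack([m.values for m in masks1])
        masks2 = noise_filter_cascade(stack, ["NDVI", "GNDVI", "SAVI"], seed=0)
        for m1, m2 in zip(masks1, masks2):
            np.testing.assert_array_equal(m1.values, m2.values)


class TestCenterAndCrop:
    def test_square_hull_center_is_vertex_mean(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[0, 0] = mask[0, 2] = mask[2, 0] = mask[2, 2] = True
        assert hull_center(mask) == (1.0, 1.0)

    def test_centered_blob_zero_shift(self):
        stack, mask = _blob_stack()
        out = center_and_crop(stack, MaskLayer(mask), crop_fraction=1.0)
        np.testing.assert_array_equal(out.values, stack.values)

    def test_crop_arithmetic(self):
        values = np.arange(100 * 100, dtype=float).reshape(1, 1, 100, 100)
        mask = np.zeros((100, 100), dtype=bool)
        mask[48:52, 48:52] = True
        stack = PlantImageStack(values=values, tp_dat=[12], layer_names=["R"],
                                mask=mask[None], pixel_area_cm2=1.0)
        out = center_and_crop(stack, crop_fraction=0.70)
        assert out.values.shape == (1, 1, 70, 70)
        np.testing.assert_array_equal(
            out.values[0, 0], values[0, 0, 15:85, 15:85]
        )

    def test_translation_equivariance(self):
        base, _ = _blob_stack(shift=(0, 0), noise_sd=0.0)
        moved, moved_mask = _blob_stack(shift=(4, -3), noise_sd=0.0)
        out_base = center_and_crop(base, crop_fraction=0.5)
        out_moved = center_and_crop(moved, MaskLayer(moved_mask), crop_fraction=0.5)
        # blob pixels land identically after recentering
        h = out_base.values.shape[2]
        c = h // 2
        sl = np.s_[:, :, c - 8 : c + 9, c - 8 : c + 9]
        np.testing.assert_allclose(out_base.values[sl], out_moved.values[sl])

    def test_empty_mask_rejected(self):
        stack, _ = _blob_stack()
        with pytest.raises(ValueError):
            center_and_crop(stack, MaskLayer(np.zeros((41, 41), dtype=bool)))
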