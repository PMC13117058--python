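import math

import numpy as np
import pytest

from paintseg.features import (
    FeatureCatalog,
    areashape_features,
    cooccurrence_matrix,
    correlation_features,
    extract_all,
    granularity_spectrum,
    haralick_texture,
    intensity_features,
    location_features,
    neighbor_features,
    quantize_intensities,
    radial_distribution,
    zernike_magnitudes,
    zernike_indices,
    _haralick_statistics,
)
from conftest import disk_mask


class TestCatalog:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {},
            {"channels": ("DNA", "RNA")},
            {"zernike_degree": 5, "granularity_scales": 4},
            {"radial_bins": 6, "texture_offsets": (1, 3)},
            {"groups": ("AreaShape", "Intensity", "Neighbors")},
        ],
    )
    def test_closed_form_count_matches_enumeration(self, kwargs):
        cat = FeatureCatalog(**kwargs)
        cols = cat.columns()
        assert len(cols) == cat.expected_column_count()
        assert len(set(cols)) == len(cols)

    def test_degree_9_has_30_zernike_indices(self):
        assert len(zernike_indices(9)) == 30

    def test_group_prefix_recoverable(self):
        cat = FeatureCatalog()
        groups = {FeatureCatalog.group_of(c) for c in cat.columns()}
        assert groups == set(cat.groups)

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            FeatureCatalog(groups=("AreaShape", "Bogus"))


class TestAreaShape:
    def test_square_metrics(self):
        sq = np.zeros((14, 14), dtype=bool)
        sq[2:12, 2:12] = True
        f = areashape_features(sq)
        assert f["Area"] == 100
        assert f["Extent"] == 1.0
        assert f["EulerNumber"] == 1
        assert f["Perimeter"] == 36.0
        assert f["BoundingBoxArea"] == 100
        assert f["MinFeretDiameter"] == pytest.approx(10.0)

    def test_digital_disk_form_factor_near_one(self):
        f = areashape_features(disk_mask(20))
        assert 0.9 <= f["FormFactor"] <= 1.05
        assert f["Compactness"] == pytest.approx(1.0, abs=0.05)

    def test_disk_eccentricity_low(self):
        assert areashape_features(disk_mask(15))["Eccentricity"] < 0.2

    def test_radii_from_distance_transform(self):
        sq = np.zeros((9, 9), dtype=bool)
        sq[2:7, 2:7] = True  # 5x5 square: max radius at center
        f = areashape_features(sq)
        assert f["MaximumRadius"] == pytest.approx(3.0)
        assert f["MeanRadius"] > 1.0

    def test_empty_object_rejected(self):
        with pytest.raises(ValueError):
            areashape_features(np.zeros((4, 4), dtype=bool))


def _zernike_integration_oracle(mask, degree, samples=6):
    """Independent numerical integration of the Zernike basis over the
    rasterized object, supersampling each pixel."""
    rows, cols = np.nonzero(mask)
    cy, cx = rows.mean(), cols.mean()
    radius = max(float(np.hypot(rows - cy, cols - cx).max()), 1.0)
    offs = (np.arange(samples) + 0.5) / samples - 0.5
    oy, ox = np.meshgrid(offs, offs, indexing="ij")
    out = {}
    sub_y = (rows[:, None, None] + oy[None]) - cy
    sub_x = (cols[:, None, None] + ox[None]) - cx
    rho = np.hypot(sub_y, sub_x) / radius
    theta = np.arctan2(sub_y, sub_x)
    d_area = 1.0 / (radius**2 * samples**2)
    for n, m in zernike_indices(degree):
        rad = np.zeros_like(rho)
        for s in range((n - m) // 2 + 1):
            c = (
                (-1) ** s
                * math.factorial(n - s)
                / (
                    math.factorial(s)
                    * math.factorial((n + m) // 2 - s)
                    * math.factorial((n - m) // 2 - s)
                )
            )
            rad += c * rho ** (n - 2 * s)
        basis = rad * np.exp(-1j * m * theta)
        out[(n, m)] = abs((n + 1) / math.pi * basis.sum() * d_area)
    return out


class TestZernike:
    def test_solid_disk_matches_integration_oracle(self):
        mask = disk_mask(30)
        impl = zernike_magnitudes(mask, 9)
        oracle = _zernike_integration_oracle(mask, 9)
        assert impl["Zernike_0_0"] == pytest.approx(oracle[(0, 0)], abs=1e-3)
        # higher orders vanish for a disk up to rim digitization residue
        for n, m in zernike_indices(9):
            if n >= 1:
                assert impl[f"Zernike_{n}_{m}"] < 0.05

    def test_centered_rectangle_kills_odd_m(self):
        mask = np.zeros((21, 31), dtype=bool)
        mask[5:16, 5:26] = True
        z = zernike_magnitudes(mask, 9)
        for n, m in zernike_indices(9):
            if m % 2 == 1:
                assert z[f"Zernike_{n}_{m}"] < 1e-2

    def test_rotation_invariance_90_degrees(self):
        rng = np.random.default_rng(3)
        mask = np.zeros((40, 40), dtype=bool)
        yy, xx = np.mgrid[:40, :40]
        mask[((yy - 20) / 12.0) ** 2 + ((xx - 20) / 7.0) ** 2 <= 1] = True
        z1 = zernike_magnitudes(mask, 9)
        z2 = zernike_magnitudes(np.rot90(mask), 9)
        for key in z1:
            assert z1[key] == pytest.approx(z2[key], abs=1e-6)


class TestIntensity:
    def test_constant_object(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:7, 2:7] = True
        f = intensity_features(np.full((10, 10), 8.0), mask)
        assert f["IntegratedIntensity"] == 8.0 * 25
        assert f["MeanIntensity"] == 8.0
        assert f["StdIntensity"] == 0.0
        assert f["MassDisplacement"] == 0.0

    def test_two_pixel_arithmetic(self):
        f = intensity_features(np.array([[10.0, 20.0]]), np.ones((1, 2), dtype=bool))
        assert (f["MeanIntensity"], f["MinIntensity"], f["MaxIntensity"]) == (15, 10, 20)
        assert f["IntegratedIntensity"] == 30

    def test_integrated_equals_mean_times_area(self, small_scene):
        ch = small_scene.stack.channel("DNA").astype(float)
        for lab in range(1, small_scene.cells.max() + 1):
            obj = small_scene.cells == lab
            f = intensity_features(ch, obj)
            assert f["IntegratedIntensity"] == pytest.approx(f["MeanIntensity"] * obj.sum())

    def test_edge_statistics_over_boundary_pixels(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[1:6, 1:6] = True
        img = np.zeros((7, 7))
        img[3, 3] = 100.0  # interior-only intensity
        f = intensity_features(img, mask)
        assert f["IntegratedIntensityEdge"] == 0.0
        assert f["MaxIntensity"] == 100.0


class TestLocation:
    def test_square_centroid(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[0:10, 0:10] = True
        f = location_features({"DNA": np.ones((12, 12))}, mask)
        assert (f["Center_X"], f["Center_Y"]) == (4.5, 4.5)

    def test_uniform_intensity_center_of_mass_equals_centroid(self):
        mask = disk_mask(8)
        f = location_features({"DNA": np.full(mask.shape, 3.0)}, mask)
        assert f["CenterMassIntensity_X_DNA"] == pytest.approx(f["Center_X"])
        assert f["CenterMassIntensity_Y_DNA"] == pytest.approx(f["Center_Y"])

    def test_single_bright_pixel_max_location(self):
        mask = np.ones((10, 10), dtype=bool)
        img = np.zeros((10, 10))
        img[2, 7] = 5.0
        f = location_features({"DNA": img}, mask)
        assert (f["MaxIntensity_X_DNA"], f["MaxIntensity_Y_DNA"]) == (7.0, 2.0)


class TestCorrelation:
    def test_identical_channels(self):
        a = np.arange(16, dtype=float).reshape(4, 4)
        f = correlation_features(a, a, np.ones((4, 4), dtype=bool))
        assert f["Correlation"] == pytest.approx(1.0)
        assert f["Slope"] == pytest.approx(1.0)
        assert f["Overlap"] == pytest.approx(1.0)

    def test_anticorrelated(self):
        a = np.arange(16, dtype=float).reshape(4, 4)
        f = correlation_features(a, -a + 20, np.ones((4, 4), dtype=bool))
        assert f["Correlation"] == pytest.approx(-1.0)

    def test_closed_form_regression(self):
        a = np.array([[1.0, 2.0, 3.0, 4.0]])
        b = 2 * a
        f = correlation_features(a, b, np.ones((1, 4), dtype=bool))
        assert f["Slope"] == pytest.approx(2.0)
        assert f["Correlation"] == pytest.approx(1.0)

    def test_zero_variance_defined_as_zero(self):
        a = np.full((2, 2), 5.0)
        f = correlation_features(a, np.arange(4.0).reshape(2, 2), np.ones((2, 2), dtype=bool))
        assert f["Correlation"] == 0.0
        assert f["Slope"] == 0.0


class TestGranularity:
    def test_constant_image_all_zero_spectrum(self):
        mask = disk_mask(10)
        assert granularity_spectrum(np.full(mask.shape, 9.0), mask, 6).sum() == 0.0

    def test_zero_channel_all_zero_spectrum(self):
        mask = disk_mask(10)
        assert granularity_spectrum(np.zeros(mask.shape), mask, 6).sum() == 0.0

    def test_bright_disk_mass_concentrates_by_its_radius(self):
        img = np.zeros((40, 40))
        mask = np.zeros((40, 40), dtype=bool)
        yy, xx = np.mgrid[:40, :40]
        mask[(yy - 20) ** 2 + (xx - 20) ** 2 <= 15**2] = True
        img[(yy - 20) ** 2 + (xx - 20) ** 2 <= 3**2] = 1000.0
        g = granularity_spectrum(img, mask, 8)
        assert g.sum() > 0
        assert g[:4].sum() / g.sum() >= 0.9

    def test_spectrum_nonnegative(self, small_scene):
        obj = small_scene.cells == 1
        g = granularity_spectrum(small_scene.stack.channel("ER").astype(float), obj, 8)
        assert (g >= 0).all()


class TestRadialDistribution:
    def test_fracatd_sums_to_one(self, small_scene):
        ch = small_scene.stack.channel("RNA").astype(float)
        obj = small_scene.cells == 2
        f = radial_distribution(ch, obj, 4)
        total = sum(f[f"FracAtD_{i}of4"] for i in range(1, 5))
        assert total == pytest.approx(1.0)

    def test_uniform_disk_ring_fractions(self):
        mask = disk_mask(20)
        f = radial_distribution(np.ones(mask.shape), mask, 4)
        for i, expected in enumerate((1 / 16, 3 / 16, 5 / 16, 7 / 16), start=1):
            assert f[f"FracAtD_{i}of4"] == pytest.approx(expected, abs=0.02)
            assert f[f"MeanFrac_{i}of4"] == pytest.approx(1.0, abs=0.12)

    def test_rotationally_uniform_intensity_zero_cv(self):
        mask = disk_mask(15)
        f = radial_distribution(np.full(mask.shape, 4.0), mask, 4)
        for i in range(1, 5):
            assert f[f"RadialCV_{i}of4"] == pytest.approx(0.0, abs=1e-12)


class TestNeighbors:
    def test_single_object_no_neighbors(self):
        mask = np.zeros((20, 20), dtype=np.int32)
        mask[5:10, 5:10] = 1
        f = neighbor_features(mask)[1]
        assert f["NumberOfNeighbors"] == 0
        assert f["PercentTouching"] == 0

    def test_two_touching_squares(self):
        mask = np.zeros((12, 22), dtype=np.int32)
        mask[3:9, 3:9] = 1
        mask[3:9, 9:15] = 2
        f = neighbor_features(mask, distance=2)
        assert f[1]["NumberOfNeighbors"] == 1
        assert f[1]["PercentTouching"] > 0

    def test_three_collinear_equidistant_objects(self):
        mask = np.zeros((20, 70), dtype=np.int32)
        mask[8:12, 5:9] = 1
        mask[8:12, 30:34] = 2
        mask[8:12, 55:59] = 3
        f = neighbor_features(mask, distance=30)[2]
        assert f["FirstClosestDistance"] == pytest.approx(25.0)
        assert f["SecondClosestDistance"] == pytest.approx(25.0)
        assert f["AngleBetweenNeighbors"] == pytest.approx(180.0)


class TestHaralick:
    def test_constant_object(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[1:7, 1:7] = True
        f = haralick_texture(np.full((8, 8), 3.0), mask)
        assert f["Contrast"] == 0.0
        assert f["AngularSecondMoment"] == 1.0

    def test_checkerboard_horizontal_direction(self):
        board = (np.indices((4, 4)).sum(axis=0) % 2).astype(float)
        q = quantize_intensities(board, 2)
        p = cooccurrence_matrix(q, np.ones((4, 4), dtype=bool), 1, (0, 1), 2)
        stats = _haralick_statistics(p)
        assert stats["Contrast"] == pytest.approx(1.0)
        assert stats["AngularSecondMoment"] == pytest.approx(0.5)

    def test_matrix_symmetric_and_normalized(self, small_scene):
        obj = small_scene.cells == 1
        rows, cols = np.nonzero(obj)
        sub = obj[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1]
        vals = small_scene.stack.channel("Mito").astype(float)[
            rows.min() : rows.max() + 1, cols.min() : cols.max() + 1
        ]
        q = np.zeros(sub.shape, dtype=int)
        q[sub] = quantize_intensities(vals[sub], 8)
        for direction in ((0, 1), (1, 1), (1, 0), (1, -1)):
            p = cooccurrence_matrix(q, sub, 3, direction, 8)
            assert p.sum() == pytest.approx(1.0)
            np.testing.assert_allclose(p, p.T, atol=1e-12)

    def test_single_pixel_object_all_zero(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        assert all(v == 0.0 for v in haralick_texture(np.ones((5, 5)), mask).values())

    def test_oracle_pair_enumeration_small_object(self):
        """GLCM statistics match a brute-force pair enumeration on a <=12x12
        object."""
        rng = np.random.default_rng(9)
        mask = rng.random((10, 12)) > 0.25
        img = rng.integers(0, 256, size=(10, 12)).astype(float)
        levels, offset = 4, 2
        q = np.zeros(mask.shape, dtype=int)
        q[mask] = quantize_intensities(img[mask], levels)
        for direction in ((0, 1), (1, 1), (1, 0), (1, -1)):
            expected = np.zeros((levels, levels))
            dr, dc = direction[0] * offset, direction[1] * offset
            for r in range(10):
                for c in range(12):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < 10 and 0 <= cc < 12 and mask[r, c] and mask[rr, cc]:
                        expected[q[r, c], q[rr, cc]] += 1
                        expected[q[rr, cc], q[r, c]] += 1
            if expected.sum():
                expected /= expected.sum()
            p = cooccurrence_matrix(q, mask, offset, direction, levels)
            np.testing.assert_allclose(p, expected, atol=1e-12)


SMALL_CATALOG = FeatureCatalog(
    channels=("DNA", "RNA"), granularity_scales=4, zernike_degree=4
)


class TestExtractAll:
    def test_empty_masks_give_empty_table_with_full_header(self, small_scene):
        empty = np.zeros(small_scene.cells.shape, dtype=np.int32)
        table = extract_all(SMALL_CATALOG, small_scene.stack, empty, empty)
        assert table.n_objects == 0
        assert table.feature_columns == SMALL_CATALOG.columns()

    def test_row_count_is_objects_times_compartments(self, small_scene):
        cat = FeatureCatalog(
            channels=("DNA", "RNA"),
            compartments=("cell", "nucleus"),
            granularity_scales=2,
            zernike_degree=2,
        )
        table = extract_all(cat, small_scene.stack, small_scene.cells, small_scene.nuclei)
        assert table.n_objects == 2 * small_scene.cells.max()

    def test_deterministic(self, small_scene):
        t1 = extract_all(SMALL_CATALOG, small_scene.stack, small_scene.cells, small_scene.nuclei)
        t2 = extract_all(SMALL_CATALOG, small_scene.stack, small_scene.cells, small_scene.nuclei)
        assert t1.frame.equals(t2.frame)

    def test_missing_channel_rejected(self, small_scene):
        cat = FeatureCatalog(channels=("DNA", "GFP"))
        with pytest.raises(ValueError, match="GFP"):
            extract_all(cat, small_scene.stack, small_scene.cells, small_scene.nuclei)

    def test_empty_cytoplasm_rows_are_zero_not_missing(self):
        from paintseg.io_plate import ChannelStack

        cells = np.zeros((16, 16), dtype=np.int32)
        cells[4:12, 4:12] = 1
        stack = ChannelStack(
            np.random.default_rng(0).integers(0, 100, (16, 16, 2), dtype=np.uint16),
            ("DNA", "RNA"),
        )
        table = extract_all(SMALL_CATALOG, stack, cells, cells)  # nucleus == cell
        cyto = table.frame[table.frame["compartment"] == "cytoplasm"]
        assert len(cyto) == 1
        assert (cyto[table.feature_columns].to_numpy() == 0).all()


class TestTranslationInvariance:
    def test_per_object_features_unchanged_by_whole_scene_shift(self):
        rng = np.random.default_rng(12)
        mask = np.zeros((48, 48), dtype=bool)
        yy, xx = np.mgrid[:48, :48]
        mask[((yy - 20) / 9.0) ** 2 + ((xx - 22) / 6.0) ** 2 <= 1] = True
        img = np.zeros((48, 48))
        img[mask] = rng.integers(10, 1000, mask.sum())
        dr, dc = 5, 7
        mask2 = np.roll(np.roll(mask, dr, axis=0), dc, axis=1)
        img2 = np.roll(np.roll(img, dr, axis=0), dc, axis=1)
        invariant = {}
        invariant.update(
            {
                f"AreaShape_{k}": v
                for k, v in areashape_features(mask).items()
                if not k.startswith(("Center", "BoundingBox"))
            }
        )
        invariant.update(intensity_features(img, mask))
        invariant.update({f"Z_{k}": v for k, v in zernike_magnitudes(mask, 4).items()})
        invariant.update({f"G_{i}": v for i, v in enumerate(granularity_spectrum(img, mask, 4))})
        invariant.update({f"R_{k}": v for k, v in radial_distribution(img, mask, 4).items()})
        invariant.update({f"T_{k}": v for k, v in haralick_texture(img, mask).items()})
        shifted = {}
        shifted.update(
            {
                f"AreaShape_{k}": v
                for k, v in areashape_features(mask2).items()
                if not k.startswith(("Center", "BoundingBox"))
            }
        )
        shifted.update(intensity_features(img2, mask2))
        shifted.update({f"Z_{k}": v for k, v in zernike_magnitudes(mask2, 4).items()})
        shifted.update({f"G_{i}": v for i, v in enumerate(granularity_spectrum(img2, mask2, 4))})
        shifted.update({f"R_{k}": v for k, v in radial_distribution(img2, mask2, 4).items()})
        shifted.update({f"T_{k}": v for k, v in haralick_texture(img2, mask2).items()})
        for key in invariant:
            assert shifted[key] == pytest.approx(invariant[key], abs=1e-9), key
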