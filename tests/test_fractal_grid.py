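"""2D/3D fractal estimators: exact cases, IFS targets, oracles."""

import numpy as np
import pytest

from fractan import (BinaryMask, DegenerateRegressionError, GeneratorSpec,
                     GreyGrid, binarize, box_counting_dim, correlation_dim,
                     ffi, fft_dim_grid, generate_image, generate_volume,
                     generalized_dims, higuchi_dim_grid, lacunarity,
                     minkowski_dim, pyramid_dim)
from fractan.fractal_grid import box_occupancy_series

from oracles import brute_box_counts, brute_lacunarity

LN8_LN3 = np.log(8) / np.log(3)
LN20_LN3 = np.log(20) / np.log(3)


@pytest.fixture(scope="module")
def carpet():
    img = generate_image(GeneratorSpec("ifs_menger", 243,
                                       params={"level": 5}))[0]
    return binarize(img)


class TestBoxCounting:
    def test_full_square_exact(self):
        res = box_counting_dim(BinaryMask(np.ones((512, 512), bool)))
        assert res.dimension == pytest.approx(2.0, abs=1e-12)
        assert res.fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_counts_match_brute_force(self, rng):
        mask = rng.random((48, 60)) < 0.2
        series = box_occupancy_series(BinaryMask(mask))
        ref = brute_box_counts(mask, [int(s) for s in series.scales])
        np.testing.assert_array_equal(series.measures, ref)

    def test_counts_match_brute_force_3d(self, rng):
        mask = rng.random((12, 16, 20)) < 0.3
        series = box_occupancy_series(BinaryMask(mask))
        ref = brute_box_counts(mask, [int(s) for s in series.scales])
        np.testing.assert_array_equal(series.measures, ref)

    def test_menger_carpet_dimension(self, carpet):
        res = box_counting_dim(carpet)
        assert res.dimension == pytest.approx(LN8_LN3, abs=0.05)

    def test_menger_cube_dimension(self):
        vol = generate_volume(GeneratorSpec("ifs_menger_cube", 27,
                                            params={"level": 3}))
        res = box_counting_dim(binarize(vol))
        assert res.dimension == pytest.approx(LN20_LN3, abs=0.1)

    def test_empty_foreground(self):
        with pytest.raises(ValueError, match="empty foreground"):
            box_counting_dim(BinaryMask(np.zeros((16, 16), bool)))

    def test_rotation_and_mirror_invariance(self, carpet):
        base = box_counting_dim(carpet).dimension
        rot = box_counting_dim(BinaryMask(np.rot90(carpet.data))).dimension
        mir = box_counting_dim(BinaryMask(carpet.data[::-1])).dimension
        assert rot == pytest.approx(base, abs=1e-12)
        assert mir == pytest.approx(base, abs=1e-12)


class TestPyramid:
    def test_full_square(self):
        res = pyramid_dim(BinaryMask(np.ones((256, 256), bool)))
        assert res.dimension == pytest.approx(2.0, abs=1e-12)

    def test_single_pixel(self):
        m = np.zeros((64, 64), bool)
        m[10, 20] = True
        res = pyramid_dim(BinaryMask(m))
        assert res.dimension == pytest.approx(0.0, abs=1e-12)

    def test_menger_carpet(self, carpet):
        res = pyramid_dim(carpet)
        assert res.dimension == pytest.approx(LN8_LN3, abs=0.08)


class TestMinkowski:
    def test_straight_line(self):
        m = np.zeros((101, 201), bool)
        m[50, :] = True
        res = minkowski_dim(BinaryMask(m))
        assert res.dimension == pytest.approx(1.0, abs=0.1)

    def test_filled_square_saturates(self):
        res = minkowski_dim(BinaryMask(np.ones((256, 256), bool)), r_max=4)
        assert res.dimension == pytest.approx(2.0, abs=0.05)

    def test_isolated_pixel(self):
        m = np.zeros((101, 101), bool)
        m[50, 50] = True
        res = minkowski_dim(BinaryMask(m))
        assert res.dimension == pytest.approx(0.0, abs=0.05)


class TestCorrelation:
    def test_uniform_square(self):
        res = correlation_dim(BinaryMask(np.ones((64, 64), bool)), seed=0)
        assert res.dimension == pytest.approx(2.0, abs=0.1)

    def test_single_row(self):
        m = np.zeros((64, 2048), bool)
        m[30, :] = True
        res = correlation_dim(BinaryMask(m), seed=0)
        assert res.dimension == pytest.approx(1.0, abs=0.05)

    def test_coincident_points_degenerate(self):
        m = np.zeros((32, 32), bool)
        m[5, 5] = True
        with pytest.raises(ValueError):
            correlation_dim(BinaryMask(m), seed=0)

    def test_subsample_deterministic(self, rng):
        m = BinaryMask(rng.random((128, 128)) < 0.5)
        a = correlation_dim(m, seed=42).dimension
        b = correlation_dim(m, seed=42).dimension
        assert a == b


class TestGeneralizedDims:
    def test_uniform_square_all_q_exact(self):
        grid = GreyGrid(np.full((128, 128), 200.0))
        for res in generalized_dims(grid, q_list=(-2.0, 0.0, 1.0, 2.0, 4.0)):
            assert res.dimension == pytest.approx(2.0, abs=1e-10)
            assert res.fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_menger_carpet_monofractal(self, carpet):
        grid = GreyGrid(carpet.data.astype(float) * 255)
        for res in generalized_dims(grid, q_list=(0.0, 1.0, 2.0)):
            assert res.dimension == pytest.approx(LN8_LN3, abs=0.08)

    def test_dq_non_increasing_in_q(self, rng):
        grid = GreyGrid(rng.integers(0, 256, (81, 81)).astype(float))
        dims = [r.dimension for r in
                generalized_dims(grid, q_list=(-2.0, 0.0, 2.0, 4.0))]
        assert all(a >= b - 1e-9 for a, b in zip(dims, dims[1:]))

    def test_d0_matches_box_counting_of_support(self, carpet):
        grid = GreyGrid(carpet.data.astype(float) * 255)
        d0 = generalized_dims(grid, q_list=(0.0,))[0].dimension
        db = box_counting_dim(carpet).dimension
        assert d0 == pytest.approx(db, abs=0.05)


class TestFftDim:
    def test_surface_recovery(self):
        imgs = generate_image(GeneratorSpec("surface_fft", (512, 512), count=3,
                                            params={"dim": 2.5}, seed=0))
        dims = [fft_dim_grid(g, window="hanning").dimension for g in imgs]
        assert np.mean(dims) == pytest.approx(2.5, abs=0.15)

    def test_volume_recovery_scaled(self):
        vol = generate_volume(GeneratorSpec("volume_fft", 64,
                                            params={"dim": 3.5}, seed=0))
        res = fft_dim_grid(vol, window="hanning")
        assert res.dimension == pytest.approx(3.5, abs=0.2)

    def test_constructed_spectrum_dimension(self, rng):
        n = 256
        f = np.fft.fftfreq(n) * n
        r = np.hypot(f[:, None], f[None, :])
        amp = np.where(r > 0, np.where(r > 0, r, 1.0) ** -1.5, 0.0)
        w = np.fft.fftn(rng.standard_normal((n, n)))
        field = np.fft.ifftn(amp * w / np.abs(np.where(w == 0, 1, w))).real
        res = fft_dim_grid(GreyGrid((field - field.min())
                                    / np.ptp(field) * 255), window=None)
        assert res.params["beta"] == pytest.approx(3.0, abs=0.1)
        assert res.dimension == pytest.approx(2.5, abs=0.05)


class TestHiguchiGrid:
    def test_plane_ramp_calibration(self):
        grid = GreyGrid(np.tile(np.linspace(0, 255, 64), (64, 1)))
        res = higuchi_dim_grid(grid, variant="direct_differences")
        assert res.dimension == pytest.approx(2.0, abs=0.02)

    def test_noise_image_approaches_three(self, rng):
        grid = GreyGrid(rng.integers(0, 256, (128, 128)).astype(float))
        res = higuchi_dim_grid(grid, variant="direct_differences")
        assert res.dimension == pytest.approx(3.0, abs=0.15)

    @pytest.mark.parametrize("variant", ["direct_differences", "profiles_1d"])
    def test_surface_consistency_with_fft(self, variant):
        imgs = generate_image(GeneratorSpec("surface_fft", (256, 256), count=2,
                                            params={"dim": 2.5}, seed=3))
        for g in imgs:
            dh = higuchi_dim_grid(g, variant=variant).dimension
            assert dh == pytest.approx(2.5, abs=0.2)
            df = fft_dim_grid(g, window="hanning").dimension
            assert abs(dh - df) < 0.3

    def test_3d_plane_calibration(self):
        ramp = np.tile(np.linspace(0, 255, 32), (32, 32, 1))
        res = higuchi_dim_grid(GreyGrid(ramp), variant="direct_differences")
        assert res.dimension == pytest.approx(3.0, abs=0.02)

    def test_constant_degenerate(self):
        with pytest.raises(DegenerateRegressionError):
            higuchi_dim_grid(GreyGrid(np.full((64, 64), 9.0)))


class TestLacunarity:
    def test_all_ones_unity(self):
        series = lacunarity(BinaryMask(np.ones((64, 64), bool)))
        np.testing.assert_allclose(series.lacunarity, 1.0, atol=1e-12)

    def test_bernoulli_inverse_p(self, rng):
        mask = BinaryMask(rng.random((512, 512)) < 0.5)
        series = lacunarity(mask, box_sizes=[1])
        assert series.lacunarity[0] == pytest.approx(2.0, rel=0.02)

    @pytest.mark.parametrize("mode", ["raster", "gliding"])
    def test_matches_brute_force(self, mode, rng):
        mask = rng.random((30, 40)) < 0.4
        series = lacunarity(BinaryMask(mask), box_sizes=[2, 5], mode=mode)
        for r, lam in zip(series.box_sizes, series.lacunarity):
            assert lam == pytest.approx(brute_lacunarity(mask, int(r), mode),
                                        abs=1e-10)

    def test_carpet_gappier_than_random(self, carpet, rng):
        p = carpet.data.mean()
        random_mask = BinaryMask(rng.random(carpet.data.shape) < p)
        lam_c = lacunarity(carpet, box_sizes=[9]).lacunarity[0]
        lam_r = lacunarity(random_mask, box_sizes=[9]).lacunarity[0]
        assert lam_c > lam_r

    def test_lacunarity_at_least_one(self, rng):
        mask = BinaryMask(rng.random((64, 64)) < 0.3)
        series = lacunarity(mask)
        assert np.all(series.lacunarity >= 1.0 - 1e-9)

    def test_oversized_box_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            lacunarity(BinaryMask(np.ones((16, 16), bool)), box_sizes=[32])


class TestFfi:
    def test_large_filled_square_near_one(self):
        m = np.zeros((256, 256), bool)
        m[10:240, 10:240] = True
        res = ffi(BinaryMask(m))
        assert res.dimension == pytest.approx(1.0, abs=0.15)

    def test_isolated_dust_exactly_zero(self):
        m = np.zeros((64, 64), bool)
        m[::4, ::4] = True
        assert ffi(BinaryMask(m)).dimension == 0.0

    def test_menger_carpet_intermediate(self):
        img = generate_image(GeneratorSpec("ifs_menger", 81,
                                           params={"level": 4}))[0]
        res = ffi(binarize(img))
        assert 0.0 < res.dimension < 1.0
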