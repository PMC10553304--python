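"""1D fractal estimators: analytic cases, oracles and recoveries."""

import numpy as np
import pytest

from fractan import (AnalysisSpec, DegenerateRegressionError, GeneratorSpec,
                     Sequence1D, dfa_alpha, generate_sequence, higuchi_dim_1d,
                     hurst_psd, katz_dim, petrosian_dim, sevcik_dim,
                     windowed_apply)
from fractan.fractal_seq import higuchi_curve

from oracles import brute_higuchi_curve


class TestHiguchi:
    def test_ramp_is_analytic_line(self):
        n = 200
        res = higuchi_dim_1d(np.arange(n, dtype=float), kmax=8)
        curve = higuchi_curve(np.arange(n, dtype=float), kmax=8)
        np.testing.assert_allclose(curve.measures,
                                   (n - 1) / curve.scales, rtol=1e-12)
        assert res.dimension == pytest.approx(1.0, abs=1e-12)
        assert res.fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_reference(self, rng):
        for n in (50, 127, 200):
            x = rng.standard_normal(n)
            mine = higuchi_curve(x, kmax=8).measures
            ref = brute_higuchi_curve(x, kmax=8)
            np.testing.assert_allclose(mine, ref, rtol=1e-12)

    def test_white_noise_dimension_two(self, rng):
        dims = [higuchi_dim_1d(rng.standard_normal(4096), kmax=8).dimension
                for _ in range(5)]
        assert np.mean(dims) == pytest.approx(2.0, abs=0.05)

    def test_constant_sequence_degenerate(self):
        with pytest.raises(DegenerateRegressionError):
            higuchi_dim_1d(np.ones(100), kmax=8)

    def test_offset_invariance(self, rng):
        x = rng.standard_normal(512)
        a = higuchi_dim_1d(x, kmax=8).dimension
        b = higuchi_dim_1d(x + 100.0, kmax=8).dimension
        assert a == pytest.approx(b, abs=1e-10)

    def test_dimension_decreases_with_hurst(self):
        means = []
        for hurst in (0.2, 0.5, 0.8):
            dims = [higuchi_dim_1d(
                generate_sequence(GeneratorSpec("fgn_dhm", 4096,
                                                params={"hurst": hurst},
                                                seed=s))[0], kmax=8).dimension
                for s in range(20)]
            means.append(np.mean(dims))
        assert means[0] > means[1] > means[2]


class TestKatz:
    def test_straight_line_exactly_one(self):
        for slope in (0.5, -2.0, 10.0):
            res = katz_dim(np.arange(100) * slope + 3.0)
            assert res.dimension == pytest.approx(1.0, abs=1e-12)

    def test_too_short(self):
        with pytest.raises(ValueError, match="too short"):
            katz_dim(np.array([0.0, 1.0]))

    def test_toy_sequence_formula_value(self):
        x = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        steps = np.hypot(1.0, np.diff(x))
        length = steps.sum()
        d = max(np.hypot(i, x[i] - x[0]) for i in range(8))
        n = 7
        expected = np.log10(n) / (np.log10(n) + np.log10(d / length))
        assert katz_dim(x).dimension == pytest.approx(expected, abs=1e-12)

    def test_amplitude_scaling_changes_value_but_stays_in_range(self, rng):
        x = rng.standard_normal(256)
        assert 1.0 <= katz_dim(x).dimension <= 2.5


class TestPetrosian:
    def test_monotone_ramp_is_one(self):
        assert petrosian_dim(np.arange(100.0)).dimension == pytest.approx(1.0)

    def test_alternating_sequence_maximal_changes(self):
        n = 64
        x = np.resize([0.0, 1.0], n)
        res = petrosian_dim(x)
        assert res.params["sign_changes"] == n - 2

    def test_formula_on_simulated_counts(self, rng):
        x = rng.standard_normal(1000)
        res = petrosian_dim(x)
        # turning-point rate of an iid sequence is 2/3
        rate = res.params["sign_changes"] / 998
        assert rate == pytest.approx(2 / 3, abs=0.06)
        expected = np.log10(1000) / (np.log10(1000) + np.log10(
            1000 / (1000 + 0.4 * res.params["sign_changes"])))
        assert res.dimension == pytest.approx(expected, abs=1e-12)


class TestSevcik:
    def test_diagonal_line_limit(self):
        # exact value is 1 + ln(sqrt 2)/ln(2(N-1)); slow logarithmic decay
        res = sevcik_dim(np.linspace(0, 1, 10 ** 4))
        expected = 1.0 + np.log(np.sqrt(2)) / np.log(2 * (10 ** 4 - 1))
        assert res.dimension == pytest.approx(expected, abs=1e-6)
        assert res.dimension == pytest.approx(1.0, abs=0.05)

    def test_hand_computed_four_points(self):
        x = np.array([0.0, 2.0, 1.0, 3.0])
        y = (x - 0) / 3.0
        t = np.arange(4) / 3.0
        length = np.hypot(np.diff(t), np.diff(y)).sum()
        expected = 1.0 + np.log(length) / np.log(2.0 * 3)
        assert sevcik_dim(x).dimension == pytest.approx(expected, abs=1e-12)

    def test_noise_dimension_grows_toward_two(self, rng):
        d_small = sevcik_dim(rng.standard_normal(256)).dimension
        d_large = sevcik_dim(rng.standard_normal(65536)).dimension
        assert 1.5 < d_small < d_large < 2.0

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="zero amplitude"):
            sevcik_dim(np.full(100, 3.0))


class TestDfa:
    def test_white_noise_half(self, rng):
        alphas = [dfa_alpha(rng.standard_normal(8192)).dimension
                  for _ in range(5)]
        assert np.mean(alphas) == pytest.approx(0.5, abs=0.05)

    def test_fgn_alpha_equals_hurst(self):
        alphas = [dfa_alpha(generate_sequence(
            GeneratorSpec("fgn_dhm", 8192, params={"hurst": 0.8},
                          seed=s))[0]).dimension for s in range(10)]
        assert np.mean(alphas) == pytest.approx(0.8, abs=0.07)

    def test_constant_degenerate(self):
        with pytest.raises(DegenerateRegressionError):
            dfa_alpha(np.zeros(1024))


class TestHurstPsd:
    def test_white_noise_is_fgn_half(self, rng):
        res = hurst_psd(rng.standard_normal(8192))
        assert res.params["signal_class"] == "fGn"
        assert res.dimension == pytest.approx(0.5, abs=0.1)

    def test_fbm_beta_and_companion_dimension(self):
        betas, dims = [], []
        for s in range(10):
            seq = generate_sequence(GeneratorSpec("fbm_ssm", 4096,
                                                  params={"hurst": 0.5},
                                                  seed=s))[0]
            res = hurst_psd(seq)
            betas.append(res.params["beta"])
            dims.append(res.params.get("companion_dimension", np.nan))
        assert np.mean(betas) == pytest.approx(2.0, abs=0.2)
        assert np.nanmean(dims) == pytest.approx(1.5, abs=0.1)

    def test_class_boundary_goes_to_fbm(self):
        # construct an exact beta = 1 spectrum: boundary classified as fBm
        rng = np.random.default_rng(0)
        n = 4096
        f = np.fft.fftfreq(n) * n
        amp = np.where(f != 0, np.abs(np.where(f == 0, 1, f)) ** -0.5, 0)
        w = np.fft.fft(rng.standard_normal(n))
        x = np.fft.ifft(amp * w / np.abs(np.where(w == 0, 1, w))).real
        res = hurst_psd(x)
        if res.params["beta"] >= 1.0:
            assert res.params["signal_class"] == "fBm"


class TestWindowedApply:
    def test_subsequent_box_count(self, rng):
        seq = Sequence1D("x", rng.standard_normal(1000))
        spec = AnalysisSpec(range_mode="subsequent_boxes", box_length=100)
        table = windowed_apply(seq, lambda w: w.values.mean(), spec)
        assert len(table) == 10

    def test_sliding_box_count(self, rng):
        seq = Sequence1D("x", rng.standard_normal(1000))
        spec = AnalysisSpec(range_mode="sliding_box", box_length=100)
        table = windowed_apply(seq, lambda w: w.values.mean(), spec)
        assert len(table) == 901

    def test_ramp_means_increase_linearly(self):
        seq = Sequence1D("ramp", np.arange(400, dtype=float) * 0.5)
        spec = AnalysisSpec(range_mode="subsequent_boxes", box_length=100)
        vals = windowed_apply(seq, lambda w: w.values.mean(),
                              spec).frame["Value"].to_numpy()
        np.testing.assert_allclose(np.diff(vals), 100 * 0.5, rtol=1e-12)

    def test_box_longer_than_sequence(self, rng):
        seq = Sequence1D("x", rng.standard_normal(50))
        spec = AnalysisSpec(range_mode="sliding_box", box_length=100)
        with pytest.raises(ValueError, match="box_length"):
            windowed_apply(seq, lambda w: 0.0, spec)
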