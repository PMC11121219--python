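"""Spectral container, I/O and pre-treatment operator behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capranir import (Spectrum, SpectraSet, TreatmentSpec, WavenumberGrid,
                      als_baseline, apply_treatment, decimate, decimate_set,
                      derivative, msc, norm_unit_area, read_spectra_csv,
                      smooth, snv, write_spectra_csv)
from capranir.spectra import (DegenerateInputError, FormatError,
                              ParameterError, fit_treatment)


class TestGrid:
    def test_default_grid_has_1501_points(self):
        grid = WavenumberGrid()
        assert grid.n_points == 1501
        assert grid.values[0] == 4000.0 and grid.values[-1] == 10000.0

    def test_non_uniform_header_rejected(self):
        with pytest.raises(FormatError):
            WavenumberGrid.from_values(np.array([4000.0, 4004.0, 4012.0]))

    def test_descending_rejected(self):
        with pytest.raises(FormatError):
            WavenumberGrid.from_values(np.array([4008.0, 4004.0, 4000.0]))

    def test_values_length_must_match_grid(self, small_grid):
        with pytest.raises(FormatError):
            Spectrum(small_grid, np.ones(small_grid.n_points + 1))


class TestCsvRoundTrip:
    def test_round_trip(self, small_set, tmp_path):
        path = tmp_path / "spectra.csv"
        write_spectra_csv(small_set, path)
        back = read_spectra_csv(path)
        assert back.n_spectra == 6 and back.n_points == 5
        np.testing.assert_allclose(back.matrix, small_set.matrix)
        assert list(back.sample_id) == list(small_set.sample_id)
        assert back.grid == small_set.grid

    def test_missing_metadata_column_rejected(self, small_set, tmp_path):
        path = tmp_path / "spectra.csv"
        df = small_set.to_frame().drop(columns=["breed"])
        df.to_csv(path, index=False)
        with pytest.raises(FormatError, match="breed"):
            read_spectra_csv(path)

    def test_non_uniform_grid_rejected(self, small_set, tmp_path):
        path = tmp_path / "spectra.csv"
        df = small_set.to_frame().drop(columns=["4004"])
        df.to_csv(path, index=False)
        with pytest.raises(FormatError):
            read_spectra_csv(path)


@pytest.fixture()
def grid101():
    return WavenumberGrid(start=4000.0, stop=4400.0, spacing=4.0)


class TestSmooth:
    def test_exact_on_low_order_polynomials(self, grid101):
        nu = grid101.values
        for coeffs in ([3.0], [0.2, 1e-3], [1.0, 2e-3, -1e-6]):  # const/lin/quad
            vals = np.polyval(coeffs[::-1], nu - nu[0])
            out = smooth(Spectrum(grid101, vals), window=11, polyorder=2)
            np.testing.assert_allclose(out.values, vals, atol=1e-8)

    def test_reduces_noise_around_smooth_curve(self, grid101):
        rng = np.random.default_rng(1)
        nu = grid101.values
        truth = np.sin((nu - 4000) / 80.0)
        noisy = truth + rng.normal(0, 0.05, nu.size)
        out = smooth(Spectrum(grid101, noisy), window=11, polyorder=2)
        assert np.var(out.values - truth) < np.var(noisy - truth)

    def test_even_window_rejected(self, grid101):
        with pytest.raises(ParameterError):
            smooth(Spectrum(grid101, np.ones(101)), window=10)


class TestNormUnitArea:
    def test_constant_becomes_reciprocal_width(self, grid101):
        width = grid101.stop - grid101.start
        out = norm_unit_area(Spectrum(grid101, np.full(101, 2.0)))
        np.testing.assert_allclose(out.values, 1.0 / width, rtol=1e-12)

    def test_integral_one_and_idempotent(self, grid101):
        rng = np.random.default_rng(2)
        s = Spectrum(grid101, rng.uniform(0.1, 1.0, 101))
        out = norm_unit_area(s)
        # independent trapezoid: explicit sum of interval averages
        v, d = out.values, grid101.spacing
        integral = float(np.sum((v[1:] + v[:-1]) / 2.0 * d))
        assert abs(integral - 1.0) < 1e-10
        np.testing.assert_allclose(norm_unit_area(out).values, out.values,
                                   atol=1e-12)

    def test_zero_integral_rejected(self, grid101):
        with pytest.raises(DegenerateInputError):
            norm_unit_area(Spectrum(grid101, np.zeros(101)))


class TestSnv:
    def test_simple_three_point_case(self):
        g = WavenumberGrid(4000, 4008, 4)
        out = snv(Spectrum(g, np.array([1.0, 2.0, 3.0])))
        np.testing.assert_allclose(out.values, [-1.0, 0.0, 1.0])

    @given(a=st.floats(-5, 5), b=st.floats(0.1, 10))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_affine_invariance_positive_gain(self, a, b):
        g = WavenumberGrid(4000, 4036, 4)
        x = np.sin(np.arange(10.0))
        base = snv(Spectrum(g, x)).values
        corrupted = snv(Spectrum(g, a + b * x)).values
        np.testing.assert_allclose(corrupted, base, atol=1e-9)

    def test_output_mean_zero_sd_one(self, grid101):
        rng = np.random.default_rng(3)
        out = snv(Spectrum(grid101, rng.uniform(0, 1, 101)))
        assert abs(out.values.mean()) < 1e-10
        assert abs(np.std(out.values, ddof=1) - 1.0) < 1e-10

    def test_constant_rejected(self, grid101):
        with pytest.raises(DegenerateInputError):
            snv(Spectrum(grid101, np.full(101, 4.2)))


class TestMsc:
    def _set(self, grid, matrix):
        n = matrix.shape[0]
        return SpectraSet(grid=grid, matrix=matrix,
                          sample_id=np.arange(n), replicate=np.ones(n, int),
                          breed=np.repeat("A", n), sex=np.repeat("M", n))

    def test_reference_itself_unchanged(self, grid101):
        base = np.sin(grid101.values / 300.0) + 2.0
        ss = self._set(grid101, np.vstack([base, base]))
        out, ref = msc(ss, "mean")
        np.testing.assert_allclose(out.matrix[0], base, atol=1e-10)

    def test_affine_corruption_inverted_exactly(self, grid101):
        base = np.sin(grid101.values / 300.0) + 2.0
        ss = self._set(grid101, np.vstack([base, 2.0 * base + 5.0]))
        out, _ = msc(ss, Spectrum(grid101, base))
        np.testing.assert_allclose(out.matrix[1], base, atol=1e-10)

    def test_recovers_common_base_from_random_scatter(self, grid101):
        rng = np.random.default_rng(4)
        base = np.sin(grid101.values / 300.0) + 2.0
        a = rng.uniform(-0.1, 0.1, 8)
        b = rng.uniform(0.8, 1.2, 8)
        mat = a[:, None] + b[:, None] * base
        out, _ = msc(self._set(grid101, mat), Spectrum(grid101, base))
        np.testing.assert_allclose(out.matrix, np.tile(base, (8, 1)), atol=1e-8)

    def test_flat_spectrum_rejected(self, grid101):
        base = np.sin(grid101.values / 300.0)
        mat = np.vstack([base, np.full(101, 0.3)])
        with pytest.raises(DegenerateInputError):
            msc(self._set(grid101, mat), Spectrum(grid101, base))


class TestAlsBaseline:
    def test_smooth_input_is_its_own_baseline(self, grid101):
        nu = grid101.values
        vals = 0.2 + 1e-4 * (nu - nu[0])
        baseline, corrected = als_baseline(Spectrum(grid101, vals), p=0.5)
        np.testing.assert_allclose(baseline.values, vals, atol=1e-3)
        assert np.max(np.abs(corrected.values)) < 1e-3

    def test_recovers_peaks_on_linear_baseline(self):
        grid = WavenumberGrid(4000.0, 6000.0, 4.0)
        nu = grid.values
        true_base = 0.1 + 5e-5 * (nu - nu[0])
        peaks = np.zeros_like(nu)
        for center, height in ((4400, 0.5), (5000, 0.8), (5600, 0.3)):
            peaks += height * np.exp(-0.5 * ((nu - center) / 30.0) ** 2)
        _, corrected = als_baseline(Spectrum(grid, true_base + peaks),
                                    lam=1e5, p=0.01, n_iter=10)
        for center, height in ((4400, 0.5), (5000, 0.8), (5600, 0.3)):
            got = corrected.values[np.argmin(np.abs(nu - center))]
            assert abs(got - height) / height < 0.05

    def test_output_lengths(self, grid101):
        s = Spectrum(grid101, np.ones(101) + np.sin(grid101.values / 50))
        baseline, corrected = als_baseline(s)
        assert baseline.values.size == corrected.values.size == 101

    def test_parameter_validation(self, grid101):
        s = Spectrum(grid101, np.ones(101))
        with pytest.raises(ParameterError):
            als_baseline(s, lam=-1)
        with pytest.raises(ParameterError):
            als_baseline(s, p=1.5)


class TestDerivative:
    def test_annihilates_polynomials_below_order(self, grid101):
        nu = grid101.values
        const = Spectrum(grid101, np.full(101, 3.0))
        assert np.max(np.abs(derivative(const, 1).values)) < 1e-12
        ramp = Spectrum(grid101, 0.5 * nu)
        d1 = derivative(ramp, 1).values
        np.testing.assert_allclose(d1[5:-5], 0.5, atol=1e-10)
        assert np.max(np.abs(derivative(ramp, 2).values[5:-5])) < 1e-10

    def test_quadratic_second_derivative(self, grid101):
        nu = grid101.values
        quad = Spectrum(grid101, 2e-4 * (nu - nu[0]) ** 2)
        d2 = derivative(quad, 2).values
        np.testing.assert_allclose(d2, 4e-4, atol=1e-8)

    def test_invalid_parameters(self, grid101):
        s = Spectrum(grid101, np.ones(101))
        with pytest.raises(ParameterError):
            derivative(s, order=3)
        with pytest.raises(ParameterError):
            derivative(s, order=2, polyorder=1)


class TestDecimate:
    def test_default_grid_reduces_1501_to_151(self):
        s = Spectrum(WavenumberGrid(), np.ones(1501))
        out = decimate(s, 10)
        assert out.values.size == 151
        assert out.grid.values[0] == 4000.0 and out.grid.spacing == 40.0

    def test_identity_at_step_one(self, grid101):
        s = Spectrum(grid101, np.arange(101.0))
        assert decimate(s, 1) is s

    def test_eleven_points_step_ten_keeps_two(self):
        g = WavenumberGrid(4000.0, 4040.0, 4.0)
        out = decimate(Spectrum(g, np.arange(11.0)), 10)
        np.testing.assert_array_equal(out.values, [0.0, 10.0])

    def test_set_decimation_matches_per_spectrum(self, small_set):
        out = decimate_set(small_set, 2)
        expected = decimate(small_set.spectrum(0), 2)
        np.testing.assert_allclose(out.matrix[0], expected.values)
        assert out.grid == expected.grid


class TestApplyTreatment:
    def test_parse_vocabulary(self):
        for label in ("SM", "DV1", "DV2", "NORM-DV1", "MSC-SM", "MSC-DV1",
                      "SNV-SM", "ALS-SM", "SNV-DV1"):
            assert str(TreatmentSpec.parse(label)) == label

    def test_unknown_code_rejected(self, small_set):
        with pytest.raises(ParameterError):
            apply_treatment(small_set, "SNV-XYZ")

    def test_composition_matches_manual_chain(self, grid101):
        rng = np.random.default_rng(5)
        base = np.sin(grid101.values / 200.0) + 1.5
        mat = rng.uniform(-0.1, 0.1, (4, 1)) + rng.uniform(0.8, 1.2, (4, 1)) * base
        ss = SpectraSet(grid=grid101, matrix=mat, sample_id=np.arange(4),
                        replicate=np.ones(4, int), breed=np.repeat("A", 4),
                        sex=np.repeat("M", 4))
        out = apply_treatment(ss, "MSC-DV1")
        corrected, _ = msc(ss, "mean")
        manual = np.vstack([
            derivative(corrected.spectrum(i), 1).values for i in range(4)
        ])
        np.testing.assert_allclose(out.matrix, manual, atol=1e-12)

    def test_fit_rows_never_reads_test_rows(self, grid101):
        rng = np.random.default_rng(6)
        mat = rng.uniform(0.5, 1.5, (6, 101))
        ss = SpectraSet(grid=grid101, matrix=mat, sample_id=np.arange(6),
                        replicate=np.ones(6, int), breed=np.repeat("A", 6),
                        sex=np.repeat("M", 6))
        fit_rows = np.array([0, 1, 2])
        _, fitted = fit_treatment(ss, "MSC-SM", fit_rows=fit_rows)
        mutated = ss.with_matrix(mat.copy())
        mutated.matrix[3:] += rng.uniform(1, 2, (3, 101))
        _, fitted2 = fit_treatment(mutated, "MSC-SM", fit_rows=fit_rows)
        np.testing.assert_array_equal(fitted.msc_references[0].values,
                                      fitted2.msc_references[0].values)
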