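"""Derivative spectrum and the 14 spectral variables."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from algaespec.features import (
    FEATURE_NAMES,
    OPTIMAL_SUBSET_8,
    SIGNIFICANCE_ORDER,
    WINDOWS,
    WindowSpec,
    build_feature_table,
    compute_indices,
    extract_features,
    find_window_extremum,
    first_derivative,
    read_feature_table,
    window_area,
    write_feature_table,
)
from algaespec.spectra import Spectrum, SpectrumSet

WL = np.arange(400.0, 901.0)


def _spectrum(values, sample_id="s", species="Ulva_pertusa"):
    return Spectrum(sample_id, species, WL.copy(), np.asarray(values, dtype=float))


def _random_curve(rng):
    # smooth random positive curve on the full grid
    raw = rng.uniform(2, 90, 26)
    return _spectrum(np.interp(WL, np.linspace(400, 900, 26), raw))


class TestFirstDerivative:
    def test_constant_curve_gives_zeros(self):
        d = first_derivative(_spectrum(np.full(WL.size, 50.0)))
        assert len(d) == WL.size - 1
        np.testing.assert_array_equal(d.values, 0.0)

    def test_linear_ramp_gives_constant_slope(self):
        d = first_derivative(_spectrum(0.1 * WL))
        np.testing.assert_allclose(d.values, 0.1, atol=1e-12)

    def test_ulva_red_edge_is_strictly_positive(self, ulva_ref):
        d = first_derivative(ulva_ref)
        mask = (d.wavelengths >= 680) & (d.wavelengths <= 755)
        assert np.all(d.values[mask] > 0)

    def test_non_uniform_grid_rejected(self):
        s = Spectrum("a", "Ulva_pertusa", [400.0, 401.0, 403.0], [5.0, 6.0, 7.0])
        with pytest.raises(ValueError, match="uniform"):
            first_derivative(s)


class TestWindowExtremum:
    def test_ulva_red_valley_printed_value(self, ulva_ref):
        loc, val = find_window_extremum(ulva_ref, WINDOWS["red_valley"])
        assert loc == 669.0
        assert val == pytest.approx(5.78, abs=1e-9)

    def test_tie_breaks_to_smallest_wavelength(self):
        loc, val = find_window_extremum(
            _spectrum(np.full(WL.size, 42.0)), WINDOWS["green_peak"]
        )
        assert (loc, val) == (510.0, 42.0)

    @pytest.mark.parametrize("mode", ["max", "min"])
    def test_matches_exhaustive_scan_on_random_curves(self, mode):
        rng = np.random.default_rng(12)
        w = WindowSpec("probe", 520, 700, "reflectance", mode)
        for _ in range(200):
            s = _random_curve(rng)
            loc, val = find_window_extremum(s, w)
            # brute-force scan oracle
            best = None
            for wl, r in zip(s.wavelengths, s.reflectance):
                if 520 <= wl <= 700:
                    better = best is None or (r < best[1] if mode == "min" else r > best[1])
                    if better:
                        best = (wl, r)
            assert (loc, val) == best

    def test_empty_window_errors(self, ulva_ref):
        w = WindowSpec("narrow", 500.2, 500.8, "reflectance", "max")
        with pytest.raises(ValueError, match="no grid points"):
            find_window_extremum(ulva_ref, w)


class TestWindowArea:
    def test_zero_derivative_zero_area(self):
        d = first_derivative(_spectrum(np.full(WL.size, 10.0)))
        assert window_area(d, WINDOWS["red_edge"]) == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_telescoping_identity(self, seed):
        # forward-difference sum over [a, b] equals R(b+1) - R(a)
        s = _random_curve(np.random.default_rng(seed))
        d = first_derivative(s)
        for lo, hi in ((680, 760), (490, 530), (412, 897)):
            area = window_area(d, WindowSpec("w", lo, hi, "derivative", "max"))
            expected = s.reflectance[hi + 1 - 400] - s.reflectance[lo - 400]
            assert area == pytest.approx(expected, abs=1e-9)

    def test_ulva_red_edge_dominates_blue_edge(self, ulva_ref):
        d = first_derivative(ulva_ref)
        a_re = window_area(d, WINDOWS["red_edge"])
        a_be = window_area(d, WINDOWS["blue_edge"])
        assert a_re > 0
        assert a_re > a_be


class TestIndices:
    def test_equal_operands(self):
        idx = compute_indices(R_g=10.0, R_r=10.0, A_re=1.0, A_be=1.0)
        assert idx.NDVI_RgRr == 0.0
        assert idx.RVI_RgRr == 1.0

    def test_printed_ulva_arithmetic(self):
        idx = compute_indices(R_g=25.27, R_r=5.78, A_re=1.0, A_be=1.0)
        assert idx.NDVI_RgRr == pytest.approx(0.62770, abs=5e-6)
        assert idx.RVI_RgRr == pytest.approx(4.3720, abs=5e-5)

    def test_doubled_area_forces_one_third(self):
        idx = compute_indices(R_g=1.0, R_r=1.0, A_re=2.0, A_be=1.0)
        assert idx.NDVI_AreAbe == pytest.approx(1 / 3)

    def test_zero_denominator_flags_missing(self):
        with pytest.warns(UserWarning, match="zero denominator"):
            idx = compute_indices(R_g=1.0, R_r=0.0, A_re=1.0, A_be=1.0)
        assert math.isnan(idx.RVI_RgRr)
        assert not math.isnan(idx.NDVI_RgRr)


class TestExtractFeatures:
    def test_ulva_reference_locations(self, ulva_ref):
        fv = extract_features(ulva_ref)
        assert fv.L_r == 669.0
        assert fv.R_r == pytest.approx(5.78, abs=1e-9)
        assert fv.L_g == 554.0
        assert fv.R_g == pytest.approx(25.27, abs=1e-9)

    def test_constant_spectrum_degenerate_features(self):
        with pytest.warns(UserWarning):
            fv = extract_features(_spectrum(np.full(WL.size, 30.0)))
        assert fv.V_re == fv.V_be == 0.0
        assert fv.A_re == fv.A_be == 0.0
        assert fv.NDVI_RgRr == 0.0
        assert (fv.L_g, fv.L_r, fv.L_re, fv.L_be) == (510.0, 640.0, 680.0, 490.0)
        assert math.isnan(fv.NDVI_AreAbe)

    def test_rhodophyta_green_peak_is_boundary_value(self, rhodophyta_ref):
        # the red-seaweed curve falls then rises over [510, 560]: the window
        # "peak" is a boundary value, and must equal the brute-force maximum
        fv = extract_features(rhodophyta_ref)
        mask = (rhodophyta_ref.wavelengths >= 510) & (rhodophyta_ref.wavelengths <= 560)
        sub = rhodophyta_ref.reflectance[mask]
        assert fv.R_g == sub.max()
        assert fv.L_g in (510.0, 560.0)

    def test_internal_consistency_with_window_extremum(self, default_dataset):
        for s in list(default_dataset)[::40]:
            fv = extract_features(s)
            loc, val = find_window_extremum(s, WINDOWS["green_peak"])
            assert (fv.L_g, fv.R_g) == (loc, val)

    def test_shift_equivariance(self, ulva_ref):
        # shifting the curve +k nm moves locations by +k, amplitudes unchanged
        k = 3
        shifted_refl = np.concatenate([np.full(k, ulva_ref.reflectance[0]),
                                       ulva_ref.reflectance[:-k]])
        shifted = ulva_ref.copy_with(reflectance=shifted_refl)
        a, b = extract_features(ulva_ref), extract_features(shifted)
        assert b.L_g == a.L_g + k
        assert b.L_r == a.L_r + k
        assert b.L_re == a.L_re + k
        assert b.R_g == pytest.approx(a.R_g, abs=1e-9)
        assert b.R_r == pytest.approx(a.R_r, abs=1e-9)
        assert b.V_re == pytest.approx(a.V_re, abs=1e-9)

    def test_ndvi_bounded_for_positive_spectra(self, default_features):
        vals = default_features["NDVI_RgRr"].to_numpy()
        assert np.all(vals > -1) and np.all(vals < 1)


class TestFeatureTable:
    def test_empty_set_gives_empty_table(self):
        table = build_feature_table(SpectrumSet([]))
        assert len(table) == 0
        assert list(table.columns[4:]) == list(FEATURE_NAMES)

    def test_default_dataset_dimensions(self, default_features):
        assert default_features.shape == (382, 4 + 14)
        assert default_features[list(FEATURE_NAMES)].notna().all().all()

    def test_csv_round_trip(self, default_features, tmp_path):
        path = tmp_path / "features.csv"
        write_feature_table(default_features, path)
        back = read_feature_table(path)
        assert list(back.columns) == list(default_features.columns)
        for col in FEATURE_NAMES:
            np.testing.assert_allclose(back[col], default_features[col], rtol=1e-9)

    def test_significance_order_constants(self):
        assert set(SIGNIFICANCE_ORDER) == set(FEATURE_NAMES)
        assert OPTIMAL_SUBSET_8 == SIGNIFICANCE_ORDER[:8]
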