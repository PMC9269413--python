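"""Spectral-library I/O and preprocessing."""

import numpy as np
import pytest

from algaespec.spectra import (
    GridError,
    SPECIES,
    SpectraError,
    Spectrum,
    SpectrumSet,
    UnitScaleError,
    average_replicates,
    read_spectra,
    resample_to_grid,
    trim_wavelengths,
    write_spectra,
)


def _random_set(rng, n=3, lo=400, hi=450):
    wl = np.arange(lo, hi + 1, dtype=float)
    spectra = [
        Spectrum(
            sample_id=f"s{i}",
            species=SPECIES[int(rng.integers(len(SPECIES)))],
            dryness=("wet", "moderate", "dry")[int(rng.integers(3))],
            wavelengths=wl,
            reflectance=rng.uniform(2.0, 90.0, wl.size),
        )
        for i in range(n)
    ]
    return SpectrumSet(spectra)


class TestSpectrumInvariants:
    def test_rejects_decreasing_wavelengths(self):
        with pytest.raises(SpectraError):
            Spectrum("a", "Ulva_pertusa", [500.0, 499.0], [10.0, 10.0])

    def test_rejects_fractional_scale(self):
        with pytest.raises(UnitScaleError):
            Spectrum("a", "Ulva_pertusa", [400.0, 401.0], [0.1, 0.9])

    def test_allows_zero_curve(self):
        s = Spectrum("a", "Ulva_pertusa", [400.0, 401.0], [0.0, 0.0])
        assert s.reflectance.sum() == 0

    def test_phylum_derivation(self):
        assert Spectrum("a", "Ulva_pertusa", [400.0], [5.0]).phylum == "Chlorophyta"
        assert Spectrum("a", "Sargassum_fusiforme", [400.0], [5.0]).phylum == "Ochrophyta"
        assert Spectrum("a", "Grateloupia_filicina", [400.0], [5.0]).phylum == "Rhodophyta"

    def test_duplicate_ids_rejected(self):
        s = Spectrum("a", "Ulva_pertusa", [400.0], [5.0])
        with pytest.raises(SpectraError, match="duplicate"):
            SpectrumSet([s, s])


class TestRoundTrip:
    @pytest.mark.parametrize("dialect", ["long_csv", "wide_csv"])
    def test_read_write_round_trip_random_sets(self, dialect, tmp_path):
        rng = np.random.default_rng(42)
        for rep in range(20):
            original = _random_set(rng, n=int(rng.integers(1, 5)))
            path = tmp_path / f"{dialect}_{rep}.csv"
            write_spectra(original, path, dialect=dialect)
            back = read_spectra(path, dialect=dialect)
            assert len(back) == len(original)
            for a, b in zip(original, back):
                assert (a.sample_id, a.species, a.dryness) == (b.sample_id, b.species, b.dryness)
                np.testing.assert_array_equal(a.wavelengths, b.wavelengths)
                np.testing.assert_allclose(a.reflectance, b.reflectance, rtol=1e-9)

    def test_second_write_is_byte_identical(self, tmp_path):
        rng = np.random.default_rng(0)
        sset = _random_set(rng)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_spectra(sset, p1)
        write_spectra(read_spectra(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_wide_csv_grid_column_count(self, tmp_path):
        wl = np.arange(400.0, 901.0)
        sset = SpectrumSet(
            [Spectrum("s0", "Ulva_pertusa", wl, np.full(wl.size, 50.0))]
        )
        path = tmp_path / "wide.csv"
        write_spectra(sset, path, dialect="wide_csv")
        back = read_spectra(path, dialect="wide_csv")
        assert len(back[0]) == 501  # 900 - 400 + 1 integer wavelengths
        header = path.read_text().splitlines()[0]
        assert len(header.split(",")) == 3 + 501

    def test_empty_set_write_errors(self, tmp_path):
        with pytest.raises(SpectraError):
            write_spectra(SpectrumSet([]), tmp_path / "x.csv")

    def test_unknown_species_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "sample_id,species,dryness,wavelength_nm,reflectance_pct\n"
            "s0,Kelpus_maximus,wet,400,10.0\n"
        )
        with pytest.raises(SpectraError, match="Kelpus_maximus"):
            read_spectra(path)

    def test_non_numeric_reflectance_reports_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "sample_id,species,dryness,wavelength_nm,reflectance_pct\n"
            "s0,Ulva_pertusa,wet,400,10.0\n"
            "s0,Ulva_pertusa,wet,401,oops\n"
        )
        with pytest.raises(SpectraError, match="row 1"):
            read_spectra(path)

    def test_fractional_flag_scales_to_percent(self, tmp_path):
        path = tmp_path / "frac.csv"
        path.write_text(
            "sample_id,species,dryness,wavelength_nm,reflectance_pct\n"
            "s0,Ulva_pertusa,wet,400,0.10\n"
            "s0,Ulva_pertusa,wet,401,0.25\n"
        )
        sset = read_spectra(path, fractional=True)
        np.testing.assert_allclose(sset[0].reflectance, [10.0, 25.0])
        with pytest.raises(UnitScaleError):
            read_spectra(path)


class TestTrim:
    def test_instrument_range_trims_to_501(self):
        wl = np.arange(325.0, 1076.0)
        s = Spectrum("a", "Ulva_pertusa", wl, np.linspace(2, 90, wl.size))
        t = trim_wavelengths(s)
        assert t.wavelengths[0] == 400 and t.wavelengths[-1] == 900
        assert len(t) == 501

    def test_idempotent(self, ulva_ref):
        once = trim_wavelengths(ulva_ref)
        twice = trim_wavelengths(once)
        np.testing.assert_array_equal(once.wavelengths, twice.wavelengths)
        np.testing.assert_array_equal(once.reflectance, twice.reflectance)

    def test_degenerate_window_errors(self, ulva_ref):
        with pytest.raises(GridError):
            trim_wavelengths(ulva_ref, lo=500, hi=450)

    def test_disjoint_window_errors(self, ulva_ref):
        with pytest.raises(GridError):
            trim_wavelengths(ulva_ref, lo=1000, hi=1100)


class TestAverageReplicates:
    def test_identical_replicates_unchanged(self):
        wl = np.arange(400.0, 411.0)
        r = np.linspace(5, 50, wl.size)
        sset = SpectrumSet(
            [Spectrum(f"s{i}", "Ulva_pertusa", wl, r.copy(), dryness="wet") for i in range(10)]
        )
        avg = average_replicates(sset)
        assert len(avg) == 1
        np.testing.assert_array_equal(avg[0].reflectance, r)
        assert avg[0].sample_id.endswith("n=10")

    def test_symmetric_pair_averages_to_midpoint(self):
        wl = np.arange(400.0, 403.0)
        sset = SpectrumSet(
            [
                Spectrum("lo", "Ulva_pertusa", wl, np.zeros(3)),
                Spectrum("hi", "Ulva_pertusa", wl, np.full(3, 100.0)),
            ]
        )
        avg = average_replicates(sset)
        np.testing.assert_array_equal(avg[0].reflectance, np.full(3, 50.0))

    def test_mean_matches_hand_sum(self):
        wl = np.array([400.0, 401.0])
        vals = [3.0, 7.0, 11.0, 20.0, 39.0]
        sset = SpectrumSet(
            [Spectrum(f"s{i}", "Ulva_pertusa", wl, [v, v]) for i, v in enumerate(vals)]
        )
        avg = average_replicates(sset)
        assert avg[0].reflectance[0] == pytest.approx(sum(vals) / 5)

    def test_mixed_grids_error(self):
        sset = SpectrumSet(
            [
                Spectrum("a", "Ulva_pertusa", [400.0, 401.0], [10.0, 10.0]),
                Spectrum("b", "Ulva_pertusa", [400.0, 402.0], [10.0, 10.0]),
            ]
        )
        with pytest.raises(GridError):
            average_replicates(sset)


class TestResample:
    def test_identity_on_integer_grid(self, ulva_ref):
        out = resample_to_grid(ulva_ref)
        np.testing.assert_array_equal(out.wavelengths, ulva_ref.wavelengths)
        np.testing.assert_array_equal(out.reflectance, ulva_ref.reflectance)

    def test_linear_midpoint(self):
        s = Spectrum("a", "Ulva_pertusa", [400.0, 402.0], [0.0, 2.0])
        out = resample_to_grid(s)
        assert out.reflectance[list(out.wavelengths).index(401.0)] == pytest.approx(1.0)

    def test_jittered_grid_matches_piecewise_linear_oracle(self):
        rng = np.random.default_rng(3)
        base = np.arange(400.0, 431.0)
        wl = base + np.concatenate([[0], rng.uniform(-0.4, 0.4, base.size - 2), [0]])
        refl = rng.uniform(2, 90, wl.size)
        s = Spectrum("a", "Ulva_pertusa", wl, refl)
        out = resample_to_grid(s)

        def oracle(x):
            # brute-force piecewise-linear evaluation
            for i in range(wl.size - 1):
                if wl[i] <= x <= wl[i + 1]:
                    t = (x - wl[i]) / (wl[i + 1] - wl[i])
                    return refl[i] * (1 - t) + refl[i + 1] * t
            raise AssertionError(x)

        expected = np.array([oracle(x) for x in out.wavelengths])
        np.testing.assert_allclose(out.reflectance, expected, atol=1e-9)

    def test_too_few_points_errors(self):
        with pytest.raises(GridError):
            resample_to_grid(Spectrum("a", "Ulva_pertusa", [400.0], [10.0]))
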