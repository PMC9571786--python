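"""Spectrum container, I/O round-trips, normalization and 1D augmentations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ramangrade.spectra import (
    DEFAULT_GRID,
    RamanSpectrum,
    SpectraDataset,
    TASK_EG1_VS_G2G3,
    augment_noise,
    augment_shift,
    read_spectra_table,
    resample_to_grid,
    write_spectra_table,
    zscore_normalize,
)


def make_spectrum(values, grid=None, **kw):
    values = np.asarray(values, dtype=float)
    grid = np.arange(len(values), dtype=float) if grid is None else grid
    return RamanSpectrum(grid, values, **kw)


class TestRamanSpectrum:
    def test_rejects_non_monotonic_grid(self):
        with pytest.raises(ValueError, match="increasing"):
            RamanSpectrum([500.0, 400.0, 600.0], [1.0, 2.0, 3.0])

    def test_rejects_nonfinite_and_length_mismatch(self):
        with pytest.raises(ValueError):
            RamanSpectrum([1.0, 2.0], [np.nan, 1.0])
        with pytest.raises(ValueError):
            RamanSpectrum([1.0, 2.0, 3.0], [1.0, 2.0])

    def test_default_grid_spacing_is_2_invcm(self):
        # 1601 points over 200-3400 -> (3400-200)/1600 spacing
        assert len(DEFAULT_GRID) == 1601
        assert np.allclose(np.diff(DEFAULT_GRID), 2.0)


class TestTableIO:
    @pytest.mark.parametrize("layout", ["wide_rows", "wide_cols", "long"])
    def test_round_trip(self, tmp_path, layout, rng):
        grid = np.linspace(200, 260, 5)
        ds = SpectraDataset(
            [RamanSpectrum(grid, rng.standard_normal(5), f"P{i}", g, f"s{i}")
             for i, g in enumerate(["E", "G1", "G3"])], grid)
        path, meta = tmp_path / "t.csv", tmp_path / "m.csv"
        write_spectra_table(ds, path, layout, metadata=meta)
        back = read_spectra_table(path, layout, metadata=meta)
        assert len(back) == 3
        np.testing.assert_allclose(back.shared_grid, grid)
        for a, b in zip(ds, back):
            np.testing.assert_allclose(a.intensities, b.intensities)
            assert (a.patient_id, a.grade, a.spectrum_id) == \
                   (b.patient_id, b.grade, b.spectrum_id)

    def test_two_row_wide_parse(self, tmp_path):
        p = tmp_path / "w.csv"
        p.write_text("spectrum_id,200,210,220,230,240\na,1,2,3,4,5\nb,5,4,3,2,1\n")
        ds = read_spectra_table(p, "wide_rows")
        assert len(ds) == 2 and len(ds[0]) == 5

    def test_non_monotonic_header_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("spectrum_id,500,400,600\na,1,2,3\n")
        with pytest.raises(ValueError, match="increasing"):
            read_spectra_table(p, "wide_rows")

    def test_non_numeric_intensity_names_location(self, tmp_path):
        p = tmp_path / "bad2.csv"
        p.write_text("spectrum_id,200,210\na,1,oops\n")
        with pytest.raises(ValueError, match="row"):
            read_spectra_table(p, "wide_rows")

    def test_empty_dataset_round_trip(self, tmp_path):
        grid = np.linspace(200, 220, 3)
        ds = SpectraDataset([], grid)
        path = tmp_path / "empty.csv"
        write_spectra_table(ds, path, "wide_rows")
        assert len(read_spectra_table(path, "wide_rows")) == 0

    def test_long_layout_row_count(self, tmp_path):
        grid = np.linspace(200, 220, 3)
        ds = SpectraDataset([RamanSpectrum(grid, [1.0, 2, 3], spectrum_id="a")], grid)
        path = tmp_path / "l.csv"
        write_spectra_table(ds, path, "long")
        assert len(path.read_text().strip().splitlines()) == 4  # header + 3 rows

    def test_case_insensitive_and_unknown_grades(self, tmp_path):
        p, m = tmp_path / "t.csv", tmp_path / "m.csv"
        p.write_text("spectrum_id,200,210\na,1,2\nb,3,4\n")
        m.write_text("spectrum_id,patient_id,grade\na,P1,g1\nb,P2,weird\n")
        ds = read_spectra_table(p, "wide_rows", metadata=m)
        assert ds[0].grade == "G1" and ds[1].grade == "unknown"


class TestResample:
    def test_identity_on_same_grid(self, rng):
        sp = make_spectrum(rng.standard_normal(10))
        out = resample_to_grid(sp, sp.wavenumbers)
        np.testing.assert_allclose(out.intensities, sp.intensities)

    def test_linear_ramp_midpoints_exact(self):
        sp = make_spectrum(np.arange(5.0) * 2.0)
        mid = np.arange(4) + 0.5
        out = resample_to_grid(sp, mid)
        np.testing.assert_allclose(out.intensities, mid * 2.0)

    def test_disjoint_ranges_rejected(self):
        sp = make_spectrum([1.0, 2.0], grid=np.array([100.0, 110.0]))
        with pytest.raises(ValueError, match="overlap"):
            resample_to_grid(sp, np.array([500.0, 510.0]))


class TestZscore:
    def test_three_point_values(self):
        out = zscore_normalize(make_spectrum([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out.intensities, [-1.22474487, 0.0, 1.22474487])

    def test_constant_maps_to_zero_with_flag(self):
        out = zscore_normalize(make_spectrum([5.0, 5.0, 5.0]))
        assert out.degenerate
        np.testing.assert_array_equal(out.intensities, 0.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=40))
    def test_moments_and_idempotence(self, values):
        sp = make_spectrum(values)
        out = zscore_normalize(sp)
        if not out.degenerate:
            assert abs(out.intensities.mean()) < 1e-9
            assert abs(out.intensities.std() - 1.0) < 1e-9
            twice = zscore_normalize(out)
            np.testing.assert_allclose(twice.intensities, out.intensities,
                                       atol=1e-9)


class TestAugmentations:
    def test_zero_noise_is_identity(self, rng):
        sp = make_spectrum(rng.standard_normal(20))
        out = augment_noise(sp, 0.0, rng=rng)
        np.testing.assert_array_equal(out.intensities, sp.intensities)

    def test_noise_sigma_proportional_to_peak(self, rng):
        sp = make_spectrum(np.r_[np.full(99, 1.0), 100.0])
        diffs = np.concatenate([
            augment_noise(sp, 0.05, rng=rng).intensities - sp.intensities
            for _ in range(100)])  # 10^4 draws
        assert diffs.std() == pytest.approx(5.0, rel=0.03)

    def test_noise_seeded_reproducibility_and_purity(self):
        sp = make_spectrum(np.arange(10.0))
        a = augment_noise(sp, 0.1, rng=np.random.default_rng(7))
        b = augment_noise(sp, 0.1, rng=np.random.default_rng(7))
        np.testing.assert_array_equal(a.intensities, b.intensities)
        assert sp.intensities[0] == 0.0  # input unmodified

    def test_negative_scale_rejected(self):
        with pytest.raises(ValueError):
            augment_noise(make_spectrum([1.0, 2.0]), -0.1)

    def test_forced_shift_moves_impulse(self):
        x = np.zeros(30)
        x[10] = 1.0
        out = augment_shift(make_spectrum(x), 5, k=2)
        assert out.intensities[12] == 1.0 and out.intensities[10] == 0.0

    def test_shift_bound_and_grid_preserved(self, rng):
        sp = make_spectrum(rng.standard_normal(50))
        for _ in range(200):
            out = augment_shift(sp, 5, rng=rng)
            assert len(out) == len(sp)
            np.testing.assert_array_equal(out.wavenumbers, sp.wavenumbers)
            # any shift is recoverable: out matches sp shifted by some |k| <= 5
            ok = any(np.array_equal(out.intensities,
                                    augment_shift(sp, 5, k=k).intensities)
                     for k in range(-5, 6))
            assert ok

    def test_shift_inverse_recovers_interior(self, rng):
        sp = make_spectrum(rng.standard_normal(40))
        k = 3
        back = augment_shift(augment_shift(sp, 5, k=k), 5, k=-k)
        np.testing.assert_array_equal(back.intensities[k:-k],
                                      sp.intensities[k:-k])

    def test_shift_too_large_rejected(self):
        with pytest.raises(ValueError):
            augment_shift(make_spectrum([1.0, 2.0, 3.0]), 3)


def test_binary_task_labeling():
    assert TASK_EG1_VS_G2G3.label("E") == 1
    assert TASK_EG1_VS_G2G3.label("G1") == 1
    assert TASK_EG1_VS_G2G3.label("G2") == 0
    assert TASK_EG1_VS_G2G3.label("G3") == 0
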