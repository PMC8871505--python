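"""Synthetic dose fields and the gel/film forward models."""

import math

import numpy as np
import pytest

from gelqa import (
    DoseGrid,
    FilmResponseModel,
    GelResponseModel,
    GridSpec,
    ShotSpec,
    extract_profile,
    fwhm,
    film_forward,
    make_shot_dose_field,
    mri_forward,
)
from gelqa.synthetic import NOMINAL_FWHM_MM, default_mri_grid

CENTER = (100.0, 100.0, 100.0)


def iso_grid(extent, spacing, center=CENTER):
    n = 2 * int(round(extent / spacing)) + 1
    return GridSpec(
        (n, n, n),
        (spacing, spacing, spacing),
        tuple(c - spacing * (n // 2) for c in center),
    )


class TestShotDoseField:
    def test_center_dose_is_prescription_over_isodose(self, truth_4mm, small_grid):
        # 4 Gy prescribed to the 50% isodose -> 8 Gy at the shot center
        idx = small_grid.nearest_index(CENTER)
        assert truth_4mm.dose[idx] == pytest.approx(8.0, abs=1e-12)

    @pytest.mark.parametrize("collimator", [4, 8, 16])
    def test_fwhm_matches_nominal_within_spacing(self, collimator):
        nominal = NOMINAL_FWHM_MM[collimator]
        grid = iso_grid(2.0 * nominal, 0.5)
        field = make_shot_dose_field([ShotSpec(collimator=collimator)], grid)
        measured = fwhm(extract_profile(field, "Z", CENTER, normalize=True)).fwhm
        assert abs(measured - nominal) < 0.5

    def test_fine_grid_fwhm_within_tenth_mm(self):
        grid = iso_grid(12.0, 0.25)
        field = make_shot_dose_field([ShotSpec(collimator=4)], grid)
        measured = fwhm(extract_profile(field, "Z", CENTER)).fwhm
        assert measured == pytest.approx(6.2, abs=0.1)

    def test_field_symmetric_about_center(self, truth_4mm, small_grid):
        ix, iy, iz = small_grid.nearest_index(CENTER)
        profile = truth_4mm.dose[ix, iy, :]
        assert np.allclose(profile, profile[::-1], atol=1e-12)

    def test_two_shots_superpose_additively(self, small_grid):
        a = ShotSpec(collimator=4, center=CENTER)
        b = ShotSpec(collimator=8, center=(100.0, 100.0, 104.0), prescription_dose=2.0)
        fa = make_shot_dose_field([a], small_grid).dose
        fb = make_shot_dose_field([b], small_grid).dose
        fab = make_shot_dose_field([a, b], small_grid).dose
        np.testing.assert_array_equal(fab, fa + fb)

    def test_center_outside_grid_rejected(self, small_grid):
        with pytest.raises(ValueError, match="outside"):
            make_shot_dose_field(
                [ShotSpec(collimator=4, center=(200.0, 100.0, 100.0))], small_grid
            )

    def test_unresolvable_fwhm_rejected(self):
        grid = iso_grid(12.0, 4.0)
        with pytest.raises(ValueError, match="unresolvable"):
            make_shot_dose_field([ShotSpec(collimator=4)], grid)  # 6.2 < 2 * 4.0

    def test_invalid_shot_parameters_rejected(self):
        with pytest.raises(ValueError):
            ShotSpec(collimator=5)
        with pytest.raises(ValueError):
            ShotSpec(collimator=4, prescription_isodose=0.0)
        with pytest.raises(ValueError):
            ShotSpec(collimator=4, output_factor=1.2)


class TestGelForwardModel:
    def test_zero_dose_gives_uniform_baseline_signal(self, small_grid, gel):
        dose = DoseGrid(np.zeros(small_grid.shape), small_grid)
        pair = mri_forward(dose, gel, seed=0)
        expected1 = gel.s0 * math.exp(-gel.r2_baseline * 0.089)
        expected2 = gel.s0 * math.exp(-gel.r2_baseline * 0.145)
        assert np.allclose(pair.s1, expected1, rtol=1e-12)
        assert np.allclose(pair.s2, expected2, rtol=1e-12)

    def test_signal_matches_scalar_forward_formula(self, gel):
        # choose the dose at which R2 reaches 20 s^-1, then S(89 ms) = s0 e^-1.78
        target_delta = 20.0 - gel.r2_baseline
        dose_value = -gel.saturation_dose * math.log(
            1.0 - target_delta / (gel.sensitivity_abs * gel.saturation_dose)
        )
        grid = GridSpec((1, 1, 1), (1, 1, 1), (0, 0, 0))
        pair = mri_forward(DoseGrid(np.full((1, 1, 1), dose_value), grid), gel, seed=0)
        assert pair.s1[0, 0, 0] == pytest.approx(gel.s0 * math.exp(-1.78), rel=1e-12)

    def test_default_protocol_echo_times(self, truth_4mm, gel):
        pair = mri_forward(truth_4mm, gel, seed=0)
        assert (pair.te1, pair.te2) == (89.0, 145.0)

    def test_seed_determinism_and_noise_variation(self, truth_4mm):
        noisy = GelResponseModel(noise_sigma=10.0)
        a = mri_forward(truth_4mm, noisy, seed=7)
        b = mri_forward(truth_4mm, noisy, seed=7)
        c = mri_forward(truth_4mm, noisy, seed=8)
        np.testing.assert_array_equal(a.s1, b.s1)
        np.testing.assert_array_equal(a.s2, b.s2)
        assert not np.array_equal(a.s1, c.s1)

    def test_low_dose_response_linear_within_five_percent(self, gel):
        doses = np.linspace(0.5, gel.saturation_dose / 10.0, 20)
        r2 = gel.r2_of_dose(doses)
        linear = gel.r2_baseline + gel.sensitivity_abs * doses
        rel = np.abs(r2 - linear) / (gel.sensitivity_abs * doses)
        assert np.all(rel < 0.05)

    def test_equal_echo_times_rejected(self, truth_4mm, gel):
        with pytest.raises(ValueError, match="distinct"):
            mri_forward(truth_4mm, gel, te_pair=(89.0, 89.0))

    def test_negative_dose_rejected(self, small_grid, gel):
        dose = DoseGrid(np.zeros(small_grid.shape), small_grid)
        dose.dose[0, 0, 0] = -1.0
        with pytest.raises(ValueError, match="nonnegative"):
            mri_forward(dose, gel)


class TestFilmForwardModel:
    def test_zero_dose_gives_unexposed_pixel_value(self):
        film = FilmResponseModel()
        scan = film_forward(np.zeros((5, 5)), film, seed=0)
        assert np.allclose(scan.pixels, film.pv0)
        assert film.net_od(0.0) == 0.0

    def test_low_dose_od_matches_slope_series(self):
        # first-order expansion: OD(D) ~= low_dose_slope * D for small D
        film = FilmResponseModel()
        assert film.low_dose_slope == pytest.approx(0.100, abs=1e-12)
        assert film.net_od(0.1) == pytest.approx(0.010, rel=0.01)

    def test_od_monotone_nondecreasing_in_dose(self):
        film = FilmResponseModel()
        doses = np.linspace(0.0, 50.0, 200)
        od = film.net_od(doses)
        assert np.all(np.diff(od) >= 0)

    def test_ebt3_slope(self):
        assert FilmResponseModel.ebt3().low_dose_slope == pytest.approx(0.101, abs=1e-9)

    def test_pixel_values_clipped_to_valid_range(self):
        film = FilmResponseModel(noise_sigma=50000.0)
        scan = film_forward(np.zeros((20, 20)), film, seed=1)
        assert scan.pixels.min() >= 0.0
        assert scan.pixels.max() <= film.pv_max

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            film_forward(np.full((3, 3), -0.1), FilmResponseModel())

    def test_scan_carries_1200dpi_pixel_spacing(self):
        scan = film_forward(np.zeros((3, 3)), FilmResponseModel(), seed=0)
        assert scan.pixel_spacing == pytest.approx(25.4 / 1200.0)
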