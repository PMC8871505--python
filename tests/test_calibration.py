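"""Calibration fitting, inversion, and linear-range detection."""

import numpy as np
import pytest

from gelqa import (
    CalibrationCurve,
    CalibrationPoint,
    film_net_od,
    fit_dose_response,
    invert_response,
    predict_response,
)
from gelqa.calibration import points_from_csv, points_to_csv


def make_points(doses, responses, sds=None):
    sds = sds if sds is not None else [0.0] * len(doses)
    return [CalibrationPoint(d, r, s) for d, r, s in zip(doses, responses, sds)]


class TestFilmNetOD:
    def test_unexposed_film_has_zero_od(self):
        assert film_net_od(40000.0, 40000.0) == 0.0

    def test_decade_attenuation_gives_unit_od(self):
        assert film_net_od(40000.0, 4000.0) == pytest.approx(1.0, abs=1e-14)

    def test_nonpositive_pixels_rejected(self):
        with pytest.raises(ValueError):
            film_net_od(40000.0, 0.0)
        with pytest.raises(ValueError):
            film_net_od(-1.0, 100.0)


def normal_equations_oracle(doses, responses, sds):
    """Brute-force weighted normal equations, written independently."""
    w = 1.0 / np.asarray(sds) ** 2 if all(s > 0 for s in sds) else np.ones(len(doses))
    d = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    sw, swd, swd2 = w.sum(), (w * d).sum(), (w * d * d).sum()
    swy, swdy = (w * y).sum(), (w * d * y).sum()
    det = sw * swd2 - swd**2
    slope = (sw * swdy - swd * swy) / det
    intercept = (swd2 * swy - swd * swdy) / det
    return slope, intercept


class TestFitDoseResponse:
    def test_exact_line_recovered(self):
        curve = fit_dose_response(make_points([0, 2, 4], [0.0, 0.2, 0.4]), 4.0)
        assert curve.slope == pytest.approx(0.100, abs=1e-12)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_normal_equations_oracle(self, rng, weighted):
        doses = [0.0, 2.0, 4.0, 6.0, 8.0, 10.0]
        responses = [0.084 * d + rng.normal(0, 0.01) for d in doses]
        sds = list(rng.uniform(0.005, 0.02, len(doses))) if weighted else [0.0] * len(doses)
        curve = fit_dose_response(make_points(doses, responses, sds), 10.0)
        slope, intercept = normal_equations_oracle(doses, responses, sds)
        assert curve.slope == pytest.approx(slope, abs=1e-10)
        assert curve.intercept == pytest.approx(intercept, abs=1e-10)

    def test_parameter_recovery_bias_and_coverage(self):
        """Over many simulated calibrations the fitted slope is unbiased
        (<1%) and the +/-2 SE interval covers the truth >= 90% of the time."""
        true_slope, sd = 0.084, 0.005
        doses = np.array([0.0, 2.0, 4.0, 6.0, 8.0, 10.0])
        rng = np.random.default_rng(2024)
        slopes, covered = [], 0
        for _ in range(200):
            responses = true_slope * doses + rng.normal(0.0, sd, doses.size)
            curve = fit_dose_response(
                make_points(doses, responses, [sd] * doses.size), 10.0
            )
            slopes.append(curve.slope)
            if abs(curve.slope - true_slope) <= 2.0 * curve.slope_se:
                covered += 1
        assert abs(np.mean(slopes) - true_slope) / true_slope < 0.01
        assert covered / 200 >= 0.90

    def test_auto_range_detects_saturation_onset(self):
        """Data linear to 8 Gy then drooping should be cut at <= 8 Gy in at
        least 90% of noisy replicates."""
        slope, sd = 0.084, 0.003
        doses = np.array([0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 20.0, 40.0])
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 50
        for _ in range(n_rep):
            clean = np.where(
                doses <= 8.0,
                slope * doses,
                slope * (8.0 + 2.0 * (1.0 - np.exp(-(doses - 8.0) / 2.0))),
            )
            responses = clean + rng.normal(0.0, sd, doses.size)
            curve = fit_dose_response(
                make_points(doses, responses, [sd] * doses.size), "auto"
            )
            if curve.linear_max_dose <= 8.0:
                hits += 1
        assert hits / n_rep >= 0.90

    def test_auto_range_keeps_full_window_for_linear_data(self):
        doses = np.array([0.0, 2.0, 4.0, 6.0, 8.0, 10.0])
        rng = np.random.default_rng(11)
        responses = 0.1 * doses + rng.normal(0, 0.002, doses.size)
        curve = fit_dose_response(
            make_points(doses, responses, [0.002] * doses.size), "auto"
        )
        assert curve.linear_max_dose == 10.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3 calibration points"):
            fit_dose_response(make_points([0, 2], [0.0, 0.2]), 4.0)

    def test_degenerate_doses_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_dose_response(make_points([2, 2, 2], [0.1, 0.2, 0.3]), 4.0)


class TestInvertResponse:
    @pytest.fixture()
    def curve(self):
        return CalibrationCurve(
            points=make_points([0, 5, 10], [0.0, 0.42, 0.84]),
            slope=0.084,
            intercept=0.0,
            slope_se=0.001,
            intercept_se=0.001,
            linear_max_dose=10.0,
        )

    def test_response_at_intercept_gives_zero_dose(self, curve):
        result = invert_response(curve, curve.intercept)
        assert result.item() == (0.0, False, False)

    def test_arithmetic_example(self, curve):
        dose, saturated, clipped = invert_response(curve, 0.42).item()
        assert dose == pytest.approx(5.0, abs=1e-12)
        assert not saturated and not clipped

    def test_round_trip_exact_within_linear_range(self, curve):
        for d in np.linspace(0.0, 10.0, 11):
            assert invert_response(curve, predict_response(curve, d)).dose == pytest.approx(
                d, abs=1e-12
            )

    def test_saturated_and_clipped_flags(self, curve):
        res = invert_response(curve, np.array([1.0, -0.1]))
        assert res.saturated[0] and not res.clipped[0]
        assert res.clipped[1] and res.dose[1] == 0.0

    def test_zero_slope_rejected(self, curve):
        curve.slope = 0.0
        with pytest.raises(ValueError, match="zero-slope"):
            invert_response(curve, 0.5)


def test_calibration_csv_round_trip(tmp_path):
    points = make_points([0.0, 2.0, 4.0], [0.0, 0.171, 0.344], [0.0, 0.01, 0.012])
    path = tmp_path / "cal.csv"
    points_to_csv(points, path)
    back = points_from_csv(path)
    assert [(p.dose, p.response, p.response_sd) for p in back] == [
        (p.dose, p.response, p.response_sd) for p in points
    ]
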