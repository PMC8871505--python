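"""Dose-map reconstruction by calibration inversion, and isodose labeling."""

import numpy as np
import pytest

from gelqa import (
    DoseGrid,
    GelResponseModel,
    GridSpec,
    compute_r2_map,
    fit_dose_response,
    mri_forward,
    normalize_response,
    reconstruct_dose_map,
    render_isodose_map,
    extract_profile,
    fwhm,
)
from gelqa.pipeline import simulate_gel_calibration

CENTER = (100.0, 100.0, 100.0)


@pytest.fixture(scope="module")
def gel_curve():
    gel = GelResponseModel()  # noise-free
    points = simulate_gel_calibration([0.0, 2.0, 4.0, 6.0, 8.0, 10.0], gel, seed=0)
    return fit_dose_response(points, 10.0)


def reconstruct_from_truth(truth, gel, curve, background_mask):
    pair = mri_forward(truth, gel, seed=0)
    r2 = compute_r2_map(pair, signal_floor=0.0)
    r2n = normalize_response(r2, background_mask)
    return reconstruct_dose_map(r2n, curve)


class TestReconstruction:
    def test_noiseless_end_to_end_recovers_truth_within_one_percent(
        self, truth_4mm, small_grid, gel_curve
    ):
        ys, zs = np.meshgrid(small_grid.coords(1), small_grid.coords(2), indexing="ij")
        background = np.broadcast_to(
            np.hypot(ys - CENTER[1], zs - CENTER[2]) > 10.0, small_grid.shape
        )
        recon = reconstruct_from_truth(truth_4mm, GelResponseModel(), gel_curve, background)
        in_range = truth_4mm.dose <= gel_curve.linear_max_dose
        err = np.abs(recon.dose - truth_4mm.dose)[in_range & recon.valid]
        assert err.max() < 0.01 * truth_4mm.dmax

    def test_vial_set_maxima_ordered_and_saturation_flagged(self, gel_curve):
        # planar dose-mapping pilot: vials at 10, 13, 18.6, 26 and 43.3 Gy
        plan_doses = [10.0, 13.0, 18.6, 26.0, 43.3]
        gel = GelResponseModel()
        grid = GridSpec((1, 5, 5), (2.5, 0.5, 0.5), (0.0, 0.0, 0.0))
        maxima, top_flags = [], []
        for dose in plan_doses:
            truth = DoseGrid(np.full(grid.shape, dose), grid)
            pair = mri_forward(truth, gel, seed=0)
            r2 = compute_r2_map(pair, signal_floor=0.0)
            # vials are read against a separately-scanned zero-dose reference
            ref = DoseGrid(np.zeros(grid.shape), grid)
            ref_r2 = compute_r2_map(mri_forward(ref, gel, seed=0), signal_floor=0.0)
            r2.r2 = (r2.r2 - ref_r2.r2.mean()) / ref_r2.r2.mean()
            r2.normalized = True
            recon = reconstruct_dose_map(r2, gel_curve)
            maxima.append(recon.dose.max())
            top_flags.append(bool(recon.saturated.all()))
        assert all(a < b for a, b in zip(maxima, maxima[1:]))
        # the 10 Gy vial stays inside the linear range; the hottest three do not
        assert not top_flags[0]
        assert all(top_flags[2:])

    def test_all_invalid_response_yields_all_invalid_map(self, gel_curve):
        from gelqa.r2map import R2Map

        grid = GridSpec((2, 2, 2), (1, 1, 1), (0, 0, 0))
        r2 = R2Map(
            r2=np.full(grid.shape, np.nan),
            valid=np.zeros(grid.shape, dtype=bool),
            grid=grid,
            normalized=True,
        )
        recon = reconstruct_dose_map(r2, gel_curve)
        assert not recon.valid.any()
        assert not recon.saturated.any()

    def test_response_kind_mismatch_rejected(self, gel_curve):
        from gelqa.core import FilmScan

        scan = FilmScan(pixels=np.full((3, 3), 30000.0), pixel_spacing=0.5)
        scan.od = np.zeros((3, 3))
        with pytest.raises(ValueError, match="does not match"):
            reconstruct_dose_map(scan, gel_curve)  # gel curve on a film scan

    def test_grid_geometry_carried_through(self, truth_4mm, small_grid, gel_curve):
        background = np.zeros(small_grid.shape, dtype=bool)
        background[:, :2, :] = True
        recon = reconstruct_from_truth(truth_4mm, GelResponseModel(), gel_curve, background)
        assert recon.grid == small_grid


class TestIsodoseRendering:
    def test_concentric_levels_are_nested(self, truth_4mm):
        labels, legend = render_isodose_map(truth_4mm, [90.0, 50.0, 10.0])
        assert set(np.unique(labels)) == {0, 1, 2, 3}
        assert (labels >= 2).sum() < (labels >= 1).sum()
        assert (labels == 3).sum() < (labels >= 2).sum()
        # every 90% voxel sits inside the 50% region, every 50% inside 10%
        assert np.all(labels[labels == 3] >= 2)
        assert legend[3] == 90.0 and legend[1] == 10.0

    def test_uniform_field_entirely_top_label(self):
        grid = GridSpec((2, 3, 3), (1, 1, 1), (0, 0, 0))
        uniform = DoseGrid(np.full(grid.shape, 5.0), grid)
        labels, _ = render_isodose_map(uniform, [90.0, 50.0])
        assert np.all(labels == 2)

    def test_half_level_band_diameter_equals_fwhm(self, truth_4mm, small_grid):
        labels, _ = render_isodose_map(truth_4mm, [50.0])
        ix, iy, _ = small_grid.nearest_index(CENTER)
        z = small_grid.coords(2)[labels[ix, iy, :] >= 1]
        diameter = z.max() - z.min() + small_grid.spacing[2]
        reference = fwhm(extract_profile(truth_4mm, "Z", CENTER)).fwhm
        assert abs(diameter - reference) <= small_grid.spacing[2]

    def test_monotone_labeling(self, truth_4mm):
        # raising doses below the half-maximum core (normalization reference
        # unchanged) can only raise band labels, never lower them
        labels, _ = render_isodose_map(truth_4mm, [90.0, 50.0, 10.0])
        boosted = truth_4mm.copy()
        cool = boosted.dose < 0.4 * boosted.dose.max()
        boosted.dose[cool] += 0.05 * boosted.dose.max()
        boosted_labels, _ = render_isodose_map(boosted, [90.0, 50.0, 10.0])
        assert np.all(boosted_labels >= labels)

    def test_empty_levels_rejected(self, truth_4mm):
        with pytest.raises(ValueError, match="nonempty"):
            render_isodose_map(truth_4mm, [])

    def test_nonmonotone_levels_rejected(self, truth_4mm):
        with pytest.raises(ValueError, match="decreasing"):
            render_isodose_map(truth_4mm, [50.0, 90.0])
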