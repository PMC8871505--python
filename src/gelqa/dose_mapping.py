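"""Dose-map reconstruction from response maps and isodose rendering.

Reconstruction is per-voxel inversion of the fitted calibration line;
voxels whose response is invalid stay invalid, voxels inverting above the
linear range are flagged saturated.  Isodose rendering labels each voxel
with the highest isodose level (% of the robust maximum) it reaches, giving
nested bands.
"""

from __future__ import annotations

from typing import Sequence, Union

import numpy as np

from .calibration import CalibrationCurve, invert_response
from .core import DoseGrid, FilmScan, GridSpec
from .r2map import R2Map

__all__ = ["reconstruct_dose_map", "render_isodose_map"]

#: Percentile of valid dose used as the "% of Dmax" normalization reference;
#: robust against single-voxel noise spikes.
ROBUST_MAX_PERCENTILE = 99.5


def _response_array(response: Union[R2Map, FilmScan]):
    if isinstance(response, R2Map):
        return response.r2, response.valid, response.grid, response.response_kind
    if isinstance(response, FilmScan):
        if response.od is None:
            raise ValueError("film scan carries no net-OD array; compute it first")
        od = response.od
        grid = GridSpec(
            shape=od.shape,
            spacing=(response.pixel_spacing, response.pixel_spacing),
            origin=(0.0, 0.0),
        )
        return od, np.isfinite(od), grid, "film_od"
    raise TypeError(f"unsupported response container: {type(response).__name__}")


def reconstruct_dose_map(
    response: Union[R2Map, FilmScan], curve: CalibrationCurve
) -> DoseGrid:
    """Reconstruct a dose map by inverting a calibration curve per voxel.

    The response kind of the map and the curve's ``method`` tag must agree
    (a film OD curve cannot invert a gel R2 map).  Grid geometry is carried
    through unchanged; provenance records the source.
    """
    values, valid, grid, kind = _response_array(response)
    if kind != curve.method:
        raise ValueError(
            f"response kind {kind!r} does not match calibration method {curve.method!r}"
        )
    inv = invert_response(curve, np.where(valid, values, np.nan))
    dose = np.where(valid, inv.dose, 0.0)
    saturated = np.where(valid, inv.saturated, False)
    provenance = "film" if kind == "film_od" else "gel-MRI"
    return DoseGrid(dose=dose, grid=grid, valid=valid, saturated=saturated, provenance=provenance)


def render_isodose_map(dose: DoseGrid, levels: Sequence[float]) -> tuple[np.ndarray, dict]:
    """Label voxels by the highest isodose level (% of robust Dmax) reached.

    Returns ``(labels, legend)``: ``labels`` holds 0 for below the lowest
    level (or invalid) and ``i`` for the band of ``levels[i-1]`` counted from
    the lowest level upward, so bands are nested; ``legend`` maps label to
    level.

    ``levels`` must be strictly decreasing percentages in (0, 100].
    """
    levels = [float(l) for l in levels]
    if len(levels) == 0:
        raise ValueError("levels must be a nonempty list")
    if any(not 0 < l <= 100 for l in levels):
        raise ValueError("levels must lie in (0, 100]")
    if any(a >= b for a, b in zip(levels[1:], levels[:-1])):
        raise ValueError("levels must be strictly decreasing")
    ref = dose.robust_max(ROBUST_MAX_PERCENTILE)
    if ref <= 0:
        raise ValueError("maximum dose must be positive to define isodose levels")
    labels = np.zeros(dose.dose.shape, dtype=np.int32)
    ascending = sorted(levels)  # lowest level -> label 1
    for i, level in enumerate(ascending, start=1):
        labels[dose.valid & (dose.dose >= level / 100.0 * ref)] = i
    legend = {int(i): lvl for i, lvl in enumerate(ascending, start=1)}
    legend[0] = None
    return labels, legend
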