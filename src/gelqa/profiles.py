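"""1D dose profiles along stereotactic axes and FWHM analysis.

The spatial-accuracy metric of the QA procedure is the full width at half
maximum of the single-shot profile, compared against the planning-system
reference width.  Half-maximum crossings are located by linear interpolation
between the bracketing samples on each side of the peak.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import DoseGrid

__all__ = [
    "Profile1D",
    "FWHMResult",
    "extract_profile",
    "fwhm",
    "fwhm_deviation",
    "profile_to_csv",
    "fwhm_table_to_csv",
]

_AXIS_INDEX = {"X": 0, "Y": 1, "Z": 2, "x": 0, "y": 1, "z": 2}


@dataclass
class Profile1D:
    """Sampled 1D profile: positions in mm (uniform, increasing), values in
    dose (Gy) or normalized percent."""

    positions: np.ndarray
    values: np.ndarray
    axis: str = "Z"
    through: tuple = ()

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape or self.positions.ndim != 1:
            raise ValueError("positions and values must be equal-length 1D arrays")
        d = np.diff(self.positions)
        if len(d) and (np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-9)):
            raise ValueError("positions must be strictly increasing and uniformly spaced")

    @property
    def spacing(self) -> float:
        return float(self.positions[1] - self.positions[0])


@dataclass
class FWHMResult:
    fwhm: float
    left_crossing: float
    right_crossing: float
    peak_value: float
    peak_position: float

    def __post_init__(self):
        if not self.left_crossing < self.right_crossing:
            raise ValueError("left crossing must precede right crossing")


def extract_profile(
    dose: DoseGrid, axis: str, through: Sequence[float], normalize: bool = False
) -> Profile1D:
    """Extract the dose profile along one axis through a stereotactic point.

    Samples the line of voxel centers nearest to ``through`` (no
    interpolation across the transverse axes); with ``normalize`` the values
    are scaled so the maximum is exactly 100.
    """
    ax = _AXIS_INDEX.get(str(axis))
    if ax is None:
        raise ValueError(f"axis must be X, Y or Z, got {axis!r}")
    if not dose.grid.contains_point(through):
        raise ValueError(f"point {tuple(through)} lies outside the grid")
    idx = list(dose.grid.nearest_index(through))
    sl = tuple(slice(None) if a == ax else idx[a] for a in range(3))
    values = np.array(dose.dose[sl], dtype=float)
    positions = dose.grid.coords(ax)
    if normalize:
        peak = values.max()
        if peak <= 0:
            raise ValueError("cannot normalize a profile with nonpositive maximum")
        values = values * (100.0 / peak)
    return Profile1D(positions=positions, values=values, axis="XYZ"[ax], through=tuple(through))


def fwhm(profile: Profile1D) -> FWHMResult:
    """Full width at half maximum of a single-peaked profile.

    The half level is half the observed peak sample (ties broken leftmost).
    Each crossing is linearly interpolated between the last sample above the
    half level and its neighbour below, moving outward from the peak; a
    profile that never falls below half maximum on a side is rejected as
    truncated.
    """
    v, x = profile.values, profile.positions
    ipeak = int(np.argmax(v))
    peak = float(v[ipeak])
    half = peak / 2.0

    def crossing(indices) -> float:
        prev = ipeak
        for i in indices:
            if v[i] < half:
                # interpolate between samples prev (>= half) and i (< half)
                return float(
                    x[prev] + (x[i] - x[prev]) * (half - v[prev]) / (v[i] - v[prev])
                )
            prev = i
        raise ValueError(
            f"profile does not fall below half maximum on one side "
            f"(truncated at {x[indices[-1]] if len(indices) else x[ipeak]:.3g} mm)"
        )

    left = crossing(range(ipeak - 1, -1, -1)) if ipeak > 0 else None
    right = crossing(range(ipeak + 1, len(v))) if ipeak < len(v) - 1 else None
    if left is None or right is None:
        raise ValueError("peak lies on the profile boundary; profile truncated")
    return FWHMResult(
        fwhm=right - left,
        left_crossing=left,
        right_crossing=right,
        peak_value=peak,
        peak_position=float(x[ipeak]),
    )


def fwhm_deviation(reference: float, measured: float, denominator: str = "reference") -> float:
    """Percent deviation between a reference and a measured FWHM.

    ``denominator`` selects the convention: ``"reference"`` divides by the
    planning-system width, ``"measured"`` by the experimental one.  The
    result is reported to one decimal, matching QA-table practice.
    """
    if reference <= 0 or measured <= 0:
        raise ValueError("widths must be positive")
    if denominator not in ("reference", "measured"):
        raise ValueError("denominator must be 'reference' or 'measured'")
    den = reference if denominator == "reference" else measured
    return round(100.0 * abs(reference - measured) / den, 1)


def profile_to_csv(profile: Profile1D, path) -> None:
    """Write a profile as two columns (position_mm, value)."""
    with open(path, "w", newline="") as fh:
        fh.write("position_mm,value\n")
        for x, v in zip(profile.positions, profile.values):
            fh.write(f"{x:.17g},{v:.17g}\n")


def fwhm_table_to_csv(rows: Sequence[dict], path) -> None:
    """Write the per-collimator FWHM comparison table (the QA report's
    deviation table) as CSV, one row per collimator and method."""
    columns = (
        "collimator_mm",
        "method",
        "reference_fwhm_mm",
        "measured_fwhm_mm",
        "deviation_pct_reference",
        "deviation_pct_measured",
    )
    with open(path, "w", newline="") as fh:
        fh.write(",".join(columns) + "\n")
        for row in rows:
            fh.write(",".join(str(row[c]) for c in columns) + "\n")
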