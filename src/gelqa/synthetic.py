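"""Synthetic single-shot dose fields and forward models for gel MRI and film.

The generator produces the study conditions of a Gamma Knife QA experiment:
radially symmetric single-shot dose fields for the 4/8/16 mm collimators
(flat top with error-function penumbra, calibrated so the profile FWHM
equals the planning-system nominal), a dual-echo spin-echo MRI forward model
of irradiated nPAG polymer gel (mono-exponential signal decay, dose-dependent
R2, Rician magnitude noise) and a flatbed-scanner model of radiochromic film
(saturating-exponential net optical density, additive pixel noise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf

from .core import DoseGrid, EchoImagePair, FilmScan, GridSpec

__all__ = [
    "ShotSpec",
    "GelResponseModel",
    "FilmResponseModel",
    "make_shot_dose_field",
    "mri_forward",
    "film_forward",
    "default_mri_grid",
]

#: Planning-system reference FWHM (mm) of the Z-axis profile per collimator.
NOMINAL_FWHM_MM = {4: 6.2, 8: 11.3, 16: 19.8}
#: Effective output factor per collimator (relative to 16 mm).
OUTPUT_FACTOR = {4: 0.814, 8: 0.90, 16: 1.00}
#: Echo times (ms) of the dual-echo evaluation protocol.
DEFAULT_TE_PAIR = (89.0, 145.0)


@dataclass(frozen=True)
class ShotSpec:
    """One Gamma Knife shot.

    ``prescription_dose`` is the dose (Gy) delivered to the prescription
    isodose surface; with the usual Gy@50% convention the dose at the shot
    center is ``prescription_dose / prescription_isodose`` (twice the
    prescription).  ``nominal_fwhm`` fixes the width of the generated field;
    ``penumbra_sigma`` the steepness of its error-function edges.
    """

    collimator: int
    center: tuple[float, float, float] = (100.0, 100.0, 100.0)
    prescription_dose: float = 4.0
    prescription_isodose: float = 0.5
    output_factor: Optional[float] = None
    dose_rate: float = 2.52
    nominal_fwhm: Optional[float] = None
    penumbra_sigma: float = 1.0

    def __post_init__(self):
        if self.collimator not in NOMINAL_FWHM_MM:
            raise ValueError(f"collimator must be one of {sorted(NOMINAL_FWHM_MM)} mm")
        if not 0 < self.prescription_isodose <= 1:
            raise ValueError("prescription_isodose must lie in (0, 1]")
        if self.output_factor is None:
            object.__setattr__(self, "output_factor", OUTPUT_FACTOR[self.collimator])
        if not 0 < self.output_factor <= 1:
            raise ValueError("output_factor must lie in (0, 1]")
        if self.nominal_fwhm is None:
            object.__setattr__(self, "nominal_fwhm", NOMINAL_FWHM_MM[self.collimator])
        if self.nominal_fwhm <= 0:
            raise ValueError("nominal_fwhm must be > 0")
        if self.penumbra_sigma <= 0:
            raise ValueError("penumbra_sigma must be > 0")

    @property
    def center_dose(self) -> float:
        """Dose (Gy) at the shot center."""
        return self.prescription_dose / self.prescription_isodose

    @property
    def beam_on_time_min(self) -> float:
        """Bookkeeping: beam-on minutes to deliver the center dose.

        The output factor scales the effective dose rate; it does not alter
        the normalized field shape.
        """
        return self.center_dose / (self.dose_rate * self.output_factor)


def _flat_top_profile(r, radius: float, sigma: float):
    """Radial profile of a flat top of half-width ``radius`` with Gaussian
    (error-function) penumbra of scale ``sigma``; equals the 1D convolution
    of a boxcar with a Gaussian evaluated at radius ``r``."""
    s = sigma * math.sqrt(2.0)
    return 0.5 * (erf((radius - r) / s) + erf((radius + r) / s))


def _solve_flat_top_radius(fwhm: float, sigma: float) -> float:
    """Flat-top half-width such that the profile's FWHM is exactly ``fwhm``."""

    def half_max_gap(radius):
        return _flat_top_profile(fwhm / 2.0, radius, sigma) - 0.5 * _flat_top_profile(
            0.0, radius, sigma
        )

    lo, hi = 1e-6 * fwhm, 4.0 * fwhm
    return brentq(half_max_gap, lo, hi, xtol=1e-12)


def make_shot_dose_field(shots: Sequence[ShotSpec] | ShotSpec, grid: GridSpec) -> DoseGrid:
    """Superpose single-shot dose fields on a grid.

    Each shot contributes a radially symmetric flat-top field with
    error-function penumbra whose central-profile FWHM equals the shot's
    ``nominal_fwhm`` (the flat-top radius is solved for, given the penumbra
    sigma), scaled so the dose at the shot center equals
    ``prescription_dose / prescription_isodose``.  Shots superpose additively.

    Raises
    ------
    ValueError
        If a shot center lies outside the grid extent, or the nominal FWHM
        is below twice the coarsest grid spacing (unresolvable).
    """
    if isinstance(shots, ShotSpec):
        shots = [shots]
    if len(shots) == 0:
        raise ValueError("at least one shot is required")
    if grid.ndim != 3:
        raise ValueError("dose grids are three-dimensional")
    dose = np.zeros(grid.shape, dtype=float)
    xs, ys, zs = grid.meshgrid()
    max_spacing = max(grid.spacing)
    for shot in shots:
        if not grid.contains_point(shot.center):
            raise ValueError(f"shot center {shot.center} lies outside the grid extent")
        if shot.nominal_fwhm < 2.0 * max_spacing:
            raise ValueError(
                f"nominal_fwhm {shot.nominal_fwhm} mm unresolvable on "
                f"{max_spacing} mm spacing (needs >= 2 voxels)"
            )
        radius = _solve_flat_top_radius(shot.nominal_fwhm, shot.penumbra_sigma)
        r = np.sqrt(
            (xs - shot.center[0]) ** 2 + (ys - shot.center[1]) ** 2 + (zs - shot.center[2]) ** 2
        )
        profile = _flat_top_profile(r, radius, shot.penumbra_sigma)
        dose += shot.center_dose * profile / _flat_top_profile(0.0, radius, shot.penumbra_sigma)
    return DoseGrid(dose, grid, provenance="truth")


@dataclass(frozen=True)
class GelResponseModel:
    """Dose response of the nPAG polymer gel read out by MRI.

    R2(D) = r2_baseline + sensitivity * r2_baseline * saturation_dose
            * (1 - exp(-D / saturation_dose))

    ``sensitivity`` is the slope of the *normalized* response
    (R2 - R2_ref)/R2_ref per Gy in the linear regime, so the absolute R2
    slope is ``sensitivity * r2_baseline`` (s^-1 Gy^-1).  The saturating
    exponential reproduces the observed linear-then-saturating behaviour;
    ``saturation_dose`` sets the dose scale at which droop becomes visible.
    """

    r2_baseline: float = 10.0
    sensitivity: float = 0.084
    saturation_dose: float = 100.0
    s0: float = 1000.0
    noise_sigma: float = 0.0

    def __post_init__(self):
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be > 0")
        if self.r2_baseline <= 0:
            raise ValueError("r2_baseline must be > 0")
        if self.saturation_dose <= 0:
            raise ValueError("saturation_dose must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def sensitivity_abs(self) -> float:
        """Absolute R2 slope (s^-1 Gy^-1) in the linear regime."""
        return self.sensitivity * self.r2_baseline

    def r2_of_dose(self, dose) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        return self.r2_baseline + self.sensitivity_abs * self.saturation_dose * (
            1.0 - np.exp(-dose / self.saturation_dose)
        )

    def signal(self, dose, te_ms: float) -> np.ndarray:
        """Noiseless magnitude signal S(TE) = s0 * exp(-R2(D) * TE)."""
        return self.s0 * np.exp(-self.r2_of_dose(dose) * (te_ms / 1000.0))


def _rician(noiseless: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of a complex signal with i.i.d. Gaussian channel noise."""
    if sigma == 0:
        return noiseless.copy()
    re = noiseless + rng.normal(0.0, sigma, noiseless.shape)
    im = rng.normal(0.0, sigma, noiseless.shape)
    return np.hypot(re, im)


def mri_forward(
    dose: DoseGrid,
    gel: GelResponseModel = GelResponseModel(),
    te_pair: tuple[float, float] = DEFAULT_TE_PAIR,
    seed: int | np.random.Generator = 0,
) -> EchoImagePair:
    """Forward-model a dose field into a dual-echo MRI magnitude pair.

    Rician magnitude noise (Gaussian on the two complex channels, SD
    ``gel.noise_sigma`` in signal units) is applied independently per echo,
    driven entirely by ``seed``.
    """
    te1, te2 = float(te_pair[0]), float(te_pair[1])
    if te1 <= 0 or te2 <= 0:
        raise ValueError("echo times must be positive")
    if te1 == te2:
        raise ValueError("echo times must be distinct")
    if np.any(dose.dose < 0):
        raise ValueError("dose must be nonnegative everywhere")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s1 = _rician(gel.signal(dose.dose, te1), gel.noise_sigma, rng)
    s2 = _rician(gel.signal(dose.dose, te2), gel.noise_sigma, rng)
    return EchoImagePair(s1=s1, s2=s2, te1=te1, te2=te2, grid=dose.grid)


@dataclass(frozen=True)
class FilmResponseModel:
    """Saturating net-OD dose response of a radiochromic film.

    OD(D) = od_saturation * (1 - exp(-D / dose_scale)); the low-dose slope
    is od_saturation / dose_scale (Gy^-1), ~0.100 for RTQA2 and 0.101 for
    EBT3 film.  Pixel value PV = pv0 * 10**(-OD) plus additive scanner noise,
    clipped to the 16-bit range.
    """

    od_saturation: float = 1.0
    dose_scale: float = 10.0
    pv0: float = 40000.0
    noise_sigma: float = 0.0
    pv_max: float = 65535.0

    def __post_init__(self):
        if self.pv0 <= 0:
            raise ValueError("pv0 must be > 0")
        if self.od_saturation <= 0 or self.dose_scale <= 0:
            raise ValueError("od_saturation and dose_scale must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def low_dose_slope(self) -> float:
        """Initial net-OD slope (Gy^-1): od_saturation / dose_scale."""
        return self.od_saturation / self.dose_scale

    @classmethod
    def rtqa2(cls, **kw) -> "FilmResponseModel":
        return cls(od_saturation=1.0, dose_scale=10.0, **kw)

    @classmethod
    def ebt3(cls, **kw) -> "FilmResponseModel":
        # dose_scale chosen so the low-dose slope is 0.101 Gy^-1
        return cls(od_saturation=1.0, dose_scale=1.0 / 0.101, **kw)

    def net_od(self, dose) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        return self.od_saturation * (1.0 - np.exp(-dose / self.dose_scale))


def film_forward(
    dose_slice: np.ndarray,
    film: FilmResponseModel = FilmResponseModel(),
    pixel_spacing: float = 25.4 / 1200.0,
    seed: int | np.random.Generator = 0,
    channel: str = "red",
) -> FilmScan:
    """Forward-model a 2D dose plane into a scanned-film pixel image.

    The default ``pixel_spacing`` corresponds to a 1200 dpi scan.
    """
    dose_slice = np.asarray(dose_slice, dtype=float)
    if dose_slice.ndim != 2:
        raise ValueError("film_forward expects a 2D dose plane")
    if np.any(dose_slice < 0):
        raise ValueError("dose must be nonnegative everywhere")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    od = film.net_od(dose_slice)
    pv = film.pv0 * np.power(10.0, -od)
    if film.noise_sigma > 0:
        pv = pv + rng.normal(0.0, film.noise_sigma, pv.shape)
    pv = np.clip(pv, 0.0, film.pv_max)
    return FilmScan(
        pixels=pv,
        pixel_spacing=pixel_spacing,
        channel=channel,
        dpi=25.4 / pixel_spacing,
    )


def default_mri_grid(
    extent_mm: float = 30.0,
    center: tuple[float, float, float] = (100.0, 100.0, 100.0),
    in_plane: float = 0.5,
    slice_thickness: float = 2.5,
) -> GridSpec:
    """Sagittal-acquisition grid: 2.5 mm slices along X, 0.5 mm in plane (Y, Z).

    ``extent_mm`` is the half-extent of the field of view around ``center``.
    """
    spacing = (slice_thickness, in_plane, in_plane)
    shape = tuple(2 * int(round(extent_mm / s)) + 1 for s in spacing)
    origin = tuple(c - s * (n // 2) for c, s, n in zip(center, spacing, shape))
    return GridSpec(shape=shape, spacing=spacing, origin=origin)
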