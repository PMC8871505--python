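"""Two-point transverse relaxation rate (R2 = 1/T2) mapping.

From a dual-echo spin-echo magnitude pair the per-voxel rate is

    R2 = ln(S(TE1) / S(TE2)) / (TE2 - TE1)

with echo times converted from ms to seconds so R2 is in s^-1.  Voxels where
either echo signal falls at or below a signal floor are masked invalid
rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import EchoImagePair, GridSpec

__all__ = ["R2Map", "compute_r2_map", "normalize_response", "estimate_background_sigma"]


@dataclass
class R2Map:
    """Per-voxel R2 (s^-1) with a validity mask.

    ``normalized`` flags a map transformed to (R2 - R2_ref)/R2_ref; the
    reference value used is kept in ``reference_r2``.
    """

    r2: np.ndarray
    valid: np.ndarray
    grid: GridSpec
    normalized: bool = False
    reference_r2: Optional[float] = None

    def __post_init__(self):
        self.r2 = np.asarray(self.r2, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.r2.shape != self.valid.shape:
            raise ValueError("r2 and valid mask must share shape")
        if self.r2.shape != tuple(self.grid.shape):
            raise ValueError("r2 shape does not match grid")
        if not np.all(np.isfinite(self.r2[self.valid])):
            raise ValueError("valid voxels must carry finite r2")

    @property
    def response_kind(self) -> str:
        return "gel_r2_normalized" if self.normalized else "gel_r2"


def estimate_background_sigma(image: np.ndarray) -> float:
    """Magnitude-noise SD estimate via wavelet-based noise estimation.

    Robust to the smooth dose structure of the image (which is not noise);
    adequate for choosing a signal floor, not for quantitative noise work.
    """
    from skimage.restoration import estimate_sigma

    sigma = estimate_sigma(np.asarray(image, dtype=float))
    return float(sigma) if np.isfinite(sigma) else 0.0


def compute_r2_map(pair: EchoImagePair, signal_floor: Optional[float] = None) -> R2Map:
    """Two-point R2 map from a dual-echo pair.

    Echoes may be supplied in either order; they are sorted so TE1 < TE2.
    ``signal_floor`` defaults to 3x the estimated background noise SD of the
    late echo; voxels with either signal <= floor are marked invalid and
    carry NaN, without raising.
    """
    te1, te2, s1, s2 = pair.te1, pair.te2, pair.s1, pair.s2
    if te1 == te2:
        raise ValueError("echo times must be distinct")
    if te1 > te2:
        te1, te2, s1, s2 = te2, te1, s2, s1
    if s1.shape != s2.shape:
        raise ValueError("echo images must share shape")
    if signal_floor is None:
        signal_floor = 3.0 * estimate_background_sigma(s2)
    valid = (s1 > signal_floor) & (s2 > signal_floor)
    dte_s = (te2 - te1) / 1000.0
    r2 = np.full(s1.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2[valid] = np.log(s1[valid] / s2[valid]) / dte_s
    # log of a ratio <= 0 cannot occur where both signals exceed the floor
    return R2Map(r2=r2, valid=valid, grid=pair.grid)


def normalize_response(r2map: R2Map, reference_region: np.ndarray) -> R2Map:
    """Normalize an R2 map against a zero-dose reference region.

    Replaces r2 by (r2 - r2_ref) / r2_ref where r2_ref is the mean over the
    valid voxels of ``reference_region`` (a boolean mask).  A second
    normalization is refused.
    """
    if r2map.normalized:
        raise ValueError("map is already normalized")
    region = np.asarray(reference_region, dtype=bool)
    if region.shape != r2map.r2.shape:
        raise ValueError("reference region mask must match map shape")
    usable = region & r2map.valid
    if not usable.any():
        raise ValueError("reference region contains no valid voxels")
    r2_ref = float(r2map.r2[usable].mean())
    if r2_ref == 0:
        raise ValueError("reference R2 is zero; cannot normalize")
    out = np.full(r2map.r2.shape, np.nan)
    out[r2map.valid] = (r2map.r2[r2map.valid] - r2_ref) / r2_ref
    return R2Map(
        r2=out,
        valid=r2map.valid.copy(),
        grid=r2map.grid,
        normalized=True,
        reference_r2=r2_ref,
    )
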