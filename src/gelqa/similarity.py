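"""Dose-distribution similarity: rigid translation alignment, Sobel-based
isodose segmentation, and per-isodose-band structural similarity (SSIM).

A reconstructed planar dose map is compared with a reference map by first
finding the integer-pixel translation maximizing normalized cross-
correlation, segmenting the normalized maps into nested isodose bands, and
averaging the local SSIM map within each band.  SSIM uses the standard
Gaussian-window formulation (window 11, sigma 1.5, C1 = (0.01 L)^2,
C2 = (0.03 L)^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity

__all__ = [
    "SimilarityResult",
    "align_translation",
    "isodose_segment",
    "ssim_compare",
    "DEFAULT_ISODOSE_LEVELS",
]

#: Default isodose levels (% of Dmax) evaluated in the similarity report.
DEFAULT_ISODOSE_LEVELS = (90.0, 80.0, 70.0, 60.0, 50.0, 30.0, 10.0)


@dataclass
class SimilarityResult:
    shift: tuple[int, int]
    global_ssim: float
    per_band: list  # (level %, ssim) pairs, levels strictly decreasing
    window: int = 11
    c1: float = 0.0
    c2: float = 0.0

    def __post_init__(self):
        scores = [self.global_ssim] + [s for _, s in self.per_band]
        if any(not -1.0 - 1e-9 <= s <= 1.0 + 1e-9 for s in scores if np.isfinite(s)):
            raise ValueError("SSIM scores must lie in [-1, 1]")
        levels = [l for l, _ in self.per_band]
        if any(a >= b for a, b in zip(levels[1:], levels[:-1])):
            raise ValueError("per-band levels must be strictly decreasing")

    def to_dict(self) -> dict:
        return {
            "shift": list(self.shift),
            "global_ssim": self.global_ssim,
            "per_band": [{"level": l, "ssim": s} for l, s in self.per_band],
            "window": self.window,
            "c1": self.c1,
            "c2": self.c2,
        }


def align_translation(
    moving: np.ndarray, fixed: np.ndarray, max_shift: Optional[int] = None
) -> tuple[int, int]:
    """Integer-pixel displacement of ``moving`` relative to ``fixed``.

    Returns the shift s such that ``moving`` best matches
    ``np.roll(fixed, s)``; apply ``np.roll(moving, (-s[0], -s[1]))`` to
    align.  Exhaustive normalized cross-correlation search over shifts up to
    ``max_shift`` (default: a quarter of the smaller image dimension, which
    keeps overlap >= 25 % of the area).  Inverse-consistent by construction:
    the score of shift s for (moving, fixed) equals that of -s for
    (fixed, moving), ties broken toward the smaller |shift|.
    """
    a = np.asarray(moving, dtype=float)
    b = np.asarray(fixed, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must share shape for alignment")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("cannot align a constant image")
    if max_shift is None:
        max_shift = min(a.shape) // 4
    best = (0, 0)
    best_score = -np.inf
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            # overlap of fixed with moving shifted by (dy, dx)
            ay0, ay1 = max(0, -dy), min(a.shape[0], a.shape[0] - dy)
            ax0, ax1 = max(0, -dx), min(a.shape[1], a.shape[1] - dx)
            if (ay1 - ay0) * (ax1 - ax0) < 0.25 * a.size:
                continue
            pa = a[ay0:ay1, ax0:ax1]
            pb = b[ay0 + dy : ay1 + dy, ax0 + dx : ax1 + dx]
            sa, sb = pa.std(), pb.std()
            if sa == 0 or sb == 0:
                continue
            score = float(np.mean((pa - pa.mean()) * (pb - pb.mean())) / (sa * sb))
            if score > best_score + 1e-12 or (
                abs(score - best_score) <= 1e-12
                and abs(dy) + abs(dx) < abs(best[0]) + abs(best[1])
            ):
                best_score = score
                best = (dy, dx)
    # the loop's (dy, dx) satisfies moving(i) ~ fixed(i + s); the
    # displacement of the moving image is therefore its negation
    return (-best[0], -best[1])


def sobel_edges(image: np.ndarray) -> np.ndarray:
    """Gradient magnitude with the standard 3x3 Sobel kernels, reflected
    boundary (a unit step yields magnitude 4 on the step columns)."""
    img = np.asarray(image, dtype=float)
    gx = ndimage.sobel(img, axis=1, mode="reflect")
    gy = ndimage.sobel(img, axis=0, mode="reflect")
    return np.hypot(gx, gy)


def isodose_segment(
    dose_map: np.ndarray, levels: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Segment a normalized dose map (0..100 %) into nested isodose bands.

    Returns ``(labels, edges)``: labels as in nested thresholding (0 below
    the lowest level, then 1, 2, ... from the lowest level up), and the
    Sobel gradient-magnitude image highlighting the isodose boundaries.
    """
    levels = [float(l) for l in levels]
    if len(levels) == 0:
        raise ValueError("levels must be nonempty")
    if any(a >= b for a, b in zip(levels[1:], levels[:-1])):
        raise ValueError("levels must be strictly decreasing")
    img = np.asarray(dose_map, dtype=float)
    if np.nanmax(img) > 100 + 1e-9 or np.nanmin(img) < -1e-9:
        raise ValueError("dose map must be normalized to [0, 100] percent")
    labels = np.zeros(img.shape, dtype=np.int32)
    for i, level in enumerate(sorted(levels), start=1):
        labels[img >= level] = i
    return labels, sobel_edges(img)


def ssim_compare(
    a: np.ndarray,
    b: np.ndarray,
    bands: Optional[np.ndarray] = None,
    band_levels: Sequence[float] = DEFAULT_ISODOSE_LEVELS,
    window: int = 11,
    dynamic_range: Optional[float] = None,
    shift: tuple[int, int] = (0, 0),
) -> SimilarityResult:
    """Mean SSIM globally and within each isodose band.

    ``a`` and ``b`` must already be aligned and share shape; ``bands`` is a
    label image as produced by :func:`isodose_segment` on the reference map
    (labels 1..n corresponding to ``band_levels`` from the lowest up).  The
    local SSIM map is computed with a Gaussian window (sigma 1.5) and
    stabilization constants C1 = (0.01 L)^2, C2 = (0.03 L)^2 with
    L = ``dynamic_range`` (defaulting to the joint value range).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share shape")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > min(a.shape):
        raise ValueError("window larger than image")
    if dynamic_range is None:
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        dynamic_range = hi - lo if hi > lo else 1.0
    _, ssim_map = structural_similarity(
        a,
        b,
        win_size=window,
        gaussian_weights=True,
        sigma=1.5,
        data_range=dynamic_range,
        use_sample_covariance=False,
        full=True,
    )
    global_ssim = float(ssim_map.mean())
    per_band = []
    if bands is not None:
        bands = np.asarray(bands)
        if bands.shape != a.shape:
            raise ValueError("band label image must match image shape")
        ascending = sorted(float(l) for l in band_levels)
        for label, level in enumerate(ascending, start=1):
            mask = bands == label
            score = float(ssim_map[mask].mean()) if mask.any() else float("nan")
            per_band.append((level, score))
        per_band = per_band[::-1]  # report levels in decreasing order
    c1 = (0.01 * dynamic_range) ** 2
    c2 = (0.03 * dynamic_range) ** 2
    return SimilarityResult(
        shift=tuple(shift),
        global_ssim=global_ssim,
        per_band=per_band,
        window=window,
        c1=c1,
        c2=c2,
    )
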