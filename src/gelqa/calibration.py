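"""Dose-response calibration: net optical density, linear-range fitting,
and inversion of response to dose.

Calibration samples (gel cuvettes read out as normalized R2 or MRI pixel
intensity, or film pieces read out as net OD) give (dose, response) points.
The sensitivity is the slope of a weighted least-squares line over the
linear range; the linear range itself can be detected automatically by a
lack-of-fit F-test against a saturating-exponential alternative.

Dose bookkeeping follows the Gy@50% prescription convention: the recorded
dose is the value delivered to the 50% isodose (total center dose is twice
that); ``dose_total`` carries the companion number.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy import optimize, stats

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "InversionResult",
    "film_net_od",
    "fit_dose_response",
    "predict_response",
    "invert_response",
    "points_to_csv",
    "points_from_csv",
]

#: Candidate linear-range upper bounds (Gy@50%) for automatic detection.
AUTO_BOUND_CANDIDATES = (4.0, 8.0, 10.0, 20.0, 40.0)


@dataclass(frozen=True)
class CalibrationPoint:
    dose: float
    response: float
    response_sd: float = 0.0
    prescription_isodose: float = 0.5

    def __post_init__(self):
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        if self.response_sd < 0:
            raise ValueError("response_sd must be >= 0")

    @property
    def dose_total(self) -> float:
        """Total dose at the shot center implied by the prescription."""
        return self.dose / self.prescription_isodose


@dataclass
class CalibrationCurve:
    points: list
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    linear_max_dose: float
    method: str = "gel_r2_normalized"

    def __post_init__(self):
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")
        max_dose = max(p.dose for p in self.points)
        if self.linear_max_dose > max_dose + 1e-12:
            raise ValueError("linear_max_dose cannot exceed the largest point dose")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_se": self.slope_se,
            "intercept_se": self.intercept_se,
            "linear_max_dose": self.linear_max_dose,
            "points": [
                {
                    "dose": p.dose,
                    "dose_total": p.dose_total,
                    "response": p.response,
                    "response_sd": p.response_sd,
                }
                for p in self.points
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        pts = [
            CalibrationPoint(p["dose"], p["response"], p.get("response_sd", 0.0))
            for p in d["points"]
        ]
        return cls(
            points=pts,
            slope=d["slope"],
            intercept=d["intercept"],
            slope_se=d["slope_se"],
            intercept_se=d["intercept_se"],
            linear_max_dose=d["linear_max_dose"],
            method=d["method"],
        )


def film_net_od(pv_unexposed, pv_exposed):
    """Net optical density log10(PV_unexposed / PV_exposed).

    Accepts scalars or arrays; every pixel value must be positive.  An
    unexposed film has OD exactly 0.
    """
    pv0 = np.asarray(pv_unexposed, dtype=float)
    pv = np.asarray(pv_exposed, dtype=float)
    if np.any(pv0 <= 0) or np.any(pv <= 0):
        raise ValueError("pixel values must be positive to form an optical density")
    od = np.log10(pv0 / pv)
    return float(od) if od.ndim == 0 else od


def _wls(dose: np.ndarray, resp: np.ndarray, sd: np.ndarray):
    """Weighted least-squares line fit.

    Weights 1/sd^2 when all sds are positive (covariance taken unscaled, the
    sds being trusted); otherwise unweighted with residual-variance scaling.
    """
    weighted = np.all(sd > 0)
    w = 1.0 / sd**2 if weighted else np.ones_like(dose)
    X = np.column_stack([dose, np.ones_like(dose)])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    beta = np.linalg.solve(xtwx, WX.T @ resp)
    resid = resp - X @ beta
    cov = np.linalg.inv(xtwx)
    if not weighted:
        dof = max(len(dose) - 2, 1)
        cov = cov * float(w @ resid**2) / dof
    sse = float(w @ resid**2)
    return beta[0], beta[1], float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1])), sse


def _saturating(d, a, b, c):
    return c + a * (1.0 - np.exp(-d / b))


def _lack_of_fit_significant(dose, resp, sd, alpha: float) -> bool:
    """Is a saturating-exponential alternative significantly better than
    the straight line?

    With trusted per-point SDs the weighted SSEs are chi-squares, so the
    improvement is tested as a chi-square difference on 1 dof; without SDs
    a nested-model style F-test on the residual SSEs is used.
    """
    n = len(dose)
    if n < 4:
        return False  # saturating model not identifiable; cannot show lack of fit
    weighted = np.all(sd > 0)
    w = 1.0 / sd**2 if weighted else np.ones(n)
    _, _, _, _, sse_lin = _wls(dose, resp, sd)
    try:
        span = resp.max() - resp.min()
        p0 = (span if span > 0 else 1.0, max(dose.max() / 2.0, 1e-3), resp.min())
        popt, _ = optimize.curve_fit(
            _saturating,
            dose,
            resp,
            p0=p0,
            sigma=sd if weighted else None,
            absolute_sigma=weighted,
            maxfev=20000,
        )
    except (RuntimeError, ValueError):
        return False
    sse_sat = float(w @ (resp - _saturating(dose, *popt)) ** 2)
    dof_sat = n - 3
    if weighted:
        return stats.chi2.sf(max(sse_lin - sse_sat, 0.0), 1) < alpha
    if sse_sat <= 0 or dof_sat <= 0:
        # perfect saturating fit: significant only if the line leaves residue
        return sse_lin > max(1e-20, 1e-12 * float(w @ resp**2))
    f = max(sse_lin - sse_sat, 0.0) / (sse_sat / dof_sat)
    return stats.f.sf(f, 1, dof_sat) < alpha


def fit_dose_response(
    points: Sequence[CalibrationPoint],
    linear_max_dose: Union[float, str] = "auto",
    method: str = "gel_r2_normalized",
    alpha: float = 0.05,
) -> CalibrationCurve:
    """Fit the linear-range sensitivity of a dose-response data set.

    Parameters
    ----------
    points
        Calibration points; at least 3 with at least 2 distinct doses must
        fall inside the linear range.
    linear_max_dose
        Upper dose bound of the linear range, or ``"auto"`` to pick the
        largest candidate from {4, 8, 10, 20, 40} Gy@50% whose data show no
        significant lack of fit (level ``alpha``) relative to a
        saturating-exponential alternative.
    method
        Response-kind tag carried into the curve (used to guard dose-map
        reconstruction against mismatched response types).
    """
    pts = list(points)
    dose_all = np.array([p.dose for p in pts], dtype=float)
    resp_all = np.array([p.response for p in pts], dtype=float)
    sd_all = np.array([p.response_sd for p in pts], dtype=float)
    if len(pts) < 3:
        raise ValueError("at least 3 calibration points are required")
    if np.unique(dose_all).size < 2:
        raise ValueError("calibration requires at least 2 distinct doses")

    def usable(bound):
        m = dose_all <= bound + 1e-12
        return m if (m.sum() >= 3 and np.unique(dose_all[m]).size >= 2) else None

    if linear_max_dose == "auto":
        chosen = None
        candidates = [b for b in AUTO_BOUND_CANDIDATES if usable(b) is not None]
        if not candidates:
            raise ValueError("no auto candidate bound leaves >= 3 usable points")
        for bound in sorted(candidates, reverse=True):
            m = usable(bound)
            if not _lack_of_fit_significant(dose_all[m], resp_all[m], sd_all[m], alpha):
                chosen = bound
                break
        if chosen is None:
            chosen = min(candidates)  # everything bends; keep the narrowest window
        linear_max_dose = chosen
    else:
        linear_max_dose = float(linear_max_dose)
        if usable(linear_max_dose) is None:
            raise ValueError("fewer than 3 usable points within linear_max_dose")

    m = usable(linear_max_dose)
    slope, intercept, slope_se, intercept_se, _ = _wls(dose_all[m], resp_all[m], sd_all[m])
    return CalibrationCurve(
        points=pts,
        slope=float(slope),
        intercept=float(intercept),
        slope_se=slope_se,
        intercept_se=intercept_se,
        linear_max_dose=float(min(linear_max_dose, dose_all.max())),
        method=method,
    )


def predict_response(curve: CalibrationCurve, dose):
    """Response predicted by the fitted line at a dose (scalar or array)."""
    dose = np.asarray(dose, dtype=float)
    out = curve.slope * dose + curve.intercept
    return float(out) if out.ndim == 0 else out


@dataclass
class InversionResult:
    """Dose obtained by inverting a calibration curve.

    ``saturated`` flags results above the curve's linear range (the value is
    still returned); ``clipped`` flags responses implying negative dose
    (clipped to 0).
    """

    dose: np.ndarray
    saturated: np.ndarray
    clipped: np.ndarray

    def item(self):
        return float(self.dose), bool(self.saturated), bool(self.clipped)


def invert_response(curve: CalibrationCurve, response) -> InversionResult:
    """Invert response to dose: (response - intercept) / slope.

    Works element-wise on arrays; NaN responses yield NaN doses with both
    flags False.
    """
    if curve.slope == 0:
        raise ValueError("cannot invert a zero-slope calibration curve")
    response = np.asarray(response, dtype=float)
    dose = (response - curve.intercept) / curve.slope
    with np.errstate(invalid="ignore"):
        saturated = dose > curve.linear_max_dose
        clipped = dose < 0
    dose = np.where(clipped, 0.0, dose)
    return InversionResult(dose=dose, saturated=saturated, clipped=clipped)


def points_to_csv(points: Sequence[CalibrationPoint], path) -> None:
    """Write a calibration table (dose_gy_at_50, response, response_sd)."""
    with open(path, "w", newline="") as fh:
        fh.write("dose_gy_at_50,response,response_sd\n")
        for p in points:
            fh.write(f"{p.dose:.17g},{p.response:.17g},{p.response_sd:.17g}\n")


def points_from_csv(path) -> list:
    pts = []
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        if header[:3] != ["dose_gy_at_50", "response", "response_sd"]:
            raise ValueError(f"unrecognized calibration CSV header: {header}")
        for line in fh:
            if not line.strip():
                continue
            d, r, s = line.strip().split(",")
            pts.append(CalibrationPoint(float(d), float(r), float(s)))
    return pts
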