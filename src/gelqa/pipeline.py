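"""End-to-end QA runs: simulate, calibrate, map dose, profile, compare.

A run is driven by a single config mapping (YAML on disk), every source of
randomness comes from its seeds, and the result is a machine-readable
QAReport.  Identical configs produce byte-identical report payloads.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from . import __version__
from .calibration import CalibrationPoint, CalibrationCurve, film_net_od, fit_dose_response
from .core import DoseGrid, GridSpec
from .dose_mapping import reconstruct_dose_map
from .io_formats import write_outputs
from .profiles import Profile1D, extract_profile, fwhm, fwhm_deviation
from .r2map import compute_r2_map, normalize_response
from .similarity import align_translation, isodose_segment, ssim_compare
from .synthetic import (
    DEFAULT_TE_PAIR,
    FilmResponseModel,
    GelResponseModel,
    NOMINAL_FWHM_MM,
    ShotSpec,
    default_mri_grid,
    film_forward,
    make_shot_dose_field,
    mri_forward,
)

__all__ = [
    "DEFAULT_CONFIG",
    "QAReport",
    "run_qa_pipeline",
    "validate_config",
    "simulate_gel_calibration",
    "simulate_film_calibration",
]

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "threshold_pct": 5.0,
    "denominator": "both",  # reference | measured | both
    "te_pair": list(DEFAULT_TE_PAIR),
    "grid": {"extent_mm": 25.0, "in_plane_mm": 0.5, "slice_thickness_mm": 2.5},
    "shots": {
        "collimators": [4, 8, 16],
        "prescription_dose": 4.0,
        "center": [100.0, 100.0, 100.0],
    },
    "gel": {
        "r2_baseline": 10.0,
        "sensitivity": 0.084,
        "saturation_dose": 100.0,
        "s0": 1000.0,
        "noise_sigma": 0.0,
    },
    "film": {"type": "rtqa2", "noise_sigma": 0.0},
    "calibration": {
        "doses": [0.0, 2.0, 4.0, 6.0, 8.0, 10.0],
        "linear_max_dose": 10.0,  # or "auto"
        "chamber_correction": 0.0,
    },
    "similarity": {"levels": [90.0, 80.0, 70.0, 60.0, 50.0, 30.0, 10.0]},
}


def validate_config(config: dict) -> dict:
    """Merge a partial config over the defaults, rejecting unknown keys.

    Returns the merged config; raises ``ValueError`` naming every offending
    key path.
    """
    merged = copy.deepcopy(DEFAULT_CONFIG)
    bad: list[str] = []

    def merge(dst: dict, src: dict, prefix: str):
        for key, value in src.items():
            if key not in dst:
                bad.append(prefix + key)
            elif isinstance(dst[key], dict):
                if isinstance(value, dict):
                    merge(dst[key], value, prefix + key + ".")
                else:
                    bad.append(prefix + key)
            else:
                dst[key] = value

    merge(merged, config, "")
    if bad:
        raise ValueError(f"unknown config keys: {', '.join(sorted(bad))}")
    if merged["denominator"] not in ("reference", "measured", "both"):
        raise ValueError("denominator must be reference, measured or both")
    return merged


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Calibration simulators (the cuvette / film-piece experiments)

def _calibration_patch_grid(shape=(3, 9, 9)) -> GridSpec:
    return GridSpec(shape=shape, spacing=(2.5, 0.5, 0.5), origin=(0.0, 0.0, 0.0))


def simulate_gel_calibration(
    doses: Sequence[float],
    gel: GelResponseModel,
    te_pair: tuple[float, float] = DEFAULT_TE_PAIR,
    seed: int | np.random.Generator = 0,
    patch_shape: tuple[int, int, int] = (3, 9, 9),
) -> list:
    """Simulate the cuvette calibration experiment for the gel readout.

    One uniformly irradiated small volume per dose is forward-modelled into
    a dual-echo pair, R2-mapped, and normalized against the zero-dose
    cuvette; the response of a cuvette is the ROI-mean normalized R2, its SD
    the standard error of that mean.  The first dose should be 0 (the
    normalization reference).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = _calibration_patch_grid(patch_shape)
    r2_means, r2_sems = [], []
    for dose in doses:
        field_ = DoseGrid(np.full(grid.shape, float(dose)), grid)
        pair = mri_forward(field_, gel, te_pair, seed=rng)
        r2 = compute_r2_map(pair, signal_floor=0.0)
        vals = r2.r2[r2.valid]
        r2_means.append(float(vals.mean()))
        r2_sems.append(float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0)
    izero = int(np.argmin(np.asarray(doses)))
    r2_ref = r2_means[izero]
    points = []
    for dose, mean, sem in zip(doses, r2_means, r2_sems):
        points.append(
            CalibrationPoint(
                dose=float(dose), response=(mean - r2_ref) / r2_ref, response_sd=sem / r2_ref
            )
        )
    return points


def simulate_film_calibration(
    doses: Sequence[float],
    film: FilmResponseModel,
    seed: int | np.random.Generator = 0,
    patch_shape: tuple[int, int] = (15, 15),
) -> list:
    """Simulate the film-piece calibration: uniform exposures, net OD
    against the mean unexposed pixel value."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scans = [
        film_forward(np.full(patch_shape, float(d)), film, seed=rng) for d in doses
    ]
    izero = int(np.argmin(np.asarray(doses)))
    pv0 = float(scans[izero].pixels.mean())
    points = []
    for dose, scan in zip(doses, scans):
        od = film_net_od(pv0, scan.pixels)
        sem = float(od.std(ddof=1) / np.sqrt(od.size)) if od.size > 1 else 0.0
        points.append(CalibrationPoint(dose=float(dose), response=float(od.mean()), response_sd=sem))
    return points


# ---------------------------------------------------------------------------
# The QA report

@dataclass
class QAReport:
    config_hash: str
    seed: int
    version: str
    calibration: dict
    fwhm_table: list
    similarity: dict
    threshold_pct: float
    pass_flags: dict

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "calibration": self.calibration,
            "fwhm_table": self.fwhm_table,
            "similarity": self.similarity,
            "threshold_pct": self.threshold_pct,
            "pass_flags": self.pass_flags,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _gel_models(cfg: dict) -> GelResponseModel:
    return GelResponseModel(**cfg["gel"])


def _film_model(cfg: dict) -> FilmResponseModel:
    film_cfg = cfg["film"]
    kind = film_cfg.get("type", "rtqa2")
    maker = {"rtqa2": FilmResponseModel.rtqa2, "ebt3": FilmResponseModel.ebt3}.get(kind)
    if maker is None:
        raise ValueError(f"unknown film type {kind!r}")
    return maker(noise_sigma=film_cfg.get("noise_sigma", 0.0))


def run_qa_pipeline(
    config: Union[dict, str, Path, None] = None,
    seed: Optional[int] = None,
    out_dir: Union[str, Path, None] = None,
    threshold_pct: Optional[float] = None,
) -> QAReport:
    """Execute the full QA chain and return the report.

    Stages: simulate single-shot truth fields per collimator; simulate and
    fit gel and film calibrations; forward-model, reconstruct and profile
    each field with both readouts; compare the reconstructed gel plane with
    the truth plane via per-isodose SSIM; flag pass/fail at the FWHM
    deviation threshold (default 5 %).
    """
    if config is None:
        config = {}
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = validate_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    if threshold_pct is not None:
        cfg["threshold_pct"] = float(threshold_pct)
    rng = np.random.default_rng(cfg["seed"])
    te_pair = tuple(cfg["te_pair"])
    gel = _gel_models(cfg)
    film = _film_model(cfg)
    cal_cfg = cfg["calibration"]
    delta = float(cal_cfg["chamber_correction"])
    doses = [float(d) * (1.0 + delta) for d in cal_cfg["doses"]]

    # --- calibration stage
    gel_points = simulate_gel_calibration(doses, gel, te_pair, seed=rng)
    film_points = simulate_film_calibration(doses, film, seed=rng)
    bound = cal_cfg["linear_max_dose"]
    gel_curve = fit_dose_response(gel_points, bound, method="gel_r2_normalized")
    film_curve = fit_dose_response(film_points, bound, method="film_od")
    calibration_summary = {
        "gel_r2": {
            "slope": gel_curve.slope,
            "slope_se": gel_curve.slope_se,
            "linear_max_dose": gel_curve.linear_max_dose,
        },
        "film_od": {
            "slope": film_curve.slope,
            "slope_se": film_curve.slope_se,
            "linear_max_dose": film_curve.linear_max_dose,
        },
    }

    # --- per-collimator simulate / reconstruct / profile
    grid_cfg = cfg["grid"]
    center = tuple(float(c) for c in cfg["shots"]["center"])
    fwhm_rows = []
    similarity_summary: dict = {}
    for coll in cfg["shots"]["collimators"]:
        shot = ShotSpec(
            collimator=int(coll),
            center=center,
            prescription_dose=float(cfg["shots"]["prescription_dose"]),
        )
        grid = default_mri_grid(
            extent_mm=float(grid_cfg["extent_mm"]),
            center=center,
            in_plane=float(grid_cfg["in_plane_mm"]),
            slice_thickness=float(grid_cfg["slice_thickness_mm"]),
        )
        truth = make_shot_dose_field([shot], grid)
        ref_fwhm = fwhm(extract_profile(truth, "Z", center, normalize=True)).fwhm

        # gel readout chain
        pair = mri_forward(truth, gel, te_pair, seed=rng)
        r2 = compute_r2_map(pair)
        ys, zs = np.meshgrid(grid.coords(1), grid.coords(2), indexing="ij")
        r_yz = np.sqrt((ys - center[1]) ** 2 + (zs - center[2]) ** 2)
        background = np.broadcast_to(
            r_yz > 0.8 * float(grid_cfg["extent_mm"]), grid.shape
        )
        r2n = normalize_response(r2, background)
        gel_dose = reconstruct_dose_map(r2n, gel_curve)
        gel_fwhm = fwhm(extract_profile(gel_dose, "Z", center, normalize=True)).fwhm

        # film readout chain: the plane through the shot center
        ix = grid.nearest_index(center)[0]
        film_scan = film_forward(
            truth.dose[ix], film, pixel_spacing=float(grid_cfg["in_plane_mm"]), seed=rng
        )
        film_scan.od = film_net_od(film.pv0, film_scan.pixels)
        film_dose = reconstruct_dose_map(film_scan, film_curve)
        iy = grid.nearest_index(center)[1]
        film_profile = film_dose.dose[iy]
        film_fwhm = fwhm(
            Profile1D(positions=grid.coords(2), values=film_profile, axis="Z")
        ).fwhm

        for method, measured in (("gel", gel_fwhm), ("film", film_fwhm)):
            fwhm_rows.append(
                {
                    "collimator_mm": int(coll),
                    "method": method,
                    "reference_fwhm_mm": round(ref_fwhm, 3),
                    "nominal_fwhm_mm": NOMINAL_FWHM_MM[int(coll)],
                    "measured_fwhm_mm": round(measured, 3),
                    "deviation_pct_reference": fwhm_deviation(ref_fwhm, measured, "reference"),
                    "deviation_pct_measured": fwhm_deviation(ref_fwhm, measured, "measured"),
                }
            )

        # similarity on the central plane, gel reconstruction vs truth
        ref_plane = truth.dose[ix]
        rec_plane = np.where(gel_dose.valid[ix], gel_dose.dose[ix], 0.0)
        ref_norm = 100.0 * ref_plane / ref_plane.max()
        rec_norm = 100.0 * rec_plane / max(rec_plane.max(), 1e-12)
        shift = align_translation(rec_norm, ref_norm, max_shift=5)
        rec_aligned = np.roll(rec_norm, (-shift[0], -shift[1]), axis=(0, 1))
        levels = [float(l) for l in cfg["similarity"]["levels"]]
        bands, _ = isodose_segment(ref_norm, levels)
        result = ssim_compare(rec_aligned, ref_norm, bands, levels, dynamic_range=100.0)
        rs_bands, _ = isodose_segment(ref_norm, [50.0])
        rs = ssim_compare(rec_aligned, ref_norm, rs_bands, [50.0], dynamic_range=100.0)
        similarity_summary[f"{int(coll)}mm"] = {
            "shift_px": list(shift),
            "global_ssim": round(result.global_ssim, 6),
            "per_band": [
                {"level": l, "ssim": (round(s, 6) if np.isfinite(s) else None)}
                for l, s in result.per_band
            ],
            "radiosurgical_ssim": round(rs.per_band[0][1], 6),
        }

    # --- pass/fail flags
    conventions = (
        ["reference", "measured"]
        if cfg["denominator"] == "both"
        else [cfg["denominator"]]
    )
    pass_flags = {}
    for method in ("gel", "film"):
        devs = [
            row[f"deviation_pct_{conv}"]
            for row in fwhm_rows
            if row["method"] == method
            for conv in conventions
        ]
        pass_flags[method] = bool(max(devs) <= cfg["threshold_pct"])

    report = QAReport(
        config_hash=_config_hash(cfg),
        seed=int(cfg["seed"]),
        version=__version__,
        calibration=calibration_summary,
        fwhm_table=fwhm_rows,
        similarity=similarity_summary,
        threshold_pct=float(cfg["threshold_pct"]),
        pass_flags=pass_flags,
    )
    if out_dir is not None:
        from .profiles import fwhm_table_to_csv

        write_outputs(gel_dose, report, out_dir)
        report.to_json(Path(out_dir) / "qa_report.json")
        fwhm_table_to_csv(fwhm_rows, Path(out_dir) / "fwhm_table.csv")
    return report
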