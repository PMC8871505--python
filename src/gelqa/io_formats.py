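"""Readers and writers for the formats the pipeline touches.

DICOM echo series (MR magnitude, echo time in the standard tag), 16-bit
grayscale TIFF film scans with dpi metadata, dose maps as CSV plus a JSON
grid sidecar, and a hashed output manifest.  Writers are deterministic:
repeated runs on identical inputs produce byte-identical CSV/JSON, and
DICOM UIDs are derived from content.
"""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, MRImageStorage, generate_uid
from PIL import Image
import tifffile

from .core import DoseGrid, EchoImagePair, FilmScan, GridSpec

__all__ = [
    "write_echo_series",
    "read_echo_series",
    "write_film_scan",
    "read_film_scan",
    "write_dose_csv",
    "read_dose_csv",
    "write_outputs",
]

_UID_ROOT = "1.2.826.0.1.3680043.10.1342."


def _content_uid(*entropy) -> str:
    return generate_uid(prefix=_UID_ROOT, entropy_srcs=[str(e) for e in entropy])


# ---------------------------------------------------------------------------
# DICOM echo series

def write_echo_series(pair: EchoImagePair, directory: Union[str, Path]) -> list:
    """Write a dual-echo pair as two DICOM series, one file per slice per echo.

    Slices are taken along the first (X) axis — the sagittal stack of the
    simulated acquisition.  Magnitude signals are rounded to uint16.
    Returns the list of written paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if pair.grid.ndim != 3:
        raise ValueError("echo series writer expects a 3D pair")
    paths = []
    study_uid = _content_uid("study", pair.grid.to_dict())
    for echo_idx, (signal, te) in enumerate(((pair.s1, pair.te1), (pair.s2, pair.te2))):
        if np.any(signal < 0) or np.any(signal > 65535):
            raise ValueError("signal outside uint16 range; rescale before writing")
        series_uid = _content_uid("series", echo_idx, te)
        for ix in range(pair.grid.shape[0]):
            ds = Dataset()
            ds.SOPClassUID = MRImageStorage
            ds.SOPInstanceUID = _content_uid("sop", echo_idx, te, ix)
            ds.StudyInstanceUID = study_uid
            ds.SeriesInstanceUID = series_uid
            ds.Modality = "MR"
            ds.SeriesNumber = echo_idx + 1
            ds.InstanceNumber = ix + 1
            ds.EchoTime = f"{te:g}"
            ds.ImageOrientationPatient = [0, 1, 0, 0, 0, 1]
            x = pair.grid.origin[0] + ix * pair.grid.spacing[0]
            ds.ImagePositionPatient = [
                f"{x:.10g}",
                f"{pair.grid.origin[1]:.10g}",
                f"{pair.grid.origin[2]:.10g}",
            ]
            ds.SliceLocation = f"{x:.10g}"
            ds.SliceThickness = f"{pair.grid.spacing[0]:.10g}"
            ds.PixelSpacing = [f"{pair.grid.spacing[1]:.10g}", f"{pair.grid.spacing[2]:.10g}"]
            arr = np.round(signal[ix]).astype(np.uint16)
            ds.Rows, ds.Columns = arr.shape
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.BitsAllocated = 16
            ds.BitsStored = 16
            ds.HighBit = 15
            ds.PixelRepresentation = 0
            ds.PixelData = arr.tobytes()
            meta = FileMetaDataset()
            meta.MediaStorageSOPClassUID = ds.SOPClassUID
            meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
            meta.TransferSyntaxUID = ExplicitVRLittleEndian
            ds.file_meta = meta
            path = directory / f"echo{echo_idx + 1}_slice{ix:03d}.dcm"
            ds.save_as(path, enforce_file_format=True)
            paths.append(path)
    return paths


def _load_series(datasets: list):
    if not datasets:
        raise ValueError("empty DICOM series")
    echo_times = {float(ds.EchoTime) for ds in datasets}
    if len(echo_times) > 1:
        raise ValueError(f"series mixes echo times {sorted(echo_times)}")
    datasets = sorted(
        datasets,
        key=lambda d: float(d.SliceLocation) if "SliceLocation" in d else d.InstanceNumber,
    )
    te = float(datasets[0].EchoTime)
    volume = np.stack([ds.pixel_array.astype(float) for ds in datasets])
    first = datasets[0]
    spacing_x = float(first.SliceThickness)
    if len(datasets) > 1:
        spacing_x = float(datasets[1].SliceLocation) - float(datasets[0].SliceLocation)
    grid = GridSpec(
        shape=volume.shape,
        spacing=(spacing_x, float(first.PixelSpacing[0]), float(first.PixelSpacing[1])),
        origin=tuple(float(v) for v in first.ImagePositionPatient),
    )
    return volume, te, grid


def read_echo_series(
    series1: Sequence[Union[str, Path]] | Union[str, Path],
    series2: Sequence[Union[str, Path]] | Union[str, Path],
) -> EchoImagePair:
    """Read two DICOM series (directories or file lists) into an echo pair.

    Slices are ordered by slice location; the geometries of the two series
    must agree exactly.  If both arguments point at the same directory the
    files are split into the two series by their echo-time tag.
    """

    def expand(s):
        p = Path(s) if isinstance(s, (str, Path)) else None
        if p is not None and p.is_dir():
            return sorted(p.glob("*.dcm"))
        return [Path(q) for q in (s if not isinstance(s, (str, Path)) else [s])]

    def load(paths):
        datasets = [pydicom.dcmread(p) for p in paths]
        for ds in datasets:
            if "EchoTime" not in ds:
                raise ValueError(f"missing echo-time tag in {ds.filename}")
        return datasets

    paths1, paths2 = expand(series1), expand(series2)
    if paths1 == paths2:
        # one directory holding both echoes: split by echo time
        by_te: dict[float, list] = {}
        for ds in load(paths1):
            by_te.setdefault(float(ds.EchoTime), []).append(ds)
        if len(by_te) != 2:
            raise ValueError(
                f"expected exactly 2 echo times in {series1}, found {sorted(by_te)}"
            )
        d1, d2 = (by_te[t] for t in sorted(by_te))
    else:
        d1, d2 = load(paths1), load(paths2)
    v1, te1, g1 = _load_series(d1)
    v2, te2, g2 = _load_series(d2)
    if g1 != g2:
        raise ValueError(f"geometry mismatch between echo series: {g1} vs {g2}")
    if te1 == te2:
        raise ValueError("the two series have identical echo times")
    return EchoImagePair(s1=v1, s2=v2, te1=te1, te2=te2, grid=g1)


# ---------------------------------------------------------------------------
# Film scans

def write_film_scan(scan: FilmScan, path: Union[str, Path]) -> Path:
    """Write a film scan as 16-bit grayscale TIFF with dpi metadata."""
    path = Path(path)
    arr = np.asarray(scan.pixels)
    if np.issubdtype(arr.dtype, np.floating):
        arr = np.round(np.clip(arr, 0, 65535)).astype(np.uint16)
    else:
        arr = arr.astype(np.uint16)
    dpi = scan.dpi if scan.dpi is not None else 25.4 / scan.pixel_spacing
    tifffile.imwrite(path, arr, resolution=(dpi, dpi), resolutionunit="INCH")
    return path


def read_film_scan(
    path: Union[str, Path], channel: str = "red", dpi_override: Optional[float] = None
) -> FilmScan:
    """Read a scanned film image and extract one analysis channel.

    Accepts 8/16-bit grayscale and 24/48-bit RGB(A) images; the red channel
    is the conventional radiochromic analysis channel.  Pixel spacing comes
    from the file's dpi metadata unless ``dpi_override`` is given.
    """
    path = Path(path)
    dpi = dpi_override
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            arr = page.asarray()
            if dpi is None:
                res = page.tags.get("XResolution")
                unit = page.tags.get("ResolutionUnit")
                if res is not None:
                    num, den = res.value
                    dpi = num / den
                    if unit is not None and getattr(unit.value, "name", str(unit.value)) in (
                        "CENTIMETER",
                        "3",
                    ):
                        dpi *= 2.54
    else:
        with Image.open(path) as img:
            if img.mode == "1":
                raise ValueError("1-bit images are not supported")
            if dpi is None and "dpi" in img.info:
                dpi = float(img.info["dpi"][0])
            arr = np.asarray(img)
    if arr.dtype == np.bool_ or (arr.dtype.kind in "iu" and arr.dtype.itemsize not in (1, 2)):
        raise ValueError(f"unsupported bit depth: {arr.dtype}")
    if arr.dtype.kind == "f":
        raise ValueError("floating-point images are not supported film scans")
    if arr.ndim == 3:
        channels = {"red": 0, "green": 1, "blue": 2}
        if channel not in channels or arr.shape[2] <= channels[channel]:
            raise ValueError(f"cannot extract channel {channel!r} from shape {arr.shape}")
        arr = arr[:, :, channels[channel]]
        used_channel = channel
    elif arr.ndim == 2:
        used_channel = "gray"
    else:
        raise ValueError(f"unsupported image dimensionality: {arr.ndim}")
    if dpi is None or dpi <= 0:
        raise ValueError("image carries no dpi metadata; pass dpi_override")
    return FilmScan(
        pixels=arr.astype(float), pixel_spacing=25.4 / dpi, channel=used_channel, dpi=float(dpi)
    )


# ---------------------------------------------------------------------------
# Dose CSV + JSON sidecar

def write_dose_csv(dose: DoseGrid, csv_path: Union[str, Path], json_path: Union[str, Path]) -> None:
    """Write a dose grid as one row per voxel (x,y,z,dose) plus JSON metadata.

    Numeric formatting is fixed (%.17g round-trips doubles exactly), so
    repeated runs write byte-identical files.
    """
    if not dose.valid.any():
        raise ValueError("refusing to write a dose grid with no valid voxels")
    grid = dose.grid
    coords = [grid.coords(a) for a in range(grid.ndim)]
    with open(csv_path, "w", newline="") as fh:
        fh.write("x_mm,y_mm,z_mm,dose_gy\n")
        for idx in np.ndindex(*grid.shape):
            if not dose.valid[idx]:
                continue
            pos = [coords[a][idx[a]] for a in range(grid.ndim)]
            while len(pos) < 3:
                pos.append(0.0)
            fh.write(
                f"{pos[0]:.17g},{pos[1]:.17g},{pos[2]:.17g},{dose.dose[idx]:.17g}\n"
            )
    meta = {
        "grid": grid.to_dict(),
        "provenance": dose.provenance,
        "n_valid": int(dose.valid.sum()),
        "n_saturated": int(dose.saturated.sum()),
    }
    with open(json_path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def read_dose_csv(csv_path: Union[str, Path], json_path: Union[str, Path]) -> DoseGrid:
    """Re-read a dose grid written by :func:`write_dose_csv`."""
    with open(json_path) as fh:
        meta = json.load(fh)
    grid = GridSpec.from_dict(meta["grid"])
    dose = np.zeros(grid.shape)
    valid = np.zeros(grid.shape, dtype=bool)
    with open(csv_path) as fh:
        header = fh.readline().strip()
        if header != "x_mm,y_mm,z_mm,dose_gy":
            raise ValueError(f"unrecognized dose CSV header: {header!r}")
        for line in fh:
            if not line.strip():
                continue
            x, y, z, d = (float(v) for v in line.split(","))
            idx = grid.nearest_index((x, y, z)[: grid.ndim])
            dose[idx] = d
            valid[idx] = True
    return DoseGrid(dose=dose, grid=grid, valid=valid, provenance=meta.get("provenance", "truth"))


# ---------------------------------------------------------------------------
# Run outputs + manifest

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _render_dose_png(dose: DoseGrid, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = dose.dose
    if arr.ndim == 3:
        ix = int(np.unravel_index(np.argmax(np.where(dose.valid, arr, -np.inf)), arr.shape)[0])
        plane = arr[ix]
    else:
        plane = arr
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(plane.T, origin="lower", cmap="viridis")
    fig.colorbar(im, ax=ax, label="dose (Gy)")
    ax.set_title(f"dose map ({dose.provenance})")
    fig.savefig(path, dpi=100, metadata={"Software": "gelqa"})
    plt.close(fig)


def write_outputs(dose: DoseGrid, report, directory: Union[str, Path]) -> dict:
    """Write dose CSV/JSON, the QA report and a rendered dose map, plus a
    manifest listing every file with its SHA-256 content hash.

    ``report`` may be a dict or any object exposing ``to_dict()``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if not dose.valid.any():
        raise ValueError("refusing to write outputs for an empty dose grid")
    if hasattr(report, "to_dict"):
        report = report.to_dict()
    files = {}
    write_dose_csv(dose, directory / "dose_map.csv", directory / "dose_map.json")
    files["dose_map.csv"] = directory / "dose_map.csv"
    files["dose_map.json"] = directory / "dose_map.json"
    with open(directory / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    files["report.json"] = directory / "report.json"
    _render_dose_png(dose, directory / "dose_map.png")
    files["dose_map.png"] = directory / "dose_map.png"
    manifest = {name: _sha256(path) for name, path in sorted(files.items())}
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
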