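"""Reading and writing volumes, force traces and result tables.

Volumes are exchanged as NIfTI-1 (read/write) or single-series axis-aligned
DICOM (read only); force traces and result tables as CSV, results also as
JSON.  Only axis-aligned orientations are supported: the specimens are
scanned cranio-caudally on a fixed table, and rejecting oblique geometry
keeps every downstream coordinate computation exact and testable.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom

from .core import CTVolume, CorrelationResult, ForceTrace

__all__ = [
    "read_volume",
    "write_volume",
    "read_force_trace",
    "write_force_trace",
    "write_results",
    "read_results",
]

_SLICE_GAP_RTOL = 1e-3


def write_volume(volume: CTVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 with a diagonal (axis-aligned) affine."""
    path = Path(path)
    affine = np.diag(np.append(volume.spacing, 1.0))
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.data.astype(np.float64), affine)
    nib.save(img, str(path))
    return path


def _read_nifti(path: Path) -> CTVolume:
    img = nib.load(str(path))
    affine = np.asarray(img.affine, dtype=np.float64)
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off_diag)) > 1e-6 * max(1.0, np.max(np.abs(rot))):
        raise ValueError(
            "oblique NIfTI orientation not supported; resample axis-aligned first"
        )
    spacing = np.diag(rot)
    if np.any(spacing <= 0):
        raise ValueError(
            "NIfTI affine must have positive diagonal (axis-aligned, no flips)"
        )
    data = np.asarray(img.dataobj, dtype=np.float64)
    return CTVolume(data, spacing, affine[:3, 3])


def _read_dicom_series(path: Path) -> CTVolume:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ".ima"))
    if not files:
        files = sorted(p for p in path.iterdir() if p.is_file())
    if not files:
        raise ValueError(f"no DICOM files found in {path}")
    slices = [pydicom.dcmread(str(f)) for f in files]

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in slices}
    if len(uids) != 1:
        raise ValueError(f"mixed DICOM series in {path}: {sorted(map(str, uids))}")

    for ds in slices:
        iop = np.asarray(ds.ImageOrientationPatient, dtype=np.float64)
        if not np.allclose(iop, [1, 0, 0, 0, 1, 0], atol=1e-6):
            raise ValueError("oblique DICOM orientation not supported")

    # rows index y, columns index x; slices stack along z
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    gaps = np.diff(zs)
    if len(gaps) == 0:
        raise ValueError("DICOM series must contain at least 2 slices")
    if np.any(gaps <= 0):
        raise ValueError("duplicate or non-monotone DICOM slice positions")
    gap = float(np.median(gaps))
    bad = np.where(np.abs(gaps - gap) > _SLICE_GAP_RTOL * gap)[0]
    if bad.size:
        raise ValueError(
            f"non-uniform DICOM slice gap at index {bad[0]}: "
            f"{gaps[bad[0]]:.6f} mm vs median {gap:.6f} mm"
        )

    first = slices[0]
    row_spacing, col_spacing = (float(v) for v in first.PixelSpacing)
    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(arr * slope + intercept)
    # pixel_array is (row, col) = (y, x); volume data is [x, y, z]
    data = np.stack([p.T for p in planes], axis=2)
    spacing = np.array([col_spacing, row_spacing, gap])
    origin = np.array(
        [
            float(first.ImagePositionPatient[0]),
            float(first.ImagePositionPatient[1]),
            zs[0],
        ]
    )
    return CTVolume(data, spacing, origin)


def read_volume(path: str | Path, format: str | None = None) -> CTVolume:
    """Read a CT volume in HU from NIfTI or an axis-aligned DICOM series.

    ``format`` may be "nifti" or "dicom_series"; by default a directory is
    treated as a DICOM series and a file as NIfTI.  DICOM rescale slope and
    intercept are applied so returned values are HU.
    """
    path = Path(path)
    if format is None:
        format = "dicom_series" if path.is_dir() else "nifti"
    if format == "nifti":
        if not path.exists():
            raise FileNotFoundError(path)
        return _read_nifti(path)
    if format == "dicom_series":
        if not path.is_dir():
            raise ValueError(f"dicom_series expects a directory, got {path}")
        return _read_dicom_series(path)
    raise ValueError(f"unknown volume format {format!r}")


def write_force_trace(trace: ForceTrace, path: str | Path) -> Path:
    """Write a force trace as CSV (time_s, force_N) plus a JSON sidecar."""
    path = Path(path)
    pd.DataFrame({"time_s": trace.t, "force_N": trace.F}).to_csv(
        path, index=False, float_format="%.15g"
    )
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {"sample_rate_hz": trace.sample_rate, "feed_velocity_mm_s": trace.feed_velocity},
            indent=1,
        )
    )
    return path


def read_force_trace(
    path: str | Path,
    sample_rate: float | None = None,
    feed_velocity: float | None = None,
) -> ForceTrace:
    """Read a force trace from CSV with columns time_s, force_N.

    Sampling rate and feed velocity come from a ``<name>.csv.json`` sidecar
    when present, from the keyword arguments otherwise (arguments win).
    Defaults: 1 kHz, 2 mm/s.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"time_s", "force_N"} - set(df.columns)
    if missing:
        raise ValueError(f"force CSV missing columns: {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=np.float64)
    F = df["force_N"].to_numpy(dtype=np.float64)
    if np.any(np.diff(t) <= 0):
        raise ValueError("non-uniform sampling: time column must be strictly increasing")

    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if sample_rate is None:
        sample_rate = float(meta.get("sample_rate_hz", 1000.0))
    if feed_velocity is None:
        feed_velocity = float(meta.get("feed_velocity_mm_s", 2.0))

    dt = np.diff(t)
    if not np.allclose(dt, 1.0 / sample_rate, rtol=1e-6):
        raise ValueError(
            "non-uniform sampling: time steps do not match sample rate "
            f"{sample_rate} Hz"
        )
    return ForceTrace(t, F, sample_rate=sample_rate, feed_velocity=feed_velocity)


_RESULT_COLUMNS = [
    "group",
    "n",
    "r_spearman",
    "p",
    "r_pearson",
    "R2",
    "strength",
    "significant",
    "length_mm",
]


def write_results(rows: list[CorrelationResult], path: str | Path) -> tuple[Path, Path]:
    """Write correlation results as CSV and JSON (same stem, both formats)."""
    if not rows:
        raise ValueError("no result rows to write")
    path = Path(path)
    records = []
    for r in rows:
        d = dataclasses.asdict(r)
        d["significant"] = r.significant
        records.append(d)
    df = pd.DataFrame.from_records(records)[_RESULT_COLUMNS]
    csv_path = path.with_suffix(".csv")
    json_path = path.with_suffix(".json")
    df.to_csv(csv_path, index=False, float_format="%.15g")
    json_path.write_text(json.dumps(records, indent=1))
    return csv_path, json_path


def read_results(path: str | Path) -> list[CorrelationResult]:
    """Read correlation results back from the JSON written by write_results."""
    records = json.loads(Path(path).read_text())
    out = []
    for d in records:
        d = dict(d)
        d.pop("significant", None)
        out.append(CorrelationResult(**d))
    return out
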