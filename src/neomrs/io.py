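"""Disk I/O for spectra, label maps and cohort tables.

All other modules touch disk only through this module. Formats:

* Spectrum: two-column plain text (real, imag) plus a JSON sidecar with the
  acquisition metadata; the jMRUI ASCII export dialect is accepted on read
  (header lines are skipped, the first two numeric columns are taken).
* Label map: NIfTI (.nii/.nii.gz) with integer data, plus a two-column TSV
  mapping label IDs to names.
* Cohort table: CSV with stable column order.
"""

from __future__ import annotations

import json
import os

import nibabel as nib
import numpy as np
import pandas as pd

from .core import LabelMap, Spectrum
from .errors import FormatError, IntegrityError

SIDECAR_REQUIRED = ("sw_hz", "f0_mhz", "tr_ms", "te_ms", "n_averages",
                    "n_dummy", "n_points", "center_ppm")

COHORT_KEY_COLUMNS = ("subject", "group", "litter", "region")


def _sidecar_path(path):
    base, _ = os.path.splitext(path)
    return base + ".json"


def write_spectrum(spectrum: Spectrum, path, sidecar_path=None):
    """Write a spectrum as (real, imag) text plus JSON sidecar.

    Intensities are written with 17 significant digits so a read round trip
    reproduces them bit-exactly.
    """
    if sidecar_path is None:
        sidecar_path = _sidecar_path(path)
    inten = np.asarray(spectrum.intensity, dtype=complex)
    data = np.column_stack([inten.real, inten.imag])
    np.savetxt(path, data, fmt="%.17e")
    center = float(spectrum.ppm_axis[spectrum.n_points // 2])
    meta = {
        "sw_hz": spectrum.sw_hz,
        "f0_mhz": spectrum.f0_mhz,
        "tr_ms": spectrum.tr_ms,
        "te_ms": spectrum.te_ms,
        "n_averages": spectrum.n_averages,
        "n_dummy": spectrum.n_dummy,
        "n_points": spectrum.n_points,
        "center_ppm": center,
        "region_label": spectrum.region_label,
        "is_water_reference": spectrum.is_water_reference,
        "subject_id": spectrum.subject_id,
    }
    with open(sidecar_path, "w") as fh:
        json.dump(meta, fh, indent=1)
    return path


def _parse_numeric_columns(path):
    """Parse whitespace/comma-separated numeric rows, skipping header lines.

    Tolerates the jMRUI ASCII dialect (text headers such as
    ``PointsInDataset:``, ``SignalNames:`` and 4-column sig/FFT exports).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.replace(",", " ").split()
            if not parts:
                continue
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                # jMRUI "Key: value" headers may end in a number; only rows
                # that are entirely numeric count as data.
                continue
            rows.append(vals)
    if not rows:
        raise FormatError(f"{path}: no numeric data rows found")
    ncol = min(len(r) for r in rows)
    return np.array([r[:ncol] for r in rows], dtype=float)


def read_spectrum(path, sidecar_path=None) -> Spectrum:
    """Read a spectrum written by :func:`write_spectrum` or a jMRUI ASCII export."""
    if sidecar_path is None:
        sidecar_path = _sidecar_path(path)
    try:
        with open(sidecar_path) as fh:
            meta = json.load(fh)
    except json.JSONDecodeError as e:
        raise FormatError(f"{sidecar_path}: malformed JSON sidecar: {e}") from e
    for key in SIDECAR_REQUIRED:
        if key not in meta:
            raise FormatError(f"{sidecar_path}: sidecar missing field '{key}'")
    data = _parse_numeric_columns(path)
    n = int(meta["n_points"])
    if data.shape[0] != n:
        raise IntegrityError(
            f"{path}: {data.shape[0]} samples but sidecar declares {n}")
    if data.shape[1] >= 2:
        inten = data[:, 0] + 1j * data[:, 1]
    else:
        inten = data[:, 0].astype(complex)
    k = np.arange(n)
    hz = (k - n // 2) * meta["sw_hz"] / n
    ppm = meta["center_ppm"] + hz / meta["f0_mhz"]
    return Spectrum(
        ppm_axis=ppm, intensity=inten, sw_hz=meta["sw_hz"],
        f0_mhz=meta["f0_mhz"], tr_ms=meta["tr_ms"], te_ms=meta["te_ms"],
        n_averages=int(meta["n_averages"]), n_dummy=int(meta["n_dummy"]),
        region_label=meta.get("region_label", ""),
        is_water_reference=bool(meta.get("is_water_reference", False)),
        subject_id=meta.get("subject_id", ""),
    )


def write_label_map(label_map: LabelMap, path, names_path=None):
    """Write a label map as NIfTI plus a two-column id<TAB>name TSV."""
    affine = np.diag(list(label_map.voxel_size_mm) + [1.0])
    affine[:3, 3] = label_map.origin_mm
    img = nib.Nifti1Image(label_map.volume.astype(np.int16), affine)
    nib.save(img, path)
    if names_path is not None:
        with open(names_path, "w") as fh:
            fh.write("id\tname\n")
            for lid in sorted(label_map.label_names):
                fh.write(f"{lid}\t{label_map.label_names[lid]}\n")
    return path


def read_label_names(names_path) -> dict:
    names = {}
    with open(names_path) as fh:
        header = fh.readline()
        if "\t" not in header:
            raise FormatError(f"{names_path}: expected two tab-separated columns")
        for line in fh:
            if not line.strip():
                continue
            lid, name = line.rstrip("\n").split("\t", 1)
            names[int(lid)] = name
    return names


def read_label_map(path, names_path) -> LabelMap:
    """Read an integer NIfTI parcellation and its label-name table."""
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if np.allclose(data, np.round(data)):
            raise TypeError(
                f"{path}: label data stored as {data.dtype}; re-save as integer")
        raise TypeError(f"{path}: non-integer label data ({data.dtype})")
    names = read_label_names(names_path)
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=float)
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return LabelMap(volume=data, voxel_size_mm=voxel_size,
                    origin_mm=origin, label_names=names)


def write_cohort_table(cohort_df: pd.DataFrame, path):
    """Write a cohort table as CSV with key columns first; round-trip stable.

    Raises IntegrityError on duplicated (subject, region) rows.
    """
    df = cohort_df.copy()
    missing = [c for c in COHORT_KEY_COLUMNS if c not in df.columns]
    if missing:
        raise IntegrityError(f"cohort table missing key columns: {missing}")
    if len(df) and df.duplicated(subset=["subject", "region"]).any():
        dup = df[df.duplicated(subset=["subject", "region"], keep=False)]
        raise IntegrityError(
            "duplicate (subject, region) rows: "
            f"{sorted(set(map(tuple, dup[['subject', 'region']].values)))}")
    ordered = list(COHORT_KEY_COLUMNS) + [c for c in df.columns
                                          if c not in COHORT_KEY_COLUMNS]
    df[ordered].to_csv(path, index=False)
    return path


def read_cohort_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_KEY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: cohort table missing columns {missing}")
    if len(df) and df.duplicated(subset=["subject", "region"]).any():
        raise IntegrityError(f"{path}: duplicate (subject, region) rows")
    return df
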