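"""Readers and writers for spectra, peak lists, peak matrices and metadata.

Plain two-column text spectra (TSV/CSV) are the canonical interchange
format; mzML is supported read-only as a convenience. Readers validate and
reject malformed input rather than repairing it silently, and every
writer/reader pair inverts on valid data (bin m/z to its printed 2-decimal
precision, intensities to 12 significant digits).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import PeakMatrix, Peak, Spectrum, SubjectRecord

PathLike = Union[str, Path]

_FORMATS = ("tsv", "csv", "mzml")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix == "txt":
        return "tsv"
    if suffix in _FORMATS:
        return suffix
    raise ValueError(f"cannot infer spectrum format from suffix {path.suffix!r}")


def read_spectrum(
    path: PathLike,
    format: Optional[str] = None,
    subject_id: Optional[str] = None,
    run_id: Optional[str] = None,
) -> Spectrum:
    """Read one spectrum from a two-column text file or an mzML file.

    Unsorted m/z values are sorted (intensities permuted accordingly);
    negative intensities and duplicate m/z values are errors. For mzML the
    first spectrum in the file is returned.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown spectrum format {fmt!r}; expected one of {_FORMATS}")
    sid = subject_id if subject_id is not None else path.stem
    rid = run_id if run_id is not None else path.stem
    if fmt == "mzml":
        mz, inten = _read_mzml_first_spectrum(path)
        return Spectrum(mz, inten, sid, rid)

    sep = "\t" if fmt == "tsv" else ","
    table = pd.read_csv(
        path, sep=sep, header=None, comment="#", dtype=float,
        float_precision="round_trip",
    )
    if table.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns, found {table.shape[1]}")
    if table.isna().any().any():
        raise ValueError(f"{path}: malformed (non-numeric or missing) values")
    return Spectrum(table[0].to_numpy(), table[1].to_numpy(), sid, rid)


def write_spectrum(spectrum: Spectrum, path: PathLike, format: Optional[str] = None) -> Path:
    """Write a spectrum as two-column text at full float precision."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "mzml":
        raise ValueError("mzML is read-only")
    sep = "\t" if fmt == "tsv" else ","
    with open(path, "w") as fh:
        for m, y in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{m:.17g}{sep}{y:.17g}\n")
    return path


def write_peak_list(peaks: Sequence[Peak], path: PathLike) -> Path:
    pd.DataFrame(
        {
            "centroid_mz": [p.centroid_mz for p in peaks],
            "intensity": [p.intensity for p in peaks],
            "snr": [p.snr for p in peaks],
        }
    ).to_csv(path, index=False, float_format="%.12g")
    return Path(path)


def read_peak_list(path: PathLike) -> list[Peak]:
    table = pd.read_csv(path)
    return [
        Peak(float(r.centroid_mz), float(r.intensity), float(r.snr))
        for r in table.itertuples()
    ]


def write_peak_matrix(matrix: PeakMatrix, path: PathLike) -> Path:
    """Write a peak matrix as CSV: sample_id column + one column per bin.

    Column headers are the consensus bin m/z formatted to 2 decimals;
    intensities are written to 12 significant digits.
    """
    matrix.to_dataframe().to_csv(path, float_format="%.12g")
    return Path(path)


def read_peak_matrix(path: PathLike, tolerance: float = 0.001) -> PeakMatrix:
    """Inverse of :func:`write_peak_matrix` (header-only file -> 0-bin matrix)."""
    table = pd.read_csv(path, index_col=0, float_precision="round_trip")
    sample_ids = [str(s) for s in table.index]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"{path}: duplicate sample_id")
    bin_mz = np.array([float(c) for c in table.columns])
    return PeakMatrix(bin_mz, sample_ids, table.to_numpy(dtype=float), tolerance)


def _read_mzml_first_spectrum(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Decode the first spectrum of an mzML document.

    Minimal reader for profile import: handles 32/64-bit float binary
    arrays, uncompressed or zlib-compressed, identified by the standard
    PSI-MS cvParam accessions. Vendor conversions beyond that (numpress
    compression, ion-mobility arrays) are out of scope.
    """
    import base64
    import zlib

    from lxml import etree

    ns = "{http://psi.hupo.org/ms/mzml}"
    arrays: dict[str, np.ndarray] = {}
    for _, spectrum in etree.iterparse(str(path), tag=f"{ns}spectrum"):
        for bda in spectrum.iter(f"{ns}binaryDataArray"):
            accessions = {cv.get("accession") for cv in bda.iter(f"{ns}cvParam")}
            dtype = "<f4" if "MS:1000521" in accessions else "<f8"
            binary = bda.find(f"{ns}binary")
            raw = base64.b64decode(binary.text or "")
            if "MS:1000574" in accessions:  # zlib compression
                raw = zlib.decompress(raw)
            values = np.frombuffer(raw, dtype=dtype).astype(float)
            if "MS:1000514" in accessions:
                arrays["mz"] = values
            elif "MS:1000515" in accessions:
                arrays["intensity"] = values
        break
    if "mz" not in arrays or "intensity" not in arrays:
        raise ValueError(f"{path}: no spectrum with m/z and intensity arrays found")
    return arrays["mz"], arrays["intensity"]


# -- subject metadata ---------------------------------------------------------

_META_COLUMNS = ["subject_id", "group", "subtype", "survival_months", "event", "run_id"]


def write_records(records: Sequence[SubjectRecord], path: PathLike) -> Path:
    rows = []
    for r in records:
        for run in r.runs or [""]:
            rows.append(
                [r.subject_id, r.group, r.subtype or "", r.survival_months,
                 "" if r.event is None else bool(r.event), run]
            )
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, index=False, float_format="%.12g")
    return Path(path)


def read_records(path: PathLike) -> list[SubjectRecord]:
    table = pd.read_csv(path, dtype={"subject_id": str, "run_id": str})
    missing = [c for c in _META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    records: dict[str, SubjectRecord] = {}
    for row in table.itertuples():
        sid = str(row.subject_id)
        months = None if pd.isna(row.survival_months) else float(row.survival_months)
        event = None if pd.isna(row.event) else bool(row.event)
        subtype = None if pd.isna(row.subtype) or row.subtype == "" else str(row.subtype)
        run = "" if pd.isna(row.run_id) else str(row.run_id)
        if sid in records:
            if run:
                records[sid].runs.append(run)
        else:
            records[sid] = SubjectRecord(
                sid, str(row.group), subtype, months, event, [run] if run else []
            )
    return list(records.values())


def write_ground_truth(truth: dict, path: PathLike) -> Path:
    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True, default=_default)
    return Path(path)
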