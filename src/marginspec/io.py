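"""Reading and writing spectral datasets.

Supported formats:

* CSV/TSV matrix — one spectrum per row, numeric wavenumber header, optional
  leading metadata columns (``patient_id, tissue, map_id, px_row, px_col``).
* JCAMP-DX — single-spectrum, ``##XYDATA=(X++(Y..Y))`` with AFFN numbers.
* HDF5 — optional container for whole datasets (axis + matrix + metadata).
"""

from __future__ import annotations

import re
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import Modality, SpectralDataset, Spectrum, WavenumberAxis
from .errors import FormatError

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_jcamp",
    "read_hdf5",
    "write_hdf5",
]


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except (TypeError, ValueError):
        return False


def read_matrix(
    path: str | Path,
    modality: Modality | str = Modality.FTIR,
    label_source: str = "tissue",
) -> SpectralDataset:
    """Read a CSV/TSV spectrum matrix with a wavenumber header row.

    Columns whose names parse as numbers are wavenumber channels; all other
    columns are carried as per-spectrum metadata.  A descending header is
    reversed to the internal ascending convention, together with the
    intensities.  ``label_source`` names the metadata column holding the
    tissue label (renamed to ``tissue`` if different).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as exc:  # ragged rows
        raise FormatError(f"malformed matrix file {path}: {exc}") from exc
    wn_cols = [c for c in df.columns if _is_number(c)]
    if len(wn_cols) < 2:
        raise FormatError("header must contain at least two numeric wavenumbers")
    wn = np.array([float(c) for c in wn_cols])
    diffs = np.diff(wn)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise FormatError("wavenumber header must be strictly monotone")
    meta_cols = [c for c in df.columns if c not in wn_cols]
    intens = df[wn_cols].to_numpy(dtype=float)
    if np.isnan(intens).any():
        raise FormatError("ragged or non-numeric intensity rows")
    if diffs[0] < 0:  # descending header: reverse consistently
        wn = wn[::-1]
        intens = intens[:, ::-1]
    meta = df[meta_cols].copy() if meta_cols else None
    if meta is not None and label_source in meta.columns and label_source != "tissue":
        meta = meta.rename(columns={label_source: "tissue"})
    return SpectralDataset(WavenumberAxis(wn), intens, modality, meta)


def write_matrix(ds: SpectralDataset, path: str | Path) -> None:
    """Write a dataset as a CSV/TSV matrix (inverse of :func:`read_matrix`)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    wn_cols = [format(float(v), ".17g") for v in ds.axis.values]  # round-trip exact
    out = pd.DataFrame(ds.intensities, columns=wn_cols)
    meta = ds.meta.copy()
    for col in reversed([c for c in meta.columns]):
        out.insert(0, col, meta[col].to_numpy())
    out.to_csv(path, sep=sep, index=False, float_format="%.17g")


_JCAMP_NUM = re.compile(r"[+-]?\d+\.?\d*(?:[eE][+-]?\d+)?")


def read_jcamp(path: str | Path, modality: Modality | str = Modality.FTIR) -> Spectrum:
    """Read a single-spectrum JCAMP-DX file (``XYDATA=(X++(Y..Y))``, AFFN).

    Applies ``XFACTOR``/``YFACTOR`` scaling.  Compressed (SQZ/DIF/DUP) forms
    and multi-block files are not supported.
    """
    path = Path(path)
    header: dict[str, str] = {}
    x_vals: list[float] = []
    y_vals: list[float] = []
    in_xydata = False
    for raw in path.read_text().splitlines():
        line = raw.split("$$")[0].strip()  # strip comments
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "XYDATA":
                if "X++(Y..Y)" not in value.replace(" ", ""):
                    raise FormatError(f"unsupported XYDATA form: {value}")
                in_xydata = True
                continue
            if in_xydata:  # any following label ends the table (e.g. END)
                in_xydata = False
            header[key] = value
            continue
        if in_xydata:
            nums = [float(t) for t in _JCAMP_NUM.findall(line)]
            if len(nums) < 2:
                raise FormatError(f"bad XYDATA line: {raw!r}")
            x_vals.append(nums[0])
            y_vals.extend(nums[1:])
    if not y_vals:
        raise FormatError("no XYDATA table found")
    xfactor = float(header.get("XFACTOR", 1.0))
    yfactor = float(header.get("YFACTOR", 1.0))
    npoints = int(float(header.get("NPOINTS", len(y_vals))))
    if npoints != len(y_vals):
        raise FormatError(f"NPOINTS={npoints} but {len(y_vals)} ordinates read")
    firstx = float(header.get("FIRSTX", x_vals[0] * xfactor)) if x_vals else float(
        header.get("FIRSTX")
    )
    lastx = float(header.get("LASTX", firstx))
    x = np.linspace(firstx, lastx, npoints)
    y = np.array(y_vals) * yfactor
    if x[0] > x[-1]:
        x, y = x[::-1], y[::-1]
    meta = {"title": header.get("TITLE", path.stem)}
    return Spectrum(WavenumberAxis(x), y, modality, meta)


def write_hdf5(ds: SpectralDataset, path: str | Path) -> None:
    """Store a dataset in an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("wavenumbers", data=ds.axis.values)
        f.create_dataset("intensities", data=ds.intensities)
        f.attrs["modality"] = ds.modality.value
        grp = f.create_group("meta")
        for col in ds.meta.columns:
            data = ds.meta[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            grp.create_dataset(col, data=data)


def read_hdf5(path: str | Path) -> SpectralDataset:
    """Load a dataset written by :func:`write_hdf5`."""
    with h5py.File(path, "r") as f:
        axis = WavenumberAxis(f["wavenumbers"][:])
        intens = f["intensities"][:]
        modality = Modality(f.attrs["modality"])
        meta = {}
        for col in f["meta"]:
            data = f["meta"][col][:]
            if data.dtype.kind == "S":
                data = data.astype(str)
            meta[col] = data
    meta_df = pd.DataFrame(meta) if meta else None
    return SpectralDataset(axis, intens, modality, meta_df)
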