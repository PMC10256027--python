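"""Delimited-text I/O for spectra and reference-concentration tables.

Spectra file (wide CSV, UTF-8, "." decimal): one uniform wavelength grid
per file, columns ``sample_id, variety, temperature_c, date, state,
wl_<nm>, ...`` with wavelengths embedded in the column names at 2-decimal
precision.  Reference file: ``sample_id, method_role, fructose_g_l,
glucose_g_l, malic_acid_g_l, tartaric_acid_g_l`` with concentrations in
g/L from a named method role ("primary" = HPLC-grade, "secondary" =
FTIR-grade).
"""
from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import GridError, SpectraCollection, SpectraError, Spectrum, STATES

__all__ = [
    "ANALYTES",
    "read_spectra",
    "write_spectra",
    "read_reference",
    "write_reference",
]

#: Analytes quantified throughout, in canonical order.
ANALYTES = ("fructose", "glucose", "malic_acid", "tartaric_acid")

_META_COLUMNS = ["sample_id", "variety", "temperature_c", "date", "state"]
_REF_COLUMNS = ["sample_id", "method_role"] + [f"{a}_g_l" for a in ANALYTES]


def write_spectra(collection: SpectraCollection, path: str | Path) -> None:
    """Write a uniform-grid collection to the wide CSV format."""
    grid = collection.grid  # raises on empty / non-uniform collections
    cols = _META_COLUMNS + [f"wl_{w:.2f}" for w in grid]
    rows = []
    for s in collection:
        rows.append(
            [s.sample_id, s.variety, s.temperature_c, s.date or "", s.state]
            + list(s.values)
        )
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_spectra(path: str | Path) -> SpectraCollection:
    """Read a spectra CSV, validating grid, states and row shapes."""
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        try:
            header = next(csv.reader(fh))
        except StopIteration:
            raise SpectraError(f"{path.name}: empty spectra file") from None
    if header[: len(_META_COLUMNS)] != _META_COLUMNS:
        raise SpectraError(
            f"{path.name}: header must start with {', '.join(_META_COLUMNS)}"
        )
    wl_cols = header[len(_META_COLUMNS):]
    if not wl_cols:
        raise SpectraError(f"{path.name}: no wavelength columns")
    bad = [c for c in wl_cols if not c.startswith("wl_")]
    if bad:
        raise SpectraError(f"{path.name}: non-wavelength trailing column {bad[0]!r}")
    if len(set(wl_cols)) != len(wl_cols):
        dup = next(c for c in wl_cols if wl_cols.count(c) > 1)
        raise SpectraError(f"{path.name}: duplicated wavelength column {dup!r}")
    try:
        grid = np.array([float(c[3:]) for c in wl_cols])
    except ValueError as exc:
        raise SpectraError(f"{path.name}: unparseable wavelength column: {exc}") from None
    if not np.all(np.diff(grid) > 0):
        raise GridError(f"{path.name}: wavelength columns not strictly increasing")

    try:
        df = pd.read_csv(path, dtype={"sample_id": str, "variety": str,
                                      "date": str, "state": str},
                         float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise SpectraError(f"{path.name}: malformed rows: {exc}") from None
    if df.empty:
        raise SpectraError(f"{path.name}: file has a header but no spectra")

    spectra = []
    values = df[wl_cols].to_numpy(dtype=float)
    for i, row in enumerate(df.itertuples(index=False)):
        if row.state not in STATES:
            raise SpectraError(
                f"{path.name}, line {i + 2}: unknown state {row.state!r}"
            )
        vals = values[i]
        if not np.all(np.isfinite(vals)):
            raise SpectraError(
                f"{path.name}, line {i + 2}: missing or non-finite intensity values"
            )
        date = None if (isinstance(row.date, float) and np.isnan(row.date)) else row.date
        date = date or None
        spectra.append(
            Spectrum(
                sample_id=row.sample_id,
                variety=row.variety,
                temperature_c=float(row.temperature_c),
                wavelengths_nm=grid.copy(),
                values=vals,
                state=row.state,
                date=date,
            )
        )
    return SpectraCollection(spectra)


def write_reference(table: pd.DataFrame, path: str | Path) -> None:
    """Write a reference-concentration table (validates the schema first)."""
    _validate_reference(table, str(path))
    table.to_csv(path, index=False, columns=_REF_COLUMNS)


def read_reference(path: str | Path) -> pd.DataFrame:
    """Read and validate a reference-concentration table."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"sample_id": str, "method_role": str},
                         float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise SpectraError(f"{path.name}: empty reference file") from None
    _validate_reference(df, path.name)
    return df


def _validate_reference(df: pd.DataFrame, name: str) -> None:
    missing = [c for c in _REF_COLUMNS if c not in df.columns]
    if missing:
        raise SpectraError(f"{name}: missing reference column {missing[0]!r}")
    for a in ANALYTES:
        col = df[f"{a}_g_l"]
        if not np.all(np.isfinite(col.to_numpy(dtype=float))):
            raise SpectraError(f"{name}: non-finite values in column '{a}_g_l'")
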