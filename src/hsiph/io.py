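"""File I/O: ENVI-style hypercubes, a portable ``.npz`` container, and spectra CSV.

The ENVI format is an ASCII ``.hdr`` file (samples/lines/bands, interleave,
data type, wavelength list) next to a raw binary file.  Only the subset this
pipeline needs is supported: BIL/BIP/BSQ interleaves, little-endian IEEE
float32/float64 (ENVI data types 4 and 5), byte order 0.  The reader
validates the header wavelength list against the declared band count.

Spectra tables are pandas DataFrames with columns ``sample_code``,
``region_id``, ``pH_ref`` and one column per band named ``w0350 ... w1100``.
"""

from __future__ import annotations

import os
import re

import numpy as np
import pandas as pd

from .core import Hypercube, WavelengthGrid

__all__ = [
    "write_envi",
    "read_envi",
    "write_cube_npz",
    "read_cube_npz",
    "wavelength_columns",
    "spectra_matrix",
    "make_spectra_table",
    "write_spectra_csv",
    "read_spectra_csv",
]

_DTYPES = {4: np.float32, 5: np.float64}
_DTYPE_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def write_envi(cube: Hypercube, path: str, interleave: str = "bil",
               dtype=np.float32) -> None:
    """Write ``path``.hdr + ``path``.raw (ENVI header + raw binary)."""
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    dtype = np.dtype(dtype)
    if dtype not in _DTYPE_CODES:
        raise ValueError(f"unsupported dtype {dtype} (float32/float64 only)")
    rows, cols, bands = cube.values.shape
    # in-memory layout is (lines, samples, bands) == BIP ordering
    if interleave == "bip":
        data = cube.values
    elif interleave == "bil":
        data = np.transpose(cube.values, (0, 2, 1))  # (lines, bands, samples)
    else:  # bsq
        data = np.transpose(cube.values, (2, 0, 1))  # (bands, lines, samples)
    wl = ", ".join(f"{w:g}" for w in cube.grid.wavelengths)
    header = (
        "ENVI\n"
        f"description = {{hsiph hypercube, domain={cube.domain}}}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength units = nm\n"
        f"wavelength = {{ {wl} }}\n"
    )
    with open(path + ".hdr", "w") as fh:
        fh.write(header)
    np.ascontiguousarray(data, dtype=dtype).tofile(path + ".raw")


def _parse_envi_header(text: str) -> dict:
    fields = {}
    # join wrapped { ... } blocks before splitting lines
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_envi(path: str, domain: str = "reflectance") -> Hypercube:
    """Read an ENVI ``path``.hdr + ``path``.raw pair written by :func:`write_envi`."""
    with open(path + ".hdr") as fh:
        fields = _parse_envi_header(fh.read())
    cols = int(fields["samples"])
    rows = int(fields["lines"])
    bands = int(fields["bands"])
    interleave = fields.get("interleave", "bil").lower()
    code = int(fields.get("data type", 4))
    if code not in _DTYPES:
        raise ValueError(f"unsupported ENVI data type {code}")
    if int(fields.get("byte order", 0)) != 0:
        raise ValueError("only little-endian (byte order 0) ENVI files are supported")
    wl_text = fields.get("wavelength", "").strip().strip("{}")
    wavelengths = np.array([float(t) for t in wl_text.split(",") if t.strip()])
    if wavelengths.size != bands:
        raise ValueError(
            f"header lists {wavelengths.size} wavelengths but declares {bands} bands"
        )
    steps = np.diff(wavelengths)
    if wavelengths.size < 2 or not np.allclose(steps, steps[0]):
        raise ValueError("wavelength list is not a uniform grid")
    grid = WavelengthGrid(float(wavelengths[0]), float(steps[0]), bands)

    data = np.fromfile(path + ".raw", dtype=_DTYPES[code])
    expected = rows * cols * bands
    if data.size != expected:
        raise ValueError(f"binary holds {data.size} values, header implies {expected}")
    if interleave == "bip":
        values = data.reshape(rows, cols, bands)
    elif interleave == "bil":
        values = data.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bsq":
        values = data.reshape(bands, rows, cols).transpose(1, 2, 0)
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")
    return Hypercube(np.ascontiguousarray(values, dtype=float), grid, domain=domain)


def write_cube_npz(cube: Hypercube, path: str) -> None:
    """Portable compressed container (numpy ``.npz``) for tests and scratch."""
    np.savez_compressed(
        path,
        values=cube.values,
        start_nm=cube.grid.start_nm,
        step_nm=cube.grid.step_nm,
        domain=np.array(cube.domain),
    )


def read_cube_npz(path: str) -> Hypercube:
    with np.load(path, allow_pickle=False) as z:
        grid = WavelengthGrid(float(z["start_nm"]), float(z["step_nm"]),
                              int(z["values"].shape[2]))
        return Hypercube(z["values"], grid, domain=str(z["domain"]))


# ---------------------------------------------------------------------------
# spectra tables

META_COLUMNS = ["sample_code", "region_id", "pH_ref"]


def wavelength_columns(grid: WavelengthGrid) -> list:
    """Column names ``w0350 ... w1100`` for the grid's bands."""
    return [f"w{int(round(w)):04d}" for w in grid.wavelengths]


def spectra_matrix(table: pd.DataFrame, grid: WavelengthGrid) -> np.ndarray:
    """Extract the (n_rows, n_bands) spectra block as a float array."""
    return table[wavelength_columns(grid)].to_numpy(dtype=float)


def make_spectra_table(sample_codes, region_ids, ph_refs, spectra: np.ndarray,
                       grid: WavelengthGrid) -> pd.DataFrame:
    """Assemble a spectra table from parallel arrays; validates invariants."""
    spectra = np.asarray(spectra, dtype=float)
    if spectra.ndim != 2 or spectra.shape[1] != grid.n_bands:
        raise ValueError(f"spectra shape {spectra.shape} does not match grid")
    table = pd.DataFrame(spectra, columns=wavelength_columns(grid))
    table.insert(0, "pH_ref", np.asarray(ph_refs, dtype=float))
    table.insert(0, "region_id", np.asarray(region_ids, dtype=int))
    table.insert(0, "sample_code", list(sample_codes))
    if table.duplicated(["sample_code", "region_id"]).any():
        raise ValueError("sample_code x region_id pairs must be unique")
    if not ((table["pH_ref"] > 0) & (table["pH_ref"] < 14)).all():
        raise ValueError("pH_ref values must lie in (0, 14)")
    return table


def write_spectra_csv(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, index=False)


def read_spectra_csv(path: str) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"spectra CSV is missing columns {missing}")
    return table
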