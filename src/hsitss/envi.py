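"""Minimal ENVI cube I/O: ASCII ``.hdr`` header plus flat binary data file.

Supports band-interleaved-by-line (BIL) and band-sequential (BSQ) layouts
with IEEE little-endian types, which covers what this pipeline writes and
what reflectance-imaging workstations typically export. The header must
carry a ``wavelength`` list; it becomes the cube's grid.
"""
from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .containers import Hypercube

_DTYPES = {4: np.dtype("<f4"), 5: np.dtype("<f8"), 12: np.dtype("<u2"), 2: np.dtype("<i2")}
_DTYPE_CODES = {np.dtype("float32"): 4, np.dtype("float64"): 5}


def write_envi(cube: Hypercube, path: str | Path, interleave: str = "bil",
               dtype: str = "float32") -> Path:
    """Write ``<path>.hdr`` + ``<path>`` (raw binary). Returns the header path."""
    interleave = interleave.lower()
    if interleave not in ("bil", "bsq"):
        raise ValueError("interleave must be 'bil' or 'bsq'")
    path = Path(path)
    dt = np.dtype(dtype).newbyteorder("<")
    rows, cols, bands = cube.shape
    if interleave == "bil":  # line-major: (rows, bands, cols)
        data = np.transpose(cube.values, (0, 2, 1))
    else:  # bsq: (bands, rows, cols)
        data = np.transpose(cube.values, (2, 0, 1))
    data.astype(dt).tofile(path)
    wavelengths = ", ".join(f"{w:.4f}" for w in cube.grid)
    hdr = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[np.dtype(dtype)]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wavelengths} }}\n"
    )
    hdr_path = path.with_suffix(path.suffix + ".hdr")
    hdr_path.write_text(hdr)
    return hdr_path


def _parse_header(text: str) -> dict:
    # fold the brace-delimited lists onto one line, then split on '='
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines():
        if "=" in line:
            key, _, value = line.partition("=")
            fields[key.strip().lower()] = value.strip()
    return fields


def read_envi(header_path: str | Path) -> Hypercube:
    """Read an ENVI cube given its ``.hdr`` path; wavelengths are mandatory."""
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text())
    rows = int(fields["lines"])
    cols = int(fields["samples"])
    bands = int(fields["bands"])
    interleave = fields.get("interleave", "bsq").lower()
    dtype = _DTYPES[int(fields["data type"])]
    if int(fields.get("byte order", 0)) != 0:
        raise ValueError("only little-endian (byte order = 0) files are supported")
    if "wavelength" not in fields:
        raise ValueError("header lacks the mandatory 'wavelength' list")
    grid = np.array(
        [float(tok) for tok in fields["wavelength"].strip("{} \t").split(",") if tok.strip()]
    )
    data_path = header_path.with_suffix("")
    if not data_path.exists():
        data_path = header_path.with_name(header_path.stem)
    flat = np.fromfile(data_path, dtype=dtype)
    if interleave == "bil":
        values = flat.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bsq":
        values = flat.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bip":
        values = flat.reshape(rows, cols, bands)
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")
    return Hypercube(values.astype(float), grid)
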