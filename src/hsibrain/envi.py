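"""ENVI-style cube I/O: a plain-text ``.hdr`` header plus a flat binary raster.

Supports the three classic interleaves (BIL, BSQ, BIP).  In memory there is a
single layout — (row, col, band) — so interleave handling lives entirely here.
Round trips are bit-exact for the values array and the wavelength list.
"""

from __future__ import annotations

import os
import re

import numpy as np

from .cube import SpectralCube
from .errors import FormatError, MetadataError

_DTYPE_CODES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
}
_DTYPE_TO_CODE = {np.dtype(v): k for k, v in _DTYPE_CODES.items()}

INTERLEAVES = ("bil", "bsq", "bip")


def _parse_header(text: str) -> dict[str, str]:
    if not text.lstrip().lower().startswith("envi"):
        raise FormatError("not an ENVI header (missing ENVI magic line)")
    # Collapse {...} blocks onto one line before splitting on '='.
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def _parse_float_list(block: str) -> np.ndarray:
    inner = block.strip().lstrip("{").rstrip("}")
    return np.array([float(tok) for tok in inner.split(",") if tok.strip()], dtype=np.float64)


def _data_path_for(header_path: str) -> str:
    base = header_path[:-4] if header_path.lower().endswith(".hdr") else header_path
    for cand in (base + ".img", base + ".dat", base + ".raw", base):
        if os.path.isfile(cand) and cand != header_path:
            return cand
    raise FileNotFoundError(f"no binary raster found next to header {header_path}")


def read_envi_cube(header_path: str, patient_id: str = "", image_id: str = "") -> SpectralCube:
    """Read an ENVI header + raster pair into a raw-stage :class:`SpectralCube`.

    Raises
    ------
    MetadataError
        If the header lacks a ``wavelength`` field.
    FormatError
        If the raster size disagrees with the header dimensions.
    """
    with open(header_path, "r") as fh:
        fields = _parse_header(fh.read())

    for key in ("samples", "lines", "bands", "interleave", "data type"):
        if key not in fields:
            raise MetadataError(f"ENVI header missing required field {key!r}")
    if "wavelength" not in fields:
        raise MetadataError("ENVI header has no 'wavelength' field")

    cols = int(fields["samples"])
    rows = int(fields["lines"])
    bands = int(fields["bands"])
    interleave = fields["interleave"].lower()
    if interleave not in INTERLEAVES:
        raise FormatError(f"unsupported interleave {interleave!r}")
    code = int(fields["data type"])
    if code not in _DTYPE_CODES:
        raise FormatError(f"unsupported ENVI data type code {code}")
    dtype = np.dtype(_DTYPE_CODES[code])
    offset = int(fields.get("header offset", "0"))

    wavelengths = _parse_float_list(fields["wavelength"])
    if len(wavelengths) != bands:
        raise MetadataError(
            f"header lists {len(wavelengths)} wavelengths for {bands} bands"
        )

    data = np.fromfile(_data_path_for(header_path), dtype=dtype, offset=offset)
    expected = rows * cols * bands
    if data.size != expected:
        raise FormatError(
            f"raster holds {data.size} values but header declares "
            f"{rows}x{cols}x{bands} = {expected}"
        )

    if interleave == "bsq":  # (band, row, col)
        values = data.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":  # (row, band, col)
        values = data.reshape(rows, bands, cols).transpose(0, 2, 1)
    else:  # bip: (row, col, band)
        values = data.reshape(rows, cols, bands)

    return SpectralCube(
        values=np.ascontiguousarray(values),
        wavelengths=wavelengths,
        patient_id=patient_id,
        image_id=image_id,
        stage="raw",
    )


def write_envi_cube(cube: SpectralCube, header_path: str, interleave: str = "bsq") -> None:
    """Write a cube as an ENVI header (``.hdr``) + float64 raster (``.img``)."""
    interleave = interleave.lower()
    if interleave not in INTERLEAVES:
        raise FormatError(f"unsupported interleave {interleave!r}")
    if not header_path.lower().endswith(".hdr"):
        header_path = header_path + ".hdr"
    data_path = header_path[:-4] + ".img"

    values = cube.values
    rows, cols, bands = values.shape
    if interleave == "bsq":
        flat = values.transpose(2, 0, 1)
    elif interleave == "bil":
        flat = values.transpose(0, 2, 1)
    else:
        flat = values

    wl = ",\n ".join(repr(float(w)) for w in cube.wavelengths)
    header = (
        "ENVI\n"
        "description = {hsibrain export}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_TO_CODE[values.dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        "wavelength = {\n " + wl + "}\n"
    )
    with open(header_path, "w") as fh:
        fh.write(header)
    np.ascontiguousarray(flat).tofile(data_path)
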