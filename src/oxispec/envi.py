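"""Minimal ENVI-dialect hypercube I/O.

Supports the common interchange subset: an ASCII ``.hdr`` with ``samples``/
``lines``/``bands``, ``data type = 4`` (little-endian float32), ``interleave``
BSQ/BIL/BIP and a mandatory ``wavelength = { ... }`` list, next to a flat
binary cube file.  Round trips are lossless to float32 precision.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .hypercube import Hypercube


class EnviFormatError(ValueError):
    """Header missing/inconsistent or an unsupported dialect feature."""


_SUPPORTED_INTERLEAVES = ("bsq", "bil", "bip")


def _parse_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise EnviFormatError("missing ENVI magic line")
    body = text[text.lower().index("envi") + 4:]
    fields: dict[str, str] = {}
    # join brace-delimited multi-line values first
    body = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), body)
    for line in body.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_envi(header_path, data_path=None) -> Hypercube:
    """Read a hypercube from an ENVI header + flat binary cube."""
    header_path = Path(header_path)
    if data_path is None:
        data_path = header_path.with_suffix(".img")
    fields = _parse_header(header_path.read_text())
    try:
        lines = int(fields["lines"])
        samples = int(fields["samples"])
        bands = int(fields["bands"])
    except KeyError as exc:
        raise EnviFormatError(f"header missing field {exc}") from None
    dtype_code = int(fields.get("data type", "4"))
    if dtype_code != 4:
        raise EnviFormatError(f"unsupported data type {dtype_code} (only 4/float32)")
    if int(fields.get("byte order", "0")) != 0:
        raise EnviFormatError("only little-endian (byte order = 0) supported")
    interleave = fields.get("interleave", "bsq").lower()
    if interleave not in _SUPPORTED_INTERLEAVES:
        raise EnviFormatError(f"unsupported interleave {interleave!r}")
    if "wavelength" not in fields:
        raise EnviFormatError("header missing required wavelength list")
    wl_text = fields["wavelength"].strip().strip("{}")
    wavelengths = np.array([float(tok) for tok in wl_text.split(",") if tok.strip()])
    if wavelengths.size != bands:
        raise EnviFormatError(
            f"bands={bands} but wavelength list has {wavelengths.size} entries")

    flat = np.fromfile(data_path, dtype="<f4")
    if flat.size != lines * samples * bands:
        raise EnviFormatError(
            f"cube file has {flat.size} values, expected {lines * samples * bands}")
    if interleave == "bsq":
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        data = flat.reshape(lines, samples, bands)
    meta = {k: v for k, v in fields.items()
            if k not in {"samples", "lines", "bands", "data type", "byte order",
                         "interleave", "wavelength", "header offset"}}
    meta["interleave"] = interleave
    return Hypercube(np.ascontiguousarray(data, dtype=np.float64), wavelengths, meta)


def write_envi(cube: Hypercube, header_path, data_path=None,
               interleave: str = "bsq") -> tuple[Path, Path]:
    """Write a hypercube as ENVI header + flat float32 cube; returns the paths."""
    interleave = interleave.lower()
    if interleave not in _SUPPORTED_INTERLEAVES:
        raise EnviFormatError(f"unsupported interleave {interleave!r}")
    header_path = Path(header_path)
    if data_path is None:
        data_path = header_path.with_suffix(".img")
    data_path = Path(data_path)
    rows, cols, bands = cube.shape
    if interleave == "bsq":
        flat = cube.data.transpose(2, 0, 1)
    elif interleave == "bil":
        flat = cube.data.transpose(0, 2, 1)
    else:
        flat = cube.data
    np.ascontiguousarray(flat, dtype="<f4").tofile(data_path)
    wl = ", ".join(f"{w:.4f}" for w in cube.wavelengths_nm)
    header_path.write_text(
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "data type = 4\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength = {{ {wl} }}\n")
    return header_path, data_path
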