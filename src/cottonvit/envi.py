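"""Minimal ENVI raw/header reader-writer.

Supports the subset of the format the pipeline needs: BIL and BSQ
interleaves, an ASCII ``.hdr`` companion file, and the ``wavelength``
list (nanometres) as the authoritative spectral axis.  Cubes are
exchanged as ``(lines, samples, bands)`` float arrays.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

# ENVI "data type" codes -> numpy dtypes (the ones we read/write)
_DTYPES = {
    1: np.uint8,
    2: np.int16,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
}
_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}


def _parse_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise ValueError("not an ENVI header (missing magic)")
    # strip the magic line, then join brace-delimited values
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    # multi-line { ... } values first
    for m in re.finditer(r"^\s*([\w ]+?)\s*=\s*\{(.*?)\}", body, re.S | re.M):
        fields[m.group(1).strip().lower()] = m.group(2).strip()
    scalar = re.sub(r"\{.*?\}", "", body, flags=re.S)
    for m in re.finditer(r"^[ \t]*([\w ]+?)[ \t]*=[ \t]*(\S[^\n]*?)[ \t]*$", scalar, re.M):
        key = m.group(1).strip().lower()
        if key not in fields:
            fields[key] = m.group(2).strip()
    return fields


def read_envi(raw_path: str | Path) -> tuple[np.ndarray, np.ndarray | None]:
    """Read an ENVI cube.

    Parameters
    ----------
    raw_path : path to the raw binary file; the header is looked up as
        ``<raw_path>.hdr`` or with the raw suffix replaced by ``.hdr``.

    Returns
    -------
    cube : ndarray, shape (lines, samples, bands)
    wavelengths : ndarray of nm values, or None if the header has none
    """
    raw_path = Path(raw_path)
    for cand in (raw_path.with_suffix(raw_path.suffix + ".hdr"),
                 raw_path.with_suffix(".hdr")):
        if cand.exists():
            hdr = cand
            break
    else:
        raise FileNotFoundError(f"no .hdr companion for {raw_path}")

    fields = _parse_header(hdr.read_text())
    lines = int(fields["lines"])
    samples = int(fields["samples"])
    bands = int(fields["bands"])
    dtype = _DTYPES[int(fields.get("data type", 4))]
    interleave = fields.get("interleave", "bil").lower()
    offset = int(fields.get("header offset", 0))

    data = np.fromfile(raw_path, dtype=dtype, offset=offset)
    if data.size != lines * samples * bands:
        raise ValueError(
            f"{raw_path}: expected {lines * samples * bands} values, got {data.size}")
    if interleave == "bil":
        cube = data.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bsq":
        cube = data.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bip":
        cube = data.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")

    wl = None
    if "wavelength" in fields:
        wl = np.array([float(v) for v in fields["wavelength"].replace("\n", " ").split(",")])
        if wl.size != bands:
            raise ValueError("wavelength list length != bands")
    return np.ascontiguousarray(cube), wl


def write_envi(raw_path: str | Path, cube: np.ndarray,
               wavelengths: np.ndarray | None = None,
               interleave: str = "bil") -> Path:
    """Write ``cube`` (lines, samples, bands) as ENVI raw + .hdr; returns hdr path."""
    raw_path = Path(raw_path)
    cube = np.asarray(cube)
    if cube.ndim != 3:
        raise ValueError("cube must be (lines, samples, bands)")
    if cube.dtype not in _CODES:
        cube = cube.astype(np.float32)
    lines, samples, bands = cube.shape
    interleave = interleave.lower()
    if interleave == "bil":
        flat = cube.transpose(0, 2, 1)
    elif interleave == "bsq":
        flat = cube.transpose(2, 0, 1)
    elif interleave == "bip":
        flat = cube
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")
    np.ascontiguousarray(flat).tofile(raw_path)

    hdr_lines = [
        "ENVI",
        "description = {cottonvit synthetic plate cube}",
        f"samples = {samples}",
        f"lines = {lines}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_CODES[cube.dtype]}",
        f"interleave = {interleave}",
        "byte order = 0",
    ]
    if wavelengths is not None:
        wl = ", ".join(f"{w:.4f}" for w in np.asarray(wavelengths))
        hdr_lines.append("wavelength units = Nanometers")
        hdr_lines.append("wavelength = {" + wl + "}")
    hdr_path = raw_path.with_suffix(raw_path.suffix + ".hdr")
    hdr_path.write_text("\n".join(hdr_lines) + "\n")
    return hdr_path
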