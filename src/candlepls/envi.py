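"""Minimal ENVI raster I/O for hyperspectral cubes.

Reads and writes the classic header (.hdr) + raw binary pair in BSQ or BIL
interleave, the two dialects transmission line-scan systems emit.  Sample
types cover the ENVI integer and IEEE-float codes; anything else — including
BIP interleave — is rejected loudly rather than guessed.

The in-memory layout is always (lines, samples, bands) = (rows, cols, bands).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np

from .hypercube import Hypercube, default_wavelength_axis

log = logging.getLogger(__name__)

# ENVI data-type code -> numpy dtype
_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
           5: np.float64, 12: np.uint16, 13: np.uint32}
_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}

_REQUIRED = ("samples", "lines", "bands", "data type", "interleave")


class EnviFormatError(ValueError):
    """Missing or malformed header content."""


class UnsupportedDialectError(ValueError):
    """Interleave or sample type outside the supported BSQ/BIL subset."""


def _parse_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise EnviFormatError("header does not start with the ENVI magic word")
    fields: dict[str, str] = {}
    key, buf, in_block = None, [], False
    for raw in text.splitlines()[1:]:
        line = raw.strip()
        if not line:
            continue
        if in_block:
            buf.append(line)
            if "}" in line:
                fields[key] = " ".join(buf)
                in_block = False
            continue
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        key, val = key.strip().lower(), val.strip()
        if val.startswith("{") and "}" not in val:
            buf = [val]
            in_block = True
        else:
            fields[key] = val
    return fields


def _block_values(text: str) -> list[float]:
    inner = text.strip().lstrip("{").rstrip("}")
    return [float(v) for v in inner.replace("\n", " ").split(",") if v.strip()]


def read_hypercube(path) -> Hypercube:
    """Read an ENVI header/binary pair into a Hypercube.

    ``path`` may name the header, the binary file, or the common stem.  A
    header without a wavelength block gets the default linear 900–1700 nm
    axis (with a warning).
    """
    hdr_path, bin_path = _resolve_pair(path)
    fields = _parse_header(hdr_path.read_text())
    missing = [f for f in _REQUIRED if f not in fields]
    if missing:
        raise EnviFormatError(f"header {hdr_path} missing field(s): {missing}")

    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    code = int(fields["data type"])
    interleave = fields["interleave"].lower()
    offset = int(fields.get("header offset", 0))
    byte_order = int(fields.get("byte order", 0))

    if interleave not in ("bsq", "bil"):
        raise UnsupportedDialectError(f"interleave {interleave!r} not supported (BSQ/BIL only)")
    if code not in _DTYPES:
        raise UnsupportedDialectError(f"ENVI data type code {code} not supported")

    dtype = np.dtype(_DTYPES[code]).newbyteorder(">" if byte_order == 1 else "<")
    raw = np.fromfile(bin_path, dtype=dtype, offset=offset)
    expected = samples * lines * bands
    if raw.size != expected:
        raise EnviFormatError(f"{bin_path}: {raw.size} samples read, header promises {expected}")
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    else:  # bil: line-major, band within line
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)

    if "wavelength" in fields:
        wavelengths = np.array(_block_values(fields["wavelength"]))
        if wavelengths.shape[0] != bands:
            raise EnviFormatError(f"wavelength block has {wavelengths.shape[0]} entries "
                                  f"for {bands} bands")
    else:
        wavelengths = default_wavelength_axis(bands)
        warnings.warn(f"{hdr_path}: no wavelength block; assuming linear "
                      f"900-1700 nm axis", stacklevel=2)
        log.warning("%s: wavelength block absent, default axis applied", hdr_path)

    meta = {"source": str(bin_path), "interleave": interleave}
    if "description" in fields:
        meta["description"] = fields["description"].strip("{} ")
    return Hypercube(data=np.ascontiguousarray(data), wavelengths=wavelengths, meta=meta)


def write_hypercube(cube: Hypercube, path, interleave: str = "bsq") -> tuple[Path, Path]:
    """Write a cube as .hdr + .img; returns the two paths."""
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil"):
        raise UnsupportedDialectError(f"interleave {interleave!r} not supported (BSQ/BIL only)")
    stem = Path(path)
    if stem.suffix in (".hdr", ".img"):
        stem = stem.with_suffix("")
    hdr_path, bin_path = stem.with_suffix(".hdr"), stem.with_suffix(".img")

    data = np.ascontiguousarray(cube.data)
    if data.dtype not in _CODES:
        data = data.astype(np.float64)
    rows, cols, bands = data.shape
    if interleave == "bsq":
        ordered = data.transpose(2, 0, 1)
    else:
        ordered = data.transpose(0, 2, 1)

    # repr keeps full double precision so read-back is bitwise lossless
    wl = ", ".join(repr(float(w)) for w in cube.wavelengths)
    hdr = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_CODES[data.dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    hdr_path.write_text(hdr)
    ordered.tofile(bin_path)
    return hdr_path, bin_path


def _resolve_pair(path) -> tuple[Path, Path]:
    p = Path(path)
    if p.suffix == ".hdr":
        hdr, stem = p, p.with_suffix("")
    else:
        stem = p.with_suffix("") if p.suffix == ".img" else p
        hdr = stem.with_suffix(".hdr")
    if not hdr.exists():
        raise EnviFormatError(f"header file {hdr} not found")
    for suffix in (".img", ".dat", ".raw", ""):
        cand = stem.with_suffix(suffix) if suffix else stem
        if cand.exists() and cand != hdr:
            return hdr, cand
    raise EnviFormatError(f"no binary file next to header {hdr}")
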