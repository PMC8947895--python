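"""ENVI-style hyperspectral cube I/O: BIP/BIL/BSQ raw binary plus text header.

A hyperspectral cube is a 3-D array indexed ``(row, col, band)``; a pixel's
band vector is its spectrum.  On disk the same samples can be laid out in
three interleaves:

* **BIP** (band interleaved by pixel): all bands of a pixel are contiguous —
  fastest spectral access.
* **BIL** (band interleaved by line): within each image row, whole lines are
  stored band after band — a spatial/spectral compromise.
* **BSQ** (band sequential): each band is stored as a complete image —
  fastest spatial access.

The header dialect is the de-facto ENVI text header (``samples``, ``lines``,
``bands``, ``interleave``, ``data type``, ``byte order``).  The in-memory
representation is interleave-agnostic: reading the same scene from any of the
three layouts yields identical arrays.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "HyperCube",
    "EnviFormatError",
    "CorruptFileError",
    "INTERLEAVES",
    "read_cube",
    "write_cube",
    "convert_interleave",
    "read_labels",
    "write_labels",
]

INTERLEAVES = ("bip", "bil", "bsq")

# ENVI "data type" codes <-> numpy dtypes (unsupported codes rejected).
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
    14: np.int64,
    15: np.uint64,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


class EnviFormatError(ValueError):
    """Malformed header or unknown interleave/data-type token."""


class CorruptFileError(IOError):
    """Raw file size inconsistent with header-declared dimensions."""


@dataclass
class HyperCube:
    """In-memory hyperspectral cube with header metadata.

    ``data`` has shape ``(rows, cols, bands)``; ``interleave`` records the
    on-disk layout the cube was read from (or will default to on write) and
    never affects ``data`` values.
    """

    data: np.ndarray
    interleave: str = "bip"
    wavelengths: np.ndarray | None = None
    band_names: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise EnviFormatError(
                f"cube data must be 3-D (rows, cols, bands), got ndim={self.data.ndim}"
            )
        if self.interleave not in INTERLEAVES:
            raise EnviFormatError(f"unknown interleave {self.interleave!r}")
        if self.wavelengths is not None:
            w = np.asarray(self.wavelengths, dtype=float)
            if w.shape != (self.bands,):
                raise EnviFormatError(
                    f"wavelengths length {w.size} != bands {self.bands}"
                )
            if np.any(np.diff(w) <= 0):
                raise EnviFormatError("wavelengths must be strictly increasing")
            self.wavelengths = w

    @property
    def rows(self) -> int:
        return self.data.shape[0]

    @property
    def cols(self) -> int:
        return self.data.shape[1]

    @property
    def bands(self) -> int:
        return self.data.shape[2]

    @property
    def dtype_code(self) -> int:
        return _DTYPE_CODES[np.dtype(self.data.dtype)]

    def spectrum(self, row: int, col: int) -> np.ndarray:
        """Band vector of one pixel."""
        return self.data[row, col, :]


# --------------------------------------------------------------------------
# interleave permutations
#
# Axis order of the raw stream, expressed relative to the canonical
# (row, col, band) array:
#   BIP: (row, col, band)   BIL: (row, band, col)   BSQ: (band, row, col)
_AXES_FROM_CANON = {"bip": (0, 1, 2), "bil": (0, 2, 1), "bsq": (2, 0, 1)}


def _to_stream(data: np.ndarray, interleave: str) -> np.ndarray:
    return np.ascontiguousarray(np.transpose(data, _AXES_FROM_CANON[interleave]))


def _from_stream(flat: np.ndarray, rows: int, cols: int, bands: int, interleave: str) -> np.ndarray:
    dims = {"bip": (rows, cols, bands), "bil": (rows, bands, cols), "bsq": (bands, rows, cols)}
    arr = flat.reshape(dims[interleave])
    inverse = np.argsort(_AXES_FROM_CANON[interleave])
    return np.transpose(arr, inverse)


def convert_interleave(
    raw: bytes,
    dims: tuple[int, int, int],
    src: str,
    dst: str,
    itemsize: int = 1,
) -> bytes:
    """Permute a raw sample stream from one interleave to another.

    Pure permutation of samples: ``src -> dst -> src`` is the identity on the
    byte string.  ``itemsize`` is the per-sample width in bytes.
    """
    src, dst = src.lower(), dst.lower()
    for tok in (src, dst):
        if tok not in INTERLEAVES:
            raise EnviFormatError(f"unknown interleave {tok!r}")
    rows, cols, bands = dims
    expected = rows * cols * bands * itemsize
    if len(raw) != expected:
        raise EnviFormatError(
            f"raw length {len(raw)} inconsistent with dims {dims} "
            f"at {itemsize} byte(s)/sample (expected {expected})"
        )
    if src == dst:
        return bytes(raw)
    flat = np.frombuffer(raw, dtype=np.dtype((np.void, itemsize)))
    canon = _from_stream(flat, rows, cols, bands, src)
    return _to_stream(canon, dst).tobytes()


# --------------------------------------------------------------------------
# header parsing / writing

def _parse_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise EnviFormatError("missing ENVI magic line in header")
    fields: dict[str, str] = {}
    body = text.lstrip()[4:]
    i = 0
    lines = body.splitlines()
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or line.startswith(";") or "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{") and "}" not in value:
            parts = [value]
            while i < len(lines) and "}" not in lines[i]:
                parts.append(lines[i])
                i += 1
            if i < len(lines):
                parts.append(lines[i])
                i += 1
            value = " ".join(p.strip() for p in parts)
        fields[key] = value
    return fields


def _brace_list(value: str) -> list[str]:
    inner = value.strip().lstrip("{").rstrip("}")
    return [t.strip() for t in inner.split(",") if t.strip()]


def read_cube(header_path: str | os.PathLike, raw_path: str | os.PathLike | None = None) -> HyperCube:
    """Read an ENVI header + raw binary pair into a :class:`HyperCube`.

    ``raw_path`` defaults to the header path with its ``.hdr`` suffix
    stripped (or ``.raw`` appended).  The parsed cube is independent of the
    on-disk interleave.
    """
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text())
    try:
        cols = int(fields["samples"])
        rows = int(fields["lines"])
        bands = int(fields["bands"])
        interleave = fields["interleave"].lower()
        dtype_code = int(fields["data type"])
    except KeyError as exc:
        raise EnviFormatError(f"header missing required field {exc}") from exc
    if interleave not in INTERLEAVES:
        raise EnviFormatError(f"unknown interleave token {interleave!r}")
    if dtype_code not in _ENVI_DTYPES:
        raise EnviFormatError(f"unsupported ENVI data type code {dtype_code}")
    byte_order = int(fields.get("byte order", 0))  # little-endian default
    dtype = np.dtype(_ENVI_DTYPES[dtype_code]).newbyteorder("<" if byte_order == 0 else ">")

    if raw_path is None:
        raw_path = _default_raw_path(header_path)
    raw_path = Path(raw_path)
    expected = rows * cols * bands * dtype.itemsize
    actual = raw_path.stat().st_size
    if actual != expected:
        raise CorruptFileError(
            f"{raw_path}: expected {expected} bytes "
            f"({rows}x{cols}x{bands} @ {dtype.itemsize} B/sample), found {actual}"
        )
    flat = np.fromfile(raw_path, dtype=dtype)
    data = _from_stream(flat, rows, cols, bands, interleave)

    wavelengths = None
    if "wavelength" in fields:
        wavelengths = np.array([float(x) for x in _brace_list(fields["wavelength"])])
    band_names = _brace_list(fields["band names"]) if "band names" in fields else None
    return HyperCube(
        data=np.ascontiguousarray(data),
        interleave=interleave,
        wavelengths=wavelengths,
        band_names=band_names,
        meta={k: v for k, v in fields.items()},
    )


def _default_raw_path(header_path: Path) -> Path:
    if header_path.suffix == ".hdr":
        stem = header_path.with_suffix("")
        if stem.exists():
            return stem
        for ext in (".raw", ".img", ".dat"):
            cand = stem.with_suffix(ext)
            if cand.exists():
                return cand
        return stem
    return header_path.with_suffix(header_path.suffix + ".raw")


def write_cube(
    cube: HyperCube,
    header_path: str | os.PathLike,
    raw_path: str | os.PathLike | None = None,
    interleave: str | None = None,
) -> None:
    """Write a cube as ENVI header + raw binary in the requested interleave."""
    interleave = (interleave or cube.interleave).lower()
    if interleave not in INTERLEAVES:
        raise EnviFormatError(f"unknown interleave {interleave!r}")
    header_path = Path(header_path)
    if raw_path is None:
        raw_path = header_path.with_suffix("") if header_path.suffix == ".hdr" else Path(
            str(header_path) + ".raw"
        )
    raw_path = Path(raw_path)

    data = cube.data
    if np.dtype(data.dtype) not in _DTYPE_CODES:
        data = data.astype(np.float64)
    dtype = np.dtype(data.dtype).newbyteorder("<")

    lines = [
        "ENVI",
        "description = {dpkhsi exported cube}",
        f"samples = {cube.cols}",
        f"lines = {cube.rows}",
        f"bands = {cube.bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_CODES[np.dtype(data.dtype)]}",
        f"interleave = {interleave}",
        "byte order = 0",
    ]
    if cube.wavelengths is not None:
        lines.append("wavelength = {" + ", ".join(f"{w:g}" for w in cube.wavelengths) + "}")
    if cube.band_names is not None:
        lines.append("band names = {" + ", ".join(cube.band_names) + "}")
    header_path.write_text("\n".join(lines) + "\n")
    _to_stream(data.astype(dtype), interleave).tofile(raw_path)


# --------------------------------------------------------------------------
# label maps
#
# Ground-truth class maps paired with a cube: 0 = unlabelled background,
# classes 1..C.  Accepted as a single-band ENVI integer image or a CSV matrix.

def read_labels(path: str | os.PathLike, raw_path: str | os.PathLike | None = None) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        labels = np.loadtxt(path, delimiter=",", dtype=np.int64, ndmin=2)
    else:
        cube = read_cube(path, raw_path)
        if cube.bands != 1:
            raise EnviFormatError(f"label map must be single-band, got {cube.bands} bands")
        labels = cube.data[:, :, 0].astype(np.int64)
    if labels.min() < 0:
        raise EnviFormatError("label map values must be >= 0 (0 = background)")
    return labels


def write_labels(labels: np.ndarray, path: str | os.PathLike) -> None:
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise EnviFormatError("label map must be 2-D")
    path = Path(path)
    if path.suffix.lower() == ".csv":
        np.savetxt(path, labels, fmt="%d", delimiter=",")
    else:
        cube = HyperCube(labels[:, :, None].astype(np.int32), interleave="bsq")
        write_cube(cube, path)
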