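"""Hyperspectral datacube container and BIP/ENVI I/O.

A micro-hyperspectral scan is a 3D array of two spatial axes and one
spectral axis; every pixel carries a full transmission spectrum.  The
acquisition system stores cubes band-interleaved-by-pixel (BIP): all band
values of one pixel are contiguous on disk, pixels in row-major order.
In memory the canonical axis order is ``(band, row, col)``; BIP is a
storage layout converted at the I/O boundary.

The nominal raw cube is 256 bands x 1000 x 1000 pixels.  The first 30 and
last 26 bands fall outside the usable range and are removed, retaining
200 bands covering 410-900 nm.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import FormatError, HeaderError

__all__ = [
    "DataCube",
    "LabelMap",
    "LABEL_CODES",
    "wavelength_axis",
    "trim_bands",
    "read_bip",
    "write_bip",
    "read_envi",
    "write_envi",
]

#: Per-pixel annotation codes used throughout the pipeline.
LABEL_CODES = {
    "unlabeled": 0,
    "normal": 1,
    "cancer": 2,
    "other": 3,
    "background": 4,
}

# ENVI numeric data-type codes <-> numpy dtypes (subset we emit/accept).
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass
class DataCube:
    """A hyperspectral cube with its wavelength axis and provenance.

    Parameters
    ----------
    values
        Array indexed ``(band, row, col)``; raw detector counts or
        unitless transmittance.
    wavelengths
        Per-band center wavelength in nm, strictly increasing.
    stage
        Processing stage tag: ``raw`` (counts), ``even`` (flat-fielded)
        or ``tran`` (standardized transmittance).
    acquisition_id
        Free-form identifier carried through processing.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    stage: str = "raw"
    acquisition_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be 3D (band, row, col)")
        if len(self.wavelengths) != self.values.shape[0]:
            raise ValueError(
                f"wavelength axis length {len(self.wavelengths)} != "
                f"band count {self.values.shape[0]}"
            )
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cube values must be finite")
        if self.stage == "tran" and self.values.size and self.values.min() < 0:
            raise ValueError("transmittance cube must be non-negative")

    @property
    def n_bands(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def spectra(self) -> np.ndarray:
        """Pixels as an ``(rows*cols, bands)`` matrix (row-major pixels)."""
        b, r, c = self.values.shape
        return self.values.reshape(b, r * c).T


@dataclass
class LabelMap:
    """Per-pixel class raster aligned to a cube (codes in LABEL_CODES)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2D raster")
        bad = set(np.unique(self.labels)) - set(LABEL_CODES.values())
        if bad:
            raise ValueError(f"unknown label codes: {sorted(bad)}")

    def mask(self, name: str) -> np.ndarray:
        return self.labels == LABEL_CODES[name]


def wavelength_axis(n_bands: int, lo_nm: float = 410.0, hi_nm: float = 900.0) -> np.ndarray:
    """Linear wavelength grid from ``lo_nm`` to ``hi_nm`` inclusive."""
    if n_bands < 2:
        raise ValueError("n_bands must be >= 2")
    if hi_nm <= lo_nm:
        raise ValueError("hi_nm must exceed lo_nm")
    return np.linspace(lo_nm, hi_nm, n_bands)


def trim_bands(cube: DataCube, leading: int = 30, trailing: int = 26) -> DataCube:
    """Drop unusable detector bands at both spectral extremes.

    The acquisition covers more than the usable 410-900 nm window; the
    default trims (30 leading, 26 trailing) reduce the nominal 256-band
    raw cube to the 200 retained bands.
    """
    if leading < 0 or trailing < 0:
        raise ValueError("trim counts must be non-negative")
    if leading + trailing >= cube.n_bands:
        raise ValueError(
            f"cannot trim {leading}+{trailing} bands from a "
            f"{cube.n_bands}-band cube"
        )
    stop = cube.n_bands - trailing
    return replace(
        cube,
        values=cube.values[leading:stop],
        wavelengths=cube.wavelengths[leading:stop],
    )


def _as_bip(values: np.ndarray) -> np.ndarray:
    # (band, row, col) -> (row, col, band), the on-disk pixel-band order
    return np.ascontiguousarray(np.transpose(values, (1, 2, 0)))


def read_bip(
    path: str | Path,
    shape: tuple[int, int, int],
    dtype=np.uint16,
    wavelengths: np.ndarray | None = None,
    stage: str = "raw",
) -> DataCube:
    """Read a raw BIP binary into a cube.

    ``shape`` is ``(bands, rows, cols)``.  The file holds pixels in
    row-major order, all bands of a pixel contiguous; element
    ``(b, r, c)`` of the returned cube is the b-th value of pixel
    ``(r, c)`` in file order.
    """
    bands, rows, cols = map(int, shape)
    if min(bands, rows, cols) <= 0:
        raise ValueError("shape components must be positive")
    dtype = np.dtype(dtype)
    path = Path(path)
    expected = bands * rows * cols * dtype.itemsize
    actual = path.stat().st_size
    if actual != expected:
        raise FormatError(
            f"{path}: size {actual} B does not match declared shape "
            f"{bands}x{rows}x{cols} {dtype.name} ({expected} B)"
        )
    flat = np.fromfile(path, dtype=dtype)
    values = np.transpose(flat.reshape(rows, cols, bands), (2, 0, 1))
    if wavelengths is None:
        wavelengths = wavelength_axis(bands) if bands >= 2 else np.array([410.0])
    return DataCube(values, wavelengths, stage=stage, acquisition_id=path.stem)


def write_bip(cube: DataCube, path: str | Path) -> None:
    """Write the cube's values in BIP pixel-band order."""
    _as_bip(cube.values).tofile(Path(path))


def write_envi(cube: DataCube, hdr_path: str | Path) -> Path:
    """Write an ENVI-style ``.hdr`` plus the BIP binary alongside it.

    Returns the path of the binary payload.
    """
    hdr_path = Path(hdr_path)
    if hdr_path.suffix != ".hdr":
        hdr_path = hdr_path.with_suffix(".hdr")
    bin_path = hdr_path.with_suffix(".bip")
    dtype = np.dtype(cube.values.dtype)
    if dtype not in _DTYPE_CODES:
        raise FormatError(f"unsupported dtype for ENVI output: {dtype}")
    bands, rows, cols = cube.shape
    wl = ", ".join(f"{w:.4f}" for w in cube.wavelengths)
    hdr = (
        "ENVI\n"
        f"description = {{hsipath stage={cube.stage} id={cube.acquisition_id}}}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        "interleave = bip\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
    )
    hdr_path.write_text(hdr)
    write_bip(cube, bin_path)
    return bin_path


def _parse_header(text: str) -> dict[str, str]:
    if not text.lstrip().startswith("ENVI"):
        raise HeaderError("missing ENVI magic line")
    fields: dict[str, str] = {}
    # join brace-delimited multi-line values
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def read_envi(hdr_path: str | Path) -> DataCube:
    """Read a cube from an ENVI-style header + BIP binary pair."""
    hdr_path = Path(hdr_path)
    if not hdr_path.exists():
        raise HeaderError(f"header not found: {hdr_path}")
    fields = _parse_header(hdr_path.read_text())
    try:
        bands = int(fields["bands"])
        rows = int(fields["lines"])
        cols = int(fields["samples"])
        code = int(fields["data type"])
    except (KeyError, ValueError) as exc:
        raise HeaderError(f"{hdr_path}: malformed or incomplete header") from exc
    if fields.get("interleave", "bip").lower() != "bip":
        raise HeaderError(f"{hdr_path}: only BIP interleave is supported")
    if code not in _ENVI_DTYPES:
        raise HeaderError(f"{hdr_path}: unsupported data type code {code}")
    wavelengths = None
    if "wavelength" in fields:
        inner = fields["wavelength"].strip("{} ")
        if inner:
            wavelengths = np.array([float(t) for t in inner.split(",")])
    stage = "raw"
    m = re.search(r"stage=(\w+)", fields.get("description", ""))
    if m:
        stage = m.group(1)
    bin_path = hdr_path.with_suffix(".bip")
    if not bin_path.exists():
        raise FormatError(f"binary payload not found: {bin_path}")
    return read_bip(
        bin_path, (bands, rows, cols), _ENVI_DTYPES[code],
        wavelengths=wavelengths, stage=stage,
    )
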