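"""Hyperspectral cube I/O, reflectance calibration, and spectrum extraction.

A *hypercube* is a 3-D array with two spatial axes (rows, cols) and one
wavelength axis.  Raw camera counts are converted to relative reflectance
with a white reference (a high-reflectance tile, treated as 100 %) and a
dark reference (lens capped, 0 %):

    R = (I_raw - I_dark) / (I_white - I_dark)

applied per pixel and per band.  Pixels where the white and dark counts
coincide carry no radiometric information; they are marked invalid (NaN)
and excluded from region-of-interest (ROI) means and from chemical maps.

Cubes are stored on disk in the ENVI convention: a raw binary file plus a
small plain-text header declaring ``samples`` (columns), ``lines`` (rows),
``bands``, ``data type``, ``interleave`` (bsq | bil | bip), ``byte order``
and the wavelength list in nanometres.
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Hypercube",
    "SpectraTable",
    "FormatError",
    "read_envi",
    "write_envi",
    "calibrate",
    "invalid_pixel_mask",
    "mean_roi_spectrum",
    "trim_bands",
]


class FormatError(ValueError):
    """Raised for malformed ENVI files or inconsistent cube metadata."""


# ENVI numeric "data type" codes <-> numpy dtypes (the subset we support).
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}

_INTERLEAVES = ("bsq", "bil", "bip")


@dataclass
class Hypercube:
    """A (rows, cols, bands) data array with its wavelength grid in nm.

    ``data`` may hold raw counts or reflectance; ``is_reflectance`` records
    which.  Wavelengths are carried explicitly per band (never an implied
    index) and must be strictly increasing.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    interleave: str = "bil"
    is_reflectance: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise FormatError(f"cube must be 3-D, got shape {self.data.shape}")
        if self.data.shape[2] != self.wavelengths.size:
            raise FormatError(
                f"bands dimension ({self.data.shape[2]}) does not match "
                f"wavelength count ({self.wavelengths.size})"
            )
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise FormatError("wavelengths must be strictly increasing")
        if self.interleave not in _INTERLEAVES:
            raise FormatError(f"unknown interleave {self.interleave!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_index(self, wavelength_nm: float, tol_nm: float | None = None) -> int:
        """Index of the band nearest ``wavelength_nm``.

        When ``tol_nm`` is given, a nearest band farther than that raises
        ``ValueError`` naming the wavelength.
        """
        i = int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))
        if tol_nm is not None and abs(self.wavelengths[i] - wavelength_nm) > tol_nm:
            raise ValueError(
                f"no band within {tol_nm} nm of requested wavelength "
                f"{wavelength_nm} nm (nearest is {self.wavelengths[i]:.2f} nm)"
            )
        return i


# ---------------------------------------------------------------------------
# ENVI I/O
# ---------------------------------------------------------------------------

def _format_header(cube: Hypercube) -> str:
    rows, cols, bands = cube.shape
    code = _DTYPE_CODES.get(np.dtype(cube.data.dtype))
    if code is None:
        raise FormatError(f"unsupported dtype for ENVI output: {cube.data.dtype}")
    wl = ",\n ".join(repr(float(w)) for w in cube.wavelengths)
    return (
        "ENVI\n"
        "description = {hypernitro hyperspectral cube}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {code}\n"
        f"interleave = {cube.interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        "wavelength = {\n " + wl + "}\n"
    )


def write_envi(cube: Hypercube, cube_path: str | os.PathLike,
               header_path: str | os.PathLike) -> None:
    """Write ``cube`` as a raw binary file plus a text header.

    The in-memory (rows, cols, bands) array is permuted to the declared
    interleave order before writing, so round-trips are bit-exact.
    """
    arr = cube.data
    if cube.interleave == "bsq":       # (bands, lines, samples)
        out = np.transpose(arr, (2, 0, 1))
    elif cube.interleave == "bil":     # (lines, bands, samples)
        out = np.transpose(arr, (0, 2, 1))
    else:                              # bip: (lines, samples, bands)
        out = arr
    with open(cube_path, "wb") as fh:
        fh.write(np.ascontiguousarray(out).tobytes())
    with open(header_path, "w") as fh:
        fh.write(_format_header(cube))


def _parse_header(text: str) -> dict:
    # Collapse {...} blocks (which may span lines) before splitting fields.
    fields: dict[str, str] = {}
    # remove the leading magic word if present
    text = re.sub(r"^ENVI\s*", "", text.strip())
    pos = 0
    pattern = re.compile(r"([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.S)
    for m in pattern.finditer(text, pos):
        key = m.group(1).strip().lower()
        fields[key] = m.group(2).strip()
    return fields


def read_envi(cube_path: str | os.PathLike,
              header_path: str | os.PathLike) -> Hypercube:
    """Read an ENVI cube + header pair written by :func:`write_envi` (or any
    byte-order-0, offset-0 ENVI file with a wavelength list)."""
    with open(header_path) as fh:
        fields = _parse_header(fh.read())

    required = ("samples", "lines", "bands", "data type", "interleave")
    missing = [k for k in required if k not in fields]
    if missing:
        raise FormatError(f"header missing required field(s): {', '.join(missing)}")

    cols = int(fields["samples"])
    rows = int(fields["lines"])
    bands = int(fields["bands"])
    code = int(fields["data type"])
    interleave = fields["interleave"].lower()
    if code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type code {code}")
    if interleave not in _INTERLEAVES:
        raise FormatError(f"unknown interleave {interleave!r}")
    if fields.get("byte order", "0").strip() not in ("0", ""):
        raise FormatError("only byte order 0 (little-endian) is supported")

    if "wavelength" not in fields:
        raise FormatError("header missing wavelength list")
    wl_text = fields["wavelength"].strip().lstrip("{").rstrip("}")
    wavelengths = np.array(
        [float(tok) for tok in re.split(r"[,\s]+", wl_text) if tok], dtype=float
    )
    if wavelengths.size != bands:
        raise FormatError(
            f"header band count ({bands}) does not match wavelength list "
            f"length ({wavelengths.size})"
        )

    dtype = np.dtype(_ENVI_DTYPES[code])
    expected = rows * cols * bands * dtype.itemsize
    actual = os.path.getsize(cube_path)
    if actual != expected:
        raise FormatError(
            f"cube file size {actual} B does not match header dimensions "
            f"({rows}x{cols}x{bands} {dtype.name} = {expected} B)"
        )
    flat = np.fromfile(cube_path, dtype=dtype)
    if interleave == "bsq":
        data = np.transpose(flat.reshape(bands, rows, cols), (1, 2, 0))
    elif interleave == "bil":
        data = np.transpose(flat.reshape(rows, bands, cols), (0, 2, 1))
    else:
        data = flat.reshape(rows, cols, bands)
    return Hypercube(data=data.copy(), wavelengths=wavelengths,
                     interleave=interleave)


# ---------------------------------------------------------------------------
# Calibration and extraction
# ---------------------------------------------------------------------------

def calibrate(raw: Hypercube, white: Hypercube, dark: Hypercube) -> Hypercube:
    """White/dark reflectance calibration, (raw - dark) / (white - dark).

    The three cubes must share shape and wavelength grid.  Entries where the
    white and dark counts coincide (zero denominator) are set to NaN and
    treated as invalid downstream.
    """
    if raw.shape != white.shape or raw.shape != dark.shape:
        raise ValueError(
            f"shape mismatch: raw {raw.shape}, white {white.shape}, "
            f"dark {dark.shape}"
        )
    if not (np.array_equal(raw.wavelengths, white.wavelengths)
            and np.array_equal(raw.wavelengths, dark.wavelengths)):
        raise ValueError("wavelength grids of raw/white/dark cubes differ")
    num = raw.data.astype(np.float64) - dark.data.astype(np.float64)
    den = white.data.astype(np.float64) - dark.data.astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = np.where(den != 0, num / np.where(den == 0, 1.0, den), np.nan)
    return Hypercube(data=refl, wavelengths=raw.wavelengths.copy(),
                     interleave=raw.interleave, is_reflectance=True)


def invalid_pixel_mask(cube: Hypercube) -> np.ndarray:
    """Boolean (rows, cols) mask of pixels invalid in at least one band."""
    return np.isnan(cube.data).any(axis=2)


def mean_roi_spectrum(cube: Hypercube, mask: np.ndarray) -> np.ndarray:
    """Arithmetic mean spectrum over the ROI pixels, one value per band.

    ``mask`` is a boolean (rows, cols) image; invalid (NaN) entries are
    excluded band-wise.  Raises ``ValueError`` for an empty ROI or a band
    with no valid ROI pixel.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match cube spatial shape "
            f"{cube.shape[:2]}"
        )
    if not mask.any():
        raise ValueError("ROI mask selects no pixels")
    pix = cube.data[mask]                     # (n_roi, bands)
    valid = ~np.isnan(pix)
    counts = valid.sum(axis=0)
    if (counts == 0).any():
        raise ValueError("a band has no valid ROI pixel")
    return np.nansum(np.where(valid, pix, 0.0), axis=0) / counts


def trim_bands(obj, low_nm: float, high_nm: float):
    """Restrict a :class:`Hypercube` or :class:`SpectraTable` to the closed
    wavelength interval [low_nm, high_nm]."""
    if low_nm >= high_nm:
        raise ValueError(f"low_nm ({low_nm}) must be < high_nm ({high_nm})")
    wl = obj.wavelengths
    keep = (wl >= low_nm) & (wl <= high_nm)
    if not keep.any():
        raise ValueError(
            f"no band survives trimming to [{low_nm}, {high_nm}] nm"
        )
    if isinstance(obj, Hypercube):
        return replace(obj, data=obj.data[:, :, keep],
                       wavelengths=wl[keep])
    if isinstance(obj, SpectraTable):
        return replace(obj, X=obj.X[:, keep], wavelengths=wl[keep])
    raise TypeError(f"cannot trim object of type {type(obj).__name__}")


# ---------------------------------------------------------------------------
# Sample-level spectra table
# ---------------------------------------------------------------------------

@dataclass
class SpectraTable:
    """n samples x p wavelengths mean-reflectance matrix with responses.

    ``X`` holds one mean ROI spectrum per row, ``y`` the total nitrogen
    content (% of dry matter), and the label arrays carry sample identity
    and organ/position grouping.
    """

    X: np.ndarray
    y: np.ndarray
    wavelengths: np.ndarray
    sample_ids: np.ndarray = field(default=None)
    organs: np.ndarray = field(default=None)
    positions: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        n, p = self.X.shape
        if self.y.shape != (n,):
            raise ValueError("y length does not match number of rows of X")
        if self.wavelengths.shape != (p,):
            raise ValueError("wavelength count does not match columns of X")
        if self.sample_ids is None:
            self.sample_ids = np.array([f"s{i:04d}" for i in range(n)])
        if self.organs is None:
            self.organs = np.array(["n/a"] * n, dtype=object)
        if self.positions is None:
            self.positions = np.array(["n/a"] * n, dtype=object)
        for name in ("sample_ids", "organs", "positions"):
            arr = np.asarray(getattr(self, name), dtype=object)
            if arr.shape != (n,):
                raise ValueError(f"{name} length does not match X")
            setattr(self, name, arr)
        if not np.isfinite(self.X).all():
            raise ValueError("X contains non-finite reflectance values")
        if not (self.y > 0).all():
            raise ValueError("responses (TNC %) must be positive")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "SpectraTable":
        idx = np.asarray(idx)
        return SpectraTable(
            X=self.X[idx], y=self.y[idx], wavelengths=self.wavelengths,
            sample_ids=self.sample_ids[idx], organs=self.organs[idx],
            positions=self.positions[idx],
        )

    def to_csv(self, path: str | os.PathLike) -> None:
        # floats written via repr: shortest round-trip representation
        df = pd.DataFrame(
            np.vectorize(repr)(self.X),
            columns=[repr(float(w)) for w in self.wavelengths])
        df.insert(0, "tnc_percent", [repr(float(v)) for v in self.y])
        df.insert(0, "position", self.positions)
        df.insert(0, "organ", self.organs)
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "SpectraTable":
        df = pd.read_csv(path, keep_default_na=False,
                         float_precision="round_trip")
        meta = ["sample_id", "organ", "position", "tnc_percent"]
        missing = [c for c in meta if c not in df.columns]
        if missing:
            raise FormatError(f"spectra CSV missing column(s): {missing}")
        wl_cols = [c for c in df.columns if c not in meta]
        return cls(
            X=df[wl_cols].to_numpy(dtype=float),
            y=df["tnc_percent"].to_numpy(dtype=float),
            wavelengths=np.array([float(c) for c in wl_cols]),
            sample_ids=df["sample_id"].astype(str).to_numpy(dtype=object),
            organs=df["organ"].astype(str).to_numpy(dtype=object),
            positions=df["position"].astype(str).to_numpy(dtype=object),
        )
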