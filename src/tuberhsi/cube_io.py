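"""Hypercube containers, ENVI I/O, reflectance calibration and reshaping.

A push-broom NIR camera records a hypercube indexed ``(row, col, band)``:
each scan line covers the spatial columns of the slit and is dispersed over
the spectral bands (here typically 320 columns x 256 bands on a 900-1700 nm
axis).  This module provides

* :class:`WavelengthAxis` / :class:`Hypercube` / :class:`ReferencePair` /
  :class:`PixelMatrix` containers,
* white/dark reflectance calibration ``R = (I - I_D) / (I_W - I_D)``
  applied per spatial column and band,
* trimming of noisy leading bands,
* a minimal classic-ENVI reader/writer (``.hdr`` key=value header plus a
  raw binary raster, BIL/BSQ/BIP interleaves), and
* unfold/fold between cube and pixels-by-bands matrix representations.

Coordinates are 0-based, row-major, origin at the top-left corner.
"""

from __future__ import annotations

import dataclasses
import enum
import pathlib
import re
from typing import Sequence

import numpy as np

from .errors import (
    DegenerateReferenceError,
    EmptySelectionError,
    FormatError,
    InvalidAxisError,
)

__all__ = [
    "CubeKind",
    "WavelengthAxis",
    "Hypercube",
    "ReferencePair",
    "PixelMatrix",
    "build_wavelength_axis",
    "trim_leading_bands",
    "calibrate_reflectance",
    "read_envi",
    "write_envi",
    "unfold",
    "fold",
    "mean_spectrum",
]

#: |I_W - I_D| below this (raw intensity units) is treated as degenerate.
REFERENCE_TOLERANCE = 1e-6

_UNIFORMITY_TOL = 1e-9


class CubeKind(str, enum.Enum):
    RAW = "raw"
    REFLECTANCE = "reflectance"


@dataclasses.dataclass(frozen=True)
class WavelengthAxis:
    """Uniform grid of band-center wavelengths in nanometres."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise InvalidAxisError("axis needs at least 2 bands")
        diffs = np.diff(values)
        if np.any(diffs <= 0):
            raise InvalidAxisError("wavelengths must be strictly increasing")
        if np.ptp(diffs) > _UNIFORMITY_TOL:
            raise InvalidAxisError(
                f"band spacing not uniform (ptp={np.ptp(diffs):.3e} nm)"
            )

    @property
    def start_nm(self) -> float:
        return float(self.values[0])

    @property
    def end_nm(self) -> float:
        return float(self.values[-1])

    @property
    def n_bands(self) -> int:
        return int(self.values.size)

    @property
    def spacing_nm(self) -> float:
        return float((self.end_nm - self.start_nm) / (self.n_bands - 1))

    def index_of(self, wavelength_nm: float) -> int:
        """Index of the band center closest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.values - wavelength_nm)))

    def band_window(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """Boolean selector for band centers within [lo_nm, hi_nm]."""
        return (self.values >= lo_nm) & (self.values <= hi_nm)


def build_wavelength_axis(start_nm: float, end_nm: float, n_bands: int) -> WavelengthAxis:
    """Uniform axis with ``values[0] == start_nm`` and ``values[-1] == end_nm``.

    The camera of the emulated instrument spans 900-1700 nm over 256 bands,
    i.e. a spacing of 800/255 = 3.14 nm (2 dp).
    """
    if n_bands < 2:
        raise InvalidAxisError(f"n_bands must be >= 2, got {n_bands}")
    if not end_nm > start_nm:
        raise InvalidAxisError(f"need end_nm > start_nm, got [{start_nm}, {end_nm}]")
    return WavelengthAxis(np.linspace(start_nm, end_nm, n_bands))


@dataclasses.dataclass
class Hypercube:
    """3-D raster (rows x cols x bands) of raw intensity or reflectance."""

    data: np.ndarray
    axis: WavelengthAxis
    kind: CubeKind = CubeKind.RAW
    sample_id: str | None = None
    class_label: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.kind = CubeKind(self.kind)
        if self.data.ndim != 3:
            raise FormatError(f"cube must be 3-D, got shape {self.data.shape}")
        if self.data.shape[2] != self.axis.n_bands:
            raise FormatError(
                f"cube has {self.data.shape[2]} bands but axis has {self.axis.n_bands}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]  # type: ignore[return-value]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclasses.dataclass
class ReferencePair:
    """White and dark reference scans.

    Stored either as a single line (cols x bands) or as a stack of scan
    lines (lines x cols x bands); :meth:`averaged` reduces over the scan
    direction, which is how push-broom references are normally applied.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.shape != self.dark.shape:
            raise FormatError(
                f"white {self.white.shape} and dark {self.dark.shape} shapes differ"
            )
        if self.white.ndim not in (2, 3):
            raise FormatError("references must be (cols, bands) or (lines, cols, bands)")

    def averaged(self) -> tuple[np.ndarray, np.ndarray]:
        """(cols x bands) white/dark averaged over the scan direction."""
        if self.white.ndim == 3:
            return self.white.mean(axis=0), self.dark.mean(axis=0)
        return self.white, self.dark


def trim_leading_bands(cube: Hypercube, n_drop: int) -> Hypercube:
    """Drop the first ``n_drop`` (noisy) bands and truncate the axis.

    With the 256-band 900-1700 nm axis and ``n_drop=30`` this leaves 226
    bands starting at 994.12 nm.
    """
    if n_drop < 0 or n_drop >= cube.n_bands:
        raise EmptySelectionError(
            f"n_drop={n_drop} outside [0, {cube.n_bands}) for this cube"
        )
    if n_drop == 0:
        return Hypercube(cube.data.copy(), cube.axis, cube.kind, cube.sample_id, cube.class_label)
    return Hypercube(
        cube.data[:, :, n_drop:].copy(),
        WavelengthAxis(cube.axis.values[n_drop:]),
        cube.kind,
        cube.sample_id,
        cube.class_label,
    )


def calibrate_reflectance(
    raw: Hypercube,
    refs: ReferencePair,
    clip: bool = False,
    clip_max: float = 2.0,
) -> Hypercube:
    """Convert raw intensity to relative reflectance against white/dark.

    ``R(x, lam) = (I(x, lam) - I_D(x, lam)) / (I_W(x, lam) - I_D(x, lam))``
    per spatial column ``x`` and band ``lam``, with the references first
    averaged over the scan direction.  The map is affine-invariant in the
    intensity scale and strictly increasing in ``I`` for valid references.

    Reflectance is optionally clamped to ``[0, clip_max]`` (off by default:
    real slices show values mostly in [0, 0.6] with a few excursions worth
    preserving).
    """
    if raw.kind is not CubeKind.RAW:
        raise FormatError("calibrate_reflectance expects a raw-intensity cube")
    white, dark = refs.averaged()
    n_cols, n_bands = raw.data.shape[1], raw.n_bands
    if white.shape != (n_cols, n_bands):
        raise FormatError(
            f"references {white.shape} incompatible with cube ({n_cols}, {n_bands})"
        )
    denom = white - dark
    bad = np.abs(denom) <= REFERENCE_TOLERANCE
    if np.any(bad):
        x, lam = np.argwhere(bad)[0]
        raise DegenerateReferenceError(
            f"|I_W - I_D| <= {REFERENCE_TOLERANCE} at column x={x}, band {lam} "
            f"({raw.axis.values[lam]:.2f} nm)"
        )
    if np.any(denom < 0):
        x, lam = np.argwhere(denom < 0)[0]
        raise DegenerateReferenceError(
            f"white below dark at column x={x}, band {lam}"
        )
    reflectance = (raw.data - dark[None, :, :]) / denom[None, :, :]
    if clip:
        reflectance = np.clip(reflectance, 0.0, clip_max)
    return Hypercube(reflectance, raw.axis, CubeKind.REFLECTANCE, raw.sample_id, raw.class_label)


# ---------------------------------------------------------------------------
# ENVI I/O (classic key=value header + raw binary raster)
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {
    1: np.dtype("uint8"),
    2: np.dtype("int16"),
    3: np.dtype("int32"),
    4: np.dtype("float32"),
    5: np.dtype("float64"),
    12: np.dtype("uint16"),
    13: np.dtype("uint32"),
}
_DTYPE_CODES = {v: k for k, v in _ENVI_DTYPES.items()}
_RASTER_SUFFIXES = (".raw", ".img", ".dat", "")


def _parse_envi_header(text: str) -> dict[str, str]:
    if not text.lstrip().lower().startswith("envi"):
        raise FormatError("missing ENVI magic line")
    body = text.lstrip()[4:]
    # join brace-delimited multi-line values
    body = re.sub(
        r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), body, flags=re.S
    )
    fields: dict[str, str] = {}
    for line in body.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def write_envi(cube: Hypercube, path: str | pathlib.Path, interleave: str = "bil") -> pathlib.Path:
    """Write ``cube`` as ``<path>.hdr`` + ``<path>.raw`` and return the header path.

    Lowercase key=value header; wavelengths written with 4 decimals; byte
    order 0 (little endian).
    """
    interleave = interleave.lower()
    if interleave not in ("bil", "bsq", "bip"):
        raise FormatError(f"unknown interleave {interleave!r}")
    base = pathlib.Path(path)
    if base.suffix == ".hdr":
        base = base.with_suffix("")
    data = np.ascontiguousarray(cube.data)
    if data.dtype not in _DTYPE_CODES:
        data = data.astype(np.float64)
    rows, cols, bands = data.shape
    if interleave == "bil":
        payload = data.transpose(0, 2, 1)  # (lines, bands, samples)
    elif interleave == "bsq":
        payload = data.transpose(2, 0, 1)  # (bands, lines, samples)
    else:
        payload = data  # bip: (lines, samples, bands)
    # shortest float repr round-trips exactly, keeping the grid uniform
    wl = ", ".join(repr(float(v)) for v in cube.axis.values)
    lines = [
        "ENVI",
        "description = {tuberhsi hypercube}",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_CODES[data.dtype]}",
        f"interleave = {interleave}",
        "byte order = 0",
        f"cube kind = {cube.kind.value}",
        "wavelength units = Nanometers",
        f"wavelength = {{ {wl} }}",
    ]
    if cube.sample_id is not None:
        lines.insert(11, f"sample id = {cube.sample_id}")
    if cube.class_label is not None:
        lines.insert(11, f"class label = {cube.class_label}")
    hdr = base.with_suffix(".hdr")
    hdr.write_text("\n".join(lines) + "\n")
    raw = base.with_suffix(".raw")
    payload.astype(payload.dtype.newbyteorder("<")).tofile(raw)
    return hdr


def read_envi(header_path: str | pathlib.Path) -> Hypercube:
    """Read a classic ENVI header + raster pair written by :func:`write_envi`.

    Raises :class:`FormatError` on missing mandatory fields or when the
    declared wavelength count disagrees with the raster band count.
    """
    hdr = pathlib.Path(header_path)
    fields = _parse_envi_header(hdr.read_text())
    for key in ("samples", "lines", "bands", "data type", "interleave"):
        if key not in fields:
            raise FormatError(f"mandatory header field {key!r} missing")
    cols = int(fields["samples"])
    rows = int(fields["lines"])
    bands = int(fields["bands"])
    code = int(fields["data type"])
    if code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported data type code {code}")
    dtype = _ENVI_DTYPES[code]
    if int(fields.get("byte order", "0")) != 0:
        dtype = dtype.newbyteorder(">")
    interleave = fields["interleave"].lower()
    if interleave not in ("bil", "bsq", "bip"):
        raise FormatError(f"unknown interleave {interleave!r}")
    if "wavelength" not in fields:
        raise FormatError("mandatory header field 'wavelength' missing")
    wl_text = fields["wavelength"].strip().strip("{}").strip()
    wavelengths = np.array([float(t) for t in wl_text.split(",") if t.strip()])
    if wavelengths.size != bands:
        raise FormatError(
            f"header declares {bands} bands but lists {wavelengths.size} wavelengths"
        )
    raster = None
    for suffix in _RASTER_SUFFIXES:
        candidate = hdr.with_suffix(suffix)
        if candidate != hdr and candidate.exists():
            raster = candidate
            break
    if raster is None:
        raise FormatError(f"no raster file found next to {hdr}")
    flat = np.fromfile(raster, dtype=dtype)
    expected = rows * cols * bands
    if flat.size != expected:
        raise FormatError(
            f"raster holds {flat.size} values; header implies {expected} "
            f"({rows}x{cols}x{bands})"
        )
    if interleave == "bil":
        data = flat.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bsq":
        data = flat.reshape(bands, rows, cols).transpose(1, 2, 0)
    else:
        data = flat.reshape(rows, cols, bands)
    return Hypercube(
        np.ascontiguousarray(data),
        WavelengthAxis(wavelengths),
        CubeKind(fields.get("cube kind", "raw")),
        sample_id=fields.get("sample id"),
        class_label=fields.get("class label"),
    )


# ---------------------------------------------------------------------------
# Unfolding / folding
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PixelMatrix:
    """Unfolded spectra (n_pixels x n_bands) with image coordinates.

    ``coords[i]`` is the (row, col) of ``spectra[i]`` in the source image;
    rows follow the row-major scan order of the mask so folding restores
    the masked cube values exactly.
    """

    spectra: np.ndarray
    coords: np.ndarray
    source_shape: tuple[int, int]
    sample_ids: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra)
        self.coords = np.asarray(self.coords, dtype=int)
        if self.coords.shape != (self.spectra.shape[0], 2):
            raise FormatError("coords must be (n_pixels, 2)")

    @property
    def n_pixels(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]


def _mask_array(mask) -> np.ndarray:
    data = getattr(mask, "data", mask)
    return np.asarray(data, dtype=bool)


def unfold(cube: Hypercube, mask) -> PixelMatrix:
    """Unfold masked cube pixels into a pixels-by-bands matrix."""
    m = _mask_array(mask)
    if m.shape != cube.spatial_shape:
        raise FormatError(f"mask {m.shape} does not match cube {cube.spatial_shape}")
    if not m.any():
        raise EmptySelectionError("mask selects no pixels")
    coords = np.argwhere(m)  # row-major order
    spectra = cube.data[m]  # same order as argwhere for boolean indexing
    labels = None
    if cube.class_label is not None:
        labels = np.full(coords.shape[0], cube.class_label, dtype=object)
    ids = None
    if cube.sample_id is not None:
        ids = np.full(coords.shape[0], cube.sample_id, dtype=object)
    return PixelMatrix(spectra, coords, cube.spatial_shape, sample_ids=ids, labels=labels)


def fold(
    values: Sequence,
    coords: np.ndarray,
    source_shape: tuple[int, int],
    background_value=0,
) -> np.ndarray:
    """Scatter per-pixel values back into a 2-D image.

    The inverse of :func:`unfold` for per-pixel scalars (e.g. predicted
    class codes); positions not listed in ``coords`` get ``background_value``.
    """
    values = np.asarray(values)
    coords = np.asarray(coords, dtype=int)
    if len(values) != len(coords):
        raise FormatError(f"{len(values)} values for {len(coords)} coords")
    if len(coords) and (
        coords.min() < 0
        or coords[:, 0].max() >= source_shape[0]
        or coords[:, 1].max() >= source_shape[1]
    ):
        raise IndexError("coordinate outside source_shape")
    image = np.full(source_shape, background_value, dtype=values.dtype if len(values) else type(background_value))
    if len(values):
        image[coords[:, 0], coords[:, 1]] = values
    return image


def mean_spectrum(cube: Hypercube, mask) -> np.ndarray:
    """Arithmetic mean spectrum over masked pixels (1 x n_bands)."""
    m = _mask_array(mask)
    if not m.any():
        raise EmptySelectionError("mask selects no pixels")
    return cube.data[m].mean(axis=0)
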