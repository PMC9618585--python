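"""Synthetic NIR hypercubes emulating fresh-cut potato slices.

No public hyperspectral potato dataset accompanies the study design this
package implements, so this module generates raw line-scan cubes with the
statistical structure the analysis assumes:

* ~320-column cubes on a 900-1700 nm, 256-band axis, an elliptical slice
  on a dark plate, and a low-reflectance central pith;
* a smooth reflectance baseline with absorption valleys near 1015, 1200
  and 1450 nm (C-H stretch, weak water combination band, first water
  overtone);
* a small class-dependent reflectance offset over 1200-1400 nm (frying
  cultivars slightly higher), attenuated in the pith whose water-rich
  tissue also deepens the 1450 nm valley;
* per-pixel multiplicative/additive scatter, sensor noise, and
  column-wise stripe noise typical of push-broom systems;
* white (99 % tile) and dark references, with the raw cube synthesized
  by inverting the reflectance calibration against them.

Ten cultivars with Solanum tuberosum chemistry (dry matter, starch and
reducing-sugar contents in the ranges reported for cooking vs crisping
cultivars) provide labels; eight tubers per cultivar reproduce the
80-tuber mean-spectra design, three per cultivar the 30-tuber pixel-wise
subset.  The reducing-sugar assay calibration
``%RS = (absorbance - 0.00385) * 1.07893`` lives here too.
"""

from __future__ import annotations

import dataclasses
import pathlib
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .cube_io import (
    CubeKind,
    Hypercube,
    ReferencePair,
    WavelengthAxis,
    build_wavelength_axis,
    write_envi,
)
from .errors import ConfigError, ParameterError
from .segmentation import Mask

__all__ = [
    "COOKING",
    "FRYING",
    "CultivarSpec",
    "SliceSpec",
    "SliceSample",
    "DEFAULT_CULTIVARS",
    "default_axis",
    "rs_from_absorbance",
    "absorbance_from_rs",
    "generate_slice",
    "select_cultivars",
    "iter_slices",
    "generate_dataset",
    "generate_chemistry",
    "split_dataset",
]

COOKING = "cooking"
FRYING = "frying"

#: Affine calibration of the reducing-sugar spectrophotometric assay.
_RS_SLOPE = 1.07893
_RS_OFFSET = 0.00385


def rs_from_absorbance(absorbance: float) -> float:
    """Reducing sugars (% fresh weight) from DNSA-assay absorbance.

    ``%RS = (absorbance - 0.00385) * 1.07893``
    """
    absorbance = np.asarray(absorbance, dtype=float)
    if np.any(absorbance < 0):
        raise ParameterError("absorbance must be >= 0")
    result = (absorbance - _RS_OFFSET) * _RS_SLOPE
    return float(result) if result.ndim == 0 else result


def absorbance_from_rs(rs_pct: float) -> float:
    """Inverse of :func:`rs_from_absorbance`."""
    return np.asarray(rs_pct, dtype=float) / _RS_SLOPE + _RS_OFFSET


@dataclasses.dataclass(frozen=True)
class CultivarSpec:
    """Cultivar identity, class and bench-chemistry distribution.

    ``reflectance_offset`` is the cultivar's mean class-band offset
    (reflectance units over 1200-1400 nm); ``None`` means the class
    default of the :class:`SliceSpec` in use.
    """

    name: str
    class_label: str
    dm_pct: tuple[float, float]  # mean, sd
    starch_pct: tuple[float, float]
    rs_pct: tuple[float, float]
    reflectance_offset: float | None = None

    def with_offset(self, offset: float) -> "CultivarSpec":
        return dataclasses.replace(self, reflectance_offset=offset)


#: Ten cultivars with the dry-matter / starch / reducing-sugar chemistry
#: typical of cooking (DM 17-19 %) vs crisping (DM 20-23.2 %) varieties.
DEFAULT_CULTIVARS: tuple[CultivarSpec, ...] = (
    CultivarSpec("Ambition", COOKING, (18.56, 0.18), (11.47, 0.09), (0.145, 0.008)),
    CultivarSpec("Laudine", COOKING, (18.57, 0.19), (11.49, 0.11), (0.116, 0.006)),
    CultivarSpec("Levantina", COOKING, (18.63, 0.22), (11.55, 0.07), (0.150, 0.010)),
    CultivarSpec("Madeleine", COOKING, (17.77, 0.23), (10.66, 0.10), (0.162, 0.012)),
    CultivarSpec("Rudolph", COOKING, (18.87, 0.14), (11.79, 0.12), (0.076, 0.007)),
    CultivarSpec("Agria", FRYING, (21.00, 0.23), (13.95, 0.11), (0.140, 0.012)),
    CultivarSpec("Corsica", FRYING, (20.93, 0.15), (13.91, 0.14), (0.065, 0.009)),
    CultivarSpec("Hermes", FRYING, (22.81, 0.17), (15.84, 0.09), (0.099, 0.010)),
    CultivarSpec("Lady Amarilla", FRYING, (20.47, 0.21), (13.44, 0.16), (0.103, 0.011)),
    CultivarSpec("Lyoness", FRYING, (23.14, 0.14), (16.18, 0.10), (0.061, 0.007)),
)

_DM_WINDOWS = {COOKING: (17.0, 19.0), FRYING: (20.0, 23.2)}


def select_cultivars(n_cultivars: int, pool: Sequence[CultivarSpec] | None = None):
    """First ``n_cultivars`` specs, class-interleaved to keep both classes.

    The full default pool is 5 cooking + 5 frying cultivars; sub-selections
    alternate classes so even a 2-cultivar dataset stays a binary problem.
    """
    pool = list(pool) if pool is not None else list(DEFAULT_CULTIVARS)
    if not 1 <= n_cultivars <= len(pool):
        raise ParameterError(f"n_cultivars must be in [1, {len(pool)}]")
    cooking = [c for c in pool if c.class_label == COOKING]
    frying = [c for c in pool if c.class_label == FRYING]
    interleaved = []
    for pair in zip(cooking, frying):
        interleaved.extend(pair)
    interleaved.extend(cooking[len(frying):] + frying[len(cooking):])
    return interleaved[:n_cultivars]


def default_axis() -> WavelengthAxis:
    """The instrument grid: 256 bands from 900 to 1700 nm (3.14 nm spacing)."""
    return build_wavelength_axis(900.0, 1700.0, 256)


@dataclasses.dataclass
class SliceSpec:
    """Geometry, optics and noise of one synthetic slice scan.

    Reflectance model for a foreground pixel at normalized elliptical
    radius ``d`` (0 center, 1 rim)::

        R(lam) = f(d) * [ B(lam) + pith(d) * W(lam) + delta_eff(d) * w(lam) ]

    with ``B`` = linear baseline minus three Gaussian absorption valleys,
    ``W`` = extra water-valley deepening in the pith, ``w`` = flat-top
    class-offset window over 1200-1400 nm with cosine ramps, ``f`` the
    radial brightness factor (reduced in the pith), and
    ``delta_eff = delta * (1 - pith_signal_atten * pith(d))`` so the pith
    carries an attenuated class signal.  Per-pixel scatter ``a*R + b``,
    additive sensor noise, column stripes and a rim taper toward the
    background complete the image; the raw cube is the inverse of the
    white/dark calibration applied to this reflectance.
    """

    shape: tuple[int, int] = (120, 320)
    center: tuple[float, float] | None = None  # default: image center, jittered
    center_jitter_px: float = 4.0
    semi_axes: tuple[float, float] = (36.0, 42.0)  # (row, col) in px
    semi_axes_jitter_px: float = 3.0
    pith_radius_frac: float = 0.28
    pith_factor: float = 0.80  # radial brightness multiplier in the pith
    pith_edge_softness: float = 0.06  # sigmoid width on normalized radius
    pith_water_extra_depth: float = 0.05  # added 1450 nm valley depth in pith
    pith_signal_atten: float = 0.6  # fraction of class offset lost in pith
    baseline: tuple[float, float] = (0.50, 0.42)  # reflectance at 900/1700 nm
    valleys: tuple[tuple[float, float, float], ...] = (
        (1015.0, 0.05, 20.0),  # center nm, depth, sigma nm
        (1200.0, 0.07, 35.0),
        (1450.0, 0.25, 45.0),
    )
    class_offset: float = 0.02  # frying-class reflectance offset
    offset_band: tuple[float, float] = (1200.0, 1400.0)
    offset_ramp_nm: float = 20.0
    cultivar_offset_sd: float = 0.003
    tuber_offset_sd: float = 0.003
    baseline_shift_sd: float = 0.010  # per-tuber flat reflectance shift
    scatter_mult_sd: float = 0.04  # per-pixel multiplicative scatter
    scatter_add_sd: float = 0.008  # per-pixel additive scatter
    noise_sd: float = 0.01  # per-pixel-per-band sensor noise
    stripe_sd: float = 0.003  # per-column stripe amplitude
    background_reflectance: float = 0.03
    edge_taper_px: float = 3.0
    white_level: float = 3000.0  # raw counts of the 99 % tile
    dark_level: float = 96.0  # sensor offset

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.stripe_sd < 0 or self.scatter_mult_sd < 0:
            raise ParameterError("noise amplitudes must be >= 0")


@dataclasses.dataclass
class SliceSample:
    """One generated scan: raw cube, references and ground truth."""

    sample_id: str
    cultivar: str
    class_label: str
    raw: Hypercube
    refs: ReferencePair
    truth_mask: Mask
    regions: np.ndarray  # 0 background, 1 cortex, 2 pith
    reflectance: Hypercube  # the constructed reflectance (incl. noise)


def _offset_window(wl: np.ndarray, lo: float, hi: float, ramp: float) -> np.ndarray:
    """Flat-top window over [lo, hi] with cosine ramps of width ``ramp`` nm."""
    w = np.zeros_like(wl)
    core = (wl >= lo) & (wl <= hi)
    w[core] = 1.0
    if ramp > 0:
        left = (wl >= lo - ramp) & (wl < lo)
        w[left] = 0.5 * (1 + np.cos(np.pi * (lo - wl[left]) / ramp))
        right = (wl > hi) & (wl <= hi + ramp)
        w[right] = 0.5 * (1 + np.cos(np.pi * (wl[right] - hi) / ramp))
    return w


def _base_profile(spec: SliceSpec, wl: np.ndarray) -> np.ndarray:
    frac = (wl - wl[0]) / (wl[-1] - wl[0])
    profile = spec.baseline[0] + (spec.baseline[1] - spec.baseline[0]) * frac
    for center, depth, sigma in spec.valleys:
        profile = profile - depth * np.exp(-0.5 * ((wl - center) / sigma) ** 2)
    return profile


def _water_extra(spec: SliceSpec, wl: np.ndarray) -> np.ndarray:
    center, _, sigma = spec.valleys[-1]
    return -spec.pith_water_extra_depth * np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def generate_slice(
    spec: SliceSpec,
    cultivar: CultivarSpec,
    axis: WavelengthAxis | None = None,
    rng: np.random.Generator | None = None,
    sample_id: str | None = None,
) -> SliceSample:
    """Generate one raw cube + references + ground truth for a cultivar."""
    axis = axis or default_axis()
    rng = rng or np.random.default_rng()
    wl = axis.values
    rows, cols = spec.shape

    # geometry (jittered ellipse)
    if spec.center is None:
        r0 = rows / 2.0 + rng.normal(0, spec.center_jitter_px)
        c0 = cols / 2.0 + rng.normal(0, spec.center_jitter_px)
    else:
        r0, c0 = spec.center
    ar = spec.semi_axes[0] + rng.normal(0, spec.semi_axes_jitter_px)
    ac = spec.semi_axes[1] + rng.normal(0, spec.semi_axes_jitter_px)
    if r0 - ar < 1 or r0 + ar > rows - 1 or c0 - ac < 1 or c0 + ac > cols - 1:
        raise ConfigError(
            f"ellipse (center=({r0:.1f},{c0:.1f}), axes=({ar:.1f},{ac:.1f})) "
            f"exceeds image bounds {spec.shape}"
        )
    rr, cc = np.mgrid[0:rows, 0:cols]
    d = np.sqrt(((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2)

    # pith weight and radial brightness factor
    soft = max(spec.pith_edge_softness, 1e-6)
    pith_w = 1.0 / (1.0 + np.exp((d - spec.pith_radius_frac) / soft))
    radial = 1.0 - (1.0 - spec.pith_factor) * pith_w

    # rim taper toward background; truth = majority-foreground pixels
    a_eff = min(ar, ac)
    taper = np.clip((1.0 - d) * a_eff / max(spec.edge_taper_px, 1e-6), 0.0, 1.0)
    truth = taper >= 0.5
    regions = np.zeros(spec.shape, dtype=np.uint8)
    regions[truth] = 1
    regions[truth & (pith_w >= 0.5)] = 2

    # spectral components
    delta_mean = (
        cultivar.reflectance_offset
        if cultivar.reflectance_offset is not None
        else (spec.class_offset if cultivar.class_label == FRYING else 0.0)
    )
    delta = delta_mean + rng.normal(0, spec.tuber_offset_sd)
    shift = rng.normal(0, spec.baseline_shift_sd)
    window = _offset_window(wl, *spec.offset_band, spec.offset_ramp_nm)
    base = _base_profile(spec, wl) + shift + delta * window
    pith_term = _water_extra(spec, wl) - spec.pith_signal_atten * delta * window

    # Per-pixel scatter, rim taper and stripes are all affine in the two
    # spectral components, so the cube is assembled in three fused passes:
    #   R = A (x) base + B (x) pith_term + C
    # with A = taper * a_px * radial, B = A * pith_w and C collecting the
    # additive scatter, background blend and column stripes.
    a_px = 1.0 + rng.normal(0, spec.scatter_mult_sd, size=spec.shape)
    b_px = rng.normal(0, spec.scatter_add_sd, size=spec.shape)
    A = taper * a_px * radial
    B = A * pith_w
    C = taper * b_px + (1.0 - taper) * spec.background_reflectance
    if spec.stripe_sd > 0:
        C = C + rng.normal(0, spec.stripe_sd, size=cols)[None, :]
    reflectance = np.multiply.outer(A, base)
    reflectance += np.multiply.outer(B, pith_term)
    reflectance += C[:, :, None]
    if spec.noise_sd > 0:
        reflectance += rng.normal(0, spec.noise_sd, size=reflectance.shape)

    # references: smooth lamp spectrum and column gain, then invert calibration
    illum = 1.0 - 0.25 * ((wl - 1300.0) / 400.0) ** 2
    col_gain = 1.0 + 0.05 * np.cos(2 * np.pi * np.arange(cols) / cols)
    white = spec.white_level * col_gain[:, None] * illum[None, :] + spec.dark_level
    dark = np.full((cols, len(wl)), spec.dark_level)
    raw = dark[None, :, :] + reflectance * (white - dark)[None, :, :]

    return SliceSample(
        sample_id=sample_id or cultivar.name,
        cultivar=cultivar.name,
        class_label=cultivar.class_label,
        raw=Hypercube(raw, axis, CubeKind.RAW, sample_id, cultivar.class_label),
        refs=ReferencePair(white, dark),
        truth_mask=Mask(truth),
        regions=regions,
        reflectance=Hypercube(
            reflectance, axis, CubeKind.REFLECTANCE, sample_id, cultivar.class_label
        ),
    )


def iter_slices(
    n_cultivars: int = 10,
    tubers_per_cultivar: int = 8,
    seed: int = 0,
    slice_spec: SliceSpec | None = None,
    cultivars: Sequence[CultivarSpec] | None = None,
    axis: WavelengthAxis | None = None,
) -> Iterator[SliceSample]:
    """Yield slice samples one at a time, reproducibly from ``seed``.

    Cultivar-level offsets are drawn first from a dedicated substream;
    each slice then uses its own counter-derived substream, so any slice
    is independent of generation order.
    """
    if n_cultivars < 1 or tubers_per_cultivar < 1:
        raise ParameterError("counts must be >= 1")
    spec = slice_spec or SliceSpec()
    axis = axis or default_axis()
    chosen = select_cultivars(n_cultivars, cultivars)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(1 + n_cultivars * tubers_per_cultivar)
    cultivar_rng = np.random.default_rng(children[0])
    offsets = []
    for cv in chosen:
        base = cv.reflectance_offset
        if base is None:
            base = spec.class_offset if cv.class_label == FRYING else 0.0
        offsets.append(base + cultivar_rng.normal(0, spec.cultivar_offset_sd))
    k = 1
    for cv, offset in zip(chosen, offsets):
        cv_off = cv.with_offset(offset)
        for t in range(tubers_per_cultivar):
            rng = np.random.default_rng(children[k])
            k += 1
            sample_id = f"{cv.name.replace(' ', '_')}_{t + 1:02d}"
            yield generate_slice(spec, cv_off, axis, rng, sample_id)


def generate_chemistry(
    cultivars: Sequence[CultivarSpec] | None = None,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Bench-chemistry table: DM/starch/RS replicates plus assay absorbance.

    DM draws are clipped into the class window (cooking 17-19 %, frying
    20-23.2 %), RS stays below 0.2 %, and the absorbance column satisfies
    the assay calibration exactly.
    """
    pool = list(cultivars) if cultivars is not None else list(DEFAULT_CULTIVARS)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC4E)))
    records = []
    for cv in pool:
        lo, hi = _DM_WINDOWS[cv.class_label]
        for rep in range(replicates):
            dm = float(np.clip(rng.normal(*cv.dm_pct), lo, hi))
            starch = float(max(rng.normal(*cv.starch_pct), 0.0))
            rs = float(np.clip(rng.normal(*cv.rs_pct), 0.005, 0.199))
            absorbance = float(absorbance_from_rs(rs))
            records.append(
                {
                    "cultivar": cv.name,
                    "class": cv.class_label,
                    "replicate": rep + 1,
                    "dm_pct": round(dm, 3),
                    "starch_pct": round(starch, 3),
                    "absorbance": absorbance,
                    "rs_pct": rs_from_absorbance(absorbance),
                }
            )
    return pd.DataFrame.from_records(records)


def generate_dataset(
    out_dir: str | pathlib.Path,
    n_cultivars: int = 10,
    tubers_per_cultivar: int = 8,
    seed: int = 0,
    slice_spec: SliceSpec | None = None,
    cultivars: Sequence[CultivarSpec] | None = None,
    interleave: str = "bil",
) -> pd.DataFrame:
    """Write ENVI cubes, references, truth masks and manifest/chemistry CSVs.

    Defaults reproduce the 80-tuber design (10 cultivars x 8 tubers,
    40 cooking / 40 frying); ``tubers_per_cultivar=3`` gives the 30-tuber
    pixel-wise subset.  Returns the manifest; rerunning with the same
    seed reproduces it byte-identically.
    """
    out = pathlib.Path(out_dir)
    (out / "cubes").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for sample in iter_slices(
        n_cultivars, tubers_per_cultivar, seed, slice_spec, cultivars
    ):
        stem = out / "cubes" / sample.sample_id
        cube_hdr = write_envi(sample.raw, stem, interleave=interleave)
        white = Hypercube(
            sample.refs.white[None, :, :], sample.raw.axis, CubeKind.RAW
        )
        dark = Hypercube(sample.refs.dark[None, :, :], sample.raw.axis, CubeKind.RAW)
        white_hdr = write_envi(white, f"{stem}_white", interleave=interleave)
        dark_hdr = write_envi(dark, f"{stem}_dark", interleave=interleave)
        mask_path = out / "masks" / f"{sample.sample_id}.png"
        Image.fromarray(
            (sample.truth_mask.data * np.uint8(255)), mode="L"
        ).save(mask_path, format="PNG")
        rows.append(
            {
                "sample_id": sample.sample_id,
                "cultivar": sample.cultivar,
                "class": sample.class_label,
                "cube": str(cube_hdr.relative_to(out)),
                "white": str(white_hdr.relative_to(out)),
                "dark": str(dark_hdr.relative_to(out)),
                "mask": str(mask_path.relative_to(out)),
            }
        )
    manifest = pd.DataFrame.from_records(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    chem = generate_chemistry(cultivars, seed=seed)
    chem.iloc[: n_cultivars * 3].to_csv(out / "chemistry.csv", index=False)
    return manifest


MEAN_SPECTRA_SPLIT = "mean_spectra_75_25"
PIXELWISE_SPLIT = "pixelwise_2_1_per_cultivar"


def split_dataset(manifest: pd.DataFrame, mode: str, seed: int = 0) -> pd.Series:
    """Calibration/validation assignment for a sample manifest.

    ``mean_spectra_75_25``
        Stratified random 75/25 split by class (80 samples -> 60/20).
    ``pixelwise_2_1_per_cultivar``
        Per cultivar: 3 tubers retained at random if more are present,
        then 2 calibration + 1 validation (30 samples -> 20/10).
        Samples not retained get the label ``"unused"``.

    Returns a Series indexed like ``manifest`` with values in
    {"calibration", "validation", "unused"}.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x59117)))
    split = pd.Series("unused", index=manifest.index, dtype=object)
    if mode == MEAN_SPECTRA_SPLIT:
        for _, group in manifest.groupby("class", sort=True):
            order = group.index.to_numpy()[rng.permutation(len(group))]
            n_cal = int(round(0.75 * len(order)))
            split.loc[order[:n_cal]] = "calibration"
            split.loc[order[n_cal:]] = "validation"
    elif mode == PIXELWISE_SPLIT:
        for cultivar, group in manifest.groupby("cultivar", sort=True):
            if len(group) < 3:
                raise ParameterError(
                    f"cultivar {cultivar!r} has {len(group)} tubers; pixel-wise "
                    "split needs at least 3"
                )
            order = group.index.to_numpy()[rng.permutation(len(group))]
            split.loc[order[:2]] = "calibration"
            split.loc[order[2]] = "validation"
    else:
        raise ConfigError(f"unknown split mode {mode!r}")
    return split
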