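"""Seed-reproducible synthetic hyperspectral scenes of pepper-plant organs.

No public hyperspectral dataset of pepper leaves/stems/roots with paired
total-nitrogen chemistry exists, so the pipeline is exercised on synthetic
scenes that carry the statistical structure the analysis assumes:

* a Vis/NIR wavelength grid (default 380-1030 nm, 512 uniform bands);
* organ-specific smooth reflectance continua (vegetation-like for leaf and
  stem with a green peak, chlorophyll trough and red edge; a flat
  soil-like ramp for root);
* Gaussian absorption features (defaults near 550, 650, 760 and 970 nm)
  whose depths scale *linearly* with the pixel's total nitrogen content
  (TNC, % dry basis), so that a linear calibration model is recoverable;
* per-pixel additive noise and multiplicative scatter, plus a per-sample
  scatter factor emulating sample-presentation effects;
* organ/position TNC distributions: leaf samples are richest in nitrogen,
  stems poorest, and within leaf and stem the upper > middle > lower
  position ordering holds, with ranges confined to leaf 2.264-4.871 %,
  stem 0.556-2.135 %, root 0.847-1.470 %.

Each sample is emitted as a raw/white/dark ENVI-style cube triplet that
white/dark calibration inverts exactly when noise is zero, together with
the ROI mask and the ground-truth per-pixel TNC field.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hypercube_io import Hypercube, SpectraTable, calibrate, mean_roi_spectrum

__all__ = [
    "SceneConfig",
    "SyntheticSample",
    "ConfigurationError",
    "generate_scene",
    "write_reference_table",
    "read_reference_table",
    "extract_spectra_table",
    "synthetic_spectra_table",
    "planted_signal_table",
    "ORGAN_TNC_RANGES",
    "POSITION_TNC_STATS",
]


class ConfigurationError(ValueError):
    """Raised when a scene configuration is internally inconsistent."""


# Organ-level TNC envelopes (%, dry basis) the generator draws within.
ORGAN_TNC_RANGES: dict[str, tuple[float, float]] = {
    "leaf": (2.264, 4.871),
    "stem": (0.556, 2.135),
    "root": (0.847, 1.470),
}

# Per-group sampling distributions (mean, sd) of sample-level TNC.  Upper
# positions of leaf and stem are nitrogen-richest; the organ means order as
# leaf > root > stem.
POSITION_TNC_STATS: dict[tuple[str, str], tuple[float, float]] = {
    ("leaf", "upper"): (4.053, 0.498),
    ("leaf", "middle"): (3.129, 0.321),
    ("leaf", "lower"): (2.703, 0.325),
    ("stem", "upper"): (1.390, 0.366),
    ("stem", "middle"): (0.849, 0.175),
    ("stem", "lower"): (0.736, 0.102),
    ("root", "n/a"): (1.186, 0.143),
}

# TNC absorption features: (center nm, width nm, reflectance depth per % TNC)
DEFAULT_BAND_EFFECTS: tuple[tuple[float, float, float], ...] = (
    (550.0, 35.0, 0.016),   # chlorophyll-related green-region feature
    (650.0, 30.0, 0.012),   # red chlorophyll absorption
    (760.0, 25.0, 0.014),   # N-H third-overtone region
    (970.0, 45.0, 0.018),   # O-H second overtone (water)
)


@dataclass
class SceneConfig:
    """Study-condition parameters of a synthetic scene."""

    rng_seed: int = 0
    n_leaf: int = 120
    n_stem: int = 120
    n_root: int = 40
    image_shape: tuple[int, int] = (20, 16)
    band_start_nm: float = 380.0
    band_end_nm: float = 1030.0
    n_bands: int = 512
    organ_tnc_ranges: dict = field(default_factory=lambda: dict(ORGAN_TNC_RANGES))
    noise_sd: float = 0.005          # additive reflectance noise, per pixel/band
    scatter_sd: float = 0.02         # multiplicative scatter (per sample & pixel)
    band_effects: tuple = DEFAULT_BAND_EFFECTS
    within_sample_cv: float = 0.10   # peak-to-peak TNC variation / sample mean
    dtype: type = np.float32         # storage dtype of the emitted cubes

    def validate(self) -> None:
        if self.n_bands < 2:
            raise ConfigurationError("n_bands: band count must be >= 2")
        if not self.band_start_nm < self.band_end_nm:
            raise ConfigurationError("band_grid: start must be < end")
        for organ, (lo, hi) in self.organ_tnc_ranges.items():
            if not (0 < lo < hi):
                raise ConfigurationError(
                    f"organ_tnc_ranges[{organ!r}]: need 0 < min < max"
                )
        if self.noise_sd < 0 or self.scatter_sd < 0:
            raise ConfigurationError("noise: standard deviations must be >= 0")
        if min(self.n_leaf, self.n_stem, self.n_root) < 0:
            raise ConfigurationError("sample counts must be non-negative")
        if len(self.image_shape) != 2 or min(self.image_shape) < 2:
            raise ConfigurationError("image_shape: need rows, cols >= 2")
        centers = [c for c, _, _ in self.band_effects]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ConfigurationError("band_effects: centers must be strictly increasing")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.band_start_nm, self.band_end_nm, self.n_bands)


@dataclass
class SyntheticSample:
    """One synthetic organ sample: cubes, ROI, and ground truth."""

    sample_id: str
    organ: str
    position: str
    tnc_true: float              # sample-level TNC = ROI mean of pixel_tnc
    raw_cube: Hypercube
    white_cube: Hypercube
    dark_cube: Hypercube
    roi_mask: np.ndarray
    pixel_tnc: np.ndarray        # per-pixel TNC (%); NaN off-ROI

    def calibrated(self) -> Hypercube:
        return calibrate(self.raw_cube, self.white_cube, self.dark_cube)


# ---------------------------------------------------------------------------
# Spectral building blocks
# ---------------------------------------------------------------------------

def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def _logistic(wl: np.ndarray, center: float, scale: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(wl - center) / scale))


def organ_baseline(organ: str, wl: np.ndarray) -> np.ndarray:
    """Smooth TNC-independent reflectance continuum per organ.

    Leaf and stem are vegetation-like (green peak near 550 nm, chlorophyll
    trough near 670 nm, red edge to a NIR plateau, fixed water dip near
    960 nm); the stem continuum sits higher than the leaf one.  Root is a
    flat, gently rising soil-like curve.
    """
    if organ == "leaf":
        base = (0.16 + 0.10 * _gauss(wl, 550, 32)
                + 0.52 * _logistic(wl, 715, 16)
                - 0.06 * _gauss(wl, 960, 40))
    elif organ == "stem":
        base = (0.24 + 0.08 * _gauss(wl, 550, 40)
                + 0.50 * _logistic(wl, 710, 20)
                - 0.05 * _gauss(wl, 960, 40))
    elif organ == "root":
        base = 0.30 + 0.25 * (wl - wl[0]) / (wl[-1] - wl[0]) - 0.04 * _gauss(wl, 960, 45)
    else:
        raise ConfigurationError(f"unknown organ {organ!r}")
    return base


_BACKGROUND_REFLECTANCE = 0.42    # flat board/soil backdrop off-ROI


def _roi_mask_for(organ: str, shape: tuple[int, int]) -> np.ndarray:
    """Organ-shaped ROI: ellipse (leaf), vertical bar (stem), blob (root)."""
    rows, cols = shape
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    cr, cc = (rows - 1) / 2.0, (cols - 1) / 2.0
    if organ == "leaf":
        mask = (((r - cr) / (0.42 * rows)) ** 2
                + ((c - cc) / (0.38 * cols)) ** 2) <= 1.0
    elif organ == "stem":
        half = max(1.0, 0.18 * cols)
        mask = (np.abs(c - cc) <= half) & (r >= 0.08 * rows) & (r <= 0.92 * rows)
    else:
        mask = (((r - cr) / (0.36 * rows)) ** 2
                + ((c - cc) / (0.36 * cols)) ** 2) <= 1.0
    mask = np.broadcast_to(mask, shape).copy()
    if not mask.any():                       # degenerate tiny images
        mask[rows // 2, cols // 2] = True
    return mask


def _pixel_tnc_field(tnc_mean: float, mask: np.ndarray, cv: float) -> np.ndarray:
    """Smooth within-sample TNC field whose ROI mean is exactly ``tnc_mean``.

    A linear ramp along the image rows (apex-to-base gradient) with
    peak-to-peak amplitude ``cv * tnc_mean``, recentred on the ROI so the
    sample-level truth is the exact ROI average.
    """
    rows, cols = mask.shape
    ramp = np.linspace(0.5, -0.5, rows)[:, None] * np.ones((1, cols))
    ramp = ramp - ramp[mask].mean()
    field = tnc_mean + cv * tnc_mean * ramp
    field = np.where(mask, field, np.nan)
    return field


def _positions_for(organ: str, n: int) -> list[str]:
    if organ == "root":
        return ["n/a"] * n
    cycle = ["upper", "middle", "lower"]
    return [cycle[(3 * i) // n] for i in range(n)]


def _draw_tnc(rng: np.random.Generator, organ: str, position: str,
              tnc_range: tuple[float, float]) -> float:
    mean, sd = POSITION_TNC_STATS[(organ, position)]
    lo, hi = tnc_range
    for _ in range(64):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _designed_reflectance(cfg: SceneConfig, organ: str, pixel_tnc: np.ndarray,
                          mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-pixel reflectance image (rows, cols, bands) before un-calibration."""
    wl = cfg.wavelengths
    base = organ_baseline(organ, wl)                         # (bands,)
    depth = np.zeros_like(wl)
    profiles = []
    for center, width, d in cfg.band_effects:
        profiles.append(d * _gauss(wl, center, width))
    absorb_per_tnc = np.sum(profiles, axis=0) if profiles else depth

    rows, cols = mask.shape
    refl = np.broadcast_to(base, (rows, cols, wl.size)).copy()
    tnc = np.where(mask, pixel_tnc, 0.0)
    refl -= tnc[:, :, None] * absorb_per_tnc[None, None, :]
    refl[~mask] = _BACKGROUND_REFLECTANCE

    if cfg.scatter_sd > 0:
        sample_factor = 1.0 + rng.normal(0.0, cfg.scatter_sd)
        pixel_factor = 1.0 + rng.normal(0.0, cfg.scatter_sd, size=(rows, cols))
        refl[mask] *= sample_factor * pixel_factor[mask][:, None]
    if cfg.noise_sd > 0:
        refl += rng.normal(0.0, cfg.noise_sd, size=refl.shape)
    return np.clip(refl, 0.0, 1.0)


def _uncalibrate(cfg: SceneConfig, refl: np.ndarray, wl: np.ndarray,
                 rng: np.random.Generator) -> tuple[Hypercube, Hypercube, Hypercube]:
    """Build a raw/white/dark counts triplet that calibration inverts.

    White is a flat high-count field with a mild column pattern; dark a
    small constant; raw = dark + reflectance * (white - dark), which keeps
    dark <= raw <= white wherever reflectance is in [0, 1].
    """
    rows, cols, bands = refl.shape
    col_pattern = 1.0 + 0.05 * np.sin(2 * np.pi * np.arange(cols) / max(cols, 1))
    white = 4000.0 * col_pattern[None, :, None] * np.ones((rows, 1, bands))
    dark = np.full((rows, cols, bands), 100.0)
    raw = dark + refl * (white - dark)
    dt = cfg.dtype
    mk = lambda a: Hypercube(data=a.astype(dt), wavelengths=wl, interleave="bil")
    return mk(raw), mk(white), mk(dark)


# ---------------------------------------------------------------------------
# Public generator operations
# ---------------------------------------------------------------------------

def generate_scene(config: SceneConfig) -> list[SyntheticSample]:
    """Generate the full synthetic cohort (default 120 leaf / 120 stem /
    40 root samples), deterministically for a fixed ``rng_seed``."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    wl = config.wavelengths

    samples: list[SyntheticSample] = []
    counts = (("leaf", config.n_leaf), ("stem", config.n_stem),
              ("root", config.n_root))
    idx = 0
    for organ, n in counts:
        positions = _positions_for(organ, n)
        tnc_range = config.organ_tnc_ranges[organ]
        for position in positions:
            tnc_mean = _draw_tnc(rng, organ, position, tnc_range)
            mask = _roi_mask_for(organ, tuple(config.image_shape))
            pixel_tnc = _pixel_tnc_field(tnc_mean, mask, config.within_sample_cv)
            refl = _designed_reflectance(config, organ, pixel_tnc, mask, rng)
            raw, white, dark = _uncalibrate(config, refl, wl, rng)
            samples.append(SyntheticSample(
                sample_id=f"{organ}-{idx:04d}", organ=organ, position=position,
                tnc_true=float(np.nanmean(pixel_tnc[mask])),
                raw_cube=raw, white_cube=white, dark_cube=dark,
                roi_mask=mask, pixel_tnc=pixel_tnc,
            ))
            idx += 1
    return samples


def write_reference_table(samples: list[SyntheticSample],
                          path: str | os.PathLike) -> None:
    """Write the per-sample reference chemistry (the stand-in for combustion
    nitrogen measurements) as a CSV with one row per sample."""
    if not samples:
        raise ValueError("no samples to write")
    df = pd.DataFrame({
        "sample_id": [s.sample_id for s in samples],
        "organ": [s.organ for s in samples],
        "position": [s.position for s in samples],
        "tnc_percent": [repr(s.tnc_true) for s in samples],
    })
    df.to_csv(path, index=False)


def read_reference_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False,
                     float_precision="round_trip")
    df["tnc_percent"] = df["tnc_percent"].astype(float)
    return df


def extract_spectra_table(samples: list[SyntheticSample]) -> SpectraTable:
    """Calibrate each sample's cube triplet and average its ROI pixels,
    assembling the n x p table the chemometrics operates on."""
    if not samples:
        raise ValueError("no samples to extract")
    X = np.stack([
        mean_roi_spectrum(s.calibrated(), s.roi_mask) for s in samples
    ])
    return SpectraTable(
        X=X,
        y=np.array([s.tnc_true for s in samples]),
        wavelengths=samples[0].raw_cube.wavelengths.copy(),
        sample_ids=np.array([s.sample_id for s in samples], dtype=object),
        organs=np.array([s.organ for s in samples], dtype=object),
        positions=np.array([s.position for s in samples], dtype=object),
    )


def synthetic_spectra_table(config: SceneConfig) -> SpectraTable:
    """Sample-level shortcut: designed mean-ROI spectra without building
    image cubes.

    Draws the same organ/position TNC distributions as
    :func:`generate_scene` and emits the sample-mean reflectance directly
    (baseline - TNC * absorption, with sample-level scatter and the
    ROI-averaged residual noise).  Used where only the n x p table matters
    and cube synthesis would be waste.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    wl = config.wavelengths
    absorb = np.sum([d * _gauss(wl, c, w) for c, w, d in config.band_effects],
                    axis=0) if config.band_effects else np.zeros_like(wl)

    rows_X, ys, ids, organs, poss = [], [], [], [], []
    n_roi = max(4, int(0.4 * config.image_shape[0] * config.image_shape[1]))
    idx = 0
    for organ, n in (("leaf", config.n_leaf), ("stem", config.n_stem),
                     ("root", config.n_root)):
        base = organ_baseline(organ, wl)
        for position in _positions_for(organ, n):
            tnc = _draw_tnc(rng, organ, position, config.organ_tnc_ranges[organ])
            spec = base - tnc * absorb
            if config.scatter_sd > 0:
                spec = spec * (1.0 + rng.normal(0.0, config.scatter_sd))
            if config.noise_sd > 0:
                # residual pixel noise after averaging ~n_roi ROI pixels
                spec = spec + rng.normal(0.0, config.noise_sd / np.sqrt(n_roi),
                                         size=wl.size)
            rows_X.append(np.clip(spec, 0.0, 1.0))
            ys.append(tnc)
            ids.append(f"{organ}-{idx:04d}")
            organs.append(organ)
            poss.append(position)
            idx += 1
    return SpectraTable(
        X=np.array(rows_X), y=np.array(ys), wavelengths=wl,
        sample_ids=np.array(ids, dtype=object),
        organs=np.array(organs, dtype=object),
        positions=np.array(poss, dtype=object),
    )


def planted_signal_table(n_samples: int = 100, n_noise: int = 100,
                         n_signal: int = 5, effect: float = 1.0,
                         noise_sd: float = 0.05,
                         rng_seed: int = 0) -> tuple[SpectraTable, np.ndarray]:
    """Benchmark table with known informative variables.

    ``n_signal`` variables are exact linear functions of the response plus
    small noise; the remaining ``n_noise`` variables are pure noise.  The
    planted variables are interleaved across the grid.  Returns the table
    and the planted column indices — the ground truth for wavelength-
    selection benchmarks.
    """
    rng = np.random.default_rng(rng_seed)
    p = n_noise + n_signal
    y = rng.uniform(1.0, 5.0, size=n_samples)
    X = rng.normal(0.0, 1.0, size=(n_samples, p))
    planted = np.linspace(0, p - 1, n_signal).round().astype(int)
    signs = np.where(np.arange(n_signal) % 2 == 0, 1.0, -1.0)
    for j, s in zip(planted, signs):
        X[:, j] = s * effect * y + rng.normal(0.0, noise_sd, size=n_samples)
    wl = np.linspace(420.0, 1000.0, p)
    return SpectraTable(X=X, y=y, wavelengths=wl), planted
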