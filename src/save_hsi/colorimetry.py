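"""Shared colorimetric substrate: wavelength grids, reflectance spectra,
spectrum-to-XYZ integration, sRGB handling and CIEDE2000 colour difference.

Conventions
-----------
* The master wavelength grid is 380-780 nm at 5 nm. Tristimulus integration
  runs over the 400-700 nm sub-range only; the extended red/NIR part of the
  grid exists for narrow-band synthesis at 600/700/780 nm.
* XYZ tristimulus values follow the reflective 0-100 convention: the
  normalisation constant k = 100 / integral(S * ybar) forces Y = 100 for a
  perfect reflector, so a perfect white patch has Y = 100 under any
  illuminant.
* Quadrature is the trapezoidal rule on the uniform grid.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from skimage.color import deltaE_ciede2000

__all__ = [
    "WavelengthGrid",
    "ReflectanceSpectrum",
    "SpectralCube",
    "Illuminant",
    "Observer",
    "XYZColor",
    "GridError",
    "master_grid",
    "integration_mask",
    "resample",
    "spectrum_to_xyz",
    "xyz_from_reflectance",
    "srgb_to_xyz",
    "xyz_to_srgb",
    "srgb_decode",
    "srgb_encode",
    "xyz_to_lab",
    "ciede2000",
    "d65",
    "cie_1931_observer",
    "D65_WHITE",
]


class GridError(ValueError):
    """Raised when wavelength grids are incompatible."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid in nanometres."""

    start_nm: float
    stop_nm: float
    step_nm: float

    def __post_init__(self) -> None:
        if self.step_nm <= 0 or self.stop_nm <= self.start_nm:
            raise GridError("grid must be increasing with positive step")

    @property
    def values(self) -> np.ndarray:
        n = int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1
        return self.start_nm + self.step_nm * np.arange(n)

    def __len__(self) -> int:
        return len(self.values)

    def covers(self, lo: float, hi: float) -> bool:
        return self.start_nm <= lo and self.stop_nm >= hi


#: Master grid: 380-780 nm at 5 nm (81 samples).
MASTER_GRID = WavelengthGrid(380.0, 780.0, 5.0)

#: Tristimulus integration limits (nm).
INTEGRATION_RANGE = (400.0, 700.0)


def master_grid() -> WavelengthGrid:
    return MASTER_GRID


def integration_mask(grid: WavelengthGrid,
                     lo: float = INTEGRATION_RANGE[0],
                     hi: float = INTEGRATION_RANGE[1]) -> np.ndarray:
    lam = grid.values
    return (lam >= lo - 1e-9) & (lam <= hi + 1e-9)


@dataclass
class ReflectanceSpectrum:
    """Unitless reflectance fraction per wavelength, clipped to [0, 1]."""

    grid: WavelengthGrid
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.reflectance.shape != (len(self.grid),):
            raise GridError("reflectance length does not match grid")


@dataclass
class SpectralCube:
    """H x W x B reflectance raster on a shared wavelength grid."""

    grid: WavelengthGrid
    data: np.ndarray
    clipped_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != len(self.grid):
            raise GridError("cube band count does not match grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class Illuminant:
    grid: WavelengthGrid
    power: np.ndarray

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (len(self.grid),):
            raise GridError("power length does not match grid")
        if np.any(self.power < 0):
            raise ValueError("illuminant power must be non-negative")


@dataclass
class Observer:
    grid: WavelengthGrid
    xbar: np.ndarray
    ybar: np.ndarray
    zbar: np.ndarray

    def __post_init__(self) -> None:
        for name in ("xbar", "ybar", "zbar"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(self.grid),):
                raise GridError(f"{name} length does not match grid")
            if np.any(arr < 0):
                raise ValueError("colour-matching functions must be non-negative")
            setattr(self, name, arr)


@dataclass(frozen=True)
class XYZColor:
    X: float
    Y: float
    Z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.X, self.Y, self.Z], dtype=float)


# --------------------------------------------------------------------------
# Packaged tables

def _load_table(name: str) -> np.ndarray:
    text = resources.files("save_hsi.data").joinpath(name).read_text()
    rows = [
        [float(tok) for tok in line.split(",")]
        for line in text.splitlines()
        if line and not line.startswith("#")
    ]
    return np.asarray(rows)


def resample(values: np.ndarray, source: WavelengthGrid,
             target: WavelengthGrid) -> np.ndarray:
    """Linear interpolation onto ``target``; constant extension outside the
    source support. Idempotent when the grids coincide."""
    if source.stop_nm < target.start_nm or source.start_nm > target.stop_nm:
        raise GridError("source and target grids are disjoint")
    values = np.asarray(values, dtype=float)
    src = source.values
    if np.array_equal(src, target.values):
        return values.copy()
    return np.interp(target.values, src, values)


@functools.lru_cache(maxsize=None)
def d65(grid: WavelengthGrid = MASTER_GRID) -> Illuminant:
    """CIE standard illuminant D65 resampled to ``grid``."""
    tab = _load_table("illuminant_d65_10nm.csv")
    src = WavelengthGrid(tab[0, 0], tab[-1, 0], tab[1, 0] - tab[0, 0])
    return Illuminant(grid, resample(tab[:, 1], src, grid))


@functools.lru_cache(maxsize=None)
def cie_1931_observer(grid: WavelengthGrid = MASTER_GRID) -> Observer:
    """CIE 1931 2-degree standard observer resampled to ``grid``."""
    tab = _load_table("cie1931_2deg_10nm.csv")
    src = WavelengthGrid(tab[0, 0], tab[-1, 0], tab[1, 0] - tab[0, 0])
    return Observer(
        grid,
        resample(tab[:, 1], src, grid),
        resample(tab[:, 2], src, grid),
        resample(tab[:, 3], src, grid),
    )


# --------------------------------------------------------------------------
# Spectrum -> XYZ

def xyz_from_reflectance(reflectance: np.ndarray, grid: WavelengthGrid,
                         illuminant: Illuminant | None = None,
                         observer: Observer | None = None) -> np.ndarray:
    """Tristimulus integration, vectorised over leading axes.

    ``reflectance`` has shape (..., B) on ``grid``; returns (..., 3) XYZ on
    the 0-100 scale with the k normalisation (perfect reflector -> Y = 100).
    """
    illuminant = illuminant if illuminant is not None else d65(grid)
    observer = observer if observer is not None else cie_1931_observer(grid)
    if not (np.array_equal(illuminant.grid.values, grid.values)
            and np.array_equal(observer.grid.values, grid.values)):
        raise GridError("illuminant/observer grids do not match spectrum grid")
    if not grid.covers(*INTEGRATION_RANGE):
        raise GridError("grid must cover the 400-700 nm integration range")

    mask = integration_mask(grid)
    lam = grid.values[mask]
    S = illuminant.power[mask]
    cmf = np.stack([observer.xbar[mask], observer.ybar[mask],
                    observer.zbar[mask]], axis=-1)  # (B, 3)
    denom = np.trapezoid(S * cmf[:, 1], lam)
    if denom <= 0:
        raise ValueError("normalisation undefined: integral of S*ybar is zero")
    k = 100.0 / denom
    R = np.asarray(reflectance, dtype=float)[..., mask]
    integrand = R[..., :, None] * (S[:, None] * cmf)
    return k * np.trapezoid(integrand, lam, axis=-2)


def spectrum_to_xyz(spectrum: ReflectanceSpectrum,
                    illuminant: Illuminant | None = None,
                    observer: Observer | None = None) -> XYZColor:
    xyz = xyz_from_reflectance(spectrum.reflectance, spectrum.grid,
                               illuminant, observer)
    return XYZColor(*xyz)


# --------------------------------------------------------------------------
# sRGB (IEC 61966-2-1)

_SRGB_TO_XYZ = np.array([
    [0.4124564, 0.3575761, 0.1804375],
    [0.2126729, 0.7151522, 0.0721750],
    [0.0193339, 0.1191920, 0.9503041],
])
_XYZ_TO_SRGB = np.array([
    [3.2404542, -1.5371385, -0.4985314],
    [-0.9692660, 1.8760108, 0.0415560],
    [0.0556434, -0.2040259, 1.0572252],
])

#: D65 reference white on the 0-100 scale (sRGB standard).
D65_WHITE = XYZColor(95.047, 100.0, 108.883)


def srgb_decode(rgb: np.ndarray) -> np.ndarray:
    """Encoded sRGB -> linear RGB (piecewise standard transfer function)."""
    rgb = np.asarray(rgb, dtype=float)
    return np.where(rgb <= 0.04045, rgb / 12.92,
                    ((rgb + 0.055) / 1.055) ** 2.4)


def srgb_encode(linear: np.ndarray) -> np.ndarray:
    linear = np.asarray(linear, dtype=float)
    return np.where(linear <= 0.0031308, 12.92 * linear,
                    1.055 * np.clip(linear, 0, None) ** (1 / 2.4) - 0.055)


def srgb_to_xyz(rgb) -> np.ndarray:
    """Encoded sRGB in [0,1] (..., 3) -> XYZ on the 0-100 scale."""
    rgb = np.asarray(rgb, dtype=float)
    if np.any(rgb < -1e-9) or np.any(rgb > 1 + 1e-9):
        raise ValueError("sRGB components must lie in [0, 1]")
    linear = srgb_decode(np.clip(rgb, 0.0, 1.0))
    return 100.0 * linear @ _SRGB_TO_XYZ.T


def xyz_to_srgb(xyz) -> np.ndarray:
    """XYZ (0-100 scale) -> encoded sRGB, clipped to [0, 1]."""
    linear = np.asarray(xyz, dtype=float) / 100.0 @ _XYZ_TO_SRGB.T
    return np.clip(srgb_encode(linear), 0.0, 1.0)


# --------------------------------------------------------------------------
# CIELAB / CIEDE2000

def xyz_to_lab(xyz, white: XYZColor = D65_WHITE) -> np.ndarray:
    wn = white.as_array()
    if np.any(wn <= 0):
        raise ValueError("reference white must be strictly positive")
    t = np.asarray(xyz, dtype=float) / wn
    delta = 6.0 / 29.0
    f = np.where(t > delta ** 3, np.cbrt(t), t / (3 * delta ** 2) + 4.0 / 29.0)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


def ciede2000(a, b, white: XYZColor = D65_WHITE) -> np.ndarray | float:
    """CIEDE2000 colour difference between XYZ colours (kL = kC = kH = 1).

    Accepts XYZColor instances or arrays of shape (..., 3); vectorises over
    leading axes and returns a scalar for single colours.
    """
    a_arr = a.as_array() if isinstance(a, XYZColor) else np.asarray(a, float)
    b_arr = b.as_array() if isinstance(b, XYZColor) else np.asarray(b, float)
    lab_a = xyz_to_lab(a_arr, white)
    lab_b = xyz_to_lab(b_arr, white)
    de = deltaE_ciede2000(lab_a, lab_b, channel_axis=-1)
    return float(de) if np.ndim(de) == 0 else de
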