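"""Self-contained data generation: the packaged 24-patch chart, a simulated
RGB camera, and a synthetic endoscopic vascular phantom.

The packaged chart (``colorchecker_synthetic.csv``) is a synthetic parametric
stand-in for a measured ColorChecker: 24 smooth reflectance spectra with the
classic chart's patch names, six neutral (gray-series) patches and realistic
reflectance levels. The camera is a generic consumer-style sensor with smooth
Gaussian spectral sensitivities. The phantom places haemoglobin-like vessel
curves (absorption dips near 415 and 540 nm) on a mucosa-like background and
is the test-bed for narrow-band contrast enhancement.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .colorimetry import (
    MASTER_GRID,
    Illuminant,
    Observer,
    ReflectanceSpectrum,
    SpectralCube,
    WavelengthGrid,
    XYZColor,
    cie_1931_observer,
    d65,
    resample,
    srgb_encode,
    xyz_from_reflectance,
)

__all__ = [
    "PatchMeasurementSet",
    "CameraModel",
    "PhantomSpec",
    "load_colorchecker",
    "default_camera",
    "simulate_camera",
    "generate_phantom",
    "NEUTRAL_PATCHES",
]

NEUTRAL_PATCHES = ("white", "neutral_8", "neutral_6_5", "neutral_5",
                   "neutral_3_5", "black")


@dataclass
class PatchMeasurementSet:
    """The 24 calibration patches: reference spectra, reference XYZ, and
    (optionally) camera RGB of the same patches."""

    patch_ids: list[str]
    spectra: np.ndarray            # (24, B) reflectance on `grid`
    grid: WavelengthGrid
    reference_xyz: np.ndarray      # (24, 3), 0-100 scale
    camera_rgb: np.ndarray | None = None   # (24, 3) encoded sRGB-ish

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.reference_xyz = np.asarray(self.reference_xyz, dtype=float)
        if len(self.patch_ids) != self.spectra.shape[0]:
            raise ValueError("patch_ids / spectra length mismatch")
        if self.spectra.shape[1] != len(self.grid):
            raise ValueError("spectra do not match grid")

    @property
    def n_patches(self) -> int:
        return len(self.patch_ids)

    def with_camera_rgb(self, rgb: np.ndarray) -> "PatchMeasurementSet":
        rgb = np.asarray(rgb, dtype=float)
        if rgb.shape != (self.n_patches, 3):
            raise ValueError("camera_rgb must be (n_patches, 3)")
        return PatchMeasurementSet(self.patch_ids, self.spectra, self.grid,
                                   self.reference_xyz, rgb)


@dataclass
class CameraModel:
    """Simulated RGB camera: three spectral response curves plus optional
    sRGB gamma encoding, additive noise and a per-channel dark offset."""

    grid: WavelengthGrid
    sensitivities: np.ndarray       # (3, B), non-negative
    gamma_encoding: bool = True
    noise_sd: float = 0.0
    dark_offset: np.ndarray = field(
        default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.sensitivities = np.asarray(self.sensitivities, dtype=float)
        if self.sensitivities.shape != (3, len(self.grid)):
            raise ValueError("sensitivities must be (3, n_wavelengths)")
        if np.any(self.sensitivities < 0):
            raise ValueError("sensitivities must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self.dark_offset = np.asarray(self.dark_offset, dtype=float)


@dataclass
class PhantomSpec:
    """Synthetic endoscopy frame: sinuous vessel curves of a haemoglobin-like
    absorber over a mucosa-like background."""

    image_size: tuple[int, int] = (64, 64)
    vessel_count: int = 4
    vessel_width_px: int = 3
    absorption_strength: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if self.vessel_width_px >= min(h, w):
            raise ValueError("vessel width must be smaller than the image")
        if not 0 < self.absorption_strength <= 1:
            raise ValueError("absorption_strength must lie in (0, 1]")


def load_colorchecker(grid: WavelengthGrid = MASTER_GRID,
                      illuminant: Illuminant | None = None,
                      observer: Observer | None = None) -> PatchMeasurementSet:
    """Load the packaged synthetic 24-patch chart on ``grid``; reference XYZ
    is derived from the spectra by tristimulus integration (camera_rgb empty).
    """
    text = resources.files("save_hsi.data").joinpath(
        "colorchecker_synthetic.csv").read_text()
    ids: list[str] = []
    rows: dict[str, list[tuple[float, float]]] = {}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        name, wl, val = line.split(",")
        if name not in rows:
            ids.append(name)
            rows[name] = []
        rows[name].append((float(wl), float(val)))
    src_wl = np.array([wl for wl, _ in rows[ids[0]]])
    src = WavelengthGrid(src_wl[0], src_wl[-1], src_wl[1] - src_wl[0])
    spectra = np.stack([
        resample(np.array([v for _, v in rows[name]]), src, grid)
        for name in ids
    ])
    xyz = xyz_from_reflectance(spectra, grid, illuminant, observer)
    return PatchMeasurementSet(ids, spectra, grid, xyz)


def default_camera(grid: WavelengthGrid = MASTER_GRID,
                   noise_sd: float = 0.0) -> CameraModel:
    """Generic consumer-style sensor: Gaussian channel sensitivities peaking
    at 600 (R), 550 (G) and 450 nm (B)."""
    lam = grid.values
    def g(c, s):
        return np.exp(-(((lam - c) / s) ** 2))
    sens = np.stack([g(600.0, 50.0), g(550.0, 45.0), g(450.0, 35.0)])
    return CameraModel(grid, sens, gamma_encoding=True, noise_sd=noise_sd)


def simulate_camera(reflectance: np.ndarray | PatchMeasurementSet | SpectralCube,
                    camera: CameraModel | None = None,
                    illuminant: Illuminant | None = None,
                    seed: int | None = None) -> np.ndarray:
    """Render camera RGB from reflectance data.

    channel = integral(S * R * sensitivity) normalised so a perfect reflector
    maps to (1, 1, 1) before gamma; optional sRGB encoding, seeded noise and
    dark offset. Accepts a (..., B) array, a PatchMeasurementSet or a
    SpectralCube; returns (..., 3) RGB in [0, 1].
    """
    if isinstance(reflectance, PatchMeasurementSet):
        grid, R = reflectance.grid, reflectance.spectra
    elif isinstance(reflectance, SpectralCube):
        grid, R = reflectance.grid, reflectance.data
    else:
        R = np.asarray(reflectance, dtype=float)
        grid = MASTER_GRID
        if R.shape[-1] != len(grid):
            raise ValueError("reflectance does not match the master grid; "
                             "pass a SpectralCube for other grids")
    camera = camera if camera is not None else default_camera(grid)
    illuminant = illuminant if illuminant is not None else d65(grid)
    if not np.array_equal(camera.grid.values, grid.values):
        raise ValueError("camera grid does not match data grid")
    lam = grid.values
    S = illuminant.power
    num = np.trapezoid(R[..., None, :] * (S * camera.sensitivities), lam,
                       axis=-1)
    denom = np.trapezoid(S * camera.sensitivities, lam, axis=-1)
    linear = num / denom
    if camera.noise_sd > 0:
        rng = np.random.default_rng(seed)
        linear = linear + rng.normal(0.0, camera.noise_sd, linear.shape)
    linear = np.clip(linear + camera.dark_offset, 0.0, None)
    rgb = srgb_encode(linear) if camera.gamma_encoding else linear
    return np.clip(rgb, 0.0, 1.0)


def _absorber_gain(grid: WavelengthGrid, strength: float) -> np.ndarray:
    """Transmission-like dip profile with minima near 415 and 540 nm."""
    lam = grid.values
    def lor(c, g):
        return (g ** 2) / ((lam - c) ** 2 + g ** 2)
    dip = 1.0 * lor(415.0, 25.0) + 0.75 * lor(540.0, 30.0)
    dip = dip / dip.max()
    return 1.0 - strength * dip


def generate_phantom(spec: PhantomSpec,
                     grid: WavelengthGrid = MASTER_GRID,
                     camera: CameraModel | None = None,
                     illuminant: Illuminant | None = None,
                     ) -> tuple[SpectralCube, np.ndarray, np.ndarray]:
    """Build the vascular phantom.

    Returns (ground-truth cube, white-light RGB rendering, vessel mask).
    Background: mucosa-like warm spectrum; vessels: background multiplied by
    a haemoglobin-like dip profile, so vessel reflectance is strictly below
    the background at 415 and 540 nm.
    """
    h, w = spec.image_size
    lam = grid.values
    # mucosa: bright, mildly red-tilted
    background = 0.45 + 0.25 / (1.0 + np.exp(-(lam - 590.0) / 40.0))
    vessel = background * _absorber_gain(grid, spec.absorption_strength)

    rng = np.random.default_rng(spec.seed)
    mask = np.zeros((h, w), dtype=bool)
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    for _ in range(spec.vessel_count):
        r0 = rng.uniform(0.15 * h, 0.85 * h)
        amp = rng.uniform(0.05 * h, 0.15 * h)
        freq = rng.uniform(0.5, 1.5) * 2 * np.pi / w
        phase = rng.uniform(0, 2 * np.pi)
        centre = r0 + amp * np.sin(freq * cols + phase)
        mask |= np.abs(rows - centre) <= spec.vessel_width_px / 2.0

    data = np.where(mask[..., None], vessel, background)
    cube = SpectralCube(grid, np.broadcast_to(data, (h, w, len(grid))).copy())
    wli = simulate_camera(cube, camera, illuminant, seed=spec.seed)
    return cube, wli, mask
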