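"""Image and spectral-cube I/O plus run configuration.

Cubes are stored ENVI-style: a plain-text ``.hdr`` with grid metadata next
to a flat band-sequential (BSQ) float32 raster, losslessly round-tripping
the stored dtype. A single-file ``.npz`` alternative is also provided.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .colorimetry import SpectralCube, WavelengthGrid

__all__ = [
    "FormatError",
    "read_image",
    "write_image",
    "write_cube",
    "read_cube",
    "RunConfig",
]


class FormatError(ValueError):
    """Unreadable or structurally invalid file."""


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF image as H x W x 3 floats in [0, 1] (bit depth
    normalised, orientation preserved)."""
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:   # noqa: BLE001 - re-raise with path context
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"{path}: expected 3 channels, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    return np.clip(arr.astype(float), 0.0, 1.0)


def write_image(image: np.ndarray, path, bit_depth: int = 8) -> None:
    """Write an RGB float image in [0, 1]: 8-bit via PNG/TIFF, 16-bit via
    TIFF (16-bit RGB PNG is not portably supported)."""
    path = Path(path)
    image = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    if bit_depth == 8:
        iio.imwrite(path, np.round(image * 255).astype(np.uint8))
    elif bit_depth == 16:
        import tifffile
        if path.suffix.lower() not in (".tif", ".tiff"):
            raise ValueError("16-bit output requires a .tif/.tiff path")
        tifffile.imwrite(path, np.round(image * 65535).astype(np.uint16))
    else:
        raise ValueError("bit_depth must be 8 or 16")


def write_cube(cube: SpectralCube, path_base) -> tuple[Path, Path]:
    """Write an ENVI-style header/raster pair (``.hdr`` + ``.raw``, BSQ,
    float32 little-endian). Returns the two paths."""
    base = Path(path_base)
    hdr_path = base.with_suffix(".hdr")
    raw_path = base.with_suffix(".raw")
    h, w, b = cube.data.shape
    lam = cube.grid.values
    hdr = "\n".join([
        "ENVI",
        "description = {save_hsi reflectance cube}",
        f"samples = {w}",
        f"lines = {h}",
        f"bands = {b}",
        "header offset = 0",
        "file type = ENVI Standard",
        "data type = 4",
        "interleave = bsq",
        "byte order = 0",
        "wavelength units = Nanometers",
        "wavelength = {" + ", ".join(f"{v:.1f}" for v in lam) + "}",
        "",
    ])
    hdr_path.write_text(hdr)
    np.ascontiguousarray(
        cube.data.transpose(2, 0, 1).astype("<f4")).tofile(raw_path)
    return hdr_path, raw_path


def _parse_hdr(text: str) -> dict:
    fields: dict[str, str] = {}
    key = None
    buffer = ""
    for line in text.splitlines():
        if "=" in line and not buffer:
            key, _, val = line.partition("=")
            key = key.strip().lower()
            val = val.strip()
            if val.startswith("{") and not val.endswith("}"):
                buffer = val
            else:
                fields[key] = val.strip("{}").strip()
        elif buffer:
            buffer += " " + line.strip()
            if line.strip().endswith("}"):
                fields[key] = buffer.strip("{}").strip()
                buffer = ""
    return fields


def read_cube(path_base) -> SpectralCube:
    base = Path(path_base)
    hdr_path = base.with_suffix(".hdr")
    raw_path = base.with_suffix(".raw")
    if not hdr_path.exists() or not raw_path.exists():
        raise FormatError(f"missing cube files for {base}")
    fields = _parse_hdr(hdr_path.read_text())
    try:
        h = int(fields["lines"])
        w = int(fields["samples"])
        b = int(fields["bands"])
        lam = np.array([float(tok) for tok in fields["wavelength"].split(",")])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"malformed header {hdr_path}: {exc}") from exc
    if len(lam) != b or np.any(np.diff(lam) <= 0):
        raise FormatError(f"{hdr_path}: wavelength list does not match bands")
    raw = np.fromfile(raw_path, dtype="<f4")
    if raw.size != h * w * b:
        raise FormatError(f"{raw_path}: truncated raster "
                          f"({raw.size} values, expected {h * w * b})")
    data = raw.reshape(b, h, w).transpose(1, 2, 0).astype(float)
    grid = WavelengthGrid(lam[0], lam[-1], lam[1] - lam[0])
    return SpectralCube(grid, data)


# --------------------------------------------------------------------------

_KNOWN_KEYS = {
    "grid_start_nm", "grid_stop_nm", "grid_step_nm", "illuminant", "observer",
    "expansion_order", "n_components", "dark_current", "feature_source",
    "bands", "schedule", "seed", "log_level", "input", "output",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    grid_start_nm: float = 380.0
    grid_stop_nm: float = 780.0
    grid_step_nm: float = 5.0
    illuminant: str = "D65"
    observer: str = "CIE1931_2deg"
    expansion_order: int = 3
    n_components: int = 6
    dark_current: float = 0.0
    feature_source: str = "xyz"
    seed: int = 0
    log_level: str = "INFO"
    input: str | None = None
    output: str | None = None
    bands: dict = field(default_factory=dict)
    schedule: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(doc) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        if cfg.illuminant != "D65":
            raise ValueError("only the D65 illuminant is packaged")
        if not 1 <= cfg.expansion_order <= 3:
            raise ValueError("expansion_order must be 1..3")
        return cfg

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]
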