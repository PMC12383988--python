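"""ColorChecker-based spectral calibration and per-pixel reflectance
reconstruction.

The pipeline fitted here turns a camera's encoded RGB into a reflectance
spectrum per pixel in four stages:

1. camera RGB -> camera XYZ (standard sRGB decoding + matrix);
2. polynomial *correction*: C maps third-order monomial features of camera
   XYZ onto the reference XYZ measured from the patch spectra,
   C = XYZ_ref @ pinv(V);
3. a mean-centred PCA of the 24 patch reflectance spectra gives a compact
   spectral basis (six components suffice for ColorChecker-like data);
4. polynomial *transformation*: M maps features of the corrected XYZ onto
   the patch PCA scores, M = Score @ pinv(V_color); a pixel's spectrum is
   then mean + basis.T @ (M @ V(xyz)).

`SpectralCalibration` is the model object (built from a PatchMeasurementSet),
`.fit()` returns a `CalibrationResult` carrying the fitted matrices,
per-patch diagnostics and a `summary()` table. Module-level functions expose
each stage for direct use.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .colorimetry import (
    MASTER_GRID,
    Illuminant,
    Observer,
    ReflectanceSpectrum,
    SpectralCube,
    WavelengthGrid,
    XYZColor,
    ciede2000,
    srgb_to_xyz,
    xyz_from_reflectance,
)
from .fixtures import PatchMeasurementSet

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureExpansionSpec",
    "CorrectionMatrix",
    "SpectralBasis",
    "TransformMatrix",
    "CalibrationModel",
    "SpectralCalibration",
    "CalibrationResult",
    "expand_features",
    "fit_correction",
    "apply_correction",
    "fit_spectral_basis",
    "fit_transform_matrix",
    "reconstruct_spectrum",
    "reconstruct_cube",
]

#: relative singular-value cutoff for all pseudo-inverse fits
PINV_RCOND = 1e-10

#: XYZ is divided by this before monomial expansion (conditioning only;
#: fit and apply share it, so fitted predictions are unchanged).
XYZ_FEATURE_SCALE = 100.0


class ExpansionSpecError(ValueError):
    """Invalid polynomial feature-expansion specification."""


def _cubic_terms(order: int) -> list[tuple[int, int, int]]:
    terms = [
        (i, j, k)
        for total in range(order + 1)
        for i in range(total, -1, -1)
        for j in range(total - i, -1, -1)
        for k in [total - i - j]
    ]
    return terms


@dataclass(frozen=True)
class FeatureExpansionSpec:
    """Trivariate monomial expansion of a colour triple.

    The default full cubic has 20 terms: 1 constant (the dark term), 3
    linear (the colour terms) and 16 higher-order (the non-linear terms).
    Order above 3 is rejected — higher orders over-correct a 24-patch fit.
    """

    order: int = 3
    term_list: tuple[tuple[int, int, int], ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 1 <= self.order <= 3:
            raise ExpansionSpecError("polynomial order must be 1..3")
        terms = self.term_list
        if terms is None:
            terms = tuple(_cubic_terms(self.order))
        else:
            terms = tuple(tuple(t) for t in terms)
            if len(set(terms)) != len(terms):
                raise ExpansionSpecError("duplicate terms in term_list")
            if (0, 0, 0) not in terms:
                raise ExpansionSpecError("constant (dark) term is required")
            if any(sum(t) > self.order for t in terms):
                raise ExpansionSpecError("term exceeds declared order")
        object.__setattr__(self, "term_list", terms)

    @property
    def n_terms(self) -> int:
        return len(self.term_list)

    @property
    def includes_constant(self) -> bool:
        return (0, 0, 0) in self.term_list


def expand_features(triple: np.ndarray,
                    spec: FeatureExpansionSpec | None = None) -> np.ndarray:
    """Monomial feature vector(s) of a colour triple, shape (..., n_terms)."""
    spec = spec if spec is not None else FeatureExpansionSpec()
    v = np.asarray(triple, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("colour triple must be finite")
    exps = np.asarray(spec.term_list)            # (T, 3)
    # v[..., None, :] ** exps -> (..., T, 3); product over the last axis
    return np.prod(v[..., None, :] ** exps, axis=-1)


@dataclass
class CorrectionMatrix:
    """C of the variable-matrix correction: expanded features -> XYZ."""

    C: np.ndarray
    expansion: FeatureExpansionSpec

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if self.C.shape != (3, self.expansion.n_terms):
            raise ValueError("C must be 3 x n_terms")


@dataclass
class SpectralBasis:
    """Mean-centred PCA basis of the patch reflectance spectra."""

    grid: WavelengthGrid
    mean_spectrum: np.ndarray              # (B,)
    components: np.ndarray                 # (n_components, B), orthonormal
    explained_variance_ratio: np.ndarray   # (n_components,)
    scores: np.ndarray                     # (n_patches, n_components)

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def cumulative_variance(self) -> float:
        return float(np.sum(self.explained_variance_ratio))


@dataclass
class TransformMatrix:
    """M: expanded (corrected-XYZ) features -> PCA scores."""

    M: np.ndarray
    expansion: FeatureExpansionSpec

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.M.shape[1] != self.expansion.n_terms:
            raise ValueError("M column count must equal n_terms")


@dataclass
class CalibrationModel:
    """Fitted calibration state (serialisable)."""

    correction: CorrectionMatrix
    basis: SpectralBasis
    transform: TransformMatrix
    grid: WavelengthGrid
    dark_current: np.ndarray = field(default_factory=lambda: np.zeros(3))
    feature_source: str = "xyz"

    def to_json(self) -> str:
        doc = {
            "grid": [self.grid.start_nm, self.grid.stop_nm, self.grid.step_nm],
            "dark_current": self.dark_current.tolist(),
            "feature_source": self.feature_source,
            "correction": {
                "C": self.correction.C.tolist(),
                "order": self.correction.expansion.order,
                "terms": [list(t) for t in self.correction.expansion.term_list],
            },
            "transform": {
                "M": self.transform.M.tolist(),
                "order": self.transform.expansion.order,
                "terms": [list(t) for t in self.transform.expansion.term_list],
            },
            "basis": {
                "mean": self.basis.mean_spectrum.tolist(),
                "components": self.basis.components.tolist(),
                "explained_variance_ratio":
                    self.basis.explained_variance_ratio.tolist(),
                "scores": self.basis.scores.tolist(),
            },
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        doc = json.loads(text)
        grid = WavelengthGrid(*doc["grid"])
        corr_spec = FeatureExpansionSpec(
            doc["correction"]["order"],
            tuple(tuple(t) for t in doc["correction"]["terms"]))
        trans_spec = FeatureExpansionSpec(
            doc["transform"]["order"],
            tuple(tuple(t) for t in doc["transform"]["terms"]))
        basis = SpectralBasis(
            grid,
            np.asarray(doc["basis"]["mean"]),
            np.asarray(doc["basis"]["components"]),
            np.asarray(doc["basis"]["explained_variance_ratio"]),
            np.asarray(doc["basis"]["scores"]),
        )
        return cls(
            CorrectionMatrix(np.asarray(doc["correction"]["C"]), corr_spec),
            basis,
            TransformMatrix(np.asarray(doc["transform"]["M"]), trans_spec),
            grid,
            np.asarray(doc["dark_current"]),
            doc["feature_source"],
        )


# --------------------------------------------------------------------------
# stage fits

def _features_from_xyz(xyz: np.ndarray,
                       spec: FeatureExpansionSpec) -> np.ndarray:
    return expand_features(np.asarray(xyz, float) / XYZ_FEATURE_SCALE, spec)


def fit_correction(patches: PatchMeasurementSet,
                   spec: FeatureExpansionSpec | None = None,
                   feature_source: str = "xyz",
                   dark_current: np.ndarray | None = None) -> CorrectionMatrix:
    """Fit C = XYZ_ref @ pinv(V) on the patch set.

    V holds the expanded features of the camera-derived XYZ (default) or of
    the raw camera RGB (``feature_source="rgb"``).
    """
    spec = spec if spec is not None else FeatureExpansionSpec()
    if patches.camera_rgb is None:
        raise ValueError("patch set carries no camera RGB; nothing to correct")
    if patches.n_patches < 24:
        warnings.warn(f"only {patches.n_patches} patches; the fit may be "
                      "poorly constrained", stacklevel=2)
    rgb = patches.camera_rgb
    if dark_current is not None:
        rgb = np.clip(rgb - np.asarray(dark_current, float), 0.0, 1.0)
    if feature_source == "xyz":
        V = _features_from_xyz(srgb_to_xyz(rgb), spec)
    elif feature_source == "rgb":
        V = expand_features(rgb, spec)
    else:
        raise ValueError("feature_source must be 'xyz' or 'rgb'")
    if np.linalg.matrix_rank(V) < min(V.shape):
        warnings.warn("rank-deficient feature matrix; pseudo-inverse fit "
                      "will use the minimum-norm solution", stacklevel=2)
    C = patches.reference_xyz.T @ np.linalg.pinv(V.T, rcond=PINV_RCOND)
    return CorrectionMatrix(C, spec)


def apply_correction(correction: CorrectionMatrix, xyz: np.ndarray,
                     feature_source: str = "xyz") -> np.ndarray:
    """XYZ_correct = C @ V; vectorised over leading axes.

    ``xyz`` is camera XYZ (0-100) for the default feature source, or raw
    RGB in [0, 1] when the correction was fitted with feature_source='rgb'.
    """
    if feature_source == "xyz":
        V = _features_from_xyz(xyz, correction.expansion)
    else:
        V = expand_features(xyz, correction.expansion)
    return V @ correction.C.T


def fit_spectral_basis(patches: PatchMeasurementSet,
                       n_components: int = 6,
                       wavelength_range: tuple[float, float] | None = None,
                       ) -> SpectralBasis:
    """Mean-centred PCA (via SVD) of the patch reflectance spectra.

    Component signs are fixed so each component's largest-magnitude
    coefficient is positive. ``wavelength_range`` restricts the fit (and the
    basis) to a sub-range of the patch grid.
    """
    grid = patches.grid
    spectra = patches.spectra
    if wavelength_range is not None:
        lam = grid.values
        mask = (lam >= wavelength_range[0] - 1e-9) \
            & (lam <= wavelength_range[1] + 1e-9)
        sub = lam[mask]
        grid = WavelengthGrid(sub[0], sub[-1], grid.step_nm)
        spectra = spectra[:, mask]
    limit = min(patches.n_patches - 1, spectra.shape[1])
    if not 1 <= n_components <= limit:
        raise ValueError(f"n_components must be in [1, {limit}]")
    if np.allclose(spectra.std(axis=0), 0.0):
        # identical spectra: zero-variance degenerate case
        mean = spectra.mean(axis=0)
        comps = np.zeros((n_components, spectra.shape[1]))
        comps[:, :n_components] = np.eye(n_components)
        return SpectralBasis(grid, mean, comps, np.zeros(n_components),
                             np.zeros((patches.n_patches, n_components)))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(spectra)
    comps = pca.components_.copy()
    flip = np.sign(comps[np.arange(len(comps)),
                         np.abs(comps).argmax(axis=1)])
    comps *= flip[:, None]
    scores = scores * flip[None, :]
    return SpectralBasis(grid, pca.mean_, comps,
                         pca.explained_variance_ratio_.copy(), scores)


def fit_transform_matrix(basis: SpectralBasis,
                         corrected_xyz: np.ndarray,
                         spec: FeatureExpansionSpec | None = None,
                         ) -> TransformMatrix:
    """Fit M = Score @ pinv(V_color) on the training patches."""
    spec = spec if spec is not None else FeatureExpansionSpec()
    corrected_xyz = np.asarray(corrected_xyz, dtype=float)
    if corrected_xyz.shape[0] != basis.scores.shape[0]:
        raise ValueError("corrected XYZ count does not match basis scores")
    V = _features_from_xyz(corrected_xyz, spec)
    M = basis.scores.T @ np.linalg.pinv(V.T, rcond=PINV_RCOND)
    return TransformMatrix(M, spec)


# --------------------------------------------------------------------------
# reconstruction

def _reconstruct_from_xyz(model: CalibrationModel,
                          xyz: np.ndarray) -> tuple[np.ndarray, float]:
    V = _features_from_xyz(xyz, model.transform.expansion)
    scores = V @ model.transform.M.T
    raw = model.basis.mean_spectrum + scores @ model.basis.components
    clipped = float(np.mean((raw < 0) | (raw > 1)))
    return np.clip(raw, 0.0, 1.0), clipped


def reconstruct_spectrum(model: CalibrationModel,
                         xyz: XYZColor | np.ndarray) -> ReflectanceSpectrum:
    """Reconstruct a reflectance spectrum from a corrected XYZ colour."""
    arr = xyz.as_array() if isinstance(xyz, XYZColor) else np.asarray(xyz)
    values, clipped = _reconstruct_from_xyz(model, arr)
    if clipped:
        logger.info("reconstruct_spectrum: %.1f%% of samples clipped",
                    100 * clipped)
    return ReflectanceSpectrum(model.grid, values)


def reconstruct_cube(model: CalibrationModel, image: np.ndarray) -> SpectralCube:
    """Per-pixel reconstruction of an H x W x 3 RGB image (values in [0,1]).

    Applies dark-current subtraction, sRGB decoding, the fitted correction
    and the spectral transform; returns an H x W x B cube with the clipped
    fraction recorded.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be H x W x 3")
    rgb = np.clip(image - model.dark_current, 0.0, 1.0)
    if model.feature_source == "xyz":
        raw = srgb_to_xyz(rgb)
    else:
        raw = rgb
    corrected = apply_correction(model.correction, raw,
                                 model.feature_source)
    values, clipped = _reconstruct_from_xyz(model, corrected)
    if clipped:
        logger.info("reconstruct_cube: %.2f%% of samples clipped",
                    100 * clipped)
    return SpectralCube(model.grid, values, clipped_fraction=clipped)


# --------------------------------------------------------------------------
# Model / Results

class SpectralCalibration:
    """Calibration model over a 24-patch measurement set.

    Parameters
    ----------
    patches
        Patch set with reference spectra, reference XYZ and camera RGB.
    expansion
        Polynomial feature expansion (default: full cubic, 20 terms).
    n_components
        PCA components retained (default 6).
    dark_current
        Per-channel offset subtracted from camera RGB before decoding.
    feature_source
        'xyz' (default): correction features from camera-derived XYZ;
        'rgb': features from raw camera RGB.
    """

    def __init__(self, patches: PatchMeasurementSet,
                 expansion: FeatureExpansionSpec | None = None,
                 n_components: int = 6,
                 dark_current=0.0,
                 feature_source: str = "xyz",
                 illuminant: Illuminant | None = None,
                 observer: Observer | None = None) -> None:
        if patches.camera_rgb is None:
            raise ValueError("patches must include camera RGB "
                             "(see fixtures.simulate_camera)")
        self.patches = patches
        self.expansion = expansion if expansion is not None \
            else FeatureExpansionSpec()
        self.n_components = n_components
        self.dark_current = np.broadcast_to(
            np.asarray(dark_current, float), (3,)).copy()
        self.feature_source = feature_source
        self.illuminant = illuminant
        self.observer = observer

    @classmethod
    def from_arrays(cls, patch_ids, spectra, grid, camera_rgb,
                    **kwargs) -> "SpectralCalibration":
        xyz = xyz_from_reflectance(np.asarray(spectra, float), grid,
                                   kwargs.get("illuminant"),
                                   kwargs.get("observer"))
        patches = PatchMeasurementSet(list(patch_ids), spectra, grid, xyz,
                                      np.asarray(camera_rgb, float))
        return cls(patches, **kwargs)

    def fit(self) -> "CalibrationResult":
        patches = self.patches
        rgb = np.clip(patches.camera_rgb - self.dark_current, 0.0, 1.0)
        if self.feature_source == "xyz":
            raw = srgb_to_xyz(rgb)
        else:
            raw = rgb
        correction = fit_correction(patches, self.expansion,
                                    self.feature_source, self.dark_current)
        corrected = apply_correction(correction, raw, self.feature_source)
        basis = fit_spectral_basis(patches, self.n_components)
        transform = fit_transform_matrix(basis, corrected, self.expansion)
        model = CalibrationModel(correction, basis, transform, patches.grid,
                                 self.dark_current, self.feature_source)
        return CalibrationResult(self, model, raw, corrected)


class CalibrationResult:
    """Fitted calibration with training diagnostics.

    Attributes
    ----------
    model : CalibrationModel
        Serialisable fitted state.
    per_patch_rmse : ndarray
        Spectral RMSE of each reconstructed training patch.
    delta_e_raw, delta_e_corrected, delta_e_reconstructed : ndarray
        Per-patch CIEDE2000 before correction, after correction, and of the
        reconstructed spectra re-integrated to XYZ.
    """

    def __init__(self, model_spec: SpectralCalibration,
                 model: CalibrationModel,
                 raw_xyz: np.ndarray,
                 corrected_xyz: np.ndarray) -> None:
        self.spec = model_spec
        self.model = model
        patches = model_spec.patches
        ref = patches.reference_xyz
        self.raw_xyz = raw_xyz
        self.corrected_xyz = corrected_xyz
        if model_spec.feature_source == "xyz":
            self.delta_e_raw = np.atleast_1d(ciede2000(raw_xyz, ref))
        else:   # raw features are RGB; no pre-correction XYZ to compare
            self.delta_e_raw = np.full(patches.n_patches, np.nan)
        self.delta_e_corrected = np.atleast_1d(ciede2000(corrected_xyz, ref))

        recon, clipped = _reconstruct_from_xyz(model, corrected_xyz)
        self.reconstructed_spectra = recon
        self.clipped_fraction = clipped
        diff = recon - patches.spectra
        self.per_patch_rmse = np.sqrt(np.mean(diff ** 2, axis=1))
        recon_xyz = xyz_from_reflectance(recon, patches.grid,
                                         model_spec.illuminant,
                                         model_spec.observer)
        self.delta_e_reconstructed = np.atleast_1d(
            ciede2000(recon_xyz, ref))

    # -- aggregates ------------------------------------------------------
    @property
    def mean_rmse(self) -> float:
        return float(self.per_patch_rmse.mean())

    @property
    def mean_delta_e_corrected(self) -> float:
        return float(self.delta_e_corrected.mean())

    @property
    def mean_delta_e_reconstructed(self) -> float:
        return float(self.delta_e_reconstructed.mean())

    @property
    def explained_variance(self) -> float:
        return self.model.basis.cumulative_variance

    # -- reconstruction front-ends --------------------------------------
    def reconstruct_spectrum(self, xyz) -> ReflectanceSpectrum:
        return reconstruct_spectrum(self.model, xyz)

    def reconstruct_cube(self, image: np.ndarray) -> SpectralCube:
        return reconstruct_cube(self.model, image)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.model.to_json())

    def summary(self) -> str:
        p = self.spec.patches
        lines = [
            "Spectral calibration summary",
            "=" * 64,
            f"patches: {p.n_patches}   expansion terms: "
            f"{self.model.correction.expansion.n_terms} "
            f"(order {self.model.correction.expansion.order})",
            f"PCA components: {self.model.basis.n_components}   "
            f"cumulative explained variance: "
            f"{100 * self.explained_variance:.2f}%",
            f"mean dE00 raw -> corrected: "
            f"{np.nanmean(self.delta_e_raw):.3f} -> "
            f"{self.mean_delta_e_corrected:.3f}",
            f"mean spectral RMSE: {self.mean_rmse:.4f}   "
            f"mean dE00 (reconstruction): "
            f"{self.mean_delta_e_reconstructed:.3f}",
            f"clipped reflectance fraction: {self.clipped_fraction:.4f}",
            "-" * 64,
            f"{'patch':<16}{'RMSE':>10}{'dE00corr':>12}{'dE00recon':>12}",
        ]
        for i, name in enumerate(p.patch_ids):
            lines.append(f"{name:<16}{self.per_patch_rmse[i]:>10.4f}"
                         f"{self.delta_e_corrected[i]:>12.4f}"
                         f"{self.delta_e_reconstructed[i]:>12.4f}")
        return "\n".join(lines)
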