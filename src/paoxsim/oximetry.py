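"""Blood-oxygenation estimation from multispectral photoacoustic data.

Two inversion routes:

* Linear spectral unmixing (`LinearSpectralUnmixer`): per-pixel least
  squares against literature whole-blood HbO2/Hb endmember spectra via the
  matrix pseudo-inverse; sO2^EST = c_HbO2 / (c_HbO2 + c_Hb). Pixels with a
  negative oxy- or deoxy-coefficient are flagged invalid and excluded from
  region summaries.
* Learned spectral decoloring (`SpectralDecoloringRegressor`): a
  histogram-based gradient-boosted regression tree trained on simulated,
  fluence-corrupted, mean-normalized p0 spectra with known ground-truth
  sO2, which learns to compensate the spectral coloring that biases the
  linear estimate.

Both are scikit-learn estimators (get_params/set_params, fitted attributes
with trailing underscores) and compose with sklearn model selection. The
module-level functions are thin wrappers.

Also provides the Severinghaus oxyhemoglobin-dissociation conversion from
oxygen partial pressure to sO2.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import HistGradientBoostingRegressor
from sklearn.utils.validation import check_is_fitted

from .spectra import WavelengthGrid, hemoglobin_endmembers, nir_grid

__all__ = [
    "Endmembers",
    "UnmixResult",
    "TrainingSet",
    "LinearSpectralUnmixer",
    "SpectralDecoloringRegressor",
    "linear_unmix",
    "region_so2",
    "normalize_spectrum",
    "build_training_set",
    "train_decoloring",
    "predict_so2",
    "severinghaus",
]


@dataclass(frozen=True)
class Endmembers:
    """Whole-blood HbO2/Hb absorption spectra on a wavelength grid."""

    grid: WavelengthGrid
    matrix: np.ndarray      # (n_wavelengths, 2): columns HbO2, Hb

    def __post_init__(self):
        if self.matrix.shape != (len(self.grid), 2):
            raise ValueError("endmember matrix must be (n_wavelengths, 2)")
        if len(self.grid) < 2:
            raise ValueError("need at least two wavelengths")
        if np.linalg.matrix_rank(self.matrix) < 2:
            raise ValueError("endmember spectra are linearly dependent")

    @classmethod
    def literature(cls, grid: WavelengthGrid | None = None) -> "Endmembers":
        if grid is None:
            grid = nir_grid()
        hbo2, hb = hemoglobin_endmembers(grid)
        return cls(grid=grid, matrix=np.column_stack([hbo2, hb]))


@dataclass
class UnmixResult:
    """Per-pixel unmixing coefficients and the derived sO2 estimate."""

    c_hbo2: np.ndarray
    c_hb: np.ndarray
    valid: np.ndarray       # c_hbo2 >= 0 and c_hb >= 0

    @property
    def thb(self) -> np.ndarray:
        return self.c_hbo2 + self.c_hb

    @property
    def so2_est(self) -> np.ndarray:
        """sO2 estimate where valid, NaN elsewhere."""
        with np.errstate(divide="ignore", invalid="ignore"):
            est = self.c_hbo2 / self.thb
        return np.where(self.valid, est, np.nan)


class LinearSpectralUnmixer(BaseEstimator):
    """Least-squares spectral unmixing against HbO2/Hb endmembers.

    Parameters
    ----------
    wavelengths : array-like or None
        Wavelength grid of the input spectra (nm). None selects the
        standard 21-point 700-900 nm photoacoustic grid.

    Attributes (after fit)
    ----------------------
    endmembers_ : Endmembers
    pinv_ : (2, n_wavelengths) pseudo-inverse of the endmember matrix
    """

    def __init__(self, wavelengths=None):
        self.wavelengths = wavelengths

    def fit(self, X=None, y=None):
        grid = (nir_grid() if self.wavelengths is None
                else WavelengthGrid(np.asarray(self.wavelengths, float)))
        self.endmembers_ = Endmembers.literature(grid)
        self.pinv_ = np.linalg.pinv(self.endmembers_.matrix)
        self.n_features_in_ = len(grid)
        return self

    def _check_x(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[-1] != self.n_features_in_:
            raise ValueError(
                f"spectra have {X.shape[-1]} wavelengths, expected "
                f"{self.n_features_in_}"
            )
        return X

    def transform(self, X) -> np.ndarray:
        """Least-squares (c_HbO2, c_Hb) coefficients, shape (n, 2)."""
        check_is_fitted(self, "pinv_")
        return self._check_x(X) @ self.pinv_.T

    def unmix(self, X) -> UnmixResult:
        coef = self.transform(X)
        c_hbo2, c_hb = coef[..., 0], coef[..., 1]
        # relative epsilon: a pure endmember must not be invalidated by the
        # machine-noise sign of its ~zero counterpart coefficient
        tol = 1e-9 * np.abs(c_hbo2 + c_hb)
        return UnmixResult(c_hbo2=c_hbo2, c_hb=c_hb,
                           valid=(c_hbo2 >= -tol) & (c_hb >= -tol))

    def predict(self, X) -> np.ndarray:
        """Per-spectrum sO2 estimate (NaN where a coefficient is negative)."""
        return self.unmix(X).so2_est


def linear_unmix(spectra, endmembers: Endmembers | None = None,
                 wavelengths=None) -> UnmixResult:
    """Unmix per-pixel spectra (n_pixels, n_wavelengths) -> UnmixResult."""
    if endmembers is not None:
        est = LinearSpectralUnmixer(wavelengths=endmembers.grid.values)
        est.fit()
        est.endmembers_ = endmembers
        est.pinv_ = np.linalg.pinv(endmembers.matrix)
    else:
        est = LinearSpectralUnmixer(wavelengths=wavelengths).fit()
    return est.unmix(spectra)


def region_so2(result: UnmixResult, mask: np.ndarray | None = None) -> float:
    """Region sO2 estimate: median(c_HbO2) / median(THb) over valid pixels.

    Pixels with any negative unmixing coefficient are excluded first; an
    empty valid set raises ValueError (undefined result).
    """
    sel = result.valid if mask is None else (result.valid & np.asarray(mask, bool))
    if not np.any(sel):
        raise ValueError("no valid pixels in region after negative-coefficient exclusion")
    return float(np.median(result.c_hbo2[sel]) / np.median(result.thb[sel]))


def normalize_spectrum(spectra) -> np.ndarray:
    """Divide each spectrum by its mean across wavelengths.

    Removes the (unknown, positive) fluence scale so only spectral shape
    remains; any all-zero spectrum is rejected.
    """
    x = np.asarray(spectra, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    mean = x.mean(axis=-1, keepdims=True)
    if np.any(mean == 0):
        raise ValueError("cannot normalize an all-zero spectrum")
    out = x / mean
    return out[0] if single else out


@dataclass
class TrainingSet:
    """Normalized p0 spectra of blood-containing voxels with true sO2."""

    spectra: np.ndarray      # (n_samples, n_wavelengths), mean-normalized
    labels: np.ndarray       # (n_samples,) true sO2 in [0, 1]
    grid: WavelengthGrid
    seed: int
    n_volumes: int

    def __post_init__(self):
        if self.spectra.shape[0] != self.labels.shape[0]:
            raise ValueError("spectra/labels length mismatch")


def build_training_set(n_volumes: int, seed: int,
                       n_photons: int = 20000,
                       grid: WavelengthGrid | None = None,
                       max_voxels_per_volume: int = 2000) -> TrainingSet:
    """Simulate randomized tissue volumes and harvest training spectra.

    For each seeded training volume a multispectral p0 image is simulated
    (disc illumination covering the surface); the per-voxel spectra of
    vessel voxels are mean-normalized and paired with the true sO2 of
    their vessel. Background voxels are excluded even though they contain
    dilute blood — their fixed 70% label would dominate the corpus and
    collapse the regressor onto a constant. Voxels whose spectrum is
    entirely zero (never visited by a photon) are dropped.
    """
    from .monte_carlo import SourceGeometry, multispectral_p0
    from .scenes import sample_training_volume

    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    if grid is None:
        grid = nir_grid()
    rng = np.random.default_rng(seed)
    spectra_parts, label_parts = [], []
    for k in range(n_volumes):
        vol_seed = int(rng.integers(0, 2**31 - 1))
        scene = sample_training_volume(vol_seed, grid)
        side = scene.shape[0] * scene.spacing_mm
        source = SourceGeometry(kind="disc", radius_mm=side / 2)
        stack = multispectral_p0(scene, source, n_photons, vol_seed)
        vessel_ids = [j for j, name in enumerate(scene.region_names)
                      if name.startswith("vessel")]
        if not vessel_ids:
            continue
        vmask = np.isin(scene.labels, vessel_ids)
        spec = stack.region_spectra(vmask)
        lab = scene.truth_so2_map[vmask]
        nonzero = spec.sum(axis=1) > 0
        spec, lab = spec[nonzero], lab[nonzero]
        if spec.shape[0] > max_voxels_per_volume:
            pick = rng.choice(spec.shape[0], max_voxels_per_volume, replace=False)
            spec, lab = spec[pick], lab[pick]
        if spec.shape[0]:
            spectra_parts.append(normalize_spectrum(spec))
            label_parts.append(lab)
    return TrainingSet(
        spectra=np.concatenate(spectra_parts, axis=0),
        labels=np.concatenate(label_parts, axis=0),
        grid=grid, seed=seed, n_volumes=n_volumes,
    )


class SpectralDecoloringRegressor(BaseEstimator, RegressorMixin):
    """Learned spectral decoloring: boosted trees from spectra to sO2.

    Histogram-based gradient boosting with max_depth 16 and otherwise
    default hyperparameters. Input spectra are mean-normalized internally
    (the same scheme used to build training sets); predictions are clipped
    to [0, 1].
    """

    def __init__(self, max_depth: int = 16, random_state: int = 0,
                 normalization: str = "mean"):
        self.max_depth = max_depth
        self.random_state = random_state
        self.normalization = normalization

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.shape[0] < 1:
            raise ValueError("empty training set")
        if self.normalization != "mean":
            raise ValueError(f"unknown normalization scheme {self.normalization!r}")
        if np.ptp(y) == 0:
            import warnings

            warnings.warn("constant training labels; model will be constant")
        self.model_ = HistGradientBoostingRegressor(
            max_depth=self.max_depth, random_state=self.random_state
        )
        self.model_.fit(normalize_spectrum(X), y)
        self.n_features_in_ = X.shape[1]
        self.metadata_ = {
            "n_samples": int(X.shape[0]),
            "normalization": self.normalization,
            "hyperparameters": self.model_.get_params(),
        }
        return self

    def fit_training_set(self, ts: TrainingSet):
        """Fit from a TrainingSet (spectra already normalized; idempotent)."""
        self.fit(ts.spectra, ts.labels)
        self.metadata_.update(n_volumes=ts.n_volumes, seed=ts.seed,
                              wavelengths=ts.grid.values.tolist())
        self.grid_ = ts.grid
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        if single:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"spectra have {X.shape[1]} wavelengths; the model was "
                f"trained with {self.n_features_in_}"
            )
        out = np.clip(self.model_.predict(normalize_spectrum(X)), 0.0, 1.0)
        return out[0] if single else out


def train_decoloring(ts: TrainingSet, max_depth: int = 16,
                     seed: int = 0) -> SpectralDecoloringRegressor:
    """Train the learned-decoloring regressor on a simulated training set."""
    if ts.spectra.shape[0] < 1000:
        raise ValueError("need at least 1000 training samples")
    model = SpectralDecoloringRegressor(max_depth=max_depth, random_state=seed)
    return model.fit_training_set(ts)


def predict_so2(model: SpectralDecoloringRegressor, spectra) -> np.ndarray:
    """Clipped sO2 predictions for spectra on the training grid."""
    return model.predict(spectra)


def severinghaus(po2) -> np.ndarray | float:
    """Blood sO2 from oxygen partial pressure (mmHg), Severinghaus curve.

    sO2 = 1 / (23400 / (pO2^3 + 150 pO2) + 1); the pO2 = 0 limit is 0.
    """
    p = np.asarray(po2, dtype=float)
    if np.any(p < 0):
        raise ValueError("pO2 must be non-negative")
    with np.errstate(divide="ignore"):
        s = 1.0 / (23400.0 / (p**3 + 150.0 * p) + 1.0)
    s = np.where(p == 0, 0.0, s)
    return float(s) if np.isscalar(po2) or np.ndim(po2) == 0 else s
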