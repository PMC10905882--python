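"""Target-mosquito detection: a Gaussian density gate over lab features.

The field system must first decide whether a recording is a target mosquito
(*Aedes*/*Culex*) at all before genus × sex classification applies.  The
gate fits a single multivariate Gaussian — sample mean and (ridge-
regularized) covariance — to the laboratory target-mosquito features; a new
recording's features are scored by the fitted log probability density and
the recording is called TARGET if and only if the value is at or above a
threshold.  The threshold is calibrated to maximize event-level balanced
accuracy on a labeled stream (in the field campaign this role is played by
previously collected trials scored against manual counts).

Because the raw feature space is high-dimensional relative to the covariance
that must stay well-conditioned, features are first standardized and reduced
to their leading principal components (default 8) before density fitting.
All density arithmetic is done in log space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy import linalg
from sklearn.decomposition import PCA

__all__ = [
    "FeatureProjector",
    "DensityModel",
    "DetectionThreshold",
    "fit_density",
    "log_density",
    "mahalanobis",
    "classify_target",
    "calibrate_threshold",
    "save_density",
    "load_density",
]


@dataclass
class FeatureProjector:
    """Standardization + PCA applied before density fitting.

    Fitted on laboratory target features only; field features go through the
    same frozen transform.
    """

    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray  # (n_components, n_features)

    @classmethod
    def fit(cls, X: np.ndarray, n_components: int = 8) -> "FeatureProjector":
        X = np.asarray(X, float)
        if len(X) < 2:
            raise ValueError("need at least 2 rows")
        mean = X.mean(axis=0)
        scale = X.std(axis=0, ddof=1)
        scale[scale == 0] = 1.0
        Z = (X - mean) / scale
        n_components = min(n_components, Z.shape[1], len(Z) - 1)
        pca = PCA(n_components=n_components, svd_solver="full")
        pca.fit(Z)
        return cls(mean=mean, scale=scale, components=pca.components_)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        return ((X - self.mean) / self.scale) @ self.components.T


@dataclass
class DensityModel:
    """Multivariate normal fitted to target-mosquito features."""

    mean: np.ndarray
    covariance: np.ndarray
    ridge: float
    _chol: np.ndarray = None  # lower Cholesky factor of regularized covariance
    log_norm_const: float = 0.0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, float)
        self.covariance = np.asarray(self.covariance, float)
        d = len(self.mean)
        if self.covariance.shape != (d, d):
            raise ValueError("covariance shape mismatch")
        reg = self.covariance + self.ridge * np.eye(d)
        self._chol = linalg.cholesky(reg, lower=True)
        # log det(2*pi*Sigma) = d*log(2*pi) + 2*sum(log(diag(L)))
        self.log_norm_const = d * np.log(2.0 * np.pi) + 2.0 * np.sum(
            np.log(np.diag(self._chol))
        )

    @property
    def dim(self) -> int:
        return len(self.mean)


@dataclass(frozen=True)
class DetectionThreshold:
    """Log-density cut: TARGET iff log density >= value."""

    value: float
    calibration_ba: Optional[float] = None  # % on the calibration stream

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError("threshold must be finite")


def fit_density(X: np.ndarray, ridge: Optional[float] = None) -> DensityModel:
    """Sample mean and ridge-regularized sample covariance of ``X``.

    The default ridge is 1e-6 × the mean diagonal variance — enough to keep
    the Cholesky factorization positive definite for collinear features
    without materially biasing the density.
    """
    X = np.atleast_2d(np.asarray(X, float))
    n, d = X.shape
    if n < 2:
        raise ValueError("need at least 2 rows to fit a density")
    mean = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1).reshape(d, d)
    if ridge is None:
        mean_diag = float(np.trace(cov)) / d
        ridge = 1e-6 * mean_diag if mean_diag > 0 else 1e-12
    if n < d + 1 and ridge <= 0:
        raise ValueError("rank-deficient covariance requires ridge > 0")
    return DensityModel(mean=mean, covariance=cov, ridge=float(ridge))


def log_density(model: DensityModel, x: np.ndarray) -> Union[float, np.ndarray]:
    """Exact multivariate normal log density.

    −½[(x−μ)ᵀΣ⁻¹(x−μ) + log det(2πΣ)], solved through the Cholesky factor of
    the regularized covariance.  Accepts a single vector or a matrix of rows.
    """
    x = np.asarray(x, float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.dim:
        raise ValueError(f"expected dimension {model.dim}, got {X.shape[1]}")
    diff = X - model.mean
    z = linalg.solve_triangular(model._chol, diff.T, lower=True)
    maha_sq = np.sum(z * z, axis=0)
    out = -0.5 * (maha_sq + model.log_norm_const)
    return float(out[0]) if single else out


def mahalanobis(model: DensityModel, x: np.ndarray) -> Union[float, np.ndarray]:
    """Mahalanobis distance from the fitted mean (regularized covariance)."""
    x = np.asarray(x, float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    diff = X - model.mean
    z = linalg.solve_triangular(model._chol, diff.T, lower=True)
    d = np.sqrt(np.sum(z * z, axis=0))
    return float(d[0]) if single else d


def classify_target(
    model: DensityModel, threshold: DetectionThreshold, x: np.ndarray
) -> Union[bool, np.ndarray]:
    """TARGET (True) iff the log density is >= the threshold (inclusive)."""
    ld = log_density(model, x)
    return ld >= threshold.value


def _event_ba(is_target: np.ndarray, called_target: np.ndarray) -> float:
    se = called_target[is_target].mean()
    sp = (~called_target[~is_target]).mean()
    return 100.0 * (se + sp) / 2.0


def calibrate_threshold(
    model: DensityModel, X: np.ndarray, is_target: np.ndarray
) -> DetectionThreshold:
    """Choose the log-density cut maximizing event-level balanced accuracy.

    Scans every observed log density (each is the lowest threshold that
    still admits that event) plus a strict sentinel above the maximum that
    rejects everything.  Ties break toward the higher (stricter) threshold.
    """
    is_target = np.asarray(is_target, bool)
    if is_target.all() or (~is_target).all():
        raise ValueError("calibration set must contain both labels")
    ld = np.asarray(log_density(model, X), float)
    candidates = np.unique(ld)
    # sentinel above max: rejects all events (BA = 50%)
    candidates = np.append(candidates, candidates[-1] + 1.0)
    best_thr, best_ba = None, -np.inf
    for thr in candidates:  # ascending: later (stricter) wins ties
        ba = _event_ba(is_target, ld >= thr)
        if ba >= best_ba:
            best_ba, best_thr = ba, thr
    return DetectionThreshold(value=float(best_thr), calibration_ba=float(best_ba))


# ---------------------------------------------------------------------------
# Persistence: CSV matrix (mean row then covariance rows) + JSON header

def save_density(
    model: DensityModel,
    path_prefix: Union[str, Path],
    threshold: Optional[DetectionThreshold] = None,
    projector: Optional[FeatureProjector] = None,
) -> None:
    prefix = Path(path_prefix)
    mat = np.vstack([model.mean[None, :], model.covariance])
    np.savetxt(prefix.with_suffix(".csv"), mat, delimiter=",")
    header = {
        "format_version": 1,
        "dimension": model.dim,
        "ridge": model.ridge,
        "threshold": None if threshold is None else threshold.value,
        "calibration_ba": None if threshold is None else threshold.calibration_ba,
    }
    if projector is not None:
        header["projector"] = {
            "mean": projector.mean.tolist(),
            "scale": projector.scale.tolist(),
            "components": projector.components.tolist(),
        }
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump(header, fh, indent=2)


def load_density(
    path_prefix: Union[str, Path],
) -> tuple[DensityModel, Optional[DetectionThreshold], Optional[FeatureProjector]]:
    prefix = Path(path_prefix)
    with open(prefix.with_suffix(".json")) as fh:
        header = json.load(fh)
    mat = np.loadtxt(prefix.with_suffix(".csv"), delimiter=",", ndmin=2)
    model = DensityModel(
        mean=mat[0], covariance=mat[1:], ridge=float(header["ridge"])
    )
    thr = None
    if header.get("threshold") is not None:
        thr = DetectionThreshold(
            value=float(header["threshold"]),
            calibration_ba=header.get("calibration_ba"),
        )
    proj = None
    if "projector" in header:
        p = header["projector"]
        proj = FeatureProjector(
            mean=np.array(p["mean"]),
            scale=np.array(p["scale"]),
            components=np.array(p["components"]),
        )
    return model, thr, proj
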