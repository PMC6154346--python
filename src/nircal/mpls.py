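"""Modified partial least squares (single-response) regression.

``mode="pls1"`` is standard NIPALS PLS1 on centred data.  ``mode="mpls"``
is the Shenk-Westerhaus modification: after each latent factor is extracted
and deflated, the spectral residual columns and the reference residuals are
standardised (divided by their current standard deviations) before the next
factor is extracted.  All scalings are composed into the accumulated
coefficient vector, so prediction is a single dot product per factor count
and reproduces the factor-wise prediction path exactly.

No autoscaling is applied before factor 1 (centring only); residual
standardisation begins after the first factor, which is what distinguishes
the "modified" algorithm from column-autoscaled PLS.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .errors import ParameterError
from .io import SpectraSet, WavelengthGrid
from .preprocessing import MathTreatment, apply_treatment

__all__ = ["MPLSRegression", "MplsModel", "fit_mpls", "predict", "loading_spectrum",
           "save_model", "load_model"]

#: residual-SD divisors are floored at this fraction of the largest column SD
SD_FLOOR_FRACTION = 1e-12


class MPLSRegression(RegressorMixin, BaseEstimator):
    """Single-response PLS with optional Shenk-Westerhaus residual scaling.

    Parameters
    ----------
    n_factors : int, default 16
        Maximum number of latent factors to extract.  Truncated with a
        warning if the residual rank is exhausted first.
    mode : {"mpls", "pls1"}, default "mpls"
        "pls1" = classical NIPALS PLS1; "mpls" = residual standardisation
        after each factor.

    Attributes
    ----------
    x_mean_, y_mean_ : calibration means used for centring.
    weights_, loadings_ : (n_factors_, p) NIPALS weight and loading vectors
        (in the residual space of their factor).
    y_loadings_ : (n_factors_,) y-loading scalars.
    x_scales_, y_scales_ : per-factor residual SD divisors (ones in pls1).
    coef_path_ : (n_factors_, p) accumulated coefficients for k = 1..K.
    intercept_path_ : (n_factors_,) matching intercepts.
    n_factors_ : number of factors actually extracted.
    """

    def __init__(self, n_factors: int = 16, mode: str = "mpls"):
        self.n_factors = n_factors
        self.mode = mode

    def fit(self, X, y):
        if self.mode not in ("mpls", "pls1"):
            raise ParameterError(f"unknown mode {self.mode!r}")
        X, y = check_X_y(X, y, y_numeric=True)
        n, p = X.shape
        if np.std(y) == 0:
            raise ParameterError("reference values are constant; nothing to fit")
        K = int(self.n_factors)
        if K < 1:
            raise ParameterError("n_factors must be >= 1")
        if K > max(1, n // 2):
            K = max(1, n // 2)
            warnings.warn(
                f"n_factors reduced to {K} (need >= 2 samples per factor)",
                stacklevel=2,
            )

        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xc = X - self.x_mean_
        yc = y - self.y_mean_

        W = np.zeros((K, p))
        P = np.zeros((K, p))
        Q = np.zeros(K)
        Dx = np.ones((K, p))
        Dy = np.ones(K)
        coef_path = np.zeros((K, p))

        A = np.eye(p)          # maps original centred x -> current residual space
        S = 1.0                # product of y-scales divided out so far
        b = np.zeros(p)
        y_norm0 = float(np.linalg.norm(yc))
        k_done = 0
        for k in range(K):
            wv = Xc.T @ yc
            wn = np.linalg.norm(wv)
            if wn <= 1e-12 * max(y_norm0, 1.0) or not np.isfinite(wn):
                warnings.warn(
                    f"residual rank exhausted after {k_done} factors", stacklevel=2
                )
                break
            wv /= wn
            tt = Xc @ wv
            tt2 = float(tt @ tt)
            if tt2 <= 1e-24:
                warnings.warn(
                    f"residual rank exhausted after {k_done} factors", stacklevel=2
                )
                break
            pv = Xc.T @ tt / tt2
            qk = float(yc @ tt) / tt2

            r = A.T @ wv                       # factor-k weight in original coords
            b = b + S * qk * r
            coef_path[k] = b
            W[k], P[k], Q[k] = wv, pv, qk

            Xc = Xc - np.outer(tt, pv)
            yc = yc - tt * qk
            A = A - np.outer(pv, r)
            if self.mode == "mpls":
                d = Xc.std(axis=0, ddof=1) if n > 1 else np.zeros(p)
                floor = SD_FLOOR_FRACTION * max(float(d.max()), 1.0)
                d = np.where(d > floor, d, 1.0)
                sy = float(np.std(yc, ddof=1)) if n > 1 else 0.0
                if sy <= SD_FLOOR_FRACTION * max(abs(self.y_mean_), 1.0):
                    sy = 1.0
                Xc = Xc / d
                yc = yc / sy
                A = A / d[:, None]
                S = S * sy
                Dx[k], Dy[k] = d, sy
            k_done = k + 1

        if k_done == 0:
            raise ParameterError("could not extract any factor (X'y is null)")
        self.n_factors_ = k_done
        self.weights_ = W[:k_done]
        self.loadings_ = P[:k_done]
        self.y_loadings_ = Q[:k_done]
        self.x_scales_ = Dx[:k_done]
        self.y_scales_ = Dy[:k_done]
        self.coef_path_ = coef_path[:k_done]
        self.intercept_path_ = self.y_mean_ - self.coef_path_ @ self.x_mean_
        self.coef_ = self.coef_path_[-1]
        self.intercept_ = float(self.intercept_path_[-1])
        self.n_features_in_ = p
        return self

    def predict(self, X, k: int | None = None):
        check_is_fitted(self, "coef_path_")
        X = check_array(X)
        k = self.n_factors_ if k is None else int(k)
        if not 1 <= k <= self.n_factors_:
            raise ParameterError(f"k must be in [1, {self.n_factors_}]")
        return X @ self.coef_path_[k - 1] + self.intercept_path_[k - 1]

    def predict_path(self, X):
        """Predictions for every factor count: shape (n_samples, n_factors_)."""
        check_is_fitted(self, "coef_path_")
        X = check_array(X)
        return X @ self.coef_path_.T + self.intercept_path_


@dataclass
class MplsModel:
    """A fitted calibration: treatment + MPLS estimator + metadata."""

    estimator: MPLSRegression
    treatment: MathTreatment
    analyte: tuple[str, str]
    grid: WavelengthGrid
    column_mask: np.ndarray

    @property
    def n_factors(self) -> int:
        return self.estimator.n_factors_

    @property
    def mode(self) -> str:
        return self.estimator.mode


def _masked(s: SpectraSet) -> np.ndarray:
    X = s.absorbance.copy()
    X[:, ~s.column_mask] = 0.0
    return X


def fit_mpls(
    spectra: SpectraSet,
    y,
    treatment: MathTreatment | None = None,
    max_factors: int = 16,
    mode: str = "mpls",
    analyte: tuple[str, str] = ("", ""),
) -> MplsModel:
    """Apply a math treatment and fit an MPLS calibration for one analyte.

    ``spectra`` are raw log(1/R); the treatment is stored on the model so
    :func:`predict` can apply it to new raw spectra.
    """
    t = treatment if treatment is not None else MathTreatment()
    pre = apply_treatment(spectra, t)
    est = MPLSRegression(n_factors=max_factors, mode=mode)
    est.fit(_masked(pre), np.asarray(y, dtype=float))
    # masked channels must carry zero coefficient
    est.coef_path_[:, ~pre.column_mask] = 0.0
    est.coef_ = est.coef_path_[-1]
    return MplsModel(est, t, tuple(analyte), spectra.grid, pre.column_mask.copy())


def predict(m: MplsModel, spectra: SpectraSet, k: int | None = None) -> np.ndarray:
    """Predict concentrations from raw spectra using a fitted calibration."""
    if (spectra.grid.start_nm, spectra.grid.step_nm, spectra.grid.n_points) != (
        m.grid.start_nm, m.grid.step_nm, m.grid.n_points,
    ):
        raise ParameterError("spectra grid does not match the calibration grid")
    pre = apply_treatment(spectra, m.treatment)
    X = pre.absorbance.copy()
    X[:, ~m.column_mask] = 0.0
    return m.estimator.predict(X, k=k)


def loading_spectrum(m: MplsModel, factor: int, kind: str = "loading") -> np.ndarray:
    """Loading (or weight) vector of one factor over the wavelength grid.

    Sign-normalised so the largest-magnitude element is positive; a loading
    and its negation describe the same model.
    """
    if not 1 <= factor <= m.n_factors:
        raise ParameterError(f"factor must be in [1, {m.n_factors}]")
    if kind == "loading":
        v = m.estimator.loadings_[factor - 1]
    elif kind == "weight":
        v = m.estimator.weights_[factor - 1]
    else:
        raise ParameterError("kind must be 'loading' or 'weight'")
    v = v.copy()
    i = int(np.argmax(np.abs(v)))
    if v[i] < 0:
        v = -v
    return v


# ---------------------------------------------------------------------------
# serialization: structured text (JSON) with embedded arrays

def save_model(m: MplsModel, path) -> None:
    est = m.estimator
    doc = {
        "format": "nircal-model-1",
        "analyte": list(m.analyte),
        "mode": est.mode,
        "treatment": {
            "derivative_order": m.treatment.derivative_order,
            "gap": m.treatment.gap,
            "smooth1": m.treatment.smooth1,
            "smooth2": m.treatment.smooth2,
            "scatter": m.treatment.scatter,
        },
        "grid": {
            "start_nm": m.grid.start_nm,
            "step_nm": m.grid.step_nm,
            "n_points": m.grid.n_points,
        },
        "n_factors": est.n_factors_,
        "x_mean": est.x_mean_.tolist(),
        "y_mean": est.y_mean_,
        "weights": est.weights_.tolist(),
        "loadings": est.loadings_.tolist(),
        "y_loadings": est.y_loadings_.tolist(),
        "x_scales": est.x_scales_.tolist(),
        "y_scales": est.y_scales_.tolist(),
        "coef_path": est.coef_path_.tolist(),
        "intercept_path": est.intercept_path_.tolist(),
        "column_mask": m.column_mask.astype(int).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> MplsModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "nircal-model-1":
        raise ParameterError(f"{path}: not a nircal model file")
    est = MPLSRegression(n_factors=doc["n_factors"], mode=doc["mode"])
    est.x_mean_ = np.array(doc["x_mean"])
    est.y_mean_ = float(doc["y_mean"])
    est.weights_ = np.array(doc["weights"])
    est.loadings_ = np.array(doc["loadings"])
    est.y_loadings_ = np.array(doc["y_loadings"])
    est.x_scales_ = np.array(doc["x_scales"])
    est.y_scales_ = np.array(doc["y_scales"])
    est.coef_path_ = np.array(doc["coef_path"])
    est.intercept_path_ = np.array(doc["intercept_path"])
    est.coef_ = est.coef_path_[-1]
    est.intercept_ = float(est.intercept_path_[-1])
    est.n_factors_ = int(doc["n_factors"])
    est.n_features_in_ = est.coef_path_.shape[1]
    t = MathTreatment(**doc["treatment"])
    grid = WavelengthGrid(**doc["grid"])
    mask = np.array(doc["column_mask"], dtype=bool)
    return MplsModel(est, t, tuple(doc["analyte"]), grid, mask)
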