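"""Spectral pre-treatments: SNV, detrend and gap-segment derivatives.

A pre-treatment is written as the four-number tuple
``(derivative_order, gap, smooth1, smooth2)`` plus a scatter-correction
mode.  Tuple units are data points (2 nm each on the standard grid).  The
identity treatment is ``(0,0,1,1)`` with scatter ``none``.

The gap-segment derivative follows the Norris convention: the spectrum is
boxcar-smoothed with window ``smooth1``, segment means separated by ``gap``
points are differenced (first order) or second-differenced (second order),
and the result is boxcar-smoothed again with window ``smooth2``.  Smoothing
windows are forced odd (even inputs are rounded up) to keep them centred.
Edge channels where the full window does not fit are filled with the
nearest valid value and flagged False in the output column mask, so the
grid length is preserved; masked channels are excluded from model fitting.

Scatter correction is always applied before derivation (SNV first, then
detrend when both are requested).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import uniform_filter1d
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array

from .errors import DegenerateSpectrumError, ParameterError
from .io import SpectraSet

__all__ = [
    "MathTreatment",
    "PAPER_TREATMENTS",
    "SNV",
    "Detrend",
    "GapSegmentDerivative",
    "snv",
    "detrend",
    "gap_segment_derivative",
    "apply_treatment",
]

_SCATTER_MODES = ("none", "snv", "dt", "snv-dt")


@dataclass(frozen=True)
class MathTreatment:
    """The four-number math-treatment tuple plus scatter-correction mode."""

    derivative_order: int = 0
    gap: int = 0
    smooth1: int = 1
    smooth2: int = 1
    scatter: str = "none"

    def __post_init__(self) -> None:
        if self.derivative_order not in (0, 1, 2):
            raise ParameterError("derivative_order must be 0, 1 or 2")
        if (self.derivative_order == 0) != (self.gap == 0):
            raise ParameterError("derivative_order 0 if and only if gap 0")
        if self.gap < 0:
            raise ParameterError("gap must be non-negative")
        if self.smooth1 < 1 or self.smooth2 < 1:
            raise ParameterError("smooth widths must be >= 1")
        if self.scatter not in _SCATTER_MODES:
            raise ParameterError(f"scatter must be one of {_SCATTER_MODES}")

    @classmethod
    def from_string(cls, tuple_str: str, scatter: str = "none") -> "MathTreatment":
        """Parse ``"d,g,s1,s2"`` (e.g. ``"2,5,5,2"``)."""
        parts = [int(x) for x in tuple_str.replace(" ", "").split(",")]
        if len(parts) != 4:
            raise ParameterError(f"treatment string needs 4 integers: {tuple_str!r}")
        return cls(parts[0], parts[1], parts[2], parts[3], scatter)

    def __str__(self) -> str:
        s = f"{self.derivative_order},{self.gap},{self.smooth1},{self.smooth2}"
        return s if self.scatter == "none" else f"{s} {self.scatter}"

    def with_scatter(self, scatter: str) -> "MathTreatment":
        return replace(self, scatter=scatter)

    @property
    def is_identity(self) -> bool:
        return self.derivative_order == 0 and self.scatter == "none"


#: The five treatment tuples used throughout, with SNV-DT scatter correction.
PAPER_TREATMENTS: tuple[MathTreatment, ...] = tuple(
    MathTreatment(*t, scatter="snv-dt")
    for t in [(0, 0, 1, 1), (1, 4, 4, 1), (1, 10, 10, 1), (2, 5, 5, 2), (2, 20, 20, 2)]
)


def _odd(width: int) -> int:
    return width if width % 2 == 1 else width + 1


# ---------------------------------------------------------------------------
# array-level operators (rows = spectra)

def snv_array(X: np.ndarray, sample_ids=None) -> np.ndarray:
    """Standard normal variate: per-row standardisation (n-1 denominator)."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    flat = np.nonzero(sd.ravel() == 0)[0]
    if flat.size:
        who = sample_ids[flat[0]] if sample_ids is not None else f"row {flat[0]}"
        raise DegenerateSpectrumError(f"constant spectrum has no SNV: {who}")
    return (X - mu) / sd


def detrend_array(X: np.ndarray, wavelengths: np.ndarray, degree: int = 2) -> np.ndarray:
    """Residual from a per-row least-squares polynomial in wavelength."""
    X = np.asarray(X, dtype=float)
    if degree >= X.shape[1]:
        raise ParameterError("detrend degree must be < number of channels")
    # orthonormal polynomial basis on a scaled axis for conditioning
    lam = np.asarray(wavelengths, dtype=float)
    t = (lam - lam.mean()) / (lam.max() - lam.min())
    V = np.vander(t, degree + 1, increasing=True)
    Q, _ = np.linalg.qr(V)
    return X - (X @ Q) @ Q.T


def gap_segment_array(
    X: np.ndarray, order: int, gap: int, smooth1: int, smooth2: int
) -> tuple[np.ndarray, np.ndarray]:
    """Norris gap-segment derivative; returns (derivative, valid-channel mask)."""
    X = np.asarray(X, dtype=float)
    if order not in (1, 2):
        raise ParameterError("derivative order must be 1 or 2 here")
    n = X.shape[1]
    w1, w2 = _odd(smooth1), _odd(smooth2)
    h1, h2 = w1 // 2, w2 // 2
    half = h1 + gap + h2
    if 2 * half >= n:
        raise ParameterError(
            f"treatment window ({2 * half + 1} points) exceeds grid ({n} points)"
        )
    xb = uniform_filter1d(X, size=w1, axis=1, mode="nearest")
    d = np.empty_like(xb)
    lo, hi = h1 + gap, n - 1 - h1 - gap  # channels where both segments fit
    idx = np.arange(lo, hi + 1)
    if order == 1:
        d[:, idx] = xb[:, idx + gap] - xb[:, idx - gap]
    else:
        d[:, idx] = xb[:, idx - gap] - 2.0 * xb[:, idx] + xb[:, idx + gap]
    d[:, :lo] = d[:, [lo]]
    d[:, hi + 1:] = d[:, [hi]]
    out = uniform_filter1d(d, size=w2, axis=1, mode="nearest")
    mask = np.zeros(n, dtype=bool)
    mask[half: n - half] = True
    return out, mask


# ---------------------------------------------------------------------------
# scikit-learn transformers

class SNV(TransformerMixin, BaseEstimator):
    """Row-wise standard normal variate transform (stateless)."""

    def fit(self, X, y=None):
        check_array(X)
        return self

    def transform(self, X):
        return snv_array(check_array(X))


class Detrend(TransformerMixin, BaseEstimator):
    """Remove a per-row polynomial baseline in wavelength.

    Parameters
    ----------
    degree : int, default 2
        Polynomial degree; 2 is the conventional SNV-DT detrend.
    wavelengths : array-like or None
        Wavelength axis; defaults to channel index, which spans the same
        polynomial space on a uniform grid.
    """

    def __init__(self, degree: int = 2, wavelengths=None):
        self.degree = degree
        self.wavelengths = wavelengths

    def fit(self, X, y=None):
        check_array(X)
        return self

    def transform(self, X):
        X = check_array(X)
        wl = np.arange(X.shape[1]) if self.wavelengths is None else self.wavelengths
        return detrend_array(X, np.asarray(wl, dtype=float), self.degree)


class GapSegmentDerivative(TransformerMixin, BaseEstimator):
    """Norris gap-segment derivative filter.

    After ``transform`` the attribute ``valid_mask_`` flags channels whose
    full filter window fit inside the grid.
    """

    def __init__(self, order: int = 2, gap: int = 5, smooth1: int = 5, smooth2: int = 2):
        self.order = order
        self.gap = gap
        self.smooth1 = smooth1
        self.smooth2 = smooth2

    def fit(self, X, y=None):
        check_array(X)
        return self

    def transform(self, X):
        out, mask = gap_segment_array(
            check_array(X), self.order, self.gap, self.smooth1, self.smooth2
        )
        self.valid_mask_ = mask
        return out


# ---------------------------------------------------------------------------
# SpectraSet-level operations

def snv(s: SpectraSet) -> SpectraSet:
    return s.copy_with(snv_array(s.absorbance, s.sample_ids))


def detrend(s: SpectraSet, degree: int = 2) -> SpectraSet:
    return s.copy_with(detrend_array(s.absorbance, s.grid.wavelengths, degree))


def gap_segment_derivative(s: SpectraSet, t: MathTreatment) -> SpectraSet:
    out, mask = gap_segment_array(s.absorbance, t.derivative_order, t.gap, t.smooth1, t.smooth2)
    return s.copy_with(out, s.column_mask & mask)


def apply_treatment(s: SpectraSet, t: MathTreatment) -> SpectraSet:
    """Scatter correction first (SNV then DT for snv-dt), then derivative."""
    out = s
    if t.scatter in ("snv", "snv-dt"):
        out = snv(out)
    if t.scatter in ("dt", "snv-dt"):
        out = detrend(out)
    if t.derivative_order > 0:
        out = gap_segment_derivative(out, t)
    return out
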