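"""Cross-validated factor selection and calibration/validation statistics.

Conventions (WinISI-style):

* ``SEP``    root mean squared prediction error with n-1 denominator,
* ``SEP(C)`` the same after subtracting the mean residual (bias),
* ``RPD``    SD of the validation reference values / SEP(C),
* ``RER``    reference range / SEP(C),
* ``R^2``    squared Pearson correlation of predictions vs reference
             (not 1 - SSE/SST; the difference is second order).

An ``N - K - 1`` error denominator (K = model factors) is available via
``denominator="n-k-1"`` for the prediction error; the default matches the
printed-table arithmetic, where RPD = SD / SEP(C) exactly.

Quality-classification bands (right-closed, so an edge value lands in the
lower band):

* R^2:  <0.26 very-low | 0.26-0.50 low | 0.50-0.65 discriminate-high-low |
        0.65-0.82 rough-prediction | 0.82-0.90 good | >0.90 excellent
* RPD:  <1.5 unusable | 1.5-2.5 screening | 2.5-3 acceptable | >3 excellent
* RER:  >=10 good-precision, else screening
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from math import inf, isnan, nan

import numpy as np
import pandas as pd
from scipy import stats

from .center import population_structure
from .errors import ParameterError
from .io import ReferenceTable, SpectraSet
from .mpls import MPLSRegression, MplsModel, predict as mpls_predict
from .preprocessing import MathTreatment, apply_treatment

__all__ = [
    "ValidationReport", "CrossValidationResult", "cross_validate",
    "external_validation", "report_from_pairs", "classify",
    "r2_class", "rpd_class", "rer_class", "pearson_matrix",
]


@dataclass
class ValidationReport:
    """All calibration/validation statistics for one analyte equation."""

    analyte: tuple[str, str] = ("", "")
    N: int = 0
    K: int = 0
    mean: float = nan
    SD: float = nan
    range_low: float = nan
    range_high: float = nan
    bias: float = nan
    SEC: float = nan
    SECV: float = nan
    SEP: float = nan
    SEP_C: float = nan
    R2C: float = nan
    R2CV: float = nan
    R2VAL: float = nan
    RPD: float = nan
    RER: float = nan
    r2_class: str = ""
    rpd_class: str = ""
    rer_class: str = ""
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["analyte"], d["unit"] = self.analyte
        return d


# ---------------------------------------------------------------------------
# classification bands

def r2_class(r2: float) -> str:
    if isnan(r2):
        return ""
    if r2 < 0.26:
        return "very-low"
    if r2 < 0.50:
        return "low"
    if r2 < 0.65:
        return "discriminate-high-low"
    if r2 < 0.82:
        return "rough-prediction"
    if r2 <= 0.90:
        return "good"
    return "excellent"


def rpd_class(rpd: float) -> str:
    if isnan(rpd):
        return ""
    if rpd < 1.5:
        return "unusable"
    if rpd <= 2.5:
        return "screening"
    if rpd <= 3.0:
        return "acceptable"
    return "excellent"


def rer_class(rer: float) -> str:
    if isnan(rer):
        return ""
    return "good-precision" if rer >= 10.0 else "screening"


def classify(report: ValidationReport) -> ValidationReport:
    """Fill the categorical quality labels from R2VAL, RPD and RER."""
    report.r2_class = r2_class(report.R2VAL)
    report.rpd_class = rpd_class(report.RPD)
    report.rer_class = rer_class(report.RER)
    return report


# ---------------------------------------------------------------------------
# statistics on (reference, predicted) pairs

def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    if np.std(yhat) == 0 or np.std(y) == 0:
        return nan
    return float(np.corrcoef(y, yhat)[0, 1] ** 2)


def report_from_pairs(
    y,
    yhat,
    analyte: tuple[str, str] = ("", ""),
    n_factors: int = 0,
    denominator: str = "n-1",
) -> ValidationReport:
    """External-validation statistics from reference/predicted value pairs.

    ``denominator="n-k-1"`` uses N - K - 1 in the prediction-error root
    (K = ``n_factors``) instead of the default N - 1.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    n = y.size
    if n < 3:
        raise ParameterError("validation statistics need at least 3 samples")
    if yhat.shape != y.shape:
        raise ParameterError("reference and predicted lengths differ")
    sd = float(np.std(y, ddof=1))
    if sd == 0:
        raise ParameterError("validation reference values are constant")
    if denominator == "n-1":
        dof = n - 1
    elif denominator == "n-k-1":
        dof = n - n_factors - 1
        if dof < 1:
            raise ParameterError("N - K - 1 < 1; too few validation samples")
    else:
        raise ParameterError("denominator must be 'n-1' or 'n-k-1'")

    e = yhat - y
    bias = float(e.mean())
    sep = float(np.sqrt(np.sum(e ** 2) / dof))
    sep_c = float(np.sqrt(np.sum((e - bias) ** 2) / dof))
    rng = float(y.max() - y.min())
    report = ValidationReport(
        analyte=tuple(analyte),
        N=n,
        K=n_factors,
        mean=float(y.mean()),
        SD=sd,
        range_low=float(y.min()),
        range_high=float(y.max()),
        bias=bias,
        SEP=sep,
        SEP_C=sep_c,
        R2VAL=1.0 if np.allclose(yhat, y) else _r2(y, yhat),
        RPD=sd / sep_c if sep_c > 0 else inf,
        RER=rng / sep_c if sep_c > 0 else inf,
        extras={"denominator": denominator},
    )
    return classify(report)


def external_validation(
    m: MplsModel,
    X_val: SpectraSet,
    y_val,
    k: int | None = None,
    denominator: str = "n-1",
) -> ValidationReport:
    """Predict an external validation set and compute its statistics."""
    k = m.n_factors if k is None else k
    yhat = mpls_predict(m, X_val, k=k)
    return report_from_pairs(
        np.asarray(y_val, dtype=float), yhat,
        analyte=m.analyte, n_factors=k, denominator=denominator,
    )


# ---------------------------------------------------------------------------
# cross-validation

@dataclass
class CrossValidationResult:
    k_best: int
    SECV: float
    R2CV: float
    secv_by_k: np.ndarray
    folds: np.ndarray
    predictions: np.ndarray  # pooled held-out predictions at k_best


def _fold_assignment(gh: np.ndarray, ids: list[str], groups: int, seed=None) -> np.ndarray:
    """Deterministic round-robin over GH rank; seeded shuffle if asked."""
    n = len(ids)
    order = sorted(range(n), key=lambda i: (gh[i], ids[i]))
    folds = np.empty(n, dtype=int)
    if seed is None:
        for pos, i in enumerate(order):
            folds[i] = pos % groups
    else:
        rng = np.random.default_rng(seed)
        folds[:] = rng.permutation(np.arange(n) % groups)
    return folds


def cross_validate(
    X: SpectraSet,
    y,
    t: MathTreatment,
    groups: int = 4,
    max_factors: int = 16,
    mode: str = "mpls",
    seed=None,
) -> CrossValidationResult:
    """Grouped cross-validation of the factor count for one treatment.

    Folds are assigned round-robin over the GH rank of the pre-treated
    spectra (spectrally balanced and deterministic); ``groups = N`` is
    leave-one-out.  SECV(k) is the root mean of squared held-out residuals
    pooled over folds, and ``k_best`` minimises it.
    """
    y = np.asarray(y, dtype=float)
    n = X.n_samples
    if groups < 2:
        raise ParameterError("groups must be >= 2")
    if n < 2 * groups and groups != n:
        raise ParameterError("need N >= 2*groups samples (or groups == N)")
    pre = apply_treatment(X, t)
    Xa = pre.absorbance.copy()
    Xa[:, ~pre.column_mask] = 0.0
    gh = population_structure(pre).gh
    folds = _fold_assignment(gh, X.sample_ids, groups, seed)

    min_train = min(n - int((folds == g).sum()) for g in range(groups))
    k_cap = min(max_factors, max(1, min_train - 1))
    if k_cap < max_factors:
        warnings.warn(
            f"max_factors capped at {k_cap} by the smallest training fold",
            stacklevel=2,
        )
    preds = np.full((n, k_cap), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-fold factor truncation is expected
        for g in range(groups):
            test = folds == g
            if not test.any():
                continue
            est = MPLSRegression(n_factors=k_cap, mode=mode)
            est.fit(Xa[~test], y[~test])
            path = est.predict_path(Xa[test])
            preds[test, : est.n_factors_] = path
            # folds whose rank is exhausted early repeat their last prediction
            preds[test, est.n_factors_:] = path[:, [-1]]
    resid2 = (preds - y[:, None]) ** 2
    secv_by_k = np.sqrt(resid2.mean(axis=0))
    k_best = int(np.argmin(secv_by_k)) + 1
    pooled = preds[:, k_best - 1]
    return CrossValidationResult(
        k_best=k_best,
        SECV=float(secv_by_k[k_best - 1]),
        R2CV=_r2(y, pooled),
        secv_by_k=secv_by_k,
        folds=folds,
        predictions=pooled,
    )


# ---------------------------------------------------------------------------
# Pearson correlation matrix

def pearson_matrix(refs: ReferenceTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p-values (t distribution).

    Constant columns yield NaN entries (flagged via a warning).
    """
    if len(refs.sample_ids) < 3:
        raise ParameterError("Pearson matrix needs at least 3 samples")
    names = refs.names
    k = len(names)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            xi, xj = refs.values[:, i], refs.values[:, j]
            if np.std(xi) == 0 or np.std(xj) == 0:
                warnings.warn(
                    f"constant column: correlation ({names[i]}, {names[j]}) undefined",
                    stacklevel=2,
                )
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = stats.pearsonr(xi, xj)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return (
        pd.DataFrame(r, index=names, columns=names),
        pd.DataFrame(p, index=names, columns=names),
    )
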