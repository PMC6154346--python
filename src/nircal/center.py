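"""Population structuring: PCA scores, Mahalanobis GH distances and the
distance-ranked calibration/validation split.

GH is the squared Mahalanobis distance of a spectrum from the population
centre in the retained principal-component score space, divided by the
number of retained components, so the population average is ~1 regardless
of dimensionality and a fixed cutoff (3 by default) flags outliers.
Validation samples are taken as every ``every``-th sample of the GH-ranked
non-outliers (ascending), which keeps the most extreme — but still
acceptable — spectra in the calibration set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .errors import ParameterError
from .io import SpectraSet

__all__ = ["PopulationModel", "PopulationStructure", "SplitPlan",
           "population_structure", "rank_and_split"]


class PopulationModel(BaseEstimator):
    """PCA + standardised Mahalanobis distance (GH) estimator.

    Parameters
    ----------
    variance_kept : float, default 0.99
        Retain the smallest number of components explaining at least this
        fraction of the spectral variance.
    threshold : float, default 3.0
        GH cutoff above which a sample is an outlier.

    Attributes
    ----------
    n_components_ : retained component count.
    eigenvalues_ : sample variances (n-1 denominator) of the retained scores.
    scores_, gh_, outlier_ : per-training-sample results.
    """

    def __init__(self, variance_kept: float = 0.99, threshold: float = 3.0):
        self.variance_kept = variance_kept
        self.threshold = threshold

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if n < 3:
            raise ParameterError("population structure needs at least 3 samples")
        if not 0 < self.variance_kept <= 1:
            raise ParameterError("variance_kept must be in (0, 1]")
        pca = PCA(n_components=min(n - 1, p))
        scores = pca.fit_transform(X)
        evr = np.cumsum(pca.explained_variance_ratio_)
        k = int(np.searchsorted(evr, self.variance_kept - 1e-12) + 1)
        k = min(k, scores.shape[1])
        if n < k + 1:
            raise ParameterError("fewer samples than retained components + 1")
        self.pca_ = pca
        self.n_components_ = k
        self.eigenvalues_ = pca.explained_variance_[:k]
        self.scores_ = scores[:, :k]
        self.gh_ = self._gh_from_scores(self.scores_)
        self.outlier_ = self.gh_ > self.threshold
        return self

    def _gh_from_scores(self, scores: np.ndarray) -> np.ndarray:
        d2 = ((scores ** 2) / self.eigenvalues_).sum(axis=1)
        return d2 / self.n_components_

    def transform(self, X) -> np.ndarray:
        """GH distances of new spectra relative to the fitted population."""
        scores = self.pca_.transform(np.asarray(X, dtype=float))[:, : self.n_components_]
        return self._gh_from_scores(scores)


@dataclass
class PopulationStructure:
    """PCA/GH summary of a spectral population."""

    sample_ids: list[str]
    n_components: int
    scores: np.ndarray
    eigenvalues: np.ndarray
    gh: np.ndarray
    outlier: np.ndarray
    threshold: float
    rank_order: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.rank_order is None:
            # ascending GH, ties broken by sample id
            order = sorted(range(len(self.sample_ids)),
                           key=lambda i: (self.gh[i], self.sample_ids[i]))
            self.rank_order = [self.sample_ids[i] for i in order]


@dataclass
class SplitPlan:
    """Disjoint calibration / validation / outlier id sets (a partition)."""

    calibration_ids: list[str]
    validation_ids: list[str]
    outlier_ids: list[str]


def population_structure(
    s: SpectraSet, variance_kept: float = 0.99, threshold: float = 3.0
) -> PopulationStructure:
    """PCA + GH on pre-treated spectra (masked channels excluded)."""
    X = s.absorbance[:, s.column_mask]
    model = PopulationModel(variance_kept=variance_kept, threshold=threshold).fit(X)
    return PopulationStructure(
        sample_ids=list(s.sample_ids),
        n_components=model.n_components_,
        scores=model.scores_,
        eigenvalues=model.eigenvalues_,
        gh=model.gh_,
        outlier=model.outlier_,
        threshold=threshold,
    )


def rank_and_split(p: PopulationStructure, every: int = 5) -> SplitPlan:
    """Order non-outliers by ascending GH; validation = every ``every``-th rank.

    Ranks are 1-based, so validation samples sit at ranks every, 2*every, ...
    and the extreme-GH end of the ranking stays in calibration.
    """
    if every < 2:
        raise ParameterError("every must be >= 2")
    out_ids = [i for i, o in zip(p.sample_ids, p.outlier) if o]
    outset = set(out_ids)
    ranked = [i for i in p.rank_order if i not in outset]
    if every > len(ranked):
        warnings.warn(
            f"every={every} exceeds the {len(ranked)} non-outliers; "
            "validation set is empty", stacklevel=2,
        )
    val = ranked[every - 1:: every]
    valset = set(val)
    cal = [i for i in ranked if i not in valset]
    return SplitPlan(calibration_ids=cal, validation_ids=val, outlier_ids=out_ids)
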